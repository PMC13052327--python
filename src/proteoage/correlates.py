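"""Pearson correlations between protein NPX values and clinical measures.

One row per (protein, measure): pairwise-complete Pearson r with a 95%
confidence interval from the Fisher z transform, z +/- 1.96 / sqrt(n - 3).
No multiplicity correction is applied (the correlations are descriptive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NPXMatrix, ValidationError


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    from scipy import stats

    if n <= 3:
        return (-1.0, 1.0)
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate(
    matrix: NPXMatrix,
    cohort: pd.DataFrame,
    proteins: list[str],
    measures: list[str],
    groups: list[str] | None = None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of proteins vs cohort measures.

    ``groups`` restricts the samples (e.g. ``["OC", "OP"]`` for older
    participants only); the default pools every sample present in both
    the matrix and the cohort table. Cells with a constant vector are
    flagged (r undefined) rather than dropped.
    """
    samples = [s for s in matrix.sample_ids if s in cohort.index]
    if groups is not None:
        samples = [s for s in samples if cohort.loc[s, "group"] in groups]
    if not samples:
        raise ValidationError("no overlapping samples between matrix and cohort")
    missing_m = [m for m in measures if m not in cohort.columns]
    if missing_m:
        raise ValidationError(f"measures not in cohort table: {missing_m}")

    rows = []
    for protein in proteins:
        x_all = matrix.data.loc[samples, protein]
        for measure in measures:
            y_all = pd.to_numeric(cohort.loc[samples, measure], errors="coerce")
            mask = x_all.notna() & y_all.notna()
            n = int(mask.sum())
            x, y = x_all[mask].to_numpy(), y_all[mask].to_numpy()
            if n < min_pairs:
                rows.append((protein, measure, n, np.nan, np.nan, np.nan, "too_few_pairs"))
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((protein, measure, n, np.nan, np.nan, np.nan, "constant"))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            lo, hi = fisher_ci(r, n)
            rows.append((protein, measure, n, r, lo, hi, "ok"))
    return pd.DataFrame(
        rows, columns=["protein_id", "measure", "n", "r", "ci_low", "ci_high", "status"]
    )
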