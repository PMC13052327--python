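"""Pairwise differential expression with normality-gated test choice.

For each protein the two groups are first screened with the Shapiro-Wilk
test; if normality cannot be rejected a t-test (independent or paired,
according to the study design) is used, otherwise a Wilcoxon rank-sum
(unpaired) or signed-rank (paired) test. Fold changes are geometric-mean
ratios on the linear scale — since NPX is log2, this is
``2 ** (mean(a) - mean(b))``. p values are Benjamini-Hochberg corrected
across the whole panel of a comparison.

The entry point is the :class:`DifferentialExpression` model:

>>> de = DifferentialExpression(matrix, cohort, ComparisonSpec("OC", "YC"))
>>> result = de.fit()
>>> result.table.head()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUPS, NPXMatrix, ValidationError

TESTS = ("t_independent", "t_paired", "wilcoxon_ranksum", "wilcoxon_signedrank")

#: exact rank-test p values up to this sample size (without ties); the
#: normal approximation with continuity correction is used above it
_EXACT_N_MAX = 25


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison between participant groups.

    ``paired=True`` matches samples through the cohort's pair_id column
    (the OP-vs-OC design); unpaired comparisons use all samples of each
    group. ``normality_rule`` decides whether the unpaired t-test requires
    both groups to pass Shapiro-Wilk ("both", default) or just one ("any").
    """

    group_a: str
    group_b: str
    paired: bool = False
    alpha_normality: float = 0.05
    alpha_fdr: float = 0.05
    normality_rule: str = "both"

    def __post_init__(self):
        if self.group_a not in GROUPS or self.group_b not in GROUPS:
            raise ValidationError(f"groups must be in {GROUPS}")
        if self.group_a == self.group_b:
            raise ValidationError("comparison groups must be disjoint")
        if self.normality_rule not in {"both", "any"}:
            raise ValidationError("normality_rule must be 'both' or 'any'")


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    """True when Shapiro-Wilk does not reject normality at level alpha."""
    if np.ptp(x) == 0:  # constant vector: statistic undefined
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue >= alpha


def choose_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool,
    alpha_normality: float = 0.05,
    normality_rule: str = "both",
) -> str:
    """Select the test for one protein by Shapiro-Wilk screening.

    Unpaired: both groups must pass (or either, under ``normality_rule=
    'any'``) for the independent t-test; otherwise Wilcoxon rank sum.
    Paired: the within-pair differences must pass for the paired t-test;
    otherwise Wilcoxon signed rank. Constant vectors (where Shapiro-Wilk
    is undefined) route to the rank test with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired comparison requires equal-length vectors")
        if len(a) < 3:
            raise ValidationError("need at least 3 pairs")
        diff = a - b
        if np.ptp(diff) == 0:
            warnings.warn("constant paired differences; using signed-rank test",
                          stacklevel=2)
            return "wilcoxon_signedrank"
        return "t_paired" if _shapiro_ok(diff, alpha_normality) else "wilcoxon_signedrank"
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need at least 3 observations per group")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant group; using rank-sum test", stacklevel=2)
        return "wilcoxon_ranksum"
    ok_a = _shapiro_ok(a, alpha_normality)
    ok_b = _shapiro_ok(b, alpha_normality)
    ok = (ok_a and ok_b) if normality_rule == "both" else (ok_a or ok_b)
    return "t_independent" if ok else "wilcoxon_ranksum"


def _rank_method(x: np.ndarray, y: np.ndarray | None = None) -> str:
    n = max(len(x), len(y) if y is not None else 0)
    vals = np.concatenate([x, y]) if y is not None else x
    has_ties = len(np.unique(vals)) < len(vals)
    return "exact" if (n <= _EXACT_N_MAX and not has_ties) else "asymptotic"


def _test_pvalue(a: np.ndarray, b: np.ndarray, test: str) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "t_independent":
            return float(stats.ttest_ind(a, b).pvalue)
        if test == "t_paired":
            return float(stats.ttest_rel(a, b).pvalue)
        if test == "wilcoxon_ranksum":
            return float(
                stats.mannwhitneyu(
                    a, b, alternative="two-sided",
                    method=_rank_method(a, b), use_continuity=True,
                ).pvalue
            )
        if test == "wilcoxon_signedrank":
            d = a - b
            d = d[d != 0]
            if len(d) == 0:
                return 1.0
            method = "exact" if _rank_method(d) == "exact" else "approx"
            return float(
                stats.wilcoxon(d, correction=True, method=method,
                               alternative="two-sided").pvalue
            )
    raise ValueError(f"unknown test {test!r}")


def geometric_fold_change(npx_a, npx_b) -> float:
    """Linear-scale fold change: geometric mean of A over geometric mean of B.

    NPX is log2-scale, so ``fc = 2 ** (mean(npx_a) - mean(npx_b))``.
    """
    a = np.asarray(npx_a, dtype=float)
    b = np.asarray(npx_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("fold change requires non-empty groups")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("fold change requires finite values")
    return float(2.0 ** (a.mean() - b.mean()))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResults:
    """Per-protein differential-expression results for one comparison."""

    spec: ComparisonSpec
    table: pd.DataFrame  # protein_id, assay, test_used, p_raw, p_adj, ...

    @property
    def significant(self) -> pd.Series:
        return self.table.set_index("protein_id")["significant"]

    @property
    def significant_proteins(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "protein_id"])

    def summary(self) -> str:
        t = self.table
        sig = t["significant"]
        lines = [
            f"Differential expression: {self.spec.group_a} vs {self.spec.group_b}"
            f" ({'paired' if self.spec.paired else 'independent'})",
            f"  proteins tested            {len(t)}",
            f"  significant (BH p < {self.spec.alpha_fdr:g})  {int(sig.sum())}",
            f"    upregulated              {int((sig & (t['direction'] == 'up')).sum())}",
            f"    downregulated            {int((sig & (t['direction'] == 'down')).sum())}",
        ]
        counts = t["test_used"].value_counts()
        for test in TESTS:
            if test in counts:
                lines.append(f"  {test:<26} {int(counts[test])}")
        return "\n".join(lines)


class DifferentialExpression:
    """Normality-gated pairwise differential-expression model.

    Parameters
    ----------
    matrix : NPXMatrix
    cohort : DataFrame
        Validated cohort table (index = sample id).
    spec : ComparisonSpec
    """

    def __init__(self, matrix: NPXMatrix, cohort: pd.DataFrame, spec: ComparisonSpec):
        self.matrix = matrix
        self.cohort = cohort
        self.spec = spec
        self._ids_a, self._ids_b = self._resolve_samples()

    def _resolve_samples(self) -> tuple[list[str], list[str]]:
        cohort = self.cohort
        in_matrix = cohort.index.isin(self.matrix.sample_ids)
        cohort = cohort.loc[in_matrix]
        spec = self.spec
        if spec.paired:
            a_rows = cohort[(cohort["group"] == spec.group_a) & cohort["pair_id"].notna()]
            b_rows = cohort[(cohort["group"] == spec.group_b) & cohort["pair_id"].notna()]
            pairs = sorted(set(a_rows["pair_id"]) & set(b_rows["pair_id"]))
            if not pairs:
                raise ValidationError("no complete pairs for paired comparison")
            a_by_pair = a_rows.set_index("pair_id")["sample_id"]
            b_by_pair = b_rows.set_index("pair_id")["sample_id"]
            return [a_by_pair[p] for p in pairs], [b_by_pair[p] for p in pairs]
        ids_a = cohort.index[cohort["group"] == spec.group_a].tolist()
        ids_b = cohort.index[cohort["group"] == spec.group_b].tolist()
        if not ids_a or not ids_b:
            raise ValidationError(
                f"empty group in comparison {spec.group_a} vs {spec.group_b}"
            )
        return ids_a, ids_b

    def fit(self) -> DEResults:
        spec = self.spec
        A = self.matrix.data.loc[self._ids_a].to_numpy()
        B = self.matrix.data.loc[self._ids_b].to_numpy()
        proteins = self.matrix.protein_ids

        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j, protein in enumerate(proteins):
                a, b = A[:, j], B[:, j]
                test = choose_test(a, b, spec.paired, spec.alpha_normality,
                                   spec.normality_rule)
                p = _test_pvalue(a, b, test)
                fc = geometric_fold_change(a, b)
                rows.append((protein, self.matrix.assay_name(protein), test, p, fc))

        table = pd.DataFrame(
            rows, columns=["protein_id", "assay", "test_used", "p_raw", "fc_linear"]
        )
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        table["log2_fc"] = np.log2(table["fc_linear"])
        table["significant"] = table["p_adj"] < spec.alpha_fdr
        table["direction"] = np.where(table["fc_linear"] > 1, "up", "down")
        table["neg_log10_p_adj"] = -np.log10(np.maximum(table["p_adj"], 1e-300))
        return DEResults(spec, table)
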