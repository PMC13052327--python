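"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a three-group plasma-proteomic study: healthy Young
Controls (YC), Older Controls (OC), and Older Patients (OP) matched 1:1 to
the controls on age and sex. Protein effects are planted on the log2 (NPX)
scale in four classes — null, age-only, disease-only, and "both" (the
ground-truth biological Aging Proteins) — with mostly-upregulated shifts,
an optional shared OC-OP pair random effect, and a minority of proteins
carrying skewed (centred log-normal) noise so that the normality-gated test
choice downstream is exercised on both branches. Survival is generated from
group-stratified exponential baseline hazards scaled by a small planted set
of hazard proteins plus a sex effect; Young Controls are administratively
censored without events.

Every public function takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUPS, NPXMatrix, LiteratureSet, ValidationError

CLASSES = ("null", "age_only", "disease_only", "both")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: 20 Young
    Controls, 52 matched OC-OP pairs, class fractions chosen so the
    significant-set sizes resemble the reference cohort's 486/450/311
    split of 5416 assays, shifts of 1 NPX unit (a doubling on the linear
    scale), and OP baseline mortality roughly ten-fold the OC rate.
    """

    n_young: int = 20
    n_older_pairs: int = 52
    n_proteins: int = 1000
    #: proportions of {null, age_only, disease_only, both} proteins
    effect_fractions: tuple[float, float, float, float] = (0.77, 0.09, 0.083, 0.057)
    delta_age: float = 1.0  # NPX (log2) shift in OC and OP
    delta_disease: float = 1.0  # NPX shift in OP only
    frac_down_age: float = 0.20  # fraction of age shifts that are negative
    frac_down_disease: float = 0.05
    sigma_protein: float = 1.0  # residual SD, NPX units
    sigma_pair: float = 0.5  # SD of shared OC-OP pair effect
    frac_paired: float = 0.5  # fraction of proteins carrying the pair effect
    frac_skewed: float = 0.2  # fraction with centred log-normal noise
    sigma_log: float = 0.8  # log-scale SD of the skewed noise
    n_hazard_proteins: int = 2  # planted mortality proteins (subset of "both")
    beta_hazard: float = 1.0  # log hazard ratio per SD of NPX
    beta_sex: float = 0.25  # log hazard ratio, male vs female
    #: per-stratum exponential event rates (per year)
    baseline_rates: dict[str, float] = field(
        default_factory=lambda: {"OC": 0.0115, "OP": 0.115}
    )
    censor_time: float = 7.0  # administrative censoring horizon, years
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_young, self.n_older_pairs, self.n_proteins) <= 0:
            raise ValidationError("all counts must be positive")
        fr = np.asarray(self.effect_fractions, dtype=float)
        if fr.shape != (4,) or (fr < 0).any() or not math.isclose(fr.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError(
                "effect_fractions must be four non-negative proportions summing to 1"
            )
        for name in ("frac_down_age", "frac_down_disease", "frac_paired", "frac_skewed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_protein <= 0:
            raise ValidationError("sigma_protein must be positive")
        if self.n_hazard_proteins < 0:
            raise ValidationError("n_hazard_proteins must be >= 0")
        n_both = _class_counts(self.n_proteins, self.effect_fractions)[3]
        if self.n_hazard_proteins > n_both:
            raise ValidationError(
                f"n_hazard_proteins={self.n_hazard_proteins} exceeds the "
                f"{n_both} planted 'both'-class proteins"
            )


def _class_counts(n_proteins: int, fractions) -> list[int]:
    """Largest-remainder apportionment of proteins to the four classes."""
    raw = np.asarray(fractions, dtype=float) * n_proteins
    counts = np.floor(raw).astype(int)
    remainder = n_proteins - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def _centered_skew_noise(rng: np.random.Generator, size, sigma_log: float) -> np.ndarray:
    """Log-normal noise centred at 0 and rescaled to unit SD."""
    mean = math.exp(sigma_log**2 / 2)
    sd = math.sqrt((math.exp(sigma_log**2) - 1) * math.exp(sigma_log**2))
    return (rng.lognormal(0.0, sigma_log, size=size) - mean) / sd


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[NPXMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate an NPX matrix, cohort table, and ground-truth table.

    Returns
    -------
    matrix : NPXMatrix
    cohort : DataFrame
        Columns sample_id, group, pair_id, sex, survival_time, event.
    truth : DataFrame
        One row per protein: class label, planted shift signs, hazard beta.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_pairs = config.n_older_pairs
    proteins = _protein_ids(config.n_proteins)
    counts = _class_counts(config.n_proteins, config.effect_fractions)
    classes = np.repeat(CLASSES, counts)
    rng.shuffle(classes)

    # --- planted per-protein effects -------------------------------------
    has_age = np.isin(classes, ("age_only", "both"))
    has_disease = np.isin(classes, ("disease_only", "both"))
    sign_age = np.where(
        rng.random(config.n_proteins) < config.frac_down_age, -1.0, 1.0
    ) * has_age
    sign_disease = np.where(
        rng.random(config.n_proteins) < config.frac_down_disease, -1.0, 1.0
    ) * has_disease
    shift_age = sign_age * config.delta_age
    shift_disease = sign_disease * config.delta_disease

    is_paired = rng.random(config.n_proteins) < config.frac_paired
    is_skewed = rng.random(config.n_proteins) < config.frac_skewed

    both_idx = np.flatnonzero(classes == "both")
    hazard_idx = rng.choice(both_idx, size=config.n_hazard_proteins, replace=False)
    beta = np.zeros(config.n_proteins)
    beta[hazard_idx] = config.beta_hazard

    # --- sample frame ----------------------------------------------------
    yc_ids = [f"YC{i:03d}" for i in range(1, config.n_young + 1)]
    oc_ids = [f"OC{i:03d}" for i in range(1, n_pairs + 1)]
    op_ids = [f"OP{i:03d}" for i in range(1, n_pairs + 1)]
    sample_ids = yc_ids + oc_ids + op_ids
    group = np.array(["YC"] * config.n_young + ["OC"] * n_pairs + ["OP"] * n_pairs)

    # matched pairs share sex; half of each group female
    yc_sex = np.array(["F", "M"] * (config.n_young // 2 + 1))[: config.n_young]
    pair_sex = np.array(["F", "M"] * (n_pairs // 2 + 1))[:n_pairs]
    sex = np.concatenate([yc_sex, pair_sex, pair_sex])
    pair_id = np.array(
        [None] * config.n_young
        + [f"PAIR{i:03d}" for i in range(1, n_pairs + 1)] * 2,
        dtype=object,
    )

    # --- expression ------------------------------------------------------
    n_samples = len(sample_ids)
    mu = rng.normal(5.0, 2.0, size=config.n_proteins)  # per-protein baseline level
    npx = np.tile(mu, (n_samples, 1))
    older = np.isin(group, ("OC", "OP"))
    npx[older] += shift_age
    npx[group == "OP"] += shift_disease

    pair_effect = rng.normal(0.0, config.sigma_pair, size=(n_pairs, config.n_proteins))
    pair_effect[:, ~is_paired] = 0.0
    npx[config.n_young : config.n_young + n_pairs] += pair_effect
    npx[config.n_young + n_pairs :] += pair_effect

    noise = rng.normal(0.0, 1.0, size=(n_samples, config.n_proteins))
    if is_skewed.any():
        noise[:, is_skewed] = _centered_skew_noise(
            rng, (n_samples, int(is_skewed.sum())), config.sigma_log
        )
    npx += config.sigma_protein * noise

    matrix = NPXMatrix(
        pd.DataFrame(npx, index=sample_ids, columns=proteins),
        {p: f"ASSAY_{p}" for p in proteins},
    )

    # --- survival --------------------------------------------------------
    survival_time = np.full(n_samples, config.censor_time)
    event = np.zeros(n_samples, dtype=int)
    if config.n_hazard_proteins or config.beta_sex:
        hazard_cols = npx[:, hazard_idx]
        older_vals = hazard_cols[older]
        # linear predictor uses protein values standardized within the
        # older participants (the analysis population for survival)
        center = older_vals.mean(axis=0)
        scale = older_vals.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        z = (hazard_cols - center) / scale
        lp = z @ beta[hazard_idx] + config.beta_sex * (sex == "M")
    else:
        lp = np.zeros(n_samples)
    for g in ("OC", "OP"):
        mask = group == g
        rate = config.baseline_rates[g] * np.exp(lp[mask])
        t = rng.exponential(1.0 / np.maximum(rate, 1e-300))
        survival_time[mask] = np.minimum(t, config.censor_time)
        event[mask] = (t <= config.censor_time).astype(int)

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "pair_id": pair_id,
            "sex": sex,
            "survival_time": survival_time,
            "event": event,
        }
    )

    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "class": classes,
            "sign_age": sign_age,
            "sign_disease": sign_disease,
            "paired_noise": is_paired,
            "skewed_noise": is_skewed,
            "beta_hazard": beta,
        }
    )
    return matrix, cohort, truth


def simulate_clusters(
    n_proteins: int,
    k_true: int,
    separation: float,
    seed: int = 0,
    n_samples: tuple[int, int, int] = (20, 52, 52),
) -> tuple[NPXMatrix, pd.Series]:
    """Simulate proteins scattered around ``k_true`` group-trajectory profiles.

    Each cluster is a distinct mean-expression trajectory across the three
    participant groups (YC, OC, OP) — e.g. progressive upregulation, or a
    disease-only rise. Because downstream clustering standardizes every
    protein (removing level and scale), clusters are distinguishable only by
    trajectory *direction*; the prototypes are therefore placed at equally
    spaced directions in the two-dimensional group-contrast space, and
    ``separation`` scales the trajectory amplitude relative to the unit
    within-protein noise. ``separation=0`` gives a structureless matrix.
    Returns the NPX matrix and the ground-truth partition.
    """
    if k_true < 2:
        raise ValidationError("k_true must be >= 2")
    if separation < 0:
        raise ValidationError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    proteins = _protein_ids(n_proteins)
    labels = np.repeat(np.arange(k_true), -(-n_proteins // k_true))[:n_proteins]
    rng.shuffle(labels)

    sample_ids, group_of = [], []
    for g, n in zip(GROUPS, n_samples):
        sample_ids += [f"{g}{i:03d}" for i in range(1, n + 1)]
        group_of += [g] * n
    group_of = np.array(group_of)

    # orthonormal basis of the group-contrast plane (zero-mean, unit
    # per-sample variance), spanning "old vs young" and "patient vs control"
    n_tot = len(group_of)
    u1 = (group_of != "YC").astype(float)
    u1 -= u1.mean()
    u1 /= u1.std()
    u2 = (group_of == "OP").astype(float) - (group_of == "OC").astype(float)
    u2 -= u2 @ u1 / n_tot * u1
    u2 -= u2.mean()
    u2 /= u2.std()
    angles = 2 * np.pi * np.arange(k_true) / k_true
    prototypes = separation * (
        np.cos(angles)[:, None] * u1 + np.sin(angles)[:, None] * u2
    )  # clusters x samples
    npx = prototypes[labels].T + rng.normal(size=(n_tot, n_proteins))
    matrix = NPXMatrix(pd.DataFrame(npx, index=sample_ids, columns=proteins))
    return matrix, pd.Series(labels, index=proteins, name="true_cluster")


def simulate_literature_lists(
    truth: pd.DataFrame,
    coverage: float,
    decoys: int = 0,
    seed: int = 0,
) -> list[LiteratureSet]:
    """Build synthetic literature lists covering the planted protein classes.

    For each source kind (age, disease, sasp) the list contains exactly
    ``floor(coverage * K)`` of the relevant planted proteins (age: the
    age-shifted classes; disease: the disease-shifted classes; sasp: the
    "both" class), chosen uniformly without replacement, plus ``decoys``
    accessions absent from the panel.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pools = {
        "age": truth.loc[truth["class"].isin(["age_only", "both"]), "protein_id"],
        "disease": truth.loc[
            truth["class"].isin(["disease_only", "both"]), "protein_id"
        ],
        "sasp": truth.loc[truth["class"] == "both", "protein_id"],
    }
    n_panel = len(truth)
    out = []
    for kind, pool in pools.items():
        pool = sorted(pool)
        n_take = int(math.floor(coverage * len(pool)))
        members = set(rng.choice(pool, size=n_take, replace=False)) if n_take else set()
        members |= {f"Q{n_panel + 1000 + i:05d}" for i in range(decoys)}
        if not members:  # keep sets structurally valid at coverage 0
            members = {f"Q{n_panel + 999:05d}"}
        out.append(
            LiteratureSet(name=f"synthetic_{kind}", source_kind=kind,
                          members=frozenset(members))
        )
    return out
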