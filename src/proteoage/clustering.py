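"""Protein co-expression clustering with a subsampling stability assessment.

Proteins are z-scored individually across all samples, then clustered by
complete-linkage agglomerative hierarchical clustering (Euclidean by
default, Manhattan as a sensitivity analysis) with proteins as objects and
samples as features. The number of clusters is chosen at the elbow of the
merge-height scree (largest second difference), overridable. Stability is
assessed by reclustering random protein subsamples (85/90/95%) and scoring
agreement with the full-data partition by the Rand index, normalized
against a random-label baseline so that 0 is chance-level agreement and 1
is perfect reproduction. Category enrichment per cluster uses upper-tail
hypergeometric tests with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import NPXMatrix, ValidationError
from .diffexp import bh_adjust
from .intersect import CategoryAssignment

DISTANCES = {"euclidean": "euclidean", "manhattan": "cityblock"}
DEFAULT_PROPORTIONS = (0.85, 0.90, 0.95)


def zscore_proteins(matrix: NPXMatrix) -> NPXMatrix:
    """Standardize each protein to mean 0, sample-SD (n-1) 1 across samples.

    Constant proteins (SD 0) are dropped with a warning.
    """
    data = matrix.data
    sd = data.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValidationError("all proteins are constant; nothing to standardize")
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant proteins before z-scoring",
            stacklevel=2,
        )
        data = data.loc[:, ~constant]
        sd = sd[~constant]
    z = (data - data.mean(axis=0)) / sd
    return NPXMatrix(z, dict(matrix.assay_names))


def scree_select_k(merge_heights, k_max: int = 20) -> int:
    """Elbow of the merge-height scree: k with the largest second difference.

    ``merge_heights`` is the agglomeration-height sequence (ascending, as
    produced by the linkage); the scree is read on the descending sequence,
    where cutting above the (k-1)-th largest height yields k clusters.
    Degenerate (flat) screes return 2 with a warning.
    """
    h = np.sort(np.asarray(merge_heights, dtype=float))[::-1]
    if len(h) < 3:
        raise ValidationError("need at least 3 merges to read a scree")
    k_hi = min(k_max, len(h) - 1)
    second_diff = {k: h[k - 2] - 2 * h[k - 1] + h[k] for k in range(2, k_hi + 1)}
    if max(second_diff.values()) <= 1e-12:
        warnings.warn("flat merge-height scree; defaulting to k=2", stacklevel=2)
        return 2
    return max(second_diff, key=second_diff.get)


def rand_index(labels_a, labels_b) -> float:
    """Classic pair-counting Rand index between two partitions.

    The fraction of element pairs on which the partitions agree (both
    together or both apart), computed from the contingency table.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("partitions must label the same elements")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least 2 elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    ct = np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb).reshape(-1, nb)
    sum_sq = int((ct.astype(np.int64) ** 2).sum())
    sum_a = int((ct.sum(axis=1).astype(np.int64) ** 2).sum())
    sum_b = int((ct.sum(axis=0).astype(np.int64) ** 2).sum())
    # pairs together in exactly one partition (both differences are even)
    disagree = (sum_a - sum_sq) // 2 + (sum_b - sum_sq) // 2
    total = n * (n - 1) // 2
    return (total - disagree) / total


def _random_partition_like(sizes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random labelling with a fixed cluster-size profile."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng.shuffle(labels)
    return labels


@dataclass
class ClusteringResults:
    """Fitted protein clustering: labels, merge heights, chosen k."""

    distance: str
    k: int
    auto_k: int
    labels: pd.Series  # protein_id -> cluster id (1..k)
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray
    matrix: NPXMatrix  # standardized matrix the model was fitted on

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster])

    def summary(self) -> str:
        sizes = self.cluster_sizes
        lines = [
            f"Hierarchical clustering (complete linkage, {self.distance} distance)",
            f"  proteins        {len(self.labels)}",
            f"  clusters (k)    {self.k}" + ("" if self.k == self.auto_k
                                             else f" (scree suggested {self.auto_k})"),
        ]
        lines += [f"    cluster {c}: {n} proteins" for c, n in sizes.items()]
        return "\n".join(lines)

    # -- stability ---------------------------------------------------------

    def stability(
        self,
        proportions=DEFAULT_PROPORTIONS,
        n_repeats: int = 100,
        n_baseline: int = 100,
        seed: int = 0,
    ) -> "StabilityResults":
        """Subsampling stability of the fitted partition.

        For each proportion nu, ``n_repeats`` protein subsamples of size
        floor(nu * P) are reclustered with the same distance, linkage and
        k; each subsample partition is compared with the full-data labels
        restricted to the subsample by the Rand index. The chance baseline
        is the mean Rand of ``n_baseline`` random partitions with the
        subsample partition's cluster-size profile; the normalized score is
        (mean Rand - baseline) / (1 - baseline).
        """
        rng = np.random.default_rng(seed)
        X = self.matrix.data.to_numpy()
        proteins = np.array(self.matrix.protein_ids)
        full = self.labels.loc[proteins].to_numpy()
        P = len(proteins)

        records = []
        for nu in proportions:
            m = int(np.floor(nu * P))
            if m < self.k:
                raise ValidationError(f"subsample of {m} proteins < k={self.k}")
            for rep in range(n_repeats):
                idx = np.sort(rng.choice(P, size=m, replace=False))
                sub = _cluster_rows(X[:, idx].T, self.distance, self.k)
                ref = full[idx]
                ri = rand_index(sub, ref)
                sizes = np.bincount(sub)[np.bincount(sub) > 0]
                base = np.mean(
                    [
                        rand_index(_random_partition_like(sizes, rng), ref)
                        for _ in range(n_baseline)
                    ]
                )
                records.append((nu, rep, ri, base))
        table = pd.DataFrame(records, columns=["proportion", "repeat", "rand", "baseline"])
        return StabilityResults(table)

    def enrichment(self, assignment: CategoryAssignment) -> pd.DataFrame:
        """Upper-tail hypergeometric enrichment of each category per cluster.

        N = panel size, K = category size, n = cluster size, k = observed
        members; p = P(X >= k), BH-corrected across all cluster x category
        tests.
        """
        panel = set(self.labels.index)
        N = len(panel)
        rows = []
        for category in ("chronological_only", "disease_only", "ap"):
            members = assignment.members(category) & panel
            K = len(members)
            for cluster, cluster_members in self.labels.groupby(self.labels):
                ids = set(cluster_members.index)
                n = len(ids)
                k = len(ids & members)
                p = hypergeom_sf(k, N, K, n)
                rows.append((int(cluster), category, k, K, n, N, p))
        table = pd.DataFrame(
            rows, columns=["cluster", "category", "k", "K", "n", "N", "p_raw"]
        )
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        return table


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_logsf(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k) computed by log-space PMF summation (underflow-safe)."""
    if k <= 0:
        return 0.0
    hi = min(K, n)
    if k > hi:
        return -np.inf
    x = np.arange(k, hi + 1)
    from scipy.special import gammaln

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_pmf = logC(K, x) + logC(N - K, n - x) - logC(N, n)
    from scipy.special import logsumexp

    return float(logsumexp(log_pmf))


def _cluster_rows(rows: np.ndarray, distance: str, k: int) -> np.ndarray:
    Z = linkage(pdist(rows, metric=DISTANCES[distance]), method="complete")
    return fcluster(Z, t=k, criterion="maxclust") - 1


@dataclass
class StabilityResults:
    """Per (proportion, repeat) Rand indices with random-label baselines."""

    table: pd.DataFrame

    def scores(self) -> pd.DataFrame:
        """Per-proportion mean Rand, baseline, and normalized score."""
        agg = self.table.groupby("proportion")[["rand", "baseline"]].mean()
        agg["normalized_score"] = (agg["rand"] - agg["baseline"]) / (1 - agg["baseline"])
        return agg.reset_index()

    def summary(self) -> str:
        lines = ["Clustering stability (subsampled Rand index, random-label baseline)"]
        for _, row in self.scores().iterrows():
            lines.append(
                f"  nu={row['proportion']:.2f}: mean Rand {row['rand']:.3f}, "
                f"baseline {row['baseline']:.3f}, "
                f"normalized score {row['normalized_score']:.3f}"
            )
        return "\n".join(lines)


def stability_by_k(
    model: "ProteinClustering",
    k_values=range(2, 16),
    proportions=DEFAULT_PROPORTIONS,
    n_repeats: int = 20,
    n_baseline: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized stability score as a function of the number of clusters.

    Refits the full-data partition at each k and runs the subsampling
    assessment, producing the per-k stability curves used to judge which
    cluster numbers are reproducible (one row per k x proportion).
    """
    rows = []
    for k in k_values:
        fitted = model.fit(k=int(k))
        scores = fitted.stability(
            proportions=proportions, n_repeats=n_repeats,
            n_baseline=n_baseline, seed=seed,
        ).scores()
        for _, row in scores.iterrows():
            rows.append((int(k), row["proportion"], row["rand"],
                         row["baseline"], row["normalized_score"]))
    return pd.DataFrame(
        rows, columns=["k", "proportion", "rand", "baseline", "normalized_score"]
    )


class ProteinClustering:
    """Complete-linkage hierarchical clustering of z-scored proteins.

    Parameters
    ----------
    matrix : NPXMatrix
        Raw NPX values; proteins are z-scored internally unless
        ``standardize=False``.
    distance : {"euclidean", "manhattan"}
    """

    def __init__(self, matrix: NPXMatrix, distance: str = "euclidean",
                 standardize: bool = True):
        if distance not in DISTANCES:
            raise ValidationError(f"distance must be one of {sorted(DISTANCES)}")
        if matrix.n_proteins < 2:
            raise ValidationError("need at least 2 proteins to cluster")
        self.distance = distance
        z = zscore_proteins(matrix) if standardize else matrix
        # deterministic input order: proteins sorted lexicographically
        order = sorted(z.protein_ids)
        self.matrix = z.subset_proteins(order)

    def fit(self, k: int | str = "auto", k_max: int = 20) -> ClusteringResults:
        X = self.matrix.data.to_numpy().T  # proteins x samples
        Z = linkage(pdist(X, metric=DISTANCES[self.distance]), method="complete")
        heights = Z[:, 2]
        auto_k = scree_select_k(heights, k_max=k_max)
        chosen = auto_k if k == "auto" else int(k)
        if chosen > X.shape[0]:
            raise ValidationError(f"k={chosen} exceeds {X.shape[0]} proteins")
        labels = pd.Series(
            fcluster(Z, t=chosen, criterion="maxclust"),
            index=self.matrix.protein_ids,
            name="cluster",
        )
        return ClusteringResults(
            distance=self.distance,
            k=chosen,
            auto_k=auto_k,
            labels=labels,
            merge_heights=heights,
            linkage_matrix=Z,
            matrix=self.matrix,
        )
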