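"""Core in-memory containers for the pipeline.

Protein expression is carried as an :class:`NPXMatrix` — a thin wrapper
around a samples x proteins :class:`pandas.DataFrame` of NPX values
(Olink's log2-scale relative expression unit) keyed by UniProt accession.
Cohort annotations travel as a validated :class:`pandas.DataFrame`
(see :func:`validate_cohort`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("YC", "OC", "OP")

#: UniProt accession, optionally with an isoform suffix ("-2").
_UNIPROT_RE = re.compile(
    r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})(-\d+)?$"
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def strip_isoform(accession: str) -> str:
    """Drop an isoform suffix: ``P10909-2`` -> ``P10909``."""
    return accession.split("-", 1)[0]


def is_valid_accession(accession: str) -> bool:
    return bool(_UNIPROT_RE.match(accession))


@dataclass
class NPXMatrix:
    """Samples x proteins matrix of NPX values.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by sample id, columns by UniProt accession; values are
        NPX (log2-scale relative expression, dimensionless).
    assay_names : dict, optional
        UniProt accession -> display name of the assay.
    """

    data: pd.DataFrame
    assay_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("NPX matrix contains non-finite values")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]

    def assay_name(self, protein_id: str) -> str:
        return self.assay_names.get(protein_id, protein_id)

    def subset_proteins(self, protein_ids) -> "NPXMatrix":
        ids = list(protein_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"proteins not in matrix: {sorted(missing)}")
        return NPXMatrix(
            self.data.loc[:, ids].copy(),
            {p: self.assay_names[p] for p in ids if p in self.assay_names},
        )

    def subset_samples(self, sample_ids) -> "NPXMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return NPXMatrix(self.data.loc[ids].copy(), dict(self.assay_names))


COHORT_COLUMNS = ("sample_id", "group", "pair_id", "sex", "survival_time", "event")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort annotation table and return it indexed by sample id.

    Enforces: groups in {YC, OC, OP}; each pair id shared by exactly one
    Older Control and one Older Patient; Young Controls event-free (none
    died during follow-up); positive survival times.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    df = cohort.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in cohort: {dups}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise ValidationError(f"unknown groups: {bad_groups} (expected {GROUPS})")
    bad_sex = sorted(set(df["sex"]) - {"F", "M"})
    if bad_sex:
        raise ValidationError(f"unknown sex codes: {bad_sex}")

    paired = df[df["pair_id"].notna()]
    for pair_id, grp in paired.groupby("pair_id"):
        counts = grp["group"].value_counts()
        if counts.get("OC", 0) != 1 or counts.get("OP", 0) != 1 or len(grp) != 2:
            raise ValidationError(
                f"pair {pair_id!r} must contain exactly one OC and one OP row, "
                f"got groups {grp['group'].tolist()}"
            )

    yc = df[df["group"] == "YC"]
    if (yc["event"].astype(int) != 0).any():
        raise ValidationError("Young Controls must be event-free (event=0)")
    times = df["survival_time"].dropna()
    if (times <= 0).any():
        raise ValidationError("survival_time must be > 0 where present")
    return df.set_index("sample_id", drop=False)


@dataclass(frozen=True)
class LiteratureSet:
    """A literature-derived protein list, keyed by UniProt accession."""

    name: str
    source_kind: str  # age | disease | sasp
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"literature set {self.name!r} is empty")
        if self.source_kind not in {"age", "disease", "sasp"}:
            raise ValidationError(f"unknown source_kind {self.source_kind!r}")
        bad = sorted(m for m in self.members if not is_valid_accession(m))
        if bad:
            raise ValidationError(
                f"literature set {self.name!r} has invalid accessions: {bad[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Stacked gene-set collection (GO/KEGG/Reactome/Hallmark), GMT-style.

    ``sets`` maps a set name to (database tag, frozenset of gene symbols).
    """

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        empty = [name for name, (_, members) in self.sets.items() if not members]
        if empty:
            raise ValidationError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()
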