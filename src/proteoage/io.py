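"""Readers and writers for the tabular formats the pipeline touches.

Long-format Olink NPX exports (SampleID/UniProt/Assay/NPX), wide matrices,
cohort annotation CSVs, literature protein lists, and GMT gene-set files.
Validation is strict: structural violations raise, they are never silently
repaired. Semicolon- and comma-delimited exports are both accepted
(delimiter sniffed); the decimal separator is always a point.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import pandas as pd

from .containers import (
    GeneSetCollection,
    LiteratureSet,
    NPXMatrix,
    ValidationError,
    validate_cohort,
)

_NPX_REQUIRED = ("SampleID", "UniProt", "Assay", "NPX")


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_npx_long(path) -> NPXMatrix:
    """Read a long-format NPX export into a samples x proteins matrix.

    Duplicate (sample, protein) measurements are an error. Rows carrying a
    QC warning are retained with a warning, consistent with an analysis in
    which no samples or proteins are removed for QC flags.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in _NPX_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"NPX file {path} missing columns: {missing}")
    npx = pd.to_numeric(df["NPX"], errors="coerce")
    if npx.isna().any():
        bad = df.loc[npx.isna()].iloc[0]
        raise ValidationError(
            f"non-numeric NPX value {bad['NPX']!r} for ({bad['SampleID']}, {bad['UniProt']})"
        )
    df = df.assign(NPX=npx)
    dup = df.duplicated(subset=["SampleID", "UniProt"], keep=False)
    if dup.any():
        first = df.loc[dup, ["SampleID", "UniProt"]].iloc[0]
        raise ValidationError(
            f"duplicate measurement for sample {first['SampleID']!r}, "
            f"protein {first['UniProt']!r}"
        )
    if "QC_Warning" in df.columns:
        flagged = df["QC_Warning"].astype(str).str.upper().isin(["WARN", "WARNING", "FAIL"])
        if flagged.any():
            warnings.warn(
                f"{int(flagged.sum())} NPX rows carry a QC warning; retained",
                stacklevel=2,
            )
    wide = df.pivot(index="SampleID", columns="UniProt", values="NPX")
    if wide.isna().any().any():
        raise ValidationError("NPX long file does not form a complete matrix")
    wide.index.name = None
    wide.columns.name = None
    assay = dict(zip(df["UniProt"], df["Assay"]))
    return NPXMatrix(wide, assay)


def write_npx_long(matrix: NPXMatrix, path) -> None:
    long = (
        matrix.data.rename_axis("SampleID")
        .reset_index()
        .melt(id_vars="SampleID", var_name="UniProt", value_name="NPX")
    )
    long["Assay"] = long["UniProt"].map(matrix.assay_name)
    long[["SampleID", "UniProt", "Assay", "NPX"]].to_csv(path, index=False)


def read_npx_wide(path) -> NPXMatrix:
    """Read a wide sample x protein matrix (first column = sample id)."""
    df = pd.read_csv(path, sep=_sniff_sep(path) if str(path).endswith(".csv") else "\t",
                     index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return NPXMatrix(df)


def write_npx_wide(matrix: NPXMatrix, path) -> None:
    matrix.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort annotation table (CSV/TSV)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df["sample_id"] = df["sample_id"].astype(str)
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].astype(object).where(df["pair_id"].notna(), None)
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.reset_index(drop=True).to_csv(path, index=False)


def read_literature(path) -> list[LiteratureSet]:
    """Read literature protein lists from a TSV with columns
    name, source_kind, uniprot (one accession per row)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "source_kind", "uniprot"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"literature file {path} must have columns {sorted(required)}"
        )
    out = []
    for (name, kind), grp in df.groupby(["name", "source_kind"], sort=False):
        out.append(
            LiteratureSet(name=name, source_kind=kind,
                          members=frozenset(grp["uniprot"]))
        )
    return out


def write_literature(sets: list[LiteratureSet], path) -> None:
    rows = [
        {"name": s.name, "source_kind": s.source_kind, "uniprot": m}
        for s in sets
        for m in sorted(s.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path, database_tag: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``.

    The database tag defaults to the second (description) field.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            tag = database_tag or description or "unknown"
            key = name if name not in sets else f"{tag}:{name}"
            sets[key] = (tag, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (tag, members) in collection.items():
            fh.write("\t".join([name, tag, *sorted(members)]) + "\n")


def read_mapping(path) -> pd.DataFrame:
    """Read a uniprot <-> gene_symbol mapping TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"uniprot", "gene_symbol"} <= set(df.columns):
        raise ValidationError("mapping file needs columns uniprot, gene_symbol")
    return df


def write_table(result: pd.DataFrame, path) -> None:
    """Write a result table as TSV (the pipeline's output dialect)."""
    result.to_csv(path, sep="\t", index=False)


def write_run_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
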