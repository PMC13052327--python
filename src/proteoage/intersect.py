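"""Classify proteins by intersecting the two differential-expression results.

A protein significant in the age comparison (Older Controls vs Young
Controls) and in the disease comparison (Older Patients vs Older Controls)
is a biological Aging Protein (AP); proteins significant in only one
comparison are chronological-age-only or disease-only; the rest are
unaffected. Literature overlap and novel-candidate calling operate on
UniProt accessions (isoform suffixes stripped), restricted to the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import LiteratureSet, ValidationError, strip_isoform
from .diffexp import DEResults

CATEGORIES = ("chronological_only", "disease_only", "ap", "neither")


@dataclass
class CategoryAssignment:
    """Per-protein category labels with per-comparison directions."""

    table: pd.DataFrame  # protein_id, category, sig_age, sig_disease, dir_age, dir_disease

    def members(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return set(self.table.loc[self.table["category"] == category, "protein_id"])

    @property
    def venn_counts(self) -> dict[str, int]:
        counts = self.table["category"].value_counts()
        out = {c: int(counts.get(c, 0)) for c in CATEGORIES}
        out["significant_age"] = out["ap"] + out["chronological_only"]
        out["significant_disease"] = out["ap"] + out["disease_only"]
        return out

    def summary(self) -> str:
        v = self.venn_counts
        return "\n".join(
            [
                "Protein category assignment",
                f"  significant, age comparison      {v['significant_age']}",
                f"  significant, disease comparison  {v['significant_disease']}",
                f"  biological aging proteins (AP)   {v['ap']}",
                f"  chronological-age-only           {v['chronological_only']}",
                f"  disease-only                     {v['disease_only']}",
                f"  neither                          {v['neither']}",
            ]
        )


def classify(de_age: DEResults, de_disease: DEResults) -> CategoryAssignment:
    """Intersect two DE results into the four protein categories."""
    age = de_age.table.set_index("protein_id")
    dis = de_disease.table.set_index("protein_id")
    if set(age.index) != set(dis.index):
        raise ValidationError("the two comparisons cover different panels")
    dis = dis.loc[age.index]

    sig_a = age["significant"].to_numpy()
    sig_d = dis["significant"].to_numpy()
    category = pd.Series("neither", index=age.index, name="category")
    category[sig_a & sig_d] = "ap"
    category[sig_a & ~sig_d] = "chronological_only"
    category[~sig_a & sig_d] = "disease_only"

    table = pd.DataFrame(
        {
            "protein_id": age.index,
            "category": category.to_numpy(),
            "sig_age": sig_a,
            "sig_disease": sig_d,
            "dir_age": age["direction"].to_numpy(),
            "dir_disease": dis["direction"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CategoryAssignment(table)


def assignment_from_sets(
    panel: list[str], significant_age: set[str], significant_disease: set[str]
) -> CategoryAssignment:
    """Build a category assignment directly from significant-protein sets.

    Useful when only the membership of the two significant sets is known
    (e.g. published totals) rather than full per-protein statistics.
    """
    rows = []
    for p in panel:
        a, d = p in significant_age, p in significant_disease
        cat = "ap" if a and d else "chronological_only" if a else (
            "disease_only" if d else "neither")
        rows.append((p, cat, a, d, "up", "up"))
    return CategoryAssignment(
        pd.DataFrame(
            rows,
            columns=["protein_id", "category", "sig_age", "sig_disease",
                     "dir_age", "dir_disease"],
        )
    )


def _round1(x: float) -> float:
    """One-decimal half-up rounding (presentation convention)."""
    import decimal

    return float(
        decimal.Decimal(x).quantize(decimal.Decimal("0.1"),
                                    rounding=decimal.ROUND_HALF_UP)
    )


def _panel_set(panel) -> set[str]:
    return {strip_isoform(p) for p in panel}


def overlap_with_literature(
    assignment: CategoryAssignment,
    lists: list[LiteratureSet],
    panel: list[str],
) -> pd.DataFrame:
    """Overlap counts and percentages per (category x literature list).

    Rows are emitted for each individual list, for the per-source-kind
    aggregates (union of the lists of one kind), and for the grand union.
    Overlap is computed on UniProt accessions restricted to the panel.
    Both the category size and the list-within-panel size are emitted as
    denominators.
    """
    if not lists:
        raise ValidationError("no literature lists supplied")
    panel_ids = _panel_set(panel)

    entries: list[tuple[str, str, set[str]]] = [
        (s.name, s.source_kind, {strip_isoform(m) for m in s.members}) for s in lists
    ]
    for kind in ("age", "disease", "sasp"):
        union = set().union(*(m for _, k, m in entries if k == kind)) if any(
            k == kind for _, k, m in entries) else None
        if union:
            entries.append((f"aggregate_{kind}", kind, union))
    grand = set().union(*(m for _, _, m in entries))
    entries.append(("aggregate_all", "all", grand))

    rows = []
    for name, kind, members in entries:
        in_panel = members & panel_ids
        for category in ("chronological_only", "disease_only", "ap"):
            cat_members = {strip_isoform(p) for p in assignment.members(category)}
            count = len(cat_members & in_panel)
            size = len(cat_members)
            rows.append(
                {
                    "list_name": name,
                    "source_kind": kind,
                    "category": category,
                    "overlap_count": count,
                    "category_size": size,
                    "pct_of_category": _round1(100.0 * count / size) if size else 0.0,
                    "list_in_panel": len(in_panel),
                    "pct_of_list_in_panel": _round1(100.0 * count / len(in_panel))
                    if in_panel
                    else 0.0,
                    "list_total": len(members),
                    "panel_coverage_pct": _round1(100.0 * len(in_panel) / len(members)),
                }
            )
    return pd.DataFrame(rows)


def novel_candidates(
    assignment: CategoryAssignment,
    lists: list[LiteratureSet],
    category: str = "ap",
) -> set[str]:
    """Category members absent from the union of every literature list.

    A protein missing from all lists is called novel even if those lists
    were derived from platforms lacking it; the panel-coverage statistics
    in :func:`overlap_with_literature` quantify that caveat.
    """
    grand = set()
    for s in lists:
        grand |= {strip_isoform(m) for m in s.members}
    return {p for p in assignment.members(category) if strip_isoform(p) not in grand}
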