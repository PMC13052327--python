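"""End-to-end pipeline: DE -> classify -> overlap -> cluster -> ORA ->
survival -> correlates, with a JSON run manifest.

Stages run in dependency order from a single config (either real input
paths or a simulation block, never both) and write TSV outputs plus a
manifest recording the seed, parameters, and row counts per stage.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .containers import NPXMatrix, ValidationError
from .coxlasso import CoxLassoSignature
from .correlates import correlate
from .clustering import ProteinClustering
from .diffexp import ComparisonSpec, DifferentialExpression
from .intersect import classify, novel_candidates, overlap_with_literature
from .ora import run_ora
from .simulate import SimulationConfig, simulate_cohort, simulate_literature_lists

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    Exactly one of ``inputs`` (paths to real NPX/cohort/literature files)
    or ``simulation`` (a SimulationConfig parameter block) must be given.
    """

    outdir: str = "proteoage_run"
    seed: int = 0
    inputs: dict | None = None
    simulation: dict | None = None
    diffexp: dict = field(default_factory=dict)  # alpha_normality, alpha_fdr
    cluster: dict = field(default_factory=dict)  # distance, k, proportions, repeats
    ora: dict = field(default_factory=dict)  # min_size, max_size, top
    survival: dict = field(default_factory=dict)  # n_lambda, n_bootstrap, threshold, rule
    correlates: dict = field(default_factory=dict)  # proteins, measures, groups

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValidationError(
                "config must provide exactly one of 'inputs' or 'simulation'"
            )


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        matrix, cohort, truth = simulate_cohort(sim)
        cohort = cohort.set_index("sample_id", drop=False)
        lists = simulate_literature_lists(truth, coverage=0.9, decoys=5,
                                          seed=config.seed + 1)
        return matrix, cohort, lists, truth
    paths = config.inputs
    matrix = (
        pio.read_npx_long(paths["npx"])
        if str(paths["npx"]).endswith(".csv")
        else pio.read_npx_wide(paths["npx"])
    )
    cohort = pio.read_cohort(paths["cohort"])
    lists = pio.read_literature(paths["literature"]) if "literature" in paths else []
    return matrix, cohort, lists, None


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    current_stage = {"name": "load"}

    def stage(name):
        current_stage["name"] = name
        start = _time.perf_counter()

        def done(rows: int, outputs: list[str]):
            manifest["stages"][name] = {
                "rows": rows,
                "outputs": outputs,
                "seconds": round(_time.perf_counter() - start, 3),
            }
            logger.info("stage %s: %d rows in %.2fs", name, rows,
                        _time.perf_counter() - start)

        return done

    try:
        done = stage("load")
        matrix, cohort, lists, truth = _load_inputs(config)
        pio.write_npx_wide(matrix, outdir / "npx_matrix.tsv")
        pio.write_cohort(cohort, outdir / "cohort.csv")
        done(matrix.n_samples, ["npx_matrix.tsv", "cohort.csv"])

        de_kwargs = dict(config.diffexp)
        done = stage("diffexp")
        de_age = DifferentialExpression(
            matrix, cohort, ComparisonSpec("OC", "YC", paired=False, **de_kwargs)
        ).fit()
        de_disease = DifferentialExpression(
            matrix, cohort, ComparisonSpec("OP", "OC", paired=True, **de_kwargs)
        ).fit()
        pio.write_table(de_age.table, outdir / "de_age.tsv")
        pio.write_table(de_disease.table, outdir / "de_disease.tsv")
        done(len(de_age.table), ["de_age.tsv", "de_disease.tsv"])

        done = stage("classify")
        assignment = classify(de_age, de_disease)
        pio.write_table(assignment.table, outdir / "categories.tsv")
        done(len(assignment.table), ["categories.tsv"])

        done = stage("overlap")
        if lists:
            overlap = overlap_with_literature(assignment, lists, matrix.protein_ids)
            novel = sorted(novel_candidates(assignment, lists))
            pio.write_table(overlap, outdir / "literature_overlap.tsv")
            (outdir / "novel_candidates.txt").write_text("\n".join(novel) + "\n")
            done(len(overlap), ["literature_overlap.tsv", "novel_candidates.txt"])
        else:
            done(0, [])

        ck = dict(config.cluster)
        done = stage("cluster")
        model = ProteinClustering(matrix, distance=ck.get("distance", "euclidean"))
        fitted = model.fit(k=ck.get("k", "auto"))
        stability = fitted.stability(
            proportions=tuple(ck.get("proportions", (0.85, 0.90, 0.95))),
            n_repeats=int(ck.get("repeats", 100)),
            seed=config.seed + 2,
        )
        enrichment = fitted.enrichment(assignment)
        pio.write_table(
            fitted.labels.rename_axis("protein_id").reset_index(),
            outdir / "cluster_labels.tsv",
        )
        pio.write_table(stability.scores(), outdir / "cluster_stability.tsv")
        pio.write_table(enrichment, outdir / "cluster_enrichment.tsv")
        done(len(fitted.labels),
             ["cluster_labels.tsv", "cluster_stability.tsv", "cluster_enrichment.tsv"])

        done = stage("ora")
        if config.inputs and "gmt" in config.inputs and "mapping" in config.inputs:
            collection = pio.read_gmt(config.inputs["gmt"])
            mapping = pio.read_mapping(config.inputs["mapping"])
            ora_table = run_ora(
                assignment.members("ap"),
                collection,
                set(matrix.protein_ids),
                mapping,
                **config.ora,
            )
            pio.write_table(ora_table, outdir / "ora_ap.tsv")
            done(len(ora_table), ["ora_ap.tsv"])
        else:
            done(0, [])  # ORA needs user-supplied gene sets and a mapping

        sv = dict(config.survival)
        done = stage("survival")
        ap = sorted(assignment.members("ap"))
        if ap and cohort.loc[cohort["group"] != "YC", "event"].sum() > 0:
            cox = CoxLassoSignature.from_cohort(matrix, cohort, proteins=ap)
            result = cox.cross_validate(
                n_folds=int(sv.get("n_folds", 10)),
                n_lambda=int(sv.get("n_lambda", 100)),
                selection_rule=sv.get("rule", "lambda_min"),
                seed=config.seed + 3,
            )
            boot = cox.bootstrap_stability(
                n_bootstrap=int(sv.get("n_bootstrap", 100)),
                threshold=float(sv.get("threshold", 0.5)),
                n_lambda=int(sv.get("n_lambda", 100)),
                selection_rule=sv.get("rule", "lambda_min"),
                seed=config.seed + 4,
            )
            pio.write_table(result.cv_table, outdir / "survival_cv.tsv")
            freq = boot.frequencies.rename_axis("protein_id").reset_index(name="frequency")
            pio.write_table(freq, outdir / "survival_frequencies.tsv")
            summary = {
                "lambda_min": result.lambda_min,
                "lambda_1se": result.lambda_1se,
                "selected_lambda_min": sorted(result.selected("lambda_min")),
                "selected_lambda_1se": sorted(result.selected("lambda_1se")),
                "robust": sorted(boot.robust),
            }
            (outdir / "survival_summary.json").write_text(json.dumps(summary, indent=2))
            done(len(freq),
                 ["survival_cv.tsv", "survival_frequencies.tsv", "survival_summary.json"])
            selected = summary["selected_lambda_min"] or ap[:2]
        else:
            done(0, [])
            selected = ap[:2]

        done = stage("correlate")
        ckw = dict(config.correlates)
        measures = ckw.get("measures") or [
            c for c in cohort.columns
            if c not in ("sample_id", "group", "pair_id", "sex", "survival_time", "event")
        ]
        proteins = ckw.get("proteins") or selected
        if proteins and measures:
            corr = correlate(matrix, cohort, proteins, measures,
                             groups=ckw.get("groups"))
            pio.write_table(corr, outdir / "correlations.tsv")
            done(len(corr), ["correlations.tsv"])
        else:
            done(0, [])
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current_stage['name']!r} failed: {exc}"
        ) from exc

    pio.write_run_summary(manifest, outdir / "manifest.json")
    return outdir
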