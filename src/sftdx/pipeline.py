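"""End-to-end orchestration of the two analysis arms.

The expression arm runs: log2 guard -> within-set quantile normalization ->
probe collapsing -> gene-universe intersection -> housekeeping stability
selection -> DWD batch merge -> PCA mixing check -> target-gene group
comparisons.  The IHC arm runs: cohort validation -> marker calls ->
contingency tables -> accuracy metrics -> combined-marker rules -> paired
sensitivity comparisons.  Every artifact embeds the configuration hash and
seed so reruns are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import accuracy as acc
from . import stats as xstats
from .dwd import merge_all, pca_batch_check
from .expression import ExpressionSet, read_expression_tsv, read_sample_annotations
from .housekeeping import (
    DEFAULT_RETAINED_FRACTION,
    build_anchor_set,
    score_stability,
    select_housekeeping,
    write_stability_report,
)
from .normalize import ensure_log2, quantile_normalize
from .probes import collapse_probes, intersect_gene_universe, read_probe_annotations
from .synthetic import TARGET_GENE

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One auditable surface for every dialect knob of the two arms."""

    out_dir: str = "results"
    seed: int = 0
    # expression arm inputs
    expression_sets: list[dict] = field(default_factory=list)  # path/set_id/platform/is_log2
    sample_annotations: str | None = None
    probe_annotations: str | None = None
    candidates: str | None = None  # housekeeping candidate list, one id per line
    target_gene: str = TARGET_GENE
    retained_fraction: float = DEFAULT_RETAINED_FRACTION
    dwd_penalty: str | float = "auto"
    merge_order: str | list[str] = "by-size"
    skip_quantile: bool = False
    skip_dwd: bool = False
    ttest_variant: str = "welch"
    # IHC arm inputs
    cohort: str | None = None
    ci_method: str = "wilson"
    reference_policy: str = "meningioma"  # or "pooled"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # the hash covers the analysis-relevant settings, not where results go
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _load_sets(config: PipelineConfig) -> list[ExpressionSet]:
    ann = read_sample_annotations(config.sample_annotations)
    return [
        read_expression_tsv(
            spec["path"], ann, spec["set_id"], spec["platform"],
            is_log2=spec.get("is_log2", True),
        )
        for spec in config.expression_sets
    ]


def run_expression_arm(
    config: PipelineConfig,
    sets: list[ExpressionSet] | None = None,
    probe_annotations=None,
    candidates: list[str] | None = None,
) -> dict:
    """Run the full expression arm; returns the results bundle.

    ``sets`` / ``probe_annotations`` / ``candidates`` may be passed in-memory
    (e.g. straight from the synthetic generator); otherwise they are read from
    the paths in the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if sets is None:
            sets = _load_sets(config)
        if probe_annotations is None:
            probe_annotations = read_probe_annotations(config.probe_annotations)
        if candidates is None:
            candidates = [
                line.strip() for line in Path(config.candidates).read_text().splitlines()
                if line.strip()
            ]
        if len(sets) < 2:
            raise ValueError("expression arm needs >=2 sets")

        stage = "normalize"
        sets = [ensure_log2(s) for s in sets]
        if not config.skip_quantile:
            sets = [quantile_normalize(s) for s in sets]

        stage = "collapse"
        gsets = [collapse_probes(s, probe_annotations) for s in sets]

        stage = "intersect"
        universe = intersect_gene_universe(gsets, required=[config.target_gene])
        usable = sorted(set(candidates) & set(universe))
        lost = len(candidates) - len(usable)
        if lost:
            logger.info("%d housekeeping candidates absent from the common universe", lost)

        stage = "housekeeping"
        scores = score_stability(gsets, usable)
        housekeeping = select_housekeeping(scores, config.retained_fraction)
        write_stability_report(scores, housekeeping, out / "stability_report.tsv")
        anchor = build_anchor_set(housekeeping, config.target_gene)

        stage = "dwd-merge"
        merged = merge_all(
            gsets, anchor, order=config.merge_order,
            penalty=config.dwd_penalty, skip_adjustment=config.skip_dwd,
        )
        merged.matrix.to_csv(out / "merged_matrix.tsv", sep="\t",
                             index_label="entrez_gene_id", lineterminator="\n")
        _write_json({**_stamp(config), "adjustments": merged.adjustment_log,
                     "uncorrected": config.skip_dwd}, out / "adjustment_log.json")

        stage = "pca-check"
        mixing = pca_batch_check(merged)

        stage = "comparisons"
        report = xstats.site_stratified_report(merged, config.target_gene)
        bundle = {
            **_stamp(config),
            "uncorrected": config.skip_dwd,
            "n_sets": len(gsets),
            "n_samples": merged.n_samples,
            "n_anchor_genes": len(anchor),
            "batch_silhouette": mixing.silhouette,
            "batches_mixed": mixing.mixed,
            "comparisons": [c.as_dict() for c in report.comparisons],
            "skipped_comparisons": report.skipped,
        }
        _write_json(bundle, out / "expression_results.json")
        bundle["_merged"] = merged
        bundle["_anchor"] = anchor
        return bundle
    except Exception as err:
        raise RuntimeError(f"expression arm failed at stage {stage!r}: {err}") from err


#: the disease / reference pairs of the diagnostic question
_DISEASE_GROUPS = (acc.MENINGEAL_SFT, acc.MENINGEAL_HPC)


def run_ihc_arm(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Run the IHC arm; returns the results bundle (and writes artifacts)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cohort is None:
            cohort = acc.read_cohort_csv(config.cohort)
        acc.validate_cohort(cohort)
        markers = [m for m in acc.MARKERS if (cohort["marker"] == m).any()]
        for m in set(acc.MARKERS) - set(markers):
            logger.warning("cohort lacks marker %s; its metrics are skipped", m)

        if config.reference_policy == "meningioma":
            reference = acc.MENINGIOMAS
        elif config.reference_policy == "pooled":
            reference = acc.CohortSelector(
                "meningiomas + synovial sarcomas", ("meningioma", "synovial_sarcoma"))
        else:
            raise ValueError(f"unknown reference_policy {config.reference_policy!r}")

        stage = "metrics"
        rules = list(markers)
        if set(acc.MARKERS) <= set(markers):
            rules.append(acc.CombinedRule("and"))
        results = []
        for rule in rules:
            for disease in _DISEASE_GROUPS:
                table = acc.build_contingency(cohort, rule, disease, reference)
                metrics = acc.diagnostic_metrics(table, ci_method=config.ci_method)
                results.append(metrics.as_dict())

        stage = "counts"
        frame, _ = acc._sample_positivity(cohort, "ALDH1")
        count_summary = (
            frame.groupby(["histotype", "site"])["positive"]
            .agg(n="count", positive="sum").reset_index().to_dict("records")
        )

        stage = "paired"
        paired = {}
        if set(acc.MARKERS) <= set(markers):
            for disease in _DISEASE_GROUPS:
                r = acc.compare_paired_sensitivity(cohort, "ALDH1", "CD34", disease)
                paired[disease.label] = {"p": r.p_value, "b": r.b, "c": r.c, "note": r.note}

        bundle = {
            **_stamp(config),
            "ci_method": config.ci_method,
            "reference_policy": config.reference_policy,
            "metrics": results,
            "aldh1_counts": count_summary,
            "paired_sensitivity": paired,
        }
        _write_json(bundle, out / "ihc_results.json")
        table3 = pd.DataFrame([
            {
                "marker": r["marker"], "disease": r["disease"],
                "SE": round(100 * r["se"], 1), "SP": round(100 * r["sp"], 1),
                "PPV": round(100 * r["ppv"], 1) if r["ppv"] is not None else None,
                "NPV": round(100 * r["npv"], 1) if r["npv"] is not None else None,
            }
            for r in results
        ])
        table3.to_csv(out / "diagnostic_accuracy.tsv", sep="\t", index=False,
                      lineterminator="\n")
        return bundle
    except Exception as err:
        raise RuntimeError(f"ihc arm failed at stage {stage!r}: {err}") from err
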