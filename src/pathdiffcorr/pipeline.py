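"""End-to-end orchestration: files in, per-condition correlation tables,
differential selection and pathway reports out.

Stages are exposed as plain functions so the CLI subcommands (correlate /
select / report) compose to exactly the same bytes as the monolithic run.
All report content is rendered in memory first and written last, so a
failing run leaves no partial reports behind.
"""

from __future__ import annotations

import functools
import json
import logging
import math
import os
from dataclasses import dataclass, field

from . import diffcorr, kgml_pathways, parallel
from .errors import ValidationError
from .expression_io import (
    ConditionDesign,
    ExpressionMatrix,
    read_annotation,
    read_design,
    read_matrix,
)
from .kgml_pathways import GenePair, PathwayGraph
from .paircorr import CorrelationConfig, PairCorrelation, classify, correlate_arrays

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    matrix_path: str
    design_path: str
    annotation_path: str
    kgml_dir: str
    out_dir: str
    reference_condition: str
    dialect: str = "tsv"
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    relation_types: frozenset[str] = kgml_pathways.DEFAULT_RELATION_TYPES
    workers: int = 1
    chunk_size: int = 10_000
    aggregation: str = "max"

    def to_dict(self) -> dict:
        return {
            "matrix_path": str(self.matrix_path),
            "design_path": str(self.design_path),
            "annotation_path": str(self.annotation_path),
            "kgml_dir": str(self.kgml_dir),
            "out_dir": str(self.out_dir),
            "reference_condition": self.reference_condition,
            "dialect": self.dialect,
            "corr_threshold": self.correlation.corr_threshold,
            "sd_multiplier": self.correlation.sd_multiplier,
            "retention_floor": self.correlation.retention_floor,
            "min_samples": self.correlation.min_samples,
            "population_sd": self.correlation.population_sd,
            "relation_types": sorted(self.relation_types),
            "workers": self.workers,
            "chunk_size": self.chunk_size,
            "aggregation": self.aggregation,
        }


def _correlate_one(
    item: tuple[str, str],
    data: dict,
    condition: str,
    config: CorrelationConfig,
) -> PairCorrelation:
    """Per-pair task run by the worker pool (must stay module-level for
    pickling)."""
    probe_a, probe_b = item
    n_total, n_used, r = correlate_arrays(data[probe_a], data[probe_b], config)
    return PairCorrelation(
        probe_a, probe_b, condition, n_total, n_used, r,
        classify(r, config.corr_threshold),
    )


def correlate_condition(
    matrix: ExpressionMatrix,
    samples: list[str],
    condition: str,
    probe_pairs: list[PairKey],
    config: CorrelationConfig,
    workers: int = 1,
    chunk_size: int = 10_000,
) -> dict[PairKey, PairCorrelation]:
    """Correlate every probe pair within one condition's samples."""
    probes = sorted({p for pair in probe_pairs for p in pair})
    data = {p: matrix.values_for(p, samples) for p in probes}
    task = functools.partial(
        _correlate_one, data=data, condition=condition, config=config
    )
    plan = parallel.partition(len(probe_pairs), chunk_size)
    results = parallel.run(task, probe_pairs, plan, workers)
    return {result.key: result for result in results}


def mapped_probe_pairs(
    pathways: list[PathwayGraph],
    annotation,
    matrix: ExpressionMatrix,
    relation_types: frozenset[str],
) -> tuple[list[PairKey], dict[PairKey, GenePair]]:
    """Gene pairs from all pathways, mapped to probe pairs present in the
    matrix. Returns the ordered unique probe-pair keys and the probe-pair ->
    gene-pair mapping."""
    gene_pairs = kgml_pathways.merge_pairs(
        [kgml_pathways.extract_gene_pairs(g, relation_types) for g in pathways]
    )
    probe_triples = kgml_pathways.pairs_to_probes(gene_pairs, annotation)
    present = set(matrix.probe_ids)
    keys: list[PairKey] = []
    gene_map: dict[PairKey, GenePair] = {}
    n_absent = 0
    for probe_a, probe_b, gene_pair in probe_triples:
        if probe_a not in present or probe_b not in present:
            n_absent += 1
            continue
        key = (probe_a, probe_b)
        if key not in gene_map:
            keys.append(key)
            gene_map[key] = gene_pair
    if n_absent:
        logger.warning(
            "%d probe pairs dropped: probe absent from matrix", n_absent
        )
    return keys, gene_map


def _fmt(value: float) -> str:
    return "nan" if math.isnan(value) else repr(float(value))


def render_correlations(results: list[PairCorrelation]) -> str:
    lines = ["probe_a\tprobe_b\tcondition\tn_total\tn_used\tr\tclass"]
    for res in results:
        lines.append(
            f"{res.probe_a}\t{res.probe_b}\t{res.condition}\t"
            f"{res.n_total}\t{res.n_used}\t{_fmt(res.r)}\t{res.cls}"
        )
    return "\n".join(lines) + "\n"


def parse_correlations(text: str) -> dict[PairKey, PairCorrelation]:
    results: dict[PairKey, PairCorrelation] = {}
    lines = text.splitlines()
    for line in lines[1:]:
        pa, pb, cond, n_total, n_used, r, cls = line.split("\t")
        results[(pa, pb)] = PairCorrelation(
            pa, pb, cond, int(n_total), int(n_used), float(r), cls
        )
    return results


def render_differential(
    pairs: list[diffcorr.DifferentialPair], selected_keys: set[PairKey]
) -> str:
    lines = [
        "probe_a\tprobe_b\tgene_a\tgene_b\tr_ref\tr_test\tcor_dif\tselected"
    ]
    ordered = sorted(pairs, key=lambda p: (-abs(p.cor_dif), p.key))
    for pair in ordered:
        gene_a = pair.gene_pair.gene_a if pair.gene_pair else ""
        gene_b = pair.gene_pair.gene_b if pair.gene_pair else ""
        lines.append(
            f"{pair.probe_a}\t{pair.probe_b}\t{gene_a}\t{gene_b}\t"
            f"{_fmt(pair.r_ref)}\t{_fmt(pair.r_test)}\t{_fmt(pair.cor_dif)}\t"
            f"{int(pair.key in selected_keys)}"
        )
    return "\n".join(lines) + "\n"


def render_pathway_report(rows: list[dict]) -> str:
    lines = ["pathway_id\tpathway_name\tpair\tcor_dif\tprobe_a\tprobe_b"]
    for row in rows:
        lines.append(
            f"{row['pathway_id']}\t{row['pathway_name']}\t{row['pair']}\t"
            f"{row['cor_dif']}\t{row['probe_a']}\t{row['probe_b']}"
        )
    return "\n".join(lines) + "\n"


def render_class_counts(rows: list[dict]) -> str:
    lines = [
        "condition\tn_pairs\tpositive\tnegative\tunrelated\tundefined"
        "\tn_differential"
    ]
    for row in rows:
        lines.append(
            f"{row['condition']}\t{row['n_pairs']}\t{row['positive']}\t"
            f"{row['negative']}\t{row['unrelated']}\t{row['undefined']}\t"
            f"{row['n_differential']}"
        )
    return "\n".join(lines) + "\n"


def select_and_report(
    results_ref: dict[PairKey, PairCorrelation],
    results_test: dict[PairKey, PairCorrelation],
    gene_map: dict[PairKey, GenePair],
    pathways: list[PathwayGraph],
    config: CorrelationConfig,
    aggregation: str = "max",
) -> dict:
    """Differential selection + report rows from two per-condition result
    sets. Returns a dict of rendered report strings plus the stats."""
    deltas = diffcorr.delta_correlations(results_ref, results_test, gene_map)
    if deltas:
        # a single defined delta cannot support an SD estimate and errors;
        # a fully empty input legitimately yields empty reports
        stats = diffcorr.selection_thresholds(
            (p.cor_dif for p in deltas),
            config.sd_multiplier, config.population_sd,
        )
        selected = diffcorr.select_differential(deltas, stats)
    else:
        stats = None
        selected = []
    aggregated = diffcorr.aggregate_gene_level(selected, aggregation)
    report_rows = diffcorr.build_pathway_report(aggregated, pathways)

    ref_label = next(iter(results_ref.values())).condition if results_ref else "ref"
    test_label = (
        next(iter(results_test.values())).condition if results_test else "test"
    )
    counts = {
        ref_label: diffcorr.count_by_class(results_ref.values()),
        test_label: diffcorr.count_by_class(results_test.values()),
    }
    count_rows = diffcorr.class_count_report(counts, len(selected))

    return {
        "stats": stats,
        "deltas": deltas,
        "selected": selected,
        "n_excluded": len(results_ref) - len(deltas),
        "differential_tsv": render_differential(
            deltas, {p.key for p in selected}
        ),
        "pathway_report_tsv": render_pathway_report(report_rows),
        "class_counts_tsv": render_class_counts(count_rows),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Full run: read inputs, correlate per condition in parallel chunks,
    select differential pairs, write reports. Returns summary metadata."""
    for path in (
        config.matrix_path, config.design_path, config.annotation_path,
        config.kgml_dir,
    ):
        if not os.path.exists(str(path)):
            raise ValidationError(f"input path does not exist: {path}")

    matrix = read_matrix(config.matrix_path, config.dialect)
    design = read_design(config.design_path)
    design.validate_against(matrix)
    annotation = read_annotation(config.annotation_path)
    pathways = kgml_pathways.load_pathway_dir(config.kgml_dir)

    conditions = design.conditions
    if config.reference_condition not in conditions:
        raise ValidationError(
            f"reference condition {config.reference_condition!r} not in "
            f"design (has {sorted(conditions)})"
        )
    test_condition = next(
        c for c in conditions if c != config.reference_condition
    )

    keys, gene_map = mapped_probe_pairs(
        pathways, annotation, matrix, config.relation_types
    )
    if not keys:
        raise ValidationError("no pathway probe pairs found in the matrix")
    logger.info("%d probe pairs mapped onto pathways", len(keys))

    per_condition: dict[str, dict[PairKey, PairCorrelation]] = {}
    for condition in (config.reference_condition, test_condition):
        per_condition[condition] = correlate_condition(
            matrix, design.samples_in(condition), condition, keys,
            config.correlation, config.workers, config.chunk_size,
        )

    outputs = select_and_report(
        per_condition[config.reference_condition],
        per_condition[test_condition],
        gene_map, pathways, config.correlation, config.aggregation,
    )

    summary = {
        "config": config.to_dict(),
        "n_probe_pairs": len(keys),
        "n_pairs_defined_both": len(outputs["deltas"]),
        "n_pairs_excluded": outputs["n_excluded"],
        "n_selected": len(outputs["selected"]),
        "selection_stats": (
            outputs["stats"].to_dict() if outputs["stats"] else None
        ),
        "test_condition": test_condition,
    }

    files = {
        f"correlations_{config.reference_condition}.tsv": render_correlations(
            list(per_condition[config.reference_condition].values())
        ),
        f"correlations_{test_condition}.tsv": render_correlations(
            list(per_condition[test_condition].values())
        ),
        "differential_pairs.tsv": outputs["differential_tsv"],
        "pathway_report.tsv": outputs["pathway_report_tsv"],
        "class_counts.tsv": outputs["class_counts_tsv"],
        "summary.json": json.dumps(summary, indent=2, sort_keys=True) + "\n",
    }
    os.makedirs(config.out_dir, exist_ok=True)
    for name, content in files.items():
        with open(
            os.path.join(config.out_dir, name), "w", encoding="utf-8"
        ) as out:
            out.write(content)
    return summary
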