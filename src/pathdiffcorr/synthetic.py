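"""Synthetic two-condition expression data with planted pair correlations.

The generator emulates an RMA-normalized two-condition microarray study:
log2 intensities around a configurable baseline, gene pairs drawn from a
bivariate normal with a planted correlation per condition (so the planted
rho is exactly the population Pearson correlation), independent null
probes, and an optional fraction of grossly aberrant samples that receive a
large additive offset on one axis of a planted pair — mimicking a corrupted
probe intensity rather than a change in correlation structure.

A matching probe annotation and a minimal KGML pathway fixture containing
exactly the planted gene pairs let the full pathway pipeline run without
any external downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import (
    ConditionDesign,
    ExpressionMatrix,
    ProbeAnnotation,
    write_annotation,
    write_design,
    write_matrix,
)

#: default per-condition sample sizes: the nonrelapse/relapse split of a
#: 249-sample breast-cancer cohort
DEFAULT_N_REF = 160
DEFAULT_N_TEST = 89


@dataclass(frozen=True)
class PlantedPair:
    """One planted gene pair with its per-condition population correlation."""

    gene_a: str
    gene_b: str
    rho_ref: float
    rho_test: float


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Baseline mean/SD (8.0 / 1.0 log2 units) match typical RMA summaries;
    outlier_magnitude of 8 log2 units models a saturated/failed probe
    reading, far outside the biological intensity range.
    """

    pair_specs: list[PlantedPair] = field(default_factory=list)
    n_ref: int = DEFAULT_N_REF
    n_test: int = DEFAULT_N_TEST
    condition_ref: str = "nonrelapse"
    condition_test: str = "relapse"
    n_null_probes: int = 0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ref < 1 or self.n_test < 1:
            raise ValidationError("n_ref and n_test must be positive")
        if self.n_null_probes < 0:
            raise ValidationError("n_null_probes must be >= 0")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValidationError(
                "outlier_rate must be in [0, 0.2] so the 80% retention floor "
                "can still remove every planted outlier"
            )
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd must be positive")
        if self.condition_ref == self.condition_test:
            raise ValidationError("condition labels must differ")
        for spec in self.pair_specs:
            for rho in (spec.rho_ref, spec.rho_test):
                if not -1.0 < rho < 1.0:
                    raise ValidationError(
                        f"pair_specs: |rho| must be < 1, got {rho} for "
                        f"{spec.gene_a}-{spec.gene_b}"
                    )
            if spec.gene_a == spec.gene_b:
                raise ValidationError(
                    f"pair_specs: self-pair {spec.gene_a}"
                )
        genes = [g for s in self.pair_specs for g in (s.gene_a, s.gene_b)]
        if len(genes) != len(set(genes)):
            raise ValidationError(
                "pair_specs: genes must be distinct across pairs so each "
                "planted correlation is independent"
            )


def probe_for(gene: str) -> str:
    """Synthetic probe id for a planted gene (one probe per gene)."""
    return f"{gene}_at"


def _bivariate(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """n draws of a standard bivariate normal with correlation rho, shape (2, n)."""
    z = rng.standard_normal((2, n))
    x = z[0]
    y = rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1]
    return np.vstack([x, y])


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ConditionDesign, ProbeAnnotation, pd.DataFrame]:
    """Generate (matrix, design, annotation, ground_truth).

    The ground-truth table lists every planted pair with its probes,
    per-condition rho and delta (rho_ref - rho_test). Identical spec (and
    seed) produces identical output.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [
        f"S{idx:04d}_{spec.condition_ref}" for idx in range(1, spec.n_ref + 1)
    ] + [
        f"S{idx:04d}_{spec.condition_test}" for idx in range(1, spec.n_test + 1)
    ]
    design = ConditionDesign(
        {
            s: (spec.condition_ref if i < spec.n_ref else spec.condition_test)
            for i, s in enumerate(sample_ids)
        }
    )
    n_samples = spec.n_ref + spec.n_test
    ref_slice = slice(0, spec.n_ref)
    test_slice = slice(spec.n_ref, n_samples)

    rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    truth_rows: list[dict] = []
    for pair in spec.pair_specs:
        block = np.empty((2, n_samples))
        block[:, ref_slice] = _bivariate(rng, pair.rho_ref, spec.n_ref)
        block[:, test_slice] = _bivariate(rng, pair.rho_test, spec.n_test)
        block = spec.baseline_mean + spec.baseline_sd * block
        if spec.outlier_rate > 0.0:
            for cond_slice, n_cond in (
                (ref_slice, spec.n_ref), (test_slice, spec.n_test),
            ):
                n_out = round(spec.outlier_rate * n_cond)
                if n_out:
                    hit = rng.choice(n_cond, size=n_out, replace=False)
                    # offset the y axis (gene_b) only: aberrant intensity,
                    # not a correlation-structure change
                    block[1, cond_slice.start + hit] += spec.outlier_magnitude
        probe_a, probe_b = probe_for(pair.gene_a), probe_for(pair.gene_b)
        probe_ids.extend([probe_a, probe_b])
        rows.extend([block[0], block[1]])
        truth_rows.append(
            {
                "gene_a": pair.gene_a, "gene_b": pair.gene_b,
                "probe_a": probe_a, "probe_b": probe_b,
                "rho_ref": pair.rho_ref, "rho_test": pair.rho_test,
                "delta": pair.rho_ref - pair.rho_test,
            }
        )

    for index in range(spec.n_null_probes):
        probe_ids.append(f"NULL{index:05d}_at")
        rows.append(
            spec.baseline_mean
            + spec.baseline_sd * rng.standard_normal(n_samples)
        )

    matrix = ExpressionMatrix(
        pd.DataFrame(np.array(rows), index=probe_ids, columns=sample_ids)
    )
    annotation = ProbeAnnotation(
        {
            probe_for(g): frozenset({g})
            for s in spec.pair_specs
            for g in (s.gene_a, s.gene_b)
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_a", "gene_b", "probe_a", "probe_b",
                 "rho_ref", "rho_test", "delta"],
    )
    return matrix, design, annotation, truth


def make_kgml_fixture(
    pair_specs: list[PlantedPair],
    pathway_id: str = "syn00001",
    name: str = "synthetic planted pathway",
) -> str:
    """Minimal valid KGML whose PPrel relations are exactly the planted
    gene pairs (entry1 -> entry2 preserving pair order)."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<pathway name="path:{pathway_id}" org="syn" number="1" '
        f'title="{name}">',
    ]
    entry_ids: dict[str, int] = {}
    next_id = 1
    for pair in pair_specs:
        for gene in (pair.gene_a, pair.gene_b):
            if gene not in entry_ids:
                entry_ids[gene] = next_id
                lines.append(
                    f'  <entry id="{next_id}" name="{gene}" type="gene"/>'
                )
                next_id += 1
    for pair in pair_specs:
        lines.append(
            f'  <relation entry1="{entry_ids[pair.gene_a]}" '
            f'entry2="{entry_ids[pair.gene_b]}" type="PPrel">'
        )
        lines.append('    <subtype name="activation" value="--&gt;"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def write_dataset(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Generate and write the full fixture set (matrix, design, annotation,
    ground truth, KGML) as the same text formats the readers consume."""
    os.makedirs(out_dir, exist_ok=True)
    matrix, design, annotation, truth = generate(spec)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "truth": os.path.join(out_dir, "ground_truth.tsv"),
        "kgml": os.path.join(out_dir, "pathway.xml"),
    }
    write_matrix(matrix, paths["matrix"])
    write_design(design, paths["design"])
    write_annotation(annotation, paths["annotation"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["kgml"], "w", encoding="utf-8") as out:
        out.write(make_kgml_fixture(spec.pair_specs))
    return paths
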