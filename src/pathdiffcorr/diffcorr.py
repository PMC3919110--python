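"""Differential-correlation selection and report building.

A pair's differential correlation (cor_dif) is its correlation in the
reference condition minus its correlation in the test condition (for the
breast-cancer application: nonrelapse minus relapse). A pair is *selected*
as condition-specific when its cor_dif lies strictly outside
[AVG - k*SD, AVG + k*SD], where AVG and SD are taken over the eligible
pair population (by default all pathway-mapped pairs defined in both
conditions) and k defaults to 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .kgml_pathways import GenePair, PathwayGraph
from .paircorr import (
    CLASS_COEXPRESSED,
    CLASS_REVERSE,
    CLASS_UNDEFINED,
    CLASS_UNRELATED,
    PairCorrelation,
)


@dataclass(frozen=True)
class DifferentialPair:
    """Per-pair correlation difference between the two conditions."""

    probe_a: str
    probe_b: str
    r_ref: float
    r_test: float
    cor_dif: float  # r_ref - r_test
    gene_pair: GenePair | None = None
    selected: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.probe_a, self.probe_b)


@dataclass(frozen=True)
class SelectionStats:
    """AVG +/- k*SD selection window over the eligible cor_dif population."""

    avg: float
    sd: float
    lower: float
    upper: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "avg": self.avg, "sd": self.sd,
            "lower": self.lower, "upper": self.upper,
            "n_pairs": self.n_pairs,
        }


def delta_correlations(
    results_ref: dict[tuple[str, str], PairCorrelation],
    results_test: dict[tuple[str, str], PairCorrelation],
    gene_pairs: dict[tuple[str, str], GenePair] | None = None,
) -> list[DifferentialPair]:
    """Pair up the two per-condition result sets and form cor_dif.

    Pairs undefined in either condition are excluded. Output follows the
    key order of ``results_ref``.
    """
    gene_pairs = gene_pairs or {}
    out: list[DifferentialPair] = []
    for key, ref in results_ref.items():
        test = results_test.get(key)
        if test is None or not ref.defined or not test.defined:
            continue
        out.append(
            DifferentialPair(
                ref.probe_a, ref.probe_b, ref.r, test.r,
                ref.r - test.r, gene_pairs.get(key),
            )
        )
    return out


def selection_thresholds(
    deltas, sd_multiplier: float = 3.0, population_sd: bool = True
) -> SelectionStats:
    """Mean, SD and AVG +/- k*SD bounds of the cor_dif population."""
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size < 2:
        raise ValidationError(
            f"need at least 2 cor_dif values to estimate SD, got {deltas.size}"
        )
    avg = float(deltas.mean())
    sd = float(np.std(deltas, ddof=0 if population_sd else 1))
    return SelectionStats(
        avg, sd, avg - sd_multiplier * sd, avg + sd_multiplier * sd,
        int(deltas.size),
    )


def select_differential(
    pairs: list[DifferentialPair], stats: SelectionStats
) -> list[DifferentialPair]:
    """Return the pairs with cor_dif strictly outside [lower, upper],
    flagged selected, sorted by |cor_dif| descending (ties by pair key)."""
    selected = [
        replace(pair, selected=True)
        for pair in pairs
        if pair.cor_dif > stats.upper or pair.cor_dif < stats.lower
    ]
    selected.sort(key=lambda p: (-abs(p.cor_dif), p.key))
    return selected


def count_by_class(results) -> dict[str, int]:
    """Tally PairCorrelation classes; counts always sum to len(results)."""
    counts = {
        CLASS_COEXPRESSED: 0, CLASS_REVERSE: 0,
        CLASS_UNRELATED: 0, CLASS_UNDEFINED: 0,
    }
    for result in results:
        counts[result.cls] += 1
    return counts


def aggregate_gene_level(
    pairs: list[DifferentialPair], method: str = "max"
) -> list[DifferentialPair]:
    """Collapse multiple probe pairs mapping to one gene pair.

    method="max": keep the probe pair with the largest |cor_dif| (ties by
    probe-pair key) — conservative and auditable. method="mean": report the
    mean cor_dif over the probe pairs (probe ids of the max-|cor_dif| pair
    are kept as the representative).
    """
    if method not in ("max", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    groups: dict[tuple[str, str], list[DifferentialPair]] = {}
    loose: list[DifferentialPair] = []
    for pair in pairs:
        if pair.gene_pair is None:
            loose.append(pair)
        else:
            groups.setdefault(pair.gene_pair.key, []).append(pair)
    out = list(loose)
    for members in groups.values():
        best = min(members, key=lambda p: (-abs(p.cor_dif), p.key))
        if method == "mean" and len(members) > 1:
            mean_dif = sum(p.cor_dif for p in members) / len(members)
            best = replace(best, cor_dif=mean_dif)
        out.append(best)
    out.sort(key=lambda p: (-abs(p.cor_dif), p.key))
    return out


def format_cor_dif(value: float) -> str:
    """Signed two-decimal rendering used in the pathway report, e.g. '+0.37'."""
    return f"{value:+.2f}"


def build_pathway_report(
    selected: list[DifferentialPair], pathways: list[PathwayGraph]
) -> list[dict]:
    """One row per (pathway, selected pair): pathway id and name, directed
    gene pair, signed cor_dif."""
    names = {p.pathway_id: p.name for p in pathways}
    rows: list[dict] = []
    for pair in selected:
        if pair.gene_pair is None:
            continue
        for pathway_id in sorted(pair.gene_pair.pathway_ids):
            rows.append(
                {
                    "pathway_id": pathway_id,
                    "pathway_name": names.get(pathway_id, ""),
                    "pair": f"{pair.gene_pair.gene_a} -> {pair.gene_pair.gene_b}",
                    "cor_dif": format_cor_dif(pair.cor_dif),
                    "probe_a": pair.probe_a,
                    "probe_b": pair.probe_b,
                }
            )
    rows.sort(key=lambda r: (r["pathway_id"], r["pair"]))
    return rows


def class_count_report(
    counts_by_condition: dict[str, dict[str, int]], n_differential: int
) -> list[dict]:
    """Per-condition class counts plus the differential-pair total — the
    positive/negative/differential summary shape."""
    rows = []
    for condition, counts in counts_by_condition.items():
        rows.append(
            {
                "condition": condition,
                "n_pairs": sum(counts.values()),
                "positive": counts[CLASS_COEXPRESSED],
                "negative": counts[CLASS_REVERSE],
                "unrelated": counts[CLASS_UNRELATED],
                "undefined": counts[CLASS_UNDEFINED],
                "n_differential": n_differential,
            }
        )
    return rows
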