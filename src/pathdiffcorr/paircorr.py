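"""Per-pair correlation with least-squares outlier rejection.

For one probe pair within one condition the procedure is:

1. restrict to samples where both probes have a value (``n_total``);
2. fit ordinary least squares of y (second probe) on x (first probe) and
   compute each sample's squared residual;
3. discard samples whose squared residual exceeds
   ``mean + sd_multiplier * SD`` of the squared residuals, but never more
   than ``floor((1 - retention_floor) * n_total)`` samples — at least 80%
   of the data is always retained at the defaults;
4. compute the Pearson correlation r on the kept samples;
5. classify the pair: r > corr_threshold -> coexpressed,
   r < -corr_threshold -> reverse-expressed, otherwise unrelated.

The regression axis is asymmetric: x is the first probe of the ordered pair
(the KGML entry1 gene, or the lexicographically smaller probe id in
all-pairs mode). Swapping the pair may change the discard set; the Pearson
correlation itself is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, ValidationError
from .expression_io import ConditionDesign, ExpressionMatrix

CLASS_COEXPRESSED = "coexpressed"
CLASS_REVERSE = "reverse"
CLASS_UNRELATED = "unrelated"
CLASS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class CorrelationConfig:
    """Tunable thresholds of the per-pair procedure.

    corr_threshold : |r| cut separating (co/reverse-)expressed from unrelated.
    sd_multiplier  : k in the mean + k*SD squared-residual discard threshold.
    retention_floor: minimum fraction of samples that must be kept.
    min_samples    : below this pairwise-complete n the pair is undefined.
    population_sd  : divide by n (True) or n-1 (False) in SD computations.
    """

    corr_threshold: float = 0.45
    sd_multiplier: float = 3.0
    retention_floor: float = 0.8
    min_samples: int = 10
    population_sd: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold < 1:
            raise ValidationError("corr_threshold must be in (0, 1)")
        if not 0 < self.retention_floor <= 1:
            raise ValidationError("retention_floor must be in (0, 1]")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be positive")
        if self.min_samples < 3:
            raise ValidationError("min_samples must be at least 3")


DEFAULT_CONFIG = CorrelationConfig()


@dataclass
class OutlierFilterResult:
    """Outcome of the squared-residual filter for one pair."""

    slope: float
    intercept: float
    squared_residuals: np.ndarray
    keep_mask: np.ndarray
    threshold: float  # NaN when the fit is degenerate

    @property
    def n_discarded(self) -> int:
        return int((~self.keep_mask).sum())


@dataclass
class PairCorrelation:
    """Correlation of one probe pair in one condition."""

    probe_a: str
    probe_b: str
    condition: str
    n_total: int
    n_used: int
    r: float  # NaN when undefined
    cls: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.probe_a, self.probe_b)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares of y on x via the normal equations.

    Returns (slope, intercept, squared_residuals). Raises DegenerateFitError
    for constant x or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"need at least 3 points, got {n}")
    x_mean = x.mean()
    y_mean = y.mean()
    dx = x - x_mean
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DegenerateFitError("constant x: slope undefined")
    slope = float(dx @ (y - y_mean)) / sxx
    intercept = y_mean - slope * x_mean
    residuals = y - (intercept + slope * x)
    return slope, float(intercept), residuals * residuals


def _sd(values: np.ndarray, population: bool) -> float:
    return float(np.std(values, ddof=0 if population else 1))


def discard_outliers(
    x: np.ndarray,
    y: np.ndarray,
    config: CorrelationConfig = DEFAULT_CONFIG,
) -> OutlierFilterResult:
    """Flag samples whose squared OLS residual exceeds mean + k*SD.

    Single pass, no refit. If more samples exceed the threshold than the
    retention floor allows, only the floor((1-retention_floor)*n) samples
    with the largest residuals are discarded (ties broken by sample order).
    A degenerate fit (constant x) keeps every sample, threshold NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    try:
        slope, intercept, sq_res = fit_line(x, y)
    except DegenerateFitError:
        return OutlierFilterResult(
            math.nan, math.nan, np.full(n, math.nan),
            np.ones(n, dtype=bool), math.nan,
        )
    threshold = sq_res.mean() + config.sd_multiplier * _sd(
        sq_res, config.population_sd
    )
    flagged = sq_res > threshold  # strict: collinear data discards nothing
    # epsilon guards against float representation of the floor fraction
    # (e.g. (1-0.8)*15 = 2.9999... must cap at 3, not 2)
    cap = math.floor((1.0 - config.retention_floor) * n + 1e-9)
    if flagged.sum() > cap:
        # keep only the `cap` largest residuals flagged; stable sort keeps
        # earlier samples first among ties
        order = np.argsort(-sq_res, kind="stable")
        flagged = np.zeros(n, dtype=bool)
        flagged[order[:cap]] = True
    return OutlierFilterResult(
        slope, intercept, sq_res, ~flagged, float(threshold)
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        return math.nan
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return math.nan
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    # guard rounding just past +/-1
    return max(-1.0, min(1.0, r))


def classify(r: float, corr_threshold: float = 0.45) -> str:
    """Three-way class by strict thresholds: the closed interval
    [-corr_threshold, corr_threshold] is 'unrelated'."""
    if math.isnan(r):
        return CLASS_UNDEFINED
    if r > corr_threshold:
        return CLASS_COEXPRESSED
    if r < -corr_threshold:
        return CLASS_REVERSE
    return CLASS_UNRELATED


def correlate_arrays(
    x: np.ndarray,
    y: np.ndarray,
    config: CorrelationConfig = DEFAULT_CONFIG,
) -> tuple[int, int, float]:
    """Filter + correlate raw value vectors (may contain NaN).

    Returns (n_total, n_used, r); r is NaN when the pair is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    present = ~(np.isnan(x) | np.isnan(y))
    x, y = x[present], y[present]
    n_total = int(present.sum())
    if n_total < config.min_samples:
        return n_total, 0, math.nan
    result = discard_outliers(x, y, config)
    keep = result.keep_mask
    n_used = int(keep.sum())
    return n_total, n_used, pearson(x[keep], y[keep])


def correlate_pair(
    matrix: ExpressionMatrix,
    probe_a: str,
    probe_b: str,
    samples: list[str],
    condition: str = "",
    config: CorrelationConfig = DEFAULT_CONFIG,
) -> PairCorrelation:
    """Run the per-pair procedure for one probe pair on a sample subset.

    ``probe_a`` is the regression x axis. Samples missing either value are
    dropped before anything else; below ``config.min_samples`` the pair is
    returned with class 'undefined'.
    """
    x = matrix.values_for(probe_a, samples)
    y = matrix.values_for(probe_b, samples)
    n_total, n_used, r = correlate_arrays(x, y, config)
    return PairCorrelation(
        probe_a, probe_b, condition, n_total, n_used, r,
        classify(r, config.corr_threshold),
    )


def log2_fold_change(
    matrix: ExpressionMatrix,
    probe: str,
    design: ConditionDesign,
    reference: str,
    test: str,
) -> float:
    """mean(test condition) - mean(reference condition) of a log2-scale probe.

    Missing values are excluded from the means; a condition with no
    non-missing values yields NaN.
    """
    values = {
        cond: matrix.values_for(probe, design.samples_in(cond))
        for cond in (reference, test)
    }
    means = {}
    for cond, vals in values.items():
        vals = vals[~np.isnan(vals)]
        means[cond] = vals.mean() if vals.size else math.nan
    return float(means[test] - means[reference])
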