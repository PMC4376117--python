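"""Optimization criteria: log-likelihood, Chi-Square, Kolmogorov-Smirnov.

Each criterion measures the distance between the observed response-time
distributions (split by response) and the model's predictions:

* ML sums log predicted densities over trials, with a floor of 1e-6 on
  the density so single unexplained responses cannot produce an infinite
  objective.
* CS compares observed and predicted counts in twelve bins per condition
  (six per response, delimited by the 0.1/0.3/0.5/0.7/0.9 empirical
  quantiles); responses observed fewer than 12 times in a condition are
  excluded because their quantiles are too unreliable.
* KS measures the largest vertical distance between the empirical and
  predicted *combined* CDFs on the signed-time axis (lower-threshold
  response times negated) and converts it to a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import kolmogorov

from .errors import EstimationError
from .fptd_cdf import cdf_full, combined_cdf
from .fptd_density import density_full
from .model_core import ParameterSet, PrecisionSettings

__all__ = [
    "DENSITY_FLOOR",
    "Dataset",
    "FitIndex",
    "log_likelihood",
    "bic",
    "cs_bins",
    "cs_statistic",
    "cs_df",
    "ks_statistic",
    "ks_pvalue",
    "aggregate_objective",
]

#: Minimum predicted density entering the log-likelihood.
DENSITY_FLOOR = 1e-6

_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
_MIN_CS_TRIALS = 12


@dataclass
class Dataset:
    """Ordered trials of a binary-decision experiment.

    ``responses`` are 0 (lower threshold) or 1 (upper threshold); ``rts``
    are response times in seconds; ``conditions`` holds one string label
    per trial and condition column named in ``labels``.
    """

    responses: np.ndarray
    rts: np.ndarray
    conditions: np.ndarray = None
    labels: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self):
        self.responses = np.asarray(self.responses, int)
        self.rts = np.asarray(self.rts, float)
        if self.conditions is None:
            self.conditions = np.empty((len(self.responses), 0), dtype=object)
        else:
            self.conditions = np.asarray(self.conditions, dtype=object)
            if self.conditions.ndim == 1:
                self.conditions = self.conditions.reshape(-1, 1)
        self.labels = tuple(self.labels)
        if self.conditions.shape != (len(self.responses), len(self.labels)):
            raise ValueError("conditions shape does not match trials x labels")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must be 0 or 1")
        if len(self.rts) != len(self.responses):
            raise ValueError("responses and rts differ in length")
        if len(self.rts) and (~np.isfinite(self.rts) | (self.rts <= 0)).any():
            raise ValueError("response times must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.responses)

    def subset(self, idx) -> "Dataset":
        return Dataset(self.responses[idx], self.rts[idx],
                       self.conditions[idx], self.labels, self.name)

    def group_cells(self, cell_labels=()) -> dict[tuple, np.ndarray]:
        """Trial indices per observed combination of the given labels."""
        cell_labels = tuple(cell_labels)
        if not cell_labels:
            return {(): np.arange(self.n)}
        missing = [l for l in cell_labels if l not in self.labels]
        if missing:
            raise KeyError(f"unknown condition labels: {missing}")
        cols = [self.labels.index(l) for l in cell_labels]
        keys = [tuple(row[c] for c in cols) for row in self.conditions]
        out: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            out.setdefault(k, []).append(i)
        return {k: np.asarray(v) for k, v in sorted(out.items())}


@dataclass(frozen=True)
class FitIndex:
    """Reported fit value of one estimation.

    ``value`` is -LL (ml), the summed Chi-Square statistic (cs) or the
    product of per-condition KS p-values (ks).  Penalized solutions carry
    the constraint-violation magnitude instead and always compare worse
    than any unpenalized solution.
    """

    method: str
    value: float
    penalized: bool = False
    penalty: float = 0.0
    components: dict = field(default_factory=dict)


def _cells_params(data: Dataset, params_by_cell: dict, cell_labels):
    """Yield (cell key, cell subset, ParameterSet) triples."""
    if cell_labels is None:
        if len(params_by_cell) == 1 and () in params_by_cell:
            cell_labels = ()
        else:
            raise ValueError("cell_labels required for multi-cell parameter maps")
    groups = data.group_cells(cell_labels)
    for key, idx in groups.items():
        if key not in params_by_cell:
            raise KeyError(f"no parameters for condition cell {key!r}")
        yield key, data.subset(idx), params_by_cell[key]


def log_likelihood(data: Dataset, params_by_cell: dict, precision=3.0,
                   cell_labels=None) -> float:
    """Summed log density over all trials, floored at ``DENSITY_FLOOR``."""
    if data.n == 0:
        raise EstimationError("cannot compute a likelihood for an empty dataset")
    prec = PrecisionSettings.coerce(precision)
    total = 0.0
    for _, cell, p in _cells_params(data, params_by_cell, cell_labels):
        for resp, thr in ((1, "upper"), (0, "lower")):
            rts = cell.rts[cell.responses == resp]
            if rts.size:
                g = density_full(rts, p, thr, prec)
                total += float(np.log(np.maximum(g, DENSITY_FLOOR)).sum())
    return total


def bic(ll: float, n_free: int, n_trials: int) -> float:
    """Bayesian Information Criterion, ``-2 LL + P ln(M)``; lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    return -2.0 * ll + n_free * float(np.log(n_trials))


def cs_bins(rts_at_threshold) -> tuple[np.ndarray, np.ndarray]:
    """Quantile bin edges and observed counts for one response's RTs.

    The five conventional quantiles split the RTs into six bins; counts
    always sum to the number of RTs, also for degenerate (tied) edges.
    """
    rts = np.sort(np.asarray(rts_at_threshold, float))
    edges = np.quantile(rts, _QUANTILES)
    cum = np.searchsorted(rts, edges, side="right")
    counts = np.diff(np.concatenate(([0], cum, [rts.size])))
    return edges, counts


def cs_statistic(data: Dataset, params_by_cell: dict, precision=3.0,
                 cell_labels=None) -> float:
    """Pearson Chi-Square over quantile bins, summed over conditions.

    Predicted bin counts are joint masses: total cell trials times the
    model probability of (response, RT bin), so response frequencies are
    part of the fit.  Responses with fewer than 12 trials in a condition
    contribute no bins.
    """
    prec = PrecisionSettings.coerce(precision)
    total = 0.0
    any_included = False
    for _, cell, p in _cells_params(data, params_by_cell, cell_labels):
        n_cell = cell.n
        for resp, thr in ((1, "upper"), (0, "lower")):
            rts = cell.rts[cell.responses == resp]
            if rts.size < _MIN_CS_TRIALS:
                continue
            any_included = True
            edges, observed = cs_bins(rts)
            f_edges = cdf_full(edges, p, thr, prec)
            f_total = cdf_full(np.inf, p, thr, prec)
            probs = np.diff(np.concatenate(([0.0], f_edges, [f_total])))
            predicted = n_cell * np.maximum(probs, 1e-10)
            total += float(((observed - predicted) ** 2 / predicted).sum())
    if not any_included:
        raise EstimationError(
            "no response reaches the 12-trial minimum in any condition; "
            "the Chi-Square criterion cannot be computed")
    return total


def cs_df(n_conditions: int, n_bins: int, n_free: int) -> int:
    """Degrees of freedom of the CS fit statistic, ``K (N - 1) - P``.

    A nonpositive result marks a model with too many free parameters to
    be testable against the binned data.
    """
    return n_conditions * (n_bins - 1) - n_free


def ks_statistic(data_cell: Dataset, params_cell: ParameterSet,
                 precision=3.0) -> float:
    """Largest |eCDF - pCDF| distance on the signed-time axis.

    The empirical CDF is evaluated on both sides of each step, the
    standard two-sided convention for the Kolmogorov-Smirnov distance.
    """
    if data_cell.n == 0:
        raise EstimationError("cannot compute a KS distance for an empty cell")
    pd = combined_cdf(params_cell, precision)
    signed = np.sort(np.where(data_cell.responses == 1, data_cell.rts, -data_cell.rts))
    n = signed.size
    model = pd.evaluate(signed)
    steps_hi = np.arange(1, n + 1) / n
    steps_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(model - steps_hi), np.abs(model - steps_lo))))


def ks_pvalue(d: float, n: int) -> float:
    """Asymptotic two-sided KS p-value with a small-sample correction.

    Uses the Kolmogorov distribution tail at
    ``lambda = (sqrt(n) + 0.12 + 0.11 / sqrt(n)) * D``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= d <= 1.0):
        raise ValueError("D must lie in [0, 1]")
    sn = np.sqrt(n)
    lam = (sn + 0.12 + 0.11 / sn) * d
    return float(kolmogorov(lam))


def aggregate_objective(method: str, components: dict) -> FitIndex:
    """Combine per-condition criterion values into one fit index.

    ml and cs values add across conditions; KS p-values multiply (the
    product is the quantity the search maximizes).
    """
    vals = np.asarray(list(components.values()), float)
    if vals.size == 0:
        raise ValueError("no components to aggregate")
    if method in ("ml", "cs"):
        value = float(vals.sum())
    elif method == "ks":
        value = float(np.prod(vals))
    else:
        raise ValueError(f"unknown method {method!r}")
    return FitIndex(method=method, value=value, components=dict(components))
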