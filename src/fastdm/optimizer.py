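"""Penalized Nelder-Mead estimation of the diffusion-model parameters.

The search works on the vector of free parameter slots defined by the
experiment specification (fixed parameters are injected, condition-
dependent parameters occupy one slot per condition cell).  Two criteria
are ranked lexicographically: a candidate violating any hard parameter
constraint is *penalized* and always compares worse than any valid
candidate, with the summed violation magnitude ordering penalized
candidates among themselves so the simplex can slide back into the valid
region.  Valid candidates compare by the optimization criterion proper
(-LL, CS, or -sum log p(KS); the latter turns maximizing the p-value
product into a numerically stable minimization).

The starting vertex comes from the EZ closed-form moment estimator; the
simplex is restarted twice more around the incumbent with re-inflated
steps and consecutively stricter stopping tolerances, because a single
downhill run is unreliable in higher dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, EstimationError
from .fit_criteria import (Dataset, FitIndex, cs_statistic, ks_pvalue,
                           ks_statistic, log_likelihood)
from .model_core import ParameterSet, PrecisionSettings, validate_parameters

__all__ = ["SimplexResult", "FitResult", "ez_start", "build_initial_simplex",
           "simplex_search", "fit"]

#: Initial simplex displacement per parameter ("a small amount").
SIMPLEX_STEPS = {"a": 0.1, "v": 0.1, "sv": 0.1, "st0": 0.1,
                 "zr": 0.05, "szr": 0.05, "t0": 0.02, "d": 0.02}

#: Objective-spread tolerances and iteration caps of the three runs.
RESTART_TOLERANCES = (1e-2, 1e-3, 1e-4)
RESTART_MAX_ITER = (400, 600, 800)

_PENALTY_FAILURE = 1e10
_TINY_P = 1e-300


def ez_start(data_cell: Dataset) -> ParameterSet:
    """Closed-form moment-based starting values for (v, a, t0).

    Uses the EZ identities on the fraction of upper-threshold responses
    and the mean and variance of the upper-threshold response times
    (s = 1 scale); ``zr`` starts at 0.5 and all variabilities at 0.
    Degenerate inputs (boundary accuracies, too few distinct RTs) fall
    back to neutral defaults so the returned set is always valid.
    """
    n = data_cell.n
    rts = data_cell.rts

    def fallback() -> ParameterSet:
        t0 = max(0.0, float(rts.min()) - 0.1) if n else 0.0
        return ParameterSet(v=0.0, a=1.0, zr=0.5, t0=t0)

    if n == 0 or np.unique(rts).size < 2:
        return fallback()
    upper = data_cell.responses == 1
    urt = rts[upper]
    if urt.size < 2 or np.var(urt, ddof=1) <= 0:
        return fallback()

    pc = float(upper.mean())
    if pc in (0.0, 1.0):
        pc = (n * pc + 0.5) / (n + 1)
    elif pc == 0.5:
        pc = 0.5 + 1.0 / (2.0 * (n + 1))
    mrt = float(urt.mean())
    vrt = float(np.var(urt, ddof=1))

    logit = math.log(pc / (1.0 - pc))
    x = logit * (logit * pc * pc - logit * pc + pc - 0.5) / vrt
    if not (x > 0) or not math.isfinite(x):
        return fallback()
    v = math.copysign(x ** 0.25, pc - 0.5)
    a = logit / v
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    t0 = mrt - mdt

    # robustness clamps into the typical parameter ranges
    a = min(max(a, 0.3), 4.0)
    v = min(max(v, -5.0), 5.0)
    t0 = min(t0, float(rts.min()) - 0.01)
    t0 = max(t0, 0.0)
    start = ParameterSet(v=v, a=a, zr=0.5, t0=t0)
    return start if validate_parameters(start) else fallback()


def build_initial_simplex(start: np.ndarray, slot_params) -> np.ndarray:
    """Vertex 0 is the start; vertex i bumps free parameter i by its step."""
    start = np.asarray(start, float)
    n = start.size
    verts = np.tile(start, (n + 1, 1))
    for i, param in enumerate(slot_params):
        verts[i + 1, i] += SIMPLEX_STEPS[param]
    return verts


@dataclass
class SimplexResult:
    x: np.ndarray
    key: tuple
    n_iter: int
    n_eval: int
    converged: bool


def simplex_search(objective, x0, steps=None, ftol=1e-4, xtol=1e-4,
                   max_iter=500, simplex=None) -> SimplexResult:
    """Nelder-Mead downhill simplex under lexicographic comparison.

    ``objective(x)`` returns a totally ordered key; here that is the
    tuple ``(penalized flag, value)``.  Terminates when the objective
    spread and the simplex diameter both fall below their tolerances (only
    meaningful once every vertex is unpenalized) or at the iteration cap.
    """
    x0 = np.asarray(x0, float)
    n = x0.size
    if simplex is None:
        if steps is None:
            steps = np.full(n, 0.1)
        simplex = np.tile(x0, (n + 1, 1))
        for i in range(n):
            simplex[i + 1, i] += steps[i]
    else:
        simplex = np.array(simplex, float)
    keys = [objective(v) for v in simplex]
    n_eval = n + 1
    converged = False

    for it in range(max_iter):
        order = sorted(range(n + 1), key=keys.__getitem__)
        simplex = simplex[order]
        keys = [keys[i] for i in order]

        if keys[0][0] == 0 and keys[-1][0] == 0:
            fspread = keys[-1][1] - keys[0][1]
            xspread = np.max(np.abs(simplex[1:] - simplex[0]))
            if fspread < ftol and xspread < xtol:
                converged = True
                break

        centroid = simplex[:-1].mean(axis=0)
        xr = centroid + (centroid - simplex[-1])
        kr = objective(xr)
        n_eval += 1
        if kr < keys[0]:
            xe = centroid + 2.0 * (centroid - simplex[-1])
            ke = objective(xe)
            n_eval += 1
            if ke < kr:
                simplex[-1], keys[-1] = xe, ke
            else:
                simplex[-1], keys[-1] = xr, kr
        elif kr < keys[-2]:
            simplex[-1], keys[-1] = xr, kr
        else:
            if kr < keys[-1]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (simplex[-1] - centroid)
            kc = objective(xc)
            n_eval += 1
            if kc < min(kr, keys[-1]):
                simplex[-1], keys[-1] = xc, kc
            else:  # shrink toward the best vertex
                for i in range(1, n + 1):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    keys[i] = objective(simplex[i])
                n_eval += n
    else:
        it = max_iter

    best = min(range(n + 1), key=keys.__getitem__)
    return SimplexResult(simplex[best].copy(), keys[best], it, n_eval, converged)


class _Objective:
    """Criterion evaluation with the penalty branch; counts evaluations."""

    def __init__(self, dataset: Dataset, table, method: str,
                 precision: PrecisionSettings):
        self.dataset = dataset
        self.table = table
        self.method = method
        self.precision = precision
        self.n_eval = 0
        self._groups = dataset.group_cells(table.labels)

    def expand_valid(self, x):
        params_by_cell = self.table.expand(x)
        penalty = 0.0
        for p in params_by_cell.values():
            verdict = validate_parameters(p)
            if not verdict:
                penalty += verdict.magnitude
        if penalty > 0 or any(not validate_parameters(p)
                              for p in params_by_cell.values()):
            return None, penalty
        return params_by_cell, 0.0

    def components(self, params_by_cell) -> dict:
        comp = {}
        for key, idx in self._groups.items():
            cell = self.dataset.subset(idx)
            p = params_by_cell[key]
            if self.method == "ml":
                comp[key] = -log_likelihood(cell, {(): p}, self.precision, ())
            elif self.method == "cs":
                comp[key] = cs_statistic(cell, {(): p}, self.precision, ())
            else:
                d = ks_statistic(cell, p, self.precision)
                comp[key] = ks_pvalue(d, cell.n)
        return comp

    def __call__(self, x) -> tuple:
        self.n_eval += 1
        params_by_cell, penalty = self.expand_valid(x)
        if params_by_cell is None:
            return (1, penalty)
        try:
            comp = self.components(params_by_cell)
        except (ConvergenceError, EstimationError, FloatingPointError):
            return (1, _PENALTY_FAILURE)
        if self.method == "ks":
            value = -float(np.log(np.maximum(list(comp.values()), _TINY_P)).sum())
        else:
            value = float(np.sum(list(comp.values())))
        if not math.isfinite(value):
            return (1, _PENALTY_FAILURE)
        return (0, value)


@dataclass
class FitResult:
    """Outcome of one dataset's estimation."""

    dataset: str
    method: str
    precision: float
    estimates: dict
    params_by_cell: dict
    fit_index: FitIndex
    run_values: list
    penalized: bool
    penalty: float
    n_free: int
    n_eval: int
    warnings: list = field(default_factory=list)


def _reported(method: str, key: tuple) -> float:
    """Convert an internal objective key to the reported fit value."""
    if key[0] == 1:
        return float(key[1])
    if method == "ks":
        return float(np.exp(-key[1]))
    return float(key[1])


def _ez_vector(dataset: Dataset, table) -> np.ndarray:
    """EZ-based start for every free slot.

    Condition-dependent slots use the EZ estimate on the trials of their
    own label combination; shared slots use the pooled estimate.
    """
    pooled = ez_start(dataset)
    x0 = np.empty(table.n_free)
    for i, slot in enumerate(table.slots):
        if slot.subkey is None:
            src = pooled
        else:
            labels = table.depends[slot.param]
            groups = dataset.group_cells(labels)
            idx = groups.get(slot.subkey)
            src = ez_start(dataset.subset(idx)) if idx is not None else pooled
        x0[i] = src.get(slot.param)
    return x0


def fit(dataset: Dataset, experiment_spec, table=None) -> FitResult:
    """Estimate all free parameters of one dataset.

    Runs the penalized simplex three times: from the EZ start, then twice
    restarted from the incumbent with a freshly inflated simplex and
    tighter stopping criteria.  The three reported fit values are
    monotone non-worsening because every restart keeps the incumbent as a
    vertex.
    """
    from .experiment_io import build_parameter_table, check_trial_minimums

    if table is None:
        table = build_parameter_table(experiment_spec, dataset)
    check_trial_minimums(dataset, experiment_spec.method, table.labels,
                         cells=table.cells)

    prec = PrecisionSettings.coerce(experiment_spec.precision)
    obj = _Objective(dataset, table, experiment_spec.method, prec)
    steps = np.array([SIMPLEX_STEPS[s.param] for s in table.slots])

    best_x = _ez_vector(dataset, table)
    best_key = obj(best_x)
    run_values = []
    warnings = []
    for ftol, cap in zip(RESTART_TOLERANCES, RESTART_MAX_ITER):
        res = simplex_search(obj, best_x, steps=steps, ftol=ftol, xtol=ftol,
                             max_iter=cap)
        if res.key < best_key:
            best_x, best_key = res.x, res.key
        if not res.converged:
            warnings.append(f"iteration cap {cap} reached at ftol={ftol:g}")
        run_values.append(_reported(experiment_spec.method, best_key))

    penalized = best_key[0] == 1
    params_by_cell = table.expand(best_x)
    if penalized:
        fit_index = FitIndex(experiment_spec.method, float("nan"),
                             penalized=True, penalty=float(best_key[1]))
    else:
        comp = obj.components(params_by_cell)
        if experiment_spec.method == "ks":
            value = float(np.prod(list(comp.values())))
        else:
            value = float(np.sum(list(comp.values())))
        fit_index = FitIndex(experiment_spec.method, value, components=comp)

    estimates = {slot.name: float(best_x[i]) for i, slot in enumerate(table.slots)}
    return FitResult(
        dataset=dataset.name, method=experiment_spec.method,
        precision=prec.precision, estimates=estimates,
        params_by_cell=params_by_cell, fit_index=fit_index,
        run_values=run_values, penalized=penalized,
        penalty=float(best_key[1]) if penalized else 0.0,
        n_free=table.n_free, n_eval=obj.n_eval, warnings=warnings)
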