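"""Companion tools: data simulation, predicted-distribution export, and
Monte-Carlo calibration of a critical fit value.

``sample_dataset`` draws random trials from the full model by inverse
transform on the predicted combined CDF: per-trial drift, starting point
and non-decision time are drawn from their inter-trial distributions and
the conditional basic-model CDF (one finite-difference solution carries
every starting point) is inverted at a uniform deviate.
``deterministic_dataset`` instead places trials exactly at the
``(i - 0.5) / n`` quantiles of the predicted combined distribution, which
yields noise-free samples for recovery checks.

``montecarlo_fit_threshold`` implements fit assessment by parametric
resampling: parameter vectors are drawn from the multivariate normal
described by the across-participant mean and covariance of the
estimates, one dataset is simulated per draw (condition cells simulated
separately and concatenated), each is refit with the identical model
specification, and the 5% worst quantile of the resulting fit indices
becomes the critical value below (KS) or above (ML, CS) which an
empirical fit counts as unsatisfactory.
"""

from __future__ import annotations

import argparse
import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError
from .fit_criteria import Dataset
from .fptd_cdf import _pde_pair_cached, combined_cdf
from .fptd_density import density_full
from .model_core import ParameterSet, PrecisionSettings, rescale_parameters, \
    validate_parameters

__all__ = ["SimConfig", "sample_dataset", "deterministic_dataset",
           "export_cdf", "export_density", "montecarlo_fit_threshold",
           "MonteCarloResult", "construct_samples_main", "plot_cdf_main",
           "plot_density_main"]


@dataclass
class SimConfig:
    """Settings of the simulation tools (defaults match the CLI defaults)."""

    params: ParameterSet = field(
        default_factory=lambda: ParameterSet(a=1.0, zr=0.5, v=0.0, t0=0.3))
    precision: float = 4.0
    n_trials: int = 100
    n_datasets: int = 1
    random: bool = False
    output: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.n_datasets > 1 and self.output is not None \
                and "%d" not in self.output:
            raise ValueError("output pattern needs %d when generating "
                             "multiple data sets")


def _require_valid(params: ParameterSet) -> ParameterSet:
    verdict = validate_parameters(params)
    if not verdict:
        raise EstimationError(
            f"invalid parameter set, violating {list(verdict.violations)}")
    return rescale_parameters(params, 1.0)


def _conditional_sampler(v: float, a: float, precision: float):
    """Per-drift sampler of (response, decision time) given a start column."""
    t, z, f_up, f_lo = _pde_pair_cached(v, a, precision)

    def draw(z_abs: float, u: float):
        i = min(max(np.searchsorted(z, z_abs) - 1, 0), len(z) - 2)
        w = (z_abs - z[i]) / (z[i + 1] - z[i])
        col_lo = (1 - w) * f_lo[:, i] + w * f_lo[:, i + 1]
        p_lo = col_lo[-1]
        if u < p_lo:
            return 0, float(np.interp(u, col_lo, t))
        col_up = (1 - w) * f_up[:, i] + w * f_up[:, i + 1]
        return 1, float(np.interp(u - p_lo, col_up, t))

    return draw


def sample_dataset(config: SimConfig, rng=None) -> Dataset:
    """Random dataset of (response, RT) pairs from the full model."""
    p = _require_valid(config.params)
    prec = PrecisionSettings.coerce(config.precision)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials

    v_trial = rng.normal(p.v, p.sv, n) if p.sv > 0 else np.full(n, p.v)
    zr_trial = rng.uniform(p.zr - 0.5 * p.szr, p.zr + 0.5 * p.szr, n) \
        if p.szr > 0 else np.full(n, p.zr)
    t0_trial = rng.uniform(p.t0 - 0.5 * p.st0, p.t0 + 0.5 * p.st0, n) \
        if p.st0 > 0 else np.full(n, p.t0)
    u = rng.uniform(0.0, 1.0, n)

    responses = np.empty(n, int)
    rts = np.empty(n)
    samplers: dict[float, object] = {}
    for i in range(n):
        key = float(v_trial[i])
        if key not in samplers:
            samplers[key] = _conditional_sampler(key, p.a, prec.precision)
        resp, t_dec = samplers[key](zr_trial[i] * p.a, u[i])
        responses[i] = resp
        rts[i] = t_dec + t0_trial[i] + (0.5 * p.d if resp == 0 else -0.5 * p.d)
    return Dataset(responses, np.maximum(rts, 1e-4), name="simulated")


def deterministic_dataset(config: SimConfig) -> Dataset:
    """Noise-free dataset at the quantiles of the predicted distribution.

    Trial ``i`` sits at the ``(i - 0.5) / n`` quantile of the combined
    CDF; the sign of the quantile determines the response, and trials are
    ordered by signed time.
    """
    p = _require_valid(config.params)
    pd_ = combined_cdf(p, config.precision)
    n = config.n_trials
    q = (np.arange(1, n + 1) - 0.5) / n
    signed = pd_.quantile(q)
    responses = (signed > 0).astype(int)
    return Dataset(responses, np.abs(signed), name="deterministic")


def export_cdf(params: ParameterSet, precision=4.0, path=None,
               t_step: float = 1e-3) -> np.ndarray:
    """Two-column table (signed RT, combined CDF), ascending in signed time."""
    p = _require_valid(params)
    pd_ = combined_cdf(p, precision)
    lo, hi = pd_.signed_t[0], pd_.signed_t[-1]
    grid = np.arange(lo, hi + t_step / 2, t_step)
    table = np.column_stack([grid, pd_.evaluate(grid)])
    if path is not None:
        np.savetxt(path, table, fmt="%.6g", delimiter=" ")
    return table


def export_density(params: ParameterSet, precision=4.0, path=None,
                   t_step: float = 1e-3) -> np.ndarray:
    """Three-column table: RT, upper density, negated lower density."""
    p = _require_valid(params)
    prec = PrecisionSettings.coerce(precision)
    t_end_u = _pde_pair_cached(p.v, p.a, prec.precision)[0][-1]
    t_end_l = _pde_pair_cached(-p.v, p.a, prec.precision)[0][-1]
    hi = p.t0 + 0.5 * p.st0 + 0.5 * abs(p.d) + max(t_end_u, t_end_l)
    grid = np.arange(0.0, hi + t_step / 2, t_step)
    g_up = density_full(grid, p, "upper", prec)
    g_lo = density_full(grid, p, "lower", prec)
    table = np.column_stack([grid, g_up, -g_lo])
    if path is not None:
        np.savetxt(path, table, fmt="%.6g", delimiter=" ")
    return table


@dataclass
class MonteCarloResult:
    """Critical fit value plus the full simulated fit-index distribution."""

    threshold: float
    fit_values: np.ndarray
    method: str

    def flags_bad_fit(self, fit_value: float) -> bool:
        """Whether an empirical fit is worse than the critical value."""
        if self.method == "ks":
            return fit_value < self.threshold
        return fit_value > self.threshold


def montecarlo_fit_threshold(estimates, spec, n_sets: int,
                             trials_per_set: int, seed=None,
                             reference_dataset: Dataset | None = None
                             ) -> MonteCarloResult:
    """Critical fit value from parametric resampling of the estimates.

    ``estimates`` is a table (DataFrame or 2-D array) of per-participant
    free-parameter vectors in the slot order of the experiment's
    parameter table.  Invalid multivariate-normal draws are rejected and
    redrawn; a singular covariance is ridge-regularized with a warning.
    """
    from .experiment_io import build_parameter_table
    from .optimizer import fit

    est = np.asarray(pd.DataFrame(estimates), float)
    if est.ndim != 2 or est.shape[0] < 2:
        raise ValueError("need estimates from at least two participants")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)

    mean = est.mean(axis=0)
    cov = np.cov(est, rowvar=False)
    cov = np.atleast_2d(cov)
    eig_min = np.linalg.eigvalsh(cov).min()
    if eig_min < 1e-10:
        warnings.warn("singular estimate covariance; ridge-regularizing")
        cov = cov + (1e-8 + max(0.0, -eig_min)) * np.eye(cov.shape[0])

    if reference_dataset is None:
        reference_dataset = Dataset(np.array([1]), np.array([0.5]))
    table = build_parameter_table(spec, reference_dataset)
    if len(table.slots) != est.shape[1]:
        raise ValueError(
            f"estimates have {est.shape[1]} columns but the specification "
            f"defines {len(table.slots)} free parameters")

    fit_values = np.empty(n_sets)
    for i in range(n_sets):
        for _ in range(1000):
            x = rng.multivariate_normal(mean, cov)
            cells = table.expand(x)
            if all(validate_parameters(p) for p in cells.values()):
                break
        else:
            raise EstimationError("could not draw a valid parameter vector")
        parts = []
        for cell, p_cell in cells.items():
            cfg = SimConfig(params=p_cell, precision=spec.precision,
                            n_trials=trials_per_set, random=True)
            sub = sample_dataset(cfg, rng=rng)
            cond = np.array([list(cell)] * sub.n, dtype=object) if cell \
                else np.empty((sub.n, 0), dtype=object)
            parts.append(Dataset(sub.responses, sub.rts, cond,
                                 table.labels))
        merged = Dataset(
            np.concatenate([d.responses for d in parts]),
            np.concatenate([d.rts for d in parts]),
            np.concatenate([d.conditions for d in parts]) if table.labels
            else None,
            table.labels, name=f"mc_{i}")
        result = fit(merged, spec, table=table)
        fit_values[i] = result.penalty if result.penalized \
            else result.fit_index.value

    q = 0.05 if spec.method == "ks" else 0.95
    return MonteCarloResult(float(np.quantile(fit_values, q)), fit_values,
                            spec.method)


# ----------------------------------------------------------------------
# command-line entry points

def _param_args(parser: argparse.ArgumentParser, precision_default: float):
    parser.add_argument("-a", type=float, default=1.0, metavar="VALUE",
                        help="threshold separation a (default 1)")
    parser.add_argument("-z", type=float, default=0.5, metavar="VALUE",
                        help="relative starting point zr (default 0.5)")
    parser.add_argument("-v", type=float, default=0.0, metavar="VALUE",
                        help="drift rate v (default 0)")
    parser.add_argument("-t", type=float, default=0.3, metavar="VALUE",
                        help="non-decision time t0 (default 0.3)")
    parser.add_argument("-d", type=float, default=0.0, metavar="VALUE",
                        help="non-decision time difference d (default 0)")
    parser.add_argument("-Z", type=float, default=0.0, metavar="VALUE",
                        help="starting point variability szr (default 0)")
    parser.add_argument("-V", type=float, default=0.0, metavar="VALUE",
                        help="drift variability sv (default 0)")
    parser.add_argument("-T", type=float, default=0.0, metavar="VALUE",
                        help="non-decision time variability st0 (default 0)")
    parser.add_argument("-p", type=float, default=precision_default,
                        metavar="VALUE",
                        help=f"computational precision (default {precision_default:g})")
    parser.add_argument("-o", type=str, default=None, metavar="FILE_NAME",
                        help="write output to FILE_NAME instead of the console")


def _params_from_args(args) -> ParameterSet:
    return ParameterSet(a=args.a, zr=args.z, v=args.v, t0=args.t, d=args.d,
                        szr=args.Z, sv=args.V, st0=args.T)


def construct_samples_main(argv=None) -> int:
    """Entry point of the ``construct-samples`` command."""
    parser = argparse.ArgumentParser(
        prog="construct-samples",
        description="Simulate (response, RT) data sets from a diffusion-"
                    "model parameter set.")
    _param_args(parser, precision_default=4.0)
    parser.add_argument("-n", type=int, default=100, metavar="VALUE",
                        help="trials per data set (default 100)")
    parser.add_argument("-r", action="store_true",
                        help="generate random data (default: deterministic "
                             "quantile data)")
    parser.add_argument("-N", type=int, default=1, metavar="VALUE",
                        help="number of random data sets (default 1)")
    parser.add_argument("--seed", type=int, default=None,
                        help="random seed for -r mode")
    args = parser.parse_args(argv)
    try:
        config = SimConfig(params=_params_from_args(args), precision=args.p,
                           n_trials=args.n, n_datasets=args.N,
                           random=args.r, output=args.o, seed=args.seed)
        rng = np.random.default_rng(config.seed)
        for k in range(config.n_datasets):
            data = sample_dataset(config, rng=rng) if config.random \
                else deterministic_dataset(config)
            lines = "".join(f"{r:d} {t:.5f}\n"
                            for r, t in zip(data.responses, data.rts))
            if config.output is None:
                sys.stdout.write(lines)
            else:
                name = config.output.replace("%d", str(k)) \
                    if "%d" in config.output else config.output
                with open(name, "w", encoding="utf-8") as fh:
                    fh.write(lines)
    except (ValueError, EstimationError) as exc:
        print(f"ERROR: {exc}", file=sys.stderr)
        return 1
    return 0


def _plot_tool_main(argv, prog, description, exporter) -> int:
    parser = argparse.ArgumentParser(prog=prog, description=description)
    _param_args(parser, precision_default=4.0)
    args = parser.parse_args(argv)
    try:
        table = exporter(_params_from_args(args), precision=args.p,
                         path=args.o)
        if args.o is None:
            np.savetxt(sys.stdout, table, fmt="%.6g", delimiter=" ")
    except (ValueError, EstimationError) as exc:
        print(f"ERROR: {exc}", file=sys.stderr)
        return 1
    return 0


def plot_cdf_main(argv=None) -> int:
    """Entry point of the ``plot-cdf`` command."""
    return _plot_tool_main(
        argv, "plot-cdf",
        "Tabulate the predicted combined CDF (lower-threshold response "
        "times negated) of a diffusion-model parameter set.", export_cdf)


def plot_density_main(argv=None) -> int:
    """Entry point of the ``plot-density`` command."""
    return _plot_tool_main(
        argv, "plot-density",
        "Tabulate the predicted response-time densities at both "
        "thresholds (lower negated) of a diffusion-model parameter set.",
        export_density)
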