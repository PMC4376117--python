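"""Parameter vocabulary of the Wiener diffusion model.

The decision process is a Wiener diffusion with drift ``v`` and diffusion
constant ``s`` running in the corridor ``[0, a]``.  It starts at
``z = zr * a`` and terminates at the first passage of either threshold;
the response time is the first-passage time plus a non-decision component.
The non-decision component has mean ``t0`` overall, and the two responses
may differ in execution speed by ``d`` seconds.  Trial-to-trial
variability is modelled by a normal distribution of the drift (SD ``sv``)
and uniform distributions of the relative starting point (width ``szr``)
and of the non-decision time (width ``st0``).

The diffusion constant is a pure scaling parameter: jointly rescaling
``v``, ``a`` and ``sv`` by ``s_new / s_old`` leaves all predicted response
time distributions unchanged.  All numerical engines in this package work
on the ``s = 1`` scale internally and rescale on entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "PrecisionSettings",
    "Validity",
    "rescale_parameters",
    "split_t0",
    "validate_parameters",
    "exit_probability_upper",
]

#: Canonical ordering of the eight model parameters, used for free-parameter
#: vectors and for output tables.
PARAM_NAMES = ("a", "zr", "v", "t0", "d", "szr", "sv", "st0")


@dataclass(frozen=True)
class ParameterSet:
    """One full set of diffusion-model parameters.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per second).
    a : float
        Threshold separation (evidence units), must be positive.
    zr : float
        Relative starting point, ``z = zr * a``; must lie strictly in (0, 1).
    t0 : float
        Mean non-decision time in seconds.
    d : float
        Difference in non-decision time between the lower- and
        upper-threshold response (seconds).
    sv : float
        Inter-trial standard deviation of the drift (normal distribution).
    szr : float
        Inter-trial range of the relative starting point (uniform).
    st0 : float
        Inter-trial range of the non-decision time (uniform, seconds).
    s : float
        Diffusion constant; a scaling parameter, 1 by convention here.
    """

    v: float = 0.0
    a: float = 1.0
    zr: float = 0.5
    t0: float = 0.3
    d: float = 0.0
    sv: float = 0.0
    szr: float = 0.0
    st0: float = 0.0
    s: float = 1.0

    def replace(self, **changes) -> "ParameterSet":
        return _dc_replace(self, **changes)

    def get(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class Validity:
    """Verdict of :func:`validate_parameters`.

    ``magnitude`` sums how far each violated constraint is missed; the
    optimizer uses it as a penalty that still orders invalid candidates,
    so the simplex can walk back into the valid region.
    """

    valid: bool
    violations: tuple[str, ...] = ()
    magnitude: float = 0.0

    def __bool__(self) -> bool:
        return self.valid


def rescale_parameters(p: ParameterSet, s_new: float) -> ParameterSet:
    """Transform a parameter set to a different diffusion constant.

    Drift, threshold separation and drift variability scale with
    ``s_new / s_old``.  The relative quantities ``zr`` and ``szr`` are
    ratios of scaled quantities and stay unchanged, as do all times.
    """
    if not (s_new > 0) or not math.isfinite(s_new):
        raise ValueError(f"diffusion constant must be positive, got {s_new!r}")
    f = s_new / p.s
    return p.replace(v=p.v * f, a=p.a * f, sv=p.sv * f, s=s_new)


def split_t0(t0: float, d: float) -> tuple[float, float]:
    """Split mean non-decision time into per-threshold values.

    Returns ``(t0_upper, t0_lower) = (t0 - d/2, t0 + d/2)``; the mean of
    the two recovers ``t0`` and their difference is ``d``.
    """
    return t0 - 0.5 * d, t0 + 0.5 * d


def validate_parameters(p: ParameterSet) -> Validity:
    """Check every hard constraint of the model; never raises.

    The constraints are: ``a > 0``, ``0 < zr < 1``, ``t0 >= 0``, all
    variabilities and ``s`` nonnegative (``s`` positive), the starting point
    distribution must stay inside the corridor
    (``zr - szr/2 > 0`` and ``zr + szr/2 < 1``), and the smallest realized
    non-decision time must be nonnegative
    (``t0 - st0/2 - |d|/2 >= 0``), so that no trial predicts a response
    before the stimulus.
    """
    violations: list[str] = []
    magnitude = 0.0

    def strict(name: str, residual: float) -> None:
        nonlocal magnitude
        if not (residual > 0.0):
            violations.append(name)
            magnitude += max(0.0, -residual) if math.isfinite(residual) else 1e6

    def nonneg(name: str, residual: float) -> None:
        nonlocal magnitude
        if not (residual >= 0.0):
            violations.append(name)
            magnitude += -residual if math.isfinite(residual) else 1e6

    for name in ("v", "a", "zr", "t0", "d", "sv", "szr", "st0", "s"):
        if not math.isfinite(p.get(name)):
            return Validity(False, (name,), 1e6)

    strict("a", p.a)
    strict("zr", p.zr)
    strict("zr", 1.0 - p.zr)
    strict("s", p.s)
    nonneg("t0", p.t0)
    nonneg("sv", p.sv)
    nonneg("szr", p.szr)
    nonneg("st0", p.st0)
    strict("zr-szr", p.zr - 0.5 * p.szr)
    strict("zr+szr", 1.0 - p.zr - 0.5 * p.szr)
    nonneg("t0-st0-d", p.t0 - 0.5 * p.st0 - 0.5 * abs(p.d))

    # deduplicate while keeping order
    seen: dict[str, None] = dict.fromkeys(violations)
    return Validity(not seen, tuple(seen), magnitude)


def exit_probability_upper(v: float, a: float, zr: float, s: float = 1.0) -> float:
    """Closed-form probability of absorbing at the upper threshold.

    For a Wiener process with drift ``v`` in ``[0, a]`` started at
    ``zr * a``::

        P(upper) = (1 - exp(-2 v zr a / s^2)) / (1 - exp(-2 v a / s^2))

    with the continuous limit ``P = zr`` when ``v = 0``.  Used throughout
    the test suite as an independent oracle for the numerical engines.
    """
    if not (a > 0 and 0 < zr < 1 and s > 0):
        raise ValueError("requires a > 0, 0 < zr < 1, s > 0")
    x = 2.0 * v * a / (s * s)
    if abs(x) < 1e-12:
        return zr
    if x < 0:
        # mirror to keep the exponentials bounded
        return 1.0 - exit_probability_upper(-v, a, 1.0 - zr, s)
    return math.expm1(-x * zr) / math.expm1(-x)


@dataclass(frozen=True)
class PrecisionSettings:
    """Single accuracy knob for all numerical routines.

    A value of ``precision = p`` targets an absolute error of roughly
    ``10**-p`` in computed densities and distribution functions.  All
    derived discretization controls follow from it:

    * series truncation tolerance ``10**-min(p, 6)``,
    * midpoint step counts for the starting-point and non-decision-time
      integrals, never below four,
    * Gauss-Hermite node count for drift variability in the CDF engine,
    * spatial grid resolution of the finite-difference CDF solver.
    """

    precision: float = 3.0

    def __post_init__(self) -> None:
        if not (self.precision > 0) or not math.isfinite(self.precision):
            raise ValueError(f"precision must be positive, got {self.precision!r}")

    @classmethod
    def coerce(cls, value) -> "PrecisionSettings":
        if isinstance(value, PrecisionSettings):
            return value
        return cls(float(value))

    @property
    def eps_series(self) -> float:
        """Truncation error bound for the density series."""
        return 10.0 ** (-min(self.precision, 6.0))

    @property
    def n_integration_steps(self) -> int:
        """Midpoint steps for the uniform szr / st0 integrals (>= 4)."""
        return max(4, math.ceil(10.0 ** (self.precision / 2.0)))

    @property
    def n_hermite(self) -> int:
        """Gauss-Hermite nodes for normal drift variability in the CDF."""
        return max(4, int(round(2.0 * self.precision)))

    @property
    def cdf_residual_target(self) -> float:
        """Unaccounted probability mass allowed at the end of the CDF grid."""
        return 0.5 * 10.0 ** (-self.precision)

    def n_z_steps(self, a: float) -> int:
        """Spatial steps of the finite-difference grid over ``[0, a]``."""
        return max(8, math.ceil(a * 30.0 * 10.0 ** ((self.precision - 3.0) / 2.0)))
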