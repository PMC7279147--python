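"""Steered-pulling analysis and a 1-D steered-Langevin reference simulator.

In a constant-velocity steered run a harmonic restraint of stiffness k is
attached to a collective variable xi (here: a COM-COM distance) and its
centre c(t) = c0 + v t is dragged at constant velocity.  The external
work done by the moving restraint is

    W(t_n) = sum_{m<n} k (c(t_m) - xi(t_m)) (c(t_{m+1}) - c(t_m)),

reported against centre displacement.  A detachment event shows up as a
jump in the work-vs-distance curve followed by a plateau; the final
plateau height measures the total work needed to desorb the ligand, i.e.
(up to dissipation) the binding free energy of the site.

The simulator integrates overdamped Langevin dynamics on a known 1-D PMF

    xi <- xi + (dt/gamma) (-U'(xi) + k (c(t) - xi))
             + sqrt(2 kB T dt / gamma) N(0,1),

providing traces whose ground-truth well depth is known exactly, so the
whole work/plateau chain is verifiable without any MD engine.  Units:
kJ/mol, Å, ns; gamma in kJ mol^-1 ns Å^-2; kB T = 2.494 kJ/mol at 300 K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .core import KB_KJ_MOL

logger = logging.getLogger(__name__)

DEFAULT_VELOCITY = 1.95  # Å/ns, the production pull speed
DEFAULT_MIN_LEN = 3.0    # Å
DEFAULT_FLATNESS = 5.0   # kJ/mol


# ---------------------------------------------------------------------------
# PMF models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorsePMF:
    """Morse well U(x) = D (1 - exp(-a (x - r0)))^2 - D.

    ``depth`` D in kJ/mol, ``width`` a in 1/Å, minimum at ``r0`` Å; the
    dissociated limit is U = 0, so the well depth equals the binding
    energy.
    """

    depth: float
    width: float = 1.0
    r0: float = 10.0

    def u(self, x: float) -> float:
        e = math.exp(-self.width * (x - self.r0))
        return self.depth * (1.0 - e) ** 2 - self.depth

    def du(self, x: float) -> float:
        a = self.width
        e = math.exp(-a * (x - self.r0))
        return 2.0 * self.depth * a * e * (1.0 - e)


@dataclass(frozen=True)
class DoubleWellPMF:
    """Two Morse-like wells separated by ``spacing`` Å."""

    depth1: float
    depth2: float
    spacing: float = 8.0
    width: float = 1.0
    r0: float = 10.0

    def _wells(self) -> "Tuple[MorsePMF, MorsePMF]":
        return (MorsePMF(self.depth1, self.width, self.r0),
                MorsePMF(self.depth2, self.width, self.r0 + self.spacing))

    def u(self, x: float) -> float:
        w1, w2 = self._wells()
        return w1.u(x) + w2.u(x) + self.depth1 + self.depth2 \
            - max(self.depth1, self.depth2)

    def du(self, x: float) -> float:
        w1, w2 = self._wells()
        return w1.du(x) + w2.du(x)


@dataclass(frozen=True)
class FlatPMF:
    r0: float = 10.0

    def u(self, x: float) -> float:
        return 0.0

    def du(self, x: float) -> float:
        return 0.0


def _max_curvature(pmf, lo: float, hi: float, n: int = 2000) -> float:
    xs = np.linspace(lo, hi, n)
    du = np.array([pmf.du(x) for x in xs])
    return float(np.abs(np.gradient(du, xs)).max())


# ---------------------------------------------------------------------------
# traces and work
# ---------------------------------------------------------------------------

@dataclass
class PullingTrace:
    """Colvar time series from a steered run, with restraint metadata."""

    time: np.ndarray
    xi: np.ndarray
    center: np.ndarray
    spring_k: float
    velocity: float

    def __post_init__(self) -> None:
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def center_residual(self) -> float:
        """RMS deviation of the centre from the constant-velocity line."""
        fit = self.center[0] + self.velocity * (self.time - self.time[0])
        return float(np.sqrt(np.mean((self.center - fit) ** 2)))


@dataclass
class WorkCurve:
    """Cumulative restraint work (kJ/mol) vs centre displacement (Å)."""

    displacement: np.ndarray
    work: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.work[0]) > 1e-12:
            raise ValueError("work must start at zero")


@dataclass
class PlateauEstimate:
    """Flat intervals of a work curve and the jumps between them."""

    intervals: "List[Tuple[float, float, float]]"  # (start Å, end Å, level)
    fallback_used: bool = False

    @property
    def levels(self) -> List[float]:
        return [lvl for _, _, lvl in self.intervals]

    @property
    def jumps(self) -> List[float]:
        lv = self.levels
        first = [lv[0]] if lv else []
        return first + [b - a for a, b in zip(lv, lv[1:])]

    @property
    def final_level(self) -> Optional[float]:
        return self.intervals[-1][2] if self.intervals else None


def accumulated_work(trace: PullingTrace,
                     scheme: str = "left") -> WorkCurve:
    """Integrate the external work of the moving restraint.

    ``scheme`` is ``"left"`` (the left-rule sum above) or ``"midpoint"``
    (average the spring extension over each step).
    """
    if trace.spring_k <= 0:
        raise ValueError("spring_k must be positive")
    if len(trace.time) < 2:
        raise ValueError("need at least 2 samples")
    ext = trace.center - trace.xi
    dc = np.diff(trace.center)
    if scheme == "left":
        dW = trace.spring_k * ext[:-1] * dc
    elif scheme == "midpoint":
        dW = trace.spring_k * 0.5 * (ext[:-1] + ext[1:]) * dc
    else:
        raise ValueError("scheme must be 'left' or 'midpoint'")
    work = np.concatenate([[0.0], np.cumsum(dW)])
    return WorkCurve(displacement=trace.center - trace.center[0], work=work)


def detect_plateaus(curve: WorkCurve, min_len: float = DEFAULT_MIN_LEN,
                    flatness: float = DEFAULT_FLATNESS,
                    resample_dx: float = 0.05) -> PlateauEstimate:
    """Maximal flat intervals of a work curve.

    The curve is first resampled onto a uniform displacement grid
    (``resample_dx`` Å); an interval qualifies when it is at least
    ``min_len`` Å long and its work range (max - min) stays below
    ``flatness`` kJ/mol.  The level of each plateau is the median work on
    the interval.  Returns an empty estimate (with a warning) when no
    interval qualifies.
    """
    span = curve.displacement[-1] - curve.displacement[0]
    if span <= min_len:
        raise ValueError(
            f"curve spans {span:.2f} Å, below min_len {min_len} Å"
        )
    grid = np.arange(curve.displacement[0], curve.displacement[-1],
                     resample_dx)
    w = np.interp(grid, curve.displacement, curve.work)
    n = len(grid)
    need = max(2, int(round(min_len / resample_dx)))

    intervals: List[Tuple[float, float, float]] = []
    i = 0
    while i < n:
        lo = hi = w[i]
        j = i
        while j + 1 < n:
            nlo, nhi = min(lo, w[j + 1]), max(hi, w[j + 1])
            if nhi - nlo >= flatness:
                break
            lo, hi = nlo, nhi
            j += 1
        if j - i + 1 >= need:
            level = float(np.median(w[i:j + 1]))
            intervals.append((float(grid[i]), float(grid[j]), level))
            i = j + 1
        else:
            i += 1
    if not intervals:
        logger.warning("no plateau of length >= %.2f Å with flatness < %.2f "
                       "kJ/mol found", min_len, flatness)
    return PlateauEstimate(intervals=intervals)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

def simulate_pull(pmf, spring_k: float, velocity: float = DEFAULT_VELOCITY,
                  temperature: float = 300.0, friction: float = 1.0,
                  dt: float = 2e-4, pull_length: float = 12.0,
                  seed: int = 0, xi0: Optional[float] = None,
                  center0: Optional[float] = None,
                  record_dx: float = 0.002) -> PullingTrace:
    """Overdamped steered-Langevin trace on a known PMF.

    The colvar starts at the PMF minimum (``xi0`` default ``pmf.r0``) and
    the restraint centre travels ``pull_length`` Å at constant velocity.
    Deterministic under a fixed seed.  ``record_dx`` sets the centre
    displacement between recorded samples; the integration step is always
    ``dt``.  Raises when dt (k + max U'') / gamma >= 0.1, the overdamped
    Euler stability margin, and suggests a workable dt.
    """
    if spring_k <= 0 or friction <= 0 or velocity <= 0 or dt <= 0:
        raise ValueError("spring_k, friction, velocity and dt must be > 0")
    x0 = pmf.r0 if xi0 is None else xi0
    c0 = x0 if center0 is None else center0
    # curvature bound over the thermally accessible range: the colvar sits
    # within a few sqrt(kT / k_eff) of the minimum on the stiff inner wall
    k_eff = spring_k + abs(_max_curvature(pmf, x0 - 0.05, x0 + 0.05))
    thermal = math.sqrt(KB_KJ_MOL * max(temperature, 1.0) / k_eff)
    stiff = spring_k + _max_curvature(pmf, x0 - 3.0 * thermal,
                                      c0 + pull_length + 1.0)
    margin = dt * stiff / friction
    if margin >= 0.1:
        raise ValueError(
            f"dt too large for stability: dt*(k+max|U''|)/gamma = "
            f"{margin:.3f} >= 0.1; try dt <= {0.09 * friction / stiff:.2e} ns"
        )

    n_steps = int(math.ceil(pull_length / (velocity * dt)))
    stride = max(1, int(round(record_dx / (velocity * dt))))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps)
    sqrt_term = math.sqrt(2.0 * KB_KJ_MOL * temperature * dt / friction)
    inv_gamma = dt / friction

    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    xi_out = np.empty(n_rec)
    c_out = np.empty(n_rec)
    xi = x0
    du = pmf.du
    k = spring_k
    rec = 0
    t_out[0], xi_out[0], c_out[0] = 0.0, xi, c0
    rec = 1
    for step in range(n_steps):
        c = c0 + velocity * (step * dt)
        xi += inv_gamma * (-du(xi) + k * (c - xi)) \
            + sqrt_term * noise[step]
        if (step + 1) % stride == 0 and rec < n_rec:
            t = (step + 1) * dt
            t_out[rec] = t
            xi_out[rec] = xi
            c_out[rec] = c0 + velocity * t
            rec += 1
    return PullingTrace(time=t_out[:rec], xi=xi_out[:rec],
                        center=c_out[:rec], spring_k=spring_k,
                        velocity=velocity)


# ---------------------------------------------------------------------------
# binding energy from work curves
# ---------------------------------------------------------------------------

@dataclass
class BindingEstimate:
    """Final plateau level per trace plus the min-max range."""

    levels: List[float]
    fallbacks: List[bool]

    @property
    def range(self) -> Tuple[float, float]:
        return (min(self.levels), max(self.levels))

    @property
    def mean(self) -> float:
        return float(np.mean(self.levels))


def binding_energy_estimate(curves: Sequence[WorkCurve],
                            min_len: float = DEFAULT_MIN_LEN,
                            flatness: float = DEFAULT_FLATNESS,
                            ) -> BindingEstimate:
    """Per-curve final plateau levels and their range.

    When the plateau detector finds no qualifying interval on a noisy
    trace, the final level falls back to the median work over the trailing
    ``min_len`` Å of the curve — the pull protocol ends in the desorbed
    regime, so the tail median is an unbiased plateau height.  The
    fallback is flagged per curve.
    """
    if not curves:
        raise ValueError("need at least one work curve")
    levels: List[float] = []
    fallbacks: List[bool] = []
    for curve in curves:
        est = detect_plateaus(curve, min_len=min_len, flatness=flatness)
        if est.final_level is not None:
            levels.append(est.final_level)
            fallbacks.append(False)
        else:
            tail = curve.displacement >= curve.displacement[-1] - min_len
            levels.append(float(np.median(curve.work[tail])))
            fallbacks.append(True)
    return BindingEstimate(levels=levels, fallbacks=fallbacks)
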