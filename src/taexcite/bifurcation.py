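"""Fixed-point continuation, Hopf detection and limit-cycle measurements.

Stress enters the normalized model through the antitoxin degradation rate
``delta_a`` and the toxin/antitoxin translation ratio ``epsilon``.  Both
are continued here in normalized space; ``delta_AT`` co-varies so that the
in-complex degradation fraction F = delta_AT * epsilon / delta_a stays
fixed.  Along a branch the fixed point loses stability in a Hopf
bifurcation (a complex eigenvalue pair crossing the imaginary axis) and a
limit cycle of toxin excitations appears; its amplitude grows to a full
excursion almost immediately past onset (Canard explosion), while its
period stays finite at onset (type II excitability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import detect_excitations
from .ode_models import MINIMAL, ModelVariant, integrate
from .parameters import NormalizedParameterSet
from .phase_plane import FixedPoint, classify_regime, find_fixed_points, jacobian_reduced

__all__ = [
    "BifurcationBranch",
    "BranchPoint",
    "HopfPoint",
    "LimitCycleMetrics",
    "with_stress_parameter",
    "continue_branch",
    "detect_hopf",
    "limit_cycle_metrics",
    "sweep_excitation_time",
]

STRESS_PARAMS = ("delta_a", "epsilon")


def with_stress_parameter(q: NormalizedParameterSet, param: str,
                          value: float,
                          mode: str = "physical") -> NormalizedParameterSet:
    """Copy of ``q`` with one stress parameter set, co-varying dependents.

    ``delta_a`` sweeps scale ``delta_AT`` along (the in-complex degradation
    fraction F = delta_AT * epsilon / delta_a is a property of the protein,
    not of the stress level); this is the same in both modes.

    ``epsilon`` is the ratio of translation rates b_2/b_1, and the stress
    that moves it acts on the toxin translation rate b_2.  Because the
    normalization divides by epsilon, changing b_2 physically rescales
    every 1/epsilon-built parameter: ``mode="physical"`` (default)
    co-varies delta_c, delta_AT, kappa and alpha accordingly, which is
    what an epsilon bifurcation diagram over the underlying reaction rates
    measures.  ``mode="normalized"`` moves epsilon (and delta_AT through
    the fixed F) while freezing the other dimensionless groups.
    """
    if param not in STRESS_PARAMS:
        raise ValueError(f"param must be one of {STRESS_PARAMS}, got {param!r}")
    if mode not in ("physical", "normalized"):
        raise ValueError(f"mode must be 'physical' or 'normalized', got {mode!r}")
    F = q.F_ratio
    if param == "delta_a":
        return replace(q, delta_a=value, delta_AT=F * value / q.epsilon)
    if mode == "normalized":
        return replace(q, epsilon=value, delta_AT=F * q.delta_a / value)
    f = value / q.epsilon
    return replace(q, epsilon=value, alpha=q.alpha * f, kappa=q.kappa / f,
                   delta_c=q.delta_c / f, delta_AT=q.delta_AT / f)


@dataclass(frozen=True)
class BranchPoint:
    param_value: float
    fixed_point: FixedPoint

    @property
    def max_real(self) -> float:
        return float(np.max(self.fixed_point.eigenvalues.real))


@dataclass(frozen=True)
class HopfPoint:
    param: str
    value: float
    eigenvalues: np.ndarray
    criticality: str       # supercritical | subcritical | undetermined
    onset_period: Optional[float] = None


@dataclass
class BifurcationBranch:
    """A parameter-indexed family of fixed points with stability labels."""

    param: str
    points: List[BranchPoint]
    base: NormalizedParameterSet
    variant: ModelVariant = MINIMAL
    mode: str = "physical"
    hopf_points: List[HopfPoint] = field(default_factory=list)
    truncated: bool = False

    @property
    def values(self) -> np.ndarray:
        return np.array([bp.param_value for bp in self.points])

    def stability_changes(self) -> List[int]:
        """Indices i where stability flips between points i and i+1."""
        s = [bp.fixed_point.stable for bp in self.points]
        return [i for i in range(len(s) - 1) if s[i] != s[i + 1]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for bp in self.points:
            fp = bp.fixed_point
            lam = fp.eigenvalues[np.argmax(fp.eigenvalues.real)]
            rows.append({self.param: bp.param_value, "x_star": fp.x,
                         "y_star": fp.y, "re_lambda": lam.real,
                         "im_lambda": abs(lam.imag),
                         "stable": fp.stable})
        return pd.DataFrame(rows)


def _solve_fixed_point(q: NormalizedParameterSet, variant: ModelVariant,
                       seed: Optional[FixedPoint] = None) -> Optional[FixedPoint]:
    from .phase_plane import _newton_polish
    from .ode_models import rhs_reduced
    if seed is not None:
        sol = _newton_polish(seed.x, seed.y, q, variant)
        if sol is not None and sol[0] >= 0 and sol[1] >= 0:
            x, y = sol
            J = jacobian_reduced(x, y, q, variant)
            return FixedPoint(x=x, y=y, jacobian=J,
                              eigenvalues=np.linalg.eigvals(J),
                              residual=float(np.max(np.abs(
                                  rhs_reduced((x, y), q, variant)))))
    fps = find_fixed_points(q, variant)
    return fps[0] if len(fps) == 1 else (fps[0] if fps else None)


def continue_branch(q: NormalizedParameterSet, param: str,
                    values: Sequence[float],
                    variant: ModelVariant = MINIMAL,
                    detect: bool = True,
                    mode: str = "physical") -> BifurcationBranch:
    """Track the fixed point over a sorted parameter range.

    Natural-parameter continuation: each Newton solve is seeded with the
    previous solution (adequate here because the branch has no folds in
    the scanned ranges).  If Newton diverges mid-branch the branch is
    truncated with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("use at least 10 continuation steps")
    if np.any(values <= 0) or np.any(np.diff(values) <= 0):
        raise ValueError("parameter values must be positive and increasing")
    points: List[BranchPoint] = []
    prev: Optional[FixedPoint] = None
    truncated = False
    for v in values:
        qv = with_stress_parameter(q, param, v, mode=mode)
        fp = _solve_fixed_point(qv, variant, seed=prev)
        if fp is None:
            warnings.warn(f"continuation truncated at {param} = {v:g}")
            truncated = True
            break
        points.append(BranchPoint(param_value=float(v), fixed_point=fp))
        prev = fp
    branch = BifurcationBranch(param=param, points=points, base=q,
                               variant=variant, mode=mode, truncated=truncated)
    if detect and branch.stability_changes():
        branch.hopf_points = detect_hopf(branch)
    return branch


def detect_hopf(branch: BifurcationBranch, refine_tol: float = 1e-8,
                classify: bool = True) -> List[HopfPoint]:
    """Refine each stability change of the branch to a Hopf point.

    The zero of the leading eigenvalue's real part is located by bisection
    (re-solving the fixed point at each midpoint).  A crossing with real
    eigenvalues is reported as ``non-hopf``.  Criticality is decided
    empirically: integrating just past the crossing, a bounded
    small-amplitude stable cycle marks the bifurcation supercritical.
    """
    out: List[HopfPoint] = []
    q, variant, param = branch.base, branch.variant, branch.param
    mode = branch.mode
    for i in branch.stability_changes():
        lo, hi = branch.points[i], branch.points[i + 1]
        a, fa = lo.param_value, lo.max_real
        b, fb = hi.param_value, hi.max_real
        fp = lo.fixed_point
        while b - a > refine_tol * max(1.0, abs(b)):
            mid = 0.5 * (a + b)
            fpm = _solve_fixed_point(with_stress_parameter(q, param, mid, mode=mode),
                                     variant, seed=fp)
            if fpm is None:
                break
            fm = float(np.max(fpm.eigenvalues.real))
            if (fm > 0) == (fb > 0):
                b, fb = mid, fm
            else:
                a, fa = mid, fm
            fp = fpm
        value = 0.5 * (a + b)
        fpc = _solve_fixed_point(with_stress_parameter(q, param, value, mode=mode),
                                 variant, seed=fp)
        eig = fpc.eigenvalues if fpc is not None else np.array([np.nan, np.nan])
        if not np.any(np.abs(np.asarray(eig).imag) > 0):
            out.append(HopfPoint(param=param, value=value, eigenvalues=eig,
                                 criticality="non-hopf"))
            continue
        crit, period = "undetermined", None
        if classify and fpc is not None:
            crit, period = _criticality_by_simulation(q, param, value, fpc,
                                                      variant, mode,
                                                      unstable_side=fb > fa)
        out.append(HopfPoint(param=param, value=value, eigenvalues=eig,
                             criticality=crit, onset_period=period))
    return out


def _criticality_by_simulation(q, param, value, fpc, variant, mode, unstable_side,
                               rel_step: float = 2e-4):
    """Supercritical if a bounded small cycle exists just past onset."""
    step = value * rel_step * (1.0 if unstable_side else -1.0)
    qv = with_stress_parameter(q, param, value + step, mode=mode)
    fp = _solve_fixed_point(qv, variant, seed=fpc)
    if fp is None:
        return "undetermined", None
    omega = float(np.max(np.abs(fp.eigenvalues.imag)))
    lin_period = 2 * np.pi / omega if omega > 0 else None
    x0 = (fp.x * 1.001, fp.y)
    t_end = (lin_period or 50.0) * 400.0
    traj = integrate(replace(variant, representation="reduced-2d"), qv, x0,
                     t_end=t_end, rtol=1e-9, n_points=8000)
    tail = traj["x"][len(traj.t) // 2:]
    amp = float(tail.max() - tail.min())
    # bounded, small relative to a full excursion, and not collapsed to zero
    if 0 < amp < 0.5 * q.kappa and tail.max() < 10 * fp.x:
        period = None
        if lin_period is not None:
            xm = tail - tail.mean()
            ups = np.where((xm[:-1] < 0) & (xm[1:] >= 0))[0]
            if len(ups) > 2:
                tt = traj.t[len(traj.t) // 2:]
                period = float(np.mean(np.diff(tt[ups])))
        return "supercritical", period or lin_period
    return "subcritical", lin_period


@dataclass
class LimitCycleMetrics:
    """Amplitude, period and excitation time of the attracting cycle."""

    amplitude: float          # mean per-cycle max of x
    period: Optional[float]   # tau between successive upward kappa-crossings
    excitation_time: float    # mean tau spent above kappa per cycle
    n_cycles: int = 0

    def __post_init__(self) -> None:
        if self.excitation_time > 0 and self.period is not None:
            assert self.period > self.excitation_time


def limit_cycle_metrics(q: NormalizedParameterSet,
                        variant: ModelVariant = MINIMAL,
                        tau_end: Optional[float] = None,
                        transient_fraction: float = 0.5,
                        kick: Optional[Sequence[float]] = None,
                        rtol: float = 1e-8) -> LimitCycleMetrics:
    """Measure the attracting oscillation by long integration.

    Starts near the fixed point (or from ``kick`` for an excitable
    single-shot measurement), discards the first ``transient_fraction`` of
    the run, and detects cycles as successive upward crossings of kappa.
    With no crossing the excitation time is zero and the period undefined.
    """
    if tau_end is None:
        tau_end = 500.0 / q.epsilon
    if kick is None:
        fps = find_fixed_points(q, variant)
        if not fps:
            raise RuntimeError("no fixed point to start from")
        fp = fps[0]
        x0 = (fp.x * 1.01 + 1e-6, fp.y)
    else:
        x0 = tuple(kick)
    rep = variant.representation if variant.representation in (
        "reduced-2d", "reduced-3d-tat") else "reduced-2d"
    v2 = replace(variant, representation=rep)
    state0 = x0 if rep == "reduced-2d" else (*x0, 0.0)
    traj = integrate(v2, q, state0, t_end=tau_end, rtol=rtol,
                     n_points=max(4000, int(tau_end / 0.5)))
    cut = int(len(traj.t) * transient_fraction)
    t, x = traj.t[cut:], traj["x"][cut:]
    events = detect_excitations((t, x), q.kappa)
    if not events:
        return LimitCycleMetrics(amplitude=float(x.max()), period=None,
                                 excitation_time=0.0, n_cycles=0)
    onsets = np.array([e.onset for e in events])
    period = float(np.mean(np.diff(onsets))) if len(onsets) > 1 else None
    return LimitCycleMetrics(
        amplitude=float(np.mean([e.peak for e in events])),
        period=period,
        excitation_time=float(np.mean([e.duration for e in events])),
        n_cycles=len(events))


def sweep_excitation_time(q: NormalizedParameterSet,
                          delta_a_values: Sequence[float],
                          eps_values: Sequence[float],
                          variant: ModelVariant = MINIMAL,
                          engine: str = "ode",
                          tau_end: Optional[float] = None,
                          seeds: Sequence[int] = (0, 1, 2),
                          t_end_seconds: float = 2.0e5,
                          mode: str = "physical") -> pd.DataFrame:
    """Mean excitation time over a (delta_a, epsilon) grid.

    ``engine="ode"`` measures the deterministic limit cycle (0 where the
    system does not oscillate); ``engine="ssa"`` pools stochastic
    excitation events over the given seeds.  Per-cell failures are
    recorded as NaN and the sweep continues.
    """
    rows = []
    for da in delta_a_values:
        for ev in eps_values:
            qv = with_stress_parameter(
                with_stress_parameter(q, "delta_a", da), "epsilon", ev,
                mode=mode)
            try:
                if engine == "ode":
                    m = limit_cycle_metrics(qv, variant, tau_end=tau_end)
                    et, per, n = m.excitation_time, m.period, m.n_cycles
                elif engine == "ssa":
                    from .ssa import excitation_stats_for
                    st = excitation_stats_for(qv, variant, seeds=seeds,
                                              t_end=t_end_seconds)
                    et = st.mean_excitation_time * 0.002 if st.n_events else 0.0
                    # seconds -> tau with the reference d_m anchor
                    per = st.mean_period * 0.002 if st.mean_period else None
                    n = st.n_events
                else:
                    raise ValueError(f"unknown engine {engine!r}")
                rows.append({"delta_a": da, "epsilon": ev,
                             "excitation_time": et, "period": per,
                             "n_events": n})
            except Exception as exc:   # noqa: BLE001 - record and continue
                warnings.warn(f"sweep cell (delta_a={da:g}, eps={ev:g}) failed: {exc}")
                rows.append({"delta_a": da, "epsilon": ev,
                             "excitation_time": np.nan, "period": np.nan,
                             "n_events": 0})
    return pd.DataFrame(rows)
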