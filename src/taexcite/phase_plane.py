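"""Nullclines, fixed points, stability and regime classification (2D system).

In the reduced (x, y) phase plane the system has a single fixed point at
the intersection of the two nullclines.  For a Hill coefficient n >= 2 the
x-nullcline NC(x) is folded; its middle branch acts as the excitation
threshold: trajectories pushed across it make a large excursion (a toxin
spike) before returning.  Three regimes are distinguished:

``monostable``
    Stable fixed point far from the threshold: intrinsic molecular noise
    cannot reach the middle branch, and no excitations occur in practice.
``excitable``
    Stable fixed point with the threshold within reach of the intrinsic
    noise, and a super-threshold displacement produces an
    order-of-magnitude toxin excursion.
``oscillatory``
    Unstable fixed point; the system orbits a limit cycle of repeated
    excitations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ode_models import (
    MINIMAL,
    ModelVariant,
    antitoxin_qss,
    dilution_factor,
    hill_cleavage,
    integrate,
    mrna_qss,
    rhs_reduced,
    translation_factor,
)
from .parameters import NormalizedParameterSet

__all__ = [
    "FixedPoint",
    "NullclineSet",
    "RegimeClassification",
    "nullclines",
    "nullcline_x",
    "nullcline_y",
    "jacobian_reduced",
    "find_fixed_points",
    "classify_regime",
    "flow_field",
]

#: molecules per unit of normalized toxin x is epsilon/d_m; this anchor
#: converts back with the reference mRNA decay rate.
DEFAULT_DM_ANCHOR = 0.002

_YMAX = 1e9  # upper bracket for implicit nullcline solves


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the reduced system with its linearization."""

    x: float
    y: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return float(np.max(self.eigenvalues.real)) < 0.0

    @property
    def oscillatory(self) -> bool:
        """Complex eigenvalue pair (spiral/center local dynamics)."""
        return bool(np.any(np.abs(self.eigenvalues.imag) > 0.0))


@dataclass
class NullclineSet:
    """Sampled nullclines on an x grid, with the folds of NC(x).

    ``folds`` are the local extrema (x, NC(x)) of the x-nullcline,
    ordered by x; for n >= 2 there are two and the segment between them is
    the threshold (unstable) branch.
    """

    x: np.ndarray
    nc_x: np.ndarray
    nc_y: np.ndarray
    folds: list = field(default_factory=list)

    @property
    def threshold_branch(self) -> Optional[tuple]:
        if len(self.folds) >= 2:
            return (self.folds[0][0], self.folds[1][0])
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "NC_x": self.nc_x, "NC_y": self.nc_y})


def nullcline_x(x, q: NormalizedParameterSet, variant: ModelVariant = MINIMAL):
    """y on the x-nullcline (dx/dtau = 0) at toxin level ``x``.

    Closed form when transcription does not depend on y:
    NC(x) = [alpha a(x) x + eps delta_c f_t x - eps gamma f_m m(x)] / (eps delta_AT).
    With DNA binding the balance is solved for y numerically.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    eps = q.epsilon
    if not variant.dna_binding:
        a = antitoxin_qss(xs, q, variant=variant)
        m = mrna_qss(xs, q, variant=variant)
        f_m = translation_factor(xs, variant)
        f_t = dilution_factor(xs, variant)
        out = (q.alpha * a * xs + eps * q.delta_c * f_t * xs
               - eps * q.gamma * f_m * m) / (eps * q.delta_AT)
    else:
        out = np.array([_implicit_nullcline(xi, q, variant, which="x") for xi in xs])
    return out if np.ndim(x) else float(out[0])


def nullcline_y(x, q: NormalizedParameterSet, variant: ModelVariant = MINIMAL):
    """y on the y-nullcline (dy/dtau = 0): complex formation balances loss."""
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    eps = q.epsilon
    if not variant.dna_binding:
        a = antitoxin_qss(xs, q, variant=variant)
        f_t = dilution_factor(xs, variant)
        out = q.alpha * a * xs / (eps * (q.delta_c * f_t + q.delta_AT))
    else:
        out = np.array([_implicit_nullcline(xi, q, variant, which="y") for xi in xs])
    return out if np.ndim(x) else float(out[0])


def _implicit_nullcline(x: float, q: NormalizedParameterSet,
                        variant: ModelVariant, which: str) -> float:
    idx = 0 if which == "x" else 1

    def g(y):
        return rhs_reduced((x, y), q, variant)[idx]

    g0 = g(0.0)
    if g0 == 0.0:
        return 0.0
    hi = 1.0
    while g(hi) * g0 > 0:
        hi *= 4.0
        if hi > _YMAX:
            return np.nan
    return brentq(g, 0.0 if g0 != 0 else 1e-30, hi, xtol=1e-12, rtol=1e-12)


def _find_folds(x: np.ndarray, v: np.ndarray) -> list:
    """Local extrema of v(x) via slope sign changes, refined by bisection
    on the finite-difference slope."""
    folds = []
    dv = np.diff(v)
    s = np.sign(dv)
    for i in range(1, len(s)):
        if s[i] != 0 and s[i - 1] != 0 and s[i] != s[i - 1]:
            folds.append((float(x[i]), float(v[i])))
    return folds


def nullclines(q: NormalizedParameterSet,
               x_grid: Optional[np.ndarray] = None,
               variant: ModelVariant = MINIMAL) -> NullclineSet:
    """Sample both nullclines and locate the folds of NC(x)."""
    if x_grid is None:
        x_grid = np.logspace(-4, 2, 1200)
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0) or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be positive and strictly increasing")
    nc_x = nullcline_x(x_grid, q, variant)
    nc_y = nullcline_y(x_grid, q, variant)
    folds = _find_folds(x_grid, nc_x)
    return NullclineSet(x=x_grid, nc_x=nc_x, nc_y=nc_y, folds=folds)


# ---------------------------------------------------------------------------
# linearization


def jacobian_reduced(x: float, y: float, q: NormalizedParameterSet,
                     variant: ModelVariant = MINIMAL) -> np.ndarray:
    """Analytic Jacobian of the reduced system, chain-ruled through the
    quasi-steady-state expressions m(x[, y]) and a(x[, y])."""
    eps = q.epsilon
    n, kap = q.n, q.kappa
    xn, kn = x**n, kap**n
    H = xn / (xn + kn)
    dH = n * kn * x**(n - 1) / (xn + kn) ** 2 if x > 0 else (
        n * kn * 0.0 if n > 1 else kn / (xn + kn) ** 2)
    bracket = 1.0 + ((q.beta - 1.0) * H if variant.cleavage else 0.0)
    m0 = (1.0 / eps) / bracket           # y-independent part of m
    dm0 = (-(q.beta - 1.0) * dH / bracket * m0) if variant.cleavage else 0.0
    if variant.dna_binding:
        r = variant.dna_binding_r
        R = r / (r + y)
        dR = -R / (r + y)
    else:
        R, dR = 1.0, 0.0
    m = m0 * R
    m_x = dm0 * R
    m_y = m0 * dR

    f_m = translation_factor(x, variant)
    df_m = (-variant.B_m * f_m / (1.0 + variant.B_m * x)
            if variant.translation_inhibition else 0.0)
    f_t = dilution_factor(x, variant)
    df_t = (-variant.B_t * f_t / (1.0 + variant.B_t * x)
            if variant.growth_inhibition else 0.0)

    denom = q.alpha * x + q.delta_a
    a = q.gamma * f_m * m / denom
    a_x = q.gamma * (df_m * m + f_m * m_x) / denom - a * q.alpha / denom
    a_y = q.gamma * f_m * m_y / denom

    J = np.empty((2, 2))
    J[0, 0] = (-q.alpha * (a_x * x + a)
               + eps * (q.gamma * (df_m * m + f_m * m_x)
                        - q.delta_c * (f_t + df_t * x)))
    J[0, 1] = -q.alpha * a_y * x + eps * (q.gamma * f_m * m_y + q.delta_AT)
    J[1, 0] = q.alpha * (a_x * x + a) - eps * q.delta_c * df_t * y
    J[1, 1] = q.alpha * a_y * x - eps * (q.delta_c * f_t + q.delta_AT)
    return J


def _newton_polish(x0: float, y0: float, q: NormalizedParameterSet,
                   variant: ModelVariant, tol: float = 1e-13,
                   maxiter: int = 50) -> Optional[tuple]:
    x, y = x0, y0
    for _ in range(maxiter):
        f = rhs_reduced((max(x, 0.0), max(y, 0.0)), q, variant)
        if np.max(np.abs(f)) < tol:
            return x, y
        J = jacobian_reduced(max(x, 1e-300), max(y, 0.0), q, variant)
        try:
            dx, dy = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        x, y = x + dx, y + dy
        if not (np.isfinite(x) and np.isfinite(y)) or x < -1 or y < -1:
            return None
    return (x, y) if np.max(np.abs(rhs_reduced((max(x, 0), max(y, 0)), q, variant))) < 1e-10 else None


def find_fixed_points(q: NormalizedParameterSet,
                      variant: ModelVariant = MINIMAL,
                      x_grid: Optional[np.ndarray] = None) -> list:
    """All equilibria of the reduced system in the positive quadrant.

    Roots are bracketed where the two nullclines cross on a log-spaced x
    grid, then polished by Newton iteration with the analytic Jacobian and
    deduplicated (merging roots closer than 1e-6 relative).
    """
    if x_grid is None:
        x_grid = np.logspace(-3, 3, 600)
    g = nullcline_x(x_grid, q, variant) - nullcline_y(x_grid, q, variant)
    seeds = []
    for i in range(len(x_grid) - 1):
        if np.isfinite(g[i]) and np.isfinite(g[i + 1]) and g[i] * g[i + 1] < 0:
            xr = brentq(
                lambda xx: nullcline_x(xx, q, variant) - nullcline_y(xx, q, variant),
                x_grid[i], x_grid[i + 1], xtol=1e-14, rtol=1e-14)
            seeds.append((xr, nullcline_y(xr, q, variant)))
    roots = []
    for x0, y0 in seeds:
        sol = _newton_polish(x0, y0, q, variant)
        if sol is None:
            continue
        x, y = sol
        if x < 0 or y < 0:
            continue
        if any(abs(x - rx) <= 1e-6 * max(abs(x), abs(rx)) for rx, _ in
               [(fp.x, fp.y) for fp in roots]):
            continue
        J = jacobian_reduced(x, y, q, variant)
        roots.append(FixedPoint(
            x=x, y=y, jacobian=J, eigenvalues=np.linalg.eigvals(J),
            residual=float(np.max(np.abs(rhs_reduced((x, y), q, variant))))))
    if not roots:
        warnings.warn("no fixed point converged from any nullcline seed")
    return sorted(roots, key=lambda fp: fp.x)


@dataclass
class RegimeClassification:
    """Outcome of the regime decision with its supporting measurements."""

    label: str                       # monostable | excitable | oscillatory | unclassified
    fixed_point: Optional[FixedPoint]
    threshold_x: Optional[float] = None     # middle-branch x at y = y*
    excursion_ratio: Optional[float] = None  # max x of the probe / x*
    threshold_distance_sd: Optional[float] = None  # (x_th - x*) in noise SDs
    diagnostic: str = ""


def classify_regime(q: NormalizedParameterSet,
                    variant: ModelVariant = MINIMAL,
                    excursion_factor: float = 10.0,
                    noise_sd_cut: float = 1.0,
                    dm_anchor: float = DEFAULT_DM_ANCHOR,
                    x_grid: Optional[np.ndarray] = None) -> RegimeClassification:
    """Label the dynamics as monostable, excitable or oscillatory.

    An unstable fixed point means oscillatory.  For a stable fixed point
    the excitation threshold is the middle branch of NC(x) at the fixed
    point's y*; the regime is excitable when (i) a probe displaced to
    1.05x the threshold produces an excursion with max x >= 10 x*, and
    (ii) the threshold lies within ``noise_sd_cut`` intrinsic-noise
    standard deviations of the fixed point (counting statistics: sd in x
    units is sqrt(x* d_m/eps), i.e. sqrt of the molecule count at the
    fixed point, converted).  Condition (ii) operationalizes whether
    stochastic fluctuations can trigger the excursion that condition (i)
    certifies.
    """
    fps = find_fixed_points(q, variant, x_grid=x_grid)
    if len(fps) != 1:
        return RegimeClassification(
            label="unclassified", fixed_point=fps[0] if fps else None,
            diagnostic=f"expected exactly one fixed point, found {len(fps)}")
    fp = fps[0]
    if not fp.stable:
        return RegimeClassification(label="oscillatory", fixed_point=fp)

    ncs = nullclines(q, variant=variant)
    branch = ncs.threshold_branch
    if branch is None:
        return RegimeClassification(
            label="monostable", fixed_point=fp,
            diagnostic="NC(x) has no fold: no excitation threshold exists")
    x_lo, x_hi = branch

    def h(xx):
        return nullcline_x(xx, q, variant) - fp.y

    if h(x_lo) * h(x_hi) > 0 or x_hi <= fp.x:
        return RegimeClassification(
            label="monostable", fixed_point=fp,
            diagnostic="fixed point's y* does not intersect the threshold branch")
    x_th = brentq(h, max(x_lo, fp.x), x_hi, xtol=1e-12)

    from dataclasses import replace as _replace
    probe = integrate(_replace(variant, representation="reduced-2d"),
                      q, (1.05 * x_th, fp.y), t_end=50.0 / q.epsilon,
                      rtol=1e-8, n_points=4000)
    ratio = float(probe["x"].max() / fp.x)
    count_scale = q.epsilon / dm_anchor          # molecules per unit x
    sd_x = np.sqrt(fp.x / count_scale)           # Poisson sd, in x units
    dist_sd = (x_th - fp.x) / sd_x
    excitable = ratio >= excursion_factor and dist_sd <= noise_sd_cut
    return RegimeClassification(
        label="excitable" if excitable else "monostable",
        fixed_point=fp, threshold_x=x_th, excursion_ratio=ratio,
        threshold_distance_sd=float(dist_sd))


def flow_field(q: NormalizedParameterSet,
               x_grid: Sequence[float], y_grid: Sequence[float],
               variant: ModelVariant = MINIMAL):
    """(U, V, speed) of the reduced flow on the tensor grid, for quiver plots."""
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    if np.any(x_grid < 0) or np.any(y_grid < 0):
        raise ValueError("grid must be non-negative")
    U = np.empty((len(y_grid), len(x_grid)))
    V = np.empty_like(U)
    for i, yv in enumerate(y_grid):
        for j, xv in enumerate(x_grid):
            U[i, j], V[i, j] = rhs_reduced((xv, yv), q, variant)
    return U, V, np.hypot(U, V)
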