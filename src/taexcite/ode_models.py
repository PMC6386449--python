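"""Right-hand sides and integration for every deterministic model variant.

Variants of the TA module, in increasing dimensionality of the
deterministic description:

``reduced-2d``
    Toxin ``x`` and complex ``y`` only; mRNA and free antitoxin are slaved
    to the toxin level through a quasi-steady-state approximation (QSSA),
    valid because their dynamics are faster by factors of 1/epsilon.
``reduced-3d-tat``
    Adds the secondary complex ``z`` (TAT): one antitoxin neutralizing two
    toxins.  In-complex antitoxin degradation returns both toxins.
``normalized-4d``
    The full dimensionless system in (m, a, x, y).
``full-4d``
    The dimensional system in ([M], [A], [T], [AT]) molecules and seconds.

Optional mechanisms, each usable with any representation where it is
defined: toxin-induced mRNA cleavage (a Hill-modulated extra mRNA decay),
transcriptional repression by DNA-bound AT complex (factor r/(r + y)),
translational inhibition (every translation term scaled by
f_m(x) = S_m/(1 + B_m x)) and growth-rate inhibition (every dilution term
scaled by f_t(x) = S_t/(1 + B_t x)).  Biochemical degradation (d_m, d_a and
in-complex antitoxin degradation) is not a dilution and is never scaled by
f_t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    NormalizedParameterSet,
    ParameterSet,
    StressSchedule,
    apply_stress,
)

__all__ = [
    "ModelVariant",
    "Trajectory",
    "IntegrationError",
    "hill_cleavage",
    "translation_factor",
    "dilution_factor",
    "rhs_full",
    "rhs_normalized",
    "mrna_qss",
    "antitoxin_qss",
    "rhs_reduced",
    "rhs_tat",
    "rhs_for",
    "state_labels",
    "integrate",
    "to_normalized_state",
]

REPRESENTATIONS = ("reduced-2d", "reduced-3d-tat", "normalized-4d", "full-4d")


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails on a segment."""


@dataclass(frozen=True)
class ModelVariant:
    """Mechanism switches selecting one concrete model.

    ``dna_binding_r`` is the repression scale of the transcription factor
    r/(r + y), expressed in normalized complex units (the same units as
    ``y``); ``None`` disables transcriptional regulation.  The inhibition
    parameters ``B_m``/``B_t`` are per normalized toxin unit ``x``.
    """

    representation: str = "reduced-2d"
    cleavage: bool = True
    dna_binding_r: Optional[float] = None
    translation_inhibition: bool = False
    S_m: float = 1.0
    B_m: float = 0.0
    growth_inhibition: bool = False
    S_t: float = 1.0
    B_t: float = 0.0

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.representation!r}; "
                f"choose from {REPRESENTATIONS}")
        if self.dna_binding_r is not None and self.dna_binding_r <= 0:
            raise ValueError("dna_binding_r must be positive when enabled")
        for name in ("S_m", "B_m", "S_t", "B_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dna_binding(self) -> bool:
        return self.dna_binding_r is not None

    def label(self) -> str:
        bits = [self.representation,
                "cleavage" if self.cleavage else "no-cleavage"]
        if self.dna_binding:
            bits.append(f"dna-binding(r={self.dna_binding_r:g})")
        if self.translation_inhibition:
            bits.append("translation-inhibition")
        if self.growth_inhibition:
            bits.append("growth-inhibition")
        return "+".join(bits)


MINIMAL = ModelVariant()


def hill_cleavage(x, K, n):
    """Fraction of maximal mRNA cleavage at toxin level ``x``.

    ``x**n / (x**n + K**n)``: 0 at x = 0, 1/2 at the threshold x = K,
    saturating at 1; monotone increasing in x.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("toxin level must be non-negative")
    if K <= 0:
        raise ValueError("cleavage threshold must be positive")
    if n < 1:
        raise ValueError("Hill coefficient must be >= 1")
    xn = x**n
    out = xn / (xn + K**n)
    return out if out.ndim else float(out)


def translation_factor(x, variant: ModelVariant):
    """f_m(x) = S_m / (1 + B_m x) when translational inhibition is on, else 1."""
    if not variant.translation_inhibition:
        return np.ones_like(np.asarray(x, dtype=float)) if np.ndim(x) else 1.0
    return variant.S_m / (1.0 + variant.B_m * np.asarray(x, dtype=float))


def dilution_factor(x, variant: ModelVariant):
    """f_t(x) = S_t / (1 + B_t x) when growth-rate inhibition is on, else 1."""
    if not variant.growth_inhibition:
        return np.ones_like(np.asarray(x, dtype=float)) if np.ndim(x) else 1.0
    return variant.S_t / (1.0 + variant.B_t * np.asarray(x, dtype=float))


def _check_state(state) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if np.any(s < 0):
        raise ValueError(f"state must be non-negative, got {s}")
    return s


# ---------------------------------------------------------------------------
# dimensional 4D model


def rhs_full(state, p: ParameterSet, variant: ModelVariant = None):
    """Time derivatives of ([M], [A], [T], [AT]) in molecules per second.

    Transcription at r_F per gene copy, translation of antitoxin and toxin
    from the shared transcript, second-order association into the AT
    complex, first-order decays, and — with cleavage on — an extra mRNA
    decay of up to d_large switched by the toxin through a Hill function.
    In-complex antitoxin degradation (rate F*d_a) releases the toxin.
    """
    if variant is None:
        variant = ModelVariant(representation="full-4d")
    M, A, T, AT = _check_state(state)
    eps = p.epsilon
    # variant hooks; r and B coefficients are specified in normalized units
    repress = 1.0
    if variant.dna_binding:
        r_c = variant.dna_binding_r * eps / p.d_m  # molecules
        repress = r_c / (r_c + AT)
    x_norm = (p.d_m / eps) * T
    f_m = translation_factor(x_norm, variant)
    f_t = dilution_factor(x_norm, variant)
    cleave = p.d_large * hill_cleavage(T, p.K_t, p.n) if variant.cleavage else 0.0
    dM = p.r_F * p.D * repress - p.d_m * M - cleave * M
    dA = p.b_1 * f_m * M - p.a_T * A * T - p.d_a * A
    dT = p.b_2 * f_m * M - p.a_T * A * T - p.d_c * f_t * T + p.d_a2 * AT
    dAT = p.a_T * A * T - p.d_c * f_t * AT - p.d_a2 * AT
    return np.array([dM, dA, dT, dAT])


# ---------------------------------------------------------------------------
# normalized 4D model


def rhs_normalized(state, q: NormalizedParameterSet, variant: ModelVariant = None):
    """Derivatives of (m, a, x, y) with respect to tau = d_m * t."""
    if variant is None:
        variant = ModelVariant(representation="normalized-4d")
    m, a, x, y = _check_state(state)
    eps = q.epsilon
    repress = 1.0
    if variant.dna_binding:
        repress = variant.dna_binding_r / (variant.dna_binding_r + y)
    f_m = translation_factor(x, variant)
    f_t = dilution_factor(x, variant)
    cleave = (q.beta - 1.0) * hill_cleavage(x, q.kappa, q.n) if variant.cleavage else 0.0
    dm = repress / eps - m - cleave * m
    da = -q.alpha * a * x + q.gamma * f_m * m - q.delta_a * a
    dx = -q.alpha * a * x + eps * (q.gamma * f_m * m + q.delta_AT * y
                                   - q.delta_c * f_t * x)
    dy = q.alpha * a * x - eps * (q.delta_c * f_t + q.delta_AT) * y
    return np.array([dm, da, dx, dy])


# ---------------------------------------------------------------------------
# quasi-steady-state reduction


def mrna_qss(x, q: NormalizedParameterSet, y=0.0, variant: ModelVariant = MINIMAL):
    """Quasi-steady-state mRNA level m(x).

    Setting dm/dtau = 0 gives m = (1/eps) / (1 + (beta-1) x^n/(x^n+kappa^n));
    with DNA binding the transcription is further repressed by r/(r + y).
    """
    x = np.asarray(x, dtype=float)
    cleave = (q.beta - 1.0) * hill_cleavage(x, q.kappa, q.n) if variant.cleavage else 0.0
    m = (1.0 / q.epsilon) / (1.0 + cleave)
    if variant.dna_binding:
        m = m * variant.dna_binding_r / (variant.dna_binding_r + np.asarray(y, dtype=float))
    return m if np.ndim(m) else float(m)


def antitoxin_qss(x, q: NormalizedParameterSet, y=0.0,
                  variant: ModelVariant = MINIMAL):
    """Quasi-steady-state free antitoxin a(x) = gamma f_m(x) m(x) / (alpha x + delta_a)."""
    x = np.asarray(x, dtype=float)
    f_m = translation_factor(x, variant)
    a = q.gamma * f_m * mrna_qss(x, q, y=y, variant=variant) / (q.alpha * x + q.delta_a)
    return a if np.ndim(a) else float(a)


def rhs_reduced(state, q: NormalizedParameterSet, variant: ModelVariant = MINIMAL):
    """Slow dynamics of toxin x and complex y with m, a at quasi-steady state."""
    x, y = _check_state(state)
    eps = q.epsilon
    a = antitoxin_qss(x, q, y=y, variant=variant)
    m = mrna_qss(x, q, y=y, variant=variant)
    f_m = translation_factor(x, variant)
    f_t = dilution_factor(x, variant)
    dx = -q.alpha * a * x + eps * (q.gamma * f_m * m + q.delta_AT * y
                                   - q.delta_c * f_t * x)
    dy = q.alpha * a * x - eps * (q.delta_c * f_t + q.delta_AT) * y
    return np.array([dx, dy])


def rhs_tat(state, q: NormalizedParameterSet, variant: ModelVariant = None):
    """Reduced dynamics with the secondary complex z (TAT).

    Both complexes form with the same association constant alpha; the TAT
    complex decays by in-complex antitoxin degradation at rate delta_AT,
    releasing its two toxins, and the total complexed toxin c = y + 2z
    obeys the same balance as y does in the 2D model with the binding flux
    alpha (a + y) x.
    """
    if variant is None:
        variant = ModelVariant(representation="reduced-3d-tat")
    x, y, z = _check_state(state)
    eps = q.epsilon
    a = antitoxin_qss(x, q, y=y, variant=variant)
    m = mrna_qss(x, q, y=y, variant=variant)
    f_m = translation_factor(x, variant)
    f_t = dilution_factor(x, variant)
    dx = (-q.alpha * (a + y) * x
          + eps * (q.gamma * f_m * m + q.delta_AT * (y + 2.0 * z)
                   - q.delta_c * f_t * x))
    dy = q.alpha * (a - y) * x - eps * (q.delta_c * f_t + q.delta_AT) * y
    dz = q.alpha * x * y - eps * (q.delta_c * f_t + q.delta_AT) * z
    return np.array([dx, dy, dz])


_RHS = {
    "full-4d": rhs_full,
    "normalized-4d": rhs_normalized,
    "reduced-2d": rhs_reduced,
    "reduced-3d-tat": rhs_tat,
}

_LABELS = {
    "full-4d": ("M", "A", "T", "AT"),
    "normalized-4d": ("m", "a", "x", "y"),
    "reduced-2d": ("x", "y"),
    "reduced-3d-tat": ("x", "y", "z"),
}


def rhs_for(variant: ModelVariant):
    """The right-hand-side function for a variant's representation."""
    return _RHS[variant.representation]


def state_labels(variant: ModelVariant) -> tuple:
    return _LABELS[variant.representation]


def to_normalized_state(traj_states: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Map dimensional states (M, A, T, AT[, TAT]) onto (m, a, x, y[, z])."""
    s = np.asarray(traj_states, dtype=float)
    eps = p.epsilon
    scale = np.full(s.shape[-1], p.d_m / eps)
    scale[0] = p.d_m / (p.r_F * p.D * eps)
    return s * scale


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    """A deterministic or stochastic time series with its provenance.

    ``t`` is in seconds for dimensional models and in tau for normalized
    ones; ``states`` has one row per time point.
    """

    t: np.ndarray
    states: np.ndarray
    labels: tuple
    variant: Optional[ModelVariant] = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    @property
    def toxin(self) -> np.ndarray:
        for name in ("x", "T"):
            if name in self.labels:
                return self[name]
        raise KeyError("trajectory has no toxin component")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "time", self.t)
        return df

    def write_csv(self, path: Union[str, Path]) -> None:
        """Tidy CSV plus a JSON sidecar with the run metadata."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"labels": list(self.labels), **self.meta}
        if self.variant is not None:
            sidecar["variant"] = self.variant.label()
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str))


def integrate(variant: ModelVariant,
              params: Union[ParameterSet, NormalizedParameterSet],
              state0: Sequence[float],
              t_end: float,
              stress_schedule: Optional[StressSchedule] = None,
              rtol: float = 1e-8,
              atol: float = 1e-10,
              n_points: int = 2000,
              t_eval: Optional[np.ndarray] = None,
              method: str = "LSODA") -> Trajectory:
    """Integrate a model variant with a stiff-capable solver.

    The system mixes O(1/eps), O(1) and O(eps) timescales, so an
    implicit/auto-stiff method with tight tolerances is the default.
    Stress windows are honored by segment-wise integration with the
    parameters switched at each window boundary.  Tiny negative
    undershoots (within 10*atol) are clipped to zero; anything larger is
    reported as an integrator failure.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    state0 = _check_state(state0)
    labels = state_labels(variant)
    if len(state0) != len(labels):
        raise ValueError(f"state0 must have {len(labels)} components {labels}")
    rhs = rhs_for(variant)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    t_eval = np.asarray(t_eval, dtype=float)

    segments = (stress_schedule.segments(0.0, t_end) if stress_schedule is not None
                else [(0.0, t_end, 1.0, 1.0)])
    ts, ys = [], []
    y0 = state0.copy()
    for t0, t1, da_f, eps_f in segments:
        p_seg = apply_stress(params, da_f, eps_f) if (da_f != 1.0 or eps_f != 1.0) else params
        mask = (t_eval >= t0) & (t_eval <= t1)
        seg_eval = np.unique(np.concatenate([[t0], t_eval[mask], [t1]]))

        def f(t, s, _p=p_seg):
            return rhs(np.clip(s, 0.0, None), _p, variant)

        sol = solve_ivp(f, (t0, t1), y0, method=method, rtol=rtol, atol=atol,
                        t_eval=seg_eval, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"integration failed on segment [{t0:g}, {t1:g}]: {sol.message}")
        undershoot = -sol.y.min() if sol.y.min() < 0 else 0.0
        if undershoot > 10.0 * max(atol, 1e-300) + 1e3 * rtol * abs(sol.y).max():
            raise IntegrationError(
                f"state went negative by {undershoot:g} on segment [{t0:g}, {t1:g}]")
        y = np.clip(sol.y, 0.0, None)
        keep = np.isin(sol.t, t_eval[mask])
        ts.append(sol.t[keep])
        ys.append(y[:, keep])
        y0 = y[:, -1]

    t = np.concatenate(ts)
    states = np.concatenate(ys, axis=1).T
    # de-duplicate points shared by adjacent segments
    uniq = np.concatenate([[True], np.diff(t) > 0])
    return Trajectory(t=t[uniq], states=states[uniq], labels=labels,
                      variant=variant,
                      meta={"solver": method, "rtol": rtol, "atol": atol,
                            "t_end": t_end,
                            "params": params.to_dict(),
                            "stressed": stress_schedule is not None})
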