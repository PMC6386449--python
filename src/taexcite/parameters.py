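"""Model constants, unit conversions and the nondimensionalization.

The dimensional model of the *mazEF*-type toxin–antitoxin (TA) module is
written in molecules and seconds.  The normalized model rescales every
variable by the mRNA decay rate ``d_m`` and the translation-rate ratio
``epsilon = b_2/b_1`` so that most parameters become O(1):

======================  =======================================
normalized parameter     definition (dimensional)
======================  =======================================
``delta_c``              d_c / (d_m * epsilon)
``delta_a``              d_a / d_m
``delta_AT``             F * d_a / (d_m * epsilon)
``beta``                 d_large / d_m + 1
``alpha``                epsilon * a_T / d_m**2
``gamma``                r_F * D * b_1 / d_m
``epsilon``              b_2 / b_1
``kappa``                K_t * d_m / epsilon
======================  =======================================

State variables scale as ``m = (d_m / (r_F * epsilon)) * M``,
``a = (d_m/epsilon) * A``, ``x = (d_m/epsilon) * T``,
``y = (d_m/epsilon) * AT``, ``z = (d_m/epsilon) * TAT`` and
``tau = d_m * t``; rates expressed in s^-1 and counts in molecules are
treated as pure numbers throughout.

Stress (e.g. amino-acid starvation activating the Lon protease) is modeled
as a multiplicative increase of the antitoxin degradation rate ``d_a``
(hence ``delta_a`` and, with the ratio ``delta_AT/delta_a = F/epsilon``
fixed, ``delta_AT``) and/or of the relative toxin translation rate
``epsilon``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence, Union

import yaml

__all__ = [
    "AVOGADRO",
    "ParameterSet",
    "NormalizedParameterSet",
    "StressSchedule",
    "StressWindow",
    "volume_factor",
    "molar_rate_to_count_rate",
    "halflife_to_rate",
    "normalize",
    "denormalize",
    "apply_stress",
    "mazef_parameters",
    "mazef_normalized",
    "round_sig",
    "load_parameters",
    "save_parameters",
]

#: Molecules per mole, at the rounding conventionally combined with the
#: 0.6 um^3 E. coli cell volume (6.02e23 * 1000 l/m^3 * 0.6e-18 m^3
#: = 3.612e8 molecules per cell per molar, exactly).
AVOGADRO = 6.02e23

#: Default E. coli cell volume in m^3 (0.6 cubic micrometre).
DEFAULT_CELL_VOLUME = 0.6e-18


class InvalidParameterError(ValueError):
    """Raised when a parameter violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def volume_factor(v_cell: float = DEFAULT_CELL_VOLUME) -> float:
    """Molecules-per-cell per molar for a cell of volume ``v_cell`` (m^3).

    ``N_A * 1000 (l/m^3) * v_cell``; for the default 0.6 um^3 cell this is
    3.612e8 molecules/(cell*M).
    """
    _require(v_cell > 0, f"cell volume must be positive, got {v_cell}")
    return AVOGADRO * 1000.0 * v_cell


def molar_rate_to_count_rate(k: float, v_cell: float = DEFAULT_CELL_VOLUME) -> float:
    """Convert a bimolecular rate constant from M^-1 s^-1 to (molecule s)^-1."""
    _require(k >= 0, f"rate constant must be non-negative, got {k}")
    return k / volume_factor(v_cell)


def halflife_to_rate(t_half: float) -> float:
    """First-order decay rate (s^-1) from a half-life in seconds."""
    _require(t_half > 0, f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Used when reporting normalized parameters at table precision.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ParameterSet:
    """Dimensional model constants (seconds and molecules).

    ``d_a2``, the degradation rate of antitoxin sequestered in complex, is
    derived as ``F * d_a``: complex formation stabilizes the antitoxin, so
    ``F < 1``.
    """

    r_F: float = 0.121        # transcription rate per gene copy, s^-1
    d_m: float = 0.002        # basal mRNA decay rate, s^-1
    d_large: float = 0.198    # maximal cleavage-induced extra mRNA decay, s^-1
    K_t: float = 15.0         # toxin threshold for mRNA cleavage, molecules
    n: int = 2                # Hill coefficient of the cleavage response
    b_1: float = 0.122        # antitoxin translation rate, s^-1
    b_2: float = 0.009        # toxin translation rate, s^-1
    a_T: float = 1.32e5 / 3.612e8   # toxin-antitoxin association, (molecule s)^-1
    d_c: float = math.log(2.0) / 2400.0   # dilution from division, s^-1
    d_a: float = 8.0 * math.log(2.0) / 2400.0  # free antitoxin degradation, s^-1
    F: float = 0.1            # in-complex antitoxin degradation fraction
    D: float = 1.0            # gene copy number
    v_cell: float = DEFAULT_CELL_VOLUME  # cell volume, m^3

    def __post_init__(self) -> None:
        for name in ("r_F", "d_m", "d_large", "K_t", "b_1", "b_2", "a_T",
                     "d_c", "d_a", "D", "v_cell"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(0 < self.F <= 1, f"F must be in (0, 1], got {self.F}")
        _require(self.b_2 < self.b_1,
                 "antitoxin must be translated faster than toxin (b_2 < b_1)")
        _require(self.n >= 1 and float(self.n).is_integer(),
                 f"Hill coefficient must be an integer >= 1, got {self.n}")

    @property
    def d_a2(self) -> float:
        """Degradation rate of antitoxin within the AT complex, s^-1."""
        return self.F * self.d_a

    @property
    def epsilon(self) -> float:
        return self.b_2 / self.b_1

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class NormalizedParameterSet:
    """Dimensionless model constants of the normalized equations."""

    delta_c: float = 1.96
    delta_a: float = 1.16
    delta_AT: float = 0.1 * 1.16 / 0.0738
    beta: float = 100.0
    alpha: float = 6.74
    gamma: float = 7.38
    epsilon: float = 0.0738
    kappa: float = 0.407
    n: int = 2

    def __post_init__(self) -> None:
        for name in ("delta_c", "delta_a", "delta_AT", "alpha", "gamma", "kappa"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(0 < self.epsilon < 1,
                 f"epsilon = b_2/b_1 must be in (0, 1), got {self.epsilon}")
        _require(self.beta >= 1, f"beta must be >= 1, got {self.beta}")
        _require(self.n >= 1 and float(self.n).is_integer(),
                 f"Hill coefficient must be an integer >= 1, got {self.n}")

    @property
    def F_ratio(self) -> float:
        """The in-complex degradation fraction F = delta_AT * epsilon / delta_a."""
        return self.delta_AT * self.epsilon / self.delta_a

    def rounded(self, sig: int = 3) -> "NormalizedParameterSet":
        """Copy with every float field rounded to ``sig`` significant figures."""
        vals = {f.name: (round_sig(getattr(self, f.name), sig)
                         if f.name != "n" else self.n)
                for f in fields(self)}
        return NormalizedParameterSet(**vals)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def normalize(p: ParameterSet) -> NormalizedParameterSet:
    """Dimensionless parameters from the dimensional set.

    Obtained by substituting the variable scalings (see module docstring)
    into the dimensional equations and collecting coefficients.
    """
    eps = p.b_2 / p.b_1
    return NormalizedParameterSet(
        delta_c=p.d_c / (p.d_m * eps),
        delta_a=p.d_a / p.d_m,
        delta_AT=p.F * p.d_a / (p.d_m * eps),
        beta=p.d_large / p.d_m + 1.0,
        alpha=eps * p.a_T / p.d_m**2,
        gamma=p.r_F * p.D * p.b_1 / p.d_m,
        epsilon=eps,
        kappa=p.K_t * p.d_m / eps,
        n=p.n,
    )


def denormalize(np_: NormalizedParameterSet, d_m: float = 0.002,
                b_1: float = 0.122, D: float = 1.0,
                v_cell: float = DEFAULT_CELL_VOLUME) -> ParameterSet:
    """Dimensional set from a normalized one, given the dimensional anchors.

    The normalization collapses four rate scales onto three dimensionless
    groups, so ``d_m``, ``b_1`` and the copy number ``D`` must be supplied
    to invert it; ``normalize(denormalize(np_))`` is then the identity.
    """
    _require(d_m > 0 and b_1 > 0 and D > 0, "anchors d_m, b_1, D must be positive")
    eps = np_.epsilon
    return ParameterSet(
        r_F=np_.gamma * d_m / (D * b_1),
        d_m=d_m,
        d_large=(np_.beta - 1.0) * d_m,
        K_t=np_.kappa * eps / d_m,
        n=np_.n,
        b_1=b_1,
        b_2=eps * b_1,
        a_T=np_.alpha * d_m**2 / eps,
        d_c=np_.delta_c * d_m * eps,
        d_a=np_.delta_a * d_m,
        F=np_.F_ratio,
        D=D,
        v_cell=v_cell,
    )


@dataclass(frozen=True)
class StressWindow:
    """One stress episode: multiplicative factors applied on [t_start, t_end)."""

    t_start: float
    t_end: float
    da_factor: float = 1.0
    eps_factor: float = 1.0

    def __post_init__(self) -> None:
        _require(self.t_end > self.t_start,
                 f"window must have t_end > t_start, got [{self.t_start}, {self.t_end})")
        _require(self.da_factor > 0 and self.eps_factor > 0,
                 "stress factors must be strictly positive")


@dataclass(frozen=True)
class StressSchedule:
    """Piecewise-constant stress: non-overlapping, ordered windows.

    Times are in the units of the model the schedule is applied to
    (seconds for dimensional models, tau for normalized ones); parameters
    switch instantaneously at window boundaries.
    """

    windows: tuple = ()

    def __post_init__(self) -> None:
        wins = tuple(w if isinstance(w, StressWindow) else StressWindow(*w)
                     for w in self.windows)
        object.__setattr__(self, "windows", wins)
        for prev, cur in zip(wins, wins[1:]):
            _require(cur.t_start >= prev.t_end,
                     "stress windows must be ordered and non-overlapping")

    def factors_at(self, t: float) -> tuple[float, float]:
        """(da_factor, eps_factor) in effect at time ``t``."""
        for w in self.windows:
            if w.t_start <= t < w.t_end:
                return w.da_factor, w.eps_factor
        return 1.0, 1.0

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Sorted switch times strictly inside (t0, t1)."""
        pts = set()
        for w in self.windows:
            for t in (w.t_start, w.t_end):
                if t0 < t < t1:
                    pts.add(t)
        return sorted(pts)

    def segments(self, t0: float, t1: float) -> list[tuple[float, float, float, float]]:
        """(start, end, da_factor, eps_factor) covering [t0, t1]."""
        edges = [t0] + self.breakpoints(t0, t1) + [t1]
        out = []
        for a, b in zip(edges, edges[1:]):
            da_f, eps_f = self.factors_at(0.5 * (a + b))
            out.append((a, b, da_f, eps_f))
        return out

    def rescaled(self, factor: float) -> "StressSchedule":
        """Schedule with all times multiplied by ``factor`` (e.g. d_m for t -> tau)."""
        return StressSchedule(tuple(
            StressWindow(w.t_start * factor, w.t_end * factor, w.da_factor, w.eps_factor)
            for w in self.windows))


Params = Union[ParameterSet, NormalizedParameterSet]


def apply_stress(p: Params, da_factor: float = 1.0, eps_factor: float = 1.0) -> Params:
    """Scale the antitoxin degradation rate and/or the translation ratio.

    On a dimensional set this scales ``d_a`` (``d_a2`` follows through the
    fixed fraction ``F``) and ``b_2``.  On a normalized set it scales
    ``delta_a`` and ``epsilon`` and recomputes ``delta_AT`` keeping the
    fraction ``F = delta_AT * epsilon / delta_a`` fixed; all other
    dimensionless parameters are left untouched (stress in normalized space
    moves only the stress axes, as in the bifurcation diagrams).
    """
    _require(da_factor > 0 and eps_factor > 0, "stress factors must be positive")
    if isinstance(p, ParameterSet):
        return replace(p, d_a=p.d_a * da_factor, b_2=p.b_2 * eps_factor)
    F = p.F_ratio
    new_da = p.delta_a * da_factor
    new_eps = p.epsilon * eps_factor
    return replace(p, delta_a=new_da, epsilon=new_eps,
                   delta_AT=F * new_da / new_eps)


def mazef_parameters(d_c: str = "derived") -> ParameterSet:
    """The reference dimensional parameter set for the *mazEF* module.

    ``d_c`` selects how the dilution rate is fixed: ``"derived"`` uses
    ln2 / (40 min) = 2.888e-4 s^-1 (the value consistent with the
    normalized delta_c = 1.96), ``"printed"`` uses the rounded 0.00028 s^-1.
    Both correspond to a 40-minute cell cycle; d_a is 8 * ln2/(40 min) in
    either case.
    """
    if d_c == "derived":
        dc = math.log(2.0) / 2400.0
    elif d_c == "printed":
        dc = 0.00028
    else:
        raise InvalidParameterError(f"unknown d_c preset {d_c!r}")
    return ParameterSet(d_c=dc)


def mazef_normalized(d_c: str = "derived") -> NormalizedParameterSet:
    """Normalized reference set computed from :func:`mazef_parameters`."""
    return normalize(mazef_parameters(d_c=d_c))


# ---------------------------------------------------------------------------
# flat key-value config I/O

_TYPE_KEY = "parameter_type"


def save_parameters(p: Params, path: Union[str, Path]) -> None:
    """Write a parameter set as flat YAML/JSON keyed by its symbol names."""
    path = Path(path)
    data = {_TYPE_KEY: type(p).__name__, **p.to_dict()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: Union[str, Path]) -> Params:
    """Read a parameter set written by :func:`save_parameters`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    kind = data.pop(_TYPE_KEY, "ParameterSet")
    cls = {"ParameterSet": ParameterSet,
           "NormalizedParameterSet": NormalizedParameterSet}.get(kind)
    if cls is None:
        raise InvalidParameterError(f"unknown {_TYPE_KEY} {kind!r} in {path}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys {sorted(unknown)} in {path}")
    if "n" in data:
        data["n"] = int(data["n"])
    return cls(**data)
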