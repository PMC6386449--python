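"""Exact stochastic simulation (Gillespie direct method) of the TA module.

The reaction channels are constructed term-by-term from the deterministic
equations, so that the stoichiometry-weighted propensities reproduce the
ODE right-hand side exactly (mean-field consistency); this is what makes
the deterministic/stochastic comparison meaningful.  Counts are integer
molecules; bimolecular rate constants are per molecule per second (use the
volume factor to convert from molar units).

Minimal network (species M, A, T, AT):

    0 -> M                   r_F * D          [x r/(r+AT) with DNA binding]
    M -> M + A               b_1 * M          [x f_m(T) with transl. inhibition]
    M -> M + T               b_2 * M          [x f_m(T)]
    M -> 0                   d_m * M
    M -> 0                   d_large * H(T) * M     (toxin-induced cleavage)
    A + T -> AT              a_T * A * T
    A -> 0                   d_a * A
    AT -> T                  F * d_a * AT     (in-complex antitoxin decay)
    T -> 0                   d_c * T          [x f_t(T) with growth inhibition]
    AT -> 0                  d_c * AT         [x f_t(T)]

The secondary-complex variant adds AT + T -> TAT (a_T), TAT -> 2 T
(F * d_a) and TAT -> 0 (d_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from numba import njit

from .metrics import detect_excitations, merge_events
from .ode_models import MINIMAL, ModelVariant, rhs_for
from .parameters import (
    NormalizedParameterSet,
    ParameterSet,
    StressSchedule,
    apply_stress,
    denormalize,
)

__all__ = [
    "ReactionSystem",
    "StochasticTrajectory",
    "ExcitationStatistics",
    "build_reactions",
    "gillespie_run",
    "occupancy_heatmap",
    "excitation_stats",
    "excitation_stats_for",
    "stationary_counts",
]

# propensity modulation codes understood by the kernel
MOD_NONE, MOD_HILL, MOD_REPRESS, MOD_FM, MOD_FT = 0, 1, 2, 3, 4

_T_IDX = 2   # toxin column in the canonical species order
_AT_IDX = 3


@dataclass
class ReactionSystem:
    """Stoichiometry + structured propensities of one model variant.

    Each propensity is ``rate * count(sp1) * count(sp2) * modulation``
    with ``sp1``/``sp2`` species indices (-1 for none) and ``modulation``
    one of: none, the cleavage Hill function of the toxin count, the
    transcription repression r_c/(r_c + AT), or the inhibition factors
    f_m(T), f_t(T).
    """

    species: tuple
    stoich: np.ndarray        # (n_reactions, n_species) int
    rate: np.ndarray          # float, s^-1 (per molecule / per pair)
    sp1: np.ndarray           # int index or -1
    sp2: np.ndarray
    mod: np.ndarray           # modulation codes
    modpar: np.ndarray        # [K_t, n, r_c, S_m, B_m_c, S_t, B_t_c]
    names: list = field(default_factory=list)
    params: Optional[ParameterSet] = None
    variant: Optional[ModelVariant] = None

    def propensities(self, state: Sequence[float]) -> np.ndarray:
        """Propensity of every channel at a (possibly non-integer) state."""
        s = np.asarray(state, dtype=float)
        if np.any(s < 0):
            raise ValueError("state counts must be non-negative")
        K_t, n, r_c, S_m, B_m, S_t, B_t = self.modpar
        a = self.rate.copy()
        for i in range(len(a)):
            if self.sp1[i] >= 0:
                a[i] *= s[self.sp1[i]]
            if self.sp2[i] >= 0:
                a[i] *= s[self.sp2[i]]
            if self.mod[i] == MOD_HILL:
                T = s[_T_IDX]
                a[i] *= T**n / (T**n + K_t**n) if T > 0 else 0.0
            elif self.mod[i] == MOD_REPRESS:
                a[i] *= r_c / (r_c + s[_AT_IDX])
            elif self.mod[i] == MOD_FM:
                a[i] *= S_m / (1.0 + B_m * s[_T_IDX])
            elif self.mod[i] == MOD_FT:
                a[i] *= S_t / (1.0 + B_t * s[_T_IDX])
        return a

    def mean_field_rhs(self, state: Sequence[float]) -> np.ndarray:
        """Deterministic rate equations implied by the reaction network."""
        return self.propensities(state) @ self.stoich


def build_reactions(variant: ModelVariant, p: ParameterSet) -> ReactionSystem:
    """Reaction channels for a variant, in counts and per-second rates.

    The DNA-binding scale r and inhibition coefficients B_m/B_t of the
    variant are specified in normalized units and converted to counts here
    (r_c = r * eps / d_m, B_c = B * d_m / eps), so that the mean field of
    the stochastic model coincides with the deterministic equations.
    """
    tat = variant.representation == "reduced-3d-tat"
    species = ("M", "A", "T", "AT", "TAT") if tat else ("M", "A", "T", "AT")
    ns = len(species)
    eps = p.epsilon
    r_c = (variant.dna_binding_r * eps / p.d_m) if variant.dna_binding else 0.0
    modpar = np.array([p.K_t, float(p.n), r_c,
                       variant.S_m, variant.B_m * p.d_m / eps,
                       variant.S_t, variant.B_t * p.d_m / eps])

    rxns = []   # (name, delta dict, rate, sp1, sp2, mod)

    def add(name, delta, rate, sp1=-1, sp2=-1, mod=MOD_NONE):
        rxns.append((name, delta, rate, sp1, sp2, mod))

    i = {s: k for k, s in enumerate(species)}
    transcribe_mod = MOD_REPRESS if variant.dna_binding else MOD_NONE
    transl_mod = MOD_FM if variant.translation_inhibition else MOD_NONE
    dil_mod = MOD_FT if variant.growth_inhibition else MOD_NONE

    add("transcription", {"M": 1}, p.r_F * p.D, mod=transcribe_mod)
    add("translation_A", {"A": 1}, p.b_1, sp1=i["M"], mod=transl_mod)
    add("translation_T", {"T": 1}, p.b_2, sp1=i["M"], mod=transl_mod)
    add("mrna_decay", {"M": -1}, p.d_m, sp1=i["M"])
    if variant.cleavage:
        add("mrna_cleavage", {"M": -1}, p.d_large, sp1=i["M"], mod=MOD_HILL)
    add("binding_AT", {"A": -1, "T": -1, "AT": 1}, p.a_T, sp1=i["A"], sp2=i["T"])
    add("antitoxin_decay", {"A": -1}, p.d_a, sp1=i["A"])
    add("complex_antitoxin_decay", {"AT": -1, "T": 1}, p.d_a2, sp1=i["AT"])
    add("toxin_dilution", {"T": -1}, p.d_c, sp1=i["T"], mod=dil_mod)
    add("complex_dilution", {"AT": -1}, p.d_c, sp1=i["AT"], mod=dil_mod)
    if tat:
        add("binding_TAT", {"AT": -1, "T": -1, "TAT": 1}, p.a_T,
            sp1=i["AT"], sp2=i["T"])
        add("tat_antitoxin_decay", {"TAT": -1, "T": 2}, p.d_a2, sp1=i["TAT"])
        add("tat_dilution", {"TAT": -1}, p.d_c, sp1=i["TAT"], mod=dil_mod)

    stoich = np.zeros((len(rxns), ns), dtype=np.int64)
    rate = np.empty(len(rxns))
    sp1 = np.empty(len(rxns), dtype=np.int64)
    sp2 = np.empty(len(rxns), dtype=np.int64)
    mod = np.empty(len(rxns), dtype=np.int64)
    names = []
    for k, (name, delta, r, s1, s2, md) in enumerate(rxns):
        names.append(name)
        for sp, d in delta.items():
            stoich[k, i[sp]] = d
        rate[k], sp1[k], sp2[k], mod[k] = r, s1, s2, md
    return ReactionSystem(species=species, stoich=stoich, rate=rate,
                          sp1=sp1, sp2=sp2, mod=mod, modpar=modpar,
                          names=names, params=p, variant=variant)


@njit(cache=True)
def _direct_ssa(seed, t0, t_end, state, stoich, rate, sp1, sp2, mod, modpar,
                grid, out):
    """Direct-method SSA over [t0, t_end], recording the state at grid times.

    ``out[k]`` receives the state in effect at time ``grid[k]``.  Returns
    the number of reaction events executed.
    """
    np.random.seed(seed)
    K_t = modpar[0]
    n = modpar[1]
    r_c = modpar[2]
    S_m = modpar[3]
    B_m = modpar[4]
    S_t = modpar[5]
    B_t = modpar[6]
    n_r = rate.shape[0]
    props = np.empty(n_r)
    t = t0
    gi = 0
    n_events = 0
    while True:
        a_tot = 0.0
        for k in range(n_r):
            a = rate[k]
            if sp1[k] >= 0:
                a *= state[sp1[k]]
            if sp2[k] >= 0:
                a *= state[sp2[k]]
            m = mod[k]
            if m == 1:
                T = state[2]
                if T > 0:
                    Tn = T**n
                    a *= Tn / (Tn + K_t**n)
                else:
                    a = 0.0
            elif m == 2:
                a *= r_c / (r_c + state[3])
            elif m == 3:
                a *= S_m / (1.0 + B_m * state[2])
            elif m == 4:
                a *= S_t / (1.0 + B_t * state[2])
            props[k] = a
            a_tot += a
        if a_tot <= 0.0:
            while gi < grid.shape[0]:
                for s in range(state.shape[0]):
                    out[gi, s] = state[s]
                gi += 1
            return n_events
        u1 = np.random.random()
        while u1 <= 0.0:
            u1 = np.random.random()
        t_new = t - np.log(u1) / a_tot
        while gi < grid.shape[0] and grid[gi] < t_new:
            for s in range(state.shape[0]):
                out[gi, s] = state[s]
            gi += 1
        if t_new >= t_end:
            return n_events
        target = np.random.random() * a_tot
        acc = 0.0
        r = n_r - 1
        for k in range(n_r):
            acc += props[k]
            if acc >= target:
                r = k
                break
        for s in range(state.shape[0]):
            state[s] += stoich[r, s]
        t = t_new
        n_events += 1


@dataclass
class StochasticTrajectory:
    """Grid-sampled sample path of the jump process, with provenance."""

    t: np.ndarray
    counts: np.ndarray     # (n_times, n_species) integers
    species: tuple
    seed: int
    n_events: int = 0
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    @property
    def toxin(self) -> np.ndarray:
        return self["T"]


def gillespie_run(rs: ReactionSystem,
                  init_counts: Sequence[int],
                  t_end: float,
                  seed: int,
                  stress_schedule: Optional[StressSchedule] = None,
                  dt: float = 2.0) -> StochasticTrajectory:
    """One statistically exact sample path, reproducible given ``seed``.

    Stress windows are honored by rebuilding the channel rates from the
    stressed parameter set at each window boundary; the exponential clock
    restarts at each switch (valid, as the exponential is memoryless only
    at fixed rates).  The state is recorded every ``dt`` seconds.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    init = np.asarray(init_counts, dtype=np.int64)
    if np.any(init < 0) or len(init) != len(rs.species):
        raise ValueError(f"init_counts must be {len(rs.species)} non-negative integers")
    if stress_schedule is not None and rs.params is None:
        raise ValueError("stress requires a ReactionSystem built from a ParameterSet")
    segments = (stress_schedule.segments(0.0, t_end) if stress_schedule is not None
                else [(0.0, t_end, 1.0, 1.0)])
    seg_seeds = np.random.SeedSequence(seed).generate_state(len(segments)) % (2**31 - 1)
    grid = np.append(np.arange(0.0, t_end, dt), t_end)
    counts = np.empty((len(grid), len(rs.species)), dtype=np.int64)
    state = init.copy()
    n_events = 0
    for (t0, t1, da_f, eps_f), sseed in zip(segments, seg_seeds):
        seg_rs = rs
        if da_f != 1.0 or eps_f != 1.0:
            seg_rs = build_reactions(rs.variant, apply_stress(rs.params, da_f, eps_f))
        mask = (grid >= t0) & (grid < t1)
        out = np.empty((int(mask.sum()), len(rs.species)), dtype=np.int64)
        n_events += _direct_ssa(np.int64(sseed), t0, t1, state,
                                seg_rs.stoich, seg_rs.rate, seg_rs.sp1,
                                seg_rs.sp2, seg_rs.mod, seg_rs.modpar,
                                grid[mask], out)
        counts[mask] = out
    counts[-1] = state
    return StochasticTrajectory(
        t=grid, counts=counts, species=rs.species, seed=seed,
        n_events=n_events,
        meta={"t_end": t_end, "dt": dt,
              "stressed": stress_schedule is not None,
              "params": rs.params.to_dict() if rs.params else None})


def stationary_counts(q_or_p, variant: ModelVariant = MINIMAL,
                      dm_anchor: float = 0.002, b1_anchor: float = 0.122):
    """Deterministic fixed point rounded to integer molecule counts.

    The default initial condition of the stochastic runs: the system
    starts near its equilibrium.  Accepts a normalized or dimensional
    parameter set; returns (ParameterSet, counts).
    """
    from .phase_plane import find_fixed_points
    from .ode_models import antitoxin_qss, mrna_qss

    if isinstance(q_or_p, NormalizedParameterSet):
        q = q_or_p
        p = denormalize(q, d_m=dm_anchor, b_1=b1_anchor)
    else:
        p = q_or_p
        from .parameters import normalize
        q = normalize(p)
    fps = find_fixed_points(q, variant)
    if not fps:
        raise RuntimeError("no deterministic fixed point found")
    fp = fps[0]
    scale = p.epsilon / p.d_m     # molecules per normalized unit
    m = mrna_qss(fp.x, q, y=fp.y, variant=variant)
    a = antitoxin_qss(fp.x, q, y=fp.y, variant=variant)
    counts = [m * p.r_F * p.epsilon / p.d_m, a * scale, fp.x * scale, fp.y * scale]
    if variant.representation == "reduced-3d-tat":
        counts.append(0.0)
    return p, np.maximum(np.round(counts).astype(np.int64), 0)


def occupancy_heatmap(trajs: Sequence[StochasticTrajectory],
                      x_edges: np.ndarray, y_edges: np.ndarray,
                      scale: Optional[float] = None):
    """Time-weighted occupancy of the (x, y) = scaled (T, AT) plane.

    Each grid sample contributes its holding time ``dt``; the total mass
    over all bins (including out-of-range states, which histogram2d drops)
    equals the total simulated time.  With log-spaced edges, zero counts
    fall outside the first bin and are therefore not shown.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    H = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for tr in trajs:
        if scale is None:
            p = tr.meta.get("params")
            sc = (p["d_m"] / (p["b_2"] / p["b_1"])) if p else 1.0
        else:
            sc = scale
        dt = float(np.median(np.diff(tr.t)))
        h, _, _ = np.histogram2d(tr["T"] * sc, tr["AT"] * sc,
                                 bins=[x_edges, y_edges],
                                 weights=np.full(len(tr.t), dt))
        H += h
    return H


@dataclass
class ExcitationStatistics:
    """Pooled excitation-event statistics across stochastic runs."""

    n_events: int
    mean_excitation_time: float      # seconds (0 when no events)
    sd_excitation_time: Optional[float]
    mean_period: Optional[float]     # mean onset-to-onset interval, seconds
    sd_period: Optional[float]
    mean_amplitude: Optional[float]  # molecules


def excitation_stats(trajs: Sequence[StochasticTrajectory],
                     K_t: float,
                     min_gap: float = 0.0,
                     min_duration: float = 0.0) -> ExcitationStatistics:
    """Excitation times/periods/amplitudes pooled over trajectories.

    Events are maximal intervals with the toxin count above ``K_t``;
    partial events at the run edges are discarded.  ``min_gap`` merges
    events split by sub-threshold shot-noise dips shorter than the mRNA
    recovery time (see :func:`taexcite.metrics.merge_events`); the raw
    crossing intervals are obtained with ``min_gap=0``.
    """
    durations, periods, peaks = [], [], []
    for tr in trajs:
        ev = detect_excitations((tr.t, tr["T"].astype(float)), K_t,
                                source="ssa", interpolate=False)
        ev = merge_events(ev, min_gap=min_gap, min_duration=min_duration)
        durations += [e.duration for e in ev]
        peaks += [e.peak for e in ev]
        periods += list(np.diff([e.onset for e in ev]))
    if not durations:
        return ExcitationStatistics(0, 0.0, None, None, None, None)
    return ExcitationStatistics(
        n_events=len(durations),
        mean_excitation_time=float(np.mean(durations)),
        sd_excitation_time=float(np.std(durations, ddof=1)) if len(durations) > 1 else None,
        mean_period=float(np.mean(periods)) if periods else None,
        sd_period=float(np.std(periods, ddof=1)) if len(periods) > 1 else None,
        mean_amplitude=float(np.mean(peaks)))


def excitation_stats_for(q: NormalizedParameterSet,
                         variant: ModelVariant = MINIMAL,
                         seeds: Sequence[int] = (0, 1, 2),
                         t_end: float = 2.0e5,
                         dt: float = 2.0,
                         dm_anchor: float = 0.002,
                         min_gap: Optional[float] = None) -> ExcitationStatistics:
    """Run the SSA for several seeds at a normalized parameter point and
    pool the excitation statistics (times in seconds).

    ``min_gap`` defaults to one mRNA lifetime 1/d_m: a shorter
    below-threshold dip cannot be a genuine quiescent interval because the
    cleaved transcript pool has not recovered.
    """
    p, init = stationary_counts(q, variant, dm_anchor=dm_anchor)
    if min_gap is None:
        min_gap = 1.0 / p.d_m
    rs = build_reactions(variant, p)
    trajs = [gillespie_run(rs, init, t_end=t_end, seed=int(s), dt=dt)
             for s in seeds]
    return excitation_stats(trajs, p.K_t, min_gap=min_gap)
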