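"""Excitation detection, the analytic excursion solution, and comparisons.

An *excitation* is a maximal interval during which the free toxin level
exceeds the mRNA-cleavage threshold (kappa in normalized units, K_t in
molecules); its duration is the *excitation time*.  During the excursion,
far above threshold, production is shut off and the toxin balance reduces
to a pair of exponentials fed by complex disassembly:

    x(tau) = (x0 + y0) exp(-eps delta_c tau) - y0 exp(-eps (delta_c + delta_AT) tau)

which fixes the shape of the decaying flank of a spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ode_models import Trajectory
from .parameters import NormalizedParameterSet

__all__ = [
    "ExcitationEvent",
    "detect_excitations",
    "merge_events",
    "analytic_excitation",
    "compare_excursion",
    "ExcursionComparison",
    "events_to_dataframe",
]


@dataclass(frozen=True)
class ExcitationEvent:
    """One threshold-crossing episode of the toxin level."""

    onset: float       # first upward crossing time
    duration: float    # time spent above threshold
    peak: float        # maximum toxin level during the event
    source: str = "ode"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("excitation duration must be positive")
        if self.peak < 0:
            raise ValueError("peak must be non-negative")


def _crossing(t0, v0, t1, v1, threshold):
    """Linear interpolation of the crossing time between two samples."""
    return t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)


def detect_excitations(traj: Union[Trajectory, tuple],
                       threshold: float,
                       source: str = "ode",
                       interpolate: bool = True) -> List[ExcitationEvent]:
    """Maximal above-threshold intervals of the toxin series.

    For sampled deterministic output the crossing times are located by
    linear interpolation between samples; for event-sampled stochastic
    output pass ``interpolate=False`` so crossings coincide with the jump
    times.  Partial events at either edge of the trajectory are discarded
    (their duration is undefined).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(traj, Trajectory):
        t, x = traj.t, traj.toxin
    else:
        t, x = np.asarray(traj[0], float), np.asarray(traj[1], float)
    above = x > threshold
    events: List[ExcitationEvent] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        # [i, j) is an above-threshold run
        if i > 0 and j < n:   # complete event only
            if interpolate:
                onset = _crossing(t[i - 1], x[i - 1], t[i], x[i], threshold)
                offset = _crossing(t[j - 1], x[j - 1], t[j], x[j], threshold)
            else:
                onset, offset = t[i], t[j]
            events.append(ExcitationEvent(
                onset=float(onset), duration=float(offset - onset),
                peak=float(x[i:j].max()), source=source))
        i = j
    return events


def merge_events(events: Sequence[ExcitationEvent],
                 min_gap: float = 0.0,
                 min_duration: float = 0.0) -> List[ExcitationEvent]:
    """Merge events separated by sub-``min_gap`` dips; drop short blips.

    Stochastic sample paths graze the threshold, splitting one physical
    toxin spike into many brief crossings.  A below-threshold dip can only
    terminate a spike once the cleaved mRNA pool has recovered, which
    takes on the order of one mRNA lifetime; gaps shorter than that are
    fluctuations within a single excitation and are merged.  Events
    shorter than ``min_duration`` after merging are discarded.
    """
    merged: List[list] = []
    for e in sorted(events, key=lambda e: e.onset):
        if merged and e.onset - (merged[-1][0] + merged[-1][1]) < min_gap:
            onset, dur, peak, src = merged[-1]
            merged[-1] = [onset, e.onset + e.duration - onset,
                          max(peak, e.peak), src]
        else:
            merged.append([e.onset, e.duration, e.peak, e.source])
    return [ExcitationEvent(onset=o, duration=d, peak=p, source=s)
            for o, d, p, s in merged if d >= min_duration]


def analytic_excitation(x0: float, y0: float, q: NormalizedParameterSet,
                        tau_grid: Sequence[float]) -> np.ndarray:
    """Closed-form toxin course during an excursion far above threshold.

    Valid while x >> kappa (production off): the toxin pool decays by
    dilution while being replenished by complex disassembly at rate
    delta_AT.
    """
    if x0 < 0 or y0 < 0:
        raise ValueError("initial levels must be non-negative")
    tau = np.asarray(tau_grid, dtype=float)
    e = q.epsilon
    return ((x0 + y0) * np.exp(-e * q.delta_c * tau)
            - y0 * np.exp(-e * (q.delta_c + q.delta_AT) * tau))


@dataclass
class ExcursionComparison:
    """Discrepancy between two toxin excursions over the super-threshold phase."""

    max_relative_deviation: Optional[float]
    excitation_time_a: Optional[float]
    excitation_time_b: Optional[float]
    overlap: bool

    @property
    def excitation_time_difference(self) -> Optional[float]:
        if self.excitation_time_a is None or self.excitation_time_b is None:
            return None
        return abs(self.excitation_time_a - self.excitation_time_b)


def compare_excursion(t_a, x_a, t_b, x_b, threshold: float,
                      decaying_flank_only: bool = False) -> ExcursionComparison:
    """Compare two toxin traces where both are above ``threshold``.

    The second trace is resampled onto the first one's time base.  With
    ``decaying_flank_only`` the comparison is restricted to times after
    the reference peak, where the closed-form excursion applies.
    """
    t_a = np.asarray(t_a, float)
    x_a = np.asarray(x_a, float)
    xb_on_a = np.interp(t_a, np.asarray(t_b, float), np.asarray(x_b, float))
    mask = (x_a > threshold) & (xb_on_a > threshold)
    ev_a = detect_excitations((t_a, x_a), threshold)
    ev_b = detect_excitations((np.asarray(t_b, float), np.asarray(x_b, float)), threshold)
    ta = ev_a[0].duration if ev_a else None
    tb = ev_b[0].duration if ev_b else None
    if decaying_flank_only and mask.any():
        mask &= t_a >= t_a[np.argmax(np.where(mask, x_a, -np.inf))]
    if not mask.any():
        return ExcursionComparison(None, ta, tb, overlap=False)
    dev = np.abs(x_a[mask] - xb_on_a[mask]) / np.abs(x_a[mask])
    return ExcursionComparison(float(dev.max()), ta, tb, overlap=True)


def events_to_dataframe(events: Sequence[ExcitationEvent],
                        scenario: str = "") -> pd.DataFrame:
    df = pd.DataFrame([{"onset": e.onset, "duration": e.duration,
                        "peak": e.peak, "source": e.source} for e in events])
    if scenario:
        df["scenario"] = scenario
    return df
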