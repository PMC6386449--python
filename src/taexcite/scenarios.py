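"""Bundled scenarios: the named parameterizations studied with this model.

Each scenario packages parameter sets, model variants, engines and seeds
into a runnable job bundle whose outputs (tidy CSVs plus a provenance
manifest) reproduce one of the canonical analyses: stochastic stress
episodes, a triggered excitation with its phase plane and closed-form
overlay, the three dynamical regimes, bifurcation diagrams and stress
sweeps, the secondary-complex and DNA-binding variants, and the
growth-rate/translational-inhibition variants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from . import bifurcation as bif
from . import metrics, phase_plane, ssa
from .ode_models import MINIMAL, ModelVariant, integrate
from .parameters import (
    NormalizedParameterSet,
    StressSchedule,
    mazef_normalized,
    mazef_parameters,
)

__all__ = ["Scenario", "list_scenarios", "get_scenario", "run_scenario",
           "ScenarioConfigError"]

DM_ANCHOR = 0.002   # s^-1, reference mRNA decay anchoring tau ~ seconds


class ScenarioConfigError(ValueError):
    """A scenario configuration failed validation."""


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified runnable analysis."""

    name: str
    description: str
    provenance: str                      # where the parameter choices come from
    runner: Callable = field(repr=False, compare=False, default=None)
    extras: dict = field(default_factory=dict)
    seeds: tuple = (0, 1, 2)

    def validate(self) -> None:
        if self.runner is None or not callable(self.runner):
            raise ScenarioConfigError(f"scenario {self.name!r} has no runner")
        if not self.seeds:
            raise ScenarioConfigError(f"scenario {self.name!r} has no seeds")


def _q_at(delta_a: Optional[float] = None, epsilon: Optional[float] = None,
          n: Optional[int] = None) -> NormalizedParameterSet:
    q = mazef_normalized()
    if delta_a is not None:
        q = bif.with_stress_parameter(q, "delta_a", delta_a)
    if epsilon is not None:
        q = bif.with_stress_parameter(q, "epsilon", epsilon)
    if n is not None:
        q = replace(q, n=n)
    return q


def _write(df: pd.DataFrame, outdir: Path, name: str, written: dict) -> None:
    path = outdir / name
    df.to_csv(path, index=False)
    written[name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _ssa_trace(q, variant, seed, t_end, stress=None, dt=5.0):
    p, init = ssa.stationary_counts(q, variant, dm_anchor=DM_ANCHOR)
    rs = ssa.build_reactions(variant, p)
    tr = ssa.gillespie_run(rs, init, t_end=t_end, seed=seed,
                           stress_schedule=stress, dt=dt)
    df = pd.DataFrame(tr.counts, columns=list(tr.species))
    df.insert(0, "time", tr.t)
    df["seed"] = seed
    return tr, df, p


# --- runners ---------------------------------------------------------------


def _run_stress_episodes(sc, outdir, written, seed0):
    """Stochastic stress episodes: excitations require mRNA cleavage."""
    t_end = 3.0e5
    stress = StressSchedule(((1.0e5, 2.0e5, 2.0, 1.0),))
    variants = {
        "minimal": ModelVariant(),
        "minimal_no_cleavage": ModelVariant(cleavage=False),
        "tat_dna": ModelVariant(representation="reduced-3d-tat",
                                dna_binding_r=sc.extras["r"]),
        "full": ModelVariant(representation="reduced-3d-tat",
                             dna_binding_r=sc.extras["r"],
                             translation_inhibition=True, growth_inhibition=True,
                             B_m=sc.extras["b_m"], B_t=sc.extras["b_t"],
                             S_m=sc.extras["s_m"], S_t=sc.extras["s_t"]),
    }
    summary = []
    for label, var in variants.items():
        for k, s in enumerate(sc.seeds):
            tr, df, p = _ssa_trace(_q_at(), var, seed0 + s, t_end, stress=stress)
            if k == 0:
                _write(df, outdir, f"trace_{label}.csv", written)
            stats = ssa.excitation_stats([tr], p.K_t, min_gap=1.0 / p.d_m)
            summary.append({"variant": label, "seed": seed0 + s,
                            "n_events": stats.n_events,
                            "mean_excitation_time_s": stats.mean_excitation_time})
    _write(pd.DataFrame(summary), outdir, "excitation_summary.csv", written)


def _run_triggered_excitation(sc, outdir, written, seed0):
    """One super-threshold kick: reduced vs full model vs closed form."""
    q = _q_at(delta_a=sc.extras["delta_a"])
    fp = phase_plane.find_fixed_points(q)[0]
    # below the cleavage threshold kappa but beyond the excitation threshold
    # branch, so the upward crossing (and hence the full event) is recorded
    kick = (0.9 * q.kappa, fp.y)
    tau_end = 40.0
    red = integrate(ModelVariant(), q, kick, t_end=tau_end, n_points=4000)
    from .ode_models import antitoxin_qss, mrna_qss
    full0 = (mrna_qss(kick[0], q), antitoxin_qss(kick[0], q), kick[0], kick[1])
    full = integrate(ModelVariant(representation="normalized-4d"), q, full0,
                     t_end=tau_end, n_points=4000)
    ipk = int(np.argmax(red["x"]))
    tau = red.t - red.t[ipk]
    ana = metrics.analytic_excitation(red["x"][ipk], red["y"][ipk], q,
                                      np.clip(tau, 0, None))
    df = red.to_dataframe()
    df["x_full"] = np.interp(red.t, full.t, full["x"])
    df["y_full"] = np.interp(red.t, full.t, full["y"])
    df["x_analytic"] = np.where(tau >= 0, ana, np.nan)
    _write(df, outdir, "excitation_traces.csv", written)
    ncs = phase_plane.nullclines(q)
    _write(ncs.to_dataframe(), outdir, "nullclines.csv", written)
    events = metrics.detect_excitations(red, q.kappa)
    _write(metrics.events_to_dataframe(events, sc.name), outdir,
           "events.csv", written)


def _run_three_regimes(sc, outdir, written, seed0):
    """Monostable / excitable / oscillatory at delta_a = 1, 2, 3."""
    rows = []
    for da in (1.0, 2.0, 3.0):
        q = _q_at(delta_a=da)
        rc = phase_plane.classify_regime(q)
        rows.append({"delta_a": da, "regime": rc.label,
                     "x_star": rc.fixed_point.x, "y_star": rc.fixed_point.y,
                     "max_re_eig": float(rc.fixed_point.eigenvalues.real.max())})
        _write(phase_plane.nullclines(q).to_dataframe(), outdir,
               f"nullclines_da{da:g}.csv", written)
        tr, df, p = _ssa_trace(q, MINIMAL, seed0 + sc.seeds[0], 2.0e5)
        _write(df, outdir, f"ssa_trace_da{da:g}.csv", written)
    _write(pd.DataFrame(rows), outdir, "regimes.csv", written)


def _run_bifurcation(sc, outdir, written, seed0):
    """Branches over delta_a (eps fixed) and eps (delta_a fixed) + sweep."""
    q = mazef_normalized()
    br_da = bif.continue_branch(q, "delta_a", np.linspace(1.0, 3.5, 60))
    _write(br_da.to_dataframe(), outdir, "branch_delta_a.csv", written)
    br_eps = bif.continue_branch(_q_at(delta_a=2.0), "epsilon",
                                 np.linspace(0.02, 0.2, 60))
    _write(br_eps.to_dataframe(), outdir, "branch_epsilon.csv", written)
    hopf = [{"param": h.param, "value": h.value, "criticality": h.criticality,
             "onset_period": h.onset_period}
            for h in br_da.hopf_points + br_eps.hopf_points]
    _write(pd.DataFrame(hopf), outdir, "hopf_points.csv", written)
    sweep = bif.sweep_excitation_time(q, np.linspace(1.5, 3.5, 5),
                                      np.linspace(0.05, 0.15, 5),
                                      engine="ode", tau_end=2000.0)
    _write(sweep, outdir, "excitation_time_map.csv", written)


def _run_complex_variants(sc, outdir, written, seed0):
    """Secondary complex (TAT) and DNA binding at low and high stress."""
    r = sc.extras["r"]
    variants = {
        "minimal": ModelVariant(),
        "tat": ModelVariant(representation="reduced-3d-tat"),
        "dna": ModelVariant(dna_binding_r=r),
        "tat_dna": ModelVariant(representation="reduced-3d-tat", dna_binding_r=r),
    }
    rows = []
    for da in sc.extras["delta_a"]:
        q = _q_at(delta_a=da)
        for label, var in variants.items():
            st = ssa.excitation_stats_for(q, var, seeds=[seed0 + s for s in sc.seeds],
                                          t_end=2.0e5, dt=5.0)
            rows.append({"delta_a": da, "variant": label,
                         "n_events": st.n_events,
                         "mean_excitation_time_s": st.mean_excitation_time,
                         "mean_period_s": st.mean_period})
    _write(pd.DataFrame(rows), outdir, "variant_excitations.csv", written)


def _run_inhibition(sc, outdir, written, seed0):
    """Growth-rate and translational inhibition for n = 1 and n = 2."""
    rows = []
    for n in (1, 2):
        for label, var in {
            "plain": ModelVariant(),
            "translation": ModelVariant(translation_inhibition=True,
                                        S_m=sc.extras["S_m"], B_m=sc.extras["B_m"]),
            "translation_growth": ModelVariant(
                translation_inhibition=True, growth_inhibition=True,
                S_m=sc.extras["S_m"], B_m=sc.extras["B_m"],
                S_t=sc.extras["S_t"], B_t=sc.extras["B_t"]),
        }.items():
            q = _q_at(delta_a=sc.extras["delta_a"], n=n)
            rc = phase_plane.classify_regime(q, variant=var)
            row = {"n": n, "variant": label, "regime": rc.label}
            if rc.label in ("excitable", "oscillatory"):
                m = bif.limit_cycle_metrics(q, var, tau_end=2000.0)
                row.update(excitation_time=m.excitation_time,
                           period=m.period, amplitude=m.amplitude)
            rows.append(row)
    _write(pd.DataFrame(rows), outdir, "inhibition_regimes.csv", written)


def _build_catalog() -> Dict[str, Scenario]:
    return {
        "fig1": Scenario(
            name="fig1",
            description=("Gillespie stress episodes (antitoxin degradation "
                         "doubled in the middle third): minimal system with "
                         "and without mRNA cleavage, with TAT + DNA binding, "
                         "and with growth/translation inhibition"),
            provenance=("stress factor two via d_a = 0.00462 /s; caption "
                        "extras c1, c2 recorded verbatim (roles defined in "
                        "unavailable supplementary material; unused)"),
            runner=_run_stress_episodes,
            extras={"c_1": 1.28e-5, "c_2": 0.00231, "c_units": "s^-1",
                    "c_status": "unused-opaque",
                    "s_t": 1.0, "s_m": 1.0, "b_t": 0.027, "b_m": 0.027,
                    "r": 4.9},
            seeds=(0, 1, 2)),
        "fig2": Scenario(
            name="fig2",
            description=("A single triggered toxin excitation: reduced 2D vs "
                         "normalized 4D trajectories, nullclines, and the "
                         "closed-form excursion overlay"),
            provenance="delta_a = 1.5, eps = 0.074",
            runner=_run_triggered_excitation,
            extras={"delta_a": 1.5},
            seeds=(0,)),
        "fig3": Scenario(
            name="fig3",
            description=("The three regimes at delta_a = 1 (monostable), 2 "
                         "(excitable), 3 (oscillatory): classification, "
                         "nullclines and SSA traces"),
            provenance="delta_a in {1, 2, 3}, eps = 0.0738",
            runner=_run_three_regimes,
            extras={"delta_a": [1.0, 2.0, 3.0]},
            seeds=(0,)),
        "fig4": Scenario(
            name="fig4",
            description=("Bifurcation diagrams over delta_a (eps = 0.0738) "
                         "and eps (delta_a = 2), Hopf points, and an ODE "
                         "excitation-time map"),
            provenance="delta_a branch at eps = 0.074; eps branch at delta_a = 2",
            runner=_run_bifurcation,
            extras={},
            seeds=(0,)),
        "fig5": Scenario(
            name="fig5",
            description=("Secondary complex TAT and DNA binding (r = 4.9) at "
                         "low (delta_a = 1.5) and high (delta_a = 3) stress: "
                         "stochastic excitation counts per variant"),
            provenance="r = 4.9 binding parameter; delta_a in {1.5, 3}",
            runner=_run_complex_variants,
            extras={"r": 4.9, "delta_a": [1.5, 3.0]},
            seeds=(0, 1, 2)),
        "fig6": Scenario(
            name="fig6",
            description=("Growth-rate and translational inhibition for Hill "
                         "coefficients n = 1 and n = 2: regime and excitation "
                         "time per variant"),
            provenance="B_t = B_m = S_t = S_m = 1; delta_a = 3",
            runner=_run_inhibition,
            extras={"S_m": 1.0, "B_m": 1.0, "S_t": 1.0, "B_t": 1.0,
                    "delta_a": 3.0},
            seeds=(0,)),
    }


_CATALOG = _build_catalog()


def list_scenarios() -> Dict[str, Scenario]:
    """The catalog of bundled scenarios, keyed by name."""
    return dict(_CATALOG)


def get_scenario(name: str) -> Scenario:
    try:
        return _CATALOG[name]
    except KeyError:
        raise ScenarioConfigError(
            f"unknown scenario {name!r}; available: {sorted(_CATALOG)}") from None


def run_scenario(name_or_scenario, outdir, seed: int = 0) -> Path:
    """Run a scenario, writing CSV outputs and a provenance manifest.

    Deterministic given ``seed``: the scenario's bundled seed offsets are
    added to it.  Returns the output directory.  No outputs are written if
    validation fails.
    """
    sc = (get_scenario(name_or_scenario) if isinstance(name_or_scenario, str)
          else name_or_scenario)
    sc.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    sc.runner(sc, outdir, written, int(seed))
    manifest = {
        "scenario": sc.name,
        "description": sc.description,
        "provenance": sc.provenance,
        "seed": int(seed),
        "scenario_seeds": list(sc.seeds),
        "extras": sc.extras,
        "base_parameters": mazef_parameters().to_dict(),
        "base_normalized": mazef_normalized().to_dict(),
        "outputs_sha256": written,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
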