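"""Protocol-driven simulation of the Akt redox network.

A :class:`Protocol` is an ordered list of timed events (set insulin, set
DPI, toggle BCNU/AF) applied after pre-equilibration to the basal steady
state. :func:`simulate` integrates the stiff ODE system piecewise between
events with LSODA and returns a :class:`TimeCourse` carrying species
trajectories plus the derived observables used throughout:

* ``Akt_PM``  — total membrane Akt (reduced + oxidized + phosphorylated),
* ``pAkt``    — activation-loop-phosphorylated Akt,
* ``pSub``    — phosphorylated substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ParameterSet, ReactionNetwork, apply_perturbations

logger = logging.getLogger(__name__)

OBSERVABLES = ("Akt_PM", "pAkt", "pSub")


@dataclass(frozen=True)
class Event:
    time: float
    action: str  # set_insulin | set_dpi | set_bcnu_af
    value: float


@dataclass
class Protocol:
    """Timed perturbation schedule.

    Events may sit at negative times (e.g. DPI 30 min before the insulin
    step at t = 0). The system is equilibrated to its basal steady state
    (insulin 0, no DPI, no BCNU/AF) before the earliest event.
    """

    protocol_id: str
    events: list[Event] = field(default_factory=list)
    horizon: float = 60.0
    n_grid: int = 241
    t_start: float | None = None
    equilibrate: bool = True

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        if self.events and self.events[-1].time > self.horizon:
            raise ValueError("event beyond protocol horizon")

    @property
    def start(self) -> float:
        t0 = min((e.time for e in self.events), default=0.0)
        t0 = min(t0, 0.0)
        return t0 if self.t_start is None else min(self.t_start, t0)

    def grid(self) -> np.ndarray:
        return np.linspace(self.start, self.horizon, self.n_grid)

    @classmethod
    def insulin_stimulation(
        cls,
        insulin: float = 1.0,
        bcnu_af: bool = False,
        dpi: float = 0.0,
        dpi_pre_min: float = 30.0,
        horizon: float = 60.0,
        protocol_id: str | None = None,
        n_grid: int = 241,
    ) -> "Protocol":
        """Standard protocol: optional DPI pre-treatment, optional BCNU/AF,
        then an insulin step at t = 0."""
        events = []
        if bcnu_af:
            events.append(Event(-max(dpi_pre_min, 0.0), "set_bcnu_af", 1.0))
        if dpi > 0:
            events.append(Event(-dpi_pre_min, "set_dpi", dpi))
        events.append(Event(0.0, "set_insulin", insulin))
        if protocol_id is None:
            protocol_id = f"ins{insulin:g}" + ("_bcnuaf" if bcnu_af else "") + (
                f"_dpi{dpi:g}" if dpi > 0 else ""
            )
        return cls(protocol_id=protocol_id, events=events, horizon=horizon, n_grid=n_grid)


class SimulationError(RuntimeError):
    pass


@dataclass
class TimeCourse:
    protocol_id: str
    time: np.ndarray
    states: pd.DataFrame  # index = time, columns = species
    akt_total: float

    def __post_init__(self) -> None:
        pm = self.observable("Akt_PM")
        if np.any(pm > self.akt_total * (1 + 1e-6)):
            raise SimulationError("membrane Akt exceeds total Akt")

    def observable(self, name: str, fold_over_baseline: bool = False) -> np.ndarray:
        if name == "Akt_PM":
            y = (
                self.states["Akt_red_PM"] + self.states["Akt_ox_PM"] + self.states["pAkt_PM"]
            ).to_numpy()
        elif name == "pAkt":
            y = self.states["pAkt_PM"].to_numpy()
        elif name == "pSub":
            y = self.states["pSub"].to_numpy()
        elif name in self.states.columns:
            y = self.states[name].to_numpy()
        else:
            raise KeyError(f"unknown observable {name!r}")
        if fold_over_baseline:
            base = y[0]
            if base <= 0:
                raise ValueError(f"observable {name!r} has non-positive baseline")
            y = y / base
        return y

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, observable, value, protocol_id."""
        rows = []
        for name in list(self.states.columns) + list(OBSERVABLES):
            if name in OBSERVABLES and name in self.states.columns:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "observable": name,
                        "value": self.observable(name) if name in OBSERVABLES
                        else self.states[name].to_numpy(),
                        "protocol_id": self.protocol_id,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _basal_state(network: ReactionNetwork, params: ParameterSet) -> np.ndarray:
    x = np.zeros(len(network.species))
    x[network.species_index("IR_inactive")] = params.ir_total
    x[network.species_index("NOX_inactive")] = params.nox_total
    x[network.species_index("Akt_red_cyt")] = params.akt_total
    x[network.species_index("Sub")] = params.sub_total
    return x


def equilibrate(
    network: ReactionNetwork,
    params: ParameterSet,
    x0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    f_tol: float = 1e-9,
    max_time: float = 1e6,
) -> np.ndarray:
    """Integrate to the basal steady state: ||dx/dt||_inf < f_tol."""
    f = network.rhs(params)
    x = _basal_state(network, params) if x0 is None else x0.copy()
    horizon = 2.0e3
    elapsed = 0.0
    while elapsed < max_time:
        sol = solve_ivp(f, (0.0, horizon), x, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"equilibration failed: {sol.message}")
        x = sol.y[:, -1]
        elapsed += horizon
        if np.max(np.abs(f(0.0, x))) < f_tol:
            return np.maximum(x, 0.0)
        horizon *= 5.0
    raise SimulationError(f"no steady state within {max_time:g} min (||f||={np.max(np.abs(f(0.0, x))):.3g})")


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    protocol: Protocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Simulate one protocol; stiff-capable, piecewise between events."""
    grid = protocol.grid()
    try:
        x = (
            equilibrate(network, params, rtol=rtol, atol=atol)
            if protocol.equilibrate
            else _basal_state(network, params)
        )
    except SimulationError as exc:
        raise SimulationError(f"protocol {protocol.protocol_id!r}: {exc}") from exc

    ins_idx = network.species_index("Ins")
    insulin, dpi, bcnu = 0.0, 0.0, False

    # breakpoints: protocol start, event times, horizon
    times = sorted({protocol.start, protocol.horizon, *(e.time for e in protocol.events)})
    events_at = {t: [e for e in protocol.events if e.time == t] for t in times}

    out = np.empty((len(grid), len(network.species)))
    filled = np.zeros(len(grid), dtype=bool)

    def record_point(t, xval):
        hits = np.flatnonzero(np.isclose(grid, t, rtol=0.0, atol=1e-12) & ~filled)
        for h in hits:
            out[h] = xval
            filled[h] = True

    for seg_start, seg_end in zip(times[:-1], times[1:]):
        for e in events_at.get(seg_start, []):
            if e.action == "set_insulin":
                insulin = e.value
            elif e.action == "set_dpi":
                dpi = e.value
            elif e.action == "set_bcnu_af":
                bcnu = bool(e.value)
            else:
                raise ValueError(f"unknown protocol action {e.action!r}")
        x[ins_idx] = insulin
        eff = apply_perturbations(params, dpi_conc=dpi, bcnu_af_on=bcnu)
        f = network.rhs(eff)
        record_point(seg_start, x)
        in_seg = (grid > seg_start + 1e-12) & (grid < seg_end - 1e-12)
        t_eval = np.concatenate([grid[in_seg], [seg_end]])
        sol = solve_ivp(
            f, (seg_start, seg_end), x, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
        )
        if not sol.success:
            raise SimulationError(
                f"protocol {protocol.protocol_id!r}: integration failed at t≈{sol.t[-1] if sol.t.size else seg_start:g} "
                f"min: {sol.message}"
            )
        y = sol.y.T
        if np.min(y) < -10 * atol:
            raise SimulationError(
                f"protocol {protocol.protocol_id!r}: negative state {np.min(y):.3g}"
            )
        if np.min(y) < 0:
            logger.debug("clipping tiny negative states (min %.3g) to 0", np.min(y))
            y = np.maximum(y, 0.0)
        out[in_seg] = y[:-1]
        filled[in_seg] = True
        x = y[-1].copy()
    record_point(times[-1], x)
    if not filled.all():
        # grid points coinciding with breakpoints within float fuzz
        for h in np.flatnonzero(~filled):
            out[h] = out[max(h - 1, 0)]
    states = pd.DataFrame(out, index=grid, columns=network.species)
    return TimeCourse(
        protocol_id=protocol.protocol_id, time=grid, states=states, akt_total=params.akt_total
    )


def moiety_drift(tc: TimeCourse, network: ReactionNetwork, params: ParameterSet) -> dict:
    """Maximum relative drift of each conserved moiety over a time course."""
    from .network import MOIETIES

    drift = {}
    for moiety, members in MOIETIES.items():
        total = tc.states[[m for m in members if m in tc.states.columns]].sum(axis=1)
        ref = params.totals()[moiety]
        drift[moiety] = float(np.max(np.abs(total - ref)) / ref)
    return drift


def pip3_dose_response(
    network: ReactionNetwork,
    params: ParameterSet,
    pip3_production_scales,
    insulin: float = 1.0,
    horizon: float = 60.0,
    with_bcnu_af: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Peak membrane-Akt response to scaled PIP3 production.

    For each scale the PIP3 synthesis rate is multiplied, the insulin
    protocol simulated, and the peak ``Akt_PM`` recorded — with and
    (optionally) without BCNU/AF. Returns a tidy DataFrame
    (pip3_scale, condition, peak_akt_pm).
    """
    scales = np.asarray(pip3_production_scales, dtype=float)
    if np.any(scales < 0):
        raise ValueError("pip3 production scales must be >= 0")
    rows = []
    conditions = [("control", False)] + ([("bcnu_af", True)] if with_bcnu_af else [])
    for scale in scales:
        p = params.with_rates(k_pip3_synth=max(params["k_pip3_synth"] * scale, 1e-300))
        for label, bcnu in conditions:
            proto = Protocol.insulin_stimulation(
                insulin=insulin, bcnu_af=bcnu, horizon=horizon,
                protocol_id=f"pip3x{scale:g}_{label}",
            )
            try:
                tc = simulate(network, p, proto, rtol=rtol, atol=atol)
            except SimulationError as exc:
                raise SimulationError(f"pip3 scale {scale:g}: {exc}") from exc
            sel = tc.time >= 0
            rows.append(
                {
                    "pip3_scale": scale,
                    "condition": label,
                    "peak_akt_pm": float(np.max(tc.observable("Akt_PM")[sel])),
                    "baseline_akt_pm": float(tc.observable("Akt_PM")[0]),
                }
            )
    return pd.DataFrame(rows)
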