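"""Closed-loop lumped-parameter network: elements, assembly, integration.

The circulation is an electrical-analog circuit: heart chambers are
time-varying elastances, vascular compartments are resistor/capacitor
(optionally inductor) segments, valves are smooth diodes.  The state vector
holds one volume unknown per chamber and per capacitive node plus one flow
unknown per inertial element; the right-hand side is a Kirchhoff flow
balance at every node with the element constitutive laws

    ΔP = R·Q,    dV_C/dt = Q_in − Q_out,   P_C = V_C/C + P_external,
    L·dQ/dt = ΔP − R·Q.

Because every element moves volume from one tracked node to another, total
blood volume is conserved by construction (up to integration tolerance);
:func:`volume_conservation_error` audits this.  Constant- or
prescribed-pressure reservoirs (``sources``) deliberately break closure and
are used for open-loop bench tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .coronary_control import CoronaryBlock
from .heart_model import HeartChamber, Valve, valve_flow

__all__ = [
    "VascularSegment",
    "Capacitor",
    "LPNModel",
    "ODESystem",
    "SimulationResult",
    "TopologyError",
    "IntegrationError",
    "assemble_system",
    "run_cycles",
    "run_to_periodic_state",
    "volume_conservation_error",
]


class TopologyError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class VascularSegment:
    """A series R(-L) element from ``upstream`` to ``downstream``.

    If ``C`` is given, the segment owns a capacitor attached at its
    downstream node; ``external_pressure_source`` names a chamber whose
    instantaneous pressure loads that capacitor (the P_v broadcast used by
    the coronary intramyocardial compartment).
    """

    name: str
    upstream: str
    downstream: str
    R: float  # mmHg·s/mL
    C: float | None = None  # mL/mmHg (capacitor at the downstream node)
    L: float = 0.0  # mmHg·s²/mL
    external_pressure_source: str | None = None
    initial_pressure: float = 5.0  # mmHg, pre-charge of the capacitor

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"segment {self.name}: R must be >= 0")
        if self.C is not None and self.C <= 0:
            raise ValueError(f"segment {self.name}: C must be > 0 if present")
        if self.L < 0:
            raise ValueError(f"segment {self.name}: L must be >= 0")


@dataclass
class Capacitor:
    """A standalone capacitive node (e.g. the aortic root behind a valve)."""

    node: str
    C: float  # mL/mmHg
    external_pressure_source: str | None = None
    initial_pressure: float = 5.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"capacitor at {self.node}: C must be > 0")


@dataclass
class LPNModel:
    """Closed-loop network of chambers, valves, segments and coronary blocks."""

    chambers: list[HeartChamber]
    valves: list[Valve]
    segments: list[VascularSegment]
    capacitors: list[Capacitor] = field(default_factory=list)
    coronary_blocks: list[CoronaryBlock] = field(default_factory=list)
    sources: dict[str, float | Callable[[float], float]] = field(default_factory=dict)

    def chamber(self, name: str) -> HeartChamber:
        for ch in self.chambers:
            if ch.name == name:
                return ch
        raise KeyError(name)

    def all_segments(self) -> list[VascularSegment]:
        """Explicit segments plus the expansion of each coronary block."""
        segs = list(self.segments)
        for blk in self.coronary_blocks:
            segs.extend(blk.as_segments())
        return segs

    @property
    def total_blood_volume(self) -> float:
        """Initial total volume (chambers + capacitor pre-charges), mL."""
        vol = sum(ch.volume for ch in self.chambers)
        for cap in self.capacitors:
            vol += cap.C * cap.initial_pressure
        for seg in self.all_segments():
            if seg.C is not None:
                vol += seg.C * seg.initial_pressure
        return vol


class ODESystem:
    """Compiled state layout + right-hand-side evaluator for an LPNModel."""

    def __init__(self, model: LPNModel):
        self.model = model
        chambers = model.chambers
        self.n_chambers = len(chambers)
        self.chamber_names = [ch.name for ch in chambers]
        segs = model.all_segments()

        # -- node bookkeeping -------------------------------------------------
        cap_nodes: list[str] = []
        cap_C: list[float] = []
        cap_ext: list[int] = []
        cap_p0: list[float] = []
        chamber_idx = {ch.name: i for i, ch in enumerate(chambers)}
        cap_decls = [(c.node, c.C, c.external_pressure_source, c.initial_pressure, c.node)
                     for c in model.capacitors]
        cap_decls += [(s.downstream, s.C, s.external_pressure_source, s.initial_pressure, s.name)
                      for s in segs if s.C is not None]
        for node, C, ext, p0, declared_by in cap_decls:
            if node in chamber_idx or node in model.sources:
                raise TopologyError(
                    f"{declared_by}: capacitor node {node} is a chamber/source")
            if node in cap_nodes:
                raise TopologyError(f"node {node} has two capacitor declarations")
            cap_nodes.append(node)
            cap_C.append(C)
            cap_p0.append(p0)
            cap_ext.append(chamber_idx[ext] if ext is not None else -1)
        self.cap_nodes = cap_nodes
        self.n_caps = len(cap_nodes)
        self.cap_C = np.asarray(cap_C, dtype=float)
        self.cap_ext = np.asarray(cap_ext, dtype=int)
        self.cap_p0 = np.asarray(cap_p0, dtype=float)

        source_nodes = list(model.sources)
        self.source_nodes = source_nodes
        node_index: dict[str, int] = {}
        for i, name in enumerate(self.chamber_names + cap_nodes + source_nodes):
            node_index[name] = i
        self.node_index = node_index
        self.n_nodes = len(node_index)

        # -- elements ---------------------------------------------------------
        self.element_names: list[str] = []
        src, dst, R, kind, steep, leak, L = [], [], [], [], [], [], []
        for seg in segs:
            for end in (seg.upstream, seg.downstream):
                if end not in node_index:
                    raise TopologyError(
                        f"segment {seg.name}: node {end} has no capacitor, chamber or source "
                        "(flow balance there would be algebraic)")
            src.append(node_index[seg.upstream])
            dst.append(node_index[seg.downstream])
            R.append(seg.R)
            kind.append(0)
            steep.append(0.0)
            leak.append(0.0)
            L.append(seg.L)
            self.element_names.append(seg.name)
        for v in model.valves:
            for end in (v.upstream, v.downstream):
                if end not in node_index:
                    raise TopologyError(f"valve {v.name}: unknown node {end}")
            src.append(node_index[v.upstream])
            dst.append(node_index[v.downstream])
            R.append(v.r_open)
            kind.append(1)
            steep.append(v.steepness)
            leak.append(v.leak_conductance)
            L.append(0.0)
            self.element_names.append(v.name)
        self.src = np.asarray(src, dtype=int)
        self.dst = np.asarray(dst, dtype=int)
        self.R = np.asarray(R, dtype=float)
        self.kind = np.asarray(kind, dtype=int)
        self.steep = np.asarray(steep, dtype=float)
        self.leak = np.asarray(leak, dtype=float)
        self.L = np.asarray(L, dtype=float)
        self.is_valve = self.kind == 1
        self.has_L = self.L > 0
        self.l_elements = np.nonzero(self.has_L)[0]
        self.n_flows = int(self.has_L.sum())
        self.n_state = self.n_chambers + self.n_caps + self.n_flows
        self._element_index = {n: i for i, n in enumerate(self.element_names)}

        # -- connectivity -----------------------------------------------------
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_nodes)}
        for a, b in zip(self.src, self.dst):
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != self.n_nodes:
            missing = [n for n, i in node_index.items() if i not in seen]
            raise TopologyError(f"disconnected topology: unreachable nodes {missing}")

        # -- chamber parameter arrays ----------------------------------------
        self.e_max = np.array([ch.elastance.e_max for ch in chambers])
        self.e_min = np.array([ch.elastance.e_min for ch in chambers])
        self.v0 = np.array([ch.elastance.v0 for ch in chambers])
        self.tp = np.array([ch.elastance.t_peak_fraction for ch in chambers])
        self.ts = np.array([ch.elastance.systole_fraction for ch in chambers])
        self.onset = np.array([ch.elastance.onset_fraction for ch in chambers])
        self.period = 1.0  # set by run_cycles

    # -- parameter access -----------------------------------------------------
    def element_R(self, name: str) -> float:
        return float(self.R[self._element_index[name]])

    def set_element_R(self, name: str, value: float) -> None:
        self.R[self._element_index[name]] = value

    def refresh_chambers(self) -> None:
        """Re-read elastance parameters from the model (after edits)."""
        for i, ch in enumerate(self.model.chambers):
            self.e_max[i] = ch.elastance.e_max
            self.e_min[i] = ch.elastance.e_min
            self.v0[i] = ch.elastance.v0
            self.tp[i] = ch.elastance.t_peak_fraction
            self.ts[i] = ch.elastance.systole_fraction
            self.onset[i] = ch.elastance.onset_fraction

    # -- state ----------------------------------------------------------------
    def default_initial_state(self) -> np.ndarray:
        y0 = np.empty(self.n_state)
        vch = np.array([ch.volume for ch in self.model.chambers])
        y0[:self.n_chambers] = vch
        p_ch0 = self._chamber_pressures(0.0, vch)
        if self.n_chambers:
            p_ext0 = np.where(self.cap_ext >= 0,
                              p_ch0[np.maximum(self.cap_ext, 0)], 0.0)
        else:
            p_ext0 = np.zeros(self.n_caps)
        y0[self.n_chambers:self.n_chambers + self.n_caps] = \
            self.cap_C * (self.cap_p0 - p_ext0)
        y0[self.n_chambers + self.n_caps:] = 0.0
        return y0

    def _chamber_pressures(self, t: float, vch: np.ndarray) -> np.ndarray:
        phi = (t / self.period - self.onset) % 1.0
        a = np.zeros(self.n_chambers)
        rise = phi < self.tp
        fall = ~rise & (phi < self.ts)
        a[rise] = 0.5 * (1.0 - np.cos(np.pi * phi[rise] / self.tp[rise]))
        a[fall] = 0.5 * (1.0 + np.cos(np.pi * (phi[fall] - self.tp[fall])
                                      / (self.ts[fall] - self.tp[fall])))
        e = self.e_min + (self.e_max - self.e_min) * a
        return e * (vch - self.v0)

    def node_pressures(self, t: float, y: np.ndarray) -> np.ndarray:
        nch, nc = self.n_chambers, self.n_caps
        p = np.empty(self.n_nodes)
        p[:nch] = self._chamber_pressures(t, y[:nch])
        vc = y[nch:nch + nc]
        p_ext = np.where(self.cap_ext >= 0, p[np.maximum(self.cap_ext, 0)], 0.0)
        p[nch:nch + nc] = vc / self.cap_C + p_ext
        for k, name in enumerate(self.source_nodes):
            val = self.model.sources[name]
            p[nch + nc + k] = val(t) if callable(val) else val
        return p

    def element_flows(self, t: float, y: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        if p is None:
            p = self.node_pressures(t, y)
        dp = p[self.src] - p[self.dst]
        q = dp / self.R
        if self.is_valve.any():
            iv = self.is_valve
            s = 1.0 / (1.0 + np.exp(np.clip(-self.steep[iv] * dp[iv], -500, 500)))
            q[iv] = dp[iv] * (s / self.R[iv] + (1.0 - s) * self.leak[iv])
        if self.n_flows:
            q[self.l_elements] = y[self.n_chambers + self.n_caps:]
        return q

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.node_pressures(t, y)
        q = self.element_flows(t, y, p)
        dv = np.bincount(self.dst, weights=q, minlength=self.n_nodes) \
            - np.bincount(self.src, weights=q, minlength=self.n_nodes)
        dy = np.empty(self.n_state)
        nvol = self.n_chambers + self.n_caps
        dy[:nvol] = dv[:nvol]
        if self.n_flows:
            le = self.l_elements
            dp_l = p[self.src[le]] - p[self.dst[le]]
            dy[nvol:] = (dp_l - self.R[le] * q[le]) / self.L[le]
        return dy


def assemble_system(model: LPNModel) -> ODESystem:
    """Validate the topology and compile the ODE system for ``model``."""
    return ODESystem(model)


@dataclass
class SimulationResult:
    """Trajectories on a uniform output grid, with cycle bookkeeping."""

    time: np.ndarray
    states: np.ndarray  # (nt, n_state)
    node_pressures: np.ndarray  # (nt, n_nodes)
    element_flows: np.ndarray  # (nt, n_elements)
    cycle_markers: np.ndarray  # indices of cycle starts
    converged: bool
    n_cycles_run: int
    hr: float
    node_names: list[str]
    element_names: list[str]
    n_chambers: int
    n_caps: int

    @property
    def chamber_volumes(self) -> np.ndarray:
        return self.states[:, :self.n_chambers]

    def pressure(self, node: str) -> np.ndarray:
        return self.node_pressures[:, self.node_names.index(node)]

    def flow(self, element: str) -> np.ndarray:
        return self.element_flows[:, self.element_names.index(element)]

    def volume(self, chamber: str) -> np.ndarray:
        return self.states[:, self.node_names.index(chamber)]

    def last_cycle(self) -> slice:
        return slice(int(self.cycle_markers[-1]), len(self.time))

    def to_tidy_csv(self, path: str | Path) -> None:
        """Long-format CSV (time, entity, quantity, value) + JSON header."""
        frames = []
        for names, arr, qty in ((self.node_names, self.node_pressures, "pressure_mmHg"),
                                (self.element_names, self.element_flows, "flow_mL_s"),
                                (self.node_names[:self.n_chambers],
                                 self.chamber_volumes, "volume_mL")):
            for j, name in enumerate(names):
                frames.append(pd.DataFrame({"time": self.time, "entity": name,
                                            "quantity": qty, "value": arr[:, j]}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        meta = {"units": {"time": "s", "pressure": "mmHg", "flow": "mL/s",
                          "volume": "mL"},
                "hr_bpm": self.hr, "converged": self.converged,
                "n_cycles_run": self.n_cycles_run}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def _integrate_cycle(system: ODESystem, t0: float, period: float, y0: np.ndarray,
                     dt: float, rtol: float, atol: float, method: str):
    n = max(int(round(period / dt)), 2)
    t_eval = t0 + np.arange(n) * (period / n)
    sol = solve_ivp(system.rhs, (t0, t0 + period), y0, method=method,
                    t_eval=np.append(t_eval, t0 + period), rtol=rtol, atol=atol)
    if not sol.success or not np.isfinite(sol.y).all():
        bad_t = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(f"non-finite state or solver failure near t={bad_t:.4f}s")
    return sol.t[:-1], sol.y[:, :-1].T, sol.y[:, -1]


def run_cycles(system: ODESystem, hr: float, n_cycles: int, dt: float = 1e-3,
               initial_state: np.ndarray | None = None, rtol: float = 1e-6,
               atol: float = 1e-8, method: str = "LSODA",
               cycle_hook: Callable | None = None,
               converged: bool = True) -> SimulationResult:
    """Integrate ``n_cycles`` heart beats, recording on a uniform grid.

    ``cycle_hook(i_cycle, t_cycle, y_cycle, system)`` runs after each beat
    and may mutate element resistances (the coronary controller hook).
    """
    if dt <= 0 or n_cycles < 1 or hr <= 0:
        raise ValueError("require dt > 0, n_cycles >= 1, hr > 0")
    period = 60.0 / hr
    system.period = period
    y = system.default_initial_state() if initial_state is None else np.asarray(initial_state, float)
    times, states, markers = [], [], []
    idx = 0
    for i in range(n_cycles):
        t_c, y_c, y = _integrate_cycle(system, i * period, period, y, dt, rtol, atol, method)
        times.append(t_c)
        states.append(y_c)
        markers.append(idx)
        idx += len(t_c)
        if cycle_hook is not None:
            cycle_hook(i, t_c, y_c, system)
    times.append(np.array([n_cycles * period]))
    states.append(y[None, :])
    t = np.concatenate(times)
    Y = np.vstack(states)
    P = np.empty((len(t), system.n_nodes))
    Q = np.empty((len(t), len(system.element_names)))
    for k in range(len(t)):
        P[k] = system.node_pressures(t[k], Y[k])
        Q[k] = system.element_flows(t[k], Y[k], P[k])
    return SimulationResult(t, Y, P, Q, np.asarray(markers), converged, n_cycles,
                            hr, list(system.node_index), list(system.element_names),
                            system.n_chambers, system.n_caps)


def run_to_periodic_state(system: ODESystem, hr: float, tol: float = 1e-3,
                          max_cycles: int = 50, dt: float = 1e-3,
                          initial_state: np.ndarray | None = None,
                          rtol: float = 1e-6, atol: float = 1e-8,
                          method: str = "LSODA",
                          cycle_hook: Callable | None = None,
                          keep_last: int = 2) -> SimulationResult:
    """Run until the relative L2 cycle-to-cycle state change drops below tol.

    Returns the last ``keep_last`` cycles of trajectory (converged flag set
    accordingly; the result is returned even when max_cycles is hit).
    """
    if not (0 < tol < 0.1):
        raise ValueError("tol must lie in (0, 0.1)")
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    period = 60.0 / hr
    system.period = period
    y = system.default_initial_state() if initial_state is None else np.asarray(initial_state, float)
    prev = None
    history = []
    converged = False
    n_run = 0
    for i in range(max_cycles):
        t_c, y_c, y = _integrate_cycle(system, i * period, period, y, dt, rtol, atol, method)
        history.append((t_c, y_c))
        if len(history) > max(keep_last, 2):
            history.pop(0)
        n_run = i + 1
        if cycle_hook is not None:
            cycle_hook(i, t_c, y_c, system)
        if prev is not None and prev.shape == y_c.shape:
            denom = np.linalg.norm(y_c)
            if denom > 0 and np.linalg.norm(y_c - prev) / denom < tol:
                converged = True
                break
        prev = y_c
    kept = history[-keep_last:]
    t = np.concatenate([h[0] for h in kept] + [np.array([kept[-1][0][0] + period])])
    Y = np.vstack([h[1] for h in kept] + [y[None, :]])
    markers = np.cumsum([0] + [len(h[0]) for h in kept[:-1]])
    P = np.empty((len(t), system.n_nodes))
    Q = np.empty((len(t), len(system.element_names)))
    for k in range(len(t)):
        P[k] = system.node_pressures(t[k], Y[k])
        Q[k] = system.element_flows(t[k], Y[k], P[k])
    return SimulationResult(t, Y, P, Q, markers, converged, n_run, hr,
                            list(system.node_index), list(system.element_names),
                            system.n_chambers, system.n_caps)


def volume_conservation_error(result: SimulationResult, model: LPNModel | None = None) -> float:
    """Max relative deviation of total tracked blood volume over the run."""
    nvol = result.n_chambers + result.n_caps
    total = result.states[:, :nvol].sum(axis=1)
    if len(total) < 2:
        return 0.0
    v0 = total[0]
    return float(np.max(np.abs(total - v0)) / abs(v0))
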