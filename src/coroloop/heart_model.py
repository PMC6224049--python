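"""Time-varying elastance heart chambers, valves, and elastance derivation.

Each chamber obeys the classic elastance law

    P(t) = E(t) · (V(t) − V0),      E(t) = E_min + (E_max − E_min) · a(t/T)

with a normalized periodic activation a ∈ [0, 1].  The activation family is
a raised-cosine ascent to a peak at phase ``t_peak_fraction`` followed by a
raised-cosine relaxation ending at ``systole_fraction``; a ≡ 0 for the rest
of the cycle (diastole).  Atria reuse the family with a phase offset so they
contract just before ventricular systole.

Patient-specific ventricular elastances are derived from one cycle of
volume data (cine-like, ~25 frames) aligned via R-wave markers with an
intraventricular pressure trace (catheter-like, ≥200 samples): the raw
elastance e(t) = P/(V − V0) is computed on a common phase grid for a
candidate unstressed volume V0, projected onto the activation family, and
V0 is chosen to minimize the pressure-reconstruction error (single-beat
surrogate; multi-load PV loops are not available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "ElastanceFunction",
    "HeartChamber",
    "Valve",
    "ClinicalCycleData",
    "ElastanceFit",
    "chamber_pressure",
    "valve_flow",
    "derive_elastance",
    "systole_interval",
    "systole_fractions_for_hr",
    "write_cycle_data",
    "read_cycle_data",
]

#: Activation level above which a phase is bookkept as systole (flow splits).
SYSTOLE_THRESHOLD = 0.05

#: Cube-root timing constant: absolute systole duration = K · T^(1/3) (s).
#: Fixed so that systole occupies 36% of the cycle at 73 bpm.
SYSTOLE_TIME_K = 0.36 * (60.0 / 73.0) ** (2.0 / 3.0)

#: Peak elastance occurs at this fraction of the systolic interval.
PEAK_WITHIN_SYSTOLE = 0.6


def systole_fractions_for_hr(hr: float, k: float = SYSTOLE_TIME_K) -> tuple[float, float]:
    """Return (t_peak_fraction, systole_fraction) for a heart rate in bpm.

    Systolic duration scales with the cube root of the period (Bazett-like
    empirical rule), so the *fraction* of the cycle spent in systole grows
    with heart rate while the absolute duration shrinks.
    """
    period = 60.0 / hr
    ts = min(k * period ** (1.0 / 3.0) / period, 0.6)
    return PEAK_WITHIN_SYSTOLE * ts, ts


@dataclass
class ElastanceFunction:
    """Time-varying chamber stiffness E(t) with unstressed volume V0."""

    e_max: float  # mmHg/mL
    e_min: float  # mmHg/mL
    v0: float  # mL
    t_peak_fraction: float
    systole_fraction: float
    onset_fraction: float = 0.0  # activation onset phase (atria fire late)

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise ValueError("require e_max > e_min > 0")
        if not (0 < self.t_peak_fraction < self.systole_fraction < 1):
            raise ValueError("require 0 < t_peak_fraction < systole_fraction < 1")

    def activation(self, phase):
        """Normalized activation a(phase) ∈ [0, 1]; periodic, a(0)=a(1)."""
        phi = (np.asarray(phase, dtype=float) - self.onset_fraction) % 1.0
        tp, ts = self.t_peak_fraction, self.systole_fraction
        a = np.zeros_like(phi)
        rise = phi < tp
        fall = (phi >= tp) & (phi < ts)
        a[rise] = 0.5 * (1.0 - np.cos(np.pi * phi[rise] / tp))
        a[fall] = 0.5 * (1.0 + np.cos(np.pi * (phi[fall] - tp) / (ts - tp)))
        return a if a.ndim else float(a)

    def elastance(self, t, period: float):
        """E(t) in mmHg/mL for time t (s) within a cycle of given period."""
        a = self.activation(np.asarray(t, dtype=float) / period)
        return self.e_min + (self.e_max - self.e_min) * a

    def with_rate(self, hr_old: float, hr_new: float) -> "ElastanceFunction":
        """Retime for a new heart rate using the cube-root systole rule."""
        t_old = 60.0 / hr_old
        t_new = 60.0 / hr_new
        ts_abs = self.systole_fraction * t_old * (t_new / t_old) ** (1.0 / 3.0)
        ts = min(ts_abs / t_new, 0.6)
        tp = ts * self.t_peak_fraction / self.systole_fraction
        return replace(self, t_peak_fraction=tp, systole_fraction=ts)


@dataclass
class HeartChamber:
    name: str  # LV / RV / LA / RA
    elastance: ElastanceFunction
    volume: float  # mL, instantaneous state (used as initial condition)
    broadcast: bool = False  # pressure transmitted to a coronary block

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"chamber {self.name}: volume must be positive")


def chamber_pressure(chamber: HeartChamber, t: float, period: float, volume: float | None = None) -> float:
    """P = E(t)·(V − V0); may be ≤ 0 if V < V0 (reported, not an error)."""
    v = chamber.volume if volume is None else volume
    return chamber.elastance.elastance(t, period) * (v - chamber.elastance.v0)


@dataclass
class Valve:
    """Smooth diode: forward conductance 1/R_open, reverse ``leak_conductance``.

    Q(dP) = dP · [ s(dP)/R_open + (1 − s(dP))·g_leak ],  s = σ(steepness·dP)

    which is continuously differentiable, has Q(0)=0, and approaches the
    ideal open/closed laws for |dP| ≫ 1/steepness.
    """

    name: str
    upstream: str
    downstream: str
    r_open: float  # mmHg·s/mL
    leak_conductance: float = 0.0  # mL/(s·mmHg)
    steepness: float = 2.0  # 1/mmHg

    def __post_init__(self) -> None:
        if self.r_open <= 0:
            raise ValueError(f"valve {self.name}: r_open must be > 0")
        if self.leak_conductance < 0:
            raise ValueError(f"valve {self.name}: leak_conductance must be >= 0")


def valve_flow(valve: Valve, dp):
    """Flow (mL/s) through the smooth diode for pressure difference dp."""
    dp = np.asarray(dp, dtype=float)
    s = 1.0 / (1.0 + np.exp(np.clip(-valve.steepness * dp, -500, 500)))
    q = dp * (s / valve.r_open + (1.0 - s) * valve.leak_conductance)
    return q if q.ndim else float(q)


# --------------------------------------------------------------------------
# Clinical-style single-cycle data and elastance derivation
# --------------------------------------------------------------------------


@dataclass
class ClinicalCycleData:
    """One cardiac cycle of ventricular volume and pressure measurements."""

    volume_t: np.ndarray  # s
    volume: np.ndarray  # mL
    pressure_t: np.ndarray  # s
    pressure: np.ndarray  # mmHg
    hr: float  # bpm
    r_wave_times: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self) -> None:
        self.volume_t = np.asarray(self.volume_t, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure_t = np.asarray(self.pressure_t, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.r_wave_times = np.asarray(self.r_wave_times, dtype=float)
        period = 60.0 / self.hr
        for name, t in (("volume", self.volume_t), ("pressure", self.pressure_t)):
            if t[-1] - t[0] < 0.95 * period:
                raise ValueError(f"{name} series must cover at least one full cycle")
        if self.pressure.min() < 0:
            raise ValueError("pressure trace has negative samples")
        if self.volume.max() <= self.volume.min():
            raise ValueError("volume curve is constant: elastance not identifiable")


@dataclass
class ElastanceFit:
    """Result of :func:`derive_elastance`."""

    elastance: ElastanceFunction
    rel_rms: float  # relative RMS pressure-reconstruction error
    phase: np.ndarray
    pressure_observed: np.ndarray
    pressure_reconstructed: np.ndarray


def _fourier_smooth(y: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Low-pass a periodic sample by truncating its Fourier series."""
    spec = np.fft.rfft(y)
    spec[n_harmonics + 1:] = 0.0
    return np.fft.irfft(spec, n=len(y))


def _phase_resample(t: np.ndarray, y: np.ndarray, t0: float, period: float,
                    phase_grid: np.ndarray) -> np.ndarray:
    """Resample a (≥1 cycle) series onto a phase grid via periodic spline."""
    phi = ((t - t0) / period) % 1.0
    order = np.argsort(phi)
    phi_s, y_s = phi[order], y[order]
    # drop duplicate phases, close the period
    keep = np.concatenate(([True], np.diff(phi_s) > 1e-9))
    phi_s, y_s = phi_s[keep], y_s[keep]
    phi_ext = np.concatenate((phi_s, [phi_s[0] + 1.0]))
    y_ext = np.concatenate((y_s, [y_s[0]]))
    return CubicSpline(phi_ext, y_ext, bc_type="periodic")(phase_grid)


def derive_elastance(data: ClinicalCycleData, n_phase: int = 256,
                     v0_candidates: int = 41,
                     v0: float | None = None) -> ElastanceFit:
    """Derive a ventricular :class:`ElastanceFunction` from cycle data.

    Volume and pressure are R-wave aligned, resampled on a common phase
    grid and lightly low-passed.  For candidate (V0, t_peak, t_systole)
    the raised-cosine reconstruction is linear in (E_min, E_max), which
    are solved by least squares on the pressure trace; the remaining
    three parameters are grid-seeded and polished by Nelder-Mead to
    minimize the relative RMS pressure error.

    Single-beat caveat: with measurement noise, V0 and E_max trade off
    along a near-flat valley of the fit (only their combination at the
    end-systolic samples is well determined), so E_max from noisy data
    carries substantially more uncertainty than the reconstruction error
    suggests.  Passing ``v0`` (e.g. from a separate estimate) fixes the
    unstressed volume and restores a well-conditioned fit.
    """
    period = 60.0 / data.hr
    t0 = float(data.r_wave_times[0])
    phase = np.arange(n_phase) / n_phase
    v = _phase_resample(data.volume_t, data.volume, t0, period, phase)
    p = _phase_resample(data.pressure_t, data.pressure, t0, period, phase)
    v = _fourier_smooth(v, 10)
    p = _fourier_smooth(p, 16)
    p = np.maximum(p, 1e-6)
    vmin = v.min()
    if v.max() - vmin < 1e-3 * max(v.max(), 1.0):
        raise ValueError("volume curve is (near) constant: elastance not identifiable")

    p_norm = float(np.sqrt(np.mean(p**2)))

    def activation_shape(tp: float, ts: float) -> np.ndarray:
        a = np.zeros_like(phase)
        rise = phase < tp
        fall = (phase >= tp) & (phase < ts)
        a[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / tp))
        a[fall] = 0.5 * (1.0 + np.cos(np.pi * (phase[fall] - tp) / (ts - tp)))
        return a

    def linear_fit(v0: float, tp: float, ts: float):
        """E_max/E_min enter P̂ linearly → solve them by least squares."""
        dv = v - v0
        if np.any(dv <= 0):
            return None, np.inf
        a = activation_shape(tp, ts)
        basis = np.column_stack(((1.0 - a) * dv, a * dv))  # [e_min, e_max]
        coef, *_ = np.linalg.lstsq(basis, p, rcond=None)
        e_min_f, e_max_f = float(coef[0]), float(coef[1])
        if not (e_max_f > e_min_f > 0):
            return None, np.inf
        resid = basis @ coef - p
        return (e_min_f, e_max_f), float(np.sqrt(np.mean(resid**2))) / p_norm

    def shape_guess(v0: float) -> tuple[float, float]:
        e = p / np.maximum(v - v0, 1e-9)
        a_raw = (e - e.min()) / max(e.max() - e.min(), 1e-12)
        i_pk = int(np.argmax(a_raw))
        tp0 = float(np.clip(phase[i_pk], 0.05, 0.85))
        below = np.nonzero(a_raw[i_pk:] < 0.05)[0]
        ts0 = phase[i_pk + below[0]] if below.size else tp0 + 0.2
        return tp0, float(np.clip(ts0, tp0 + 0.03, 0.97))

    if v0 is not None and not (0.0 <= v0 < vmin):
        raise ValueError(f"fixed V0 {v0} must lie in [0, min volume {vmin:.1f})")

    def cost(x) -> float:
        if v0 is not None:
            v0_c, (tp, ts) = v0, x
        else:
            v0_c, tp, ts = x
        if not (0.0 <= v0_c <= 0.95 * vmin and 0.01 < tp < ts < 0.99):
            return 1e6
        return linear_fit(v0_c, tp, ts)[1]

    if v0 is not None:
        x0 = np.array(shape_guess(v0))
    else:
        v0_grid = np.linspace(0.0, 0.9 * vmin, v0_candidates)
        guesses = [(g, *shape_guess(g)) for g in v0_grid]
        errs = [cost(g) for g in guesses]
        x0 = np.array(guesses[int(np.argmin(errs))])
    res = minimize(cost, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600})
    if v0 is not None:
        v0_best, (tp, ts) = v0, (float(res.x[0]), float(res.x[1]))
    else:
        v0_best, tp, ts = (float(val) for val in res.x)
    coef, err = linear_fit(v0_best, tp, ts)
    e_min_f, e_max_f = coef
    ef = ElastanceFunction(e_max_f, e_min_f, v0_best, tp, ts)
    p_hat = ef.elastance(phase * period, period) * (v - ef.v0)
    return ElastanceFit(ef, err, phase, p, p_hat)


def systole_interval(elastance: ElastanceFunction, hr: float,
                     threshold: float = SYSTOLE_THRESHOLD) -> tuple[float, float]:
    """Contiguous in-cycle interval (s) where a(t/T) exceeds ``threshold``.

    The complement of the interval is diastole.  Ties (a == threshold) are
    broken toward diastole (strict inequality).
    """
    period = 60.0 / hr
    n = 4096
    phase = np.arange(n) / n
    above = elastance.activation(phase) > threshold
    if not above.any():
        return (0.0, 0.0)
    if above.all():
        return (0.0, period)
    # rotate so the systolic run is contiguous
    first_below = int(np.argmin(above))
    rolled = np.roll(above, -first_below)
    start = int(np.argmax(rolled))
    length = int(rolled[start:].argmin()) if not rolled[start:].all() else n - start
    i0 = (start + first_below) % n
    t_start = phase[i0] * period
    t_end = t_start + length / n * period
    return (t_start, t_end)


# --------------------------------------------------------------------------
# CSV/JSON round trip for clinical-style cycle data
# --------------------------------------------------------------------------


def write_cycle_data(data: ClinicalCycleData, directory: str | Path, stem: str = "cycle") -> None:
    """Write volume/pressure as two-column CSVs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, t, y in (("volumes", data.volume_t, data.volume),
                       ("pressures", data.pressure_t, data.pressure)):
        arr = np.column_stack((t, y))
        np.savetxt(directory / f"{stem}_{name}.csv", arr, delimiter=",",
                   header="t_seconds,value", comments="", fmt="%.9g")
    sidecar = {
        "hr": data.hr,
        "r_wave_times": data.r_wave_times.tolist(),
        "units": {"volume": "mL", "pressure": "mmHg", "time": "s"},
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=1))


def read_cycle_data(directory: str | Path, stem: str = "cycle") -> ClinicalCycleData:
    directory = Path(directory)
    vol = np.loadtxt(directory / f"{stem}_volumes.csv", delimiter=",", skiprows=1)
    pre = np.loadtxt(directory / f"{stem}_pressures.csv", delimiter=",", skiprows=1)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return ClinicalCycleData(vol[:, 0], vol[:, 1], pre[:, 0], pre[:, 1],
                             hr=meta["hr"], r_wave_times=np.array(meta["r_wave_times"]))
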