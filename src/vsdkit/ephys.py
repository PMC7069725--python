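"""Quantification of two-electrode voltage-clamp (TEVC) and voltage-clamp
fluorometry (VCF) sweeps.

The module turns raw sweep sets into conductance-voltage (G-V) and
fluorescence-voltage (F-V) relations, fits single or double Boltzmann
functions of the form

    B(V) = 1 / (1 + exp(-z F (V - V_1/2) / (R T)))

and quantifies state-dependent XE991 block through the chromanol-subtracted
inhibition fraction

    f_XE991 = (I_control - I_XE991) / (I_control - I_chromanol).

Voltages are mV, currents µA, times s, temperature K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

FARADAY = 96485.0       # C / mol
GAS_CONSTANT = 8.314    # J / (mol K)
ROOM_TEMPERATURE = 295.15  # K; oocyte recordings at 21-23 °C

__all__ = [
    "VoltageProtocol", "Sweep", "SweepSet", "BoltzmannFit", "InhibitionResult",
    "gv_from_tails", "fv_from_fluorescence", "fit_boltzmann",
    "steady_state_current", "xe991_inhibition", "time_dependent_inhibition",
    "boltzmann",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol: hold, test pulse, tail pulse."""

    holding_mV: float = -80.0
    pre_duration_s: float = 2.0      # time at holding before the test pulse
    test_duration_s: float = 4.0
    tail_voltage_mV: float = -40.0
    tail_duration_s: float = 2.0
    dt_s: float = 0.005

    @property
    def test_start(self) -> float:
        return self.pre_duration_s

    @property
    def tail_start(self) -> float:
        return self.pre_duration_s + self.test_duration_s

    @property
    def total_duration(self) -> float:
        return self.pre_duration_s + self.test_duration_s + self.tail_duration_s


@dataclass
class Sweep:
    test_voltage_mV: float
    time_s: np.ndarray
    current_uA: np.ndarray
    fluorescence_au: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_uA = np.asarray(self.current_uA, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sweep time base must be strictly increasing")
        if self.fluorescence_au is not None:
            self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)


@dataclass
class SweepSet:
    """One sweep per test voltage, under a shared step protocol."""

    sweeps: list[Sweep]
    protocol: VoltageProtocol
    temperature_K: float = ROOM_TEMPERATURE

    def __post_init__(self):
        volts = [s.test_voltage_mV for s in self.sweeps]
        if len(set(volts)) != len(volts):
            raise ValueError("duplicate test voltages in sweep set")

    def voltages(self) -> np.ndarray:
        return np.array([s.test_voltage_mV for s in self.sweeps])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sweeps:
            df = pd.DataFrame({"time_s": s.time_s, "current_uA": s.current_uA})
            if s.fluorescence_au is not None:
                df["fluorescence_au"] = s.fluorescence_au
            df["test_voltage_mV"] = s.test_voltage_mV
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        """Long-format CSV with the protocol in '#'-prefixed header lines."""
        import json
        from dataclasses import asdict
        header = {"protocol": asdict(self.protocol),
                  "temperature_K": self.temperature_K}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "SweepSet":
        import json
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing protocol header line")
            meta = json.loads(first.lstrip("# "))
            df = pd.read_csv(fh)
        sweeps = []
        for v, sub in df.groupby("test_voltage_mV", sort=True):
            fluo = (sub["fluorescence_au"].to_numpy()
                    if "fluorescence_au" in sub.columns else None)
            sweeps.append(Sweep(float(v), sub["time_s"].to_numpy(),
                                sub["current_uA"].to_numpy(), fluo))
        return cls(sweeps, VoltageProtocol(**meta["protocol"]),
                   meta.get("temperature_K", ROOM_TEMPERATURE))


# -- Boltzmann machinery ---------------------------------------------------

def boltzmann(v_mV, z: float, v_half_mV: float,
              t_kelvin: float = ROOM_TEMPERATURE):
    """Single Boltzmann activation curve."""
    v = np.asarray(v_mV, dtype=float)
    x = z * FARADAY * (v - v_half_mV) * 1e-3 / (GAS_CONSTANT * t_kelvin)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class BoltzmannFit:
    """Result of a single or double Boltzmann fit.

    ``components`` holds (z, V_1/2, amplitude) triples with amplitudes
    summing to 1 and, for the double form, V_1/2 ordered ascending.
    """

    components: list[tuple[float, float, float]]
    rss: float
    t_kelvin: float = ROOM_TEMPERATURE

    def predict(self, v_mV) -> np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        out = np.zeros_like(v)
        for z, vh, amp in self.components:
            out = out + amp * boltzmann(v, z, vh, self.t_kelvin)
        return out

    def summary(self) -> str:
        lines = [f"Boltzmann fit ({len(self.components)} component"
                 f"{'s' if len(self.components) > 1 else ''}), "
                 f"T = {self.t_kelvin:.2f} K, RSS = {self.rss:.4g}"]
        for i, (z, vh, amp) in enumerate(self.components, 1):
            lines.append(f"  component {i}: z = {z:.3f}, "
                         f"V1/2 = {vh:.2f} mV, amplitude = {amp:.3f}")
        return "\n".join(lines)


def fit_boltzmann(v_mV: Sequence[float], y: Sequence[float],
                  n_components: int = 1,
                  t_kelvin: float = ROOM_TEMPERATURE) -> BoltzmannFit:
    """Least-squares Boltzmann fit with a multi-start grid over V_1/2.

    For ``n_components == 2`` the curve is A·B(z1,V1) + (1-A)·B(z2,V2) with
    V1 < V2 enforced by ordering and A bounded to [0.05, 0.95] to prevent
    component collapse.
    """
    v = np.asarray(v_mV, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(v) < (5 if n_components == 1 else 8):
        raise ValueError("not enough points for the requested fit")

    grid = np.arange(-150.0, 50.1, 20.0)
    best = None

    if n_components == 1:
        def model(vv, z, vh):
            return boltzmann(vv, z, vh, t_kelvin)
        for vh0 in grid:
            try:
                popt, _ = curve_fit(model, v, y, p0=[1.0, vh0],
                                    bounds=([1e-3, -400], [20, 400]),
                                    maxfev=5000)
            except RuntimeError:
                continue
            rss = float(np.sum((model(v, *popt) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            raise RuntimeError("single-Boltzmann fit failed from every start")
        rss, (z, vh) = best
        return BoltzmannFit([(float(z), float(vh), 1.0)], rss, t_kelvin)

    def model2(vv, a, z1, vh1, z2, vh2):
        return (a * boltzmann(vv, z1, vh1, t_kelvin)
                + (1 - a) * boltzmann(vv, z2, vh2, t_kelvin))

    for vh1 in grid:
        for vh2 in grid:
            if vh2 <= vh1:
                continue
            try:
                popt, _ = curve_fit(
                    model2, v, y, p0=[0.5, 1.5, vh1, 1.5, vh2],
                    bounds=([0.05, 1e-3, -400, 1e-3, -400],
                            [0.95, 20, 400, 20, 400]),
                    maxfev=5000)
            except RuntimeError:
                continue
            rss = float(np.sum((model2(v, *popt) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
    if best is None:
        raise RuntimeError("double-Boltzmann fit failed from every start")
    rss, (a, z1, vh1, z2, vh2) = best
    comps = [(float(z1), float(vh1), float(a)),
             (float(z2), float(vh2), float(1 - a))]
    comps.sort(key=lambda c: c[1])  # V1 < V2
    return BoltzmannFit(comps, rss, t_kelvin)


# -- G-V and F-V -----------------------------------------------------------

def gv_from_tails(sweeps: SweepSet, tail_window_s: float = 0.1,
                  settle_gap_s: float = 0.005) -> pd.DataFrame:
    """Conductance-voltage relation from instantaneous tail currents.

    The instantaneous tail current is the mean current over
    ``tail_window_s`` starting ``settle_gap_s`` after the step to the tail
    voltage (the gap skips the capacitive transient); the column
    ``g_normalized`` is scaled by the maximum across test voltages.
    """
    p = sweeps.protocol
    t0 = p.tail_start + settle_gap_s
    t1 = t0 + tail_window_s
    rows = []
    for s in sweeps.sweeps:
        mask = (s.time_s >= t0) & (s.time_s < t1)
        if not mask.any():
            raise ValueError(
                f"sweep at {s.test_voltage_mV} mV has no tail samples")
        rows.append((s.test_voltage_mV, float(np.mean(s.current_uA[mask]))))
    df = pd.DataFrame(rows, columns=["test_voltage_mV", "tail_current_uA"])
    gmax = df["tail_current_uA"].abs().max()
    if gmax == 0:
        raise ValueError("all tail currents are zero; cannot normalize")
    # preserve sign structure relative to the largest tail current
    ref = df.loc[df["tail_current_uA"].abs().idxmax(), "tail_current_uA"]
    df["g_normalized"] = df["tail_current_uA"] / ref
    return df.sort_values("test_voltage_mV", ignore_index=True)


def _fit_baseline(t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exponential-plus-constant photobleaching baseline fitted on the
    pre-pulse segment; linear fallback when the exponential degenerates."""
    def expmodel(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c
    try:
        popt, _ = curve_fit(expmodel, t, f,
                            p0=[max(f[0] - f[-1], 1e-6), max(t[-1], 1.0),
                                f[-1]],
                            bounds=([-np.inf, 1e-3, -np.inf],
                                    [np.inf, 1e6, np.inf]),
                            maxfev=5000)
        if np.all(np.isfinite(popt)):
            return np.asarray(popt)
    except RuntimeError:
        pass
    slope, intercept = np.polyfit(t, f, 1)
    return np.array([np.nan, slope, intercept])  # marker for linear model


def _eval_baseline(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    if np.isnan(params[0]):
        return params[1] * t + params[2]
    a, tau, c = params
    return a * np.exp(-t / tau) + c


def fv_from_fluorescence(sweeps: SweepSet,
                         baseline_window_s: float = 2.0) -> pd.DataFrame:
    """ΔF/F-voltage relation with photobleaching correction.

    Per sweep, a bleaching baseline is fitted on the first
    ``baseline_window_s`` at the holding potential, extrapolated over the
    whole sweep and subtracted; ΔF/F is read at the end of the test pulse
    and normalized by the maximum magnitude across voltages.
    """
    p = sweeps.protocol
    rows = []
    for s in sweeps.sweeps:
        if s.fluorescence_au is None:
            raise ValueError(
                f"sweep at {s.test_voltage_mV} mV has no fluorescence channel")
        base_mask = s.time_s < min(baseline_window_s, p.pre_duration_s)
        params = _fit_baseline(s.time_s[base_mask],
                               s.fluorescence_au[base_mask])
        baseline = _eval_baseline(params, s.time_s)
        if not np.all(np.isfinite(baseline)):
            continue  # baseline fit failure: sweep excluded
        f0 = baseline[0]
        df_over_f = (s.fluorescence_au - baseline) / f0
        # value at the end of the test pulse (mean of last 100 ms)
        mask = (s.time_s >= p.tail_start - 0.1) & (s.time_s < p.tail_start)
        rows.append((s.test_voltage_mV, float(np.mean(df_over_f[mask]))))
    df = pd.DataFrame(rows, columns=["test_voltage_mV", "delta_f_over_f"])
    ref = df["delta_f_over_f"].abs().max()
    if ref == 0:
        df["f_normalized"] = 0.0
    else:
        sign_ref = df.loc[df["delta_f_over_f"].abs().idxmax(),
                          "delta_f_over_f"]
        df["f_normalized"] = df["delta_f_over_f"] / sign_ref
    return df.sort_values("test_voltage_mV", ignore_index=True)


# -- XE991 / chromanol quantification -------------------------------------

def steady_state_current(sweep: Sweep, protocol: VoltageProtocol,
                         window_s: float = 0.1) -> float:
    """Steady-state current: mean over the final ``window_s`` of the test
    pulse."""
    t0 = protocol.tail_start - window_s
    mask = (sweep.time_s >= t0) & (sweep.time_s < protocol.tail_start)
    if not mask.any():
        raise ValueError("no samples in the steady-state window")
    return float(np.mean(sweep.current_uA[mask]))


@dataclass
class InhibitionResult:
    f_xe991: float
    i_control: float
    i_xe991: float
    i_chromanol: float
    n_cells: int = 1
    flagged: bool = False

    def summary(self) -> str:
        note = "  [outside [0, 1]]" if self.flagged else ""
        return (f"XE991 inhibition fraction = {self.f_xe991:.3f}{note}\n"
                f"  I_control = {self.i_control:.3f} uA, "
                f"I_XE991 = {self.i_xe991:.3f} uA, "
                f"I_chromanol = {self.i_chromanol:.3f} uA (n = {self.n_cells})")


def xe991_inhibition(i_control: float, i_xe991: float, i_chromanol: float,
                     tol: float = 1e-12) -> InhibitionResult:
    """Chromanol-subtracted XE991 inhibition fraction:

    f = (I_control - I_XE991) / (I_control - I_chromanol).
    """
    denom = i_control - i_chromanol
    if abs(denom) <= tol:
        raise ZeroDivisionError(
            "control and chromanol currents are equal; inhibition undefined")
    f = (i_control - i_xe991) / denom
    return InhibitionResult(
        f_xe991=float(f), i_control=float(i_control), i_xe991=float(i_xe991),
        i_chromanol=float(i_chromanol), flagged=not (0.0 <= f <= 1.0))


def time_dependent_inhibition(sweep_control: Sweep, sweep_drug: Sweep,
                              protocol: VoltageProtocol,
                              smooth_window: int | None = None) -> pd.DataFrame:
    """Pointwise I_drug(t)/I_control(t) from test-pulse onset.

    Points where the control current crosses zero are masked (NaN) and
    flagged in the ``masked`` column.
    """
    if sweep_control.test_voltage_mV != sweep_drug.test_voltage_mV:
        raise ValueError("sweeps recorded at different test voltages")
    if (len(sweep_control.time_s) != len(sweep_drug.time_s)
            or not np.allclose(sweep_control.time_s, sweep_drug.time_s)):
        raise ValueError("sweeps do not share a time base")
    mask = ((sweep_control.time_s >= protocol.test_start)
            & (sweep_control.time_s < protocol.tail_start))
    t = sweep_control.time_s[mask] - protocol.test_start
    ic = sweep_control.current_uA[mask].copy()
    idr = sweep_drug.current_uA[mask].copy()
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ic = np.convolve(ic, kernel, mode="same")
        idr = np.convolve(idr, kernel, mode="same")
    scale = np.max(np.abs(ic))
    bad = np.abs(ic) < 1e-6 * max(scale, 1e-12)
    ratio = np.where(bad, np.nan, idr / np.where(bad, 1.0, ic))
    df = pd.DataFrame({"time_s": t, "ratio": ratio, "masked": bad})
    df.attrs["smooth_window"] = smooth_window
    return df
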