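"""Single-compartment voltage-clamp simulation of VGCC and NMDAR calcium gating.

The voltage-gated calcium channel (VGCC) carries an activation gate m (squared)
and an inactivation gate h; its open probability is m^2 h.  The NMDA receptor's
voltage dependence arises from magnesium block with on/off rates k_on, k_off;
its unblocked (open) fraction is n.  Gate dynamics follow first-order kinetics

    dm/dt = alpha(V) - m * (alpha(V) + beta(V))

integrated with forward Euler at dt = 0.01 ms.  Calcium influx through an open
channel uses the Goldman-Hodgkin-Katz (GHK) constant-field current form

    I_Ca = P_open * V * ([Ca]_in - [Ca]_out e^{-2VF/RT}) / (1 - e^{-2VF/RT})

with inward (influx) current negative.  Command waveforms are quadratic
depolarizations step(t) = V_amp - (a t)^2 that mimic the shape of an action
potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GatingParams",
    "StimulusWaveform",
    "GatingTrace",
    "vgcc_rates",
    "vgcc_steady_state",
    "nmdar_rates",
    "nmdar_open_probability",
    "quadratic_stimulus",
    "simulate_gating",
    "ghk_current",
    "influx_sweep",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)


@dataclass
class GatingParams:
    """Physical parameters of the gating/influx simulation.

    Concentrations follow dendritic recording conditions: 75 nM resting
    internal calcium, 1.5 mM external.  Temperature defaults to 307.15 K
    (34 C, the recording bath temperature), giving RT/2F ~ 13.2 mV.
    """

    mg_um: float = 1.0          # [Mg2+] in uM seen by the blocking rate
    ca_in_mM: float = 75e-6     # 75 nM
    ca_out_mM: float = 1.5
    temperature_K: float = 307.15
    dt_ms: float = 0.01
    baseline_mV: float = -70.0

    def __post_init__(self):
        if self.mg_um <= 0 or self.ca_in_mM <= 0 or self.ca_out_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")

    @property
    def vt_mV(self) -> float:
        """RT/2F in mV for a divalent ion."""
        return 1e3 * GAS_CONSTANT * self.temperature_K / (2 * FARADAY)


def vgcc_rates(V):
    """Forward/backward rates (ms^-1) of the VGCC activation and inactivation gates.

    alpha_m has a removable singularity at V = -27 mV, handled by its analytic
    limit 0.055 * 3.8.
    """
    V = np.asarray(V, dtype=float)
    u = -27.0 - V
    with np.errstate(over="ignore", invalid="ignore"):
        alpha_m = np.where(
            np.abs(u) < 1e-7,
            0.055 * 3.8,
            0.055 * u / np.expm1(u / 3.8),
        )
    beta_m = 0.94 * np.exp((-75.0 - V) / 17.0)
    alpha_h = 0.000457 * np.exp((-13.0 - V) / 50.0)
    beta_h = 0.0065 / (np.exp((-V - 15.0) / 28.0) + 1.0)
    return alpha_m, beta_m, alpha_h, beta_h


def vgcc_steady_state(V):
    """Steady-state m_inf, h_inf and time constants tau_m, tau_h (ms)."""
    am, bm, ah, bh = vgcc_rates(V)
    return am / (am + bm), ah / (ah + bh), 1.0 / (am + bm), 1.0 / (ah + bh)


def min_inactivation_tau(v_lo: float = -80.0, v_hi: float = 40.0,
                         dv: float = 0.1) -> tuple[float, float]:
    """Minimum of tau_h over a voltage grid; returns (tau_min_ms, argmin_mV).

    The inactivation gate is slow everywhere in the physiological range
    (minimum near 170 ms), so over millisecond stimuli it is effectively
    constant.
    """
    grid = np.arange(v_lo, v_hi + dv / 2, dv)
    _, _, _, tau_h = vgcc_steady_state(grid)
    i = int(np.argmin(tau_h))
    return float(tau_h[i]), float(grid[i])


def nmdar_rates(V, mg_um: float = 1.0):
    """Mg-block rates (k_on, k_off) in ms^-1; k_on scales linearly with [Mg2+] (uM)."""
    if mg_um <= 0:
        raise ValueError("Mg concentration must be positive")
    V = np.asarray(V, dtype=float)
    k_off = np.exp(0.017 * V + 0.96)
    k_on = mg_um * np.exp(-0.045 * V - 6.97)
    return k_on, k_off


def nmdar_open_probability(V, mg_um: float = 1.0):
    k_on, k_off = nmdar_rates(V, mg_um)
    return k_off / (k_on + k_off)


@dataclass
class StimulusWaveform:
    """Quadratic depolarization riding on a holding potential."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    v_amp: float
    v_dur: float
    baseline: float
    a: float

    @property
    def dt(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])


def quadratic_stimulus(v_amp: float, v_dur: float, baseline: float = -70.0,
                       dt: float = 0.01, pad_ms: float = 2.0) -> StimulusWaveform:
    """Parabolic voltage command peaking at baseline + v_amp.

    The coefficient a solves V_amp = (a * V_dur / 2)^2, so the waveform
    step(t) = V_amp - (a t)^2 rises from baseline at t = -V_dur/2 to its peak
    at t = 0 and returns to baseline at t = +V_dur/2.  ``pad_ms`` of holding
    potential is appended on each side.  A zero-amplitude stimulus is allowed
    (flat hold at baseline).
    """
    if v_amp < 0 or v_dur <= 0:
        raise ValueError("require v_amp >= 0 and v_dur > 0")
    a = 2.0 * np.sqrt(v_amp) / v_dur
    t = np.arange(-pad_ms - v_dur / 2, pad_ms + v_dur / 2 + dt / 2, dt)
    v = np.full_like(t, float(baseline))
    inside = np.abs(t) < v_dur / 2
    v[inside] = baseline + v_amp - (a * t[inside]) ** 2
    # exact samples at the peak and edges where the grid hits them
    v[np.isclose(t, 0.0, atol=dt / 4)] = baseline + v_amp
    return StimulusWaveform(t, v, float(v_amp), float(v_dur), float(baseline), float(a))


@dataclass
class GatingTrace:
    """Gate and open-probability time courses under a voltage command."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    params: GatingParams = field(repr=False, default_factory=GatingParams)

    @property
    def p_open_vgcc(self) -> np.ndarray:
        return self.m ** 2 * self.h

    @property
    def p_open_nmdar(self) -> np.ndarray:
        return self.n


def simulate_gating(waveform: StimulusWaveform, params: GatingParams | None = None) -> GatingTrace:
    """Integrate m, h, n along a voltage command with forward Euler.

    Gates start at their analytic steady state for the waveform's first
    sample.  Raises if the explicit step is unstable (a gate leaves [0, 1]).
    """
    params = params or GatingParams()
    v = waveform.v_mV
    dt = waveform.dt
    am, bm, ah, bh = vgcc_rates(v)
    k_on, k_off = nmdar_rates(v, params.mg_um)

    m = np.empty_like(v)
    h = np.empty_like(v)
    n = np.empty_like(v)
    m[0] = am[0] / (am[0] + bm[0])
    h[0] = ah[0] / (ah[0] + bh[0])
    n[0] = k_off[0] / (k_on[0] + k_off[0])
    for i in range(len(v) - 1):
        m[i + 1] = m[i] + dt * (am[i] - m[i] * (am[i] + bm[i]))
        h[i + 1] = h[i] + dt * (ah[i] - h[i] * (ah[i] + bh[i]))
        n[i + 1] = n[i] + dt * (k_off[i] - n[i] * (k_off[i] + k_on[i]))
    gates = np.stack([m, h, n])
    if gates.min() < -1e-12 or gates.max() > 1 + 1e-12:
        raise RuntimeError(
            f"gate left [0, 1] during Euler integration; reduce dt below {dt} ms")
    return GatingTrace(waveform.t_ms, v, m, h, n, params)


def ghk_current(p_open, V, params: GatingParams | None = None):
    """GHK calcium current (arbitrary units; inward/influx negative).

    The V = 0 singularity is removable; the analytic limit is
    (RT/2F) * ([Ca]_in - [Ca]_out) * P_open.
    """
    params = params or GatingParams()
    p_open = np.asarray(p_open, dtype=float)
    V = np.asarray(V, dtype=float)
    vt = params.vt_mV
    u = V / vt  # 2VF/RT, dimensionless
    with np.errstate(over="ignore", invalid="ignore"):
        flux = np.where(
            np.abs(u) < 1e-9,
            vt * (params.ca_in_mM - params.ca_out_mM),
            V * (params.ca_in_mM - params.ca_out_mM * np.exp(-u)) / (-np.expm1(-u)),
        )
    out = p_open * flux
    return out if out.ndim else float(out)


def _integrated_influx(trace: GatingTrace, p_open: np.ndarray,
                       params: GatingParams) -> float:
    """Time integral of the baseline-subtracted GHK current (a.u. * ms).

    NMDARs are partially open at rest, so the holding-potential current is
    subtracted before integration.
    """
    i_ca = ghk_current(p_open, trace.v_mV, params)
    i_base = ghk_current(p_open[0], trace.v_mV[0], params)
    return float(np.trapezoid(i_ca - i_base, trace.t_ms))


def influx_sweep(v_amps, v_durs=(1.0, 0.5), params: GatingParams | None = None) -> pd.DataFrame:
    """Peak open probability and integrated calcium influx per stimulus.

    One row per (channel, V_amp, V_dur).  ``influx_au`` is the integrated
    baseline-subtracted GHK current (negative = net influx); ``influx_norm``
    is each channel's influx normalized to its maximum magnitude within the
    sweep, for cross-channel comparison.
    """
    params = params or GatingParams()
    rows = []
    for v_dur in v_durs:
        for v_amp in v_amps:
            wf = quadratic_stimulus(v_amp, v_dur, params.baseline_mV, params.dt_ms)
            tr = simulate_gating(wf, params)
            for channel, p in (("VGCC", tr.p_open_vgcc), ("NMDAR", tr.p_open_nmdar)):
                rows.append({
                    "channel": channel,
                    "v_amp_mV": float(v_amp),
                    "v_dur_ms": float(v_dur),
                    "v_peak_mV": params.baseline_mV + float(v_amp),
                    "peak_popen": float(p.max()),
                    "influx_au": _integrated_influx(tr, p, params),
                })
    df = pd.DataFrame(rows)
    for channel in df["channel"].unique():
        sel = df["channel"] == channel
        peak = df.loc[sel, "influx_au"].abs().max()
        df.loc[sel, "influx_norm"] = df.loc[sel, "influx_au"].abs() / (peak if peak else 1.0)
    return df
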