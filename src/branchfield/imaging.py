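"""Quantification of fluorescence and electrophysiology trials.

Calcium transients are measured as dG/R: the stimulus-evoked change in the
calcium-sensitive green channel relative to a pre-stimulus baseline, divided
by the baseline of the structural red channel.  Amplitudes are the mean of the
trial-averaged dG/R over a 10 ms window centered on the site's average peak
time.  Supralinear amplification of paired stimulation is

    dCa_amp = dCa_pairing - (dCa_AP + dCa_uEPSP)

Sites are classified by their bAP-evoked transient (two-photon bands:
high 0.1 < dCa_AP < 0.3, low dCa_AP < 0.04; one-photon bands scaled by 1.75).
The module also covers uncaging-EPSP metrics, loose-patch spike amplitudes,
conduction-velocity regression from fluorescence-derivative latencies,
spike-triggered-average dF/F0 mapping, and the group statistics used to
compare site populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "FluorescenceRecording",
    "TransientSet",
    "VoltageTrial",
    "transient_amplitude",
    "uepsp_metrics",
    "amplification",
    "classify_site",
    "classify_and_pair",
    "loose_patch_amplitude",
    "conduction_velocity",
    "fwhm",
    "bap_spatial_width",
    "sta_dff_map",
    "group_stats",
    "cohens_d",
]

HIGH_BAND = (0.1, 0.3)
LOW_MAX = 0.04
ONE_PHOTON_SCALE = 1.75
PAIR_RATIO_MIN_PROXIMAL = 0.1


@dataclass
class FluorescenceRecording:
    """Per-trial two-channel line-scan fluorescence at one site.

    ``g`` and ``r`` are (n_trials, n_samples); ``rate`` in kHz (samples/ms);
    ``stim_ms`` marks stimulus onset relative to trace start.
    """

    g: np.ndarray
    r: np.ndarray
    rate: float
    stim_ms: float
    condition: str = "bAP"
    site: str = ""
    baseline_ms: float = 50.0

    def __post_init__(self):
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if self.g.shape != self.r.shape:
            raise ValueError("G and R must have the same shape")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.g.shape[1]) / self.rate

    def dgr(self) -> np.ndarray:
        """Trial-averaged dG/R trace."""
        i_stim = int(self.stim_ms * self.rate)
        i0 = max(0, i_stim - int(self.baseline_ms * self.rate))
        if i_stim <= i0:
            raise ValueError("baseline period must precede the stimulus")
        g_mean = self.g.mean(axis=0)
        r0 = self.r[:, i0:i_stim].mean()
        if r0 <= 0:
            raise ValueError("red-channel baseline must be positive")
        return (g_mean - g_mean[i0:i_stim].mean()) / r0


@dataclass
class TransientSet:
    """Trial-averaged transient with its derived amplitude."""

    trace: np.ndarray
    t_ms: np.ndarray
    amplitude: float
    peak_time_ms: float
    condition: str


def transient_amplitude(recording: FluorescenceRecording, window_ms: float = 10.0,
                        peak_time_ms: float | None = None) -> TransientSet:
    """Stimulus-evoked dG/R amplitude.

    The amplitude is the mean of the trial-averaged dG/R over a window of
    ``window_ms`` centered on the site's average peak time.  If
    ``peak_time_ms`` is not given it is taken from the post-stimulus maximum
    of this recording's own trial average.
    """
    trace = recording.dgr()
    t = recording.t_ms
    i_stim = int(recording.stim_ms * recording.rate)
    if peak_time_ms is None:
        post = trace[i_stim:]
        peak_time_ms = t[i_stim + int(np.argmax(post))]
    if not (t[0] <= peak_time_ms <= t[-1]):
        raise ValueError("peak time lies outside the recorded trace")
    half = window_ms / 2
    sel = (t >= peak_time_ms - half) & (t <= peak_time_ms + half)
    amp = float(trace[sel].mean())
    return TransientSet(trace, t, amp, float(peak_time_ms), recording.condition)


@dataclass
class VoltageTrial:
    """Whole-cell or loose-patch voltage trials (n_trials, n_samples), mV."""

    v: np.ndarray
    rate: float            # kHz
    event_ms: float        # uncaging or AP-command time
    configuration: str = "whole-cell"

    def __post_init__(self):
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))


def uepsp_metrics(trials: VoltageTrial, search_ms: float = 25.0,
                  median_ms: float = 1.0):
    """Uncaging-EPSP amplitude (mV) and peak time (ms after uncaging).

    Trials are averaged, baseline-subtracted, median-filtered over a 1 ms
    window (reflect padding), and the maximum on (0, 25] ms after uncaging is
    taken.  A flat trace reports amplitude 0 with the peak time flagged
    (returned as nan) rather than raising.
    """
    v = trials.v.mean(axis=0)
    rate = trials.rate
    i_ev = int(trials.event_ms * rate)
    base = v[:i_ev].mean() if i_ev > 0 else v[0]
    v = v - base
    size = max(1, int(round(median_ms * rate)))
    if size % 2 == 0:
        size += 1
    vf = ndimage.median_filter(v, size=size, mode="reflect")
    i0, i1 = i_ev + 1, min(len(vf), i_ev + int(search_ms * rate) + 1)
    if i1 <= i0:
        raise ValueError("search window lies outside the trace")
    seg = vf[i0:i1]
    k = int(np.argmax(seg))
    amp = float(seg[k])
    peak_t = (i0 + k) / rate - trials.event_ms
    if np.ptp(seg) < 1e-12:
        return 0.0, float("nan")
    return amp, float(peak_t)


def amplification(dca_ap: float, dca_uepsp: float, dca_pairing: float) -> float:
    """Supralinear pairing amplification; negative (sublinear) values allowed."""
    return dca_pairing - (dca_ap + dca_uepsp)


def classify_site(dca_ap: float, mode: str = "2p") -> str:
    """High/low/unclassified label from the bAP-evoked transient amplitude.

    One-photon recordings rescale the selection bands by the 1.75 sensitivity
    factor between the modalities (one-photon transients run smaller, so the
    bands shrink by that factor).
    """
    scale = 1.0 / ONE_PHOTON_SCALE if mode == "1p" else 1.0
    lo, hi = HIGH_BAND[0] * scale, HIGH_BAND[1] * scale
    if lo < dca_ap < hi:
        return "high"
    if dca_ap < LOW_MAX * scale:
        return "low"
    return "unclassified"


def classify_and_pair(table: pd.DataFrame, mode: str = "2p") -> dict:
    """Classify sites and compare transient ratios within vs across branch points.

    ``table`` columns: site, dca_ap, distance_um, segment_pair_id (sites
    sharing an id form a proximal/distal pair), spans_branch_point (bool for
    the pair).  Ratios dCa_AP(distal)/dCa_AP(proximal) are computed only when
    the proximal site exceeds 0.1; within-segment and across-branch-point
    ratio distributions are compared with a rank-sum test.
    """
    out = table.copy()
    out["label"] = [classify_site(a, mode) for a in out["dca_ap"]]

    ratios = []
    excluded = []
    for pid, grp in out.dropna(subset=["segment_pair_id"]).groupby("segment_pair_id"):
        if len(grp) != 2:
            continue
        grp = grp.sort_values("distance_um")
        prox, dist = grp.iloc[0], grp.iloc[1]
        if prox["dca_ap"] <= PAIR_RATIO_MIN_PROXIMAL:
            excluded.append(pid)
            continue
        ratios.append({
            "pair_id": pid,
            "ratio": dist["dca_ap"] / prox["dca_ap"],
            "spans_branch_point": bool(prox["spans_branch_point"]),
        })
    ratio_df = pd.DataFrame(ratios)
    result = {"table": out, "ratios": ratio_df, "excluded_pairs": excluded,
              "ranksum": None}
    if len(ratio_df) and ratio_df["spans_branch_point"].nunique() == 2:
        within = ratio_df.loc[~ratio_df["spans_branch_point"], "ratio"]
        across = ratio_df.loc[ratio_df["spans_branch_point"], "ratio"]
        stat, p = stats.ranksums(across, within)
        result["ranksum"] = {"statistic": float(stat), "p": float(p),
                             "median_within": float(within.median()),
                             "median_across": float(across.median())}
    return result


def loose_patch_amplitude(pre_seal: VoltageTrial, sealed: VoltageTrial,
                          window_ms: float = 0.2) -> float:
    """Loose-patch spike amplitude: sealed minus pre-seal estimate.

    Per trial, the signal is the mean over a 0.2 ms window centered on the
    peak voltage (baseline-subtracted); the recording's estimate averages the
    trials in the top half of signal-to-noise ratio (peak / baseline SD).
    """

    def estimate(trials: VoltageTrial) -> float:
        if trials.v.shape[0] < 2:
            raise ValueError("need at least 2 trials")
        rate = trials.rate
        i_ev = int(trials.event_ms * rate)
        half = max(1, int(round(window_ms / 2 * rate)))
        amps, snrs = [], []
        for trial in trials.v:
            base = trial[:i_ev]
            b_mean, b_sd = base.mean(), base.std()
            seg = trial[i_ev:] - b_mean
            k = i_ev + int(np.argmax(np.abs(seg)))
            lo, hi = max(0, k - half), min(len(trial), k + half + 1)
            peak = trial[k] - b_mean
            amps.append((trial[lo:hi] - b_mean).mean())
            snrs.append(abs(peak) / b_sd if b_sd > 0 else np.inf)
        amps, snrs = np.array(amps), np.array(snrs)
        top = snrs >= np.median(snrs)
        return float(amps[top].mean())

    return estimate(sealed) - estimate(pre_seal)


def conduction_velocity(distances_um, latencies_ms=None, recordings=None):
    """bAP conduction velocity from latency-vs-distance regression.

    Latencies may be given directly, or derived from fluorescence recordings
    as the time of peak influx rate (argmax of the central-difference
    derivative of the trial-averaged dG/R).  Velocity is the inverse slope of
    the latency-on-distance regression.  Returns a dict with velocity (um/ms),
    slope, intercept, r2, F, p and a flag for an unphysical (non-positive)
    slope.
    """
    distances = np.asarray(distances_um, dtype=float)
    if latencies_ms is None:
        if recordings is None:
            raise ValueError("give latencies_ms or recordings")
        latencies_ms = [peak_influx_latency(r) for r in recordings]
    lat = np.asarray(latencies_ms, dtype=float)
    if len(distances) < 3 or len(np.unique(distances)) < 3:
        raise ValueError("need >= 3 sites at distinct distances")
    fit = stats.linregress(distances, lat)
    n = len(distances)
    f_stat = fit.rvalue ** 2 / (1 - fit.rvalue ** 2) * (n - 2) if abs(fit.rvalue) < 1 else np.inf
    return {
        "velocity_um_per_ms": (1.0 / fit.slope) if fit.slope > 0 else np.nan,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue ** 2),
        "F": float(f_stat),
        "p": float(fit.pvalue),
        "unphysical": bool(fit.slope <= 0),
    }


def peak_influx_latency(recording: FluorescenceRecording) -> float:
    """Latency (ms from stimulus) of the peak fluorescence rise rate."""
    trace = recording.dgr()
    t = recording.t_ms
    deriv = np.gradient(trace, t)
    i_stim = int(recording.stim_ms * recording.rate)
    k = i_stim + int(np.argmax(deriv[i_stim:]))
    return float(t[k] - recording.stim_ms)


def fwhm(t_ms: np.ndarray, trace: np.ndarray) -> float:
    """Full width at half maximum of a single peak, by linear interpolation."""
    t_ms = np.asarray(t_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    base, peak = trace.min(), trace.max()
    if peak <= base:
        raise ValueError("flat trace has no width")
    half = base + (peak - base) / 2
    idx = np.flatnonzero(trace >= half)
    i0, i1 = idx[0], idx[-1]

    def interp(ia, ib):
        # half-crossing time on the segment between samples ia (below) and ib
        if trace[ib] == trace[ia]:
            return t_ms[ib]
        frac = (half - trace[ia]) / (trace[ib] - trace[ia])
        return t_ms[ia] + frac * (t_ms[ib] - t_ms[ia])

    left = interp(i0 - 1, i0) if i0 > 0 else t_ms[0]
    right = interp(i1 + 1, i1) if i1 + 1 < len(trace) else t_ms[-1]
    return float(right - left)


def bap_spatial_width(velocity_um_per_ms: float, ap_fwhm_ms: float) -> float:
    """Spatial extent of a propagating bAP: conduction velocity x AP duration."""
    return velocity_um_per_ms * ap_fwhm_ms


# ---------------------------------------------------------------------------
# STA dF/F0 mapping
# ---------------------------------------------------------------------------

def sta_dff_map(movie: np.ndarray, spike_frames, window: tuple[int, int] = (-2, 6),
                roi_percentile: float = 95.0) -> dict:
    """Spike-triggered-average dF/F0 from a voltage-imaging movie.

    Pipeline: (1) average movie windows around each spike into an STA movie;
    (2) take the mean trace over the brightest 5% of pixels as the initial
    waveform estimate and normalize it; (3) regress every pixel's STA trace
    against the waveform (with offset) to obtain per-pixel baseline F
    (offset) and spike-dependent dF (slope); (4) watershed-segment the dF map
    and keep the region containing the highest dF; (5) within that region
    regress F on dF -- the inverse slope is dF/F0.
    """
    from skimage.segmentation import watershed

    movie = np.asarray(movie, dtype=float)
    spike_frames = np.asarray(spike_frames, dtype=int)
    if len(spike_frames) < 1:
        raise ValueError("need at least one spike")
    w0, w1 = window
    segs = [movie[s + w0:s + w1] for s in spike_frames
            if s + w0 >= 0 and s + w1 <= movie.shape[0]]
    if not segs:
        raise ValueError("no spike windows fit inside the movie")
    sta = np.mean(segs, axis=0)  # (T, H, W)
    T = sta.shape[0]

    mean_img = sta.mean(axis=0)
    thresh = np.percentile(mean_img, roi_percentile)
    roi = mean_img >= thresh
    if not roi.any():
        raise ValueError("no pixels above the ROI brightness threshold")
    # initial waveform estimate, normalized to unit peak above its baseline so
    # the per-pixel slope is the spike-evoked dF in fluorescence units
    wave = sta[:, roi].mean(axis=1)
    wave = wave - wave.min()
    if wave.max() == 0:
        raise ValueError("flat STA waveform; no spike-dependent signal")
    wave = wave / wave.max()

    # per-pixel least-squares of trace = offset + slope * wave
    flat = sta.reshape(T, -1)
    wc = wave - wave.mean()
    slope = (wc @ (flat - flat.mean(axis=0))) / float(wc @ wc)
    offset = flat.mean(axis=0) - slope * wave.mean()
    df_map = slope.reshape(mean_img.shape)
    f_map = offset.reshape(mean_img.shape)

    if df_map.max() <= 0 or df_map.max() < 5 * np.median(np.abs(df_map)):
        raise ValueError("no spike-dependent signal detected in the dF map")

    # watershed on the inverted dF map splits it into catchment basins around
    # each local maximum; keep the basin of the global dF peak, restricted to
    # pixels with appreciable spike-dependent signal
    markers, _ = ndimage.label(df_map >= 0.5 * df_map.max())
    labels = watershed(-df_map, markers=markers, mask=df_map > 0.1 * df_map.max())
    peak_label = labels[np.unravel_index(np.argmax(df_map), df_map.shape)]
    if peak_label == 0:
        raise ValueError("watershed produced no region at the dF peak")
    region = labels == peak_label
    if region.sum() < 3:
        raise ValueError("spike-dependent region too small for the F-vs-dF fit")

    fit = stats.linregress(df_map[region], f_map[region])
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise ValueError("degenerate F-vs-dF fit")
    dff = 1.0 / fit.slope
    return {"f_map": f_map, "df_map": df_map, "region": region,
            "dff": float(dff), "waveform": wave, "labels": labels}


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def group_stats(a, b, test: str = "mannwhitney") -> dict:
    """Two-sample comparison with effect size.

    ``test``: 'mannwhitney' (U with z from the tie-corrected normal
    approximation; exact p for n <= 8 per group), 'ranksum', 'ttest', or
    'regression' (slope/R^2/F/p of b on a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "regression":
        fit = stats.linregress(a, b)
        n = len(a)
        f_stat = fit.rvalue ** 2 / (1 - fit.rvalue ** 2) * (n - 2) if abs(fit.rvalue) < 1 else np.inf
        return {"slope": float(fit.slope), "intercept": float(fit.intercept),
                "r2": float(fit.rvalue ** 2), "F": float(f_stat), "p": float(fit.pvalue)}
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if test == "mannwhitney":
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        # z from the tie-corrected normal approximation
        n1, n2 = len(a), len(b)
        mu = n1 * n2 / 2
        combined = np.concatenate([a, b])
        _, counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie))
        z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
        return {"statistic": float(res.statistic), "z": float(z),
                "p": float(res.pvalue), "effect_size": cohens_d(a, b)}
    if test == "ranksum":
        stat, p = stats.ranksums(a, b)
        return {"statistic": float(stat), "z": float(stat), "p": float(p),
                "effect_size": cohens_d(a, b)}
    if test == "ttest":
        res = stats.ttest_ind(a, b)
        return {"statistic": float(res.statistic), "z": None,
                "p": float(res.pvalue), "effect_size": cohens_d(a, b)}
    raise ValueError(f"unknown test {test!r}")
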