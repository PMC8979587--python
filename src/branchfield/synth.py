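"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the experimental regime in layer-2/3 pyramidal-cell
apical dendrites: trees with uniform 1 um dendritic diameter and recording
sites 75-300 um from the soma at branch orders ~1-6; two-channel line-scan
fluorescence trials with dG/R transient amplitudes in the observed 0-0.3
range; voltage trials with a 0.5 mV uncaging EPSP and a bAP command 5 ms
later; voltage-imaging movies with a known dF/F0; and latency-vs-distance
data around the measured 154.9 um/ms conduction velocity.

Each generator is deterministic per seed and returns its ground truth
alongside the data, so recovery tests never re-derive the truth from the
generated records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import FluorescenceRecording, VoltageTrial
from .morphology import Morphology, Node, Site, branch_complexity, site_metrics

__all__ = [
    "MorphologyConfig",
    "SyntheticCell",
    "gen_morphology",
    "gen_ensemble",
    "TrialConfig",
    "gen_imaging_trials",
    "gen_sta_movie",
    "gen_latency_data",
]

DEFAULT_LAMBDA = 145.0


@dataclass(frozen=True)
class MorphologyConfig:
    """Growth parameters of the synthetic apical tree.

    One daughter subtree of the first bifurcation is 'elaborated': its branch
    rate is multiplied by ``elaboration``, manufacturing a high-complexity
    region so that every cell contains a distance-matched site pair whose
    branch complexity differs by at least ``min_omega_ratio``.
    """

    target_depth: float = 330.0       # um of apical extent beyond the trunk
    branch_rate: float = 1.0 / 80.0   # bifurcations per um of path
    elaboration: float = 6.0          # branch-rate multiplier in the hotspot
    hotspot_len: float = 90.0         # um of elevated branching past the site
    trunk_length: float = 50.0        # um from soma to the first bifurcation
    dendrite_diam: float = 1.0        # um
    seg_step: float = 15.0            # um between geometry nodes
    max_order: int = 8
    site_distance: tuple[float, float] = (100.0, 160.0)  # um from soma
    pair_max_offset: float = 10.0     # um distance mismatch within a pair
    min_omega_ratio: float = 1.3
    max_retries: int = 30


@dataclass
class SyntheticCell:
    """A generated morphology with its annotated matched site pair.

    ``site_high`` is the higher-complexity member (the low-dCa_AP analog),
    ``site_low`` the lower-complexity member.  ``truth`` carries the
    generator-side per-site transient amplitudes used by the trial generator.
    """

    morphology: Morphology
    site_high: Site
    site_low: Site
    omega_high: float
    omega_low: float
    cell_id: str
    seed: int
    truth: dict = field(default_factory=dict)


class _TreeBuilder:
    def __init__(self, rng: np.random.Generator, cfg: MorphologyConfig):
        self.rng = rng
        self.cfg = cfg
        self.nodes: list[Node] = []
        self._next_id = 1

    def add(self, parent_id, pos, radius, region) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes.append(Node(nid, parent_id, np.asarray(pos, float), radius, region))
        return nid

    def chain(self, parent_id, start, direction, length, radius, region,
              jitter=0.25) -> tuple[int, np.ndarray, np.ndarray]:
        """Grow a node chain of given length with small direction jitter."""
        step = self.cfg.seg_step
        n = max(1, int(round(length / step)))
        pos = np.asarray(start, float)
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        for _ in range(n):
            d = d + jitter * self.rng.standard_normal(3)
            d = d / np.linalg.norm(d)
            pos = pos + d * (length / n)
            parent_id = self.add(parent_id, pos, radius, region)
        return parent_id, pos, d


def _grow_subtree(tb: _TreeBuilder, parent_id, pos, direction, depth_left,
                  dist_soma, rate_fn, order, cfg: MorphologyConfig):
    """Grow recursively; ``rate_fn(dist_from_soma)`` gives the local branch
    rate per um, which lets one subtree carry a branching hotspot."""
    rng = tb.rng
    radius = cfg.dendrite_diam / 2
    rate = rate_fn(dist_soma)
    seg = float(rng.exponential(1.0 / rate))
    seg = float(np.clip(seg, 12.0, 120.0))
    if seg >= depth_left or order >= cfg.max_order:
        # terminal branch: run out the remaining depth (at least 15 um)
        length = max(15.0, depth_left * float(rng.uniform(0.6, 1.0)))
        tb.chain(parent_id, pos, direction, length, radius, "dendrite")
        return
    parent_id, pos, direction = tb.chain(parent_id, pos, direction, seg, radius,
                                         "dendrite")
    # bifurcate: two daughters diverging around the parent direction
    for sign in (-1.0, 1.0):
        dev = rng.uniform(0.3, 0.8)
        perp = rng.standard_normal(3)
        perp -= perp @ direction * direction
        perp /= np.linalg.norm(perp)
        d_new = direction + sign * dev * perp
        d_new /= np.linalg.norm(d_new)
        _grow_subtree(tb, parent_id, pos, d_new, depth_left - seg,
                      dist_soma + seg, rate_fn, order + 1, cfg)


def _build_tree(seed: int, cfg: MorphologyConfig,
                hotspot: tuple[float, float]) -> tuple[Morphology, int, int]:
    """One tree; returns (morphology, sparse-subtree root edge, elaborated-root edge).

    The elaborated subtree branches at ``elaboration`` times the base rate for
    on-path soma distances inside ``hotspot`` (just distal to the
    high-complexity site), emulating sites immediately proximal to dendritic
    branch elaboration.
    """
    rng = np.random.default_rng(seed)
    tb = _TreeBuilder(rng, cfg)
    root = tb.add(None, (0.0, 0.0, 0.0), 6.0, "soma")
    soma_top = tb.add(root, (0.0, 12.0, 0.0), 6.0, "soma")
    # AIS and axon hang off the soma base
    ais = tb.chain(root, (0.0, 0.0, 0.0), (0.0, -1.0, 0.0), 30.0, 1.0, "AIS",
                   jitter=0.0)[0]
    tb.chain(ais, (0.0, -30.0, 0.0), (0.0, -1.0, 0.0), 300.0, 0.5, "axon",
             jitter=0.05)
    # apical trunk, then one sparse and one elaborated daughter subtree
    trunk_id, trunk_pos, trunk_dir = tb.chain(
        soma_top, (0.0, 12.0, 0.0), (0.0, 1.0, 0.0), cfg.trunk_length,
        cfg.dendrite_diam / 2, "dendrite", jitter=0.1)
    base = cfg.branch_rate
    d0 = 12.0 + cfg.trunk_length

    def sparse_rate(_d):
        return base

    def elab_rate(d):
        return base * cfg.elaboration if hotspot[0] <= d <= hotspot[1] else base

    n_before = len(tb.nodes)
    depth = cfg.target_depth
    _grow_subtree(tb, trunk_id, trunk_pos, trunk_dir + np.array([-0.6, 0.3, 0.0]),
                  depth, d0, sparse_rate, 1, cfg)
    sparse_root = tb.nodes[n_before].id
    n_before = len(tb.nodes)
    _grow_subtree(tb, trunk_id, trunk_pos, trunk_dir + np.array([0.6, 0.3, 0.0]),
                  depth, d0, elab_rate, 1, cfg)
    elab_root = tb.nodes[n_before].id
    return Morphology(tb.nodes), sparse_root, elab_root


def _site_at_distance(morph: Morphology, subtree_root_edge: int, target: float,
                      cell_id: str, label: str) -> Site | None:
    """A dendritic site at the given on-path soma distance within a subtree."""
    for eid in sorted(morph.subtree(subtree_root_edge)):
        if eid not in morph.nodes or morph.nodes[eid].region != "dendrite":
            continue
        node = morph.nodes[eid]
        if node.parent_id is None:
            continue
        d_child = sum(morph.edge_length(e) for e in morph.path_to_root(eid))
        L = morph.edge_length(eid)
        d_parent = d_child - L
        if d_parent <= target <= d_child:
            off = (target - d_parent) / L
            return Site(morph, eid, float(np.clip(off, 0.0, 1.0)), cell_id, label)
    return None


def gen_morphology(seed: int = 0, config: MorphologyConfig | None = None,
                   cell_id: str | None = None) -> SyntheticCell:
    """Synthetic apical tree with a distance-matched, complexity-split site pair.

    Retries (with derived sub-seeds) until the pair satisfies the distance and
    complexity-ratio requirements; raises after ``max_retries`` failures.
    """
    cfg = config or MorphologyConfig()
    cell_id = cell_id or f"synth{seed}"
    base = np.random.SeedSequence(seed)
    for attempt, child in enumerate(base.spawn(cfg.max_retries)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed + 1)
        target = float(rng.uniform(*cfg.site_distance))
        target_b = target + float(rng.uniform(-cfg.pair_max_offset,
                                              cfg.pair_max_offset))
        hotspot = (target_b, target_b + cfg.hotspot_len)
        morph, sparse_root, elab_root = _build_tree(sub_seed, cfg, hotspot)
        s_low = _site_at_distance(morph, sparse_root, target, cell_id, "low_omega")
        s_high = _site_at_distance(morph, elab_root, target_b, cell_id, "high_omega")
        if s_low is None or s_high is None:
            continue
        om_low = branch_complexity(s_low, DEFAULT_LAMBDA)
        om_high = branch_complexity(s_high, DEFAULT_LAMBDA)
        if om_high < cfg.min_omega_ratio * om_low:
            continue
        truth = {
            "low_omega": {"dca_ap": 0.2, "dca_uepsp": 0.06, "dca_amp": 0.12},
            "high_omega": {"dca_ap": 0.02, "dca_uepsp": 0.06, "dca_amp": 0.15},
        }
        return SyntheticCell(morph, s_high, s_low, float(om_high), float(om_low),
                             cell_id, seed, truth)
    raise RuntimeError(
        f"no valid matched site pair after {cfg.max_retries} attempts (seed {seed}); "
        "increase elaboration or relax the omega ratio")


def gen_ensemble(n_cells: int = 20, seed: int = 0,
                 config: MorphologyConfig | None = None) -> list[SyntheticCell]:
    """Independent cells from sub-seeds of one master seed."""
    ss = np.random.SeedSequence(seed)
    return [
        gen_morphology(int(c.generate_state(1)[0] % (2 ** 31)), config,
                       cell_id=f"cell{i}")
        for i, c in enumerate(ss.spawn(n_cells))
    ]


# ---------------------------------------------------------------------------
# Imaging / electrophysiology trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialConfig:
    """Noise and kinetics of synthetic line-scan and voltage trials."""

    n_trials: int = 20
    rate_khz: float = 0.5          # 2 ms line-scan period
    duration_ms: float = 700.0
    stim_ms: float = 150.0
    rise_ms: float = 4.0
    decay_ms: float = 90.0
    g_baseline: float = 200.0
    r_baseline: float = 1000.0
    g_noise_sd: float = 8.0
    r_noise_sd: float = 8.0
    shot_scale: float = 0.4        # signal-scaled noise ~ shot noise
    pairing_delay_ms: float = 5.0  # bAP follows the uEPSP by 5 ms
    v_rate_khz: float = 20.0
    v_noise_sd_mv: float = 0.05
    uepsp_mv: float = 0.5
    uepsp_rise_ms: float = 2.0
    uepsp_decay_ms: float = 15.0


def _kernel(t: np.ndarray, onset: float, rise: float, decay: float) -> np.ndarray:
    s = t - onset
    k = np.zeros_like(t)
    on = s >= 0
    raw = np.exp(-s[on] / decay) - np.exp(-s[on] / rise)
    tpk = rise * decay / (decay - rise) * math.log(decay / rise)
    k[on] = raw / (math.exp(-tpk / decay) - math.exp(-tpk / rise))
    return k


def gen_imaging_trials(seed: int, truth: dict, config: TrialConfig | None = None,
                       site: str = "site") -> dict:
    """Two-channel fluorescence + voltage trials for one site.

    ``truth`` maps conditions to dG/R amplitudes, e.g. {'bAP': 0.2,
    'uEPSP': 0.06, 'pairing': 0.30}; the pairing transient places the bAP
    contribution 5 ms after the uEPSP onset.  Returns
    {'recordings': {condition: FluorescenceRecording},
     'voltage': {condition: VoltageTrial}, 'truth': truth}.
    """
    cfg = config or TrialConfig()
    if any(a < 0 for a in truth.values()):
        raise ValueError("truth amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(cfg.duration_ms * cfg.rate_khz)
    t = np.arange(n) / cfg.rate_khz
    recordings = {}
    voltage = {}
    for cond, amp in truth.items():
        onset = cfg.stim_ms + (cfg.pairing_delay_ms if cond == "pairing" else 0.0)
        signal = amp * cfg.r_baseline * _kernel(t, onset, cfg.rise_ms, cfg.decay_ms)
        g = (cfg.g_baseline + signal
             + rng.normal(0, cfg.g_noise_sd, (cfg.n_trials, n))
             + rng.normal(0, 1, (cfg.n_trials, n)) * cfg.shot_scale * np.sqrt(
                 np.maximum(cfg.g_baseline + signal, 0)))
        r = cfg.r_baseline + rng.normal(0, cfg.r_noise_sd, (cfg.n_trials, n))
        recordings[cond] = FluorescenceRecording(
            g, r, cfg.rate_khz, cfg.stim_ms, condition=cond, site=site)

        nv = int(cfg.duration_ms * cfg.v_rate_khz)
        tv = np.arange(nv) / cfg.v_rate_khz
        v = np.full((cfg.n_trials, nv), -75.0)
        v += rng.normal(0, cfg.v_noise_sd_mv, (cfg.n_trials, nv))
        if cond in ("uEPSP", "pairing"):
            v += cfg.uepsp_mv * _kernel(tv, cfg.stim_ms, cfg.uepsp_rise_ms,
                                        cfg.uepsp_decay_ms)
        if cond in ("bAP", "pairing"):
            onset_ap = cfg.stim_ms + (cfg.pairing_delay_ms if cond == "pairing" else 0.0)
            v += 90.0 * _kernel(tv, onset_ap, 0.2, 0.6)  # AP command artifact
        voltage[cond] = VoltageTrial(v, cfg.v_rate_khz, cfg.stim_ms)
    return {"recordings": recordings, "voltage": voltage, "truth": dict(truth)}


# ---------------------------------------------------------------------------
# STA movie
# ---------------------------------------------------------------------------

def gen_sta_movie(seed: int = 0, dff: float = 0.15, shape=(48, 48),
                  n_spikes: int = 100, frames_per_spike: int = 12,
                  noise_scale: float = 0.5, background: bool = True) -> dict:
    """Voltage-imaging movie with a known spike-evoked dF/F0.

    A dendrite-shaped mask carries heterogeneous baseline brightness and a
    spike-locked fluorescence change proportional to baseline (dF = dff * F);
    background structures are bright but spike-independent.  Returns
    {'movie', 'spike_frames', 'dff', 'mask'}.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # dendrite: a diagonal band plus one side branch
    mask = (np.abs(yy - (0.6 * xx + 5)) < 2.0) | \
           ((xx > w // 2) & (np.abs(yy - (-0.8 * (xx - w // 2) + 0.6 * (w // 2) + 5)) < 1.5))
    mask &= (yy >= 0) & (yy < h)

    f0 = np.full(shape, 20.0)
    f0[mask] = 400.0 * rng.lognormal(0.0, 0.35, mask.sum())
    if background:
        blob = ((yy - h * 0.8) ** 2 + (xx - w * 0.2) ** 2) < (h * 0.12) ** 2
        blob &= ~mask
        f0[blob] = 250.0

    n_frames = n_spikes * frames_per_spike + frames_per_spike
    spike_frames = np.arange(1, n_spikes + 1) * frames_per_spike
    resp = np.zeros(n_frames)
    for s in spike_frames:
        resp[s] = 0.7
        if s + 1 < n_frames:
            resp[s + 1] = 1.0
        if s + 2 < n_frames:
            resp[s + 2] = 0.4
    movie = f0[None, :, :] * (1.0 + dff * resp[:, None, None] * mask[None, :, :])
    movie = movie + rng.normal(0, 1, movie.shape) * noise_scale * np.sqrt(movie)
    return {"movie": movie, "spike_frames": spike_frames, "dff": dff, "mask": mask}


# ---------------------------------------------------------------------------
# Latency data
# ---------------------------------------------------------------------------

def gen_latency_data(seed: int = 0, velocity: float = 154.9, n_sites: int = 20,
                     jitter_sd_ms: float = 0.05, onset_delay_ms: float = 0.2,
                     distance_range=(75.0, 300.0)) -> dict:
    """Site distances and bAP-arrival latencies at a known conduction velocity."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    rng = np.random.default_rng(seed)
    d = rng.uniform(*distance_range, n_sites)
    lat = onset_delay_ms + d / velocity + rng.normal(0, jitter_sd_ms, n_sites)
    return {"distances_um": d, "latencies_ms": lat, "velocity": velocity,
            "jitter_sd_ms": jitter_sd_ms}
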