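"""Synthetic multichannel EEG with emotion-dependent band power.

Ground truth for the whole pipeline: each discrete emotion is given a
spectral profile over the canonical rhythm bands (theta 4-8, alpha
8-13, beta 13-30, gamma 30-45 Hz), and a scripted scenario is rendered
as a sum of band-limited sinusoids -- one tone per band per channel,
frequency drawn uniformly inside the band, random phase -- plus
broadband white noise.  Scripted emotion transitions happen at known
times, with a 50 ms amplitude crossfade so the switch is spectrally
clean but still sharp relative to the 0.5 s recognition update period.

The default native rate is 1000 Hz so the 200 Hz downsampling path of
the preprocessing module is always exercised.  The three default
profiles (alpha-, beta- and gamma-dominant) are linearly separable in
mean band power, making end-to-end classification accuracy auditable
against a simple band-power centroid oracle.

This is a statistical stand-in, not physiological EEG: no 1/f
background, no ERPs, no artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preproc import RawRecording, PreprocessConfig, preprocess, trim_edges
from .windowing import SegmentationConfig, SegmentSet, segment

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

CROSSFADE_S = 0.05


@dataclass
class EmotionProfile:
    """Band-power signature of one discrete emotion."""

    name: str
    band_power: dict[str, float]  # band name -> mean tone amplitude (a.u.)
    channel_gains: np.ndarray | None = None
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for band, amp in self.band_power.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError("band amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_profiles(noise_sd: float = 0.3) -> dict[str, EmotionProfile]:
    """Three separable classes: alpha-, beta- and gamma-dominant."""
    minor = 0.1
    return {
        "neutral": EmotionProfile("neutral", {
            "alpha": 1.0, "beta": minor, "gamma": minor}, noise_sd=noise_sd),
        "happy": EmotionProfile("happy", {
            "alpha": minor, "beta": 1.0, "gamma": minor}, noise_sd=noise_sd),
        "sad": EmotionProfile("sad", {
            "alpha": minor, "beta": minor, "gamma": 1.0}, noise_sd=noise_sd),
    }


@dataclass
class ScenarioScript:
    """Ordered emotion blocks rendered into one recording."""

    blocks: list[tuple[str, float]]  # (emotion label, duration in s)
    n_channels: int = 4
    sampling_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("scenario script needs at least one block")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("block durations must be positive")
        if sum(d for _, d in self.blocks) < 1.0:
            raise ValueError("total scripted duration must be at least 1 s")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.blocks))


def generate_recording(script: ScenarioScript,
                       profiles: dict[str, EmotionProfile] | None = None
                       ) -> RawRecording:
    """Render a scripted scenario; same script (incl. seed) => identical output."""
    profiles = profiles if profiles is not None else default_profiles()
    for label, _ in script.blocks:
        if label not in profiles:
            raise ValueError(f"no emotion profile for scripted label {label!r}")
    fs = script.sampling_rate_hz
    rng = np.random.default_rng(script.seed)
    n_total = int(round(script.duration_s * fs))
    t = np.arange(n_total) / fs
    samples = np.zeros((script.n_channels, n_total))
    label_track = np.empty(n_total, dtype=object)
    fade_n = int(round(CROSSFADE_S * fs))

    edges = np.cumsum([0.0] + [d for _, d in script.blocks])
    transitions = []
    for k, (label, _) in enumerate(script.blocks):
        prof = profiles[label]
        i0 = int(round(edges[k] * fs))
        i1 = int(round(edges[k + 1] * fs))
        label_track[i0:i1] = label
        if k > 0 and label != script.blocks[k - 1][0]:
            transitions.append((float(edges[k]), label))
        # amplitude envelope: ramp up/down over the crossfade at interior edges
        lo = max(0, i0 - fade_n // 2)
        hi = min(n_total, i1 + fade_n // 2)
        env = np.ones(hi - lo)
        if k > 0:
            ramp = min(fade_n, hi - lo)
            env[:ramp] = np.linspace(0.0, 1.0, ramp)
        if k < len(script.blocks) - 1:
            ramp = min(fade_n, hi - lo)
            env[-ramp:] = np.minimum(env[-ramp:], np.linspace(1.0, 0.0, ramp))
        tb = t[lo:hi]
        for c in range(script.n_channels):
            sig = np.zeros(hi - lo)
            for band, amp in sorted(prof.band_power.items()):
                f = rng.uniform(*BANDS[band])
                phi = rng.uniform(0.0, 2.0 * np.pi)
                if amp > 0:
                    sig += amp * np.sin(2.0 * np.pi * f * tb + phi)
            gain = 1.0 if prof.channel_gains is None else prof.channel_gains[c]
            samples[c, lo:hi] += gain * sig * env
    # broadband noise, per-sample sd from the active emotion's profile
    sds = np.array([profiles[lab].noise_sd for lab in label_track])
    for c in range(script.n_channels):
        samples[c] += rng.standard_normal(n_total) * sds
    names = [f"CH{c + 1}" for c in range(script.n_channels)]
    return RawRecording(names, fs, samples,
                        label_track=label_track.astype(str),
                        meta={"transitions": transitions,
                              "source_id": "synthetic"})


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean Welch PSD power of one channel inside a band (oracle helper)."""
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=min(len(x), 2048))
    sel = (f >= band[0]) & (f < band[1])
    return float(np.trapezoid(p[sel], f[sel]))


def band_power_features(rec_samples: np.ndarray, fs: float) -> np.ndarray:
    """Per-channel band powers, flattened; the centroid oracle's features."""
    feats = []
    for c in range(rec_samples.shape[0]):
        for band in ("alpha", "beta", "gamma"):
            feats.append(band_power(rec_samples[c], fs, BANDS[band]))
    return np.array(feats)


def make_benchmark(n_per_class: int,
                   profiles: dict[str, EmotionProfile] | None = None,
                   seed: int = 0, n_channels: int = 4,
                   segmentation: SegmentationConfig | None = None,
                   preprocess_config: PreprocessConfig | None = None,
                   ) -> tuple[SegmentSet, SegmentSet]:
    """Labeled train/test segments, one homogeneous recording per class.

    Each class is rendered at 1000 Hz, preprocessed (200 Hz, 8-45 Hz),
    trimmed of 1 s filter padding at each end, and segmented (default
    1 s windows, 50% overlap).  The first ``n_per_class`` segments per
    class are split 80/20 stratified, so classes stay balanced within
    one segment.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be at least 10")
    profiles = profiles if profiles is not None else default_profiles()
    seg_cfg = segmentation or SegmentationConfig()
    pre_cfg = preprocess_config or PreprocessConfig()
    classes = sorted(profiles)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(classes) + 1)
    split_rng = np.random.default_rng(children[-1])
    duration = ((n_per_class - 1) * seg_cfg.step_s + seg_cfg.window_length_s
                + 2.0 + 0.5)  # + filter padding + margin
    # render each class as consecutive same-label blocks so the tone
    # frequencies are redrawn every few seconds: a class is its band
    # profile, not one incidental frequency draw
    block_s = max(2.0, seg_cfg.window_length_s)
    n_blocks = int(np.ceil(duration / block_s))
    train_segs, test_segs = [], []
    for k, cls in enumerate(classes):
        script = ScenarioScript([(cls, block_s)] * n_blocks,
                                n_channels=n_channels,
                                seed=int(children[k].generate_state(1)[0] % (2 ** 31)))
        rec = trim_edges(preprocess(generate_recording(script, profiles), pre_cfg))
        segs = segment(rec, seg_cfg).segments[:n_per_class]
        if len(segs) < n_per_class:
            raise RuntimeError("benchmark recording too short; internal error")
        for s in segs:
            s.label = cls
        order = split_rng.permutation(n_per_class)
        n_test = int(round(0.2 * n_per_class))
        test_idx = set(order[:n_test].tolist())
        for i, s in enumerate(segs):
            (test_segs if i in test_idx else train_segs).append(s)
    fs = pre_cfg.target_rate_hz
    return (SegmentSet(train_segs, fs, seg_cfg),
            SegmentSet(test_segs, fs, seg_cfg))


def make_transition_scenario(pairs: list[tuple[str, str]], segment_s: float,
                             seed: int = 0, n_channels: int = 4,
                             sampling_rate_hz: float = 1000.0,
                             profiles: dict[str, EmotionProfile] | None = None
                             ) -> RawRecording:
    """Alternating A/B emotion blocks with known transition times.

    Transition times (and new labels) are recorded in
    ``rec.meta["transitions"]`` and equal the label-track change points.
    """
    if not pairs:
        raise ValueError("need at least one (A, B) emotion pair")
    blocks = []
    for a, b in pairs:
        blocks.append((a, segment_s))
        blocks.append((b, segment_s))
    script = ScenarioScript(blocks, n_channels=n_channels,
                            sampling_rate_hz=sampling_rate_hz, seed=seed)
    return generate_recording(script, profiles)
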