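"""Per-channel short-time Fourier features.

Each segment is turned into a time sequence of spectral frames: the
signal of every channel is cut into short sub-windows (default 0.25 s,
50% sub-window overlap), each sub-window is tapered and Fourier
transformed, and only the bins inside the analysis band (default
8-45 Hz) are kept.  Channels are featurized independently and occupy
disjoint blocks of the feature axis -- they are never concatenated into
a single spectrum or mixed, preserving per-channel detail.  Frames are
ordered by time, so the newest data is the last element of the
sequence the recurrent model consumes.

With the defaults on a 1 s segment at 200 Hz: sub-windows of 50
samples hopped by 25 give 7 frames, each with a 4 Hz bin grid
(8, 12, ..., 44 Hz; 10 bins per channel).  Magnitudes are returned on a
log scale by default since EEG band powers span orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import get_window

from .windowing import Segment, SegmentSet

WINDOW_FUNCTIONS = ("hann", "hamming", "rect")


@dataclass
class STFTConfig:
    subwindow_s: float = 0.25
    hop_s: float = 0.125
    window_function: str = "hann"
    fmin_hz: float = 8.0
    fmax_hz: float = 45.0
    log_magnitude: bool = True
    log_epsilon: float = 1e-8
    #: optional FFT length (zero-padding) for a finer bin grid; default
    #: uses the sub-window length itself
    nfft: int | None = None

    def __post_init__(self) -> None:
        if self.subwindow_s <= 0 or self.hop_s <= 0:
            raise ValueError("subwindow_s and hop_s must be positive")
        if self.hop_s > self.subwindow_s:
            raise ValueError("hop_s must not exceed subwindow_s")
        if self.window_function not in WINDOW_FUNCTIONS:
            raise ValueError(f"unknown window function {self.window_function!r}")
        if not (self.fmin_hz < self.fmax_hz):
            raise ValueError("need fmin_hz < fmax_hz")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")

    def subwindow_samples(self, fs: float) -> int:
        return int(np.floor(self.subwindow_s * fs + 0.5))

    def hop_samples(self, fs: float) -> int:
        return int(np.floor(self.hop_s * fs + 0.5))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpectralFeatureTensor:
    """Sequence of spectral frames for one segment.

    ``frames`` is n_frames x (n_channels * n_bins); channel ``c``
    occupies columns ``[c * n_bins, (c + 1) * n_bins)``.
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    start_s: float = 0.0
    label: str | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _taper(cfg: STFTConfig, n: int) -> np.ndarray:
    if cfg.window_function == "rect":
        return np.ones(n)
    return get_window(cfg.window_function, n, fftbins=True)


def bin_frequencies(fs: float, cfg: STFTConfig) -> np.ndarray:
    """The retained frequency grid: rFFT bins inside [fmin, fmax]."""
    if cfg.fmax_hz > fs / 2:
        raise ValueError(
            f"fmax_hz={cfg.fmax_hz} exceeds the Nyquist frequency {fs / 2}"
        )
    nfft = cfg.nfft or cfg.subwindow_samples(fs)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return freqs[(freqs >= cfg.fmin_hz) & (freqs <= cfg.fmax_hz)]


def n_frames(n_samples: int, fs: float, cfg: STFTConfig) -> int:
    sub = cfg.subwindow_samples(fs)
    hop = cfg.hop_samples(fs)
    if n_samples < sub:
        raise ValueError(
            f"signal of {n_samples} samples shorter than one "
            f"{sub}-sample sub-window"
        )
    return (n_samples - sub) // hop + 1


def stft_channel(x: np.ndarray, fs: float, cfg: STFTConfig | None = None) -> np.ndarray:
    """Windowed DFT of one channel: complex n_frames x n_bins matrix.

    Frame ``f``, bin ``k`` is ``sum_n x[f*hop + n] w[n] exp(-2j pi f_k n / fs)``
    over the sub-window; bins outside [fmin, fmax] are discarded.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft_channel expects a single-channel vector")
    sub = cfg.subwindow_samples(fs)
    hop = cfg.hop_samples(fs)
    nf = n_frames(len(x), fs, cfg)
    nfft = cfg.nfft or sub
    if nfft < sub:
        raise ValueError("nfft must be at least the sub-window length")
    taper = _taper(cfg, sub)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    keep = (freqs >= cfg.fmin_hz) & (freqs <= cfg.fmax_hz)
    if cfg.fmax_hz > fs / 2:
        raise ValueError(
            f"fmax_hz={cfg.fmax_hz} exceeds the Nyquist frequency {fs / 2}"
        )
    idx = np.arange(nf)[:, None] * hop + np.arange(sub)[None, :]
    frames = x[idx] * taper
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    return spec[:, keep]


def frame_times(n_samples: int, fs: float, cfg: STFTConfig,
                start_s: float = 0.0) -> np.ndarray:
    """Center time of each frame, offset by the segment start."""
    cfg_nf = n_frames(n_samples, fs, cfg)
    sub = cfg.subwindow_samples(fs)
    hop = cfg.hop_samples(fs)
    return start_s + (np.arange(cfg_nf) * hop + sub / 2) / fs


def featurize_segment(seg: Segment, fs: float,
                      cfg: STFTConfig | None = None) -> SpectralFeatureTensor:
    """Per-channel STFT magnitudes of one segment, channels kept separate."""
    cfg = cfg or STFTConfig()
    n_samp = seg.samples.shape[1]
    blocks = []
    for c in range(seg.samples.shape[0]):
        spec = np.abs(stft_channel(seg.samples[c], fs, cfg))
        if cfg.log_magnitude:
            spec = np.log(spec + cfg.log_epsilon)
        blocks.append(spec)
    return SpectralFeatureTensor(
        frames=np.concatenate(blocks, axis=1),
        frame_times_s=frame_times(n_samp, fs, cfg, start_s=seg.start_s),
        bin_freqs_hz=bin_frequencies(fs, cfg),
        start_s=seg.start_s,
        label=seg.label,
    )


def featurize_set(segset: SegmentSet,
                  cfg: STFTConfig | None = None) -> list[SpectralFeatureTensor]:
    cfg = cfg or STFTConfig()
    return [featurize_segment(s, segset.sampling_rate_hz, cfg) for s in segset]


def write_features(tensors: list[SpectralFeatureTensor], cfg: STFTConfig,
                   path) -> None:
    """Feature tensors in the HDF5 container (/features, /frame_times, ...)."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.stack([t.frames for t in tensors]))
        f.create_dataset("frame_times",
                         data=np.stack([t.frame_times_s for t in tensors]))
        f.create_dataset("bin_freqs", data=tensors[0].bin_freqs_hz)
        f.create_dataset("start_s", data=np.array([t.start_s for t in tensors]))
        labels = [t.label for t in tensors]
        if all(lab is not None for lab in labels):
            alphabet = sorted(set(labels))
            f.create_dataset("labels", data=np.array(
                [alphabet.index(lab) for lab in labels], dtype=np.int16))
            f.attrs["label_alphabet"] = alphabet
        f.attrs["stft_config"] = json.dumps(cfg.to_dict())


def read_features(path) -> tuple[list[SpectralFeatureTensor], STFTConfig]:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        frames = f["features"][()]
        times = f["frame_times"][()]
        freqs = f["bin_freqs"][()]
        starts = f["start_s"][()]
        cfg = STFTConfig(**json.loads(f.attrs["stft_config"]))
        labels = [None] * len(frames)
        if "labels" in f:
            alphabet = [str(a) for a in f.attrs["label_alphabet"]]
            labels = [alphabet[i] for i in f["labels"][()]]
    tensors = [SpectralFeatureTensor(fr, tt, freqs, start_s=float(s0), label=lab)
               for fr, tt, s0, lab in zip(frames, times, starts, labels)]
    return tensors, cfg
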