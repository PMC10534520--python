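"""Sliding-window segmentation, batch and streaming.

Emotion changes on a sub-second scale, so recognition operates on short
overlapping windows rather than whole trials: a window short enough to
follow changes (at most 3 s, typically 1 s) slid by a step of 50-80% of
its length.  With a 1 s window and 50% overlap a new recognition result
is available every 0.5 s.

Batch segmentation cuts ``floor((duration - window) / step) + 1``
fully-contained windows; a trailing partial window is dropped rather
than zero-padded (padding would dilute the spectral features).  The
streaming segmenter consumes arbitrary chunks and emits exactly the
segments batch segmentation would produce on the concatenated signal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_preproc import RawRecording

LABEL_POLICIES = ("majority", "newest_tiebreak_majority")


@dataclass
class SegmentationConfig:
    window_length_s: float = 1.0
    step_s: float = 0.5
    #: windows beyond 3 s average over too much signal for real-time use;
    #: set to use them anyway (e.g. for latency comparisons), with a warning
    allow_long_window: bool = False

    def __post_init__(self) -> None:
        if self.window_length_s <= 0 or self.step_s <= 0:
            raise ValueError("window_length_s and step_s must be positive")
        if self.step_s > self.window_length_s:
            raise ValueError(
                f"step_s={self.step_s} exceeds window_length_s="
                f"{self.window_length_s}: the step must not exceed the window"
            )
        if self.window_length_s > 3.0:
            if not self.allow_long_window:
                raise ValueError(
                    "window_length_s > 3 s is unsuitable for real-time "
                    "recognition; pass allow_long_window=True to override"
                )
            warnings.warn(
                f"window of {self.window_length_s} s exceeds the 3 s "
                "real-time guideline", UserWarning, stacklevel=2)
        if not (0.5 * self.window_length_s <= self.step_s
                <= 0.8 * self.window_length_s):
            warnings.warn(
                f"step {self.step_s} s outside the recommended 50-80% of "
                f"the {self.window_length_s} s window", UserWarning,
                stacklevel=2)

    @property
    def overlap_rate(self) -> float:
        return 1.0 - self.step_s / self.window_length_s

    # window/step rounded half-up to whole samples for bit-exact cuts
    def window_samples(self, fs: float) -> int:
        return int(np.floor(self.window_length_s * fs + 0.5))

    def step_samples(self, fs: float) -> int:
        return int(np.floor(self.step_s * fs + 0.5))


@dataclass
class Segment:
    start_s: float
    end_s: float
    samples: np.ndarray  # channels x window_samples
    label: str | None = None
    source_id: str = ""


@dataclass
class SegmentSet:
    segments: list[Segment]
    sampling_rate_hz: float
    config: SegmentationConfig

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.segments]


def assign_label(seg: Segment, label_track: np.ndarray, sampling_rate_hz: float,
                 policy: str = "majority", t0_s: float = 0.0) -> str:
    """Ground-truth label of a window from a per-sample label track.

    ``majority``: the label covering the most samples, exact ties broken
    toward the label occurring earliest in the window (deterministic).
    ``newest_tiebreak_majority``: same counts, ties broken toward the
    label that appears latest in the window -- the convention matching a
    real-time reading, where the newest emotion wins a dead heat.
    """
    if policy not in LABEL_POLICIES:
        raise ValueError(f"unknown label policy {policy!r}")
    i0 = int(round((seg.start_s - t0_s) * sampling_rate_hz))
    n = seg.samples.shape[1]
    if i0 < 0 or i0 + n > len(label_track):
        raise ValueError(
            f"label track does not cover window [{seg.start_s}, {seg.end_s}) s"
        )
    window = label_track[i0:i0 + n]
    counts = Counter(window.tolist())
    best = max(counts.values())
    candidates = [lab for lab, c in counts.items() if c == best]
    if len(candidates) == 1:
        return candidates[0]
    if policy == "newest_tiebreak_majority":
        last_pos = {lab: i for i, lab in enumerate(window.tolist())}
        return max(candidates, key=lambda lab: last_pos[lab])
    first_pos = {}
    for i, lab in enumerate(window.tolist()):
        first_pos.setdefault(lab, i)
    return min(candidates, key=lambda lab: first_pos[lab])


def segment(rec: RawRecording, cfg: SegmentationConfig | None = None,
            policy: str = "newest_tiebreak_majority",
            source_id: str | None = None) -> SegmentSet:
    """Cut a recording into overlapping fixed-length windows.

    Every window lies fully inside the recording; labels are assigned
    from the recording's label track when present.
    """
    cfg = cfg or SegmentationConfig()
    fs = rec.sampling_rate_hz
    win_n = cfg.window_samples(fs)
    step_n = cfg.step_samples(fs)
    if rec.n_samples < win_n:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{cfg.window_length_s} s window; nothing to segment"
        )
    src = source_id if source_id is not None else rec.meta.get("source_id", "")
    segments = []
    for i0 in range(0, rec.n_samples - win_n + 1, step_n):
        seg = Segment(
            start_s=rec.t0_s + i0 / fs,
            end_s=rec.t0_s + (i0 + win_n) / fs,
            samples=rec.samples[:, i0:i0 + win_n],
            source_id=src,
        )
        if rec.label_track is not None:
            seg.label = assign_label(seg, rec.label_track, fs, policy=policy,
                                     t0_s=rec.t0_s)
        segments.append(seg)
    return SegmentSet(segments, fs, cfg)


@dataclass
class StreamSegmenter:
    """Incremental segmentation over pushed chunks.

    Emits every segment whose final sample has arrived, in time order,
    and provably matches batch :func:`segment` on the concatenation of
    all pushed chunks.  Only samples still needed for future windows are
    retained.
    """

    n_channels: int
    sampling_rate_hz: float
    config: SegmentationConfig = field(default_factory=SegmentationConfig)
    source_id: str = "stream"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self._buf = np.empty((self.n_channels, 0))
        self._offset = 0        # absolute index of first buffered sample
        self._next_start = 0    # absolute index of next window start

    def push(self, chunk: np.ndarray) -> list[Segment]:
        chunk = np.asarray(chunk, dtype=np.float64)
        if chunk.ndim != 2 or chunk.shape[0] != self.n_channels:
            raise ValueError(
                f"chunk has {chunk.shape[0] if chunk.ndim == 2 else '?'} "
                f"channels, segmenter configured for {self.n_channels}"
            )
        fs = self.sampling_rate_hz
        win_n = self.config.window_samples(fs)
        step_n = self.config.step_samples(fs)
        self._buf = np.concatenate([self._buf, chunk], axis=1)
        total = self._offset + self._buf.shape[1]
        emitted = []
        while self._next_start + win_n <= total:
            j0 = self._next_start - self._offset
            emitted.append(Segment(
                start_s=self.t0_s + self._next_start / fs,
                end_s=self.t0_s + (self._next_start + win_n) / fs,
                samples=self._buf[:, j0:j0 + win_n].copy(),
                source_id=self.source_id,
            ))
            self._next_start += step_n
        drop = self._next_start - self._offset
        if drop > 0:
            self._buf = self._buf[:, drop:]
            self._offset += drop
        return emitted


def stream_push(buffer: StreamSegmenter, chunk: np.ndarray) -> list[Segment]:
    """Functional alias for :meth:`StreamSegmenter.push`."""
    return buffer.push(chunk)


def write_segments(segset: SegmentSet, path) -> None:
    """Segment table in the HDF5 container (samples, starts, labels)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples",
                         data=np.stack([s.samples for s in segset.segments]))
        f.create_dataset("start_s",
                         data=np.array([s.start_s for s in segset.segments]))
        labels = [s.label for s in segset.segments]
        if all(lab is not None for lab in labels):
            alphabet = sorted(set(labels))
            f.create_dataset("labels", data=np.array(
                [alphabet.index(lab) for lab in labels], dtype=np.int16))
            f.attrs["label_alphabet"] = alphabet
        f.attrs["sampling_rate_hz"] = segset.sampling_rate_hz
        f.attrs["window_length_s"] = segset.config.window_length_s
        f.attrs["step_s"] = segset.config.step_s
        f.attrs["source_id"] = segset.segments[0].source_id if segset.segments else ""


def read_segments(path) -> SegmentSet:
    import h5py

    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        starts = f["start_s"][()]
        fs = float(f.attrs["sampling_rate_hz"])
        cfg = SegmentationConfig(
            float(f.attrs["window_length_s"]), float(f.attrs["step_s"]),
            allow_long_window=True)
        src = str(f.attrs.get("source_id", ""))
        labels = [None] * len(samples)
        if "labels" in f:
            alphabet = [str(a) for a in f.attrs["label_alphabet"]]
            labels = [alphabet[i] for i in f["labels"][()]]
    win_s = samples.shape[2] / fs
    segments = [Segment(float(t0), float(t0) + win_s, s, label=lab, source_id=src)
                for t0, s, lab in zip(starts, samples, labels)]
    return SegmentSet(segments, fs, cfg)
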