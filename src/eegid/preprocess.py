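"""Signal conditioning: notch, band-pass, region selection, common average
reference, sliding-window segmentation, and z-score normalization.

The pipeline order is fixed: notch -> band-pass -> task selection ->
segmentation -> region selection -> CAR -> normalization.  CAR is computed
over the channels *available after selection*, and normalization statistics
come from the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import (
    CarError,
    DataShapeError,
    InvalidFilterError,
    InvalidSelectionError,
    NormalizationError,
    SegmentationError,
)
from .montage import REGIONS, channels_for_regions
from .synthetic import Recording

EPS_SIGMA = 1e-8


@dataclass(frozen=True)
class FilterSpec:
    """Notch + Butterworth band-pass cascade parameters.

    The band-pass is a cascade of a Butterworth high-pass at ``bp_low_hz``
    and a Butterworth low-pass at ``bp_high_hz``, each of order ``order``.
    All filters are applied forward-backward (zero phase).
    """

    notch_hz: float = 50.0
    bp_low_hz: float = 0.5
    bp_high_hz: float = 95.0
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs_hz: float) -> None:
        nyq = fs_hz / 2.0
        if not (0.0 < self.bp_low_hz < self.bp_high_hz):
            raise InvalidFilterError(
                f"need 0 < bp_low_hz < bp_high_hz, got ({self.bp_low_hz}, {self.bp_high_hz})"
            )
        if self.bp_high_hz >= nyq:
            raise InvalidFilterError(f"bp_high_hz {self.bp_high_hz} >= Nyquist {nyq}")
        if self.notch_hz >= nyq:
            raise InvalidFilterError(f"notch_hz {self.notch_hz} >= Nyquist {nyq}")
        if self.order < 2 or self.order % 2:
            raise InvalidFilterError(f"order must be even and >= 2, got {self.order}")
        if self.notch_q <= 0:
            raise InvalidFilterError("notch_q must be positive")


@dataclass(frozen=True)
class RegionSelection:
    """Subset of scalp regions, resolved to channels in fixed montage order."""

    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise InvalidSelectionError(f"unknown region codes {sorted(unknown)}")
        if not self.regions:
            raise InvalidSelectionError("region selection must be non-empty")

    @property
    def channels(self) -> list[str]:
        return channels_for_regions(self.regions)

    def label(self) -> str:
        ordered = [r for r in REGIONS if r in self.regions]
        return "all" if len(ordered) == 4 else "+".join(ordered)


ALL_REGIONS = RegionSelection(tuple(REGIONS))


@dataclass
class SegmentSet:
    """Stack of fixed-length multichannel epochs with full provenance.

    ``data`` is (n_segments, n_channels, window).  Each segment carries its
    subject label, source task, source-recording index, and 0-based start
    sample; windows are half-open ``[start, start + window)``.
    """

    data: np.ndarray
    subject_labels: np.ndarray  # (n,) int
    task_ids: np.ndarray  # (n,) str
    record_ids: np.ndarray  # (n,) int — index of the source recording
    start_samples: np.ndarray  # (n,) int
    channel_labels: list[str]
    fs_hz: float
    window: int
    step: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        n = self.data.shape[0]
        for name in ("subject_labels", "task_ids", "record_ids", "start_samples"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise DataShapeError(f"{name} length {arr.shape[0]} != {n} segments")
            setattr(self, name, arr)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.channel_labels):
            raise DataShapeError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_labels)} channels"
            )
        if n and self.data.shape[2] != self.window:
            raise DataShapeError(f"segment length {self.data.shape[2]} != window {self.window}")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def subset(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            data=self.data[idx],
            subject_labels=self.subject_labels[idx],
            task_ids=self.task_ids[idx],
            record_ids=self.record_ids[idx],
            start_samples=self.start_samples[idx],
            channel_labels=list(self.channel_labels),
            fs_hz=self.fs_hz,
            window=self.window,
            step=self.step,
        )

    def provenance(self) -> list[tuple[int, str, int]]:
        """(subject, task, start-sample) triple per segment."""
        return list(
            zip(
                self.subject_labels.tolist(),
                self.task_ids.tolist(),
                self.start_samples.tolist(),
            )
        )

    @staticmethod
    def concatenate(sets: list["SegmentSet"]) -> "SegmentSet":
        if not sets:
            raise DataShapeError("cannot concatenate zero segment sets")
        head = sets[0]
        for s in sets[1:]:
            if s.channel_labels != head.channel_labels or s.window != head.window:
                raise DataShapeError("segment sets differ in channels or window")
        return SegmentSet(
            data=np.concatenate([s.data for s in sets], axis=0),
            subject_labels=np.concatenate([s.subject_labels for s in sets]),
            task_ids=np.concatenate([s.task_ids for s in sets]),
            record_ids=np.concatenate([s.record_ids for s in sets]),
            start_samples=np.concatenate([s.start_samples for s in sets]),
            channel_labels=list(head.channel_labels),
            fs_hz=head.fs_hz,
            window=head.window,
            step=head.step,
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and standard deviation fitted on training data."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0):
            raise NormalizationError("sigma entries must be non-negative")
        if np.asarray(self.mu).shape != np.asarray(self.sigma).shape:
            raise NormalizationError("mu and sigma must have equal length")


# ---------------------------------------------------------------------------
# filtering


def _check_recording(rec: Recording) -> None:
    if not np.all(np.isfinite(rec.data)):
        raise InvalidFilterError("recording contains non-finite samples")


def notch_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase IIR notch at ``spec.notch_hz`` (powerline suppression)."""
    _check_recording(rec)
    spec.validate(rec.fs_hz)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs_hz)
    out = sps.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=out, meta={**rec.meta, "notch_hz": spec.notch_hz})


def bandpass_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth high-pass + low-pass cascade."""
    _check_recording(rec)
    spec.validate(rec.fs_hz)
    sos_hp = sps.butter(spec.order, spec.bp_low_hz, btype="highpass", fs=rec.fs_hz, output="sos")
    sos_lp = sps.butter(spec.order, spec.bp_high_hz, btype="lowpass", fs=rec.fs_hz, output="sos")
    out = sps.sosfiltfilt(sos_hp, rec.data, axis=1)
    out = sps.sosfiltfilt(sos_lp, out, axis=1)
    return replace(
        rec, data=out, meta={**rec.meta, "bandpass_hz": (spec.bp_low_hz, spec.bp_high_hz)}
    )


def filter_recording(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Notch then band-pass, the fixed first stage of the pipeline."""
    return bandpass_filter(notch_filter(rec, spec), spec)


# ---------------------------------------------------------------------------
# channel operations (work on both Recording and SegmentSet)


def select_regions(obj, sel: RegionSelection):
    """Restrict channels to the selected regions, montage order preserved."""
    wanted = sel.channels
    missing = [ch for ch in wanted if ch not in obj.channel_labels]
    if missing:
        raise InvalidSelectionError(f"channels {missing} absent from input")
    idx = [obj.channel_labels.index(ch) for ch in wanted]
    if isinstance(obj, SegmentSet):
        return SegmentSet(
            data=obj.data[:, idx, :],
            subject_labels=obj.subject_labels,
            task_ids=obj.task_ids,
            record_ids=obj.record_ids,
            start_samples=obj.start_samples,
            channel_labels=wanted,
            fs_hz=obj.fs_hz,
            window=obj.window,
            step=obj.step,
        )
    return replace(obj, data=obj.data[idx, :], channel_labels=wanted)


def apply_car(obj):
    """Common average reference: subtract the per-sample mean over the
    available channels from every channel.  Output channels sum to zero at
    every sample."""
    n_ch = obj.data.shape[-2]
    if n_ch < 2:
        raise CarError(f"CAR needs at least 2 channels, got {n_ch}")
    mean = obj.data.mean(axis=-2, keepdims=True)
    out = obj.data - mean
    if isinstance(obj, SegmentSet):
        return SegmentSet(
            data=out,
            subject_labels=obj.subject_labels,
            task_ids=obj.task_ids,
            record_ids=obj.record_ids,
            start_samples=obj.start_samples,
            channel_labels=list(obj.channel_labels),
            fs_hz=obj.fs_hz,
            window=obj.window,
            step=obj.step,
        )
    return replace(obj, data=out)


# ---------------------------------------------------------------------------
# segmentation


def segment(rec: Recording, window: int = 1000, step: int = 500, record_id: int = 0) -> SegmentSet:
    """Sliding-window epochs: ``floor((T - window)/step) + 1`` segments of
    ``window`` samples with hop ``step``; windows are ``[k*step, k*step+window)``.
    A too-short recording yields an empty set with a warning."""
    if window <= 0 or step <= 0:
        raise SegmentationError(f"window and step must be positive, got ({window}, {step})")
    if step > window:
        raise SegmentationError(f"step {step} exceeds window {window}")
    T = rec.n_samples
    if T < window:
        warnings.warn(
            f"recording of {T} samples shorter than window {window}; zero segments",
            stacklevel=2,
        )
        n = 0
        data = np.empty((0, len(rec.channel_labels), window))
        starts = np.empty(0, dtype=int)
    else:
        n = (T - window) // step + 1
        views = sliding_window_view(rec.data, window, axis=1)[:, ::step, :]
        data = np.ascontiguousarray(views[:, :n].transpose(1, 0, 2))
        starts = np.arange(n) * step
    return SegmentSet(
        data=data,
        subject_labels=np.full(n, rec.subject_id, dtype=int),
        task_ids=np.full(n, rec.task_id, dtype=object),
        record_ids=np.full(n, record_id, dtype=int),
        start_samples=starts,
        channel_labels=list(rec.channel_labels),
        fs_hz=rec.fs_hz,
        window=window,
        step=step,
    )


def segment_recordings(recs: list[Recording], window: int = 1000, step: int = 500) -> SegmentSet:
    """Segment several recordings and concatenate, tagging each segment with
    its source recording index."""
    parts = [segment(r, window, step, record_id=i) for i, r in enumerate(recs)]
    return SegmentSet.concatenate(parts)


# ---------------------------------------------------------------------------
# normalization


def fit_normalization(train: SegmentSet) -> NormalizationStats:
    """Per-channel mean/SD pooled over all samples of all training segments.

    SD is the population standard deviation, floored at ``EPS_SIGMA`` so a
    constant channel normalizes to zeros instead of dividing by zero.
    """
    if len(train) == 0:
        raise NormalizationError("cannot fit normalization on an empty segment set")
    mu = train.data.mean(axis=(0, 2))
    sigma = train.data.std(axis=(0, 2))
    sigma = np.maximum(sigma, EPS_SIGMA)
    return NormalizationStats(mu=mu, sigma=sigma)


def apply_normalization(s: SegmentSet, stats: NormalizationStats) -> SegmentSet:
    """z-score every value with the fitted per-channel (mu, sigma)."""
    if len(stats.mu) != s.n_channels:
        raise DataShapeError(
            f"stats for {len(stats.mu)} channels applied to {s.n_channels}-channel data"
        )
    mu = np.asarray(stats.mu)[None, :, None]
    sigma = np.asarray(stats.sigma)[None, :, None]
    out = (s.data - mu) / sigma
    return SegmentSet(
        data=out,
        subject_labels=s.subject_labels,
        task_ids=s.task_ids,
        record_ids=s.record_ids,
        start_samples=s.start_samples,
        channel_labels=list(s.channel_labels),
        fs_hz=s.fs_hz,
        window=s.window,
        step=s.step,
    )


# ---------------------------------------------------------------------------
# composed pipeline stages


def condition_and_segment(
    recs: list[Recording],
    spec: FilterSpec = FilterSpec(),
    window: int = 1000,
    step: int = 500,
) -> SegmentSet:
    """Filtering + segmentation on the full montage (region selection and
    CAR are applied later, per study case)."""
    filtered = [filter_recording(r, spec) for r in recs]
    return segment_recordings(filtered, window, step)


def reduce_and_rereference(segs: SegmentSet, sel: RegionSelection) -> SegmentSet:
    """Region selection followed by CAR over the surviving channels."""
    return apply_car(select_regions(segs, sel))
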