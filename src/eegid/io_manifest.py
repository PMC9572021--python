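"""Signal file I/O (EDF and per-channel CSV) and cohort manifests.

The EDF writer/reader implements the classic European Data Format: a
256-byte fixed header, 256 bytes of per-signal headers, and little-endian
16-bit samples.  Signals are stored in a single data record spanning the
whole recording, with physical scaling over +/-500 µV, so round-trips are
exact to within one 16-bit quantization step (~0.015 µV).

A cohort manifest is a JSON file listing (subject, task, path, duration,
sampling rate, channels) per recording; (subject, task) pairs are unique.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatParseError, ManifestError
from .montage import CHANNELS
from .synthetic import Recording

MANIFEST_VERSION = "1"
# +/-2000 µV spans the synthetic cohort's worst-case transients; one 16-bit
# step is ~0.06 µV, far below any signal feature of interest
PHYS_MIN, PHYS_MAX = -2000.0, 2000.0
DIG_MIN, DIG_MAX = -32768, 32767


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: int
    task_id: str
    path: str
    duration_s: float
    fs_hz: float
    channel_labels: tuple[str, ...]


@dataclass
class CohortManifest:
    entries: list[ManifestEntry] = field(default_factory=list)
    version: str = MANIFEST_VERSION

    def add(self, entry: ManifestEntry) -> None:
        if any(
            (e.subject_id, e.task_id) == (entry.subject_id, entry.task_id) for e in self.entries
        ):
            raise ManifestError(
                f"duplicate (subject {entry.subject_id}, task {entry.task_id!r}) in manifest"
            )
        self.entries.append(entry)

    def save(self, path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "subject_id": e.subject_id,
                    "task_id": e.task_id,
                    "path": e.path,
                    "duration_s": e.duration_s,
                    "fs_hz": e.fs_hz,
                    "channel_labels": list(e.channel_labels),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @staticmethod
    def load(path, check_files: bool = True) -> "CohortManifest":
        path = Path(path)
        try:
            payload = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
        manifest = CohortManifest(version=payload.get("version", "?"))
        for d in payload["entries"]:
            entry = ManifestEntry(
                subject_id=int(d["subject_id"]),
                task_id=d["task_id"],
                path=d["path"],
                duration_s=float(d["duration_s"]),
                fs_hz=float(d["fs_hz"]),
                channel_labels=tuple(d["channel_labels"]),
            )
            if check_files and not (path.parent / entry.path).exists():
                raise ManifestError(f"manifest references missing file {entry.path}")
            manifest.add(entry)
        return manifest


# ---------------------------------------------------------------------------
# EDF


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raise FormatParseError(f"field {text!r} exceeds {width} EDF header bytes")
    return raw.ljust(width)


def _format_duration(seconds: float) -> str:
    text = f"{seconds:.6f}".rstrip("0").rstrip(".")
    if len(text) > 8:
        raise FormatParseError(f"record duration {seconds} does not fit the 8-byte EDF field")
    return text


def write_edf(rec: Recording, path) -> None:
    """Write one recording as EDF with a single data record."""
    n_ch, n_samp = rec.data.shape
    if n_samp == 0:
        raise FormatParseError("refusing to write an empty recording")
    clipped = np.clip(rec.data, PHYS_MIN, PHYS_MAX)
    if np.any(clipped != rec.data):
        warnings.warn(f"samples clipped to [{PHYS_MIN}, {PHYS_MAX}] µV on EDF write", stacklevel=2)
    gain = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)
    digital = np.round((clipped - PHYS_MIN) / gain + DIG_MIN).astype("<i2")

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(f"subject {rec.subject_id}", 80),
            _fixed(f"task {rec.task_id}", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (n_ch + 1)), 8),
            _fixed("", 44),
            _fixed("1", 8),
            _fixed(_format_duration(n_samp / rec.fs_hz), 8),
            _fixed(str(n_ch), 4),
        ]
    )
    labels = [ch for ch in rec.channel_labels]
    sig_header = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in labels),
            b"".join(_fixed("", 80) for _ in labels),
            b"".join(_fixed("uV", 8) for _ in labels),
            b"".join(_fixed(str(PHYS_MIN), 8) for _ in labels),
            b"".join(_fixed(str(PHYS_MAX), 8) for _ in labels),
            b"".join(_fixed(str(DIG_MIN), 8) for _ in labels),
            b"".join(_fixed(str(DIG_MAX), 8) for _ in labels),
            b"".join(_fixed("", 80) for _ in labels),
            b"".join(_fixed(str(n_samp), 8) for _ in labels),
            b"".join(_fixed("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def _parse_field(raw: bytes, name: str, cast):
    try:
        return cast(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise FormatParseError(f"EDF field {name!r} unparsable: {raw!r}") from exc


def read_edf(path) -> Recording:
    """Read an EDF file back into a Recording (µV, montage channel order).

    Channels whose labels are not part of the 8-channel montage are kept and
    flagged in ``meta['unknown_channels']``.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatParseError(f"{path}: too short to contain an EDF header ({len(raw)} bytes)")
    n_records = _parse_field(raw[236:244], "n_records", int)
    record_dur = _parse_field(raw[244:252], "record_duration", float)
    n_ch = _parse_field(raw[252:256], "n_signals", int)
    if n_ch <= 0 or n_records <= 0 or record_dur <= 0:
        raise FormatParseError(f"{path}: degenerate EDF geometry")
    subject_field = raw[8:88].decode("ascii", errors="replace").strip()
    task_field = raw[88:168].decode("ascii", errors="replace").strip()

    sig = raw[256 : 256 * (n_ch + 1)]
    if len(sig) < 256 * n_ch:
        raise FormatParseError(f"{path}: truncated signal header")

    def block(offset: int, width: int, cast, name: str):
        return [
            _parse_field(sig[offset * n_ch + i * width : offset * n_ch + (i + 1) * width], name, cast)
            for i in range(n_ch)
        ]

    labels = block(0, 16, str, "label")
    phys_min = block(16 + 80 + 8, 8, float, "phys_min")
    phys_max = block(16 + 80 + 8 + 8, 8, float, "phys_max")
    dig_min = block(16 + 80 + 8 + 8 + 8, 8, float, "dig_min")
    dig_max = block(16 + 80 + 8 + 8 + 8 + 8, 8, float, "dig_max")
    nr = block(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8, int, "samples_per_record")

    data_bytes = raw[256 * (n_ch + 1) :]
    per_record = sum(nr)
    expect = n_records * per_record * 2
    if len(data_bytes) < expect:
        raise FormatParseError(f"{path}: expected {expect} data bytes, found {len(data_bytes)}")
    flat = np.frombuffer(data_bytes[:expect], dtype="<i2").astype(np.float64)

    channels = [np.empty(n_records * nr[i]) for i in range(n_ch)]
    pos = 0
    for r in range(n_records):
        for i in range(n_ch):
            channels[i][r * nr[i] : (r + 1) * nr[i]] = flat[pos : pos + nr[i]]
            pos += nr[i]
    for i in range(n_ch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels[i] = (channels[i] - dig_min[i]) * gain + phys_min[i]

    fs = round(nr[0] / record_dur, 6)
    known = [lab for lab in CHANNELS if lab in labels]
    unknown = [lab for lab in labels if lab not in CHANNELS]
    order = [labels.index(lab) for lab in known] + [labels.index(lab) for lab in unknown]
    if unknown:
        warnings.warn(f"{path}: non-montage channel labels {unknown}", stacklevel=2)

    subject_id = -1
    if subject_field.startswith("subject "):
        try:
            subject_id = int(subject_field.split()[-1])
        except ValueError:
            pass
    task_id = task_field.removeprefix("task ").strip() or "rest"

    return Recording(
        subject_id=subject_id,
        task_id=task_id if task_id in ("rest", "level1", "level2", "level3") else "rest",
        channel_labels=[labels[i] for i in order],
        fs_hz=fs,
        data=np.stack([channels[i] for i in order]),
        meta={"source": str(path), "format": "edf", "unknown_channels": unknown},
    )


# ---------------------------------------------------------------------------
# CSV


def write_csv(rec: Recording, path) -> None:
    """Per-channel-column CSV: header row of channel labels, one sample per
    row, '.' decimal separator."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path, fs_hz: float = 1000.0, subject_id: int = -1, task_id: str = "rest") -> Recording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatParseError(f"cannot parse CSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatParseError(f"{path}: CSV holds no samples")
    labels = [str(c) for c in df.columns]
    known = [lab for lab in CHANNELS if lab in labels]
    unknown = [lab for lab in labels if lab not in CHANNELS]
    if unknown:
        warnings.warn(f"{path}: non-montage channel labels {unknown}", stacklevel=2)
    ordered = known + unknown
    return Recording(
        subject_id=subject_id,
        task_id=task_id,
        channel_labels=ordered,
        fs_hz=fs_hz,
        data=df[ordered].to_numpy().T,
        meta={"source": str(path), "format": "csv", "unknown_channels": unknown},
    )


# ---------------------------------------------------------------------------
# high-level round trips


def write_recording(rec: Recording, path, fmt: str = "edf") -> ManifestEntry:
    """Write a recording and return its manifest entry."""
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "csv":
        write_csv(rec, path)
    else:
        raise FormatParseError(f"unsupported format {fmt!r}")
    return ManifestEntry(
        subject_id=rec.subject_id,
        task_id=rec.task_id,
        path=Path(path).name,
        duration_s=rec.n_samples / rec.fs_hz,
        fs_hz=rec.fs_hz,
        channel_labels=tuple(rec.channel_labels),
    )


def read_recording(path, fmt: str = "edf", **kwargs) -> Recording:
    if fmt == "edf":
        return read_edf(path)
    if fmt == "csv":
        return read_csv(path, **kwargs)
    raise FormatParseError(f"unsupported format {fmt!r}")


def write_cohort(recordings, directory, fmt: str = "edf") -> CohortManifest:
    """Write every recording under ``directory`` plus a ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest()
    for rec in recordings:
        name = f"sub{rec.subject_id:02d}_{rec.task_id}.{fmt}"
        manifest.add(write_recording(rec, directory / name, fmt))
    manifest.save(directory / "manifest.json")
    return manifest


def load_cohort(manifest_path, fmt: str | None = None) -> list[Recording]:
    """Read back every recording listed in a manifest."""
    manifest_path = Path(manifest_path)
    manifest = CohortManifest.load(manifest_path)
    out = []
    for entry in manifest.entries:
        file_fmt = fmt or Path(entry.path).suffix.lstrip(".")
        rec = read_recording(
            manifest_path.parent / entry.path,
            fmt=file_fmt,
            **({"fs_hz": entry.fs_hz, "subject_id": entry.subject_id, "task_id": entry.task_id}
               if file_fmt == "csv" else {}),
        )
        rec.subject_id = entry.subject_id
        rec.task_id = entry.task_id
        out.append(rec)
    return out
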