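"""Domain types and readers/writers for imagined-speech EEG recordings.

The canonical in-memory layout is channels x samples (rows are electrodes),
in microvolts, with an explicit sampling rate.  All readers normalise to this
orientation; file naming conventions are never parsed for metadata — the
dataset manifest is the single source of subject/class truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: 14-channel consumer-headset montage (international 10-20 names).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "T7", "T8", "P7", "P8", "O1", "O2",
)

#: Canonical sampling rate (Hz) and trial length (samples) of the target
#: dataset layout: 10-second epochs at 128 Hz.
CANONICAL_FS = 128.0
CANONICAL_N_SAMPLES = 1280

CATEGORIES = ("characters", "digits", "objects")

#: The five classification settings, by the categories they pool.
SETTINGS: dict[str, tuple[str, ...]] = {
    "characters": ("characters",),
    "digits": ("digits",),
    "objects": ("objects",),
    "chardig": ("characters", "digits"),
    "chardigobj": ("characters", "digits", "objects"),
}


class FormatError(ValueError):
    """File could not be parsed as the declared format."""


class ShapeError(ValueError):
    """Array dimensions disagree with the declared montage/layout."""


class ValidationError(ValueError):
    """Manifest content violates its invariants."""


@dataclass(frozen=True)
class Recording:
    """One subject/class trial: a channels x samples matrix in microvolts."""

    subject_id: str
    class_label: str
    category: str
    data: np.ndarray          # (n_channels, n_samples), float64, microvolts
    fs: float = CANONICAL_FS
    channel_names: tuple[str, ...] = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise ShapeError(f"recording data must be 2-D, got {data.ndim}-D")
        if data.shape[0] != len(self.channel_names):
            raise ShapeError(
                f"{data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            ch, idx = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at channel {self.channel_names[ch]!r}, sample {idx}"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the signal matrix replaced."""
        return replace(self, data=data)


@dataclass(frozen=True)
class ManifestEntry:
    recording_id: str
    subject_id: str
    class_label: str
    category: str
    file_path: str = ""


@dataclass(frozen=True)
class DatasetManifest:
    """Index of a dataset: who recorded what, and where the file lives."""

    entries: tuple[ManifestEntry, ...]
    class_universe: tuple[str, ...]
    subject_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "class_universe", tuple(self.class_universe))
        object.__setattr__(self, "subject_universe", tuple(self.subject_universe))
        ids = [e.recording_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate recording_id {dup!r}")
        known = set(self.class_universe)
        for e in self.entries:
            if e.class_label not in known:
                raise ValidationError(
                    f"class {e.class_label!r} of {e.recording_id!r} not in class universe"
                )
            if e.category not in CATEGORIES:
                raise ValidationError(
                    f"unknown category token {e.category!r} in {e.recording_id!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def filter_setting(
        self, setting: str, *, require_complete: bool = False
    ) -> "DatasetManifest":
        """Restrict to one of the five classification settings.

        With ``require_complete`` subjects lacking a recording for every class
        of the setting are dropped (mirrors exclusion of partially recorded
        participants from multi-category experiments).
        """
        if setting not in SETTINGS:
            raise ValidationError(
                f"unknown setting {setting!r}; expected one of {sorted(SETTINGS)}"
            )
        cats = SETTINGS[setting]
        entries = [e for e in self.entries if e.category in cats]
        classes = tuple(c for c in self.class_universe
                        if any(e.class_label == c for e in entries))
        if require_complete:
            need = set(classes)
            keep: set[str] = set()
            for s in {e.subject_id for e in entries}:
                have = {e.class_label for e in entries if e.subject_id == s}
                if need <= have:
                    keep.add(s)
            entries = [e for e in entries if e.subject_id in keep]
        subjects = tuple(s for s in self.subject_universe
                         if any(e.subject_id == s for e in entries))
        return DatasetManifest(tuple(entries), classes, subjects)


# ---------------------------------------------------------------------------
# CSV recordings
# ---------------------------------------------------------------------------

def read_recording_csv(
    path: str | Path,
    layout: str,
    *,
    subject_id: str,
    class_label: str,
    category: str,
    fs: float = CANONICAL_FS,
    channel_names: Sequence[str] = DEFAULT_MONTAGE,
    delimiter: str = ",",
) -> Recording:
    """Read a plain numeric matrix CSV as one Recording.

    ``layout`` must be ``"channels_as_rows"`` or ``"channels_as_columns"``;
    the orientation is never guessed from the matrix shape.
    """
    if layout not in ("channels_as_rows", "channels_as_columns"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, header=None, delimiter=delimiter)
    mat = frame.to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        coerced = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(coerced))
        r, c = (bad[0] if len(bad) else (0, 0))
        raise FormatError(f"non-numeric cell at row {r}, column {c} of {path.name}")
    mat = mat.astype(np.float64)
    if not np.all(np.isfinite(mat)):
        r, c = np.argwhere(~np.isfinite(mat))[0]
        raise FormatError(f"non-finite cell at row {r}, column {c} of {path.name}")
    if layout == "channels_as_columns":
        mat = mat.T
    if mat.shape[0] != len(channel_names):
        raise ShapeError(
            f"{path.name}: {mat.shape[0]} channels found, montage declares "
            f"{len(channel_names)}"
        )
    return Recording(subject_id, class_label, category, mat, fs, tuple(channel_names))


def write_recording_csv(
    recording: Recording,
    path: str | Path,
    *,
    layout: str = "channels_as_rows",
    delimiter: str = ",",
) -> None:
    """Write the signal matrix as a headerless numeric CSV."""
    mat = recording.data if layout == "channels_as_rows" else recording.data.T
    np.savetxt(path, mat, delimiter=delimiter, fmt="%.10g")


# ---------------------------------------------------------------------------
# EDF recordings
# ---------------------------------------------------------------------------

def _edf_samples_per_record(path: Path) -> list[int]:
    # EDF headers are fixed-width ASCII; the per-signal sample counts sit in
    # the last ns*8 bytes of the signal header block.
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path.name}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path.name}: unreadable EDF header") from exc
        sig_header = fh.read(ns * 256)
        if len(sig_header) < ns * 256:
            raise FormatError(f"{path.name}: truncated EDF signal header")
        off = ns * 216  # after label/transducer/dim/phys+dig ranges/prefilter
        return [
            int(sig_header[off + i * 8: off + (i + 1) * 8].decode("ascii").strip())
            for i in range(ns)
        ]


def read_recording_edf(
    path: str | Path,
    *,
    subject_id: str = "unknown",
    class_label: str = "unknown",
    category: str = "objects",
) -> list[Recording]:
    """Read an EDF/EDF+ file as one Recording per annotated trial.

    Without annotations the whole file becomes a single Recording.  Values
    are returned in microvolts; the sampling rate and channel names come from
    the EDF header.  Files mixing per-channel sampling rates are rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rates = _edf_samples_per_record(path)
    if len(set(rates)) > 1:
        raise FormatError(
            f"{path.name}: heterogeneous per-channel sampling rates {sorted(set(rates))} "
            "are not supported"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    names = tuple(raw.ch_names)
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts

    def make(seg: np.ndarray) -> Recording:
        return Recording(subject_id, class_label, category, seg, fs, names)

    spans = [
        (int(round(on * fs)), int(round((on + dur) * fs)))
        for on, dur in zip(raw.annotations.onset, raw.annotations.duration)
        if dur > 0
    ]
    if not spans:
        return [make(data_uv)]
    return [make(data_uv[:, a:b]) for a, b in spans if b > a]


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("recording_id", "subject_id", "class_label", "category", "file_path")


def load_manifest(path: str | Path, *, drop_incomplete_subjects: bool = False,
                  setting: str = "chardigobj") -> DatasetManifest:
    """Load a TSV or JSON manifest and validate it.

    With ``drop_incomplete_subjects`` subjects lacking full class coverage for
    ``setting`` are removed, mirroring the exclusion of partially recorded
    participants from multi-category experiments.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise ValidationError(f"manifest missing required columns {missing}")
    if "file_path" not in frame.columns:
        frame["file_path"] = ""
    if len(frame) == 0:
        raise ValidationError(f"manifest {path.name} contains no entries")
    entries = tuple(
        ManifestEntry(str(r.recording_id), str(r.subject_id), str(r.class_label),
                      str(r.category), str(r.file_path))
        for r in frame.itertuples()
    )
    classes = tuple(dict.fromkeys(e.class_label for e in entries))
    subjects = tuple(dict.fromkeys(e.subject_id for e in entries))
    manifest = DatasetManifest(entries, classes, subjects)
    if drop_incomplete_subjects:
        manifest = manifest.filter_setting(setting, require_complete=True)
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame([e.__dict__ for e in manifest.entries],
                         columns=list(_MANIFEST_COLUMNS))
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, sep="\t", index=False)
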