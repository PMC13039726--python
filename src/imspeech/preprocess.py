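"""Six-phase ICA-assisted frequency-domain preprocessing (FD-F).

Phases, in execution order:

1. ICA artifact removal — PCA rank selection retaining 99.99% of variance,
   independent-component unmixing, automatic rejection of components whose
   artifact score exceeds mean + 2.5 sigma of the across-component score
   distribution, reconstruction to channel space.
2. FFT of each channel to the frequency domain.
3. Zero-phase band-reject mask: unit gain outside 4-15 Hz, zero gain inside,
   2 Hz raised-cosine ramps placed on [2, 4] and [15, 17] Hz so the whole
   nominal stopband is fully suppressed.
4. Inverse FFT back to the time domain.
5. Sliding-window segmentation: Scheme A (32-sample windows, stride 8,
   overlapping) or Scheme B (8/8, non-overlapping).
6. Channel-wise z-score normalization with statistics fit on training
   windows only.

Two comparison modes share the same surface: ``td_bandreject`` (a zero-phase
forward-backward Butterworth band-stop, the conventional temporal filter) and
``full_band`` (identity).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .io_core import Recording, ShapeError

FILTER_MODES = ("fd_bandreject", "td_bandreject", "full_band")


class SpecError(ValueError):
    """Filter/ICA/windowing specification violates its invariants."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the phase."""


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICAConfig:
    """Automatic IC rejection: score each component, reject outliers.

    ``reject_threshold_sigma`` is the z-score cut on the across-component
    score distribution; ``variance_retained`` drives PCA rank selection
    before unmixing.  The artifact statistic is the per-component peak
    amplitude z, excess-kurtosis z, or the max of both (default).
    """

    reject_threshold_sigma: float = 2.5
    variance_retained: float = 0.9999
    artifact_statistic: str = "max_of_both"
    fit_scope: str = "per_subject"
    seed: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.variance_retained <= 1:
            raise SpecError(f"variance_retained must be in (0, 1], got "
                            f"{self.variance_retained}")
        if not self.reject_threshold_sigma > 0:
            raise SpecError("reject_threshold_sigma must be positive")
        if self.artifact_statistic not in ("peak_z", "kurtosis_z", "max_of_both"):
            raise SpecError(f"unknown artifact_statistic {self.artifact_statistic!r}")
        if self.fit_scope not in ("per_recording", "per_subject"):
            raise SpecError(f"unknown fit_scope {self.fit_scope!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Band-reject specification shared by the FD-F and TD-F paths."""

    mode: str = "fd_bandreject"
    stop_lo: float = 4.0
    stop_hi: float = 15.0
    ramp: float = 2.0
    fd_application: str = "single_pass"
    td_order: int = 4

    def __post_init__(self) -> None:
        if self.mode not in FILTER_MODES:
            raise SpecError(f"unknown filter mode {self.mode!r}")
        if self.mode == "full_band":
            return
        if not self.stop_lo < self.stop_hi:
            raise SpecError(f"stop_lo {self.stop_lo} must be < stop_hi {self.stop_hi}")
        if self.stop_lo - self.ramp < 0:
            raise SpecError("lower transition ramp extends below 0 Hz")
        if self.fd_application not in ("single_pass", "squared_gain"):
            raise SpecError(f"unknown fd_application {self.fd_application!r}")

    def validate_against_fs(self, fs: float) -> None:
        if self.mode != "full_band" and not self.stop_hi + self.ramp < fs / 2:
            raise SpecError(
                f"upper transition ramp reaches {self.stop_hi + self.ramp} Hz, "
                f"at/above Nyquist {fs / 2} Hz"
            )


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window segmentation parameters.

    Scheme A: 32-sample (250 ms) windows, stride 8 — overlapping.
    Scheme B: 8-sample (62.5 ms) windows, stride 8 — non-overlapping,
    used wherever temporal leakage must be excluded.
    """

    name: str = "A"
    ws: int = 32
    stride: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.ws:
            raise SpecError(f"need 0 < stride <= ws, got stride={self.stride}, "
                            f"ws={self.ws}")
        if self.name == "B" and self.ws != self.stride:
            raise SpecError("Scheme B requires ws == stride (non-overlapping)")

    @property
    def overlapping(self) -> bool:
        return self.stride < self.ws

    @classmethod
    def scheme_a(cls) -> "WindowingScheme":
        return cls("A", 32, 8)

    @classmethod
    def scheme_b(cls) -> "WindowingScheme":
        return cls("B", 8, 8)


def expected_window_count(n_recordings: int, n_spr: int, ws: int, stride: int) -> int:
    """Total window count: N_rec * (floor((N_spr - WS) / Stride) + 1)."""
    if ws > n_spr:
        raise SpecError(f"window size {ws} exceeds recording length {n_spr}")
    return n_recordings * ((n_spr - ws) // stride + 1)


@dataclass
class WindowSet:
    """Segmented windows with labels and full provenance.

    ``windows`` is (N, ws, n_channels); ``starts`` holds each window's start
    sample within its source recording, which the leakage audits rely on.
    """

    windows: np.ndarray
    labels: np.ndarray            # int class indices
    subject_ids: np.ndarray       # str array
    recording_ids: np.ndarray     # str array
    starts: np.ndarray            # int start-sample indices
    scheme: WindowingScheme
    class_labels: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        n = len(self.windows)
        for name in ("labels", "subject_ids", "recording_ids", "starts"):
            if len(getattr(self, name)) != n:
                raise ShapeError(f"provenance array {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[idx], self.labels[idx],
                         self.subject_ids[idx], self.recording_ids[idx],
                         self.starts[idx], self.scheme, self.class_labels,
                         self.normalized)

    def save(self, path: str | Path) -> None:
        """Binary array container plus a JSON sidecar of labels/provenance."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.windows)
        sidecar = {
            "labels": self.labels.tolist(),
            "subject_ids": self.subject_ids.tolist(),
            "recording_ids": self.recording_ids.tolist(),
            "starts": self.starts.tolist(),
            "scheme": {"name": self.scheme.name, "ws": self.scheme.ws,
                       "stride": self.scheme.stride},
            "class_labels": list(self.class_labels),
            "normalized": self.normalized,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        windows = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(windows, np.asarray(meta["labels"]),
                   np.asarray(meta["subject_ids"]),
                   np.asarray(meta["recording_ids"]),
                   np.asarray(meta["starts"]),
                   WindowingScheme(**meta["scheme"]),
                   tuple(meta["class_labels"]), meta["normalized"])


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel train-set mean/sd for z-score normalization."""

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.sd):
            raise ShapeError("mean and sd length mismatch")
        if not self.sd_floor > 0:
            raise SpecError("sd_floor must be positive")
        if np.any(self.sd < self.sd_floor):
            raise SpecError("sd entries below sd_floor")


# ---------------------------------------------------------------------------
# Phase 1: ICA artifact removal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICAReport:
    """Per-fit component scores and rejection decisions."""

    scope_key: str
    n_components: int
    scores: np.ndarray
    rejected: tuple[int, ...]
    skipped: bool = False
    reason: str = ""


def _component_scores(sources: np.ndarray, statistic: str) -> np.ndarray:
    """Artifact statistic per component (rows of ``sources``)."""
    from scipy import stats as sp_stats

    peak = np.max(np.abs(sources), axis=1) / (np.std(sources, axis=1) + 1e-12)
    kurt = sp_stats.kurtosis(sources, axis=1, fisher=True)
    if statistic == "peak_z":
        return peak
    if statistic == "kurtosis_z":
        return kurt

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    return np.maximum(z(peak), z(kurt))


def _clean_matrix(data: np.ndarray, config: ICAConfig,
                  scope_key: str) -> tuple[np.ndarray, ICAReport]:
    """ICA-clean one channels x samples matrix (possibly concatenated trials)."""
    from sklearn.decomposition import FastICA

    n_ch, n_samp = data.shape
    if n_samp < 10 * n_ch ** 2:
        warnings.warn(
            f"ICA fit for {scope_key!r}: {n_samp} samples < 10*n_channels^2 "
            f"({10 * n_ch ** 2}); skipping with identity transform",
            stacklevel=3,
        )
        return data, ICAReport(scope_key, 0, np.empty(0), (), True,
                               "insufficient samples")
    ch_sd = data.std(axis=1)
    if np.any(ch_sd < 1e-12):
        bad = int(np.argmin(ch_sd))
        raise PipelineError(
            f"phase 1 (ICA): channel index {bad} is constant; rank-deficient input"
        )
    mean = data.mean(axis=1, keepdims=True)
    centred = data - mean
    # PCA rank selection: smallest rank explaining >= variance_retained.
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s ** 2
    frac = np.cumsum(var) / var.sum()
    rank = int(np.searchsorted(frac, config.variance_retained) + 1)
    rank = min(rank, len(s))
    reduced = (u[:, :rank].T @ centred)  # rank x samples
    ica = FastICA(n_components=rank, whiten="unit-variance",
                  random_state=config.seed, max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(reduced.T).T  # rank x samples
    scores = _component_scores(sources, config.artifact_statistic)
    mu, sd = scores.mean(), scores.std()
    threshold = mu + config.reject_threshold_sigma * (sd if sd > 0 else 1.0)
    rejected = tuple(int(i) for i in np.flatnonzero(scores > threshold))
    kept_sources = sources.copy()
    for i in rejected:
        kept_sources[i] = 0.0
    restored = ica.inverse_transform(kept_sources.T).T  # rank x samples
    cleaned = u[:, :rank] @ restored + mean
    return cleaned, ICAReport(scope_key, rank, scores, rejected)


def ica_clean(recordings: Sequence[Recording],
              config: ICAConfig = ICAConfig()) -> tuple[list[Recording],
                                                        list[ICAReport]]:
    """Phase 1: decompose, reject outlier components, reconstruct.

    With ``fit_scope='per_subject'`` all of a subject's recordings are
    concatenated for a single label-blind fit, then split back; with
    ``'per_recording'`` each trial is fit independently.
    """
    if not recordings:
        return [], []
    for rec in recordings:
        if rec.n_channels < 2:
            raise PipelineError("phase 1 (ICA): need at least 2 channels")
        if not np.all(np.isfinite(rec.data)):
            raise PipelineError("phase 1 (ICA): non-finite input")
    reports: list[ICAReport] = []
    cleaned: list[Recording] = []
    if config.fit_scope == "per_recording":
        for rec in recordings:
            key = f"{rec.subject_id}/{rec.class_label}"
            out, rep = _clean_matrix(rec.data, config, key)
            cleaned.append(rec.with_data(out))
            reports.append(rep)
        return cleaned, reports
    # per_subject: concatenate along time, preserve input order on return
    order: dict[str, list[int]] = {}
    for i, rec in enumerate(recordings):
        order.setdefault(rec.subject_id, []).append(i)
    out_data: dict[int, np.ndarray] = {}
    for subject, idxs in order.items():
        lengths = [recordings[i].n_samples for i in idxs]
        stacked = np.concatenate([recordings[i].data for i in idxs], axis=1)
        cleaned_mat, rep = _clean_matrix(stacked, config, subject)
        reports.append(rep)
        pos = 0
        for i, ln in zip(idxs, lengths):
            out_data[i] = cleaned_mat[:, pos: pos + ln]
            pos += ln
    cleaned = [recordings[i].with_data(out_data[i]) for i in range(len(recordings))]
    return cleaned, reports


# ---------------------------------------------------------------------------
# Phases 2-4: frequency-domain band-reject
# ---------------------------------------------------------------------------

def design_fd_mask(spec: FilterSpec, n_samples: int, fs: float) -> np.ndarray:
    """Real gain over the non-negative (rfft) frequency grid.

    Unit gain up to ``stop_lo - ramp``, raised-cosine descent to zero at
    ``stop_lo``, zero through ``stop_hi``, raised-cosine ascent back to unit
    gain at ``stop_hi + ramp``.  With ``fd_application='squared_gain'`` the
    returned mask is the square of that profile (the literal forward-backward
    magnitude response).
    """
    if spec.mode != "fd_bandreject":
        raise SpecError(f"design_fd_mask requires fd_bandreject mode, got {spec.mode!r}")
    spec.validate_against_fs(fs)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.ones_like(freqs)
    lo0, lo1 = spec.stop_lo - spec.ramp, spec.stop_lo
    hi0, hi1 = spec.stop_hi, spec.stop_hi + spec.ramp
    down = (freqs > lo0) & (freqs < lo1)
    gain[down] = 0.5 * (1 + np.cos(np.pi * (freqs[down] - lo0) / spec.ramp))
    gain[(freqs >= lo1) & (freqs <= hi0)] = 0.0
    up = (freqs > hi0) & (freqs < hi1)
    gain[up] = 0.5 * (1 - np.cos(np.pi * (freqs[up] - hi0) / spec.ramp))
    if spec.fd_application == "squared_gain":
        gain = gain ** 2
    return gain


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Phases 2-4: forward transform, mask, inverse transform.

    ``td_bandreject`` runs a zero-phase forward-backward Butterworth
    band-stop instead; ``full_band`` is the identity.
    """
    if spec.mode == "full_band":
        return recording
    spec.validate_against_fs(recording.fs)
    if spec.mode == "fd_bandreject":
        mask = design_fd_mask(spec, recording.n_samples, recording.fs)
        spectrum = np.fft.rfft(recording.data, axis=1)
        filtered = np.fft.irfft(spectrum * mask, n=recording.n_samples, axis=1)
        return recording.with_data(filtered)
    # td_bandreject: conventional temporal-filter baseline
    sos = sp_signal.butter(spec.td_order, [spec.stop_lo, spec.stop_hi],
                           btype="bandstop", fs=recording.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.with_data(filtered)


# ---------------------------------------------------------------------------
# Phase 5: segmentation
# ---------------------------------------------------------------------------

def segment(recordings: Sequence[Recording],
            scheme: WindowingScheme,
            class_labels: Sequence[str] | None = None,
            recording_ids: Sequence[str] | None = None) -> WindowSet:
    """Slide windows over each recording; windows never cross recordings.

    Start indices are 0, stride, 2*stride, ... while start + ws <= n_samples;
    trailing samples that do not fill a window are dropped.
    """
    if not recordings:
        raise SpecError("segment: no recordings given")
    if class_labels is None:
        class_labels = tuple(dict.fromkeys(r.class_label for r in recordings))
    label_index = {c: i for i, c in enumerate(class_labels)}
    if recording_ids is None:
        recording_ids = [f"{r.subject_id}_{r.class_label}_{i:03d}"
                         for i, r in enumerate(recordings)]
    chunks, labels, subjects, rec_ids, starts = [], [], [], [], []
    for rec, rid in zip(recordings, recording_ids):
        if scheme.ws > rec.n_samples:
            raise SpecError(
                f"segment: window size {scheme.ws} exceeds length "
                f"{rec.n_samples} of recording {rid!r}"
            )
        n_win = (rec.n_samples - scheme.ws) // scheme.stride + 1
        for k in range(n_win):
            s = k * scheme.stride
            chunks.append(rec.data[:, s: s + scheme.ws].T)  # (ws, n_channels)
            labels.append(label_index[rec.class_label])
            subjects.append(rec.subject_id)
            rec_ids.append(rid)
            starts.append(s)
    return WindowSet(np.stack(chunks), np.asarray(labels, dtype=np.int64),
                     np.asarray(subjects), np.asarray(rec_ids),
                     np.asarray(starts, dtype=np.int64), scheme,
                     tuple(class_labels))


# ---------------------------------------------------------------------------
# Phase 6: normalization
# ---------------------------------------------------------------------------

def fit_normalizer(train: WindowSet, sd_floor: float = 1e-8) -> NormalizationStats:
    """Per-channel mean/sd over all training windows and timepoints pooled."""
    if len(train) == 0:
        raise SpecError("fit_normalizer: empty training set")
    if train.normalized:
        raise SpecError("fit_normalizer: training set is already normalized")
    mean = train.windows.mean(axis=(0, 1))
    sd = train.windows.std(axis=(0, 1))  # population convention
    return NormalizationStats(mean, np.maximum(sd, sd_floor), sd_floor)


def apply_normalizer(stats: NormalizationStats, ws: WindowSet) -> WindowSet:
    """(X - mu_train) / sigma_train per channel; never refits on ``ws``."""
    if ws.normalized:
        raise SpecError("apply_normalizer: window set is already normalized")
    if ws.n_channels != len(stats.mean):
        raise ShapeError(f"{ws.n_channels} channels vs {len(stats.mean)} stats")
    out = ws.subset(np.arange(len(ws)))
    out.windows = (ws.windows - stats.mean) / stats.sd
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    timings: dict[str, float] = field(default_factory=dict)
    ica_reports: list[ICAReport] = field(default_factory=list)
    n_train_windows: int = 0
    n_test_windows: int = 0


def run_pipeline(
    recordings: Sequence[Recording],
    recording_ids: Sequence[str],
    split: tuple[Sequence[str], Sequence[str]],
    *,
    ica: ICAConfig = ICAConfig(),
    filt: FilterSpec = FilterSpec(),
    scheme: WindowingScheme = WindowingScheme.scheme_a(),
    class_labels: Sequence[str] | None = None,
    sd_floor: float = 1e-8,
) -> tuple[WindowSet, WindowSet, PipelineReport]:
    """Phases 1-6 end to end for one train/test recording split.

    ``split`` is a pair of recording-id collections (train, test) that must
    cover all recordings disjointly.  Normalization statistics are fit on
    training windows only.
    """
    train_ids, test_ids = set(split[0]), set(split[1])
    overlap = train_ids & test_ids
    if overlap:
        raise SpecError(f"split error: recordings in both train and test: "
                        f"{sorted(overlap)[:3]}")
    uncovered = set(recording_ids) - train_ids - test_ids
    if uncovered:
        raise SpecError(f"split error: recordings in neither role: "
                        f"{sorted(uncovered)[:3]}")
    report = PipelineReport()
    t0 = time.perf_counter()
    if ica.enabled:
        try:
            recs, report.ica_reports = ica_clean(list(recordings), ica)
        except PipelineError:
            raise
        except Exception as exc:  # attach phase context
            raise PipelineError(f"phase 1 (ICA): {exc}") from exc
    else:
        recs = list(recordings)
    report.timings["phase1_ica"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    recs = [apply_filter(r, filt) for r in recs]
    report.timings["phase2_4_filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    windows = segment(recs, scheme, class_labels=class_labels,
                      recording_ids=recording_ids)
    report.timings["phase5_segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    in_train = np.isin(windows.recording_ids, list(train_ids))
    train_ws = windows.subset(np.flatnonzero(in_train))
    test_ws = windows.subset(np.flatnonzero(~in_train))
    stats = fit_normalizer(train_ws, sd_floor)
    train_ws = apply_normalizer(stats, train_ws)
    test_ws = apply_normalizer(stats, test_ws) if len(test_ws) else test_ws
    report.timings["phase6_normalize"] = time.perf_counter() - t0
    report.n_train_windows = len(train_ws)
    report.n_test_windows = len(test_ws)
    return train_ws, test_ws, report
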