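"""Shared fixtures: tiny synthetic datasets and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from imspeech.io_core import DEFAULT_MONTAGE
from imspeech.synthetic import SynthConfig, generate_dataset


def write_edf(path: Path, data_uv: np.ndarray, fs: float,
              channel_names: list[str],
              samples_per_record: list[int] | None = None) -> np.ndarray:
    """Minimal synthetic EDF writer for round-trip fixtures only.

    Encodes ``data_uv`` (channels x samples, microvolts) as 16-bit EDF with
    physical range ±400 uV.  Returns the quantized physical values actually
    stored, for comparison against what a reader recovers.  This exists
    purely to exercise the EDF reader; it is not a general-purpose exporter.
    """
    n_ch, n_samp = data_uv.shape
    if samples_per_record is None:
        samples_per_record = [int(fs)] * n_ch
    n_records = n_samp // samples_per_record[0]
    phys_min, phys_max = -400.0, 400.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 + 256 * n_ch), 8), pad("EDF", 44),
        pad(str(n_records), 8), pad(f"{1.0 / (fs / samples_per_record[0]):g}", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min:g}", 8)] * n_ch,
        [pad(f"{phys_max:g}", 8)] * n_ch,
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8) for spr in samples_per_record],
        [pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data_uv - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype(np.int16)
    body = bytearray()
    for rec in range(n_records):
        for ch in range(n_ch):
            spr = samples_per_record[ch]
            chunk = digital[ch, rec * spr: (rec + 1) * spr]
            body.extend(struct.pack(f"<{len(chunk)}h", *chunk))
    path.write_bytes(header + sig_header + bytes(body))
    return (digital.astype(float) - dig_min) / scale + phys_min


@pytest.fixture(scope="session")
def montage() -> tuple[str, ...]:
    return DEFAULT_MONTAGE


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 3 classes x 2 trials of short, clean recordings."""
    cfg = SynthConfig(n_subjects=2, classes=("A", "C", "F"),
                      trials_per_class=2, n_samples=256, snr_db=10.0, seed=42)
    manifest, recordings, events = generate_dataset(cfg)
    return cfg, manifest, recordings, events
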