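"""Minimal synthetic EDF+C writer for import tests.

Writes just enough of the EDF+ continuous format (16-bit samples, one
annotation channel carrying timestamped event labels) for mne's reader
to ingest.  Test-fixture generation only — not a general EDF exporter.
"""

from __future__ import annotations

import numpy as np


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {value!r}")
    return b.ljust(width)


def write_edf(
    path,
    signals: np.ndarray,
    fs: int,
    annotations: list[tuple[float, str]],
    phys_range: float = 500.0,
) -> None:
    """Write channels x samples ``signals`` (microvolts) with annotations.

    The sample count must be a multiple of ``fs`` (1-second records).
    ``annotations`` is a list of (onset_seconds, label) pairs.
    """
    signals = np.asarray(signals, dtype=np.float64)
    n_ch, n_samp = signals.shape
    if n_samp % fs:
        raise ValueError("sample count must be a multiple of fs")
    n_rec = n_samp // fs
    ns = n_ch + 1  # + annotation channel
    annot_samples = 60  # int16 "samples" -> 120 bytes of TAL text per record

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2020 X X X", 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + ns)), 8),
        _field("EDF+C", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    labels = [f"EEG ch{i}" for i in range(n_ch)] + ["EDF Annotations"]
    sig_fields = [
        ("".join, [_field(lab, 16) for lab in labels]),
        ("".join, [_field("", 80)] * ns),
        ("".join, [_field("uV", 8)] * n_ch + [_field("", 8)]),
        ("".join, [_field(f"{-phys_range:g}", 8)] * n_ch + [_field("-1", 8)]),
        ("".join, [_field(f"{phys_range:g}", 8)] * n_ch + [_field("1", 8)]),
        ("".join, [_field("-32768", 8)] * ns),
        ("".join, [_field("32767", 8)] * ns),
        ("".join, [_field("", 80)] * ns),
        ("".join, [_field(str(fs), 8)] * n_ch + [_field(str(annot_samples), 8)]),
        ("".join, [_field("", 32)] * ns),
    ]
    header += b"".join(b"".join(parts) for _, parts in sig_fields)

    scale = 32767.0 / phys_range
    digital = np.clip(np.round(signals * scale), -32768, 32767).astype("<i2")

    per_record_annots: list[list[tuple[float, str]]] = [[] for _ in range(n_rec)]
    for onset, text in annotations:
        rec = min(int(onset), n_rec - 1)
        per_record_annots[rec].append((onset, text))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            fh.write(digital[:, rec * fs : (rec + 1) * fs].tobytes(order="C"))
            tal = f"+{rec}\x14\x14\x00".encode("ascii")
            for onset, text in per_record_annots[rec]:
                tal += f"+{onset:g}\x14{text}\x14\x00".encode("ascii")
            tal = tal.ljust(2 * annot_samples, b"\x00")
            if len(tal) > 2 * annot_samples:
                raise ValueError("too many annotations in one record")
            fh.write(tal)
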