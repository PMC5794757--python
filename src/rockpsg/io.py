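"""File formats: EDF signals, hypnogram CSV, ground-truth JSON, YAML config.

EDF (European Data Format) files are written with 16-bit samples in
physical units of microvolts, 1-s data records, and per-channel physical
scaling chosen from the data range, so a write/read round trip is exact
to one quantization step.  The reader validates the header and the data
length and reports the byte offset of any truncation instead of silently
clipping.

Hypnograms travel as CSV with columns ``epoch_index, stage, artifact``
(stage in {W, N1, N2, N3, REM}, artifact in {0, 1}); epoch 0 is the
first epoch after lights out.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import yaml

from .core import EEGRecording, EpochedHypnogram
from .synthetic import ConditionEffects, GroundTruth, SimulationConfig

__all__ = [
    "write_edf",
    "read_edf",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "load_config_yaml",
    "save_config_yaml",
]

_HDR = 256  # bytes, fixed part
_SIG_HDR = 256  # bytes per signal


class EDFParseError(ValueError):
    """Malformed or truncated EDF content; message includes a byte offset."""


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: Union[str, Path]) -> None:
    """Write a recording as EDF with 16-bit samples and 1-s records.

    The recording length must be a whole number of seconds.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.channel_labels)
    if rec.n_samples % fs != 0:
        raise ValueError("recording length must be a whole number of seconds")
    n_records = rec.n_samples // fs

    phys_min, phys_max, scaled = [], [], []
    for ch in rec.samples:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        # widen a hair so extremes stay inside the digital range
        span = hi - lo
        lo -= 1e-6 * span
        hi += 1e-6 * span
        dig = np.round(
            (ch - lo) / (hi - lo) * (32767 - (-32768)) + (-32768)
        ).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(dig)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad(f"Startdate X rockpsg ref:{rec.reference}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_HDR + n_ch * _SIG_HDR), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        [_pad(lbl, 16) for lbl in rec.channel_labels],
        [_pad("EEG electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.8g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.8g}"[:8], 8) for v in phys_max],
        [_pad("-32768", 8)] * n_ch,
        [_pad("32767", 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * fs : (r + 1) * fs].tobytes())


def read_edf(path: Union[str, Path]) -> EEGRecording:
    """Read a 16-bit EDF file into an :class:`EEGRecording` (uV)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HDR:
        raise EDFParseError(f"file shorter than EDF header (offset {len(raw)})")

    def field(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    if field(0, 8) not in ("0", "255"):
        raise EDFParseError("unrecognized EDF version field (offset 0)")
    try:
        header_bytes = int(field(184, 8))
        n_records = int(field(236, 8))
        record_dur = float(field(244, 8))
        n_ch = int(field(252, 4))
    except ValueError as exc:
        raise EDFParseError(f"malformed numeric header field: {exc} (offset 184)")
    expected_hdr = _HDR + n_ch * _SIG_HDR
    if header_bytes != expected_hdr or len(raw) < expected_hdr:
        raise EDFParseError(
            f"header size mismatch at offset 184: {header_bytes} != {expected_hdr}"
        )

    def sig_field(block: int, width: int, i: int) -> str:
        off = _HDR + block + i * width
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    labels = [sig_field(0, 16, i) for i in range(n_ch)]
    off = n_ch * 16 + n_ch * 80 + n_ch * 8  # skip transducer + phys dim
    phys_min = [float(sig_field(off, 8, i)) for i in range(n_ch)]
    off += n_ch * 8
    phys_max = [float(sig_field(off, 8, i)) for i in range(n_ch)]
    off += n_ch * 8
    dig_min = [int(sig_field(off, 8, i)) for i in range(n_ch)]
    off += n_ch * 8
    dig_max = [int(sig_field(off, 8, i)) for i in range(n_ch)]
    off += n_ch * 8 + n_ch * 80
    spr = [int(sig_field(off, 8, i)) for i in range(n_ch)]

    rec_len = sum(spr) * 2
    data = raw[expected_hdr:]
    if len(data) < n_records * rec_len:
        raise EDFParseError(
            f"truncated data: expected {n_records * rec_len} bytes, got "
            f"{len(data)} (offset {expected_hdr + len(data)})"
        )
    sigs: List[np.ndarray] = [np.empty(n_records * spr[i]) for i in range(n_ch)]
    pos = 0
    for r in range(n_records):
        for i in range(n_ch):
            chunk = np.frombuffer(data, dtype="<i2", count=spr[i], offset=pos)
            gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
            sigs[i][r * spr[i] : (r + 1) * spr[i]] = (
                (chunk.astype(float) - dig_min[i]) * gain + phys_min[i]
            )
            pos += spr[i] * 2
    fs = spr[0] / record_dur
    if any(s != spr[0] for s in spr):
        raise EDFParseError("channels with differing sampling rates not supported")
    ref = "Cz"
    rec_field = field(88, 80)
    if "ref:" in rec_field:
        ref = rec_field.split("ref:")[1].split()[0]
    return EEGRecording(
        samples=np.vstack(sigs),
        sampling_rate=fs,
        channel_labels=labels,
        reference=ref,
    )


def write_hypnogram_csv(h: EpochedHypnogram, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "epoch_index": np.arange(h.n_epochs),
            "stage": h.stages,
            "artifact": h.artifact_flags.astype(int),
        }
    ).to_csv(path, index=False)


def read_hypnogram_csv(path: Union[str, Path]) -> EpochedHypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "stage", "artifact"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    df = df.sort_values("epoch_index")
    return EpochedHypnogram(
        stages=df["stage"].to_numpy(),
        artifact_flags=df["artifact"].to_numpy().astype(bool),
        lights_out_epoch=0,
    )


def write_ground_truth_json(truth: GroundTruth, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth_json(path: Union[str, Path]) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        spindle_events=[tuple(e) for e in d["spindle_events"]],
        so_events=[tuple(e) for e in d["so_events"]],
        delta_power=np.asarray(d["delta_power"], dtype=float),
    )


def save_config_yaml(config: SimulationConfig, path: Union[str, Path]) -> None:
    d = asdict(config)
    d["stage_transition_matrix"] = [
        list(map(float, row)) for row in config.stage_transition_matrix
    ]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config_yaml(path: Union[str, Path]) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "condition_effects" in d and isinstance(d["condition_effects"], dict):
        d["condition_effects"] = ConditionEffects(**d["condition_effects"])
    for key in ("conditions", "spindle_freq_range", "spindle_duration_range",
                "spindle_amp_range", "so_freq_range", "so_amp_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
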