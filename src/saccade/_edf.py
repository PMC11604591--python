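"""Minimal EDF (European Data Format) record-oriented reader/writer.

Only the subset needed for the optional external-EEG path: fixed-length data
records, 16-bit samples with per-channel physical scaling, ASCII headers.  One
data record holds one trial.
"""

from __future__ import annotations

import numpy as np

_HEADER = 256
_PER_SIGNAL = 256


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path,
    records: np.ndarray,
    ch_names: list[str],
    sfreq: float,
    phys_dim: str = "uV",
) -> None:
    """Write ``records`` (n_records, n_channels, samples_per_record) as EDF."""
    records = np.asarray(records, dtype=np.float64)
    if records.ndim != 3:
        raise ValueError(f"records must be 3-D, got shape {records.shape}")
    n_rec, n_ch, spr = records.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count does not match data")
    dig_min, dig_max = -32768, 32767
    phys_min = records.min(axis=(0, 2))
    phys_max = records.max(axis=(0, 2))
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header_bytes = _HEADER + _PER_SIGNAL * n_ch
    duration = spr / sfreq
    head = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field(f"{duration:g}", 8),
            _field(str(n_ch), 4),
        ]
    )

    def per_signal(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    head += per_signal(ch_names, 16)
    head += per_signal([""] * n_ch, 80)
    head += per_signal([phys_dim] * n_ch, 8)
    head += per_signal([f"{v:.6g}" for v in phys_min], 8)
    head += per_signal([f"{v:.6g}" for v in phys_max], 8)
    head += per_signal([str(dig_min)] * n_ch, 8)
    head += per_signal([str(dig_max)] * n_ch, 8)
    head += per_signal([""] * n_ch, 80)
    head += per_signal([str(spr)] * n_ch, 8)
    head += per_signal([""] * n_ch, 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(head)
        for rec in records:
            dig = np.rint((rec - phys_min[:, None]) * scale[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path) -> dict:
    """Read an EDF file written by :func:`write_edf` (or compatible).

    Returns ``{"records": (n_rec, n_ch, spr) float array, "ch_names": [...],
    "sfreq": float}``.
    """
    with open(path, "rb") as fh:
        head = fh.read(_HEADER)
        if len(head) < _HEADER:
            raise ValueError(f"{path}: truncated EDF header")
        n_rec = int(head[236:244].decode("ascii").strip())
        duration = float(head[244:252].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(_PER_SIGNAL * n_ch)

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        # field-major layout: 16 label, 80 transducer, 8 phys_dim, 8 phys_min,
        # 8 phys_max, 8 dig_min, 8 dig_max, 80 prefilter, 8 samples, 32 reserved
        ch_names = col(0, 16)
        phys_min = np.array([float(v) for v in col(104, 8)])
        phys_max = np.array([float(v) for v in col(112, 8)])
        dig_min = np.array([float(v) for v in col(120, 8)])
        dig_max = np.array([float(v) for v in col(128, 8)])
        spr_list = [int(v) for v in col(216, 8)]
        if len(set(spr_list)) != 1:
            raise ValueError("mixed samples-per-record not supported")
        spr = spr_list[0]
        raw = np.frombuffer(fh.read(n_rec * n_ch * spr * 2), dtype="<i2")
    dig = raw.reshape(n_rec, n_ch, spr).astype(np.float64)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    phys = (dig - dig_min[None, :, None]) * scale[None, :, None] + phys_min[None, :, None]
    return {"records": phys, "ch_names": ch_names, "sfreq": spr / duration}
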