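"""Plain-text I/O for recordings, protocols, MAD tables and heart rate.

All on-disk formats are headered CSV:

* raw recording: ``t_s,ax_mg,ay_mg,az_mg`` (or ``ax_g,...`` when values
  are in g; they are converted to mg on read), one file per device per
  participant;
* bout protocol: ``participant,label,intensity_class,start_s,end_s``;
* MAD table: ``participant,device,bout_index,label,intensity_class,
  epoch_slot,mad_mg``;
* heart rate: ``participant,bout_label,hr_start_bpm,hr_1min_bpm,
  hr_2min_bpm``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal_core import ActivityBout, RawRecording

__all__ = [
    "read_bout_protocol",
    "read_heart_rate_table",
    "read_mad_table",
    "read_raw_recording",
    "write_bout_protocol",
    "write_heart_rate_table",
    "write_mad_table",
    "write_raw_recording",
]

_MG_COLS = ["t_s", "ax_mg", "ay_mg", "az_mg"]
_G_COLS = ["t_s", "ax_g", "ay_g", "az_g"]
MAD_TABLE_COLS = [
    "participant", "device", "bout_index", "label", "intensity_class",
    "epoch_slot", "mad_mg",
]
HR_TABLE_COLS = [
    "participant", "bout_label", "hr_start_bpm", "hr_1min_bpm", "hr_2min_bpm",
]


def read_raw_recording(
    path: str | Path,
    device_id: str,
    dynamic_range_mg: float,
    sampling_rate_hz: float | None = None,
) -> RawRecording:
    """Read a tri-axial recording CSV, converting g to mg if needed.

    The unit is declared by the header (``ax_mg`` vs ``ax_g``).  When the
    sampling rate is not given it is inferred from the median timestamp
    step.  Timestamps must be strictly increasing; malformed rows raise
    with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:4] == _MG_COLS:
        scale = 1.0
    elif cols[:4] == _G_COLS:
        scale = 1000.0
    else:
        raise ValueError(
            f"{path}: header must start with {_MG_COLS} or {_G_COLS}; got {cols}"
        )
    values = df.iloc[:, :4].to_numpy(dtype=float, na_value=np.nan)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    t = values[:, 0]
    if t.size > 1 and (np.diff(t) <= 0).any():
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{path}: non-monotone timestamp at line {i + 3}")
    if sampling_rate_hz is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from one row")
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(
        device_id=device_id,
        sampling_rate_hz=float(sampling_rate_hz),
        dynamic_range_mg=float(dynamic_range_mg),
        samples=values[:, 1:4] * scale,
        start_time_s=float(t[0]),
    )


def write_raw_recording(recording: RawRecording, path: str | Path) -> None:
    t = recording.start_time_s + np.arange(recording.n_samples) / recording.sampling_rate_hz
    df = pd.DataFrame(
        {
            "t_s": t,
            "ax_mg": recording.samples[:, 0],
            "ay_mg": recording.samples[:, 1],
            "az_mg": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.3f")


def read_bout_protocol(path: str | Path) -> dict[str, list[ActivityBout]]:
    """Read a bout protocol CSV into per-participant bout lists."""
    df = pd.read_csv(path)
    required = {"participant", "label", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: protocol needs columns {sorted(required)}")
    out: dict[str, list[ActivityBout]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.participant), []).append(
            ActivityBout(label=row.label, start_s=float(row.start_s),
                         end_s=float(row.end_s))
        )
    return out


def write_bout_protocol(
    bouts_by_participant: dict[str, list[ActivityBout]], path: str | Path
) -> None:
    rows = [
        {
            "participant": pid,
            "label": b.label,
            "intensity_class": b.intensity_class,
            "start_s": b.start_s,
            "end_s": b.end_s,
        }
        for pid, bouts in bouts_by_participant.items()
        for b in bouts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mad_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MAD_TABLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: MAD table missing columns {sorted(missing)}")
    return df


def write_mad_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MAD_TABLE_COLS].to_csv(path, index=False)


def read_heart_rate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(HR_TABLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: heart-rate table missing columns {sorted(missing)}")
    return df


def write_heart_rate_table(table: pd.DataFrame, path: str | Path) -> None:
    table[HR_TABLE_COLS].to_csv(path, index=False)
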