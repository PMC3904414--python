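"""Plain-text (TSV) input/output for signals and tables.

Signal files carry a comment header line ``# sampling_rate_hz: <rate>`` and a
tab-separated header row; column 1 is time in seconds, remaining columns are
channels.  All floats are written with a fixed format so repeated runs with
the same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cardio import BreathTrace
from .emg import EmgRecording
from .nirs import NirsTrace

FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _write_signal(path: Path, sampling_rate: float, header: list[str],
                  columns: list[np.ndarray]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.column_stack(columns)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {sampling_rate:g}\n")
        fh.write("\t".join(header) + "\n")
        np.savetxt(fh, arr, fmt="%.4f", delimiter="\t")


def _read_signal(path: Path) -> tuple[float, list[str], np.ndarray]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# sampling_rate_hz:"):
            raise ValueError(f"{path}: missing sampling-rate comment line")
        rate = float(first.split(":", 1)[1])
        header = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return rate, header, data


def write_emg(rec: EmgRecording, path: Path) -> None:
    _write_signal(path, rec.sampling_rate, ["time_s", *rec.channel_names],
                  [rec.times, *rec.data])


def read_emg(path: Path) -> EmgRecording:
    rate, header, data = _read_signal(path)
    return EmgRecording(sampling_rate=rate, channel_names=tuple(header[1:]),
                        data=data[:, 1:].T, t0=float(data[0, 0]))


def write_nirs(trace: NirsTrace, path: Path) -> None:
    _write_signal(path, trace.sampling_rate, ["time_s", "hbo2_um", "hhb_um"],
                  [trace.times, trace.hbo2, trace.hhb])


def read_nirs(path: Path, site: str, baseline_window=(-30.0, 0.0),
              dpf: float = 3.83) -> NirsTrace:
    rate, _, data = _read_signal(path)
    return NirsTrace(sampling_rate=rate, site=site, hbo2=data[:, 1],
                     hhb=data[:, 2], t0=float(data[0, 0]),
                     baseline_window=baseline_window, dpf=dpf)


def write_breath(trace: BreathTrace, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_s\tvo2_mlminkg\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.values]),
                   fmt="%.4f", delimiter="\t")


def read_breath(path: Path) -> BreathTrace:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return BreathTrace(times=data[:, 0], values=data[:, 1])
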