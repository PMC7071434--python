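"""Reading and writing recordings, combinations, and study configuration.

Simulated recordings interchange as columnar CSV: one column per channel
(chest electrodes ``ch01``..``ch35``, limb electrodes ``LA``/``RA``/``LL``,
precordial electrodes ``V1``..``V6``), values in uV, with recording metadata
(sampling rate, subject, session) in ``#``-prefixed header comments. Real
multichannel recordings can be imported from EDF via :mod:`mne` (optional
dependency). Study configuration round-trips through YAML with every seed
explicit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    LIMB_NAMES,
    PRECORDIAL_NAMES,
    CohortConfig,
    MultichannelRecording,
)

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_edf",
    "save_config",
    "load_config",
]


def _chest_columns() -> list[str]:
    return [f"ch{i:02d}" for i in range(1, 36)]


def write_recording_csv(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording to columnar CSV with metadata header comments."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for i, name in enumerate(_chest_columns()):
        cols[name] = rec.chest[i]
    for name in LIMB_NAMES:
        cols[name] = rec.limb_electrodes[name]
    for name in PRECORDIAL_NAMES:
        cols[name] = rec.precordial_electrodes[name]
    frame = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# session_id={rec.session_id}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")
    return path


def _parse_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_recording_csv(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording_csv`."""
    path = Path(path)
    meta = _parse_header(path)
    frame = pd.read_csv(path, comment="#")
    missing = [
        c
        for c in _chest_columns() + list(LIMB_NAMES) + list(PRECORDIAL_NAMES)
        if c not in frame.columns
    ]
    if missing:
        raise ValueError(f"recording CSV misses channels: {missing}")
    chest = np.stack([frame[c].to_numpy(float) for c in _chest_columns()])
    return MultichannelRecording(
        fs=float(meta.get("fs", "nan")),
        chest=chest,
        limb_electrodes={n: frame[n].to_numpy(float) for n in LIMB_NAMES},
        precordial_electrodes={n: frame[n].to_numpy(float) for n in PRECORDIAL_NAMES},
        subject_id=meta.get("subject_id", ""),
        session_id=int(meta.get("session_id", "0")),
    )


def read_recording_edf(
    path: str | Path,
    channel_map: Mapping[str, str],
    subject_id: str = "",
    session_id: int = 0,
) -> MultichannelRecording:
    """Import a real multichannel recording from EDF.

    ``channel_map`` maps this package's channel names (``"1"``..``"35"``,
    ``"LA"``, ``"RA"``, ``"LL"``, ``"V1"``..``"V6"``) to EDF channel labels.
    Requires :mod:`mne` (install the ``edf`` extra). Signals are converted
    from volts to uV.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra"
        ) from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    index = {name: i for i, name in enumerate(raw.ch_names)}

    def grab(our_name: str) -> np.ndarray:
        label = channel_map[our_name]
        if label not in index:
            raise ValueError(f"EDF channel {label!r} (for {our_name}) not found")
        return data[index[label]]

    chest = np.stack([grab(str(i)) for i in range(1, 36)])
    return MultichannelRecording(
        fs=float(raw.info["sfreq"]),
        chest=chest,
        limb_electrodes={n: grab(n) for n in LIMB_NAMES},
        precordial_electrodes={n: grab(n) for n in PRECORDIAL_NAMES},
        subject_id=subject_id,
        session_id=session_id,
    )


def save_config(config, path: str | Path) -> Path:
    """Serialize a StudyConfig (or any nested dataclass) to YAML."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def load_config(path: str | Path):
    """Load a StudyConfig from YAML written by :func:`save_config`."""
    from .study import StudyConfig  # local import avoids a cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohort = raw.pop("cohort", {})
    for key in ("heart_origin_jitter",):
        if key in cohort and cohort[key] is not None:
            cohort[key] = tuple(cohort[key])
    for key in ("families", "models", "ensemble_seeds"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return StudyConfig(cohort=CohortConfig(**cohort), **raw)
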