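"""Filtering, lead algebra, segmentation, and cross-subject merging.

Lead algebra follows the clinical definitions. With limb electrode
potentials LA, RA, LL:

    I = LA - RA,  II = LL - RA,  III = LL - LA
    WCT = (LA + RA + LL) / 3
    aVR = -(I + II) / 2,  aVL = (I - III) / 2,  aVF = (II + III) / 2
    Vi  = precordial_i - WCT

so that I - II + III = 0 (Einthoven) and aVR + aVL + aVF = 0 (Goldberger)
hold identically. Filtering is a zero-phase (forward-backward) second-order
Butterworth band-pass, 0.5–35 Hz by default.

For the universal-coefficient study, one randomly placed 20 s segment is
taken from each subject's recording and the segments are concatenated into a
single pooled signal (14 subjects -> 280 s); session 1 provides the training
merge, session 2 the test merge. Segment starts are kept >= 2 s away from
the recording edges so filter transients never enter metric windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import MultichannelRecording

__all__ = [
    "LEAD_NAMES",
    "LeadSet12",
    "WCTReference",
    "SegmentInfo",
    "MergedRecording",
    "bandpass",
    "bandpass_recording",
    "two_pass_gain",
    "compute_wct",
    "derive_12lead",
    "extract_and_merge",
    "ChannelStandardizer",
    "standardize",
]

LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


@dataclass
class WCTReference:
    """Wilson's central terminal: mean of the three limb electrode potentials."""

    wct: np.ndarray


@dataclass
class LeadSet12:
    """The 12 standard leads, equal-length signals in uV."""

    leads: dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        missing = set(LEAD_NAMES) - set(self.leads)
        if missing:
            raise ValueError(f"missing leads: {sorted(missing)}")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise ValueError("all leads must have equal length")

    def matrix(self) -> np.ndarray:
        """(12, T) array in canonical lead order."""
        return np.stack([self.leads[name] for name in LEAD_NAMES])


def bandpass(
    x: np.ndarray,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 35.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is applied forward then backward (``sosfiltfilt``), which
    cancels phase distortion and squares the single-pass magnitude response.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < fs/2 = {fs / 2}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def two_pass_gain(
    freq_hz: float | np.ndarray,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 35.0,
    order: int = 2,
) -> np.ndarray:
    """|H(f)|^2: the magnitude response of the forward-backward filter."""
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(freq_hz) / fs)
    return np.abs(h) ** 2


def bandpass_recording(
    rec: MultichannelRecording,
    low_hz: float = 0.5,
    high_hz: float = 35.0,
    order: int = 2,
) -> MultichannelRecording:
    """Apply the band-pass to every channel of a recording."""
    return rec.map_channels(lambda x: bandpass(x, rec.fs, low_hz, high_hz, order))


def compute_wct(limb_electrodes: Mapping[str, np.ndarray]) -> WCTReference:
    """WCT = (LA + RA + LL) / 3."""
    try:
        la, ra, ll = (
            np.asarray(limb_electrodes[k], dtype=float) for k in ("LA", "RA", "LL")
        )
    except KeyError as e:
        raise ValueError(f"missing limb electrode channel {e.args[0]!r}") from e
    if not (len(la) == len(ra) == len(ll)):
        raise ValueError("limb electrode channels must have equal length")
    return WCTReference(wct=(la + ra + ll) / 3.0)


def derive_12lead(rec: MultichannelRecording) -> LeadSet12:
    """Derive the 12 standard leads from limb and precordial electrodes."""
    limb = rec.limb_electrodes
    try:
        la, ra, ll = (np.asarray(limb[k], dtype=float) for k in ("LA", "RA", "LL"))
    except KeyError as e:
        raise ValueError(f"missing limb electrode channel {e.args[0]!r}") from e
    lead_i = la - ra
    lead_ii = ll - ra
    lead_iii = ll - la
    wct = compute_wct(limb).wct
    leads = {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_iii,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": (lead_i - lead_iii) / 2.0,
        "aVF": (lead_ii + lead_iii) / 2.0,
    }
    for name in ("V1", "V2", "V3", "V4", "V5", "V6"):
        if name not in rec.precordial_electrodes:
            raise ValueError(f"missing precordial electrode channel {name!r}")
        leads[name] = np.asarray(rec.precordial_electrodes[name], dtype=float) - wct
    return LeadSet12(leads=leads, fs=rec.fs)


@dataclass(frozen=True)
class SegmentInfo:
    """Provenance of one extracted segment within a merged signal."""

    subject_id: str
    session_id: int
    source_start_s: float
    start_idx: int  # within the merged signal
    stop_idx: int


@dataclass
class MergedRecording(MultichannelRecording):
    """Concatenation of per-subject segments, with segment boundaries."""

    segments: list[SegmentInfo] = field(default_factory=list)


def extract_and_merge(
    recordings: Sequence[MultichannelRecording],
    seed: int,
    length_s: float = 20.0,
    edge_guard_s: float = 2.0,
) -> MergedRecording:
    """Extract one random segment per recording and concatenate in order.

    The start point is drawn uniformly in
    ``[edge_guard_s, duration - length_s - edge_guard_s]`` so segments stay
    clear of filter edge transients. Deterministic for a fixed seed.
    """
    if not recordings:
        raise ValueError("need at least one recording to merge")
    if length_s <= 0:
        raise ValueError("segment length must be positive")
    fs = recordings[0].fs
    rng = np.random.default_rng(seed)
    n_seg = int(round(length_s * fs))
    pieces: list[MultichannelRecording] = []
    segments: list[SegmentInfo] = []
    cursor = 0
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("all recordings must share a sampling rate")
        latest = rec.duration_s - length_s - edge_guard_s
        if latest < edge_guard_s:
            raise ValueError(
                f"recording {rec.subject_id}/{rec.session_id} is shorter than "
                f"segment length {length_s}s plus {edge_guard_s}s guards"
            )
        start_s = float(rng.uniform(edge_guard_s, latest))
        i0 = int(round(start_s * fs))
        sl = slice(i0, i0 + n_seg)
        pieces.append(rec.map_channels(lambda x, sl=sl: x[..., sl]))
        segments.append(
            SegmentInfo(
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                source_start_s=start_s,
                start_idx=cursor,
                stop_idx=cursor + n_seg,
            )
        )
        cursor += n_seg
    merged = MergedRecording(
        fs=fs,
        chest=np.concatenate([p.chest for p in pieces], axis=-1),
        limb_electrodes={
            k: np.concatenate([p.limb_electrodes[k] for p in pieces])
            for k in recordings[0].limb_electrodes
        },
        precordial_electrodes={
            k: np.concatenate([p.precordial_electrodes[k] for p in pieces])
            for k in recordings[0].precordial_electrodes
        },
        subject_id="merged",
        session_id=recordings[0].session_id,
        segments=segments,
    )
    return merged


class ChannelStandardizer(BaseEstimator, TransformerMixin):
    """Zero-mean / unit-SD per-channel scaling with exact inversion.

    Follows the scikit-learn transformer contract on (n_samples, n_channels)
    arrays. Constant channels are rejected: they carry no signal and make the
    scaling non-invertible.
    """

    def fit(self, X: np.ndarray, y=None) -> "ChannelStandardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("expected a 2-D (n_samples >= 2, n_channels) array")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        if np.any(self.scale_ <= 0):
            bad = np.flatnonzero(self.scale_ <= 0).tolist()
            raise ValueError(f"constant channel(s) at index {bad}: cannot standardize")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def standardize(channels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize channel-major (n_channels, T) signals.

    Returns ``(standardized, mean, sd)``; ``standardized * sd[:, None] +
    mean[:, None]`` reproduces the input exactly.
    """
    scaler = ChannelStandardizer().fit(np.asarray(channels, dtype=float).T)
    return scaler.transform(channels.T).T, scaler.mean_, scaler.scale_
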