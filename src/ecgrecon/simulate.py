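"""Synthetic chest-grid ECG cohorts from a dipole volume-conductor model.

Cardiac electrical activity is approximated by one or more current dipoles
inside an infinite homogeneous volume conductor. The surface potential at an
electrode located at ``r`` due to a dipole with moment ``p`` at ``r0`` is

    phi(r) = p . (r - r0) / (4 pi sigma |r - r0|^3)

which is linear in the instantaneous moment — the structural property that
makes a 12-lead ECG reconstructible from three bipolar chest leads. Each
dipole's moment traces a periodic cardiac cycle built from sums of Gaussians
per axis (P, QRS, and T deflections), in the spirit of dynamical synthetic-ECG
generators.

Geometry lives in cm with the 35-electrode grid on the z = 0 chest plane;
dipoles sit at negative z inside the torso. Potentials are returned in uV.
Dipole moments are expressed in mA*cm (1 mA*cm = 1e-5 A*m).

Two source modes are provided:

* ``single`` — one fixed dipole and no noise sources enabled by default.
  Every electrode potential is then an exact linear combination of the three
  moment components, so chest recordings have channel-space rank 3 and a
  pooled linear reconstruction is exact. This is the physics oracle.
* ``multi`` — three dipoles (ventricular, atrial, and a posterior-septal
  secondary) with inter-subject heart position/orientation jitter,
  beat-to-beat amplitude jitter, and additive white / baseline-wander /
  powerline noise, so reconstruction from 3 leads is non-trivially imperfect
  as it is for real torsos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .grid import GridLayout

__all__ = [
    "GaussianWave",
    "DipoleSource",
    "TorsoModel",
    "SubjectParams",
    "MultichannelRecording",
    "CohortConfig",
    "make_beat_template",
    "default_sources",
    "default_torso",
    "surface_potential",
    "lead_field",
    "simulate_subject",
    "simulate_cohort",
    "physics_oracle_config",
]

LIMB_NAMES = ("LA", "RA", "LL")
PRECORDIAL_NAMES = ("V1", "V2", "V3", "V4", "V5", "V6")

# Conversion: p [mA*cm], distances [cm], sigma [S/m]  ->  phi [uV].
# p_SI = 1e-5 p, d_SI = 1e-2 d  =>  phi_V = 0.1 * p.d / (4 pi sigma |d|^3),
# and 1 V = 1e6 uV.
_UV_FACTOR = 1e5


@dataclass(frozen=True)
class GaussianWave:
    """One Gaussian deflection of the cardiac cycle, in beat-phase units."""

    amplitude: float  # mA*cm
    center: float  # fraction of the beat in [0, 1)
    width: float  # SD, fraction of the beat

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("Gaussian width must be positive")


# Default beat morphology: P / QRS (Q, R, S) / T per dipole axis, scaled so
# that the R peak projects to roughly 1 mV on the nearest grid electrodes.
# x = subject's left, y = cranial, z = anterior (out of the chest).
DEFAULT_MORPHOLOGY: dict[str, tuple[GaussianWave, ...]] = {
    "x": (
        GaussianWave(0.50, 0.180, 0.025),
        GaussianWave(-0.45, 0.355, 0.008),
        GaussianWave(5.00, 0.375, 0.011),
        GaussianWave(-0.65, 0.396, 0.009),
        GaussianWave(1.60, 0.630, 0.055),
    ),
    "y": (
        GaussianWave(0.30, 0.190, 0.027),
        GaussianWave(2.70, 0.380, 0.013),
        GaussianWave(-1.20, 0.400, 0.010),
        GaussianWave(0.90, 0.640, 0.060),
    ),
    "z": (
        GaussianWave(0.20, 0.175, 0.025),
        GaussianWave(0.55, 0.360, 0.009),
        GaussianWave(-1.80, 0.378, 0.012),
        GaussianWave(0.60, 0.615, 0.050),
    ),
}

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class DipoleSource:
    """A periodic current-dipole source.

    ``morphology`` maps each axis to Gaussian deflections in beat phase; the
    moment at time ``t`` is the per-axis Gaussian sum evaluated at
    ``phase = (t * heart_rate / 60) mod 1``, rotated by ``orientation`` and
    scaled by ``amplitude_scale``.
    """

    morphology: Mapping[str, tuple[GaussianWave, ...]]
    heart_rate: float = 72.9  # beats/min
    origin: tuple[float, float, float] = (16.3, -11.7, -8.5)  # cm
    orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )  # 3x3 rotation
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.all(np.isfinite(R)):
            raise ValueError("orientation must be a finite 3x3 matrix")
        object.__setattr__(self, "orientation", R)
        object.__setattr__(
            self, "origin", tuple(float(v) for v in self.origin)
        )
        morph = {a: tuple(self.morphology.get(a, ())) for a in _AXES}
        object.__setattr__(self, "morphology", morph)

    def phase_moment(self, phase: np.ndarray) -> np.ndarray:
        """Unrotated moment (3, len(phase)) at the given beat phases."""
        phase = np.asarray(phase, dtype=float) % 1.0
        out = np.zeros((3, phase.size))
        for i, axis in enumerate(_AXES):
            for w in self.morphology[axis]:
                # wrap-around neighbours keep the trajectory periodic/smooth
                for shift in (-1.0, 0.0, 1.0):
                    d = phase - (w.center + shift)
                    out[i] += w.amplitude * np.exp(-0.5 * (d / w.width) ** 2)
        return out

    def moment(self, t: np.ndarray) -> np.ndarray:
        """Dipole moment (3, len(t)) in mA*cm at times ``t`` (s)."""
        phase = np.atleast_1d(np.asarray(t, dtype=float)) * self.heart_rate / 60.0
        return self.amplitude_scale * (self.orientation @ self.phase_moment(phase))


def make_beat_template(
    morphology_params: Mapping[str, Sequence[tuple[float, float, float]]]
    | Mapping[str, Sequence[GaussianWave]]
    | None = None,
    heart_rate: float = 72.9,
    origin: Sequence[float] = (16.3, -11.7, -8.5),
    amplitude_scale: float = 1.0,
) -> DipoleSource:
    """Build a dipole source from per-axis (amplitude, center, width) waves."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if morphology_params is None:
        morph = DEFAULT_MORPHOLOGY
    else:
        morph = {}
        for axis, waves in morphology_params.items():
            if axis not in _AXES:
                raise ValueError(f"unknown dipole axis {axis!r}")
            morph[axis] = tuple(
                w if isinstance(w, GaussianWave) else GaussianWave(*w)
                for w in waves
            )
    return DipoleSource(
        morphology=morph,
        heart_rate=heart_rate,
        origin=tuple(origin),
        amplitude_scale=amplitude_scale,
    )


def default_sources(mode: str = "multi") -> list[DipoleSource]:
    """Population-level source template for the cohort generator."""
    primary = make_beat_template()
    if mode == "single":
        return [primary]
    if mode != "multi":
        raise ValueError("source mode must be 'single' or 'multi'")
    # Atrial source: small, anterior-superior, active around the P/QRS window.
    atrial = make_beat_template(
        {
            "x": [(0.9, 0.16, 0.030), (0.35, 0.40, 0.015)],
            "y": [(0.6, 0.20, 0.028), (-0.30, 0.37, 0.012)],
            "z": [(0.4, 0.17, 0.026), (0.20, 0.42, 0.018)],
        },
        origin=(14.0, -6.0, -7.0),
    )
    # Posterior-septal secondary: shifted repolarization emphasis.
    septal = make_beat_template(
        {
            "x": [(0.5, 0.385, 0.010), (-0.45, 0.66, 0.055)],
            "y": [(-0.6, 0.392, 0.011), (0.50, 0.60, 0.050)],
            "z": [(0.7, 0.370, 0.012), (0.30, 0.68, 0.060)],
        },
        origin=(19.5, -15.0, -10.0),
    )
    return [primary, atrial, septal]


def _default_electrode_positions(grid: GridLayout) -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for eid in grid.ids():
        x, y = grid.xy_cm(eid)
        pos[str(eid)] = np.array([x, y, 0.0])
    # Limb electrodes far from the grid approximate limb-lead geometry.
    pos["LA"] = np.array([45.0, 5.0, 0.0])
    pos["RA"] = np.array([-15.0, 5.0, 0.0])
    pos["LL"] = np.array([25.0, -95.0, 0.0])
    # Precordial electrode positions on the chest plane (V1..V6 sweep).
    precordial = {
        "V1": (13.0, -9.0),
        "V2": (17.0, -9.0),
        "V3": (19.5, -11.5),
        "V4": (22.0, -14.0),
        "V5": (26.0, -14.0),
        "V6": (30.0, -14.0),
    }
    for name, (x, y) in precordial.items():
        pos[name] = np.array([x, y, 0.0])
    return pos


@dataclass(frozen=True)
class TorsoModel:
    """Homogeneous volume conductor with named electrode positions (cm)."""

    conductivity: float = 0.2  # S/m
    electrode_positions: Mapping[str, np.ndarray] = field(default_factory=dict)
    min_clearance_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        pos = {k: np.asarray(v, dtype=float) for k, v in self.electrode_positions.items()}
        keys = list(pos)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if np.allclose(pos[a], pos[b]):
                    raise ValueError(f"electrodes {a} and {b} share a position")
        object.__setattr__(self, "electrode_positions", pos)

    def position(self, electrode: str | int) -> np.ndarray:
        return self.electrode_positions[str(electrode)]

    def check_clearance(self, origin: Sequence[float]) -> None:
        o = np.asarray(origin, dtype=float)
        for name, r in self.electrode_positions.items():
            if np.linalg.norm(r - o) < self.min_clearance_cm:
                raise ValueError(
                    f"electrode {name} is within {self.min_clearance_cm} cm "
                    "of the dipole origin"
                )


def default_torso(grid: GridLayout | None = None) -> TorsoModel:
    grid = grid or GridLayout()
    return TorsoModel(electrode_positions=_default_electrode_positions(grid))


def _gain_vector(torso: TorsoModel, r: np.ndarray, origin: np.ndarray) -> np.ndarray:
    d = r - origin
    dist = np.linalg.norm(d)
    if dist < 1e-9:
        raise ValueError("electrode coincides with the dipole origin")
    return _UV_FACTOR * d / (4.0 * math.pi * torso.conductivity * dist**3)


def lead_field(
    torso: TorsoModel, origin: Sequence[float], electrodes: Sequence[str | int]
) -> np.ndarray:
    """Gain matrix G (n_electrodes, 3): phi_uV = G @ p_mAcm for a dipole at origin."""
    o = np.asarray(origin, dtype=float)
    return np.stack([_gain_vector(torso, torso.position(e), o) for e in electrodes])


def surface_potential(
    source: DipoleSource,
    torso: TorsoModel,
    electrode_id: str | int,
    t: float | np.ndarray,
) -> np.ndarray | float:
    """Potential (uV) at one electrode; linear in the instantaneous moment."""
    g = _gain_vector(
        torso, torso.position(electrode_id), np.asarray(source.origin, dtype=float)
    )
    phi = g @ source.moment(t)
    return float(phi[0]) if np.isscalar(t) else phi


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters (seed fully determines realization)."""

    seed: int
    heart_origin_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)  # SD, cm
    orientation_jitter_deg: float = 0.0  # SD of each Euler angle
    beat_amplitude_scale: float = 1.0
    heart_rate: float = 72.9  # beats/min
    beat_jitter_sd: float = 0.0  # beat-to-beat amplitude SD (fraction)
    noise_white_sd: float = 0.0  # uV
    baseline_amp: float = 0.0  # uV
    baseline_freq: float = 0.25  # Hz
    powerline_amp: float = 0.0  # uV
    powerline_freq: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.heart_origin_jitter):
            raise ValueError("origin jitter SDs must be >= 0")
        for name in (
            "orientation_jitter_deg",
            "beat_jitter_sd",
            "noise_white_sd",
            "baseline_amp",
            "powerline_amp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.heart_rate <= 0 or self.beat_amplitude_scale <= 0:
            raise ValueError("heart rate and amplitude scale must be positive")


@dataclass
class MultichannelRecording:
    """Time-aligned chest-grid, limb, and precordial electrode signals (uV)."""

    fs: float
    chest: np.ndarray  # (35, T)
    limb_electrodes: dict[str, np.ndarray]  # LA, RA, LL -> (T,)
    precordial_electrodes: dict[str, np.ndarray]  # V1..V6 -> (T,)
    subject_id: str = ""
    session_id: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        T = self.chest.shape[1]
        for d in (self.limb_electrodes, self.precordial_electrodes):
            for name, sig in d.items():
                if len(sig) != T:
                    raise ValueError(f"channel {name} length differs from chest")

    @property
    def n_samples(self) -> int:
        return int(self.chest.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def map_channels(self, fn) -> "MultichannelRecording":
        """Apply ``fn`` (array -> array, last axis = time) to every channel."""
        return MultichannelRecording(
            fs=self.fs,
            chest=fn(self.chest),
            limb_electrodes={k: fn(v) for k, v in self.limb_electrodes.items()},
            precordial_electrodes={
                k: fn(v) for k, v in self.precordial_electrodes.items()
            },
            subject_id=self.subject_id,
            session_id=self.session_id,
        )


def _subject_anatomy(
    params: SubjectParams, sources: Sequence[DipoleSource]
) -> list[DipoleSource]:
    """Realize per-subject heart geometry: one shared shift + rotation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 7]))
    shift = rng.normal(0.0, 1.0, size=3) * np.asarray(params.heart_origin_jitter)
    angles = rng.normal(0.0, params.orientation_jitter_deg, size=3)
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    out = []
    for src in sources:
        out.append(
            replace(
                src,
                origin=tuple(np.asarray(src.origin) + shift),
                orientation=R @ src.orientation,
                heart_rate=params.heart_rate,
                amplitude_scale=src.amplitude_scale * params.beat_amplitude_scale,
            )
        )
    return out


def simulate_subject(
    params: SubjectParams,
    torso: TorsoModel,
    duration_s: float = 120.0,
    fs: float = 250.0,
    sources: Sequence[DipoleSource] | None = None,
    subject_id: str = "S01",
    session_id: int = 1,
) -> MultichannelRecording:
    """Simulate one recording session for one subject.

    Anatomy (heart shift/rotation, amplitude scale, heart rate) is drawn from
    ``params.seed`` and shared across sessions; beat-to-beat jitter and noise
    use an independent stream keyed by (seed, session).
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    sources = list(sources) if sources is not None else default_sources("multi")
    realized = _subject_anatomy(params, sources)
    for src in realized:
        torso.check_clearance(src.origin)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    electrodes: list[str] = (
        [str(i) for i in range(1, 36)] + list(LIMB_NAMES) + list(PRECORDIAL_NAMES)
    )

    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 11, int(session_id)])
    )
    # Beat-to-beat amplitude jitter: one multiplicative factor per beat,
    # common to all sources (a global contractility fluctuation).
    beat_idx = np.floor(t * params.heart_rate / 60.0).astype(int)
    n_beats = int(beat_idx.max()) + 1
    factors = 1.0 + params.beat_jitter_sd * rng.standard_normal(n_beats)
    beat_gain = factors[beat_idx]

    signals = np.zeros((len(electrodes), n))
    for src in realized:
        G = lead_field(torso, src.origin, electrodes)  # (n_el, 3)
        m = src.moment(t) * beat_gain  # (3, n)
        signals += G @ m

    if params.noise_white_sd > 0:
        signals += params.noise_white_sd * rng.standard_normal(signals.shape)
    if params.baseline_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(electrodes))
        signals += params.baseline_amp * np.sin(
            2 * np.pi * params.baseline_freq * t[None, :] + phases[:, None]
        )
    if params.powerline_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(electrodes))
        signals += params.powerline_amp * np.sin(
            2 * np.pi * params.powerline_freq * t[None, :] + phases[:, None]
        )

    chest = signals[:35]
    limb = {name: signals[35 + i] for i, name in enumerate(LIMB_NAMES)}
    prec = {name: signals[38 + i] for i, name in enumerate(PRECORDIAL_NAMES)}
    return MultichannelRecording(
        fs=fs,
        chest=chest,
        limb_electrodes=limb,
        precordial_electrodes=prec,
        subject_id=subject_id,
        session_id=session_id,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generative conditions.

    Defaults emulate the measurement design this pipeline analyses: 14
    subjects, 2 sessions of 2 min at 250 Hz, with inter-subject heart
    geometry variation and realistic noise. Heart rate is drawn from the
    cohort statistics 72.9 +/- 8.2 beats/min.
    """

    n_subjects: int = 14
    n_sessions: int = 2
    duration_s: float = 120.0
    fs: float = 250.0
    master_seed: int = 20200963
    source_mode: str = "multi"  # 'single' | 'multi'
    heart_origin_jitter: tuple[float, float, float] = (0.8, 0.8, 0.5)
    orientation_jitter_deg: float = 8.0
    amplitude_scale_sd: float = 0.15  # lognormal sigma
    heart_rate_mean: float = 72.9
    heart_rate_sd: float = 8.2
    beat_jitter_sd: float = 0.05
    noise_white_sd: float = 8.0
    baseline_amp: float = 80.0
    baseline_freq: float = 0.25
    powerline_amp: float = 15.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if self.source_mode not in ("single", "multi"):
            raise ValueError("source mode must be 'single' or 'multi'")


def physics_oracle_config(master_seed: int = 20200963) -> CohortConfig:
    """Noiseless single-dipole cohort: the linear-physics exactness regime.

    Subjects still differ in heart orientation, amplitude and rate — a shared
    rotation commutes with the electrode-to-lead map, so a pooled linear
    reconstruction remains exact. Heart position jitter and all noise are off.
    """
    return CohortConfig(
        master_seed=master_seed,
        source_mode="single",
        heart_origin_jitter=(0.0, 0.0, 0.0),
        orientation_jitter_deg=8.0,
        amplitude_scale_sd=0.15,
        beat_jitter_sd=0.03,
        noise_white_sd=0.0,
        baseline_amp=0.0,
        powerline_amp=0.0,
    )


def subject_params_from_config(
    config: CohortConfig, subject_index: int
) -> SubjectParams:
    """Deterministic per-subject parameters from the cohort master seed."""
    ss = np.random.SeedSequence([int(config.master_seed), int(subject_index)])
    rng = np.random.default_rng(ss)
    hr = float(
        np.clip(
            rng.normal(config.heart_rate_mean, config.heart_rate_sd), 45.0, 120.0
        )
    )
    scale = float(np.exp(rng.normal(0.0, config.amplitude_scale_sd)))
    seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
    return SubjectParams(
        seed=seed,
        heart_origin_jitter=config.heart_origin_jitter,
        orientation_jitter_deg=config.orientation_jitter_deg,
        beat_amplitude_scale=scale,
        heart_rate=hr,
        beat_jitter_sd=config.beat_jitter_sd,
        noise_white_sd=config.noise_white_sd,
        baseline_amp=config.baseline_amp,
        baseline_freq=config.baseline_freq,
        powerline_amp=config.powerline_amp,
    )


def simulate_cohort(
    config: CohortConfig | None = None,
    torso: TorsoModel | None = None,
    sources: Sequence[DipoleSource] | None = None,
) -> list[MultichannelRecording]:
    """Simulate the full cohort: n_subjects x n_sessions recordings.

    Recordings are ordered subject-major (S01 session 1, S01 session 2, ...).
    Identical config -> bitwise-identical cohort.
    """
    config = config or CohortConfig()
    torso = torso or default_torso()
    sources = (
        list(sources) if sources is not None else default_sources(config.source_mode)
    )
    out = []
    for i in range(config.n_subjects):
        params = subject_params_from_config(config, i)
        for s in range(1, config.n_sessions + 1):
            out.append(
                simulate_subject(
                    params,
                    torso,
                    duration_s=config.duration_s,
                    fs=config.fs,
                    sources=sources,
                    subject_id=f"S{i + 1:02d}",
                    session_id=s,
                )
            )
    return out
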