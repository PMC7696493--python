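"""Synthetic cycling-kinematics generator with ground-truth phase labels.

One crank revolution of the prosthetic-side leg is divided into four phases
by the crank angle :math:`\\varphi_c` (the angle between the pedal crank and
the horizontal plane):

====================  ==================  =====
phase                 crank interval      label
====================  ==================  =====
pedaling              (-45°, 45°]           1
upper buffer          (45°, 135°]           4
relaxation            (135°, 225°]          3
lower buffer          (225°, 315°]          2
====================  ==================  =====

The lower-buffer quadrant is the one left unassigned by the published
interval scheme; the four bands tile the circle.  During riding the phases
are traversed in the order pedaling -> lower buffer -> relaxation -> upper
buffer, which with the intervals above means the crank angle *decreases*
with time; :class:`SimConfig.direction` defaults to ``-1`` accordingly.

The knee-joint angle is a smooth periodic curve pinned to one anchor value
at each phase onset (static-experiment ranges: pedaling 84-87°, lower
buffer 106-108°, relaxation 95-98°, upper buffer 73-76°; midpoints by
default).  The joint accelerations are modelled as the first two harmonics
of the crank frequency -- the ankle rides the circular pedal path, so its
acceleration is a pure first harmonic; the knee, closer to the hip, gets a
smaller amplitude plus a second-harmonic component.  Frame/stump vibration
is emulated by Gaussian white noise band-passed to 5-20 Hz and scaled to a
requested per-channel SNR.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "PHASE_NAMES",
    "PHASE_ONSET_CRANK",
    "SimConfig",
    "CyclingRecording",
    "crank_trajectory",
    "label_from_crank",
    "knee_angle_waveform",
    "generate_recording",
]

#: label -> human-readable phase name
PHASE_NAMES = {1: "pedaling", 2: "lower buffer", 3: "relaxation", 4: "upper buffer"}

#: crank angle (degrees) at which each phase begins, traversing the cycle
#: in riding order (crank angle decreasing)
PHASE_ONSET_CRANK = {1: 45.0, 2: 315.0, 3: 225.0, 4: 135.0}

# band-limited vibration noise (Hz)
NOISE_BAND_HZ = (5.0, 20.0)

#: CSV column order used by every module in the package
CSV_COLUMNS = ["t", "crank", "kx", "ky", "hx", "hy", "a", "label"]


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic riding session.

    Attributes
    ----------
    cadence_rpm:
        Crank revolutions per minute (> 0).
    sample_rate_hz:
        Sampling frequency of every channel (> 0).
    n_cycles:
        Number of full crank revolutions to generate (>= 1).
    knee_angle_anchors:
        Knee angle (degrees) at the onset of (pedaling, lower buffer,
        relaxation, upper buffer).  The lower-buffer anchor is the cycle
        maximum, the upper-buffer anchor the minimum.
    accel_amplitude:
        Peak ankle acceleration in m/s^2; the knee channels use half of it.
    vibration_snr_db:
        Per-channel SNR of the added band-limited noise; ``inf`` disables
        the noise entirely.
    seed:
        RNG seed; fixed seed gives bit-identical output.
    phi0:
        Crank angle at t = 0 (degrees).  The default 45° starts the
        recording exactly at pedaling onset.
    direction:
        +1 for increasing crank angle, -1 (default) for the riding
        direction in which the phases appear in order 1, 2, 3, 4.
    """

    cadence_rpm: float = 60.0
    sample_rate_hz: float = 100.0
    n_cycles: int = 50
    knee_angle_anchors: tuple[float, float, float, float] = (85.5, 107.0, 96.5, 74.5)
    accel_amplitude: float = 5.0
    vibration_snr_db: float = 10.0
    seed: int = 0
    phi0: float = 45.0
    direction: int = -1

    def __post_init__(self) -> None:
        if not self.cadence_rpm > 0:
            raise ConfigurationError(f"cadence_rpm must be > 0, got {self.cadence_rpm}")
        if not self.sample_rate_hz > 0:
            raise ConfigurationError(
                f"sample_rate_hz must be > 0, got {self.sample_rate_hz}"
            )
        if int(self.n_cycles) < 1:
            raise ConfigurationError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if len(self.knee_angle_anchors) != 4:
            raise ConfigurationError("knee_angle_anchors needs exactly four angles")
        if self.direction not in (-1, 1):
            raise ConfigurationError(f"direction must be +1 or -1, got {self.direction}")
        _validate_anchors(self.knee_angle_anchors)

    @property
    def period_s(self) -> float:
        """Duration of one crank revolution in seconds."""
        return 60.0 / self.cadence_rpm

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.period_s * self.sample_rate_hz))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def _validate_anchors(anchors: Sequence[float]) -> None:
    a_ped, a_lb, a_rel, a_ub = (float(v) for v in anchors)
    others = (a_ped, a_rel, a_ub)
    if a_lb < max(others):
        raise ConfigurationError(
            "lower-buffer anchor must be the cycle maximum knee angle"
        )
    if a_ub > min(a_ped, a_lb, a_rel):
        raise ConfigurationError(
            "upper-buffer anchor must be the cycle minimum knee angle"
        )


@dataclass
class CyclingRecording:
    """A labeled multichannel riding time series (the pipeline's I/O unit).

    Channels: ``t`` seconds, ``crank`` degrees in [0, 360), knee
    accelerations ``kx``/``ky`` and ankle accelerations ``hx``/``hy`` in
    m/s^2, knee angle ``a`` in degrees, and an optional integer phase
    ``label`` in {1, 2, 3, 4}.
    """

    t: np.ndarray
    crank: np.ndarray
    kx: np.ndarray
    ky: np.ndarray
    hx: np.ndarray
    hy: np.ndarray
    a: np.ndarray
    label: np.ndarray | None = None

    ACCEL_CHANNELS = ("kx", "ky", "hx", "hy")

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("crank", "kx", "ky", "hx", "hy", "a"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from t")
        if self.label is not None and len(self.label) != n:
            raise ValueError("label length differs from t")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def replace(self, **changes) -> "CyclingRecording":
        return dataclasses.replace(self, **changes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in CSV_COLUMNS[:-1]})
        if self.label is not None:
            df["label"] = self.label.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CyclingRecording":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValueError(f"recording CSV missing columns: {missing}")
        label = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
        return cls(
            t=df["t"].to_numpy(float),
            crank=df["crank"].to_numpy(float),
            kx=df["kx"].to_numpy(float),
            ky=df["ky"].to_numpy(float),
            hx=df["hx"].to_numpy(float),
            hy=df["hy"].to_numpy(float),
            a=df["a"].to_numpy(float),
            label=label,
        )


def crank_trajectory(config: SimConfig) -> np.ndarray:
    """Crank angle series (degrees in [0, 360)) under constant cadence.

    ``phi(t) = (phi0 + direction * 6 * cadence_rpm * t) mod 360`` --
    6 deg/s per rpm.  With the default ``direction=-1`` and ``phi0=45``
    the recording starts at pedaling onset and the phases follow riding
    order.
    """
    t = config.times()
    rate = 6.0 * config.cadence_rpm  # deg/s
    return np.mod(config.phi0 + config.direction * rate * t, 360.0)


def _reduce_crank(phi: np.ndarray) -> np.ndarray:
    """Reduce crank angles into (-45, 315] so the four bands are (lo, hi]."""
    r = np.mod(np.asarray(phi, dtype=float) + 45.0, 360.0) - 45.0  # [-45, 315)
    return np.where(r == -45.0, 315.0, r)


def label_from_crank(phi_c) -> np.ndarray | int:
    """Phase label for crank angle(s): the quadrant bands of the table above.

    Bands are half-open (lo, hi]; angles are reduced mod 360 into
    (-45°, 315°].  Scalar input gives a scalar label.
    """
    arr = np.asarray(phi_c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("crank angle must be finite")
    r = _reduce_crank(arr)
    quadrant = np.ceil((r + 45.0) / 90.0).astype(int)  # 1..4 from -45
    quadrant = np.clip(quadrant, 1, 4)
    labels = np.array([0, 1, 4, 3, 2])[quadrant]
    if np.ndim(phi_c) == 0:
        return int(labels)
    return labels


def _cycle_fraction(phi: np.ndarray) -> np.ndarray:
    """Fraction of the riding cycle elapsed since pedaling onset (phi=45°),
    measured in the riding direction (decreasing crank angle)."""
    return np.mod(45.0 - np.asarray(phi, dtype=float), 360.0) / 360.0


def knee_angle_waveform(phi_c, anchors: Sequence[float]) -> np.ndarray:
    """Smooth periodic knee-angle curve through the four phase-onset anchors.

    ``anchors`` are the knee angles at (pedaling, lower buffer, relaxation,
    upper buffer) onset.  A monotone piecewise-cubic (PCHIP) interpolant in
    the cycle-fraction coordinate guarantees exactly one local maximum (at
    lower-buffer onset) and one local minimum (at upper-buffer onset) per
    cycle, with each anchor attained exactly at its onset crank angle.
    """
    if len(anchors) != 4:
        raise ConfigurationError("exactly four anchors required")
    _validate_anchors(anchors)
    a_ped, a_lb, a_rel, a_ub = (float(v) for v in anchors)
    # knots at phase-onset fractions, repeated over three cycles so the
    # interpolant is periodic-smooth in the central one
    base_s = np.array([0.0, 0.25, 0.5, 0.75])
    base_v = np.array([a_ped, a_lb, a_rel, a_ub])
    s_knots = np.concatenate([base_s - 1.0, base_s, base_s + 1.0, [2.0]])
    v_knots = np.concatenate([base_v, base_v, base_v, [a_ped]])
    interp = PchipInterpolator(s_knots, v_knots)
    s = _cycle_fraction(phi_c)
    return interp(s)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-scale Gaussian noise band-passed to the vibration band."""
    white = rng.standard_normal(n)
    lo, hi = NOISE_BAND_HZ
    nyq = fs / 2.0
    hi = min(hi, 0.9 * nyq)
    if hi <= lo:  # sample rate too low to shape the band; keep it white
        return white
    sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    padlen = min(n - 1, 3 * (2 * len(sos) + 1))
    return sosfiltfilt(sos, white, padlen=padlen)


def generate_recording(config: SimConfig) -> CyclingRecording:
    """Generate a labeled synthetic riding recording.

    Clean accelerations are harmonic functions of the crank angle (ankle:
    first harmonic of the circular pedal path; knee: half amplitude, first
    plus a 30% second harmonic with a small phase lead so the five channels
    jointly disambiguate the phases).  Band-limited vibration noise is then
    scaled per channel to exactly ``vibration_snr_db`` (measured on RMS of
    noisy - clean) and added to the four acceleration channels only; the
    knee angle is left noise-free.
    """
    t = config.times()
    phi = crank_trajectory(config)
    theta = np.deg2rad(phi)
    amp = config.accel_amplitude

    hx = -amp * np.cos(theta)
    hy = -amp * np.sin(theta)
    kx = 0.5 * amp * (np.cos(theta + 0.35) + 0.3 * np.cos(2.0 * theta))
    ky = 0.5 * amp * (np.sin(theta + 0.35) + 0.3 * np.sin(2.0 * theta + 0.8))

    a = knee_angle_waveform(phi, config.knee_angle_anchors)
    labels = label_from_crank(phi)

    channels = {"kx": kx, "ky": ky, "hx": hx, "hy": hy}
    snr = config.vibration_snr_db
    if np.isfinite(snr):
        rng = np.random.default_rng(config.seed)
        factor = 10.0 ** (snr / 20.0)
        for name in ("kx", "ky", "hx", "hy"):  # fixed order: reproducibility
            clean = channels[name]
            noise = _band_limited_noise(rng, len(t), config.sample_rate_hz)
            rms_clean = math.sqrt(float(np.mean(clean**2)))
            rms_noise = math.sqrt(float(np.mean(noise**2)))
            if rms_noise > 0 and rms_clean > 0:
                noise = noise * (rms_clean / (rms_noise * factor))
            channels[name] = clean + noise

    return CyclingRecording(
        t=t, crank=phi, a=a, label=np.asarray(labels, dtype=int), **channels
    )
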