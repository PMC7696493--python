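"""Combined soft-hard threshold wavelet-packet denoising.

Frame and stump vibration contaminate the wearable acceleration channels.
Each channel is decomposed into a full wavelet-packet tree, every subband
except the lowest-frequency one is shrunk with the combined soft-hard rule

    G = sign(g) * (|g| - k*alpha)   if |g| > alpha
    G = 0                           if |g| <= alpha

and the signal is rebuilt by the inverse transform.  ``k = 0`` is the hard
threshold (supra-threshold coefficients kept), ``k = 1`` the soft threshold
(shrunk by the full alpha); the default ``k = 0.5`` mixes the two.  The
threshold is the universal (Donoho-Johnstone) value

    alpha = tau * sqrt(2 * ln D)

with D the signal length and tau a robust noise scale estimated from the
highest-frequency packet subband as median(|coeff|) / 0.6745.  The knee
angle channel comes from an interference-proof angle sensor and is never
denoised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .sim import CyclingRecording

__all__ = [
    "ShrinkageSpec",
    "SubbandSet",
    "estimate_tau",
    "universal_threshold",
    "shrink",
    "denoise_channel",
    "denoise_recording",
]

MAD_TO_SIGMA = 0.6745  # |N(0,1)| median


@dataclass(frozen=True)
class ShrinkageSpec:
    """Parameters of the wavelet-packet shrinkage.

    ``tau`` and ``alpha`` are normally left ``None`` and estimated per run;
    setting them overrides estimation (in signal units).  ``per_subband``
    switches from one global threshold (default) to a per-subband tau/alpha.
    """

    k: float = 0.5
    tau: float | None = None
    alpha: float | None = None
    wavelet: str = "db4"
    level: int = 3
    per_subband: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"mix factor k must be in [0, 1], got {self.k}")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.tau is not None and self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if int(self.level) < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")


@dataclass
class SubbandSet:
    """Wavelet-packet leaf coefficients of one signal.

    ``paths`` are the pywt node paths in frequency order (index 0 = lowest
    band); ``coeffs`` the matching coefficient arrays.  Reconstruction of
    unmodified subbands reproduces the input within numerical tolerance.
    """

    paths: list[str]
    coeffs: list[np.ndarray]
    wavelet: str
    level: int
    length: int
    mode: str = "symmetric"
    shrunk: list[np.ndarray] | None = field(default=None)

    def reconstruct(self, use_shrunk: bool = True) -> np.ndarray:
        coeffs = self.shrunk if (use_shrunk and self.shrunk is not None) else self.coeffs
        wp = pywt.WaveletPacket(
            data=None, wavelet=self.wavelet, mode=self.mode, maxlevel=self.level
        )
        for path, c in zip(self.paths, coeffs):
            wp[path] = c
        out = wp.reconstruct(update=False)
        return np.asarray(out)[: self.length]


def decompose(signal: np.ndarray, spec: ShrinkageSpec) -> SubbandSet:
    """Full wavelet-packet decomposition to ``spec.level``, leaves in
    frequency order."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 2**spec.level:
        raise ValueError(
            f"signal length {len(x)} too short for level {spec.level} "
            f"(needs >= {2 ** spec.level})"
        )
    wp = pywt.WaveletPacket(data=x, wavelet=spec.wavelet, mode="symmetric",
                            maxlevel=spec.level)
    nodes = wp.get_level(spec.level, order="freq")
    return SubbandSet(
        paths=[n.path for n in nodes],
        coeffs=[np.asarray(n.data, dtype=float) for n in nodes],
        wavelet=spec.wavelet,
        level=spec.level,
        length=len(x),
    )


def estimate_tau(detail_coeffs: Sequence[float]) -> float:
    """Robust noise scale: median absolute coefficient / 0.6745.

    Applied to the finest (highest-frequency) detail subband, where the
    signal contribution is smallest and the coefficients are noise-dominated.
    """
    c = np.asarray(detail_coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("cannot estimate noise scale from empty coefficients")
    return float(np.median(np.abs(c)) / MAD_TO_SIGMA)


def universal_threshold(tau: float, D: int) -> float:
    """Universal threshold alpha = tau * sqrt(2 ln D) for D coefficients."""
    if D < 1:
        raise ValueError(f"coefficient count D must be >= 1, got {D}")
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return float(tau * math.sqrt(2.0 * math.log(D)))


def shrink(g, alpha: float, k: float):
    """Combined soft-hard shrinkage of coefficient(s) ``g``.

    Elementwise: ``sign(g)*(|g| - k*alpha)`` where ``|g| > alpha``, else 0.
    Nonexpansive and odd-symmetric; continuous for ``k = 1``, a pure keep/kill
    rule for ``k = 0``.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"mix factor k must be in [0, 1], got {k}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    arr = np.asarray(g, dtype=float)
    out = np.where(np.abs(arr) > alpha, np.sign(arr) * (np.abs(arr) - k * alpha), 0.0)
    if np.ndim(g) == 0:
        return float(out)
    return out


def denoise_channel(signal: np.ndarray, spec: ShrinkageSpec | None = None) -> np.ndarray:
    """Denoise one channel by wavelet-packet shrinkage.

    The lowest-frequency subband (where the slow pedaling harmonics live)
    is passed through untouched; every other subband is shrunk.  By default
    one global threshold -- from a tau estimated on the highest-frequency
    subband and D equal to the signal length -- is applied everywhere;
    ``spec.per_subband`` re-estimates tau and alpha per subband with D the
    subband size.  Output has the input's length.
    """
    spec = spec or ShrinkageSpec()
    x = np.asarray(signal, dtype=float)
    bands = decompose(x, spec)

    if spec.per_subband:
        shrunk = [bands.coeffs[0]]
        for c in bands.coeffs[1:]:
            tau = spec.tau if spec.tau is not None else estimate_tau(c)
            alpha = (
                spec.alpha
                if spec.alpha is not None
                else universal_threshold(tau, len(c))
            )
            shrunk.append(shrink(c, alpha, spec.k))
    else:
        tau = spec.tau if spec.tau is not None else estimate_tau(bands.coeffs[-1])
        alpha = (
            spec.alpha if spec.alpha is not None else universal_threshold(tau, len(x))
        )
        shrunk = [bands.coeffs[0]] + [shrink(c, alpha, spec.k) for c in bands.coeffs[1:]]

    bands.shrunk = shrunk
    return bands.reconstruct()


def denoise_recording(
    rec: CyclingRecording, spec: ShrinkageSpec | None = None
) -> CyclingRecording:
    """Denoise the four acceleration channels of a recording.

    The knee angle channel is exempt (its sensor is interference-proof);
    timestamps, crank angle and labels are preserved unchanged.
    """
    spec = spec or ShrinkageSpec()
    changes = {
        name: denoise_channel(getattr(rec, name), spec)
        for name in CyclingRecording.ACCEL_CHANNELS
    }
    return rec.replace(**changes)
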