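"""Random Gaussian noise at a controlled SNR.

Noisy replicates of an ideal frame carry zero-mean Gaussian noise whose
scale is set by the stated SNR level.  Three modes:

``per-channel`` (default)
    sd_i = |u_i| * 10^(-SNR/20): every measurement channel carries the
    stated SNR, the convention used for EI measurement-device noise
    figures.  The expected frame L2 SNR,
    ``20 log10(||u||_2 / ||u_noise - u||_2)``, equals the same level
    identically.
``frame-uniform``
    one sd for all channels, referenced to ``max|u|`` and calibrated so
    the expected frame L2 SNR matches the level (``snr-calibrated`` is
    accepted as an alias of the default mode).
``eq-literal``
    a Gaussian *density* evaluated at each potential with uniformly
    random mean and sd on ``(0, 10^(SNR/20)]`` -- a smooth, signal-
    dependent warp rather than white noise; kept for comparison because
    the originating formulation is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import Frame

__all__ = ["NoiseSpec", "add_rgwn", "empirical_snr", "noise_sigma_for"]

MODES = ("per-channel", "frame-uniform", "eq-literal")
_MODE_ALIASES = {"snr-calibrated": "per-channel"}


@dataclass(frozen=True)
class NoiseSpec:
    """Target SNR (dB), replicate count and seeded RNG stream."""

    snr_db: float
    n_noisy: int
    seed: object = 0  # int or numpy SeedSequence
    mode: str = "per-channel"

    def __post_init__(self):
        if not (10.0 <= self.snr_db <= 130.0):
            raise ValueError(f"snr_db {self.snr_db} outside [10, 130] dB")
        if self.n_noisy < 0:
            raise ValueError("n_noisy must be non-negative")
        mode = _MODE_ALIASES.get(self.mode, self.mode)
        if mode not in MODES:
            raise ValueError(f"unknown noise mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)


def noise_sigma_for(u: np.ndarray, snr_db: float) -> float:
    """Per-measurement noise sd (in units of max|u|) hitting the target SNR."""
    umax = float(np.max(np.abs(u)))
    if umax == 0.0:
        raise ValueError("cannot scale noise for an all-zero frame")
    target_norm = float(np.linalg.norm(u)) / 10.0 ** (snr_db / 20.0)
    return target_norm / (umax * np.sqrt(u.size))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def noisy_matrix(u: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """(n_noisy, len(u)) noisy replicates; rows use distinct sub-streams."""
    u = np.asarray(u, dtype=float)
    umax = float(np.max(np.abs(u)))
    if umax == 0.0:
        raise ValueError("cannot add noise to an all-zero frame")
    children = _as_seedseq(spec.seed).spawn(spec.n_noisy)
    out = np.empty((spec.n_noisy, u.size))
    if spec.mode == "per-channel":
        # sd proportional to each measurement: every channel carries the
        # stated SNR, and the expected frame L2 SNR equals it too
        s = 10.0 ** (-spec.snr_db / 20.0)
        au = np.abs(u)
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            out[r] = u + au * rng.normal(0.0, s, size=u.size)
    elif spec.mode == "frame-uniform":
        s = noise_sigma_for(u, spec.snr_db)
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            out[r] = u + umax * rng.normal(0.0, s, size=u.size)
    else:  # eq-literal
        scale = 10.0 ** (spec.snr_db / 20.0)
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            mu = rng.uniform(0.0, scale)
            sd = rng.uniform(np.finfo(float).tiny ** 0.25, scale)
            eta = np.exp(-((u - mu) ** 2) / (2.0 * sd**2)) / (sd * np.sqrt(2.0 * np.pi))
            out[r] = u + umax * eta
    return out


def add_rgwn(frame: Frame, spec: NoiseSpec) -> list[Frame]:
    """Corrupt an ideal frame, returning ``spec.n_noisy`` noisy frames."""
    if frame.snr_db is not None:
        raise ValueError("add_rgwn expects an ideal (noise-free) frame")
    mat = noisy_matrix(frame.voltages, spec)
    seed_repr = _as_seedseq(spec.seed).entropy
    return [
        frame.with_(voltages=mat[r], snr_db=spec.snr_db, index=r + 1, seed=seed_repr)
        for r in range(spec.n_noisy)
    ]


def empirical_snr(ideal, noisy) -> float:
    """Realised frame SNR in dB, ``20 log10(||u|| / ||u_noisy - u||)``."""
    u = ideal.voltages if isinstance(ideal, Frame) else np.asarray(ideal, float)
    v = noisy.voltages if isinstance(noisy, Frame) else np.asarray(noisy, float)
    if u.shape != v.shape:
        raise ValueError("frame length mismatch")
    dn = float(np.linalg.norm(v - u))
    if dn == 0.0:
        warnings.warn("frames are identical: SNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return 20.0 * float(np.log10(np.linalg.norm(u) / dn))
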