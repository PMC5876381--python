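"""Skip patterns, conductivity assignment and the EIT forward solve.

A *frame* is the vector of differential boundary voltages collected over
every injection of the stimulation pattern at one time instant.  With 32
electrodes and a measurement skip of 4, the three measurement pairs that
share an electrode with the active injection pair are discarded, leaving
29 retained pairs per injection and 928 values per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._fem import ForwardSystem
from .geometry import Mesh

__all__ = [
    "StimulationPattern",
    "ConductivityMap",
    "Frame",
    "make_stim_pattern",
    "assign_conductivity",
    "forward_solve",
    "frame_contrast",
]

BACKGROUND_CONDUCTIVITY = 0.2  # S/m, weighted pelvic soft-tissue average
DEFAULT_CURRENT_MA = 5.0


@dataclass(frozen=True)
class StimulationPattern:
    """Injection pairs and retained measurement pairs on an electrode ring.

    Pair ``i`` is ``(i, (i + skip + 1) mod n)``; measurement pairs use the
    same offset and any pair sharing an electrode with the active
    injection is dropped.  Ordering is injection-major, then by leading
    measurement electrode.
    """

    n_electrodes: int
    skip: int
    current_ma: float
    injections: tuple
    measurements: tuple  # per injection: tuple of retained (m1, m2)

    @property
    def n_measurements(self) -> int:
        return sum(len(m) for m in self.measurements)

    @property
    def current_amp(self) -> float:
        return self.current_ma * 1e-3


def make_stim_pattern(n_electrodes: int = 32, skip: int = 4,
                      current_ma: float = DEFAULT_CURRENT_MA) -> StimulationPattern:
    if n_electrodes < 8:
        raise ValueError("need at least 8 electrodes")
    if not (0 <= skip <= n_electrodes - 4):
        raise ValueError(f"skip {skip} invalid for {n_electrodes} electrodes")
    if current_ma <= 0:
        raise ValueError("current must be positive")
    off = skip + 1
    injections = []
    measurements = []
    for i in range(n_electrodes):
        a, b = i, (i + off) % n_electrodes
        injections.append((a, b))
        kept = []
        for m in range(n_electrodes):
            m2 = (m + off) % n_electrodes
            if len({m, m2} & {a, b}) == 0:
                kept.append((m, m2))
        measurements.append(tuple(kept))
    return StimulationPattern(n_electrodes=n_electrodes, skip=skip,
                              current_ma=current_ma,
                              injections=tuple(injections),
                              measurements=tuple(measurements))


@dataclass(frozen=True)
class ConductivityMap:
    """Per-element conductivity in S/m (two-valued in this study)."""

    values: np.ndarray
    sigma_bg: float
    sigma_urine: float


def assign_conductivity(mesh: Mesh, sigma_bg: float = BACKGROUND_CONDUCTIVITY,
                        sigma_urine: float = 1.75) -> ConductivityMap:
    if sigma_bg <= 0 or sigma_urine <= 0:
        raise ValueError("conductivities must be positive")
    values = np.where(mesh.element_tags == 1, sigma_urine, sigma_bg).astype(float)
    return ConductivityMap(values=values, sigma_bg=sigma_bg, sigma_urine=sigma_urine)


@dataclass(frozen=True)
class Frame:
    """One voltage frame plus provenance metadata.

    ``snr_db`` is ``None`` for an ideal (noise-free) frame.
    """

    voltages: np.ndarray
    volume_ml: float | None = None
    sigma_urine: float | None = None
    boundary: str | None = None
    snr_db: float | None = None
    index: int = 0
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("frame contains non-finite voltages")
        object.__setattr__(self, "voltages", v)

    def __len__(self) -> int:
        return len(self.voltages)

    def with_(self, **kw) -> "Frame":
        return replace(self, **kw)


def forward_solve(mesh: Mesh, cond: ConductivityMap,
                  pattern: StimulationPattern) -> Frame:
    """Solve the conduction problem and collect the differential frame.

    The stiffness matrix is factorised once per conductivity map and all
    injections are solved as one right-hand-side block.  Measurement
    polarity is potential(first electrode) - potential(second).
    """
    if len(cond.values) != len(mesh.elements):
        raise ValueError("conductivity map does not match the mesh")
    if pattern.n_electrodes != mesh.n_electrodes:
        raise ValueError("pattern and mesh disagree on electrode count")
    system = ForwardSystem(mesh, cond.values)
    u = system.solve_injections(pattern.injections, pattern.current_amp)
    ue = system.electrode_potentials(u)
    out = np.empty(pattern.n_measurements)
    k = 0
    for i, pairs in enumerate(pattern.measurements):
        for (m1, m2) in pairs:
            out[k] = ue[i, m1] - ue[i, m2]
            k += 1
    meta = {}
    if mesh.bladder is not None:
        meta["volume_ml"] = mesh.bladder.volume_ml
    if mesh.boundary is not None:
        meta["boundary"] = mesh.boundary.boundary_id
    return Frame(voltages=out, sigma_urine=cond.sigma_urine, **meta)


def frame_contrast(frame_a, frame_b) -> float:
    """Mean absolute per-measurement difference between two frames."""
    a = frame_a.voltages if isinstance(frame_a, Frame) else np.asarray(frame_a)
    b = frame_b.voltages if isinstance(frame_b, Frame) else np.asarray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))
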