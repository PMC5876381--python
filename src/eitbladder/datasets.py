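"""Factor-grid dataset construction, labelling and stratified 10-fold splits.

The three main test cases grow in complexity: TC1 varies only the bladder
volume, TC2 adds the urine conductivity, TC3 adds the pelvic boundary.
Each is built at one SNR with one ideal frame plus a fixed number of
noisy replicates per factor combination.  TC4 is a withheld "realistic
scenario" grid sharing no factor value with the TC3 training grid.

Volumes (ml): not-full 40:40:280 and full 300:20:420, split at 300 ml.
Conductivities: thirteen 0.25 S/m steps from 0.5 S/m (the published
factor table lists 13 conductivity levels; a 0.25-step grid starting at
0.5 S/m therefore runs to 3.5 S/m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import (BACKGROUND_CONDUCTIVITY, Frame, StimulationPattern,
                      assign_conductivity, forward_solve, make_stim_pattern)
from .geometry import (MeshDensity, PelvisBoundary, RadiiModel,
                       bladder_radii_from_volume, build_pelvis_mesh,
                       place_bladder)
from .noise import NoiseSpec, noisy_matrix

__all__ = [
    "LABEL_FULL",
    "LABEL_NOT_FULL",
    "TestCaseSpec",
    "LabeledDataset",
    "FoldSplit",
    "label_by_threshold",
    "matlab_range",
    "tc_spec",
    "IdealFrameSimulator",
    "build_testcase",
    "make_folds",
    "build_tc4_withheld",
]

LABEL_FULL = "full"
LABEL_NOT_FULL = "not_full"
#: integer encoding: class 1 = full, class 0 = not full (ties in a k-NN
#: vote therefore resolve conservatively to "not full").
LABEL_CODES = {LABEL_NOT_FULL: 0, LABEL_FULL: 1}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

DEFAULT_THRESHOLD_ML = 300.0


def matlab_range(start: float, step: float, stop: float) -> tuple[float, ...]:
    """Colon-operator range: endpoints included only when hit exactly."""
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


def label_by_threshold(volume_ml: float, threshold_ml: float = DEFAULT_THRESHOLD_ML) -> str:
    """'full' iff volume >= threshold."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return LABEL_FULL if volume_ml >= threshold_ml else LABEL_NOT_FULL


# ---------------------------------------------------------------------------
# test-case specifications
# ---------------------------------------------------------------------------

VOLUMES_ML = matlab_range(40, 40, 280) + matlab_range(300, 20, 420)
CONDUCTIVITIES = matlab_range(0.5, 0.25, 3.5)          # 13 levels
TC4_VOLUMES_ML = (matlab_range(20, 40, 290) + (295.0, 299.0, 301.0, 305.0)
                  + matlab_range(310, 20, 430))
TC4_CONDUCTIVITIES = matlab_range(0.625, 0.25, 3.125)  # 11 levels
TC4_SNRS = (30.0, 50.0, 70.0)


def _boundaries_tc3() -> tuple[PelvisBoundary, ...]:
    return tuple(PelvisBoundary.standard(sex, s)
                 for sex in ("male", "female") for s in (0.9, 1.0, 1.1))


def _boundaries_tc4() -> tuple[PelvisBoundary, ...]:
    return tuple(PelvisBoundary.standard(sex, s)
                 for sex in ("male", "female") for s in (0.85, 0.95, 1.05, 1.15))


@dataclass(frozen=True)
class TestCaseSpec:
    """Factor grid for one test case."""

    name: str
    volumes_ml: tuple
    conductivities: tuple
    boundaries: tuple
    snr_levels: tuple
    n_noisy: int
    threshold_ml: float = DEFAULT_THRESHOLD_ML

    def __post_init__(self):
        v = self.volumes_ml
        if any(v[i] >= v[i + 1] for i in range(len(v) - 1)):
            raise ValueError("volumes must be sorted ascending")
        if not (min(v) < self.threshold_ml <= max(v)):
            raise ValueError("threshold must lie strictly inside the volume range")
        if self.n_noisy < 0:
            raise ValueError("n_noisy must be non-negative")

    @property
    def n_scenarios(self) -> int:
        return len(self.volumes_ml) * len(self.conductivities) * len(self.boundaries)

    @property
    def n_observations(self) -> int:
        """Observation count for a single SNR level."""
        return self.n_scenarios * (1 + self.n_noisy)

    def scaled(self, n_noisy: int) -> "TestCaseSpec":
        """Same factor grid with a reduced replicate count."""
        return replace(self, n_noisy=n_noisy, name=f"{self.name}@n{n_noisy}")


def tc_spec(tc, threshold_ml: float = DEFAULT_THRESHOLD_ML,
            n_noisy: int | None = None) -> TestCaseSpec:
    """Published factor grids: tc in {1, 2, 3, 4, '360'}.

    ``'360'`` is the threshold-variant of TC3: every volume shifted up by
    60 ml and the full/not-full split moved to 360 ml.
    """
    male = (PelvisBoundary.standard("male"),)
    if tc in (1, "1"):
        return TestCaseSpec("tc1", VOLUMES_ML, (1.75,), male,
                            (20.0, 40.0, 60.0, 80.0),
                            99 if n_noisy is None else n_noisy, threshold_ml)
    if tc in (2, "2"):
        return TestCaseSpec("tc2", VOLUMES_ML, CONDUCTIVITIES, male,
                            (20.0, 40.0, 60.0, 80.0),
                            39 if n_noisy is None else n_noisy, threshold_ml)
    if tc in (3, "3"):
        return TestCaseSpec("tc3", VOLUMES_ML, CONDUCTIVITIES, _boundaries_tc3(),
                            (20.0, 40.0, 60.0, 80.0),
                            9 if n_noisy is None else n_noisy, threshold_ml)
    if tc in (4, "4"):
        return TestCaseSpec("tc4", tuple(sorted(TC4_VOLUMES_ML)), TC4_CONDUCTIVITIES,
                            _boundaries_tc4(), TC4_SNRS,
                            20 if n_noisy is None else n_noisy, DEFAULT_THRESHOLD_ML)
    if tc in ("360", 360):
        vols = tuple(v + 60.0 for v in VOLUMES_ML)
        return TestCaseSpec("tc3-threshold360", vols, CONDUCTIVITIES,
                            _boundaries_tc3(), (20.0,),
                            9 if n_noisy is None else n_noisy, 360.0)
    raise ValueError(f"unknown test case {tc!r}")


# ---------------------------------------------------------------------------
# dataset containers
# ---------------------------------------------------------------------------

META_COLUMNS = ["volume_ml", "sigma_urine", "boundary", "snr_db", "ideal",
                "replicate"]


@dataclass
class LabeledDataset:
    """Frames with full/not-full labels and per-frame provenance."""

    frames: np.ndarray          # (n_obs, n_measurements)
    meta: pd.DataFrame          # META_COLUMNS
    labels: np.ndarray          # (n_obs,) int8; 1 = full
    threshold_ml: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) != len(self.meta) or len(self.frames) != len(self.labels):
            raise ValueError("frames, meta and labels must align")

    @property
    def n_obs(self) -> int:
        return len(self.frames)

    @property
    def n_measurements(self) -> int:
        return self.frames.shape[1]

    def class_counts(self) -> dict:
        return {LABEL_NAMES[c]: int((self.labels == c).sum()) for c in (0, 1)}

    def label_names(self) -> np.ndarray:
        return np.array([LABEL_NAMES[int(c)] for c in self.labels])

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(self.frames[idx], self.meta.iloc[idx].reset_index(drop=True),
                              self.labels[idx], self.threshold_ml,
                              dict(self.provenance, subset=True))

    @staticmethod
    def concatenate(parts: list["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        thr = {p.threshold_ml for p in parts}
        if len(thr) != 1:
            raise ValueError("cannot concatenate datasets with different thresholds")
        return LabeledDataset(np.vstack([p.frames for p in parts]),
                              pd.concat([p.meta for p in parts], ignore_index=True),
                              np.concatenate([p.labels for p in parts]),
                              parts[0].threshold_ml, dict(parts[0].provenance))


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint, exhaustive, class-stratified train/test partitions."""

    n_folds: int
    test_indices: tuple  # tuple of int arrays

    def train_indices(self, fold: int, n_obs: int) -> np.ndarray:
        mask = np.ones(n_obs, bool)
        mask[self.test_indices[fold]] = False
        return np.flatnonzero(mask)

    def validate(self, labels: np.ndarray) -> None:
        n = len(labels)
        allidx = np.concatenate(self.test_indices)
        if len(allidx) != n or len(np.unique(allidx)) != n:
            raise ValueError("test folds are not a partition of the dataset")
        # stratification: per-class fold counts may differ by at most 1
        for c in np.unique(labels):
            counts = [int((labels[t] == c).sum()) for t in self.test_indices]
            if max(counts) - min(counts) > 1:
                raise ValueError(f"fold class counts for class {c} unbalanced: {counts}")


def make_folds(dataset: LabeledDataset, n_folds: int = 10, seed: int = 0) -> FoldSplit:
    """Seeded stratified k-fold partition (90/10 per class for k = 10).

    Observations of each class are shuffled once; remainders go to the
    earliest folds deterministically.
    """
    rng = np.random.default_rng(seed)
    per_fold: list[list] = [[] for _ in range(n_folds)]
    for c in (0, 1):
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) and len(idx) < n_folds:
            raise ValueError(f"class {LABEL_NAMES[c]!r} has fewer than {n_folds} observations")
        rng.shuffle(idx)
        base = len(idx) // n_folds
        extra = len(idx) % n_folds
        start = 0
        for f in range(n_folds):
            size = base + (1 if f < extra else 0)
            per_fold[f].append(idx[start:start + size])
            start += size
    tests = tuple(np.sort(np.concatenate(parts)) for parts in per_fold)
    split = FoldSplit(n_folds=n_folds, test_indices=tests)
    split.validate(dataset.labels)
    return split


# ---------------------------------------------------------------------------
# simulation-backed dataset builder
# ---------------------------------------------------------------------------


class IdealFrameSimulator:
    """Forward-simulates (and caches) ideal frames over factor grids.

    Meshes are cached per (boundary, volume) and frames per
    (boundary, volume, conductivity), so overlapping test-case grids
    reuse each other's solves.
    """

    def __init__(self, radii_model: RadiiModel | None = None,
                 density: MeshDensity | None = None, domain: str = "2d",
                 pattern: StimulationPattern | None = None,
                 sigma_bg: float = BACKGROUND_CONDUCTIVITY):
        self.radii_model = radii_model or RadiiModel()
        self.density = density or MeshDensity()
        self.domain = domain
        self.pattern = pattern or make_stim_pattern()
        self.sigma_bg = sigma_bg
        self._meshes: dict = {}
        self._frames: dict = {}

    def mesh_for(self, boundary: PelvisBoundary, volume_ml: float):
        key = (boundary.boundary_id, round(volume_ml, 6))
        if key not in self._meshes:
            radii = bladder_radii_from_volume(volume_ml, self.radii_model)
            bl = place_bladder(radii, boundary, self.radii_model, volume_ml=volume_ml)
            self._meshes[key] = build_pelvis_mesh(boundary, bl, self.density,
                                                  domain=self.domain,
                                                  n_electrodes=self.pattern.n_electrodes)
        return self._meshes[key]

    def ideal_frame(self, volume_ml: float, sigma_urine: float,
                    boundary: PelvisBoundary) -> Frame:
        key = (boundary.boundary_id, round(volume_ml, 6), round(sigma_urine, 6))
        if key not in self._frames:
            mesh = self.mesh_for(boundary, volume_ml)
            cond = assign_conductivity(mesh, self.sigma_bg, sigma_urine)
            fr = forward_solve(mesh, cond, self.pattern)
            self._frames[key] = fr.with_(volume_ml=volume_ml)
        return self._frames[key]


def _scenario_grid(spec: TestCaseSpec):
    for boundary in spec.boundaries:
        for volume in spec.volumes_ml:
            for sigma in spec.conductivities:
                yield boundary, volume, sigma


def build_testcase(spec: TestCaseSpec, snr_db: float, seed: int = 0,
                   simulator: IdealFrameSimulator | None = None,
                   noise_mode: str = "snr-calibrated") -> LabeledDataset:
    """Build the labelled dataset of one test case at one SNR level.

    For every (boundary, volume, conductivity) scenario the dataset holds
    the ideal frame plus ``spec.n_noisy`` seeded noisy replicates.
    Deterministic for a fixed seed.
    """
    if snr_db not in spec.snr_levels:
        raise ValueError(f"snr {snr_db} dB not in spec levels {spec.snr_levels}")
    sim = simulator or IdealFrameSimulator()
    children = np.random.SeedSequence(seed).spawn(spec.n_scenarios)
    blocks, rows, labels = [], [], []
    errors = []
    for k, (boundary, volume, sigma) in enumerate(_scenario_grid(spec)):
        try:
            ideal = sim.ideal_frame(volume, sigma, boundary)
        except Exception as exc:  # report the offending factor tuple
            errors.append((boundary.boundary_id, volume, sigma, str(exc)))
            continue
        nspec = NoiseSpec(snr_db=snr_db, n_noisy=spec.n_noisy,
                          seed=children[k], mode=noise_mode)
        noisy = noisy_matrix(ideal.voltages, nspec) if spec.n_noisy else \
            np.empty((0, len(ideal.voltages)))
        blocks.append(ideal.voltages[None, :])
        blocks.append(noisy)
        lab = LABEL_CODES[label_by_threshold(volume, spec.threshold_ml)]
        for r in range(1 + spec.n_noisy):
            rows.append((volume, sigma, boundary.boundary_id,
                         np.nan if r == 0 else snr_db, r == 0, r))
            labels.append(lab)
    if errors:
        raise RuntimeError(f"infeasible scenario combinations: {errors}")
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return LabeledDataset(
        frames=np.vstack(blocks), meta=meta,
        labels=np.asarray(labels, dtype=np.int8),
        threshold_ml=spec.threshold_ml,
        provenance={"spec": spec.name, "snr_db": snr_db, "seed": seed,
                    "n_noisy": spec.n_noisy, "noise_mode": noise_mode})


def _assert_disjoint(name: str, withheld, training) -> None:
    overlap = sorted(set(withheld) & set(training))
    if overlap:
        raise ValueError(f"withheld {name} value(s) {overlap} collide with the training grid")


def build_tc4_withheld(spec: TestCaseSpec | None = None, seed: int = 0,
                       simulator: IdealFrameSimulator | None = None,
                       train_spec: TestCaseSpec | None = None) -> LabeledDataset:
    """Build the withheld realistic-scenario test set (all its SNR levels).

    Every factor value is verified to be absent from the training grid
    (TC3 by default) before any simulation is run.
    """
    spec = spec or tc_spec(4)
    train = train_spec or tc_spec(3)
    _assert_disjoint("volume", spec.volumes_ml, train.volumes_ml)
    _assert_disjoint("conductivity", spec.conductivities, train.conductivities)
    _assert_disjoint("boundary",
                     [(b.sex_tag, b.ap_scale) for b in spec.boundaries],
                     [(b.sex_tag, b.ap_scale) for b in train.boundaries])
    _assert_disjoint("snr", spec.snr_levels, train.snr_levels)
    for v in (295.0, 299.0, 301.0, 305.0):
        if v not in spec.volumes_ml:
            raise ValueError(f"near-threshold volume {v} ml missing from the withheld grid")
    sim = simulator or IdealFrameSimulator()
    parts = []
    for i, snr in enumerate(spec.snr_levels):
        parts.append(build_testcase(spec, snr, seed=seed + i, simulator=sim))
    ds = LabeledDataset.concatenate(parts)
    ds.provenance.update({"spec": spec.name, "trained_on": f"{train.name}@40dB",
                          "seed": seed})
    return ds
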