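"""Reproduction experiments: the TC1-TC4 study grid at desk scale.

These drivers bind the simulator, dataset builder and classifiers into
the published study design.  Problem sizes are the package's desk-scale
defaults: TC1 keeps its 99 noisy frames per ideal frame; TC2 runs with
9 (instead of 39) and TC3 with 3 (instead of 9) replicates; the TC4
withheld grid is thinned uniformly (6 of 11 conductivities, 4 of 8
boundary variants, 2 noisy frames per ideal frame and SNR).  TC1 uses
the full 3-D forward model (14 meshes); the combinatorially large
TC2-TC4 grids use the 2-D electrode-plane reduction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .classify import (CLASSIFIER_KINDS, ClassifierSpec, FoldResult,
                       MetricsReport, evaluate, misclassification_by_factor,
                       run_10fold)
from .datasets import (IdealFrameSimulator, LabeledDataset, build_tc4_withheld,
                       build_testcase, make_folds, matlab_range, tc_spec)

__all__ = [
    "DESK_SCALE",
    "ExperimentResult",
    "run_tc_experiment",
    "run_tc_grid",
    "run_tc4_experiment",
    "run_threshold_variant",
]

SNR_LEVELS = (20.0, 40.0, 60.0, 80.0)

#: noisy-frame counts used by the reproduction experiments
DESK_SCALE = {"1": 99, "2": 9, "3": 3, "4": 2, "360": 3}

#: TC4 desk-scale thinning: every other conductivity, half the boundaries
TC4_DESK_CONDUCTIVITIES = matlab_range(0.625, 0.5, 3.125)
TC4_DESK_BOUNDARIES = (("male", 0.95), ("male", 1.15),
                       ("female", 0.85), ("female", 1.05))


@dataclass
class ExperimentResult:
    """One test case at one SNR: dataset + per-classifier fold results."""

    tc: str
    snr_db: float
    dataset: LabeledDataset
    results: dict  # kind -> FoldResult

    def mean_accuracy(self, kind: str) -> float:
        return 100.0 * self.results[kind].metrics.mean_accuracy

    def error_percent(self, kind: str) -> float:
        return self.results[kind].error_percent


def _classifier_specs(kinds=CLASSIFIER_KINDS):
    return [ClassifierSpec(k) for k in kinds]


def desk_spec(tc, n_noisy: int | None = None):
    """Test-case spec at the desk-scale replicate count."""
    key = str(tc)
    spec = tc_spec(tc, n_noisy=DESK_SCALE[key] if n_noisy is None else n_noisy)
    if key == "4":
        boundaries = tuple(b for b in spec.boundaries
                           if (b.sex_tag, b.ap_scale) in set(TC4_DESK_BOUNDARIES))
        spec = dataclasses.replace(spec, conductivities=TC4_DESK_CONDUCTIVITIES,
                                   boundaries=boundaries)
    return spec


def default_simulators() -> dict:
    """Fresh simulator caches: 3-D for TC1, 2-D for the large grids."""
    return {"3d": IdealFrameSimulator(domain="3d"),
            "2d": IdealFrameSimulator(domain="2d")}


def run_tc_experiment(tc, snr_db: float, seed: int,
                      simulator: IdealFrameSimulator | None = None,
                      kinds=CLASSIFIER_KINDS, n_noisy: int | None = None,
                      keep_models: bool = False) -> ExperimentResult:
    """Build one test-case dataset at one SNR and run 10-fold evaluation."""
    key = str(tc)
    if simulator is None:
        simulator = IdealFrameSimulator(domain="3d" if key == "1" else "2d")
    spec = desk_spec(tc, n_noisy=n_noisy)
    ds = build_testcase(spec, snr_db, seed=seed, simulator=simulator)
    folds = make_folds(ds, 10, seed=seed)
    results = run_10fold(ds, folds, _classifier_specs(kinds), keep_models=keep_models)
    return ExperimentResult(tc=key, snr_db=snr_db, dataset=ds, results=results)


def run_tc_grid(seed: int, tcs=("1", "2", "3"), snrs=SNR_LEVELS,
                simulators: dict | None = None,
                keep_models_for: tuple = ("3", 40.0)) -> dict:
    """The full TC1-TC3 x SNR grid.  Returns {(tc, snr): ExperimentResult}.

    Simulator caches are shared across SNRs (ideal frames are
    noise-independent) and across TC2/TC3 (TC2's grid is a subset of
    TC3's).  ``keep_models_for`` retains the trained fold classifiers of
    one cell, for reuse on the TC4 withheld grid.
    """
    sims = simulators or default_simulators()
    out = {}
    for tc in tcs:
        sim = sims["3d" if str(tc) == "1" else "2d"]
        for i, snr in enumerate(snrs):
            keep = (str(tc), snr) == tuple(keep_models_for)
            out[(str(tc), snr)] = run_tc_experiment(
                tc, snr, seed=seed + 1000 * i, simulator=sim, keep_models=keep)
    return out


def min_mean_accuracy(grid: dict) -> tuple[float, tuple]:
    """Smallest mean accuracy over every (tc, snr, classifier) cell, in %."""
    best = None
    where = None
    for cell, exp in grid.items():
        for kind in exp.results:
            acc = exp.mean_accuracy(kind)
            if best is None or acc < best:
                best, where = acc, cell + (kind,)
    return best, where


@dataclass
class TC4Result:
    dataset: LabeledDataset
    accuracies: dict        # kind -> (mean %, sd %) balanced accuracy over models
    per_model: dict         # kind -> list of per-model balanced accuracies (%)
    near_threshold: dict    # volume -> misclassified % (linear SVM)


def run_tc4_experiment(tc3_result: ExperimentResult, seed: int,
                       simulator: IdealFrameSimulator | None = None) -> TC4Result:
    """Evaluate TC3-trained classifiers on the withheld realistic grid.

    The ten fold classifiers of each kind (trained on the TC3 40 dB
    dataset) are each evaluated on the full withheld set; reported
    accuracy is the mean and sd over the ten classifiers.
    """
    sim = simulator or IdealFrameSimulator(domain="2d")
    spec = desk_spec(4)
    ds = build_tc4_withheld(spec, seed=seed, simulator=sim)
    accuracies, per_model = {}, {}
    for kind, fold_res in tc3_result.results.items():
        if not fold_res.models:
            raise ValueError("TC3 result was run without keep_models")
        accs = [100.0 * evaluate(m, ds.frames, ds.labels).mean_accuracy
                for m in fold_res.models]
        per_model[kind] = accs
        accuracies[kind] = (float(np.mean(accs)), float(np.std(accs, ddof=1)))
    # near-threshold misclassification, averaged over the linear-SVM models
    vols = ds.meta["volume_ml"].to_numpy()
    near = {}
    lin_models = tc3_result.results["linear_svm"].models
    for v in (295.0, 299.0, 301.0, 305.0):
        mask = vols == v
        rates = [100.0 * np.mean(m.predict(ds.frames[mask]) != ds.labels[mask])
                 for m in lin_models]
        near[v] = float(np.mean(rates))
    return TC4Result(dataset=ds, accuracies=accuracies, per_model=per_model,
                     near_threshold=near)


def run_threshold_variant(seed: int, snr_db: float = 20.0,
                          simulator: IdealFrameSimulator | None = None,
                          kinds=CLASSIFIER_KINDS) -> ExperimentResult:
    """TC3 factors shifted +60 ml with the fullness threshold at 360 ml."""
    sim = simulator or IdealFrameSimulator(domain="2d")
    return run_tc_experiment("360", snr_db, seed=seed, simulator=sim, kinds=kinds)
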