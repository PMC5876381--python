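"""Frame-archive readers/writers, external frame import, run configs.

Datasets are stored one row per frame: provenance columns, the label,
then the 928 voltage columns (``v0000`` .. ``v0927``).  Two dialects are
supported with identical ordering: delimited text (CSV) and HDF5
(``/frames`` matrix plus ``/meta/<column>`` tables).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .datasets import (LABEL_CODES, LABEL_NAMES, META_COLUMNS, LabeledDataset,
                       label_by_threshold)

__all__ = [
    "FormatError",
    "RunConfig",
    "write_frames",
    "read_frames",
    "import_external",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed frame archive or external frame table."""


def _voltage_columns(n: int) -> list[str]:
    return [f"v{i:04d}" for i in range(n)]


def _infer_dialect(path, dialect: str | None) -> str:
    if dialect not in (None, "infer"):
        return dialect
    suffix = pathlib.Path(path).suffix.lower()
    return "hdf5" if suffix in (".h5", ".hdf5") else "csv"


def write_frames(dataset: LabeledDataset, path, dialect: str = "infer") -> None:
    """Write a labelled dataset to a frame archive."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        df = dataset.meta.copy()
        df["label"] = dataset.label_names()
        volt = pd.DataFrame(dataset.frames,
                            columns=_voltage_columns(dataset.n_measurements))
        pd.concat([df, volt], axis=1).to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=dataset.frames)
            fh.create_dataset("labels", data=dataset.labels)
            grp = fh.create_group("meta")
            for col in dataset.meta.columns:
                vals = dataset.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
            fh.attrs["threshold_ml"] = dataset.threshold_ml
            fh.attrs["provenance"] = json.dumps(dataset.provenance, default=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_frames(path, dialect: str = "infer",
                threshold_ml: float | None = None) -> LabeledDataset:
    """Read a frame archive written by :func:`write_frames`."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        df = pd.read_csv(path)
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        vcols.sort()
        if not vcols:
            raise FormatError("no voltage columns found")
        frames = df[vcols].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(frames).all(axis=1))
        if len(bad):
            raise FormatError(f"row(s) {bad.tolist()} have missing/invalid voltages")
        if "label" not in df.columns:
            raise FormatError("missing label column")
        labels = np.array([LABEL_CODES[s] for s in df["label"]], dtype=np.int8)
        meta = df[[c for c in META_COLUMNS if c in df.columns]].copy()
        thr = threshold_ml if threshold_ml is not None else 300.0
        return LabeledDataset(frames=frames, meta=meta.reset_index(drop=True),
                              labels=labels, threshold_ml=thr,
                              provenance={"source": str(path)})
    with h5py.File(path, "r") as fh:
        frames = fh["frames"][...]
        labels = fh["labels"][...].astype(np.int8)
        meta = {}
        for col in fh["meta"]:
            vals = fh["meta"][col][...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            meta[col] = vals
        meta = pd.DataFrame(meta)[[c for c in META_COLUMNS if c in meta]]
        thr = float(fh.attrs.get("threshold_ml", 300.0))
        prov = json.loads(fh.attrs.get("provenance", "{}"))
    return LabeledDataset(frames=frames, meta=meta, labels=labels,
                          threshold_ml=thr, provenance=prov)


def import_external(table, threshold_ml: float = 300.0,
                    n_measurements: int = 928) -> LabeledDataset:
    """Import externally recorded voltage frames (phantom-style data).

    ``table`` is a delimited-text path or DataFrame whose rows carry
    either a ``volume_ml`` or a ``label`` column plus exactly
    ``n_measurements`` voltage columns.  Labels are derived from volumes
    by the fullness threshold when not given explicitly.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    known = {"frame_id", "volume_ml", "label"}
    vcols = [c for c in table.columns if c not in known]
    if len(vcols) != n_measurements:
        raise FormatError(
            f"expected {n_measurements} voltage columns, found {len(vcols)}")
    frames = table[vcols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(frames).all(axis=1))
    if len(bad):
        raise FormatError(f"row(s) {bad.tolist()} have missing/invalid voltages")
    if "label" in table.columns:
        labels = np.array([LABEL_CODES[s] for s in table["label"]], dtype=np.int8)
        volumes = table.get("volume_ml", pd.Series(np.nan, index=table.index))
    elif "volume_ml" in table.columns:
        volumes = table["volume_ml"]
        labels = np.array(
            [LABEL_CODES[label_by_threshold(v, threshold_ml)] for v in volumes],
            dtype=np.int8)
    else:
        raise FormatError("table must provide a 'volume_ml' or 'label' column")
    meta = pd.DataFrame({
        "volume_ml": np.asarray(volumes, dtype=float),
        "sigma_urine": np.nan, "boundary": "external", "snr_db": np.nan,
        "ideal": False, "replicate": np.arange(len(table))})
    return LabeledDataset(frames=frames, meta=meta, labels=labels,
                          threshold_ml=threshold_ml,
                          provenance={"source": "external"})


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a simulation/classification run."""

    seed: int = 0
    outdir: str = "runs"
    geometry: dict = field(default_factory=lambda: {
        "domain": "2d", "sex": "male", "ap_scale": 1.0,
        "density_scale": 1.0, "radii_ratios": [1.2, 1.0, 0.9]})
    noise: dict = field(default_factory=lambda: {
        "mode": "per-channel", "snr_db": 20.0})
    testcase: dict = field(default_factory=lambda: {
        "tc": 1, "n_noisy": None, "threshold_ml": 300.0})
    classifiers: list = field(default_factory=lambda: [
        "linear_svm", "cubic_svm", "cosine_knn"])
    folds: dict = field(default_factory=lambda: {"n_folds": 10})

    _SECTIONS = ("geometry", "noise", "testcase", "classifiers", "folds")

    def validate(self) -> "RunConfig":
        from .classify import CLASSIFIER_KINDS
        if self.geometry.get("domain") not in ("2d", "3d"):
            raise ValueError("geometry.domain must be '2d' or '3d'")
        for kind in self.classifiers:
            if kind not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier {kind!r}")
        if int(self.folds.get("n_folds", 10)) < 2:
            raise ValueError("folds.n_folds must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SECTIONS) - {"seed", "outdir"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        cfg = cls()
        for key, val in raw.items():
            if isinstance(val, dict) and key in cls._SECTIONS:
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(outdir, config: RunConfig, extra: dict | None = None) -> pathlib.Path:
    """Record config hash, seed and library versions next to run outputs."""
    import scipy
    import sklearn

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
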