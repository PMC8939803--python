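"""CSV/JSON/YAML serialisation for every pipeline stage.

All formats are plain text: series and manifests as CSV, projections,
posteriors and run manifests as JSON, configuration as flat YAML whose
keys mirror the dataclass field names exactly (unknown keys are errors).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cohort import CohortDataset, Subject
from .inference import PosteriorSamples, PriorSpec
from .map_estimation import MAPEstimate
from .simulator import PARAM_NAMES, DepositionParams, DeviceConfig, DepositionTimeSeries
from .summaries import FeatureExpansion, SummaryProjection

__all__ = [
    "SERIES_COLUMNS",
    "read_series",
    "write_series",
    "read_cohort_manifest",
    "write_cohort",
    "read_params",
    "read_config",
    "read_prior",
    "write_projection",
    "read_projection",
    "write_posterior",
    "read_posterior",
    "write_run_manifest",
]

SERIES_COLUMNS = (
    "time_s",
    "n_clusters_per_mm2",
    "mean_cluster_size_cells",
    "n_platelet_per_ul",
)


def write_series(series: DepositionTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.times,
            "n_clusters_per_mm2": series.n_clusters,
            "mean_cluster_size_cells": series.mean_cluster_size,
            "n_platelet_per_ul": series.n_platelet,
        }
    )
    df.to_csv(path, index=False)
    if series.meta:
        Path(path).with_suffix(".json").write_text(json.dumps(series.meta, indent=2))


def read_series(path: str | Path) -> DepositionTimeSeries:
    """Read a series CSV with a strict header and per-row validation."""
    df = pd.read_csv(path)
    if tuple(df.columns) != SERIES_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {list(SERIES_COLUMNS)}, found {list(df.columns)}"
        )
    for col in SERIES_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3  # 1-based incl. header
        raise ValueError(f"{path}: times not strictly increasing at row {row}")
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DepositionTimeSeries(
        times=t,
        n_clusters=df["n_clusters_per_mm2"].to_numpy(dtype=float),
        mean_cluster_size=df["mean_cluster_size_cells"].to_numpy(dtype=float),
        n_platelet=df["n_platelet_per_ul"].to_numpy(dtype=float),
        meta=meta,
    )


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """One series CSV per subject plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.csv"
        write_series(s.series, out_dir / fname)
        row = {"subject_id": s.subject_id, "group": s.group, "series_path": fname}
        if s.params is not None:
            row.update({f"true_{n}": v for n, v in zip(PARAM_NAMES, s.params.as_array())})
        rows.append(row)
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(path: str | Path) -> CohortDataset:
    """Load a cohort manifest CSV and every referenced series."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "group", "series_path"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing manifest column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject id {dup.iloc[0]!r}")
    true_cols = [c for c in df.columns if c.startswith("true_")]
    subjects = []
    for _, row in df.iterrows():
        series_path = path.parent / row["series_path"]
        if not series_path.exists():
            raise FileNotFoundError(f"{path}: series file missing for {row['subject_id']}")
        series = read_series(series_path)
        params = None
        if len(true_cols) == len(PARAM_NAMES):
            params = DepositionParams.from_array(
                [row[f"true_{n}"] for n in PARAM_NAMES]
            )
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                params=params,
                series=series,
            )
        )
    try:
        return CohortDataset(subjects)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


# ---------------------------------------------------------------------------
# configuration (flat YAML mirroring dataclass fields)
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, path):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{path}: unknown {cls.__name__} keys {sorted(unknown)}")
    if cls is DeviceConfig and "obs_times" in data:
        data = {**data, "obs_times": tuple(data["obs_times"])}
    return cls(**data)


def read_config(path: str | Path) -> DeviceConfig:
    return _from_mapping(DeviceConfig, yaml.safe_load(Path(path).read_text()) or {}, path)


def read_params(path: str | Path) -> DepositionParams:
    return _from_mapping(DepositionParams, yaml.safe_load(Path(path).read_text()) or {}, path)


def read_prior(path: str | Path) -> PriorSpec:
    """Prior YAML: parameter name -> [low, high]."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown prior keys {sorted(unknown)}")
    from .inference import DEFAULT_PRIOR_BOUNDS

    bounds = [
        tuple(data.get(name, DEFAULT_PRIOR_BOUNDS[k]))
        for k, name in enumerate(PARAM_NAMES)
    ]
    return PriorSpec(bounds=tuple(bounds))


# ---------------------------------------------------------------------------
# projection / posterior / manifest
# ---------------------------------------------------------------------------

def write_projection(proj: SummaryProjection, path: str | Path) -> None:
    payload = {
        "L": proj.L.tolist(),
        "expansion": {
            "orders": list(proj.expansion.orders),
            "include_cross_products": proj.expansion.include_cross_products,
            "standardize": proj.expansion.standardize,
        },
        "input_mean": proj.input_mean.tolist(),
        "input_std": proj.input_std.tolist(),
        "feature_mean": proj.feature_mean.tolist(),
        "feature_std": proj.feature_std.tolist(),
        "k_neighbors": proj.k_neighbors,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_projection(path: str | Path) -> SummaryProjection:
    data = json.loads(Path(path).read_text())
    return SummaryProjection(
        L=np.asarray(data["L"], dtype=float),
        expansion=FeatureExpansion(
            orders=tuple(data["expansion"]["orders"]),
            include_cross_products=data["expansion"]["include_cross_products"],
            standardize=data["expansion"]["standardize"],
        ),
        input_mean=np.asarray(data["input_mean"], dtype=float),
        input_std=np.asarray(data["input_std"], dtype=float),
        feature_mean=np.asarray(data["feature_mean"], dtype=float),
        feature_std=np.asarray(data["feature_std"], dtype=float),
        k_neighbors=int(data["k_neighbors"]),
    )


def write_posterior(samples: PosteriorSamples, path: str | Path) -> None:
    df = pd.DataFrame(samples.samples, columns=list(samples.param_names))
    df["distance"] = samples.distances
    df.to_csv(path, index=False)


def read_posterior(path: str | Path, subject_id: str = "") -> PosteriorSamples:
    df = pd.read_csv(path)
    if "distance" not in df.columns:
        raise ValueError(f"{path}: missing 'distance' column")
    names = tuple(c for c in df.columns if c != "distance")
    return PosteriorSamples(
        samples=df[list(names)].to_numpy(dtype=float),
        distances=df["distance"].to_numpy(dtype=float),
        epsilon_schedule=np.array([float(df["distance"].max())]),
        subject_id=subject_id,
        param_names=names,
    )


def write_map_estimate(est: MAPEstimate, path: str | Path) -> None:
    payload = {
        "theta_hat": dict(zip(est.param_names, np.asarray(est.theta_hat).tolist())),
        "kde_bandwidth": est.kde_bandwidth,
        "optimizer_iterations": est.optimizer_iterations,
        "log_density_at_mode": est.log_density_at_mode,
        "subject_id": est.subject_id,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_run_manifest(
    path: str | Path,
    command: str,
    seed: int | None,
    inputs: dict[str, str | Path] | None = None,
    config: dict | None = None,
) -> None:
    """Record the provenance of one CLI run (inputs hashed by content)."""
    hashes = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    payload = {
        "command": command,
        "seed": seed,
        "input_hashes": hashes,
        "config": config or {},
        "package_version": _pkg_version,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
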