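"""Flat-file persistence for pipeline products.

Every artifact kind writes deterministic file names under an output directory
and round-trips exactly (write -> read -> equal; numeric CSVs use 17
significant digits so float64 values survive bitwise).  ``save_artifacts``
accepts one artifact or a list and returns the manifest it wrote.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DependencyWeights, DistanceMatrix
from .profiling import ClusterProfile, TestResults
from .schema import MixedDataMatrix, save_dataset, load_dataset
from .spectral import ClusteringResult
from .stability import LOOReport, StabilityReport
from .validity import ValidityCurve

_FLOAT = "%.17g"


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=_FLOAT, index=index)


def save_artifacts(result, out_dir: str | Path) -> dict:
    """Write one artifact (or a list) and a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items = result if isinstance(result, (list, tuple)) else [result]
    entries = []
    for item in items:
        kind, files = _save_one(item, out_dir)
        entries.append({"kind": kind, "files": [f.name for f in files]})
    manifest = {"artifacts": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _save_one(item, out_dir: Path) -> tuple[str, list[Path]]:
    if isinstance(item, DistanceMatrix):
        p = out_dir / "distance_matrix.csv"
        df = pd.DataFrame(item.values, index=item.sample_ids,
                          columns=item.sample_ids)
        _write_df(df, p)
        return "distance_matrix", [p]
    if isinstance(item, DependencyWeights):
        p1 = out_dir / "dependency_weights.csv"
        _write_df(item.as_series().to_frame(), p1)
        p2 = out_dir / "nmi_matrix.csv"
        _write_df(item.nmi, p2)
        return "dependency_weights", [p1, p2]
    if isinstance(item, ClusteringResult):
        p1 = out_dir / "labels.csv"
        _write_df(pd.DataFrame({"sample_id": item.sample_ids or range(len(item.labels)),
                                "label": item.labels}), p1, index=False)
        p2 = out_dir / "embedding_2d.csv"
        if item.embedding_2d is not None:
            emb = pd.DataFrame(item.embedding_2d, columns=["dim1", "dim2"])
            emb.insert(0, "sample_id", item.sample_ids or range(len(item.labels)))
            emb["label"] = item.labels
            _write_df(emb, p2, index=False)
            return "clustering_result", [p1, p2]
        return "clustering_result", [p1]
    if isinstance(item, ValidityCurve):
        p = out_dir / "validity_curve.csv"
        _write_df(item.table, p)
        meta = out_dir / "validity_selection.json"
        with open(meta, "w") as fh:
            json.dump({"chosen_k": item.chosen_k, "cvnn_argmin": item.cvnn_argmin,
                       "sdbw_argmin": item.sdbw_argmin}, fh)
        return "validity_curve", [p, meta]
    if isinstance(item, StabilityReport):
        p = out_dir / "stability_report.csv"
        _write_df(item.table, p, index=False)
        return "stability_report", [p]
    if isinstance(item, LOOReport):
        p1 = out_dir / "loo_accuracy.json"
        with open(p1, "w") as fh:
            json.dump({"accuracy": item.accuracy}, fh)
        p2 = out_dir / "loo_confusion.csv"
        _write_df(item.confusion, p2)
        return "loo_report", [p1, p2]
    if isinstance(item, ClusterProfile):
        p1 = out_dir / "z_profiles.csv"
        _write_df(item.z, p1)
        p2 = out_dir / "qualitative_labels.csv"
        _write_df(item.qualitative, p2)
        p3 = out_dir / "population_scale.csv"
        _write_df(pd.DataFrame({"mean": item.population_mean,
                                "sd": item.population_sd}), p3)
        return "cluster_profile", [p1, p2, p3]
    if isinstance(item, TestResults):
        p1 = out_dir / "kruskal_tests.csv"
        _write_df(item.kruskal, p1, index=False)
        p2 = out_dir / "conover_posthoc.csv"
        _write_df(item.conover, p2, index=False)
        p3 = out_dir / "one_vs_rest_tests.csv"
        _write_df(item.one_vs_rest, p3, index=False)
        return "test_results", [p1, p2, p3]
    if isinstance(item, MixedDataMatrix):
        p1 = out_dir / "data.csv"
        p2 = out_dir / "schema.yml"
        save_dataset(item, p1, p2)
        return "mixed_data", [p1, p2]
    raise TypeError(f"no writer for artifact type {type(item).__name__}")


def load_distance_matrix(out_dir: str | Path) -> DistanceMatrix:
    df = pd.read_csv(Path(out_dir) / "distance_matrix.csv", index_col=0,
                     float_precision="round_trip")
    return DistanceMatrix(values=df.to_numpy(float),
                          sample_ids=list(df.index))


def load_labels(out_dir: str | Path) -> np.ndarray:
    df = pd.read_csv(Path(out_dir) / "labels.csv")
    return df["label"].to_numpy(int)


def load_mixed_data(out_dir: str | Path) -> MixedDataMatrix:
    out_dir = Path(out_dir)
    return load_dataset(out_dir / "data.csv", out_dir / "schema.yml")
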