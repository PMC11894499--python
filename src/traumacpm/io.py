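"""Plain-text I/O: manifests, time series, connectomes, phenotypes, atlases.

Everything is delimited text or JSON so fixtures are diff-able and
language-agnostic.  Numeric payloads round-trip at full precision
(``repr``-level floats).  Schema violations raise errors naming the file
and the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, average_connectomes, compute_connectome, \
    NodeTimeSeries, n_edges, vectorize
from .networks import NetworkAtlas
from .simulate import SyntheticCohort, TIMEPOINTS

MANIFEST_COLUMNS = ["subject_id", "scan_label", "path", "valid", "kind"]
CLUSTER_NAMES = ("B", "C", "D", "E")


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# -- time series ---------------------------------------------------------

def write_timeseries(ts: NodeTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=ts.node_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path: str | Path, subject_id: str,
                    scan_label: str) -> NodeTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return NodeTimeSeries(subject_id, scan_label, df.to_numpy(float),
                          [str(c) for c in df.columns])


# -- connectome matrices -------------------------------------------------

def write_connectome(c: Connectome, path: str | Path) -> None:
    """N x N matrix as CSV plus a ``.json`` sidecar (node order, provenance)."""
    path = Path(path)
    np.savetxt(path, c.z, delimiter=",", fmt="%.17g")
    sidecar = {"subject_id": c.subject_id,
               "n_scans_averaged": c.n_scans_averaged,
               "node_ids": c.node_ids}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    z = np.loadtxt(path, delimiter=",", ndmin=2)
    if z.shape[0] != z.shape[1]:
        raise SchemaError(f"{path}: connectome matrix is not square {z.shape}")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Connectome(meta.get("subject_id", path.stem), z,
                      n_scans_averaged=meta.get("n_scans_averaged", 1),
                      node_ids=meta.get("node_ids"))


# -- manifest ------------------------------------------------------------

def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    root = Path(path).parent
    for row, rel in df["path"].items():
        if not (root / rel).exists():
            raise SchemaError(f"{path}: row {row} references missing file {rel}")
    df = df.copy()
    df["path"] = [str(root / rel) for rel in df["path"]]
    return df


def connectomes_from_manifest(manifest: pd.DataFrame) -> list[Connectome]:
    """One averaged connectome per subject from its valid scans."""
    out = []
    valid = manifest[manifest["valid"].astype(bool)]
    for sid, grp in valid.groupby("subject_id", sort=True):
        per_scan = []
        for _, row in grp.iterrows():
            if row["kind"] == "timeseries":
                ts = read_timeseries(row["path"], sid, row["scan_label"])
                per_scan.append(compute_connectome(ts))
            elif row["kind"] == "connectome":
                c = read_connectome(row["path"])
                c.subject_id = sid
                per_scan.append(c)
            else:
                raise SchemaError(f"manifest: unknown kind {row['kind']!r}")
        out.append(average_connectomes(per_scan))
    return out


# -- cohort edges table --------------------------------------------------

def write_edges_table(subject_ids, edges: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(edges, columns=[f"e{i}" for i in range(edges.shape[1])])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_edges_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id"], path)
    ids = df["subject_id"].astype(str).tolist()
    return ids, df.drop(columns="subject_id").to_numpy(float)


# -- phenotype -----------------------------------------------------------

def validate_phenotype(df: pd.DataFrame, path: str | Path = "<phenotype>") -> None:
    """CAPS-5 invariants: totals in 0-80, cluster sums equal totals."""
    _require_columns(df, ["subject_id"] +
                     [f"caps_total_{tp}" for tp in TIMEPOINTS], path)
    for tp in TIMEPOINTS:
        total = df[f"caps_total_{tp}"]
        bad = total.dropna()[(total.dropna() < 0) | (total.dropna() > 80)]
        if len(bad):
            raise SchemaError(
                f"{path}: caps_total_{tp} outside 0-80 at row(s) {bad.index.tolist()}")
        cl_cols = [f"caps_{c}_{tp}" for c in CLUSTER_NAMES]
        if all(c in df.columns for c in cl_cols):
            sums = df[cl_cols].sum(axis=1, skipna=False)
            mism = df.index[(sums - total).abs() > 0].tolist()
            mism = [r for r in mism if not (np.isnan(sums[r]) and np.isnan(total[r]))]
            if mism:
                raise SchemaError(
                    f"{path}: cluster scores do not sum to caps_total_{tp} "
                    f"at row(s) {mism}")


def write_phenotype(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotype(df, path)
    df.to_csv(path, index=False)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_phenotype(df, path)
    return df


# -- atlas ---------------------------------------------------------------

def write_atlas(atlas: NetworkAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def read_atlas(path: str | Path) -> NetworkAtlas:
    df = pd.read_csv(path)
    _require_columns(df, ["node_id", "network"], path)
    if df["node_id"].duplicated().any():
        dup = df["node_id"][df["node_id"].duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate node_id(s) {dup}")
    return NetworkAtlas.from_frame(df)


# -- results JSON --------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(results: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=1))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# -- cohort round trip ---------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 per_scan: bool = False) -> dict[str, Path]:
    """Write a synthetic cohort in the pipeline's input formats.

    Always writes the averaged edges table, phenotype, atlas and ground
    truth; with ``per_scan`` also one connectome matrix per subject-scan
    plus a manifest (slower, larger, exercises the connectome stage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.csv",
        "phenotype": out / "phenotype.csv",
        "atlas": out / "atlas.csv",
        "truth": out / "ground_truth.json",
    }
    write_edges_table(cohort.subject_ids, cohort.edges, paths["edges"])
    write_phenotype(cohort.phenotype, paths["phenotype"])
    write_atlas(cohort.atlas, paths["atlas"])
    write_results({
        "planted_edges": cohort.truth.planted_edges,
        "effects": cohort.truth.effects,
        "target_networks": list(cohort.truth.target_networks),
        "classes": list(cohort.truth.classes),
        "seed": cohort.seed,
    }, paths["truth"])
    if per_scan:
        from .connectome import devectorize
        scan_dir = out / "connectomes"
        scan_dir.mkdir(exist_ok=True)
        rows = []
        n_nodes = len(cohort.atlas.node_ids)
        for s, sid in enumerate(cohort.subject_ids):
            for scan in range(cohort.scan_edges.shape[1]):
                c = devectorize(cohort.scan_edges[s, scan], n_nodes, sid)
                c.node_ids = cohort.atlas.node_ids
                rel = f"connectomes/{sid}_scan{scan}.csv"
                write_connectome(c, out / rel)
                rows.append({"subject_id": sid, "scan_label": f"scan{scan}",
                             "path": rel, "valid": True, "kind": "connectome"})
        paths["manifest"] = out / "manifest.csv"
        write_manifest(pd.DataFrame(rows), paths["manifest"])
    return paths
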