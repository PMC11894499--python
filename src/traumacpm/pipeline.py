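"""End-to-end pipeline: data assembly, per-timepoint CPM, significance,
cluster models, virtual lesions, and a provenance-stamped results bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cpm, inference, io, networks, report

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; echoed into every artifact."""

    phenotype: str
    atlas: str
    out_dir: str
    edges: str | None = None          # cohort edges table ...
    manifest: str | None = None       # ... or a manifest of raw scans
    target: str = "1m"                # timepoint: 1m | 6m | 14m
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    k: int = 10
    repeats: int = 100
    n_perm: int = 1000
    perm_repeats: int = 10
    seed: int = 0
    variant: str = "combined"
    consensus: float = 1.0
    run_lesion: bool = True
    run_clusters: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.edges is None and self.manifest is None:
            raise ValueError("config needs either an edges table or a manifest")
        for name in ("phenotype", "atlas"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config: {name} file not found: {p}")
        if self.run_lesion and self.atlas is None:
            raise ValueError("lesion analysis requested but no atlas given")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def covariate_matrix(phenotype: pd.DataFrame, covariates,
                     target: str) -> np.ndarray:
    """Covariate columns, with 1-month severity appended for follow-up targets."""
    cols = list(covariates)
    if target in ("6m", "14m") and "caps_total_1m" not in cols:
        cols = cols + ["caps_total_1m"]
    if not cols:
        return np.empty((len(phenotype), 0))
    return phenotype[cols].to_numpy(float)


def assemble(edges: np.ndarray, phenotype: pd.DataFrame, target: str,
             covariates=DEFAULT_COVARIATES, outcome: str = "total"
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rows modeled for a target timepoint: subjects with a non-missing
    outcome.  Returns (kept_index, edges, y, X)."""
    col = f"caps_{outcome}_{target}"
    if col not in phenotype.columns:
        raise ValueError(f"phenotype has no column {col}")
    keep = phenotype[col].notna().to_numpy()
    X = covariate_matrix(phenotype, covariates, target)
    return (np.flatnonzero(keep), edges[keep],
            phenotype.loc[keep, col].to_numpy(float), X[keep])


def run_pipeline(config: RunConfig) -> dict:
    """Execute connectome -> CPM -> permutation -> clusters -> lesion -> report.

    Returns the results bundle (also written to ``out_dir``); deterministic
    from ``config.seed``.
    """
    config.validate()
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.edges is not None:
        subject_ids, edges = io.read_edges_table(config.edges)
    else:
        log.info("building connectomes from manifest %s", config.manifest)
        manifest = io.read_manifest(config.manifest)
        from .connectome import vectorize
        conns = io.connectomes_from_manifest(manifest)
        subject_ids = [c.subject_id for c in conns]
        edges = np.vstack([vectorize(c) for c in conns])
    phen = io.read_phenotype(config.phenotype)
    phen = phen.set_index("subject_id").loc[subject_ids].reset_index()
    atlas = io.read_atlas(config.atlas)

    kept, e, y, X = assemble(edges, phen, config.target, config.covariates)
    log.info("target %s: %d modeled subjects, %d edges",
             config.target, len(kept), e.shape[1])

    sel_counts = np.zeros(e.shape[1], dtype=int)
    run = cpm.run_cv(e, y, X, k=config.k, repeats=config.repeats,
                     alpha=config.alpha, seed=config.seed,
                     variant=config.variant, selection_counts=sel_counts)
    median_rho = cpm.score(run)
    log.info("median rho = %.3f over %d repeats", median_rho, config.repeats)

    perm = inference.permutation_test(
        e, y, X, k=config.k, repeats=config.repeats, alpha=config.alpha,
        n_perm=config.n_perm, perm_repeats=config.perm_repeats,
        seed=config.seed, variant=config.variant, observed_run=run)
    log.info("permutation p = %.4g (%d shuffles)", perm.p_one_tailed,
             perm.n_perm)

    # consensus selection on the full modeled sample, for attribution maps
    r_full, p_full = cpm.partial_corr_edges(e, y, X)
    sel_full = cpm.select_edges(r_full, p_full, config.alpha)
    n_fits = config.k * config.repeats
    consensus = report.selection_frequency_summary(
        sel_counts, n_fits, config.consensus)

    bundle: dict = {
        "provenance": {"config": asdict(config), "config_hash": config.digest(),
                       "seed": config.seed, "version": __version__},
        "cpm": {"target": config.target, "n_subjects": int(len(kept)),
                "median_rho": median_rho,
                "rho_per_repeat": run.rho_per_repeat,
                "n_pos_edges_full_sample": sel_full.n_pos,
                "n_neg_edges_full_sample": sel_full.n_neg,
                "selection_frequency": sel_counts / n_fits,
                "consensus": consensus},
        "permutation": {"observed": perm.observed, "p": perm.p_one_tailed,
                        "n_perm": perm.n_perm,
                        "null_rhos": perm.null_rhos},
    }
    preds = pd.DataFrame({
        "subject_id": [subject_ids[i] for i in kept],
        "observed": y,
        "predicted_median": np.median(run.predictions, axis=0),
    })
    preds.to_csv(out_dir / "predictions.csv", index=False)

    if config.run_clusters:
        scores = {c: phen.loc[kept, f"caps_{c}_{config.target}"].to_numpy(float)
                  for c in inference.CLUSTERS}
        bundle["clusters"] = inference.cluster_models(
            e, scores, X, k=config.k, repeats=config.repeats,
            alpha=config.alpha, n_perm=config.n_perm,
            perm_repeats=config.perm_repeats, seed=config.seed,
            variant=config.variant)
        pd.DataFrame(bundle["clusters"]).T.rename_axis("cluster").to_csv(
            out_dir / "clusters.csv")

    if config.run_lesion:
        n_nodes = len(atlas.node_ids)
        lesion = networks.run_lesion_cpm(
            e, y, atlas, X, k=config.k, repeats=config.repeats,
            alpha=config.alpha, seed=config.seed, variant=config.variant,
            whole_brain_run=run)
        bundle["lesion"] = {
            "whole_brain_median": lesion.whole_brain_median,
            "driving_networks": lesion.driving_networks,
            "per_network": {net: d["median_rho"]
                            for net, d in lesion.per_network.items()},
        }
        for sign, mask in (("positive", sel_full.pos_mask),
                           ("negative", sel_full.neg_mask)):
            deg = networks.degree_centrality(mask, n_nodes)
            pd.DataFrame({"node_id": atlas.node_ids, "degree": deg}).to_csv(
                out_dir / f"degree_{sign}.csv", index=False)
            raw, norm = networks.network_contribution(mask, atlas)
            raw.to_csv(out_dir / f"contribution_{sign}_counts.csv")
            norm.to_csv(out_dir / f"contribution_{sign}_density.csv")
        bundle["degree_files"] = ["degree_positive.csv", "degree_negative.csv"]

    bundle["elapsed_s"] = round(time.time() - t0, 3)
    io.write_results(bundle, out_dir / "results.json")
    return bundle
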