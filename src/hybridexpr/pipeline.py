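"""Orchestration of the three analyses behind the CLI.

Species comparison (parentA vs parentB per zone, with a DET-percentage
summary row per comparison), hybrid-zone inheritance classification
(three pairwise comparisons per zone, with a mode-count summary), and
the edaphic association chain (soil PCA
-> PC1 predictor -> ridge LFMM -> GIF-calibrated tests -> elim-KS
enrichment with redundancy reduction).  All outputs are plain TSV/JSON;
every threshold actually applied is logged and recorded in the run
metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import DataError, RunConfig
from .diffexpr import ComparisonSpec, DEResult, run_exact_de
from .enrichment import elim_ks, propagate_annotations, reduce_redundancy
from .envassoc import association_tests, fit_lfmm_ridge, gif_calibrate, soil_pca
from .inheritance import classify_zone
from .normalization import normalize

logger = logging.getLogger("hybridexpr")


def _load_expression(cfg: RunConfig):
    cm = io.read_counts(cfg.counts, cfg.lengths)
    meta = io.read_metadata(cfg.metadata)
    missing = set(meta["sample"]) - set(cm.sample_ids)
    if missing:
        raise DataError(f"metadata samples absent from counts: {sorted(missing)}")
    return cm, meta


def _zone_samples(meta: pd.DataFrame, zone: str, taxon: str) -> list[str]:
    sel = meta[(meta["zone"] == zone) & (meta["taxon"] == taxon)]
    return list(sel["sample"])


def _pair_spec(
    meta: pd.DataFrame, zone: str, taxon_a: str, taxon_b: str, cfg: RunConfig
) -> ComparisonSpec:
    group_a = _zone_samples(meta, zone, taxon_a)
    group_b = _zone_samples(meta, zone, taxon_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError(
            f"zone {zone!r} needs >= 2 samples of {taxon_a!r} and {taxon_b!r}"
        )
    return ComparisonSpec(
        group_a=group_a,
        group_b=group_b,
        label=f"{taxon_a} vs {taxon_b} in {zone}",
        min_total_count=cfg.min_total_count,
    )


def _run_de(cm, spec, cfg: RunConfig) -> DEResult:
    logger.info(
        "DE %s: fdr_max=%g min_abs_log2fc=%g min_total_count=%d",
        spec.label, cfg.fdr_max, cfg.min_abs_log2fc, cfg.min_total_count,
    )
    de = run_exact_de(
        cm, spec, fdr_max=cfg.fdr_max, min_abs_log2fc=cfg.min_abs_log2fc
    )
    logger.info(
        "DE %s: %d expressed, %d DETs (%.2f%%), dispersion=%.4f",
        spec.label, de.n_expressed, de.n_det, de.pct_det, de.dispersion,
    )
    return de


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def summary_frame(results: list[DEResult]) -> pd.DataFrame:
    """Per-comparison summary with a rendered percentage column."""
    rows = []
    for de in results:
        row = de.summary_row()
        row["det_display"] = f"{de.n_det} ({de.pct_det:.2f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def run_species_comparison(cfg: RunConfig) -> pd.DataFrame:
    """parentA vs parentB differential expression in every zone."""
    cm, meta = _load_expression(cfg)
    out = _outdir(cfg)
    results = []
    for zone in meta["zone"].unique():
        spec = _pair_spec(meta, zone, "parentA", "parentB", cfg)
        de = _run_de(cm, spec, cfg)
        de.table.to_csv(
            out / f"de_{zone}_parentA_vs_parentB.tsv", sep="\t", index=False
        )
        results.append(de)
    summary = summary_frame(results)
    summary.to_csv(out / "species_comparison_summary.tsv", sep="\t", index=False)
    return summary


def run_hybrid_zone(cfg: RunConfig, zone: str) -> tuple[pd.DataFrame, pd.Series]:
    """Three pairwise comparisons and inheritance-mode accounting."""
    cm, meta = _load_expression(cfg)
    taxa = set(meta.loc[meta["zone"] == zone, "taxon"])
    if not {"parentA", "parentB", "hybrid"}.issubset(taxa):
        raise DataError(f"zone {zone!r} lacks a taxon: has {sorted(taxa)}")
    de_ab = _run_de(cm, _pair_spec(meta, zone, "parentA", "parentB", cfg), cfg)
    de_ah = _run_de(cm, _pair_spec(meta, zone, "parentA", "hybrid", cfg), cfg)
    de_bh = _run_de(cm, _pair_spec(meta, zone, "parentB", "hybrid", cfg), cfg)
    calls, summary = classify_zone(de_ab, de_ah, de_bh)
    out = _outdir(cfg)
    calls.to_csv(out / f"inheritance_calls_{zone}.tsv", sep="\t", index=False)
    summary.rename_axis("mode").to_frame("count").to_csv(
        out / f"inheritance_summary_{zone}.tsv", sep="\t"
    )
    logger.info("inheritance %s: %s", zone, summary.to_dict())
    return calls, summary


def run_env_association(cfg: RunConfig, zone: str) -> dict:
    """Edaphic association and enrichment for one hybrid zone."""
    cm, meta = _load_expression(cfg)
    if cfg.soil is None:
        raise DataError("env association needs a soil table")
    soil = io.read_soil(cfg.soil)
    zone_samples = list(meta.loc[meta["zone"] == zone, "sample"])
    if not zone_samples:
        raise DataError(f"no samples in zone {zone!r}")
    missing = [s for s in zone_samples if s not in soil.index]
    if missing:
        raise DataError(f"soil table lacks sites for samples: {missing[:5]}")
    soil_zone = soil.loc[zone_samples]

    # edaphic predictor: PC1 of the standardized soil panel
    pca = soil_pca(soil_zone, standardize=True)
    x = pca.pc1.to_numpy()

    # response: log2(FPKM + 1) of the zone's DET transcripts
    de_ab = _run_de(cm, _pair_spec(meta, zone, "parentA", "parentB", cfg), cfg)
    det_ids = list(de_ab.table.loc[de_ab.table["is_det"], "transcript"])
    if not det_ids:
        raise DataError(f"no DETs to associate in zone {zone!r}")
    sub = cm.subset_samples(zone_samples)
    norm = normalize(sub, center_rows=False)
    idx = [sub.transcript_ids.index(t) for t in det_ids]
    y = norm.log_expression[idx].T  # samples x transcripts

    logger.info(
        "LFMM %s: K=%d lambda=%g alpha=%g on %d DETs, %d samples",
        zone, cfg.lfmm_k, cfg.ridge_lambda, cfg.alpha, len(det_ids), len(zone_samples),
    )
    fit = fit_lfmm_ridge(y, x, K=cfg.lfmm_k, ridge_lambda=cfg.ridge_lambda)
    z, raw_p = association_tests(y, x, fit.U)
    gif, cal_p, significant = gif_calibrate(z, alpha=cfg.alpha)
    logger.info("LFMM %s: lambda_GIF=%.3f, %d significant", zone, gif,
                int(significant.sum()))
    assoc = pd.DataFrame(
        {
            "transcript": det_ids,
            "effect": fit.B[:, 0],
            "z": z,
            "raw_p": raw_p,
            "calibrated_p": cal_p,
            "significant": significant,
        }
    )
    out = _outdir(cfg)
    assoc.to_csv(out / f"association_{zone}.tsv", sep="\t", index=False)
    pca.scores.rename_axis("site").to_csv(out / f"soil_pca_scores_{zone}.tsv", sep="\t")
    pca.loadings.rename_axis("variable").to_csv(
        out / f"soil_pca_loadings_{zone}.tsv", sep="\t"
    )

    enrich = None
    if cfg.go_edges is not None and cfg.annotations is not None:
        dag = io.read_go(cfg.go_edges)
        ann = propagate_annotations(dag, io.read_annotations(cfg.annotations))
        scores = dict(zip(assoc["transcript"], assoc["calibrated_p"]))
        scores = {g: s for g, s in scores.items() if g in ann.direct}
        if scores:
            enrich = elim_ks(
                scores, ann, dag,
                elim_cutoff=cfg.elim_cutoff, min_genes=cfg.min_genes,
            )
            sig = enrich[enrich["elim_p"] < cfg.alpha]
            enrich = enrich.merge(
                reduce_redundancy(
                    sig, ann, dag, sim_threshold=cfg.sim_threshold
                )[["term", "representative"]],
                on="term", how="left",
            )
            rep = enrich["representative"]
            enrich["representative"] = rep.where(rep.notna(), False).astype(bool)
            enrich.to_csv(out / f"enrichment_{zone}.tsv", sep="\t", index=False)

    run_meta = {
        "zone": zone,
        "seed": cfg.seed,
        "lfmm_k": cfg.lfmm_k,
        "ridge_lambda": cfg.ridge_lambda,
        "alpha": cfg.alpha,
        "fdr_max": cfg.fdr_max,
        "min_abs_log2fc": cfg.min_abs_log2fc,
        "elim_cutoff": cfg.elim_cutoff,
        "sim_threshold": cfg.sim_threshold,
        "lambda_gif": gif,
        "n_dets": len(det_ids),
        "n_significant": int(significant.sum()),
    }
    with open(out / f"run_metadata_{zone}.json", "w") as fh:
        json.dump(run_meta, fh, indent=2)
    return {
        "association": assoc,
        "gif": gif,
        "pca": pca,
        "enrichment": enrich,
        "metadata": run_meta,
    }
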