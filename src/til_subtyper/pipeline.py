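"""End-to-end orchestration: simulate -> gate -> features -> cluster ->
score -> tcr -> report.

A run directory receives every stage's outputs plus ``manifest.json``
(config hash, seed, stage list, per-file checksums).  One run seed fans out
to per-stage child seeds through ``numpy.random.SeedSequence`` so stages
reproduce identically in isolation.  The synthetic-truth channel is written
under ``truth/`` for external comparison only; no analysis stage reads it —
downstream grouping uses the predicted subtype labels from the clustering
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import gating, outcomes, subtyping, synthetic_data, tcr, transcriptome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "gate", "features", "cluster", "score", "tcr", "report")

_FACTOR_CONTRASTS = [
    ("Age", "Age", "<65", ">=65"),
    ("Gender", "Gender", "female", "male"),
    ("pT", "pT", "1-2", "3-4"),
    ("ly", "ly", "ly0", "ly1"),
    ("N", "N", "0", "1-3"),
    ("STAS", "STAS", "0", "1"),
    ("Stage", "Stage", "I-II", "III-IV"),
    ("Differentiation", "Differentiation", "well-moderate", "poor"),
    ("Surgical_margin", "Surgical_margin", "negative", "positive"),
    ("TIL_CD8_Myeloid", "subtype", "CD8", "Myeloid"),
    ("TIL_CD8_Cold", "subtype", "CD8", "Cold"),
]

_SIGNATURE_SETS = {
    "cd8_chemokines": ["CCL5", "CXCL9", "CXCL11"],
    "ifng": ["IFNG", "GZMB", "PRF1", "CD8A", "CD3E"],
    "type1_ifn": ["IFIT1", "IFIT3", "ISG15", "MX1", "OAS1"],
}


@dataclass
class RunConfig:
    outdir: str | Path
    template: str = "mini"
    seed: int = 0
    k: int = 3
    feature_preset: str = "fig2"
    clade_preset: str = "fig1g_23"
    min_umi: int = tcr.DEFAULT_MIN_UMI
    selection_alpha: float = 0.05
    umi_depth: int = 10_000
    write_events: bool = False
    gating_config: str | Path | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["gating_config"] = (
            None if self.gating_config is None else str(self.gating_config)
        )
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the run seed."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages into ``cfg.outdir``; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = (
        gating.load_gating_config(cfg.gating_config)
        if cfg.gating_config
        else gating.default_gating_tree()
    )
    stages_done: list[str] = []
    files: dict[str, str] = {}

    def record(path: Path) -> None:
        files[str(path.relative_to(outdir))] = _sha256(path)

    # --- simulate ------------------------------------------------------
    logger.info("stage simulate: template=%s", cfg.template)
    spec = synthetic_data.default_cohort_spec(cfg.template)
    spec.seed = _stage_seed(cfg.seed, "simulate")
    cohort, truth = synthetic_data.simulate_cohort(spec, tree)
    truth_dir = outdir / "truth"
    synthetic_data.write_cohort(cohort, truth_dir, include_events=False)
    tumor_truth = truth.labels[truth.labels["subtype"] != "none"]
    expr = synthetic_data.simulate_expression(
        tumor_truth["subtype"], seed=_stage_seed(cfg.seed, "expression")
    )
    clonotypes = synthetic_data.simulate_tcr(
        tumor_truth["subtype"], umi_depth=cfg.umi_depth,
        seed=_stage_seed(cfg.seed, "tcr"),
    )
    clinical = synthetic_data.simulate_clinical(
        tumor_truth["subtype"], seed=_stage_seed(cfg.seed, "clinical")
    )
    clinical = clinical.drop(columns=["subtype"])  # grouping comes from clustering
    expr.rename_axis("gene").to_csv(outdir / "expression_tpm.tsv", sep="\t")
    tcr.write_airr_tsv(clonotypes, outdir / "clonotypes.tsv")
    clinical.to_csv(outdir / "clinical.csv")
    masses = cohort.masses
    masses.rename_axis("sample_id").to_csv(outdir / "masses.csv")
    if cfg.write_events:
        synthetic_data.write_cohort(cohort, outdir, include_events=True)
    for f in ("expression_tpm.tsv", "clonotypes.tsv", "clinical.csv", "masses.csv"):
        record(outdir / f)
    stages_done.append("simulate")

    # --- gate ----------------------------------------------------------
    logger.info("stage gate: %d samples", len(cohort.samples))
    pcs = [gating.gate_events(ev, tree, rec.sample_id)
           for rec, ev in cohort.iter_events()]
    gating.write_counts_csv(pcs, outdir / "counts.csv")
    counts = gating.counts_wide(pcs)
    record(outdir / "counts.csv")
    stages_done.append("gate")

    # --- features ------------------------------------------------------
    fractions = feat.fraction_tables(counts, tree)
    fm_tumor = feat.build_feature_matrix(
        counts.loc[tumor_truth.index], masses.loc[tumor_truth.index],
        cfg.feature_preset, tree,
    )
    fm_tumor.rename_axis("sample_id").to_csv(outdir / "features.tsv", sep="\t")
    for name, table in fractions.items():
        table.rename_axis("sample_id").to_csv(outdir / f"{name}.csv")
        record(outdir / f"{name}.csv")
    record(outdir / "features.tsv")
    stages_done.append("features")

    # --- cluster -------------------------------------------------------
    dend = subtyping.ward_d2_linkage(subtyping.spearman_distance(fm_tumor))
    (outdir / "dendrogram.nwk").write_text(subtyping.to_newick(dend) + "\n")
    subtyping.merge_table(dend).to_csv(outdir / "merges.tsv", sep="\t", index=False)
    record(outdir / "dendrogram.nwk")
    record(outdir / "merges.tsv")
    groups = subtyping.cut_clusters(dend, cfg.k)
    if cfg.k == 3:
        labels = subtyping.label_subtypes(
            groups, counts.loc[groups.index], masses.loc[groups.index], tree
        )
    else:
        labels = groups.map(lambda g: f"cluster{g}").rename("subtype")
    labels.rename_axis("sample_id").to_csv(outdir / "labels.csv")
    record(outdir / "labels.csv")
    has_nat = (truth.labels["subtype"] == "none").any()
    if has_nat:
        fm_all = feat.build_feature_matrix(counts, masses, cfg.clade_preset, tree)
        clades = subtyping.cut_clusters(
            subtyping.ward_d2_linkage(subtyping.spearman_distance(fm_all)), 2
        )
        clades.map({1: "clade1", 2: "clade2"}).rename("clade").rename_axis(
            "sample_id"
        ).to_csv(outdir / "clades.csv")
        record(outdir / "clades.csv")
    stages_done.append("cluster")

    # --- score ---------------------------------------------------------
    scores = pd.DataFrame({
        name: transcriptome.signature_score(expr, genes)
        for name, genes in _SIGNATURE_SETS.items()
    })
    scores.join(labels, how="left").rename_axis("sample_id").to_csv(
        outdir / "signature_scores.csv"
    )
    immunogram = transcriptome.compute_immunogram(expr)
    immunogram.rename_axis("sample_id").to_csv(outdir / "immunogram.csv")
    record(outdir / "signature_scores.csv")
    record(outdir / "immunogram.csv")
    stages_done.append("score")

    # --- tcr -----------------------------------------------------------
    filtered = tcr.filter_clonotypes(clonotypes, cfg.min_umi)
    entropy = tcr.shannon_entropy(filtered)
    entropy.to_csv(outdir / "tcr_entropy.csv", index=False)
    record(outdir / "tcr_entropy.csv")
    stages_done.append("tcr")

    # --- report --------------------------------------------------------
    clin = clinical.join(labels, how="inner")
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    km = outcomes.km_logrank(clin)
    km["curves"].to_csv(report_dir / "km_curves.csv", index=False)
    km["pairwise"].to_csv(report_dir / "logrank_pairwise.csv", index=False)
    scan_features = pd.concat(
        [
            feat.density_table(
                counts.loc[clin.index,
                           feat.resolve_feature_set(cfg.feature_preset, tree)],
                masses.loc[clin.index],
            ).add_prefix("dens_"),
            fractions["pct_cd45"].loc[
                clin.index, feat.resolve_feature_set(cfg.feature_preset, tree)
            ].add_prefix("pct_"),
        ],
        axis=1,
    )
    cox = outcomes.cox_scan(scan_features, clin)
    cox.to_csv(report_dir / "cox_scan.csv")
    tables = {}
    for name, column, *_ in _FACTOR_CONTRASTS:
        if column == "subtype" or column not in clin.columns:
            continue
        tables[name] = pd.crosstab(clin[column], clin["subtype"]).to_numpy()
    fisher = outcomes.fisher_holm_scan(tables, seed=_stage_seed(cfg.seed, "fisher"))
    fisher.to_csv(report_dir / "fisher_scan.csv")
    try:
        mv = outcomes.multivariate_cox(
            _FACTOR_CONTRASTS, clin, selection_alpha=cfg.selection_alpha
        )
        mv.to_csv(report_dir / "cox_factors.csv")
    except ValueError as exc:  # rank deficiency is diagnostic, not fatal here
        logger.warning("multivariate Cox skipped: %s", exc)
        (report_dir / "cox_factors.csv").write_text(f"error,{exc}\n")
    for f in report_dir.iterdir():
        record(f)
    stages_done.append("report")

    manifest = {
        "seed": cfg.seed,
        "config": cfg.as_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.as_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": stages_done,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
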