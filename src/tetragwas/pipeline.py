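"""End-to-end orchestration of the bruising-GWAS workflow.

Stages: variant/sample filtering -> LD pruning -> population structure
(PCA, k-means/BIC, DAPC; optionally imported STRUCTURE memberships) ->
phenotype BLUEs and normalization -> the full 8-genetic-model x
6-population-setting GWAS grid with LOCO kinship -> inflation summary and
population-setting selection -> FDR and high-scoring marker extraction ->
optional DE integration -> HIDECAN data/plot.  A JSON manifest records
parameters, seeds and per-stage row counts so a run can be reproduced.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import geno, gwas, hidecan, ldprune, phenotype, popstructure

__all__ = ["PipelineConfig", "run_end_to_end", "summarize_inflation",
           "stage_seed", "kmeans_soft_membership"]


@dataclass
class PipelineConfig:
    """Configuration of a full run; paths may be None for optional stages."""

    geno_path: str | None = None            # dosage CSV or VCF
    pheno_path: str | None = None           # genotype,replicate,tuber,score
    de_path: str | None = None              # DE result table CSV
    candidates_path: str | None = None      # gene,chromosome,position,source
    layout_path: str | None = None          # chromosome lengths
    structure_memberships_path: str | None = None  # STRUCTURE output file
    out_dir: str = "results"
    seed: int = 0
    max_missing: float = 0.10
    min_qd: float = 2.0
    min_maf: float = 0.01
    prune_window_bp: int = 100_000
    prune_r2: float = 0.5
    n_pca_components: int = 10
    alpha: float = 0.05
    marker_min_score: float = 4.0
    models: tuple[str, ...] = gwas.GENETIC_MODELS
    hidecan_window_bp: int = 1_000_000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("pipeline config must set an explicit seed")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Expand the global seed into a per-stage seed by a counter scheme."""
    stages = ("filter", "prune", "structure", "phenotype", "gwas", "de",
              "hidecan", "simulate")
    idx = stages.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0]
               % (2 ** 31))


def kmeans_soft_membership(pca_scores: np.ndarray, k: int, seed: int,
                           samples: list[str]
                           ) -> popstructure.MembershipMatrix:
    """Distance-based soft k-means membership on PCA scores.

    Used as the second, admixture-style membership source when no external
    STRUCTURE output is supplied: posteriors come from squared distances to
    the k-means centroids under a common isotropic Gaussian.
    """
    from sklearn.cluster import KMeans
    x = np.asarray(pca_scores, dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    d2 = ((x[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
    labels = km.labels_
    within = np.mean([d2[i, labels[i]] for i in range(len(x))]) + 1e-12
    logp = -0.5 * d2 / within
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return popstructure.MembershipMatrix(
        samples=samples, groups=[f"S{j + 1}" for j in range(k)], probs=p)


def summarize_inflation(results: list[gwas.GwasResult]) -> pd.DataFrame:
    """Per-setting inflation factors across genetic models, plus the mean.

    Settings with missing models are averaged over the available ones and
    flagged in the ``incomplete`` column.
    """
    rows: dict[str, dict] = {}
    for r in results:
        rows.setdefault(r.setting, {})[r.model] = r.inflation_factor
    out = []
    for setting, vals in rows.items():
        rec = {"setting": setting, **vals}
        rec["mean"] = float(np.nanmean(list(vals.values())))
        rec["incomplete"] = len(vals) < len(gwas.GENETIC_MODELS)
        out.append(rec)
    return pd.DataFrame(out).set_index("setting")


def _load_genotypes(cfg: PipelineConfig) -> geno.GenotypeMatrix:
    path = cfg.geno_path
    if path is None:
        raise ValueError("geno_path is required")
    if path.endswith((".vcf", ".vcf.gz")):
        return geno.read_vcf_dosages(path)
    return geno.read_dosage_csv(path)


def run_end_to_end(cfg: PipelineConfig,
                   g: geno.GenotypeMatrix | None = None,
                   scores: pd.DataFrame | None = None,
                   de_table: pd.DataFrame | None = None,
                   candidates: pd.DataFrame | None = None,
                   layout: hidecan.ChromosomeLayout | None = None,
                   plot: bool = False) -> dict:
    """Execute the full workflow; returns the run manifest.

    Inputs may be passed in memory (as from the simulator) or read from the
    configured paths.  Results are written under ``cfg.out_dir``.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()}, "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts

    # --- load + filter -----------------------------------------------------
    if g is None:
        g = _load_genotypes(cfg)
    n_raw = g.n_markers
    g = geno.select_biallelic_het_snps(g)
    g, report = geno.apply_variant_filters(
        g, max_missing=cfg.max_missing, min_qd=cfg.min_qd,
        min_maf=cfg.min_maf)
    g = geno.apply_sample_filter(g, max_missing=cfg.max_missing)
    stage("filter", markers_in=n_raw, markers_out=g.n_markers,
          samples_out=g.n_samples, report=report)

    # --- prune -------------------------------------------------------------
    pres = ldprune.prune_genome(g, window_bp=cfg.prune_window_bp,
                                r2_threshold=cfg.prune_r2,
                                seed=stage_seed(cfg.seed, "prune"))
    g = g.select_markers_by_id(pres.retained)
    geno.write_dosage_csv(g, str(out / "pruned.csv"))
    stage("prune", markers_out=g.n_markers,
          markers_dropped=len(pres.dropped))

    # --- population structure ---------------------------------------------
    sseed = stage_seed(cfg.seed, "structure")
    n_comp = min(cfg.n_pca_components, g.n_samples - 1, g.n_markers)
    scores_pca, _ = popstructure.pca_dosage(g, n_comp)
    n_clusters, bic = popstructure.select_n_clusters(
        scores_pca, seed=sseed)
    n_clusters = max(n_clusters, 2)  # Q covariates need >= 2 groups
    assign = popstructure.kmeans_assign(scores_pca, n_clusters, seed=sseed)
    dapc = popstructure.dapc_fit(scores_pca, assign,
                                 n_pcs=min(n_comp, max(n_clusters - 1, 2)),
                                 sample_ids=g.samples)
    q_dapc = dapc.membership
    if cfg.structure_memberships_path:
        q_struct = popstructure.import_structure_memberships(
            cfg.structure_memberships_path)
    else:
        q_struct = kmeans_soft_membership(scores_pca, n_clusters,
                                          seed=sseed, samples=g.samples)
    kinship = popstructure.compute_kinship(
        g, loco=len(g.chromosomes) >= 2)
    stage("structure", n_clusters=int(n_clusters),
          q_source="structure-import" if cfg.structure_memberships_path
          else "kmeans-soft")

    # --- phenotype ---------------------------------------------------------
    if scores is None:
        if cfg.pheno_path is None:
            raise ValueError("phenotype scores required")
        scores = pd.read_csv(cfg.pheno_path)
    blues = phenotype.compute_blues(scores)
    normalized, lam = phenotype.yeo_johnson_standardize(
        blues["blue"].to_numpy())
    blues["normalized"] = normalized
    y = blues.set_index("genotype")["normalized"]
    mean_scores = phenotype.replicate_mean_scores(scores)
    groups = phenotype.classify_bruising_groups(mean_scores)
    blues["group"] = groups.reindex(blues["genotype"]).to_numpy()
    blues.to_csv(out / "phenotypes.csv", index=False)
    stage("phenotype", genotypes=len(blues), yeo_johnson_lambda=float(lam),
          low=int((groups == "low").sum()),
          high=int((groups == "high").sum()))

    # --- GWAS grid ---------------------------------------------------------
    settings = [
        gwas.PopulationSetting.naive(),
        gwas.PopulationSetting.k_only(),
        gwas.PopulationSetting.q_only(q_struct, "struct"),
        gwas.PopulationSetting.q_only(q_dapc, "dapc"),
        gwas.PopulationSetting.k_plus_q(q_struct, "struct"),
        gwas.PopulationSetting.k_plus_q(q_dapc, "dapc"),
    ]
    results: list[gwas.GwasResult] = []
    for setting in settings:
        for model in cfg.models:
            res = gwas.score_markers(g, y, model, setting, kinship,
                                     alpha=cfg.alpha)
            results.append(res)
    gwas_dir = out / "gwas"
    gwas_dir.mkdir(exist_ok=True)
    for r in results:
        tag = f"{r.setting}__{r.model}".replace("+", "_")
        r.table.to_csv(gwas_dir / f"{tag}.csv", index=False)
        with open(gwas_dir / f"{tag}.json", "w") as fh:
            json.dump({"setting": r.setting, "model": r.model,
                       "inflation_factor": r.inflation_factor,
                       "fdr_threshold": r.fdr_threshold}, fh)
    stage("gwas", n_result_sets=len(results),
          markers_scored=int(results[0].table["score"].notna().sum()))

    # --- inflation summary + setting selection -----------------------------
    infl = summarize_inflation(results)
    infl.to_csv(out / "inflation.csv")
    choice = gwas.select_population_setting(infl["mean"].to_dict())
    chosen = [r for r in results if r.setting == choice.name]
    stage("setting_selection", chosen=choice.name,
          mean_inflation=float(choice.mean_inflation),
          below_one=choice.below_one)

    # --- significant + high-scoring markers --------------------------------
    sig_ids: set = set()
    high_ids: set = set()
    for r in chosen:
        _, sig = gwas.fdr_score_threshold(r.pvalues, alpha=cfg.alpha)
        sig_ids.update(sig)
        high_ids.update(gwas.select_high_scoring(
            r.scores, min_score=cfg.marker_min_score))
    stage("significance", significant=len(sig_ids),
          high_scoring=len(high_ids))

    # --- DE integration (optional) -----------------------------------------
    if de_table is None and cfg.de_path:
        de_table = pd.read_csv(cfg.de_path)
    if de_table is not None:
        up, down, ambiguous = de_mod.significant_de(de_table,
                                                    alpha=cfg.alpha)
        stage("de", up=len(up), down=len(down), ambiguous=len(ambiguous))

    # --- HIDECAN -----------------------------------------------------------
    if candidates is None and cfg.candidates_path:
        candidates = pd.read_csv(cfg.candidates_path)
    if layout is None and cfg.layout_path:
        layout = hidecan.read_layout(cfg.layout_path)
    if layout is None:
        lengths = (g.markers.groupby("chromosome")["position"].max() * 1.05
                   ).astype(int).to_dict()
        layout = hidecan.ChromosomeLayout(labels=sorted(lengths),
                                          lengths=lengths)
    hdata = hidecan.build_hidecan_data(
        chosen, de_table, candidates, layout,
        marker_min_score=cfg.marker_min_score, de_alpha=cfg.alpha)
    hdata.to_csv(out / "hidecan.csv", index=False)
    coloc = hidecan.colocalization_windows(
        hdata, window_bp=cfg.hidecan_window_bp)
    coloc.to_csv(out / "colocalization.csv", index=False)
    if plot:
        hidecan.plot_hidecan(hdata, layout, str(out / "hidecan.svg"))
    stage("hidecan", rows=len(hdata), colocalization_regions=len(coloc))

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
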