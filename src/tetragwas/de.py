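"""Differential-expression integration and functional-class-scoring enrichment.

DE model fitting proper is consumed from upstream tools; this module
filters count tables, classifies significance, provides a lightweight
convenience DE test (Welch t on log2 median-of-ratios-normalized counts),
and implements the gage-style prototype two-sample t-test that contrasts a
gene set's mean score against a virtual random background set of the same
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "filter_low_expression",
    "significant_de",
    "simple_de_test",
    "fcs_enrichment",
    "read_gene_sets",
]

DE_COLUMNS = ["gene_id", "chromosome", "start", "end",
              "log2_fold_change", "p_value", "adjusted_p"]


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative integer counts with optional coordinates."""

    counts: pd.DataFrame
    coords: pd.DataFrame | None = None   # index gene, cols chromosome/start/end

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def filter_low_expression(x: ExpressionMatrix, min_count: int = 5,
                          max_low_samples: int = 4) -> ExpressionMatrix:
    """Drop genes with too many low-count samples.

    A gene is removed when the number of samples with count < ``min_count``
    exceeds ``max_low_samples`` (i.e. at least five low-count samples under
    the defaults).
    """
    low = (x.counts < min_count).sum(axis=1)
    keep = low <= max_low_samples
    coords = None if x.coords is None else x.coords.loc[
        x.coords.index.intersection(x.counts.index[keep])]
    return ExpressionMatrix(counts=x.counts.loc[keep], coords=coords)


def significant_de(de: pd.DataFrame, alpha: float = 0.05
                   ) -> tuple[list, list, list]:
    """Split strictly significant genes (adjusted p < alpha) by fold-change sign.

    Returns (up ids, down ids, ambiguous ids); a significant gene with
    log2 fold change exactly zero is reported as ambiguous.
    """
    sig = de[de["adjusted_p"] < alpha]
    up = sig.loc[sig["log2_fold_change"] > 0, "gene_id"].tolist()
    down = sig.loc[sig["log2_fold_change"] < 0, "gene_id"].tolist()
    ambiguous = sig.loc[sig["log2_fold_change"] == 0, "gene_id"].tolist()
    return up, down, ambiguous


def _size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios library-size factors."""
    logc = np.log(counts.to_numpy(dtype=float))
    with np.errstate(divide="ignore"):
        logc[np.isneginf(logc)] = np.nan
    log_geo = np.nanmean(logc, axis=1)
    usable = np.isfinite(log_geo)
    if usable.sum() == 0:
        tot = counts.sum(axis=0).to_numpy(dtype=float)
        return tot / np.median(tot[tot > 0])
    ratios = logc[usable] - log_geo[usable, None]
    sf = np.exp(np.nanmedian(ratios, axis=0))
    sf = np.where(np.isfinite(sf) & (sf > 0), sf, 1.0)
    return sf


def simple_de_test(x: ExpressionMatrix, groups: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test per gene on log2 median-of-ratios-normalized counts.

    ``groups`` maps sample id to 'low'/'high'; log2FC is the high-minus-low
    difference of group means on the log2 scale.  Genes with zero variance
    in both groups get p = 1.  P-values are Benjamini-Hochberg adjusted.
    This is a plumbing convenience, not a negative-binomial DE model.
    """
    samples = [s for s in x.samples if s in groups.index]
    grp = groups.reindex(samples)
    low = [s for s in samples if grp[s] == "low"]
    high = [s for s in samples if grp[s] == "high"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need >= 2 samples per group")
    counts = x.counts[samples]
    sf = _size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    logn = np.log2(norm + 1.0)
    li = [samples.index(s) for s in low]
    hi = [samples.index(s) for s in high]
    a, b = logn[:, hi], logn[:, li]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "gene_id": x.genes,
        "log2_fold_change": lfc,
        "p_value": p,
        "adjusted_p": padj,
    })
    if x.coords is not None:
        out = out.merge(x.coords.reset_index().rename(
            columns={x.coords.index.name or "index": "gene_id"}),
            on="gene_id", how="left")
    return out.reset_index(drop=True)


def fcs_enrichment(gene_scores: pd.Series, sets: dict[str, list[str]],
                   alternative: str = "greater",
                   virtual_set: bool = False,
                   permutations: int = 0,
                   seed: int | None = None) -> pd.DataFrame:
    """Functional-class scoring with a prototype two-sample t-test.

    Per set of size m, the set's mean gene score is contrasted against the
    background (all scored genes outside the set) with a Welch t statistic,
    t = (mean_set - mean_bg) / sqrt(var_set/m + var_bg/n_bg), which is
    calibrated under random sets (null rejection rate ~ alpha).  With
    ``virtual_set=True`` the background variance term becomes var_bg/m —
    contrasting the set against a virtual random background set of the same
    size; this variant is deliberately conservative.  P-values use
    Welch-Satterthwaite degrees of freedom and are BH-adjusted across sets.
    ``permutations`` > 0 adds an empirical permutation p-value column for
    cross-checking.  Unscored set members are ignored (logged in the
    ``n_unscored`` column); sets with < 2 scored members are skipped.
    """
    scores = gene_scores.dropna()
    all_genes = set(scores.index)
    rng = np.random.default_rng(seed)
    rows = []
    for set_id, members in sets.items():
        members = list(dict.fromkeys(members))
        scored = [m for m in members if m in all_genes]
        n_unscored = len(members) - len(scored)
        if len(scored) < 2:
            rows.append({"set_id": set_id, "set_size": len(scored),
                         "n_unscored": n_unscored, "t_statistic": np.nan,
                         "p_value": np.nan, "skipped_reason": "too_few_scored"})
            continue
        sv = scores.loc[scored].to_numpy(dtype=float)
        bg = scores.drop(index=scored).to_numpy(dtype=float)
        m = len(sv)
        n_bg = m if virtual_set else len(bg)
        vs = sv.var(ddof=1)
        vb = bg.var(ddof=1)
        se2 = vs / m + vb / n_bg
        if se2 == 0:
            t = 0.0
            df = 2 * m - 2
        else:
            t = (sv.mean() - bg.mean()) / np.sqrt(se2)
            df = se2 ** 2 / ((vs / m) ** 2 / (m - 1)
                             + (vb / n_bg) ** 2 / (max(len(bg), 2) - 1))
        if alternative == "greater":
            p = float(stats.t.sf(t, df))
        elif alternative == "two-sided":
            p = float(2 * stats.t.sf(abs(t), df))
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        row = {"set_id": set_id, "set_size": m, "n_unscored": n_unscored,
               "t_statistic": float(t), "p_value": p, "skipped_reason": None}
        if permutations > 0:
            null = np.empty(permutations)
            pool = scores.to_numpy(dtype=float)
            for i in range(permutations):
                pick = rng.choice(len(pool), size=m, replace=False)
                mask = np.zeros(len(pool), bool)
                mask[pick] = True
                null[i] = pool[mask].mean() - pool[~mask].mean()
            observed = sv.mean() - bg.mean()
            row["perm_p_value"] = float(
                (1 + (null >= observed).sum()) / (1 + permutations))
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["adjusted_p"] = np.nan
    if ok.any():
        _, padj, _, _ = multipletests(out.loc[ok, "p_value"], method="fdr_bh")
        out.loc[ok, "adjusted_p"] = padj
    return out


def read_gene_sets(path: str) -> dict[str, list[str]]:
    """Read gene sets from GMT (tab-separated) or two-column CSV."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t" in first:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets[parts[0]] = [p for p in parts[2:] if p]
        else:
            df = pd.read_csv(fh)
            for set_id, grp in df.groupby(df.columns[0]):
                sets[str(set_id)] = grp[df.columns[1]].astype(str).tolist()
    return sets
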