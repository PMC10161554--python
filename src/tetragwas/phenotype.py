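"""Phenotype processing: genotype BLUEs, normalization and bruising groups.

Bruising is scored visually on a 0 (no visible bruising) to 5 (extensive
bruise) scale for several tubers per biological replicate per genotype.
Per-genotype phenotypic values are the fixed-effect estimates (BLUEs) from

    y_ijk = mu + G_i + b_(i)j + e_ijk

with genotype G fixed, replicate b nested within genotype and random, and
residual e.  BLUEs are then normalized with a standardized Yeo-Johnson
transformation before GWAS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "validate_scores",
    "compute_blues",
    "gls_blues",
    "yeo_johnson_standardize",
    "classify_bruising_groups",
    "replicate_mean_scores",
]

SCORE_COLUMNS = ["genotype", "replicate", "tuber", "score"]


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Check the (genotype, replicate, tuber, score) table of bruising scores."""
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table lacks columns {missing}")
    s = scores["score"].dropna()
    if ((s < 0) | (s > 5)).any():
        raise ValueError("bruising scores must lie in [0, 5]")
    return scores


def _design(scores: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    y = scores["score"].to_numpy(dtype=float)
    genos = list(pd.unique(scores["genotype"]))
    gidx = scores["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    X = np.zeros((len(y), len(genos)))
    X[np.arange(len(y)), gidx] = 1.0  # cell-means coding: beta_i = mu + G_i
    rep_key = (scores["genotype"].astype(str) + "//"
               + scores["replicate"].astype(str))
    reps = list(pd.unique(rep_key))
    ridx = rep_key.map({r: i for i, r in enumerate(reps)}).to_numpy()
    Z = np.zeros((len(y), len(reps)))
    Z[np.arange(len(y)), ridx] = 1.0
    return y, X, Z, genos


def gls_blues(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
              ratio: float) -> np.ndarray:
    """Generalized least squares under V = I + ratio * ZZ^T."""
    V = np.eye(len(y)) + ratio * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def _reml_neg_loglik(log_ratio: float, y: np.ndarray, X: np.ndarray,
                     eigvals: np.ndarray, U: np.ndarray) -> float:
    ratio = np.exp(log_ratio)
    w = 1.0 / (ratio * eigvals + 1.0)
    ys = U.T @ y
    Xs = U.T @ X
    Xw = Xs * w[:, None]
    XtVX = Xs.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ ys)
    r = ys - Xs @ beta
    rss = float(r @ (w * r))
    n, p = X.shape
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    logdet_v = float(-np.sum(np.log(w)))
    # saturated model (n == p): the profiled residual term vanishes
    rss_term = (n - p) * np.log(rss) if n > p and rss > 0 else 0.0
    return 0.5 * (rss_term + logdet_v + logdet_xvx)


def compute_blues(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype BLUEs from the replicate-nested mixed model.

    The replicate-to-residual variance ratio is profiled out of the REML
    likelihood and maximized by bounded scalar optimization; the returned
    frame has columns ``genotype`` and ``blue``.  Genotypes with no
    non-missing score are excluded with a warning.
    """
    scores = validate_scores(scores).copy()
    empty = (scores.groupby("genotype")["score"]
             .apply(lambda s: s.isna().all()))
    dropped = empty[empty].index.tolist()
    if dropped:
        warnings.warn(f"genotypes with all-missing scores excluded: {dropped}")
        scores = scores[~scores["genotype"].isin(dropped)]
    scores = scores.dropna(subset=["score"]).reset_index(drop=True)
    genos_all = pd.unique(scores["genotype"])
    if len(genos_all) < 2:
        raise ValueError("compute_blues requires at least two genotypes")
    y, X, Z, genos = _design(scores)
    ZZt = Z @ Z.T
    eigvals, U = np.linalg.eigh(ZZt)
    eigvals = np.clip(eigvals, 0.0, None)

    def obj(lr: float) -> float:
        return _reml_neg_loglik(lr, y, X, eigvals, U)

    res = minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    ratio = float(np.exp(res.x))
    # boundary check: no replicate variance
    if obj(-30.0) <= res.fun:
        ratio = 0.0
    beta = gls_blues(y, X, Z, ratio)
    return pd.DataFrame({"genotype": genos, "blue": beta})


def yeo_johnson_standardize(values: np.ndarray
                            ) -> tuple[np.ndarray, float]:
    """Yeo-Johnson transform with ML lambda, then center/scale to (0, 1).

    The profile Gaussian log-likelihood is maximized over lambda in
    [-2, 2]; the standardized output has mean 0 and sd 1 (ddof=1).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 3 finite values")
    if np.std(x) == 0:
        raise ValueError("constant input cannot be standardized")

    res = minimize_scalar(lambda lam: -stats.yeojohnson_llf(lam, x),
                          bounds=(-2.0, 2.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(res.x)
    # prefer the identity on a flat likelihood (ties broken toward 1)
    if -stats.yeojohnson_llf(1.0, x) <= res.fun + 1e-10:
        lam = 1.0
    t = stats.yeojohnson(x, lmbda=lam)
    z = (t - t.mean()) / t.std(ddof=1)
    return z, lam


def replicate_mean_scores(scores: pd.DataFrame) -> pd.Series:
    """Mean score over the tubers of each genotype (across replicates)."""
    validate_scores(scores)
    return scores.groupby("genotype")["score"].mean()


def classify_bruising_groups(mean_scores: pd.Series, low_max: float = 1.0,
                             high_min: float = 2.0) -> pd.Series:
    """Classify genotypes into low (<= low_max), high (>= high_min) or excluded."""
    def one(v: float) -> str:
        if v <= low_max:
            return "low"
        if v >= high_min:
            return "high"
        return "excluded"

    return mean_scores.map(one).rename("group")
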