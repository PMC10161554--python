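"""Mixed-model GWAS for tetraploid dosages.

The per-marker model is

    y = X beta + S tau + Q v + Z u + e,   Var(u) = sg2 K,  Var(e) = se2 I

where S encodes the marker dosage under one of eight genetic models and the
population setting decides which of K (realized relationship matrix, with
leave-one-chromosome-out variants) and Q (subpopulation membership
covariates) enter the model.  Variance components are estimated once per
(setting, chromosome) under the null by REML on the eigenbasis of K and
reused for every marker (the P3D approximation); each marker is then tested
with a GLS F-test of its encoded columns, and the marker score is
-log10(p).  Diagnostics include the genomic inflation factor, a
Benjamini-Hochberg score threshold and cross-model score correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .geno import GenotypeMatrix
from .popstructure import KinshipSet, MembershipMatrix

__all__ = [
    "GENETIC_MODELS",
    "POPULATION_SETTINGS",
    "PopulationSetting",
    "NullModelFit",
    "GwasResult",
    "encode_dosage",
    "fit_null_model",
    "score_markers",
    "inflation_factor",
    "select_population_setting",
    "fdr_score_threshold",
    "select_high_scoring",
    "score_correlation_matrix",
]

GENETIC_MODELS = (
    "general", "additive", "1-dom-ref", "1-dom-alt",
    "2-dom-ref", "2-dom-alt", "diplo-general", "diplo-additive",
)

POPULATION_SETTINGS = ("naive", "K", "Q_struct", "Q_dapc",
                       "K+Q_struct", "K+Q_dapc")

_DIPLO_ADDITIVE_MAP = np.array([0.0, 1.0, 1.0, 1.0, 2.0])


def encode_dosage(model: str, dosage) -> np.ndarray:
    """Encode dosages 0..4 into design column(s) for a genetic model.

    Returns an (n, q) array.  The additive model uses the dosage as given
    (so posterior-mean dosages stay fractional); all other models are
    defined on integer dosage classes and round to the nearest integer
    first.  For the general model, indicator columns contrast each observed
    dosage level against the lowest observed level.
    """
    d = np.atleast_1d(np.asarray(dosage, dtype=float))
    with np.errstate(invalid="ignore"):
        if np.any((d < 0) | (d > 4)):
            raise ValueError("dosage outside [0, 4]")
    if model == "additive":
        return d[:, None]
    r = np.rint(d)
    if model == "1-dom-ref":
        return (r <= 3).astype(float)[:, None]
    if model == "1-dom-alt":
        return (r >= 1).astype(float)[:, None]
    if model == "2-dom-ref":
        return (r <= 2).astype(float)[:, None]
    if model == "2-dom-alt":
        return (r >= 2).astype(float)[:, None]
    if model == "diplo-additive":
        out = np.where(np.isnan(r), np.nan, _DIPLO_ADDITIVE_MAP[
            np.nan_to_num(r, nan=0.0).astype(int)])
        return out[:, None]
    if model == "diplo-general":
        het = ((r >= 1) & (r <= 3)).astype(float)
        hom_alt = (r == 4).astype(float)
        return np.column_stack([het, hom_alt])
    if model == "general":
        levels = np.unique(r[~np.isnan(r)])
        cols = [(r == lv).astype(float) for lv in levels[1:]]
        if not cols:
            return np.zeros((len(r), 1))
        return np.column_stack(cols)
    raise ValueError(f"unknown genetic model {model!r}")


@dataclass
class PopulationSetting:
    """How population structure enters the model.

    ``uses_kinship`` switches Var(u) from the identity ("naive"/Q-only) to
    the realized relationship matrix; ``membership`` adds the posterior
    subpopulation probabilities as fixed covariates (last column dropped,
    as rows sum to one and would be collinear with the intercept).
    """

    name: str
    uses_kinship: bool = False
    membership: MembershipMatrix | None = None

    @classmethod
    def naive(cls) -> "PopulationSetting":
        return cls("naive", uses_kinship=False, membership=None)

    @classmethod
    def k_only(cls) -> "PopulationSetting":
        return cls("K", uses_kinship=True, membership=None)

    @classmethod
    def q_only(cls, membership: MembershipMatrix,
               source: str = "struct") -> "PopulationSetting":
        return cls(f"Q_{source}", uses_kinship=False, membership=membership)

    @classmethod
    def k_plus_q(cls, membership: MembershipMatrix,
                 source: str = "struct") -> "PopulationSetting":
        return cls(f"K+Q_{source}", uses_kinship=True, membership=membership)

    def covariates(self, samples: list[str]) -> np.ndarray:
        """Intercept plus membership columns (last dropped)."""
        cols = [np.ones(len(samples))]
        if self.membership is not None:
            q = self.membership.to_frame().reindex(samples)
            if q.isna().any().any():
                missing = q.index[q.isna().any(axis=1)].tolist()
                raise ValueError(f"membership missing for samples {missing}")
            cols.extend(q.to_numpy().T[:-1])
        return np.column_stack(cols)


@dataclass
class NullModelFit:
    """Variance components and the spectral basis of the working covariance."""

    sigma_g2: float
    sigma_e2: float
    ratio: float                 # sigma_g2 / sigma_e2
    beta: np.ndarray             # fixed effects on the original scale
    eigvals: np.ndarray          # eigenvalues of K
    U: np.ndarray                # eigenvectors of K
    weights: np.ndarray          # 1 / (ratio * eigvals + 1)
    chromosome: str | None = None
    setting: str = "naive"


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0)).tolist()
        raise ValueError(f"singular covariate matrix: collinear columns {bad}")


def fit_null_model(y: np.ndarray, setting: PopulationSetting,
                   kinship: KinshipSet | None, samples: list[str],
                   chromosome: str | None = None) -> NullModelFit:
    """REML fit of the no-marker model on the eigenbasis of K.

    For kinship settings the LOCO matrix of ``chromosome`` is used when
    available.  The genetic-to-residual variance ratio is profiled and
    maximized by bounded scalar optimization; for settings without kinship
    the covariance collapses to the identity (ratio 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = setting.covariates(samples)
    _check_full_rank(X)
    if setting.uses_kinship:
        if kinship is None:
            raise ValueError(f"setting {setting.name} requires a kinship matrix")
        K = kinship.for_chromosome(chromosome)
    else:
        K = np.eye(n)
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X
    p = X.shape[1]

    def negloglik(log_ratio: float) -> float:
        ratio = math.exp(log_ratio)
        w = 1.0 / (ratio * eigvals + 1.0)
        Xw = Xs * w[:, None]
        XtVX = Xs.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (w * r))
        _, logdet_xvx = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * math.log(rss)
                      - float(np.sum(np.log(w))) + logdet_xvx)

    if setting.uses_kinship:
        res = minimize_scalar(negloglik, bounds=(-12.0, 12.0),
                              method="bounded", options={"xatol": 1e-8})
        ratio = float(math.exp(res.x))
        if negloglik(-30.0) <= res.fun:  # boundary: no genetic variance
            ratio = 0.0
    else:
        ratio = 0.0
    w = 1.0 / (ratio * eigvals + 1.0)
    Xw = Xs * w[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ beta
    sigma_e2 = float(r @ (w * r)) / (n - p)
    return NullModelFit(sigma_g2=ratio * sigma_e2, sigma_e2=sigma_e2,
                        ratio=ratio, beta=beta, eigvals=eigvals, U=U,
                        weights=w, chromosome=chromosome,
                        setting=setting.name)


@dataclass
class GwasResult:
    """Per-marker scores for one (genetic model, population setting) pair."""

    model: str
    setting: str
    table: pd.DataFrame          # marker, chromosome, position, score, ...
    inflation_factor: float = float("nan")
    fdr_threshold: float = float("nan")
    alpha: float = 0.05

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("marker")["score"]

    @property
    def pvalues(self) -> pd.Series:
        t = self.table.dropna(subset=["pvalue"])
        return t.set_index("marker")["pvalue"]


def _marker_encoding(model: str, col: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, then encode."""
    if np.isnan(col).any():
        m = np.nanmean(col)
        if np.isnan(m):
            m = 0.0
        col = np.where(np.isnan(col), m, col)
    return encode_dosage(model, col)


def score_markers(g: GenotypeMatrix, y: pd.Series, model: str,
                  setting: PopulationSetting,
                  kinship: KinshipSet | None = None,
                  alpha: float = 0.05) -> GwasResult:
    """Score every marker with the P3D GLS F-test.

    ``y`` is indexed by sample id; samples are aligned to the intersection
    with ``g`` (in genotype-matrix order).  Markers with a constant or
    collinear encoding are skipped with a reason and carry no score.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    keep = [i for i, s in enumerate(g.samples) if s in y.index]
    if len(keep) < 3:
        raise ValueError("fewer than 3 samples shared between g and y")
    if len(keep) < g.n_samples:
        g = g.subset_samples(keep)
    yv = y.reindex(g.samples).to_numpy(dtype=float)

    chroms = g.chromosomes
    loco = (setting.uses_kinship and kinship is not None
            and len(kinship.per_chromosome) > 0)
    fits: dict[str | None, NullModelFit] = {}
    if loco:
        for c in chroms:
            fits[c] = fit_null_model(yv, setting, kinship, g.samples, c)
    else:
        fits[None] = fit_null_model(yv, setting, kinship, g.samples, None)

    records = []
    chrom_arr = g.markers["chromosome"].to_numpy()
    cache_key: object = object()  # sentinel so the first marker initializes
    for j in range(g.n_markers):
        c = chrom_arr[j] if loco else None
        fit = fits[c]
        if cache_key != c:
            # residual-maker of the null fixed effects in whitened space
            sw = np.sqrt(fit.weights)
            Xw = (fit.U.T @ setting.covariates(g.samples)) * sw[:, None]
            yw = (fit.U.T @ yv) * sw
            Q0, _ = np.linalg.qr(Xw)
            rz = yw - Q0 @ (Q0.T @ yw)
            rss0 = float(rz @ rz)
            rank0 = Xw.shape[1]
            Ut = fit.U.T
            cache_key = c
        col = g.dosage[:, j]
        n_obs = int((~np.isnan(col)).sum())
        row = {
            "marker": g.markers.loc[j, "marker_id"],
            "chromosome": g.markers.loc[j, "chromosome"],
            "position": int(g.markers.loc[j, "position"]),
            "score": np.nan, "F": np.nan, "df": np.nan, "pvalue": np.nan,
            "skipped_reason": None,
        }
        if n_obs < 3:
            row["skipped_reason"] = "too_few_samples"
            records.append(row)
            continue
        enc = _marker_encoding(model, col)
        if np.allclose(enc, enc[0], equal_nan=True):
            row["skipped_reason"] = "constant_encoding"
            records.append(row)
            continue
        ew = (Ut @ enc) * sw[:, None]
        ez = ew - Q0 @ (Q0.T @ ew)
        rank_e = int(np.linalg.matrix_rank(ez, tol=1e-8))
        if rank_e == 0:
            row["skipped_reason"] = "collinear_encoding"
            records.append(row)
            continue
        coef, _, _, _ = np.linalg.lstsq(ez, rz, rcond=None)
        fitted = ez @ coef
        rss1 = float((rz - fitted) @ (rz - fitted))
        q = rank_e
        n = len(yv)
        dfe = n - rank0 - q
        if dfe <= 0:
            row["skipped_reason"] = "degenerate_fit"
            records.append(row)
            continue
        if rss1 <= 1e-12 * max(rss0, 1.0):  # perfect fit
            p = 0.0
            F = float("inf")
        else:
            F = max(((rss0 - rss1) / q) / (rss1 / dfe), 0.0)
            p = float(stats.f.sf(F, q, dfe))
        row.update({"score": -np.log10(max(p, 1e-300)), "F": float(F),
                    "df": q, "pvalue": p})
        records.append(row)

    table = pd.DataFrame.from_records(records)
    result = GwasResult(model=model, setting=setting.name, table=table,
                        alpha=alpha)
    scored = table["score"].dropna().to_numpy()
    if len(scored) >= 10:
        result.inflation_factor = inflation_factor(scored)
    pvals = table["pvalue"].dropna()
    if len(pvals):
        thr, _ = fdr_score_threshold(pvals, alpha=alpha)
        result.fdr_threshold = thr
    return result


def inflation_factor(scores: np.ndarray) -> float:
    """Genomic inflation: no-intercept regression of observed on expected scores.

    Observed -log10 p scores are sorted and paired with the null
    expectation -log10(i / (m + 1)); the factor is the through-the-origin
    regression slope, 1 when the test is well calibrated.
    """
    obs = np.sort(np.asarray(scores, dtype=float))[::-1]
    m = len(obs)
    if m < 10:
        raise ValueError("need >= 10 scores for the inflation factor")
    if np.all(obs == obs[0]):
        raise ValueError("inflation factor undefined for constant scores")
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    return float((obs @ expected) / (expected @ expected))


@dataclass
class SettingChoice:
    name: str
    mean_inflation: float
    below_one: bool = False


def select_population_setting(mean_inflation: dict[str, float]
                              ) -> SettingChoice:
    """Pick the setting with mean inflation closest to 1 from above.

    Among settings whose mean inflation exceeds one, the smallest mean
    wins; if none exceed one, the mean closest to one is returned with a
    below-one flag.
    """
    if not mean_inflation:
        raise ValueError("no inflation means supplied")
    above = {k: v for k, v in mean_inflation.items() if v > 1.0}
    if above:
        name = min(above, key=lambda k: (above[k], k))
        return SettingChoice(name=name, mean_inflation=above[name])
    name = min(mean_inflation, key=lambda k: (abs(mean_inflation[k] - 1.0), k))
    return SettingChoice(name=name, mean_inflation=mean_inflation[name],
                         below_one=True)


def fdr_score_threshold(pvalues, alpha: float = 0.05
                        ) -> tuple[float, list]:
    """Benjamini-Hochberg threshold on the -log10 p score scale.

    Returns (-log10 of the largest significant p, significant ids); with
    no significant marker the threshold is +inf and the list empty.
    """
    if isinstance(pvalues, pd.Series):
        ids = pvalues.index.to_numpy()
        p = pvalues.to_numpy(dtype=float)
    else:
        p = np.asarray(pvalues, dtype=float)
        ids = np.arange(len(p))
    m = len(p)
    if m == 0:
        return float("inf"), []
    order = np.argsort(p, kind="stable")
    ps = p[order]
    crit = np.arange(1, m + 1) * alpha / m
    passing = np.flatnonzero(ps <= crit)
    if passing.size == 0:
        return float("inf"), []
    k = passing[-1]
    p_star = max(ps[k], 1e-300)
    sig = [ids[i] for i in order[:k + 1]]
    return float(-np.log10(p_star)), sig


def select_high_scoring(scores: pd.Series, min_score: float = 4.0) -> list:
    """Markers with score strictly above ``min_score`` (p < 10^-min_score)."""
    s = scores.dropna()
    return s.index[s > min_score].tolist()


def score_correlation_matrix(results: list[GwasResult]
                             ) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlations between result-set score vectors, with a
    hierarchical (average linkage on 1 - r) display order."""
    if len(results) < 2:
        raise ValueError("need at least two result sets")
    cols = {}
    for r in results:
        cols[f"{r.setting}|{r.model}"] = r.scores
    df = pd.DataFrame(cols)
    corr = df.corr(method="pearson", min_periods=2)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    labels = [corr.columns[i] for i in order]
    return corr, labels
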