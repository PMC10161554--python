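"""Population-structure utilities for dosage genotypes.

Covers PCA on dosages, DAPC-style clustering (k-means with BIC model
selection, then linear discriminant analysis with cross-validated choice of
the number of retained principal components), post-processing of STRUCTURE
runs (Evanno-style delta, label-switching alignment and averaging), and the
realized-relationship kinship matrix with leave-one-chromosome-out (LOCO)
variants for mixed-model GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .geno import GenotypeMatrix

__all__ = [
    "MembershipMatrix",
    "StructureRunSet",
    "KinshipSet",
    "DapcModel",
    "pca_dosage",
    "select_n_clusters",
    "dapc_fit",
    "dapc_predict_membership",
    "dapc_cross_validate",
    "evanno_delta",
    "align_structure_runs",
    "compute_kinship",
    "subsample_markers",
    "export_structure_input",
    "import_structure_memberships",
]


@dataclass
class MembershipMatrix:
    """Samples x subpopulations posterior membership probabilities (Q)."""

    samples: list[str]
    groups: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.samples), len(self.groups)):
            raise ValueError("membership shape inconsistent with labels")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("membership probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.samples, columns=self.groups)


@dataclass
class StructureRunSet:
    """Replicate STRUCTURE runs plus the per-nS likelihood traces."""

    runs: list[MembershipMatrix]
    log_likelihoods: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("at least one run required")
        ref = self.runs[0]
        for r in self.runs[1:]:
            if r.samples != ref.samples:
                raise ValueError("runs must share the same sample order")


@dataclass
class KinshipSet:
    """Global and leave-one-chromosome-out realized-relationship matrices."""

    samples: list[str]
    global_: np.ndarray
    per_chromosome: dict[str, np.ndarray] = field(default_factory=dict)

    def for_chromosome(self, chromosome: str | None) -> np.ndarray:
        if chromosome is not None and chromosome in self.per_chromosome:
            return self.per_chromosome[chromosome]
        return self.global_


@dataclass
class DapcModel:
    n_pcs_retained: int
    cluster_count: int
    cluster_assignments: np.ndarray
    discriminant_axes: np.ndarray
    membership: MembershipMatrix
    bic_curve: dict[int, float] = field(default_factory=dict)
    cv_curve: dict[int, tuple[float, float]] = field(default_factory=dict)
    # internals for prediction
    _means: np.ndarray | None = None
    _pooled_cov_inv: np.ndarray | None = None


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_dosage(g: GenotypeMatrix, n_components: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA of the dosage matrix.

    Missing dosages are mean-imputed per marker.  Returns (scores,
    explained_variance), the latter non-increasing.
    """
    if g.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    if n_components > min(g.n_samples, g.n_markers):
        raise ValueError("n_components exceeds min(n_samples, n_markers)")
    x = g.imputed_dosage()
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_


# ---------------------------------------------------------------------------
# k-means + BIC cluster-count selection
# ---------------------------------------------------------------------------

def select_n_clusters(pca_scores: np.ndarray,
                      nc_range=range(1, 11), seed: int | None = None,
                      n_init: int = 10) -> tuple[int, dict[int, float]]:
    """Pick the number of k-means clusters minimizing an adegenet-style BIC.

    BIC(k) = n log(WSS/n) + k log(n) with WSS the total within-cluster sum
    of squares.  Ties and equal minima resolve to the smallest k.
    """
    x = np.asarray(pca_scores, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("pca_scores must be finite")
    n = x.shape[0]
    ks = [k for k in nc_range if k <= n]
    if len(ks) < len(list(nc_range)):
        import warnings
        warnings.warn("cluster range restricted to the number of samples")
    bic = {}
    rng = np.random.default_rng(seed)
    for k in ks:
        if k == 1:
            wss = float(((x - x.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_init,
                        random_state=int(rng.integers(2 ** 31)))
            km.fit(x)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)  # guard log of zero for duplicated points
        bic[k] = n * np.log(wss / n) + k * np.log(n)
    best = min(bic, key=lambda k: (round(bic[k], 10), k))
    return best, bic


def kmeans_assign(pca_scores: np.ndarray, k: int,
                  seed: int | None = None) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(np.asarray(pca_scores, dtype=float))


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def _lda_axes(x: np.ndarray, labels: np.ndarray, n_axes: int) -> np.ndarray:
    """Discriminant axes maximizing between/within variance (generalized
    eigenproblem B a = lambda W a), columns ordered by decreasing ratio."""
    classes = np.unique(labels)
    n, p = x.shape
    mean = x.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        d = xc - mc
        W += d.T @ d
        B += len(xc) * np.outer(mc - mean, mc - mean)
    W += np.eye(p) * 1e-8 * max(np.trace(W) / p, 1.0)
    from scipy.linalg import eigh
    vals, vecs = eigh(B, W)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:n_axes]]


def dapc_fit(pca_scores: np.ndarray, cluster_assignments: np.ndarray,
             n_pcs: int, sample_ids: list[str] | None = None) -> DapcModel:
    """Linear discriminant analysis on retained PCs with Gaussian posteriors.

    Memberships are posterior probabilities under equal priors with a
    pooled within-cluster covariance in discriminant space.
    """
    x = np.asarray(pca_scores, dtype=float)[:, :n_pcs]
    labels = np.asarray(cluster_assignments)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("DAPC requires at least two clusters")
    for ci, c in enumerate(classes):
        if (y == ci).sum() < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 members")
    n_axes = min(len(classes) - 1, n_pcs)
    axes = _lda_axes(x, y, n_axes)
    z = x @ axes
    means = np.vstack([z[y == ci].mean(axis=0) for ci in range(len(classes))])
    resid = z - means[y]
    pooled = (resid.T @ resid) / max(len(z) - len(classes), 1)
    pooled += np.eye(n_axes) * 1e-10
    pinv = np.linalg.inv(pooled)
    probs = _gaussian_posteriors(z, means, pinv)
    samples = (sample_ids if sample_ids is not None
               else [f"s{i}" for i in range(len(z))])
    membership = MembershipMatrix(samples=samples,
                                  groups=[f"C{c}" for c in classes],
                                  probs=probs)
    model = DapcModel(n_pcs_retained=n_pcs, cluster_count=len(classes),
                      cluster_assignments=labels, discriminant_axes=axes,
                      membership=membership)
    model._means = means
    model._pooled_cov_inv = pinv
    return model


def _gaussian_posteriors(z: np.ndarray, means: np.ndarray,
                         pinv: np.ndarray) -> np.ndarray:
    d2 = np.stack([np.einsum("ij,jk,ik->i", z - m, pinv, z - m)
                   for m in means], axis=1)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def dapc_predict_membership(model: DapcModel,
                            pca_scores: np.ndarray) -> np.ndarray:
    z = np.asarray(pca_scores, dtype=float)[:, :model.n_pcs_retained] \
        @ model.discriminant_axes
    return _gaussian_posteriors(z, model._means, model._pooled_cov_inv)


def dapc_cross_validate(pca_scores: np.ndarray,
                        cluster_assignments: np.ndarray,
                        n_pcs_grid, n_reps: int = 30,
                        seed: int | None = None,
                        ) -> tuple[dict[int, tuple[float, float]], int]:
    """Stratified 90/10 cross-validation of the number of retained PCs.

    For each candidate, ``n_reps`` random splits fit the discriminant
    analysis on 90% of samples and measure hold-out assignment accuracy and
    the RMSE between predicted membership and the 0/1 truth.  The selected
    value maximizes mean accuracy, ties resolved to the smaller candidate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    x = np.asarray(pca_scores, dtype=float)
    labels = np.asarray(cluster_assignments)
    classes, y = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    curve: dict[int, tuple[float, float]] = {}
    splits = []
    for _ in range(n_reps):
        test_idx = []
        for ci in range(len(classes)):
            members = np.flatnonzero(y == ci)
            n_test = max(1, int(round(0.1 * len(members))))
            if len(members) - n_test < 2:
                n_test = max(0, len(members) - 2)
            if n_test:
                test_idx.extend(rng.choice(members, n_test, replace=False))
        splits.append(np.asarray(sorted(test_idx)))
    for n_pcs in n_pcs_grid:
        accs, rmses = [], []
        for test in splits:
            mask = np.ones(len(y), bool)
            mask[test] = False
            if len(np.unique(y[mask])) < 2 or test.size == 0:
                continue
            model = dapc_fit(x[mask], y[mask], n_pcs)
            probs = dapc_predict_membership(model, x[test])
            pred = probs.argmax(axis=1)
            truth = np.eye(len(classes))[y[test]]
            accs.append(float((pred == y[test]).mean()))
            rmses.append(float(np.sqrt(((probs - truth) ** 2).mean())))
        curve[int(n_pcs)] = (float(np.mean(accs)), float(np.mean(rmses)))
    best = max(curve, key=lambda k: (curve[k][0], -k))
    return curve, best


# ---------------------------------------------------------------------------
# STRUCTURE post-processing
# ---------------------------------------------------------------------------

def evanno_delta(log_likelihoods: dict[int, list[float]]
                 ) -> dict[int, float]:
    """Second-derivative statistic over replicate STRUCTURE likelihoods.

    delta(nS) = |mean L(nS+1) - 2 mean L(nS) + mean L(nS-1)| / sd(L(nS)),
    undefined (NaN) at the range endpoints or when the replicate sd is 0.
    """
    ks = sorted(log_likelihoods)
    means = {k: float(np.mean(log_likelihoods[k])) for k in ks}
    sds = {k: float(np.std(log_likelihoods[k], ddof=1))
           if len(log_likelihoods[k]) > 1 else 0.0 for k in ks}
    delta = {}
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            continue
        if ks[i - 1] != k - 1 or ks[i + 1] != k + 1:
            raise ValueError("log-likelihoods must cover consecutive nS values")
        if sds[k] == 0.0:
            delta[k] = float("nan")
            continue
        delta[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
    return delta


def align_structure_runs(runs: StructureRunSet) -> MembershipMatrix:
    """Align replicate runs for label switching and average them.

    Each run's columns are matched to the first run's by maximizing the
    total column-wise Pearson correlation (optimal linear assignment); the
    aligned runs are averaged element-wise and rows renormalized.
    """
    mats = [r.probs for r in runs.runs]
    q = mats[0].shape[1]
    for m in mats[1:]:
        if m.shape[1] != q:
            raise ValueError("all runs must have the same group count")
    ref = mats[0]
    acc = ref.copy()
    for m in mats[1:]:
        corr = np.zeros((q, q))
        for a in range(q):
            for b in range(q):
                ca = ref[:, a] - ref[:, a].mean()
                cb = m[:, b] - m[:, b].mean()
                denom = np.sqrt((ca @ ca) * (cb @ cb))
                corr[a, b] = (ca @ cb) / denom if denom > 0 else 0.0
        rows, cols = linear_sum_assignment(-corr)
        perm = np.empty(q, dtype=int)
        perm[rows] = cols
        acc += m[:, perm]
    mean = acc / len(mats)
    mean /= mean.sum(axis=1, keepdims=True)
    return MembershipMatrix(samples=runs.runs[0].samples,
                            groups=list(runs.runs[0].groups), probs=mean)


def export_structure_input(g: GenotypeMatrix, path: str) -> None:
    """Write dosages in STRUCTURE's multi-row haploid-allele format.

    Each sample is written as four rows of 0/1 alleles per marker (the
    alternate allele appearing ``dosage`` times); missing calls are -9.
    """
    with open(path, "w") as fh:
        fh.write(" ".join(g.marker_ids) + "\n")
        for i, s in enumerate(g.samples):
            rows = [[], [], [], []]
            for v in g.dosage[i]:
                if np.isnan(v):
                    alleles = [-9] * 4
                else:
                    d = int(round(v))
                    alleles = [1] * d + [0] * (4 - d)
                for r, a in zip(rows, alleles):
                    r.append(str(a))
            for r in rows:
                fh.write(str(s) + " " + " ".join(r) + "\n")


def import_structure_memberships(path: str) -> MembershipMatrix:
    """Parse the inferred-ancestry block of a STRUCTURE output file."""
    samples, rows = [], []
    in_block = False
    with open(path) as fh:
        for line in fh:
            if "Inferred ancestry of individuals" in line:
                in_block = True
                continue
            if in_block:
                s = line.strip()
                if not s:
                    if samples:
                        break
                    continue
                if s.lower().startswith("label"):
                    continue
                if ":" not in s:
                    if samples:
                        break
                    continue
                left, _, right = s.partition(":")
                parts = left.split()
                probs = [float(p) for p in right.split()]
                samples.append(parts[1] if len(parts) > 1 else parts[0])
                rows.append(probs)
    if not samples:
        raise ValueError(f"{path}: no inferred-ancestry block found")
    probs = np.asarray(rows, dtype=float)
    probs = probs / probs.sum(axis=1, keepdims=True)
    groups = [f"S{j + 1}" for j in range(probs.shape[1])]
    return MembershipMatrix(samples=samples, groups=groups, probs=probs)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def _kinship_from(d: np.ndarray) -> np.ndarray:
    m = d - d.mean(axis=0, keepdims=True)
    k = m @ m.T
    tr = np.trace(k)
    if tr <= 0:
        return np.eye(d.shape[0])
    return k * (d.shape[0] / tr)


def compute_kinship(g: GenotypeMatrix, loco: bool = True) -> KinshipSet:
    """Realized relationship matrix K = MM^T from centered dosages.

    Columns are centered at their mean dosage (missing entries mean-imputed
    first) and K is scaled so the mean diagonal equals one.  With ``loco``,
    K(chr) is computed from all markers NOT on that chromosome.
    """
    if g.n_samples < 2:
        raise ValueError("kinship requires at least two samples")
    d = g.imputed_dosage()
    ks = KinshipSet(samples=list(g.samples), global_=_kinship_from(d))
    if loco:
        chroms = g.chromosomes
        if len(chroms) < 2:
            raise ValueError("LOCO requires >= 2 chromosomes")
        chrom_arr = g.markers["chromosome"].to_numpy()
        for c in chroms:
            ks.per_chromosome[c] = _kinship_from(d[:, chrom_arr != c])
    return ks


def subsample_markers(g: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Random marker subsample (without replacement) with an explicit seed."""
    if n >= g.n_markers:
        return g
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_markers, size=n, replace=False))
    return g.subset_markers(idx)
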