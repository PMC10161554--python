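"""Synthetic autotetraploid half-sib panels, phenotypes and expression counts.

The generator emulates a multi-cross half-sib breeding panel: founder
genotypes are binomial dosages drawn from per-marker allele frequencies
(optionally from two diverged founder pools to plant population structure),
each cross transmits gametes under random bivalent pairing (gamete dosage ~
Hypergeometric(4, parental dosage, 2); no double reduction, no
recombination map — markers are independent given the parents).  Phenotypes
combine planted QTL effects, a polygenic term and residual noise scaled to
a target heritability, discretized to the 0-5 bruising scale with
replicate/tuber structure.  Expression counts are negative-binomial with
planted differentially expressed genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .geno import GenotypeMatrix
from .gwas import encode_dosage

__all__ = [
    "CrossDesign",
    "QtlSpec",
    "SimulationConfig",
    "SimulatedTruth",
    "table1_design",
    "simulate_cross",
    "simulate_panel",
    "simulate_phenotype",
    "simulate_expression",
    "plant_ld_blocks",
]


@dataclass
class CrossDesign:
    """List of (parent1, parent2, n_progeny) crosses; parents may repeat."""

    crosses: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        for p1, p2, n in self.crosses:
            if n < 0:
                raise ValueError(f"cross {p1} x {p2}: n_progeny must be >= 0")

    @property
    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for p1, p2, _ in self.crosses:
            seen.setdefault(p1)
            seen.setdefault(p2)
        return list(seen)

    @property
    def total_progeny(self) -> int:
        return sum(n for _, _, n in self.crosses)


def table1_design() -> CrossDesign:
    """The study's half-sib cross design: two recurrent parents crossed with
    21 other varieties, 158 progeny genotypes in total."""
    crosses = [
        ("Crop20", "V390", 7), ("Crop20", "964/8", 5),
        ("Crop20", "SummitRusset", 9), ("Crop20", "VR808", 3),
        ("Crop20", "Crop37", 5), ("Crop20", "LT1", 5),
        ("Crop20", "810_76", 6),
        ("Crop52", "V390", 11), ("Crop52", "Admiral", 10),
        ("Crop52", "DolceVita", 13), ("Crop52", "Driver", 16),
        ("Crop52", "Karaka", 4), ("Crop52", "Crop18", 10),
        ("Crop52", "Markies", 3), ("Crop52", "Mondial", 2),
        ("Crop52", "Moonlight", 7), ("Crop52", "Crop33", 5),
        ("Crop52", "RedRascal", 8), ("Crop52", "SummitRusset", 7),
        ("Crop52", "VR808", 2), ("Crop52", "Crop9", 8),
        ("Crop52", "Crop37", 6), ("Crop52", "Crop58", 6),
    ]
    return CrossDesign(crosses=crosses)


@dataclass
class QtlSpec:
    marker_index: int
    model: str = "additive"
    pve: float = 0.2          # fraction of phenotypic variance explained


@dataclass
class SimulationConfig:
    """Panel and trait parameters; the defaults mirror the study's design
    (12 potato chromosomes, two biological replicates of three tubers,
    0-5 bruising scale) at desk-scale marker counts."""

    n_chromosomes: int = 12
    markers_per_chromosome: int = 100
    chromosome_length: int = 60_000_000
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    founder_pools: int = 1
    pool_freq_shift: float = 0.0
    qtls: list[QtlSpec] = field(default_factory=list)
    heritability: float = 0.5
    n_replicates: int = 2
    n_tubers: int = 3
    replicate_sd: float = 0.3
    tuber_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    # expression block (group sizes follow the study: 41 low vs 33 high)
    n_genes: int = 25_000
    n_de: int = 57
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")


@dataclass
class SimulatedTruth:
    """Ground truth accompanying a simulated dataset."""

    qtls: list[dict] = field(default_factory=list)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    subpopulation: dict[str, str] = field(default_factory=dict)
    parental_dosages: dict[str, list[int]] = field(default_factory=dict)
    progeny_cross: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "qtls": self.qtls,
                "de_genes": self.de_genes,
                "subpopulation": self.subpopulation,
                "progeny_cross": {k: list(v)
                                  for k, v in self.progeny_cross.items()},
            }, fh, indent=1)


def simulate_cross(parent1: np.ndarray, parent2: np.ndarray, n_progeny: int,
                   seed: int | np.random.Generator) -> np.ndarray:
    """Progeny dosages from two tetraploid parents.

    Each parent transmits per marker a gamete dosage drawn from
    Hypergeometric(4, parental dosage, 2) — random bivalent pairing without
    double reduction; progeny dosage is the sum of the two gametes.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p1 = np.asarray(parent1, dtype=int)
    p2 = np.asarray(parent2, dtype=int)
    for p in (p1, p2):
        if np.any((p < 0) | (p > 4)):
            raise ValueError("parental dosages must lie in 0..4")
    g1 = rng.hypergeometric(p1[None, :], 4 - p1[None, :], 2,
                            size=(n_progeny, len(p1)))
    g2 = rng.hypergeometric(p2[None, :], 4 - p2[None, :], 2,
                            size=(n_progeny, len(p2)))
    return g1 + g2


def _distinct_positions(rng: np.random.Generator, length: int,
                        m: int) -> np.ndarray:
    """m distinct sorted positions in [1, length) without materializing
    the whole range."""
    pos = np.unique(rng.integers(1, length, size=2 * m + 16))
    while len(pos) < m:  # pragma: no cover - vanishing collision odds
        pos = np.unique(np.concatenate(
            [pos, rng.integers(1, length, size=m)]))
    pick = np.sort(rng.choice(len(pos), size=m, replace=False))
    return pos[pick]


def simulate_panel(design: CrossDesign, config: SimulationConfig
                   ) -> tuple[GenotypeMatrix, SimulatedTruth]:
    """Simulate founder genotypes and all crosses of the design."""
    if design.total_progeny == 0:
        raise ValueError("design has zero total progeny")
    rng = np.random.default_rng(config.seed)
    n_markers = config.n_chromosomes * config.markers_per_chromosome
    lo, hi = config.allele_freq_range
    base_freq = rng.uniform(lo, hi, size=n_markers)

    parents = design.parents
    # contiguous blocks of parents per pool, so crosses stay within pools
    n_pools = max(config.founder_pools, 1)
    pool_of = {p: min((i * n_pools) // len(parents), n_pools - 1)
               for i, p in enumerate(parents)}
    truth = SimulatedTruth()
    parental = {}
    for p in parents:
        freq = base_freq.copy()
        if config.founder_pools > 1 and config.pool_freq_shift > 0:
            shift = config.pool_freq_shift * (1 if pool_of[p] % 2 else -1)
            freq = np.clip(freq + shift / 2.0, 0.01, 0.99)
        parental[p] = rng.binomial(4, freq)
        # planted QTLs must segregate: force duplex founders there
        for q in config.qtls:
            parental[p][q.marker_index] = 2
        truth.parental_dosages[p] = parental[p].tolist()

    rows = []
    sample_ids = []
    for ci, (p1, p2, n) in enumerate(design.crosses):
        if n == 0:
            continue
        prog = simulate_cross(parental[p1], parental[p2], n, rng)
        rows.append(prog)
        for k in range(n):
            sid = f"{p1}x{p2}_{k:03d}"
            sample_ids.append(sid)
            truth.progeny_cross[sid] = (p1, p2)
            truth.subpopulation[sid] = f"pool{pool_of[p1]}"
    dosage = np.vstack(rows).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    chroms = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)
              for _ in range(config.markers_per_chromosome)]
    positions = np.concatenate([
        _distinct_positions(rng, config.chromosome_length,
                            config.markers_per_chromosome)
        for _ in range(config.n_chromosomes)])
    markers = pd.DataFrame({
        "marker_id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
        "chromosome": chroms,
        "position": positions,
        "ref": "A",
        "alt": [("T",)] * n_markers,
        "qual": 100.0,
    })
    g = GenotypeMatrix(samples=sample_ids, markers=markers, dosage=dosage)
    for q in config.qtls:
        truth.qtls.append({"marker_id": g.markers.loc[q.marker_index,
                                                      "marker_id"],
                           "model": q.model, "pve": q.pve})
    return g, truth


def _unit_scale(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def simulate_phenotype(g: GenotypeMatrix, qtls: list[QtlSpec],
                       heritability: float, n_replicates: int = 2,
                       n_tubers: int = 3, replicate_sd: float = 0.3,
                       tuber_sd: float = 0.5,
                       seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Replicate-structured 0-5 bruising scores with planted QTLs.

    The genotype latent value sums unit-scaled QTL encodings weighted by
    sqrt(pve), a polygenic term (random marker effects through the dosage
    matrix) filling the remaining genetic variance up to ``heritability``,
    and residual noise for the rest.  Latent observations (genotype value
    plus replicate and tuber noise) are discretized to 0..5 by fixed
    population quantiles.  Returns a (genotype, replicate, tuber, score)
    table.
    """
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = g.n_samples
    d = g.imputed_dosage()
    pve_total = sum(q.pve for q in qtls)
    if pve_total > heritability + 1e-9:
        raise ValueError("sum of QTL pve cannot exceed heritability")
    latent = np.zeros(n)
    for q in qtls:
        enc = encode_dosage(q.model, d[:, q.marker_index])
        comp = _unit_scale(enc.sum(axis=1))
        latent += np.sqrt(q.pve) * comp
    poly_share = heritability - pve_total
    if poly_share > 0:
        u = rng.normal(size=g.n_markers)
        latent += np.sqrt(poly_share) * _unit_scale(d @ u)
    noise_share = 1.0 - heritability
    if noise_share > 0:
        latent += np.sqrt(noise_share) * _unit_scale(rng.normal(size=n))

    # fixed population quantiles of the genotype latent define the 0-5 bins
    edges = np.quantile(latent, np.linspace(0, 1, 7)[1:-1])
    records = []
    for i, geno in enumerate(g.samples):
        for r in range(n_replicates):
            rep_eff = rng.normal(0, replicate_sd)
            for t in range(n_tubers):
                obs = latent[i] + rep_eff + rng.normal(0, tuber_sd)
                score = int(np.searchsorted(edges, obs))
                records.append({"genotype": geno, "replicate": f"rep{r + 1}",
                                "tuber": f"tuber{t + 1}",
                                "score": float(score)})
    return pd.DataFrame.from_records(records)


def simulate_expression(groups: pd.Series, config: SimulationConfig,
                        seed: int | np.random.Generator | None = None
                        ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Negative-binomial counts with planted DE genes between two groups.

    Gene baselines are log-normal; planted DE genes (half up, half down in
    the high group) have a group mean ratio of 2**de_log2fc.  Counts are
    gamma-Poisson with the configured dispersion (Poisson when 0) times
    per-sample library-size factors.  Returns the matrix and the truth
    mapping gene -> 'up'/'down'.
    """
    samples = list(groups.index)
    n_low = int((groups == "low").sum())
    n_high = int((groups == "high").sum())
    if n_low < 2 or n_high < 2:
        raise ValueError("need >= 2 samples per group")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    ng = config.n_genes
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=ng)
    genes = [f"gene{i:05d}" for i in range(ng)]
    de_idx = rng.choice(ng, size=config.n_de, replace=False)
    direction = {}
    lfc = np.zeros(ng)
    for k, gi in enumerate(de_idx):
        sign = 1 if k % 2 == 0 else -1
        lfc[gi] = sign * config.de_log2fc
        direction[genes[gi]] = "up" if sign > 0 else "down"
    lo, hi = config.library_size_range
    sf = rng.uniform(lo, hi, size=len(samples))
    is_high = (groups == "high").to_numpy()
    mu = base[:, None] * np.where(is_high[None, :], 2.0 ** lfc[:, None], 1.0)
    mu = mu * sf[None, :]
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    x = ExpressionMatrix(counts=pd.DataFrame(counts, index=genes,
                                             columns=samples))
    return x, direction


def plant_ld_blocks(g: GenotypeMatrix, block_size: int = 5,
                    noise_rate: float = 0.05,
                    seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Inject LD by copying each block's first marker with light perturbation.

    Within consecutive blocks of ``block_size`` markers (per chromosome),
    every marker becomes a copy of the block head whose entries are
    resampled with probability ``noise_rate``.  This plants strong local
    correlation without a recombination model, for exercising LD pruning.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d = g.dosage.copy()
    chrom = g.markers["chromosome"].to_numpy()
    for c in g.chromosomes:
        idx = np.flatnonzero(chrom == c)
        for b in range(0, len(idx), block_size):
            block = idx[b:b + block_size]
            head = d[:, block[0]].copy()
            for j in block[1:]:
                col = head.copy()
                flip = rng.random(len(col)) < noise_rate
                col[flip] = rng.integers(0, 5, size=flip.sum())
                d[:, j] = col
    return GenotypeMatrix(samples=list(g.samples), markers=g.markers.copy(),
                          dosage=d, dosage_kind=g.dosage_kind)
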