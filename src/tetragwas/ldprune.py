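"""Bidirectional windowed LD pruning of dosage markers.

For each chromosome, markers are ordered by position and a random start
marker seeds the retained set S.  Scanning rightwards from the start, a
candidate j is dropped when some retained marker k lies within the window
(|pos_j - pos_k| <= window_bp) and r2(j, k) exceeds the threshold; when the
chromosome end is reached the scan resumes at the marker left of the start
and proceeds towards the beginning under the same rule.  r2 is the squared
Pearson correlation over complete (both non-missing) observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geno import GenotypeMatrix

__all__ = ["PruneResult", "pairwise_r2", "prune_chromosome", "prune_genome"]


@dataclass
class PruneResult:
    """Outcome of LD pruning.

    ``dropped`` maps each removed marker id to the retained marker that
    blocked it and their r2.  ``undefined_pairs`` logs (candidate, retained)
    pairs whose r2 was undefined (too few complete pairs or zero variance)
    and was treated as no linkage.
    """

    retained: list[str]
    dropped: dict[str, tuple[str, float]]
    seed: int | None
    window_bp: int
    r2_threshold: float
    start_markers: dict[str, str] = field(default_factory=dict)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def merge(self, other: "PruneResult") -> None:
        self.retained.extend(other.retained)
        self.dropped.update(other.dropped)
        self.start_markers.update(other.start_markers)
        self.undefined_pairs.extend(other.undefined_pairs)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over complete observations.

    Returns NaN (undefined) with fewer than two complete pairs or when
    either column is constant over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return min(r * r, 1.0)


def _scan(order: list[int], retained: list[int], positions: np.ndarray,
          dosage: np.ndarray, ids: list[str], window_bp: int,
          r2_threshold: float, drop_undefined: bool,
          result: PruneResult) -> None:
    for j in order:
        blocked = None
        for k in retained:
            if abs(int(positions[j]) - int(positions[k])) > window_bp:
                continue
            r2 = pairwise_r2(dosage[:, j], dosage[:, k])
            if np.isnan(r2):
                result.undefined_pairs.append((ids[j], ids[k]))
                if drop_undefined:
                    blocked = (k, float("nan"))
                    break
                continue
            if r2 > r2_threshold:
                blocked = (k, r2)
                break
        if blocked is None:
            retained.append(j)
        else:
            result.dropped[ids[j]] = (ids[blocked[0]], blocked[1])


def prune_chromosome(g: GenotypeMatrix, window_bp: int = 100_000,
                     r2_threshold: float = 0.5, seed: int | None = None,
                     start_index: int | None = None,
                     drop_undefined: bool = False) -> PruneResult:
    """Prune one chromosome; the start marker is drawn uniformly from ``seed``.

    ``start_index`` overrides the random choice (used for reproducing a
    documented trace).  Markers whose r2 with a retained marker is
    undefined are retained unless ``drop_undefined``.
    """
    if len(g.chromosomes) > 1:
        raise ValueError("prune_chromosome expects a single-chromosome matrix")
    n = g.n_markers
    result = PruneResult(retained=[], dropped={}, seed=seed,
                         window_bp=window_bp, r2_threshold=r2_threshold)
    if n == 0:
        return result
    positions = g.markers["position"].to_numpy()
    ids = g.marker_ids
    if start_index is None:
        rng = np.random.default_rng(seed)
        start_index = int(rng.integers(n))
    retained = [start_index]
    chrom = str(g.markers.loc[0, "chromosome"])
    result.start_markers[chrom] = ids[start_index]
    _scan(list(range(start_index + 1, n)), retained, positions, g.dosage,
          ids, window_bp, r2_threshold, drop_undefined, result)
    _scan(list(range(start_index - 1, -1, -1)), retained, positions,
          g.dosage, ids, window_bp, r2_threshold, drop_undefined, result)
    # report retained markers in genomic order
    result.retained = [ids[i] for i in sorted(retained)]
    return result


def prune_genome(g: GenotypeMatrix, window_bp: int = 100_000,
                 r2_threshold: float = 0.5, seed: int | None = None,
                 drop_undefined: bool = False) -> PruneResult:
    """Prune every chromosome independently and merge the results."""
    result = PruneResult(retained=[], dropped={}, seed=seed,
                         window_bp=window_bp, r2_threshold=r2_threshold)
    for i, chrom in enumerate(g.chromosomes):
        sub = g.restrict_chromosome(chrom)
        sub_seed = None if seed is None else np.random.SeedSequence(
            [seed, i]).generate_state(1)[0] % (2 ** 31)
        res = prune_chromosome(sub, window_bp=window_bp,
                               r2_threshold=r2_threshold, seed=int(sub_seed)
                               if sub_seed is not None else None,
                               drop_undefined=drop_undefined)
        result.merge(res)
    return result
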