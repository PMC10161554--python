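"""Tetraploid genotype I/O and variant/sample-level filtering.

Genotypes are represented as allele dosages: the number of alternate-allele
copies carried at a marker, an integer in 0..4 for called ("most probable")
genotypes or a real in [0, 4] for posterior-mean dosages.  Missing calls are
stored as NaN.  Markers are kept sorted by (chromosome, position).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerInfo",
    "GenotypeMatrix",
    "PloidyError",
    "VcfParseError",
    "read_vcf_dosages",
    "compute_qd",
    "select_biallelic_het_snps",
    "apply_variant_filters",
    "apply_sample_filter",
    "read_dosage_csv",
    "write_dosage_csv",
]

MARKER_COLUMNS = ["marker_id", "chromosome", "position", "ref", "alt", "qual"]


class PloidyError(ValueError):
    """A VCF genotype call does not have four alleles."""


class VcfParseError(ValueError):
    """The VCF input could not be parsed."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for a single variant.

    ``alt`` is the list of alternate alleles (one entry for biallelic
    markers); ``depths`` is the per-sample read depth in the same sample
    order as the genotype matrix (NaN where unavailable).
    """

    marker_id: str
    chromosome: str
    position: int
    ref: str
    alt: tuple[str, ...]
    qual: float = 0.0
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")
        if self.qual < 0:
            raise ValueError(f"marker {self.marker_id}: qual must be >= 0")


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage matrix with marker coordinates.

    ``dosage`` has shape (n_samples, n_markers); missing entries are NaN.
    ``markers`` is a DataFrame with columns marker_id, chromosome, position,
    ref, alt (list of strings), qual.  ``depths``, when present, carries the
    per-sample read depth with the same shape as ``dosage``.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    dosage_kind: str = "most_probable"
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.dosage_kind not in ("most_probable", "posterior_mean"):
            raise ValueError(f"unknown dosage_kind {self.dosage_kind!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 4)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 4] or be NaN")
        if self.dosage_kind == "most_probable":
            obs = self.dosage[~np.isnan(self.dosage)]
            if not np.allclose(obs, np.rint(obs)):
                raise ValueError("most_probable dosages must be integers")
        self.markers = self.markers.reset_index(drop=True)
        self._sort_markers()

    def _sort_markers(self) -> None:
        order = np.lexsort(
            (self.markers["position"].to_numpy(),
             self.markers["chromosome"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]
            if self.depths is not None:
                self.depths = self.depths[:, order]

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.markers["chromosome"]))

    def subset_markers(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            dosage_kind=self.dosage_kind,
            depths=None if self.depths is None else self.depths[:, index],
        )

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers.copy(),
            dosage=self.dosage[index, :],
            dosage_kind=self.dosage_kind,
            depths=None if self.depths is None else self.depths[index, :],
        )

    def restrict_chromosome(self, chromosome: str) -> "GenotypeMatrix":
        mask = (self.markers["chromosome"] == chromosome).to_numpy()
        return self.subset_markers(np.flatnonzero(mask))

    def select_markers_by_id(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.markers["marker_id"])}
        return self.subset_markers([pos[m] for m in ids])

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-marker mean."""
        d = self.dosage.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_vcf_dosages(path: str, dosage_kind: str = "most_probable",
                     dosage_field: str | None = None) -> GenotypeMatrix:
    """Read tetraploid genotypes from a VCF file as alternate-allele dosages.

    With the default ``dosage_kind='most_probable'`` the dosage is the count
    of alternate alleles in the (tetraploid) GT call; ``dosage_field`` may
    name a numeric per-sample FORMAT field (e.g. posterior-mean dosages)
    used with ``dosage_kind='posterior_mean'``.  Fully missing calls
    (``./././.``) become NaN.  Multi-allelic records are read as-is and are
    excluded later by :func:`select_biallelic_het_snps`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows = []
    dosages = []
    depths = []
    for rec in vcf:
        if dosage_field is not None:
            vals = rec.format(dosage_field)
            if vals is None:
                raise VcfParseError(
                    f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT "
                    f"field {dosage_field!r}"
                )
            d = np.asarray(vals, dtype=float).reshape(len(samples))
            d = np.where(d < 0, np.nan, d)
        else:
            d = np.empty(len(samples))
            for i, call in enumerate(rec.genotypes):
                alleles = call[:-1]  # last element is the phased flag
                if len(alleles) != 4:
                    raise PloidyError(
                        f"{path}: record {rec.CHROM}:{rec.POS} sample "
                        f"{samples[i]} has ploidy {len(alleles)}, expected 4"
                    )
                if all(a < 0 for a in alleles):
                    d[i] = np.nan
                else:
                    d[i] = sum(1 for a in alleles if a > 0)
        dosages.append(d)

        dp = rec.format("DP")
        if dp is None:
            depths.append(np.full(len(samples), np.nan))
        else:
            dp = np.asarray(dp, dtype=float).reshape(len(samples))
            depths.append(np.where(dp < 0, np.nan, dp))

        rows.append({
            "marker_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
            "chromosome": rec.CHROM,
            "position": rec.POS,
            "ref": rec.REF,
            "alt": tuple(rec.ALT),
            "qual": float(rec.QUAL) if rec.QUAL is not None else 0.0,
        })

    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    dosage = np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    depth = np.column_stack(depths) if depths else None
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          dosage_kind=dosage_kind, depths=depth)


# ---------------------------------------------------------------------------
# QD and filters
# ---------------------------------------------------------------------------

def compute_qd(qual: float, dosages: np.ndarray,
               depths: np.ndarray) -> float:
    """QualByDepth: variant quality over summed depth of non-homozygous samples.

    Non-homozygous means dosage in {1, 2, 3}.  Returns NaN (QD undefined)
    when no non-homozygous sample has positive depth.
    """
    dosages = np.asarray(dosages, dtype=float)
    depths = np.asarray(depths, dtype=float)
    d = np.rint(dosages)
    het = (~np.isnan(dosages)) & (d >= 1) & (d <= 3)
    total = np.nansum(np.where(het, depths, 0.0))
    if not het.any() or total <= 0 or np.isnan(total):
        return float("nan")
    return float(qual) / float(total)


def _is_snp(ref: str, alts: tuple[str, ...]) -> bool:
    return len(ref) == 1 and all(len(a) == 1 for a in alts)


def select_biallelic_het_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Retain heterozygous biallelic SNPs.

    A marker is kept when it is a single-nucleotide variant with exactly one
    alternate allele and at least one sample carries a heterozygous dosage
    (1, 2 or 3).  Multi-allelic records and indels are dropped, never
    decomposed.
    """
    keep = []
    for j, row in g.markers.iterrows():
        alts = tuple(row["alt"])
        if len(alts) != 1 or not _is_snp(row["ref"], alts):
            continue
        col = g.dosage[:, j]
        r = np.rint(col)
        if np.any((~np.isnan(col)) & (r >= 1) & (r <= 3)):
            keep.append(j)
    return g.subset_markers(keep)


def apply_variant_filters(g: GenotypeMatrix, max_missing: float = 0.10,
                          min_qd: float = 2.0, min_maf: float = 0.01,
                          strict_missing: bool = False,
                          ) -> tuple[GenotypeMatrix, dict]:
    """Apply missingness, QD and MAF filters to markers.

    A marker passes when (i) its missing fraction is <= ``max_missing``
    (strictly < when ``strict_missing``), (ii) QD >= ``min_qd`` and
    (iii) MAF > ``min_maf`` (strict), where MAF = min(f, 1 - f) with f the
    mean dosage over non-missing samples divided by four.  The QD rule only
    applies when quality scores and read depths are available (VCF input);
    a marker whose QD is undefined fails it.  Each removed marker is
    counted against the first rule it fails; the report's counts therefore
    sum to the number of markers removed.
    """
    n = g.n_samples
    report = {"missing": 0, "qd": 0, "maf": 0}
    has_depth = g.depths is not None
    keep = []
    for j in range(g.n_markers):
        col = g.dosage[:, j]
        miss = np.isnan(col).sum() / n if n else 0.0
        fail_missing = miss > max_missing if not strict_missing else miss >= max_missing
        if fail_missing:
            report["missing"] += 1
            continue
        if has_depth:
            qd = compute_qd(g.markers.loc[j, "qual"], col, g.depths[:, j])
            if np.isnan(qd) or qd < min_qd:
                report["qd"] += 1
                continue
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            report["maf"] += 1
            continue
        f = obs.mean() / 4.0
        maf = min(f, 1.0 - f)
        if not maf > min_maf:
            report["maf"] += 1
            continue
        keep.append(j)
    report["retained"] = len(keep)
    report["input"] = g.n_markers
    return g.subset_markers(keep), report


def apply_sample_filter(g: GenotypeMatrix,
                        max_missing: float = 0.10) -> GenotypeMatrix:
    """Remove samples with missing fraction strictly greater than ``max_missing``."""
    if g.n_markers == 0:
        return g
    frac = np.isnan(g.dosage).mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValueError("no samples remain after sample missingness filter")
    if keep.size == g.n_samples:
        return g
    return g.subset_samples(keep)


# ---------------------------------------------------------------------------
# Dosage CSV dialect
# ---------------------------------------------------------------------------
# Layout: header row of marker ids; three metadata rows (chromosome,
# position, ref/alt as "REF/ALT"); then one row per sample.  Missing dosages
# are empty cells.

def write_dosage_csv(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("marker," + ",".join(g.marker_ids) + "\n")
        fh.write("chromosome," + ",".join(map(str, g.markers["chromosome"])) + "\n")
        fh.write("position," + ",".join(map(str, g.markers["position"])) + "\n")
        refalt = [f"{r}/{'|'.join(a)}" for r, a in
                  zip(g.markers["ref"], g.markers["alt"])]
        fh.write("ref_alt," + ",".join(refalt) + "\n")
        for i, s in enumerate(g.samples):
            vals = []
            for v in g.dosage[i]:
                if np.isnan(v):
                    vals.append("")
                elif float(v).is_integer():
                    vals.append(str(int(v)))
                else:
                    vals.append(repr(float(v)))
            fh.write(str(s) + "," + ",".join(vals) + "\n")


def read_dosage_csv(path: str,
                    dosage_kind: str | None = None) -> GenotypeMatrix:
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if len(lines) < 4:
        raise ValueError(f"{path}: not a dosage CSV (needs 4 header rows)")
    header = lines[0].split(",")[1:]
    chroms = lines[1].split(",")[1:]
    positions = [int(p) for p in lines[2].split(",")[1:]]
    refalt = lines[3].split(",")[1:]
    refs, alts = [], []
    for ra in refalt:
        r, _, a = ra.partition("/")
        refs.append(r)
        alts.append(tuple(a.split("|")) if a else ())
    samples = []
    rows = []
    for ln in lines[4:]:
        parts = ln.split(",")
        samples.append(parts[0])
        rows.append([float(p) if p != "" else np.nan for p in parts[1:]])
    dosage = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    if dosage_kind is None:
        obs = dosage[~np.isnan(dosage)]
        dosage_kind = ("most_probable"
                       if obs.size == 0 or np.allclose(obs, np.rint(obs))
                       else "posterior_mean")
    markers = pd.DataFrame({
        "marker_id": header,
        "chromosome": chroms,
        "position": positions,
        "ref": refs,
        "alt": alts,
        "qual": 0.0,
    })
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          dosage_kind=dosage_kind)
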