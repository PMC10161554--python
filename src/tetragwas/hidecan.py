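"""HIDECAN plot: HIgh-scoring markers, DE genes and CANdidate genes.

A layered per-chromosome display integrating GWAS results (markers with
score above a threshold), differential-expression results (genes with
adjusted p below a threshold, plotted at their interval midpoint) and
literature candidate genes (always shown).  A windowed colocalization
report formalizes "regions containing both high-scoring markers and DE
genes" by single-linkage chaining of marker/gene pairs within a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import GwasResult

__all__ = [
    "ChromosomeLayout",
    "build_hidecan_data",
    "plot_hidecan",
    "colocalization_windows",
    "read_layout",
]

LAYERS = ("marker", "de_gene", "candidate")
HIDECAN_COLUMNS = ["chromosome", "position", "layer", "label", "value",
                   "source_id"]


@dataclass
class ChromosomeLayout:
    """Ordered chromosome labels with lengths in base pairs."""

    labels: list[str]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("chromosome labels must be unique")
        for c in self.labels:
            if self.lengths.get(c, 0) <= 0:
                raise ValueError(f"chromosome {c}: length must be > 0")


def read_layout(path: str) -> ChromosomeLayout:
    """Two-column whitespace/comma text: chromosome, length."""
    labels, lengths = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            labels.append(parts[0])
            lengths[parts[0]] = int(parts[1])
    return ChromosomeLayout(labels=labels, lengths=lengths)


def build_hidecan_data(gwas: list[GwasResult] | GwasResult | None,
                       de: pd.DataFrame | None,
                       candidates: pd.DataFrame | None,
                       layout: ChromosomeLayout,
                       marker_min_score: float = 4.0,
                       de_alpha: float = 0.05,
                       min_abs_log2fc: float = 0.0) -> pd.DataFrame:
    """Assemble the tidy layered table feeding the HIDECAN plot.

    Markers present in several GWAS result sets are deduplicated keeping
    the best score; DE genes are placed at the midpoint of (start, end);
    candidate rows are passed through unfiltered.  Rows are sorted by
    (chromosome, position).  Rows referencing a chromosome absent from the
    layout raise an error naming them.
    """
    rows = []
    if gwas is not None:
        if isinstance(gwas, GwasResult):
            gwas = [gwas]
        best: dict[str, dict] = {}
        for res in gwas:
            t = res.table.dropna(subset=["score"])
            for _, r in t.iterrows():
                cur = best.get(r["marker"])
                if cur is None or r["score"] > cur["value"]:
                    best[r["marker"]] = {
                        "chromosome": str(r["chromosome"]),
                        "position": int(r["position"]),
                        "layer": "marker", "label": r["marker"],
                        "value": float(r["score"]),
                        "source_id": f"{res.setting}|{res.model}",
                    }
        rows.extend(r for r in best.values()
                    if r["value"] > marker_min_score)
    if de is not None and len(de):
        sig = de[(de["adjusted_p"] < de_alpha)
                 & (de["log2_fold_change"].abs() >= min_abs_log2fc)]
        for _, r in sig.iterrows():
            rows.append({
                "chromosome": str(r["chromosome"]),
                "position": int(round((r["start"] + r["end"]) / 2)),
                "layer": "de_gene", "label": r["gene_id"],
                "value": float(r["log2_fold_change"]),
                "source_id": "de",
            })
    if candidates is not None and len(candidates):
        for _, r in candidates.iterrows():
            rows.append({
                "chromosome": str(r["chromosome"]),
                "position": int(r["position"]),
                "layer": "candidate", "label": r["gene"],
                "value": float(r.get("value", np.nan))
                if "value" in candidates.columns else np.nan,
                "source_id": str(r.get("source", "literature")),
            })
    data = pd.DataFrame(rows, columns=HIDECAN_COLUMNS)
    if len(data):
        known = set(layout.labels)
        bad = data[~data["chromosome"].isin(known)]
        if len(bad):
            raise ValueError(
                "chromosomes absent from layout: "
                + ", ".join(f"{r.label}@{r.chromosome}"
                            for r in bad.itertuples()))
        data = data.sort_values(["chromosome", "position"],
                                kind="stable").reset_index(drop=True)
    return data


_LAYER_STYLE = {
    "marker": {"color": "#c0392b", "dy": 0.30, "m": "v"},
    "de_gene": {"color": "#2471a3", "dy": 0.0, "m": "o"},
    "candidate": {"color": "#1e8449", "dy": -0.30, "m": "^"},
}


def plot_hidecan(data: pd.DataFrame, layout: ChromosomeLayout, out: str,
                 split: int | None = None, fmt: str | None = None) -> list[str]:
    """Render the HIDECAN plot and write the tidy CSV sidecar.

    One horizontal track per chromosome (x scaled to true length), three
    stacked layers per track.  With ``split`` = k, two image files are
    produced covering the first k chromosomes and the remainder (suffixes
    ``_a``/``_b``).  Returns the written image paths; the CSV sidecar is
    written next to the (first) image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not layout.labels:
        raise ValueError("no chromosomes to render")
    base, dot, ext = out.rpartition(".")
    if not dot:
        base, ext = out, (fmt or "svg")
    panels = ([layout.labels] if split is None
              else [layout.labels[:split], layout.labels[split:]])
    panels = [p for p in panels if p]
    written = []
    for pi, chroms in enumerate(panels):
        fig, ax = plt.subplots(
            figsize=(10, 0.9 * len(chroms) + 1.2))
        max_len = max(layout.lengths[c] for c in chroms)
        for yi, c in enumerate(chroms):
            y = len(chroms) - 1 - yi
            ax.hlines(y, 0, layout.lengths[c] / 1e6, color="0.75", lw=6,
                      zorder=1)
            sub = data[data["chromosome"] == c]
            for layer, style in _LAYER_STYLE.items():
                pts = sub[sub["layer"] == layer]
                if len(pts):
                    ax.scatter(pts["position"] / 1e6,
                               np.full(len(pts), y + style["dy"]),
                               s=28, marker=style["m"],
                               color=style["color"], zorder=2)
        ax.set_yticks(range(len(chroms)))
        ax.set_yticklabels(list(reversed(chroms)))
        ax.set_xlim(-0.01 * max_len / 1e6, 1.02 * max_len / 1e6)
        ax.set_xlabel("Position (Mb)")
        handles = [plt.Line2D([], [], linestyle="", marker=s["m"],
                              color=s["color"], label=name)
                   for name, s in _LAYER_STYLE.items()]
        ax.legend(handles=handles, loc="upper right", frameon=False)
        fig.tight_layout()
        path = (f"{base}.{ext}" if len(panels) == 1
                else f"{base}_{'ab'[pi]}.{ext}")
        fig.savefig(path, metadata={"Date": None} if ext == "svg" else None)
        plt.close(fig)
        written.append(path)
    data.to_csv(f"{base}.csv", index=False)
    return written


def colocalization_windows(data: pd.DataFrame, window_bp: int = 1_000_000
                           ) -> pd.DataFrame:
    """Regions where DE genes sit within ``window_bp`` of high-scoring markers.

    On each chromosome, DE-gene rows are linked to every marker row within
    the window; connected components (single-linkage chaining through
    shared markers/genes) containing at least one of each become a region.
    Bounds are the members' min/max positions rounded outward to 0.1 Mb.
    Output columns: chromosome, start, end, marker_ids, gene_ids.
    """
    regions = []
    for chrom, sub in data.groupby("chromosome"):
        markers = sub[sub["layer"] == "marker"]
        genes = sub[sub["layer"] == "de_gene"]
        if markers.empty or genes.empty:
            continue
        nodes = ([("m", i) for i in markers.index]
                 + [("g", i) for i in genes.index])
        parent = {n: n for n in nodes}

        def find(n):
            while parent[n] != n:
                parent[n] = parent[parent[n]]
                n = parent[n]
            return n

        def union(a, b):
            parent[find(a)] = find(b)

        for gi in genes.index:
            gp = data.loc[gi, "position"]
            for mi in markers.index:
                if abs(int(gp) - int(data.loc[mi, "position"])) <= window_bp:
                    union(("g", gi), ("m", mi))
        comps: dict = {}
        for n in nodes:
            comps.setdefault(find(n), []).append(n)
        for members in comps.values():
            ms = [i for t, i in members if t == "m"]
            gs = [i for t, i in members if t == "g"]
            if not ms or not gs:
                continue
            pos = data.loc[ms + gs, "position"]
            regions.append({
                "chromosome": chrom,
                "start": int(np.floor(pos.min() / 1e5) * 1e5),
                "end": int(np.ceil(pos.max() / 1e5) * 1e5),
                "marker_ids": sorted(data.loc[ms, "label"].tolist()),
                "gene_ids": sorted(data.loc[gs, "label"].tolist()),
            })
    out = pd.DataFrame(regions,
                       columns=["chromosome", "start", "end",
                                "marker_ids", "gene_ids"])
    if len(out):
        out = out.sort_values(["chromosome", "start"]).reset_index(drop=True)
    return out
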