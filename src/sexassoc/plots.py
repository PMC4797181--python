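"""Plot surfaces: volcano, Manhattan, MAF concordance and enrichment bars.

Every plot has a pure numeric layer (``*_coords``) returning the exact
coordinates and highlight masks that get rendered, so the plotting data
can be unit-tested without touching matplotlib.  Rendering is
deterministic for identical inputs.  Highlighting uses strict
inequality (P < threshold).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datamodel import (
    CHROMOSOMES,
    AssocResult,
    DataError,
    EnrichmentTable,
    MafSummary,
    SexDiffResult,
    VariantInfo,
)


def volcano_coords(results: Sequence[AssocResult], threshold: float = 0.01) -> pd.DataFrame:
    """x = log2(OR), y = -log10(P), highlight = (P < threshold)."""
    if not 0 < threshold < 1:
        raise DataError("threshold must be in (0,1)")
    ok = [r for r in results if r.ok]
    if not ok:
        raise DataError("no cleanly fitted results to plot")
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in ok],
            "x": [np.log2(r.or_) for r in ok],
            "y": [-np.log10(r.p) for r in ok],
            "highlight": [r.p < threshold for r in ok],
        }
    )


def volcano(
    results: Sequence[AssocResult],
    path: str | Path,
    threshold: float = 0.01,
    title: str = "",
) -> pd.DataFrame:
    """Volcano plot of one association scan; returns the plotted coordinates."""
    coords = volcano_coords(results, threshold)
    fig, ax = plt.subplots(figsize=(5, 4))
    base = coords[~coords.highlight]
    hot = coords[coords.highlight]
    ax.scatter(base.x, base.y, s=12, c="grey", alpha=0.7)
    ax.scatter(hot.x, hot.y, s=16, c="crimson")
    ax.axhline(-np.log10(threshold), ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2 odds ratio (fold change)")
    ax.set_ylabel("-log10 P value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return coords


_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}  # X after 22


def manhattan_coords(
    results: Sequence[SexDiffResult],
    variants: Sequence[VariantInfo],
    threshold: float = 0.01,
) -> pd.DataFrame:
    """x = cumulative position in chromosome order, y = -log10(p_het)."""
    if not 0 < threshold < 1:
        raise DataError("threshold must be in (0,1)")
    vmap = {v.rsid: v for v in variants}
    missing = [r.rsid for r in results if r.rsid not in vmap]
    if missing:
        raise DataError(f"no chromosome annotation for rsIDs: {missing[:5]}")
    rows = []
    for r in results:
        v = vmap[r.rsid]
        rows.append(
            {
                "rsid": r.rsid,
                "chrom": v.chromosome,
                "chrom_rank": _CHROM_ORDER[v.chromosome],
                "pos": v.position,
                "y": -np.log10(r.p_het),
                "highlight": r.p_het < threshold,
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom_rank", "pos"], kind="stable")
    # lay chromosomes side by side on a cumulative axis
    offset = 0.0
    xs = np.empty(len(df))
    for _, idx in df.groupby("chrom_rank", sort=True).groups.items():
        block = df.loc[idx]
        xs[df.index.get_indexer(idx)] = offset + block["pos"].to_numpy()
        offset += block["pos"].max() + 1.0
    df["x"] = xs
    return df.reset_index(drop=True)


def manhattan_sexdiff(
    results: Sequence[SexDiffResult],
    variants: Sequence[VariantInfo],
    path: str | Path,
    threshold: float = 0.01,
    title: str = "",
) -> pd.DataFrame:
    """Manhattan plot of sex-differentiated (heterogeneity) P values."""
    coords = manhattan_coords(results, variants, threshold)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for rank, block in coords.groupby("chrom_rank"):
        c = "steelblue" if rank % 2 == 0 else "lightsteelblue"
        ax.scatter(block.x, block.y, s=10, c=c)
    hot = coords[coords.highlight]
    ax.scatter(hot.x, hot.y, s=16, c="darkblue")
    ax.axhline(-np.log10(threshold), ls="--", lw=0.8, c="black")
    ax.set_xlabel("chromosome (1..22, X)")
    ax.set_ylabel("-log10 sex-differentiated P")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return coords


def maf_scatter(
    summaries: Sequence[MafSummary],
    path: str | Path,
    r_squared: float | None = None,
) -> pd.DataFrame:
    """Female vs male MAF scatter with an R^2 annotation.

    If ``r_squared`` is not given it is recomputed from the points shown.
    """
    pts = pd.DataFrame(
        {
            "rsid": [s.rsid for s in summaries],
            "maf_f": [s.maf_f for s in summaries],
            "maf_m": [s.maf_m for s in summaries],
        }
    ).dropna()
    if len(pts) < 2:
        raise DataError("need at least two variants with both-sex frequencies")
    if r_squared is None:
        r = np.corrcoef(pts.maf_f, pts.maf_m)[0, 1]
        r_squared = float(r * r)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pts.maf_f, pts.maf_m, s=10, alpha=0.7)
    lim = max(0.5, pts.maf_f.max(), pts.maf_m.max())
    ax.plot([0, lim], [0, lim], lw=0.8, c="grey")
    ax.annotate(f"$R^2$ = {r_squared:.3f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("MAF (females)")
    ax.set_ylabel("MAF (males)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    pts.attrs["r_squared"] = r_squared
    return pts


def enrichment_bars(tables: Sequence[EnrichmentTable], path: str | Path) -> pd.DataFrame:
    """Grouped bars of protective/risk percentages by sex, counts on top."""
    rows = []
    for t in tables:
        for sex, prot, risk, pct in (
            ("F", t.prot_f, t.risk_f, t.pct_prot_f),
            ("M", t.prot_m, t.risk_m, t.pct_prot_m),
        ):
            total = prot + risk
            rows.append(
                {
                    "trait": t.trait,
                    "sex": sex,
                    "prot": prot,
                    "risk": risk,
                    "pct_prot": pct,
                    "pct_risk": 100.0 - pct if total else float("nan"),
                }
            )
    df = pd.DataFrame(rows)
    traits = [t.trait for t in tables]
    x = np.arange(len(traits))
    width = 0.2
    fig, ax = plt.subplots(figsize=(1.3 * len(traits) + 2, 4))
    series = [
        ("F", "prot", -1.5, "seagreen", "F protective"),
        ("F", "risk", -0.5, "lightgreen", "F risk"),
        ("M", "prot", 0.5, "royalblue", "M protective"),
        ("M", "risk", 1.5, "lightblue", "M risk"),
    ]
    for sex, kind, off, color, label in series:
        sub = df[df.sex == sex].set_index("trait").loc[traits]
        heights = sub["pct_prot" if kind == "prot" else "pct_risk"].to_numpy()
        counts = sub[kind].to_numpy()
        bars = ax.bar(x + off * width, heights, width=width, color=color, label=label)
        for b, c in zip(bars, counts):
            ax.annotate(
                str(int(c)),
                (b.get_x() + b.get_width() / 2, b.get_height()),
                ha="center",
                va="bottom",
                fontsize=7,
            )
    ax.set_xticks(x, traits)
    ax.set_ylabel("% of significant associations")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return df
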