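"""Relating H-H sites and TnG repeats to differential gene expression.

The differential-expression table is an input (gene id, interval, log2 fold
change, adjusted p); genes with adjusted p < 0.05 are the regulated
("significant") group.  Two summaries are computed:

* feature density (overlapping feature bp per Mb of window) within windows
  expanding from the gene body by 1 kb up to 1 Mb, averaged per group;
* the fraction of genes with >= 1 feature within a fixed expansion
  (default 2 kb), binned by adjusted p and split by fold-change direction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pyranges as pr

DEFAULT_WINDOWS = (1_000, 3_000, 10_000, 30_000, 100_000, 300_000, 1_000_000)
DEFAULT_P_BINS = (0.0, 1e-10, 1e-5, 0.05, 1.0)
SIGNIFICANCE_ALPHA = 0.05

DE_COLUMNS = ["gene_id", "Chromosome", "Start", "End", "log2fc", "padj"]


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


def _overlap_bp_per_window(windows: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Total merged-feature bp overlapping each window row.

    Features are merged first so density is invariant under splitting a
    feature into adjacent pieces.
    """
    out = np.zeros(len(windows), dtype=float)
    if len(features) == 0 or len(windows) == 0:
        return out
    w = windows.reset_index(drop=True).copy()
    w["_widx"] = np.arange(len(w))
    merged = pr.PyRanges(features[["Chromosome", "Start", "End"]]).merge()
    joined = pr.PyRanges(w[["Chromosome", "Start", "End", "_widx"]]).join(merged).df
    if len(joined) == 0:
        return out
    ov = np.minimum(joined["End"], joined["End_b"]) - np.maximum(
        joined["Start"], joined["Start_b"]
    )
    sums = pd.Series(ov.to_numpy()).groupby(joined["_widx"].to_numpy()).sum()
    out[sums.index.to_numpy()] = sums.to_numpy()
    return out


def density_profile(
    genes: pd.DataFrame,
    features: pd.DataFrame,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Mean feature density (bp/Mb) per expansion window and gene group.

    Each gene's window is its body expanded by ``w`` on both sides (clipped
    at 0); density = overlapping feature bp x 1e6 / window length, averaged
    within the significant (padj < alpha) and non-significant groups.
    """
    windows = sorted(windows)
    sig = genes["padj"] < alpha
    rows = []
    for w in windows:
        expanded = genes[["Chromosome", "Start", "End"]].copy()
        expanded["Start"] = (expanded["Start"] - w).clip(lower=0)
        expanded["End"] = expanded["End"] + w
        bp = _overlap_bp_per_window(expanded, features)
        density = bp * 1e6 / (expanded["End"] - expanded["Start"]).to_numpy()
        for label, mask in (("significant", sig), ("non_significant", ~sig)):
            vals = density[mask.to_numpy()]
            rows.append(
                (w, label, float(vals.mean()) if len(vals) else np.nan, int(mask.sum()))
            )
    return pd.DataFrame(rows, columns=["window", "group", "mean_density", "n_genes"])


def fraction_within(
    genes: pd.DataFrame,
    features: pd.DataFrame,
    radius: int = 2_000,
    p_bins: Sequence[float] = DEFAULT_P_BINS,
    split_direction: bool = True,
) -> pd.DataFrame:
    """Fraction of genes with >= 1 feature within ``radius`` of the gene.

    Genes are binned by adjusted p (half-open bins over [0, 1]) and, when
    ``split_direction``, further split by log2 fold-change sign.  Overlap
    is half-open: an expansion that merely abuts a feature does not count.
    Empty bins report NaN.
    """
    expanded = genes[["Chromosome", "Start", "End"]].copy()
    expanded["Start"] = (expanded["Start"] - radius).clip(lower=0)
    expanded["End"] = expanded["End"] + radius
    has_feature = _overlap_bp_per_window(expanded, features) > 0
    # half-open [lo, hi) bins; padj == 1.0 is folded into the last bin
    padj = genes["padj"].clip(upper=np.nextafter(p_bins[-1], 0))
    bins = pd.cut(padj, bins=list(p_bins), right=False, include_lowest=True)
    direction = (
        np.where(genes["log2fc"] >= 0, "up", "down")
        if split_direction
        else np.repeat("all", len(genes))
    )
    df = pd.DataFrame(
        {"p_bin": bins, "direction": direction, "hit": has_feature}
    )
    grouped = df.groupby(["p_bin", "direction"], observed=False)["hit"]
    out = grouped.agg(n_genes="size", n_with_feature="sum").reset_index()
    out["fraction"] = np.where(
        out["n_genes"] > 0, out["n_with_feature"] / out["n_genes"], np.nan
    )
    return out
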