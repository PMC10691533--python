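"""Cytoband-level chromatin accessibility signal.

Fixed-width accessibility peaks are averaged within each cytoband, fold
changes are taken against the genome background (the mean over all peak
values from all samples), and module-enriched cytobands are compared with
module-depleted ones by a two-sided Wilcoxon rank-sum test (exact for small
groups, normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger("panconet")


def cytoband_peak_signal(peaks: pd.DataFrame,
                         bands: pd.DataFrame) -> pd.Series:
    """Mean peak signal per cytoband (over overlapping regions x samples).

    ``peaks`` carries chrom/start/end plus one column per sample (1-based
    inclusive coordinates); ``bands`` is a cytoband table with a ``name``
    column. A region overlapping a band by any amount counts in that band
    (regions spanning a boundary count in every overlapped band). Bands
    without peaks are NaN.
    """
    sample_cols = [c for c in peaks.columns
                   if c not in ("chrom", "start", "end")]
    if not sample_cols:
        raise ValueError("peak matrix has no sample columns")
    out = {}
    any_overlap = False
    for row in bands.itertuples(index=False):
        hit = ((peaks["chrom"] == row.chrom) & (peaks["start"] <= row.end)
               & (peaks["end"] >= row.start))
        if hit.any():
            any_overlap = True
            out[row.name] = float(
                peaks.loc[hit, sample_cols].to_numpy().mean())
        else:
            out[row.name] = np.nan
    if not any_overlap:
        raise ValueError("no peak overlaps any cytoband")
    sig = pd.Series(out, name="signal")
    n_empty = int(sig.isna().sum())
    if n_empty:
        logger.info("cytoband_peak_signal: %d bands without peaks", n_empty)
    return sig


def fold_change_vs_background(band_signals: pd.Series,
                              peaks: pd.DataFrame) -> pd.Series:
    """Per-band fold change against the genome background mean.

    Background = mean of all peak values over all samples; FC(band) =
    band mean / background. Bands without signal stay NaN.
    """
    sample_cols = [c for c in peaks.columns
                   if c not in ("chrom", "start", "end")]
    background = float(peaks[sample_cols].to_numpy().mean())
    if background <= 0:
        raise ValueError("zero or negative genome background signal")
    return (band_signals / background).rename("fold_change")


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    median_enriched: float
    median_depleted: float
    n_enriched: int
    n_depleted: int
    method: str


def compare_enriched_vs_depleted(fold_changes: pd.Series,
                                 module_enriched_bands: set[str],
                                 exact_max: int = 10) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum of FC: module-enriched vs depleted bands."""
    fc = fold_changes.dropna()
    enriched = fc[fc.index.isin(module_enriched_bands)]
    depleted = fc[~fc.index.isin(module_enriched_bands)]
    if len(enriched) < 2 or len(depleted) < 2:
        raise ValueError("both band groups need >= 2 members")
    method = ("exact" if max(len(enriched), len(depleted)) <= exact_max
              else "asymptotic")
    stat, p = mannwhitneyu(enriched, depleted, alternative="two-sided",
                           method=method, use_continuity=True)
    return WilcoxonResult(float(stat), float(p), float(enriched.median()),
                          float(depleted.median()), len(enriched),
                          len(depleted), method)
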