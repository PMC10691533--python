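"""Differential expression and promoter methylation analysis.

Tumor-vs-normal contrasts are tested per feature with an empirical-Bayes
moderated t-statistic: ordinary least squares on group + covariates gives a
residual variance per feature, variances are shrunk toward a common prior
(d0, s0^2) estimated by moment matching of the log variances, and the
moderated t uses d0 + d residual degrees of freedom. Differentially expressed
genes (DEGs) require fold change > 2 and BH-adjusted P < 0.05; differentially
methylated CpGs (DMCs) require |delta beta| > 0.2 and adjusted P < 0.05 after
masking probes on common SNPs (MAF > 0.05). CpG probes are lifted to genes
through promoter windows (2 kb upstream, 200 bp downstream of the TSS,
strand-aware), and modules are labeled by their joint enrichment for
up/down DEG and DMC gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .enrichment import GeneSetCollection, bh_adjust, fisher_enrichment

logger = logging.getLogger("panconet")


# ---------------------------------------------------- empirical Bayes prior

def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log residual variances.

    With s^2 ~ s0^2 * chi^2_d / d scaled by a feature effect, log s^2 has
    known digamma/trigamma moments; the excess variance of log s^2 over
    trigamma(d/2) identifies d0, the mean identifies s0^2. Returns
    (inf, exp(mean)) when the log variances are no more dispersed than the
    sampling noise (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    if len(z) < 2 or z.var(ddof=1) < 1e-15:
        # literally identical sample variances carry no dispersion signal:
        # the prior equals the common value and shrinkage is a fixed point
        return np.inf, float(np.exp(z.mean()))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - _trigamma(df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


# ------------------------------------------------------------- moderated t

def moderated_t_test(values: pd.DataFrame, groups: pd.Series,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-feature moderated t-test of a two-group contrast.

    ``values`` is feature x sample; ``groups`` maps samples to two labels
    (the lexicographically larger label is the "case" whose effect is
    reported, i.e. tumor > normal). Covariates enter the design as in
    :func:`panconet.preprocess.adjust_covariates`. Returns a frame with
    effect, t, p, adj_p, df, s2, s2_post per feature.
    """
    from .preprocess import _design_matrix

    groups = groups.loc[values.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 samples")
    g = (groups == labels[1]).astype(float)  # case indicator

    if covariates is not None and len(covariates.columns):
        X = _design_matrix(covariates.loc[values.columns])
    else:
        X = pd.DataFrame({"(intercept)": np.ones(len(values.columns))},
                         index=values.columns)
    X = X.assign(group=g.to_numpy())
    Xv = X.to_numpy(dtype=float)
    n, p_cols = Xv.shape
    rank = np.linalg.matrix_rank(Xv)
    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")

    Y = values.to_numpy(dtype=float)
    XtX_inv = np.linalg.pinv(Xv.T @ Xv)
    B = Y @ Xv @ XtX_inv.T                      # features x coefficients
    resid = Y - B @ Xv.T
    s2 = (resid ** 2).sum(axis=1) / df_resid
    effect = B[:, -1]
    se_unscaled = np.sqrt(XtX_inv[-1, -1])

    d0, s0_sq = estimate_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = effect / (np.sqrt(s2_post) * se_unscaled)
    if np.isinf(df_total):
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(t_stat))
    else:
        p = 2 * t_dist.sf(np.abs(t_stat), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({"effect": effect, "s2": s2, "s2_post": s2_post,
                        "t": t_stat, "p": p, "adj_p": bh_adjust(p)},
                       index=values.index)
    out.attrs.update(d0=d0, s0_sq=s0_sq, df_resid=df_resid,
                     case=labels[1], control=labels[0])
    return out


# ---------------------------------------------------------------- calling

def call_degs(results: pd.DataFrame, fc_threshold: float = 2.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Label features up/down/ns: fold change > threshold and adj p < alpha.

    Effects are log2 fold changes; the rule is applied on the natural scale
    as 2^|effect| > fc_threshold with the sign giving the direction.
    """
    out = results.copy()
    up = (2.0 ** out["effect"] > fc_threshold) & (out["adj_p"] < alpha)
    down = (2.0 ** (-out["effect"]) > fc_threshold) & (out["adj_p"] < alpha)
    out["direction"] = np.select([up, down], ["up", "down"], default="ns")
    return out


def map_promoter_probes(probe_annot: pd.DataFrame, gene_annot: pd.DataFrame,
                        upstream: int = 2000,
                        downstream: int = 200) -> pd.DataFrame:
    """Map CpG probes to genes through TSS promoter windows.

    For a + strand gene with TSS t the promoter is [t - upstream,
    t + downstream]; for - strand genes the window is mirrored
    ([t - downstream, t + upstream]). Coordinates are 1-based inclusive. A
    probe inside several genes' windows yields one row per gene. Unknown
    strands are treated as + with a warning.
    """
    strands = gene_annot["strand"].astype(str)
    unknown = ~strands.isin(["+", "-"])
    if unknown.any():
        logger.warning("map_promoter_probes: %d genes with unknown strand "
                       "treated as +", int(unknown.sum()))
        strands = strands.where(~unknown, "+")
    tss = gene_annot["tss"].astype(int)
    lo = np.where(strands == "+", tss - upstream, tss - downstream)
    hi = np.where(strands == "+", tss + downstream, tss + upstream)
    windows = pd.DataFrame({"gene": gene_annot.index, "chrom":
                            gene_annot["chrom"].astype(str), "lo": lo,
                            "hi": hi})
    rows = []
    probes = probe_annot.rename_axis("probe").reset_index()
    for chrom, wsub in windows.groupby("chrom"):
        psub = probes[probes["chrom"].astype(str) == chrom]
        if psub.empty:
            continue
        pos = psub["pos"].to_numpy(int)
        for g, glo, ghi in zip(wsub["gene"], wsub["lo"], wsub["hi"]):
            hit = (pos >= glo) & (pos <= ghi)
            rows.extend({"probe": pr, "gene": g}
                        for pr in psub["probe"].to_numpy()[hit])
    return pd.DataFrame(rows, columns=["probe", "gene"])


def call_dmcs(results: pd.DataFrame, probe_annot: pd.DataFrame,
              delta_threshold: float = 0.2, alpha: float = 0.05,
              maf_cut: float = 0.05) -> pd.DataFrame:
    """Label probes up/down/ns DMCs; SNP-overlapping probes are excluded.

    Probes whose annotated SNP minor allele frequency exceeds ``maf_cut`` are
    dropped before thresholding (|delta beta| > delta_threshold and
    adj p < alpha).
    """
    maf = probe_annot["maf"].reindex(results.index)
    keep = ~(maf > maf_cut)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("call_dmcs: %d probes masked for SNP MAF > %g",
                    n_drop, maf_cut)
    out = results.loc[keep].copy()
    up = (out["effect"] > delta_threshold) & (out["adj_p"] < alpha)
    down = (out["effect"] < -delta_threshold) & (out["adj_p"] < alpha)
    out["direction"] = np.select([up, down], ["up", "down"], default="ns")
    return out


# -------------------------------------------------------- module categories

def categorize_modules(hierarchy, deg_results: pd.DataFrame,
                       dmc_results: pd.DataFrame,
                       probe_to_gene: pd.DataFrame,
                       universe: set[str],
                       size_bounds: tuple[int, int] = (10, 500),
                       min_overlap: int = 4,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Label modules by joint DEG/DMC enrichment (e.g. "dDEG-uDMC").

    DMC probes are lifted to genes via the promoter mapping; each eligible
    module is Fisher-tested against the four sets (up/down DEG genes, up/down
    DMC genes) with the standard significance rule, and the combined label
    concatenates the significant flags ("none" when no flag fires).
    """
    p2g = dict(zip(probe_to_gene["probe"], probe_to_gene["gene"]))
    sets = {
        "uDEG": set(deg_results.index[deg_results["direction"] == "up"]),
        "dDEG": set(deg_results.index[deg_results["direction"] == "down"]),
        "uDMC": {p2g[p] for p in
                 dmc_results.index[dmc_results["direction"] == "up"]
                 if p in p2g},
        "dDMC": {p2g[p] for p in
                 dmc_results.index[dmc_results["direction"] == "down"]
                 if p in p2g},
    }
    coll = GeneSetCollection("regulation",
                             {k: v for k, v in sets.items() if v}, universe)
    rows = []
    for mod in hierarchy.modules:
        if mod.parent is None:
            continue
        if not size_bounds[0] <= len(mod.genes) <= size_bounds[1]:
            continue
        flags = {k: False for k in ("uDEG", "dDEG", "uDMC", "dDMC")}
        if coll.sets:
            try:
                res = fisher_enrichment(set(mod.genes), coll, mod.id,
                                        size_bounds, min_overlap, alpha)
            except ValueError:
                res = []
            for r in res:
                flags[r.set_id] = r.significant
        label = "-".join(k for k in ("uDEG", "dDEG", "uDMC", "dDMC")
                         if flags[k]) or "none"
        rows.append({"module_id": mod.id, **flags, "label": label})
    return pd.DataFrame(rows, columns=["module_id", "uDEG", "dDEG", "uDMC",
                                       "dDMC", "label"])
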