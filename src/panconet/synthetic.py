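"""Multi-cohort, multi-omic synthetic data with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
covariate-adjusted tumor expression data: correlated gene modules are
planted through a spiked-covariance latent-factor model (each module gene
loads on a shared factor, optionally plus a child factor, with loadings tuned
so the mean within-module |Pearson r| hits a target), modules can be shared
across cohorts or private to one, demographic covariates (age, sex, race)
contribute linear effects, survival times follow an exponential hazard that
is log-linear in chosen modules' standardized factor scores, promoter CpG
beta values of coupled modules are logistic transforms of expression (hence
anti-correlated), genes of cytoband-assigned modules are colocalized on a
synthetic genome, and fixed-width accessibility peaks carry elevated signal
in the "open" cytobands that host modules. Everything is deterministic under
the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio

# synthetic genome layout: 4 chromosomes x 6 bands of 10 Mb
_CHROMS = ["chr1", "chr2", "chr3", "chr4"]
_BANDS = ["p13", "p12", "p11", "q11", "q12", "q13"]
_BAND_LEN = 10_000_000
_STAINS = ["gneg", "gpos50", "gneg", "gpos50", "gneg", "gpos75"]


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    ``cohorts`` is "all" or a tuple of cohort indices; ``children`` optionally
    lists child-module gene counts (summing to n_genes) for a two-level
    layout; ``cytoband`` pins the module's genes to one synthetic band;
    ``log_hr`` is the per-SD log hazard ratio of the module factor;
    ``meth_coupling`` in {-1, 0, +1} couples promoter methylation to
    expression (-1: beta anti-correlated, the canonical direction).
    """
    id: str
    n_genes: int
    target_r: float = 0.6
    cohorts: tuple[int, ...] | str = "all"
    children: tuple[int, ...] | None = None
    cytoband: str | None = None
    log_hr: float = 0.0
    meth_coupling: int = 0


@dataclass
class SimulationConfig:
    n_cohorts: int = 3
    genes_per_cohort: int = 1200
    samples_per_cohort: int = 200
    modules: list[ModuleSpec] = field(default_factory=list)
    censoring_fraction: float = 0.3
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.4, "race": 0.2})
    n_normal_samples: int = 60
    deg_log2fc: float = 2.0        # tumor-vs-normal shift for coupled modules
    meth_slope: float = 3.0        # logistic slope of the beta~expression link
    cross_child_fraction: float = 0.5  # parent-factor share of target_r
    baseline_hazard: float = 1e-3  # events per day
    n_atac_samples: int = 20
    open_band_uplift: float = 1.8  # added log2 signal in open bands
    seed: int = 0

    def __post_init__(self):
        for m in self.modules:
            if not 10 <= m.n_genes <= 500:
                raise ValueError(f"module {m.id}: gene count {m.n_genes} "
                                 "outside [10, 500]")
            if m.children is not None and sum(m.children) != m.n_genes:
                raise ValueError(f"module {m.id}: child sizes must sum to "
                                 "n_genes")
            if m.meth_coupling not in (-1, 0, 1):
                raise ValueError(f"module {m.id}: meth_coupling must be "
                                 "-1, 0, or 1")
        total = sum(m.n_genes for m in self.modules)
        if total > self.genes_per_cohort:
            raise ValueError(f"module gene counts ({total}) exceed "
                             f"genes_per_cohort ({self.genes_per_cohort})")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        ids = [m.id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate module ids")

    def cohort_labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_cohorts)]

    def module_in_cohort(self, m: ModuleSpec, cohort_idx: int) -> bool:
        return m.cohorts == "all" or cohort_idx in tuple(m.cohorts)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study fixture: 3 cohorts x 1,200 genes x 200 samples with
    12 planted modules (4 shared by all cohorts, 2 shared by two, 6 private),
    two prognostic modules (HR 2.0 and 0.5), two methylation-coupled modules,
    and four cytoband-colocalized modules."""
    modules = [
        ModuleSpec("S1", 24, 0.7, "all", None, "chr1q11", np.log(2.0), 0),
        ModuleSpec("S2", 24, 0.7, "all", None, "chr2q11", np.log(0.5), 0),
        ModuleSpec("S3", 22, 0.7, "all", None, "chr3q11", 0.0, -1),
        ModuleSpec("S4", 22, 0.7, "all", None, "chr4q11", 0.0, -1),
        ModuleSpec("D1", 22, 0.7, (0, 1)),
        ModuleSpec("D2", 22, 0.7, (1, 2)),
        ModuleSpec("P1", 20, 0.7, (0,)),
        ModuleSpec("P2", 20, 0.7, (0,)),
        ModuleSpec("P3", 20, 0.7, (1,)),
        ModuleSpec("P4", 20, 0.7, (1,)),
        ModuleSpec("P5", 20, 0.7, (2,)),
        ModuleSpec("P6", 20, 0.7, (2,)),
    ]
    return SimulationConfig(modules=modules, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure: who belongs where, and every downstream truth."""
    assignments: dict[str, dict[str, str]]   # cohort -> gene -> leaf module
    module_genes: dict[str, list[str]]       # module (incl. children) -> genes
    module_cohorts: dict[str, list[str]]     # module -> cohort labels
    module_cytoband: dict[str, str | None]
    module_loghr: dict[str, float]
    meth_coupling: dict[str, int]
    deg_genes: dict[str, list[str]]          # "up"/"down" -> genes
    dmc_probes: dict[str, list[str]]         # "up"/"down" -> probes
    open_bands: list[str]

    def leaf_labels(self, cohort: str) -> pd.Series:
        return pd.Series(self.assignments[cohort])

    def to_json(self, path) -> None:
        pio.write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


def _gene_names(config: SimulationConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(config.genes_per_cohort)]


def _allocate_genes(config: SimulationConfig) -> dict[str, list[str]]:
    """Assign disjoint gene blocks (from one shared universe) to modules."""
    genes = _gene_names(config)
    out: dict[str, list[str]] = {}
    cursor = 0
    for m in config.modules:
        out[m.id] = genes[cursor:cursor + m.n_genes]
        cursor += m.n_genes
    return out


def generate_multi_cohort(config: SimulationConfig,
                          ) -> tuple[dict[str, dict], GroundTruth]:
    """Generate per-cohort expression (+ covariates, tumor/normal labels).

    Returns ``(cohorts, truth)`` where ``cohorts[label]`` is a dict with
    ``expression`` (genes x samples log2-scale DataFrame, tumor then normal
    samples), ``covariates`` (samples x age/sex/race) and ``groups``
    (tumor/normal labels). The expression model is a spiked-covariance
    latent-factor draw: module gene = sqrt(r)*factor + noise (plus a child
    factor for two-level modules), so mean within-module |r| matches the
    target; shared modules reuse identical gene sets in every cohort.
    """
    gene_alloc = _allocate_genes(config)
    genes = _gene_names(config)
    labels = config.cohort_labels()
    rng_c = _rngs(config, config.n_cohorts + 1)
    rng_global = rng_c[-1]

    # per-gene baseline abundance, shared across cohorts
    baseline = pd.Series(rng_global.normal(7.0, 1.0, len(genes)), index=genes)

    assignments: dict[str, dict[str, str]] = {}
    module_genes: dict[str, list[str]] = {}
    module_cohorts: dict[str, list[str]] = {m.id: [] for m in config.modules}
    cohorts: dict[str, dict] = {}

    for ci, label in enumerate(labels):
        rng = rng_c[ci]
        n_t, n_n = config.samples_per_cohort, config.n_normal_samples
        n_s = n_t + n_n
        sample_ids = ([f"{label}T{j + 1:04d}" for j in range(n_t)]
                      + [f"{label}N{j + 1:04d}" for j in range(n_n)])
        groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n,
                           index=sample_ids)
        X = rng.normal(0.0, 1.0, (len(genes), n_s))
        gene_pos = {g: i for i, g in enumerate(genes)}
        assign: dict[str, str] = {}
        factors: dict[str, np.ndarray] = {}
        for m in config.modules:
            if not config.module_in_cohort(m, ci):
                continue
            module_cohorts[m.id].append(label)
            mg = gene_alloc[m.id]
            module_genes.setdefault(m.id, list(mg))
            rows = [gene_pos[g] for g in mg]
            f_parent = rng.normal(size=n_s)
            factors[m.id] = f_parent
            if m.children is None:
                a = np.sqrt(m.target_r)
                X[rows] = (a * f_parent
                           + np.sqrt(1 - m.target_r) * X[rows])
                for g in mg:
                    assign[g] = m.id
            else:
                r_parent = config.cross_child_fraction * m.target_r
                a_p = np.sqrt(r_parent)
                a_c = np.sqrt(m.target_r - r_parent)
                start = 0
                for k, size in enumerate(m.children):
                    child_id = f"{m.id}.{k + 1}"
                    cg = mg[start:start + size]
                    module_genes.setdefault(child_id, list(cg))
                    crows = [gene_pos[g] for g in cg]
                    f_child = rng.normal(size=n_s)
                    X[crows] = (a_p * f_parent + a_c * f_child
                                + np.sqrt(1 - m.target_r) * X[crows])
                    for g in cg:
                        assign[g] = child_id
                    start += size
            # tumor-vs-normal shift for methylation-coupled modules:
            # coupling -1 plants down-regulated DEGs (whose promoters will
            # be hyper-methylated), +1 the mirror image
            if m.meth_coupling != 0 and n_n > 0:
                shift = m.meth_coupling * config.deg_log2fc
                X[np.ix_(rows, np.arange(n_t))] += shift

        # covariates with linear effects on every gene
        age = rng.normal(60.0, 10.0, n_s)
        sex = rng.choice(["F", "M"], n_s)
        race = rng.choice(["A", "B", "C"], n_s, p=[0.5, 0.3, 0.2])
        cov = pd.DataFrame({"age": age, "sex": sex, "race": race},
                           index=sample_ids)
        designs = {"age": (age - 60.0) / 10.0,
                   "sex": (sex == "M").astype(float),
                   "race_B": (race == "B").astype(float),
                   "race_C": (race == "C").astype(float)}
        for name, coef in config.covariate_effects.items():
            cols = [k for k in designs if k == name or k.startswith(name + "_")]
            for k in cols:
                w = rng.normal(0.0, 1.0, len(genes))
                X += coef * np.outer(w, designs[k])

        expr = pd.DataFrame(X + baseline.to_numpy()[:, None],
                            index=genes, columns=sample_ids)
        assignments[label] = assign
        cohorts[label] = {"expression": expr, "covariates": cov,
                          "groups": groups,
                          "factors": pd.DataFrame(factors,
                                                  index=sample_ids)}

    deg_dir = {-1: "down", 1: "up"}
    deg_genes = {"up": [], "down": []}
    dmc_probes = {"up": [], "down": []}
    for m in config.modules:
        if m.meth_coupling != 0 and config.n_normal_samples > 0:
            deg_genes[deg_dir[m.meth_coupling]].extend(gene_alloc[m.id])
            # beta follows coupling * expression, so its tumor shift is
            # coupling * expression-shift = coupling^2 = up for either sign
            dmc_probes["up"].extend(f"cg_{g}" for g in gene_alloc[m.id])
    truth = GroundTruth(
        assignments=assignments,
        module_genes=module_genes,
        module_cohorts=module_cohorts,
        module_cytoband={m.id: m.cytoband for m in config.modules},
        module_loghr={m.id: float(m.log_hr) for m in config.modules},
        meth_coupling={m.id: m.meth_coupling for m in config.modules},
        deg_genes=deg_genes,
        dmc_probes=dmc_probes,
        open_bands=sorted({m.cytoband for m in config.modules
                           if m.cytoband}),
    )
    return cohorts, truth


def true_factor_scores(cohort_data: dict, truth: GroundTruth,
                       cohort: str) -> pd.DataFrame:
    """Standardized per-sample module activity scores over tumor samples.

    Uses the generator's latent module factors when available (the module's
    true activity, free of measurement and covariate noise); otherwise falls
    back to the mean expression of the planted gene set."""
    tumor = cohort_data["groups"][cohort_data["groups"] == "tumor"].index
    out = {}
    factors = cohort_data.get("factors")
    for mid, genes in truth.module_genes.items():
        if "." in mid or cohort not in truth.module_cohorts.get(mid, []):
            continue
        if factors is not None and mid in factors.columns:
            score = factors.loc[tumor, mid]
        else:
            sub = cohort_data["expression"].loc[
                cohort_data["expression"].index.intersection(genes), tumor]
            score = sub.mean(axis=0)
        out[mid] = (score - score.mean()) / score.std(ddof=1)
    return pd.DataFrame(out)


def generate_survival(eigengene_scores: pd.DataFrame, truth: GroundTruth,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in module scores.

    hazard_i = baseline * exp(sum_m logHR_m * z_mi); censoring times are
    independent exponentials with rate tuned to the configured censoring
    fraction. Returns a frame (sample, time, event).
    """
    if eigengene_scores.shape[0] == 0:
        raise ValueError("empty sample set")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
    lp = np.zeros(len(eigengene_scores))
    for mid in eigengene_scores.columns:
        beta = truth.module_loghr.get(mid, 0.0)
        if beta:
            z = eigengene_scores[mid].to_numpy(dtype=float)
            lp = lp + beta * z
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    f = config.censoring_fraction
    if f > 0:
        c_rate = config.baseline_hazard * f / (1.0 - f)
        t_cens = rng.exponential(1.0 / c_rate, len(rate))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(rate), dtype=int)
        time = t_event
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": event},
                        index=eigengene_scores.index).rename_axis("sample")


def generate_annotation(config: SimulationConfig,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic genome: cytoband table, gene annotation, and peak matrix.

    24 cytobands (4 chromosomes x 6 bands of 10 Mb); genes of
    cytoband-assigned modules sit contiguously inside their band, other genes
    are uniform over the genome; fixed-width 500 bp peaks tile the genome
    every 50 kb, with elevated log2 signal in the "open" bands hosting
    modules. Returns (bands, gene_annotation, peaks).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11]).generate_state(1)[0])
    rows = []
    for chrom in _CHROMS:
        for bi, band in enumerate(_BANDS):
            start = bi * _BAND_LEN + 1
            rows.append({"chrom": chrom, "start": start,
                         "end": start + _BAND_LEN - 1, "band": band,
                         "stain": _STAINS[bi],
                         "name": f"{chrom}{band}"})
    bands = pd.DataFrame(rows)
    band_by_name = bands.set_index("name")

    gene_alloc = _allocate_genes(config)
    genes = _gene_names(config)
    placed: dict[str, tuple[str, int]] = {}
    for m in config.modules:
        if m.cytoband is None:
            continue
        if m.cytoband not in band_by_name.index:
            raise ValueError(f"unknown cytoband {m.cytoband!r}")
        b = band_by_name.loc[m.cytoband]
        pos = int(b["start"]) + 100_000
        for g in gene_alloc[m.id]:
            placed[g] = (str(b["chrom"]), pos)
            pos += 25_000
    chrom_len = len(_BANDS) * _BAND_LEN
    ann_rows = []
    for g in genes:
        if g in placed:
            chrom, tss = placed[g]
        else:
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            tss = int(rng.integers(10_000, chrom_len - 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        band_idx = min((tss - 1) // _BAND_LEN, len(_BANDS) - 1)
        ann_rows.append({"gene": g, "chrom": chrom, "tss": tss,
                         "strand": strand,
                         "cytoband": f"{chrom}{_BANDS[band_idx]}"})
    gene_annot = pd.DataFrame(ann_rows).set_index("gene")

    open_bands = {m.cytoband for m in config.modules if m.cytoband}
    peak_rows = []
    width, step = 500, 50_000
    for chrom in _CHROMS:
        for start in range(1, chrom_len - width, step):
            band_idx = min((start - 1) // _BAND_LEN, len(_BANDS) - 1)
            peak_rows.append({"chrom": chrom, "start": start,
                              "end": start + width - 1,
                              "band": f"{chrom}{_BANDS[band_idx]}"})
    peaks = pd.DataFrame(peak_rows)
    peaks.index = [f"peak_{i + 1:05d}" for i in range(len(peaks))]
    n_peaks = len(peaks)
    base = rng.normal(2.0, 0.4, (n_peaks, config.n_atac_samples))
    uplift = peaks["band"].isin(open_bands).to_numpy()[:, None]
    values = base + config.open_band_uplift * uplift
    for j in range(config.n_atac_samples):
        peaks[f"A{j + 1:03d}"] = values[:, j]
    peaks = peaks.drop(columns=["band"])
    return bands, gene_annot, peaks


def generate_methylation(expr: pd.DataFrame, truth: GroundTruth,
                         config: SimulationConfig,
                         gene_annot: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One promoter CpG probe per gene; coupled modules get
    beta = logistic(coupling * slope * z_expression + noise).

    Probes sit inside the promoter window of their gene's TSS (strand-aware).
    A small fraction of probes on unplanted genes carry a SNP with
    MAF > 0.05 (to exercise the mask). Returns (beta matrix, probe
    annotation with chrom/pos/maf/gene).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 13]).generate_state(1)[0])
    coupled: dict[str, int] = {}
    for mid, sign in truth.meth_coupling.items():
        if sign:
            for g in truth.module_genes[mid]:
                coupled[g] = sign
    genes = [g for g in expr.index if g in gene_annot.index]
    n_s = expr.shape[1]
    beta = np.empty((len(genes), n_s))
    probe_rows = []
    for i, g in enumerate(genes):
        x = expr.loc[g].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std(ddof=1) or 1.0)
        if g in coupled:
            logit = (coupled[g] * config.meth_slope * z
                     + rng.normal(0.0, 0.3, n_s))
        else:
            logit = rng.normal(0.0, 1.0) + rng.normal(0.0, 0.8, n_s)
        beta[i] = 1.0 / (1.0 + np.exp(-logit))
        ann = gene_annot.loc[g]
        offset = 500 if ann["strand"] == "+" else -500
        maf = np.nan
        if g not in coupled and rng.random() < 0.02:
            maf = 0.10  # common SNP -> probe must be masked
        probe_rows.append({"probe": f"cg_{g}", "chrom": ann["chrom"],
                           "pos": int(ann["tss"]) - offset, "maf": maf,
                           "gene": g})
    beta_df = pd.DataFrame(beta, index=[f"cg_{g}" for g in genes],
                           columns=expr.columns)
    probe_annot = pd.DataFrame(probe_rows).set_index("probe")
    return beta_df, probe_annot


def generate_all(config: SimulationConfig) -> dict:
    """Run every generator consistently; returns a bundle dict."""
    cohorts, truth = generate_multi_cohort(config)
    bands, gene_annot, peaks = generate_annotation(config)
    surv_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
    meth_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 13]).generate_state(1)[0])
    for ci, label in enumerate(config.cohort_labels()):
        data = cohorts[label]
        scores = true_factor_scores(data, truth, label)
        surv = generate_survival(scores, truth, config, surv_rng)
        clin = surv.join(data["covariates"], how="left")
        data["clinical"] = clin
        beta, probe_annot = generate_methylation(
            data["expression"], truth, config, gene_annot, meth_rng)
        data["beta"] = beta
        data["probe_annotation"] = probe_annot
    return {"config": config, "cohorts": cohorts, "truth": truth,
            "bands": bands, "gene_annotation": gene_annot, "peaks": peaks}


def write_fixture(bundle: dict, out_dir) -> None:
    """Write a bundle in the pipeline's on-disk formats (plus truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: SimulationConfig = bundle["config"]
    for label in cfg.cohort_labels():
        data = bundle["cohorts"][label]
        pio.write_expression(data["expression"], out / f"{label}.expr.tsv")
        clin = data["clinical"].copy()
        clin["group"] = data["groups"].reindex(clin.index)
        pio.write_clinical(clin, out / f"{label}.clinical.tsv")
        groups_all = data["groups"].rename("group").to_frame()
        groups_all.index.name = "sample"
        cov_all = data["covariates"].join(groups_all)
        pio.write_clinical(cov_all, out / f"{label}.samples.tsv")
        pio.write_beta(data["beta"], out / f"{label}.beta.tsv")
        pio.write_probe_annotation(data["probe_annotation"],
                                   out / f"{label}.probes.tsv")
    pio.write_cytoband(bundle["bands"], out / "cytoband.tsv")
    pio.write_gene_annotation(bundle["gene_annotation"], out / "genes.tsv")
    pio.write_peaks(bundle["peaks"], out / "peaks.bed", out / "peaks.counts.tsv")
    sets = {mid: set(genes) for mid, genes in
            bundle["truth"].module_genes.items()}
    pio.write_gmt(sets, out / "planted_modules.gmt")
    bundle["truth"].to_json(out / "truth.json")


# ------------------------------------------------------- truth evaluation

def module_recovery_ari(hierarchy, truth: GroundTruth, cohort: str) -> float:
    """Adjusted Rand index between detected leaf modules and planted leaf
    assignments, over the cohort's planted genes."""
    from sklearn.metrics import adjusted_rand_score
    planted = truth.assignments[cohort]
    detected = {}
    for leaf in hierarchy.leaves():
        for g in leaf.genes:
            detected[g] = leaf.id
    genes = sorted(planted)
    a = [planted[g] for g in genes]
    b = [detected.get(g, "unassigned") for g in genes]
    return float(adjusted_rand_score(a, b))


def best_match_modules(hierarchies: dict, truth: GroundTruth,
                       min_jaccard: float = 0.25) -> pd.DataFrame:
    """Match each planted (module, cohort) to its best-overlapping detected
    module (by Jaccard over the cohort's hierarchy, root excluded)."""
    rows = []
    for mid, cohorts in truth.module_cohorts.items():
        planted = set(truth.module_genes[mid])
        for cohort in cohorts:
            h = hierarchies[cohort]
            best, best_j = None, -1.0
            for m in h.modules:
                if m.parent is None:
                    continue
                j = len(planted & m.genes) / len(planted | m.genes)
                if j > best_j:
                    best, best_j = m.id, j
            rows.append({"planted": mid, "cohort": cohort,
                         "detected": best if best_j >= min_jaccard else None,
                         "jaccard": best_j})
    return pd.DataFrame(rows)


def preservation_recall(classes: pd.DataFrame, hierarchies: dict,
                        truth: GroundTruth) -> dict[str, float]:
    """Recall of the conserved/specific classification against the plant.

    A planted module shared by >= 2 cohorts counts as recovered-conserved
    when its best-matching detected module is classified conserved in every
    cohort carrying it; a private module counts as recovered-specific when
    its best match is classified specific. Returns
    {"conserved_recall": ..., "specific_recall": ...}.
    """
    match = best_match_modules(hierarchies, truth)
    lab = {(r.cohort, r.module): r.label
           for r in classes.itertuples(index=False)}
    hits = {"conserved": [0, 0], "specific": [0, 0]}
    for mid, cohorts in truth.module_cohorts.items():
        expected = "conserved" if len(cohorts) >= 2 else "specific"
        sub = match[match["planted"] == mid]
        ok = all(row.detected is not None
                 and lab.get((row.cohort, row.detected)) == expected
                 for row in sub.itertuples(index=False))
        hits[expected][1] += 1
        hits[expected][0] += int(ok)
    return {"conserved_recall": hits["conserved"][0] / hits["conserved"][1],
            "specific_recall": hits["specific"][0] / hits["specific"][1]}


def deg_dmc_sensitivity(degs: pd.DataFrame, dmcs: pd.DataFrame,
                        truth: GroundTruth) -> float:
    """Fraction of methylation-coupled module genes recovered as DEG with a
    DMC at their promoter probe (gene-level DEG ∩ DMC sensitivity)."""
    coupled = {g for mid, sign in truth.meth_coupling.items() if sign
               for g in truth.module_genes[mid]}
    if not coupled:
        raise ValueError("no methylation-coupled modules planted")
    deg_hit = set(degs.index[degs["direction"] != "ns"])
    dmc_hit = {p[len("cg_"):] for p in
               dmcs.index[dmcs["direction"] != "ns"]}
    return len(coupled & deg_hit & dmc_hit) / len(coupled)
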