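"""Seeded synthetic methylome/expression/genome-feature generator.

Emulates the statistical structure of a multi-cancer-type Infinium beta-value
study together with the matched normal-tissue expression panel and promoter
genome-feature tracks, and emits machine-readable ground truth so that every
downstream stage of the analysis can be validated offline against planted
gene classes.

The planted structure:

* Genes fall into four classes: ``resistant`` (CGI promoter unmethylated in
  normals and in every tumor), ``cm`` (consistently methylated: susceptible
  in every cancer type), ``vm`` (variably methylated: susceptible in a proper
  nonempty subset of types) and ``background`` (methylated already in normal
  tissue, hence excluded by the normal-unmethylated filter).
* For a susceptible (gene, type) pair each tumor of the type is methylated
  with the planted per-type frequency. Methylation indicators share a
  per-tumor latent load through a Gaussian copula, and the mean beta of
  methylated entries rises with that load (a tumor-purity admixture effect),
  planting a dominant global methylation-load factor in the tumor methylomes.
* Expression across ``n_tissues_expr`` normal tissues is tied to
  susceptibility: a gene susceptible in a cancer type is repressed in the
  tissue matched to that type. Consistently methylated genes are active in
  the fewest tissues, variably methylated genes in more, resistant
  (housekeeping-like) genes in all.
* Promoter windows of hypermethylation-prone genes are depleted of repeats,
  enriched in conservation and indel-purified coverage, and preferentially
  neighbored by lincRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfigError",
    "SynthConfig",
    "GroundTruth",
    "SyntheticBundle",
    "generate_dataset",
    "generate_genome_features",
]

GENE_SPACING = 100_000
GENES_PER_CHROM = 100
TSS0 = 50_000
CGI_HALF = 300          # CGI spans [tss-300, tss+300)
PROBE_HALF = 150        # qualifying probes fall within +-150 bp of the TSS
REPEAT_CLASSES = ("LINE", "SINE", "LTR")
BG_BETA_MEAN = 0.75     # constitutively methylated (background) CGIs
N_EXPR_REPS = 4
SEQ_ELEVATION_FOLD = 4.0
SEQ_PAIR_ELEVATION_P = 0.95
SEQ_BASE_LAMBDA = 12.0
SEQ_BG_LAMBDA = 150.0


class ConfigError(ValueError):
    """Invalid generator configuration; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid config field '{field_name}': {message}")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the conditions exercised throughout the test suite: 3 cancer
    types with 40 tumors and 8 normals each, 2,000 genes, planted per-type
    methylation frequency 0.35 for susceptible genes.
    """

    n_types: int = 3
    tumors_per_type: int = 40
    normals_per_type: int = 8
    n_genes: int = 2000
    frac_resistant: float = 0.30
    frac_cm: float = 0.06
    frac_vm: float = 0.12
    probes_per_gene: tuple[int, int] = (1, 3)
    beta_unmeth_mean: float = 0.10
    beta_meth_mean: float = 0.50
    beta_concentration: float = 50.0
    meth_freq_range: tuple[float, float] = (0.35, 0.35)
    cm_min_freq: float = 0.15
    missing_rate: float = 0.01
    n_tissues_expr: int = 9
    repression_fold: float = 8.0
    load_correlation: float = 0.9
    repeat_rate_bg: float = 0.8     # repeats per kb (all classes pooled)
    repeat_rate_prone: float = 0.2
    cons_high: float = 0.6
    cons_low: float = 0.2
    indel_cov_prone: float = 0.50
    indel_cov_bg: float = 0.15
    p_lincrna_prone: float = 0.35
    p_lincrna_resistant: float = 0.10
    n_seq_pairs: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_types", "tumors_per_type", "normals_per_type", "n_genes",
                     "n_tissues_expr", "n_seq_pairs"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be a positive count")
        for name in ("frac_resistant", "frac_cm", "frac_vm", "missing_rate",
                     "p_lincrna_prone", "p_lincrna_resistant", "cm_min_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(name, "must lie in [0, 1]")
        if self.frac_resistant + self.frac_cm + self.frac_vm > 1.0 + 1e-12:
            raise ConfigError("frac_resistant", "class fractions must sum to <= 1")
        if not (0.0 < self.beta_unmeth_mean < 1.0):
            raise ConfigError("beta_unmeth_mean", "must lie in (0, 1)")
        if not (0.0 < self.beta_meth_mean < 1.0):
            raise ConfigError("beta_meth_mean", "must lie in (0, 1)")
        if self.beta_unmeth_mean >= self.beta_meth_mean:
            raise ConfigError("beta_unmeth_mean", "must be below beta_meth_mean")
        if self.beta_concentration <= 0:
            raise ConfigError("beta_concentration", "must be > 0")
        lo, hi = self.meth_freq_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("meth_freq_range", "must satisfy 0 < lo <= hi <= 1")
        if not (0.0 <= self.load_correlation < 1.0):
            raise ConfigError("load_correlation", "must lie in [0, 1)")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ConfigError("probes_per_gene", "must be a nonempty positive range")
        for name in ("repression_fold", "repeat_rate_bg", "repeat_rate_prone"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be nonnegative")
        if self.n_tissues_expr < self.n_types:
            raise ConfigError("n_tissues_expr", "needs at least one tissue per cancer type")

    @property
    def type_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_types)]

    @property
    def tissue_names(self) -> list[str]:
        """Matched tissues first, then extra panel tissues, reference last."""
        matched = [f"tissue_{t}" for t in self.type_names]
        n_extra = self.n_tissues_expr - self.n_types
        extra = [f"tissue_x{i}" for i in range(max(0, n_extra - 1))]
        ref = ["tissue_ref"] if n_extra >= 1 else []
        return matched + extra + ref

    def to_json(self) -> str:
        d = asdict(self)
        d["probes_per_gene"] = list(self.probes_per_gene)
        d["meth_freq_range"] = list(self.meth_freq_range)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        d["probes_per_gene"] = tuple(d["probes_per_gene"])
        d["meth_freq_range"] = tuple(d["meth_freq_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted gene classes and effects; the oracle for recovery tests.

    ``genes`` is indexed by gene id with columns ``class_label``, ``chrom``,
    ``strand``, ``tss`` and ``n_active_tissues``; ``susceptibility`` and
    ``planted_freq`` are gene x cancer-type; ``active`` is gene x tissue
    (False = repressed or unexpressed in that tissue).
    """

    genes: pd.DataFrame
    susceptibility: pd.DataFrame
    planted_freq: pd.DataFrame
    active: pd.DataFrame
    qualifying_probes: list[str] = field(default_factory=list)

    def gene_set(self, label: str) -> set[str]:
        return set(self.genes.index[self.genes["class_label"] == label])

    @property
    def prone_genes(self) -> set[str]:
        return self.gene_set("cm") | self.gene_set("vm")

    def susceptible_types(self, gene: str) -> set[str]:
        row = self.susceptibility.loc[gene]
        return set(row.index[row])

    def check_premise(self) -> None:
        """Every susceptible (gene, type) is repressed in the matched tissue."""
        for t in self.susceptibility.columns:
            tissue = f"tissue_{t}"
            susceptible = self.susceptibility[t]
            if bool(self.active.loc[susceptible, tissue].any()):
                raise AssertionError(f"susceptible gene active in matched {tissue}")

    def to_json(self) -> str:
        payload = {
            "classes": self.genes["class_label"].to_dict(),
            "susceptible_types": {
                g: sorted(self.susceptible_types(g)) for g in self.susceptibility.index
            },
            "planted_freq": {
                g: {t: float(v) for t, v in row.items() if v > 0}
                for g, row in self.planted_freq.iterrows()
            },
            "active_tissues": {
                g: sorted(row.index[row]) for g, row in self.active.iterrows()
            },
            "qualifying_probes": sorted(self.qualifying_probes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    """All tables of one synthetic study, cross-referenced by shared ids."""

    config: SynthConfig
    truth: GroundTruth
    beta: pd.DataFrame              # probes x samples
    detection_p: pd.DataFrame       # probes x samples
    samples: pd.DataFrame           # sample_id -> role, cancer_type
    tss: pd.DataFrame               # gene_id -> chrom, strand, tss
    probes: pd.DataFrame            # probe_id -> chrom, pos, gene (planted)
    cgi: pd.DataFrame               # chrom, start, end
    expression: pd.DataFrame        # genes x tissues
    expression_reps: pd.DataFrame   # genes x (tissue x replicate)
    presence: pd.DataFrame          # genes x tissues, "P"/"A"
    repeats: pd.DataFrame           # chrom, start, end, class
    indel_purified: pd.DataFrame    # chrom, start, end
    conservation: pd.DataFrame      # chrom, start, end, score
    lincrna: pd.DataFrame           # chrom, start, end, name
    terms: dict[str, list[str]]     # term -> genes
    cgi_counts: pd.DataFrame        # cgi_id x seq samples (+ length column)
    seq_samples: pd.DataFrame       # sample_id -> role, pair_id, source_sample, total_reads
    meth_state: pd.DataFrame | None = None  # planted gene x sample indicators (not serialized)

    def write(self, outdir: str | Path) -> None:
        from . import io as lio

        lio.write_bundle(self, Path(outdir))


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["truth", "beta", "detection", "expression", "features", "terms", "seq"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_truth(config: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    config.validate()
    n = config.n_genes
    gene_ids = [f"GENE{i:05d}" for i in range(n)]
    n_res = round(config.frac_resistant * n)
    n_cm = round(config.frac_cm * n)
    n_vm = round(config.frac_vm * n)
    labels = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_res]] = "resistant"
    labels[order[n_res:n_res + n_cm]] = "cm"
    labels[order[n_res + n_cm:n_res + n_cm + n_vm]] = "vm"

    idx = np.arange(n)
    genes = pd.DataFrame(
        {
            "class_label": labels,
            "chrom": [f"chr{i // GENES_PER_CHROM + 1}" for i in idx],
            "strand": np.where(idx % 2 == 0, "+", "-"),
            "tss": TSS0 + (idx % GENES_PER_CHROM) * GENE_SPACING,
        },
        index=pd.Index(gene_ids, name="gene"),
    )

    types = config.type_names
    susceptibility = pd.DataFrame(False, index=genes.index, columns=types)
    planted_freq = pd.DataFrame(0.0, index=genes.index, columns=types)
    lo, hi = config.meth_freq_range
    for g, lab in zip(gene_ids, labels):
        if lab == "cm":
            susc = types
        elif lab == "vm":
            if config.n_types == 1:
                raise ConfigError("n_types", "vm genes need >= 2 cancer types")
            k = int(rng.integers(1, config.n_types))
            susc = list(rng.choice(types, size=k, replace=False))
        else:
            continue
        susceptibility.loc[g, susc] = True
        freqs = rng.uniform(lo, hi, size=len(susc))
        if lab == "cm":
            freqs = np.maximum(freqs, config.cm_min_freq)
        planted_freq.loc[g, susc] = freqs

    active = _plant_expression_status(genes, susceptibility, config, rng)
    genes["n_active_tissues"] = active.sum(axis=1).astype(int)

    truth = GroundTruth(genes=genes, susceptibility=susceptibility,
                        planted_freq=planted_freq, active=active)
    truth.check_premise()
    return truth


def _plant_expression_status(genes, susceptibility, config, rng) -> pd.DataFrame:
    tissues = config.tissue_names
    matched = {t: f"tissue_{t}" for t in config.type_names}
    other = [ts for ts in tissues if ts not in matched.values() and ts != "tissue_ref"]
    has_ref = "tissue_ref" in tissues
    active = pd.DataFrame(False, index=genes.index, columns=tissues)
    for g, lab in genes["class_label"].items():
        if lab == "resistant":
            active.loc[g, :] = True
        elif lab == "cm":
            # tissue-restricted: active in 1-2 non-matched tissues, maybe ref
            pool = list(other)
            k = int(rng.integers(1, min(2, len(pool)) + 1)) if pool else 0
            chosen = list(rng.choice(pool, size=k, replace=False)) if k else []
            if has_ref and rng.random() < 0.5:
                chosen.append("tissue_ref")
            if not chosen and has_ref:
                chosen = ["tissue_ref"]
            active.loc[g, chosen] = True
        elif lab == "vm":
            non_susc = [matched[t] for t in config.type_names
                        if not susceptibility.loc[g, t]]
            chosen = list(non_susc)
            if other:
                k = int(rng.integers(1, min(2, len(other)) + 1))
                chosen += list(rng.choice(other, size=k, replace=False))
            if has_ref and rng.random() < 0.5:
                chosen.append("tissue_ref")
            active.loc[g, chosen] = True
        else:  # background: random pattern; a few genes unexpressed everywhere
            if rng.random() < 0.02:
                continue
            mask = rng.random(len(tissues)) < 0.6
            if not mask.any():
                mask[int(rng.integers(len(tissues)))] = True
            active.loc[g, np.array(tissues)[mask]] = True
    return active


def _plant_probes(truth: GroundTruth, config: SynthConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    qualifying = []
    counter = 0
    n_lo, n_hi = config.probes_per_gene
    for i, (g, row) in enumerate(truth.genes.iterrows()):
        n_p = int(rng.integers(n_lo, n_hi + 1))
        offs = rng.integers(-PROBE_HALF, PROBE_HALF + 1, size=n_p)
        for off in offs:
            pid = f"cg{counter:07d}"
            rows.append((pid, row["chrom"], int(row["tss"] + off), g, True))
            qualifying.append(pid)
            counter += 1
        # deliberately non-qualifying plants: inside CGI but beyond 200 bp,
        # and outside the CGI entirely
        if i % 10 == 5:
            pid = f"cg{counter:07d}"
            rows.append((pid, row["chrom"], int(row["tss"] + 250), g, False))
            counter += 1
        if i % 10 == 7:
            pid = f"cg{counter:07d}"
            rows.append((pid, row["chrom"], int(row["tss"] + 400), g, False))
            counter += 1
    probes = pd.DataFrame(rows, columns=["probe", "chrom", "pos", "gene", "qualifying"])
    probes = probes.set_index("probe")
    truth.qualifying_probes = qualifying
    return probes


def _sample_sheet(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for t in config.type_names:
        for j in range(config.tumors_per_type):
            rows.append((f"{t}_tumor{j:03d}", "tumor", t))
        for j in range(config.normals_per_type):
            rows.append((f"{t}_normal{j:02d}", "normal", t))
    return pd.DataFrame(rows, columns=["sample_id", "role", "cancer_type"]).set_index("sample_id")


def _beta_params(mean: np.ndarray | float, conc: float):
    a = np.asarray(mean, dtype=float) * conc
    return a, conc - a


def _plant_methylation(truth, samples, config, rng):
    """Gene x sample methylation indicator plus per-tumor methylated-beta mean.

    Susceptible tumors are methylated with the planted frequency through a
    Gaussian copula: indicator = 1{ sqrt(rho) Z_t + sqrt(1-rho) eps < q(f) }
    with a per-tumor load Z_t, so the marginal per-gene count across tumors
    is exactly Binomial(n_tumors, f) while indicators are correlated across
    genes within a tumor.
    """
    genes = truth.genes.index
    state = pd.DataFrame(False, index=genes, columns=samples.index)
    bg = truth.genes["class_label"] == "background"
    state.loc[bg, :] = True  # constitutively methylated, tumors and normals

    rho = config.load_correlation
    # stratified per-tumor load: each type's tumors take a shuffled grid of
    # normal quantiles, so every cohort spans the full load spectrum (as the
    # observed methylomes do) while gene-level indicators stay random
    z_tumor = pd.Series(0.0, index=samples.index)
    for t in config.type_names:
        t_tumors = samples.index[(samples["role"] == "tumor") & (samples["cancer_type"] == t)]
        n_t = len(t_tumors)
        if n_t == 0:
            continue
        grid = norm.ppf((np.arange(n_t) + 0.5) / n_t)
        z_tumor.loc[t_tumors] = rng.permutation(grid)

    for t in config.type_names:
        t_tumors = samples.index[(samples["role"] == "tumor") & (samples["cancer_type"] == t)]
        susc = truth.susceptibility.index[truth.susceptibility[t]]
        if len(susc) == 0 or len(t_tumors) == 0:
            continue
        f = truth.planted_freq.loc[susc, t].to_numpy()[:, None]
        z = (np.sqrt(rho) * z_tumor.loc[t_tumors].to_numpy()[None, :]
             + np.sqrt(1.0 - rho) * rng.standard_normal((len(susc), len(t_tumors))))
        state.loc[susc, t_tumors] = z < norm.ppf(f)

    # methylated-beta mean per tumor: admixture purity rises with load (-Z)
    purity = 0.15 + 0.9 * norm.cdf(-z_tumor.to_numpy())
    span = (config.beta_meth_mean - 0.05) / 0.6
    meth_mean = pd.Series(np.clip(0.05 + span * purity, 0.05, 0.95),
                          index=samples.index)
    meth_mean[samples["role"] == "normal"] = config.beta_meth_mean
    return state, meth_mean


def _draw_beta_matrix(truth, probes, samples, config, state, meth_mean, rng):
    qual = probes["qualifying"].to_numpy()
    gene_of_probe = probes["gene"].to_numpy()
    n_p, n_s = len(probes), len(samples)
    # per-entry mean
    state_np = state.loc[gene_of_probe].to_numpy()          # probes x samples
    mean = np.where(state_np, meth_mean.to_numpy()[None, :], config.beta_unmeth_mean)
    # background genes and non-qualifying plants: high beta everywhere
    bg_probe = (truth.genes.loc[gene_of_probe, "class_label"] == "background").to_numpy()
    fixed_high = bg_probe[:, None] | (~qual[:, None])
    mean = np.where(fixed_high, BG_BETA_MEAN, mean)
    a, b = _beta_params(mean, config.beta_concentration)
    values = rng.beta(a, b)
    return pd.DataFrame(values, index=probes.index, columns=samples.index)


def _draw_detection(beta: pd.DataFrame, config: SynthConfig, rng) -> pd.DataFrame:
    miss = rng.random(beta.shape) < config.missing_rate
    p = rng.uniform(0.0, 0.005, size=beta.shape)
    p[miss] = rng.uniform(0.02, 1.0, size=int(miss.sum()))
    return pd.DataFrame(p, index=beta.index, columns=beta.columns)


def generate_expression(truth: GroundTruth, config: SynthConfig,
                        rng: np.random.Generator):
    """Gene x tissue expression, replicate matrix and presence calls."""
    tissues = config.tissue_names
    base = rng.lognormal(mean=np.log(100.0), sigma=0.4, size=len(truth.genes))
    active = truth.active.to_numpy()
    unexpressed = ~active.any(axis=1)
    level = np.where(active, base[:, None], base[:, None] / config.repression_fold)
    level[unexpressed, :] = 0.0

    noise = rng.lognormal(mean=0.0, sigma=0.25, size=level.shape)
    expression = pd.DataFrame(level * noise, index=truth.genes.index, columns=tissues)

    rep_cols = [f"{ts}_rep{r}" for ts in tissues for r in range(N_EXPR_REPS)]
    rep_noise = rng.lognormal(mean=0.0, sigma=0.25,
                              size=(level.shape[0], level.shape[1] * N_EXPR_REPS))
    reps = np.repeat(level, N_EXPR_REPS, axis=1) * rep_noise
    expression_reps = pd.DataFrame(reps, index=truth.genes.index, columns=rep_cols)

    presence = pd.DataFrame(np.where(active, "P", "A"),
                            index=truth.genes.index, columns=tissues)
    return expression, expression_reps, presence


def generate_genome_features(truth: GroundTruth, config: SynthConfig,
                             rng: np.random.Generator | None = None):
    """Repeat, conservation, indel-purified and lincRNA tracks around TSSs.

    Repeats follow a homogeneous point process whose rate inside +-2 kb of a
    hypermethylation-prone TSS is ``repeat_rate_prone`` and ``repeat_rate_bg``
    everywhere else; conservation averages ``cons_high`` inside +-2 kb of
    prone TSSs and ``cons_low`` elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed + 104729))
    config.validate()
    prone = truth.prone_genes
    span, inner = 5000, 2000
    repeat_rows, cons_rows, indel_rows, linc_rows = [], [], [], []
    for g, row in truth.genes.iterrows():
        chrom, tss = row["chrom"], int(row["tss"])
        is_prone = g in prone
        # --- repeats: inner +-2 kb at class rate, flanks at background rate
        segs = [(tss - span, tss - inner, config.repeat_rate_bg),
                (tss - inner, tss + inner,
                 config.repeat_rate_prone if is_prone else config.repeat_rate_bg),
                (tss + inner, tss + span, config.repeat_rate_bg)]
        for s, e, rate in segs:
            k = rng.poisson(rate * (e - s) / 1000.0)
            if k == 0:
                continue
            starts = np.sort(rng.integers(s, e, size=k))
            lengths = rng.integers(150, 301, size=k)
            classes = rng.choice(REPEAT_CLASSES, size=k)
            for st, ln, cl in zip(starts, lengths, classes):
                repeat_rows.append((chrom, int(st), int(st + ln), cl))
        # --- conservation: 100 bp bins across +-5 kb
        starts = np.arange(tss - span, tss + span, 100)
        mids = starts + 50
        high = is_prone & (np.abs(mids - tss) <= inner)
        level = np.where(high, config.cons_high, config.cons_low)
        scores = np.clip(level + rng.normal(0.0, 0.03, size=level.shape), 0.0, 1.0)
        for st, sc in zip(starts, scores):
            cons_rows.append((chrom, int(st), int(st) + 100, round(float(sc), 4)))
        # --- indel-purified elements: one per 500 bp window in +-2 kb
        cov = config.indel_cov_prone if is_prone else config.indel_cov_bg
        for wst in range(tss - inner, tss + inner, 500):
            frac = rng.uniform(0.6 * cov, 1.4 * cov)
            ln = max(1, int(round(min(frac, 1.0) * 500)))
            off = int(rng.integers(0, 500 - ln + 1))
            indel_rows.append((chrom, wst + off, wst + off + ln))
        # --- lincRNA adjacency
        p = (config.p_lincrna_prone if is_prone
             else config.p_lincrna_resistant)
        if rng.random() < p:
            s = tss + 20_000
            linc_rows.append((chrom, s, s + 1000, f"linc_{g}"))

    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "class"])
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])
    indel = pd.DataFrame(indel_rows, columns=["chrom", "start", "end"])
    lincrna = pd.DataFrame(linc_rows, columns=["chrom", "start", "end", "name"])
    return repeats, conservation, indel, lincrna


def _plant_terms(truth: GroundTruth, config: SynthConfig, rng) -> dict[str, list[str]]:
    genes = list(truth.genes.index)
    prone = sorted(truth.prone_genes)
    resistant = sorted(truth.gene_set("resistant"))
    terms: dict[str, list[str]] = {}

    def sample_term(name, favored, size, frac_favored=0.7):
        n_fav = min(int(round(size * frac_favored)), len(favored))
        fav = list(rng.choice(favored, size=n_fav, replace=False))
        rest_pool = [g for g in genes if g not in set(fav)]
        rest = list(rng.choice(rest_pool, size=size - n_fav, replace=False))
        terms[name] = sorted(fav + rest)

    n_dev = max(2, min(6, len(prone) // 40))
    for i in range(n_dev):
        sample_term(f"GO_DEVELOPMENT_{i}", prone, min(80, max(12, len(prone) // 3)))
    for i in range(n_dev):
        sample_term(f"GO_HOUSEKEEPING_{i}", resistant, min(80, max(12, len(resistant) // 4)))
    for i in range(4):
        terms[f"GO_RANDOM_{i}"] = sorted(rng.choice(genes, size=min(60, len(genes)), replace=False))
    terms["GO_TINY"] = sorted(rng.choice(genes, size=min(5, len(genes)), replace=False))
    return terms


def _plant_cgi_counts(truth: GroundTruth, config: SynthConfig, rng):
    """CGI read counts for a paired tumor/normal MBD-seq-like experiment.

    The sequenced tissue is the first cancer type: CGIs of genes susceptible
    in that type are elevated in most tumor pairs; CGIs without planted
    elevation carry tumor counts copied from the matched normal (no
    methylation difference); background CGIs are high in normals and tumors.
    One normal sample is provided as two identical replicate lanes to
    exercise replicate averaging.
    """
    n_pairs = config.n_seq_pairs
    genes = truth.genes.index
    lengths = pd.Series(2 * CGI_HALF, index=[f"CGI_{g}" for g in genes], name="length")
    seq_type = config.type_names[0]
    elevated_genes = truth.susceptibility[seq_type].to_numpy()
    bg = (truth.genes["class_label"] == "background").to_numpy()

    normal_cols = [f"seqN{i}" for i in range(n_pairs)]
    tumor_cols = [f"seqT{i}" for i in range(n_pairs)]
    lam = np.where(bg, SEQ_BG_LAMBDA, SEQ_BASE_LAMBDA)
    counts = {}
    for i in range(n_pairs):
        normal = rng.poisson(lam)
        elev = elevated_genes & (rng.random(len(genes)) < SEQ_PAIR_ELEVATION_P)
        tumor = normal.copy()
        tumor[elev] = rng.poisson(SEQ_BASE_LAMBDA * SEQ_ELEVATION_FOLD, size=int(elev.sum()))
        tumor[bg] = rng.poisson(SEQ_BG_LAMBDA, size=int(bg.sum()))
        counts[normal_cols[i]] = normal
        counts[tumor_cols[i]] = tumor
    cgi_counts = pd.DataFrame(counts, index=lengths.index)
    # split the first normal into two identical replicate lanes
    rep_a, rep_b = "seqN0_repA", "seqN0_repB"
    cgi_counts[rep_a] = cgi_counts["seqN0"]
    cgi_counts[rep_b] = cgi_counts["seqN0"]
    cgi_counts = cgi_counts.drop(columns=["seqN0"])

    total = 2_000_000
    rows = []
    for i in range(n_pairs):
        pair = f"pair{i}"
        if i == 0:
            rows.append((rep_a, "normal", pair, "seqN0", total))
            rows.append((rep_b, "normal", pair, "seqN0", total))
        else:
            rows.append((normal_cols[i], "normal", pair, normal_cols[i], total))
        rows.append((tumor_cols[i], "tumor", pair, tumor_cols[i], total))
    seq_samples = pd.DataFrame(
        rows, columns=["sample_id", "role", "pair_id", "source_sample", "total_reads"]
    ).set_index("sample_id")
    cgi_counts.insert(0, "length", lengths)
    return cgi_counts, seq_samples


def generate_dataset(config: SynthConfig) -> SyntheticBundle:
    """Generate a complete seeded bundle with planted ground truth."""
    config.validate()
    rngs = _spawn_rngs(config.seed)
    truth = generate_truth(config, rngs["truth"])
    probes = _plant_probes(truth, config, rngs["truth"])
    samples = _sample_sheet(config)
    state, meth_mean = _plant_methylation(truth, samples, config, rngs["beta"])
    beta = _draw_beta_matrix(truth, probes, samples, config, state, meth_mean, rngs["beta"])
    detection_p = _draw_detection(beta, config, rngs["detection"])
    expression, expression_reps, presence = generate_expression(truth, config, rngs["expression"])
    repeats, conservation, indel, lincrna = generate_genome_features(
        truth, config, rngs["features"])
    terms = _plant_terms(truth, config, rngs["terms"])
    cgi_counts, seq_samples = _plant_cgi_counts(truth, config, rngs["seq"])

    tss = truth.genes[["chrom", "strand", "tss"]].copy()
    cgi = pd.DataFrame({
        "chrom": truth.genes["chrom"],
        "start": truth.genes["tss"] - CGI_HALF,
        "end": truth.genes["tss"] + CGI_HALF,
        "name": [f"CGI_{g}" for g in truth.genes.index],
    }).reset_index(drop=True)

    return SyntheticBundle(
        config=config, truth=truth, beta=beta, detection_p=detection_p,
        samples=samples, tss=tss, probes=probes, cgi=cgi,
        expression=expression, expression_reps=expression_reps, presence=presence,
        repeats=repeats, indel_purified=indel, conservation=conservation,
        lincrna=lincrna, terms=terms, cgi_counts=cgi_counts, seq_samples=seq_samples,
        meth_state=state,
    )
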