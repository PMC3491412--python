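# Methods

## Scope and model

The package implements a promoter-hypermethylation analysis for
multi-cancer-type methylome panels. Its object of study is the set of genes
with CpG-island (CGI) promoters that are unmethylated in normal tissue, and
the question of which of them become aberrantly methylated in tumors of each
type. The central biological premise encoded throughout — and planted in the
synthetic data — is that susceptibility follows the transcriptional state of
the tissue of origin: a gene repressed in a normal tissue is prone to
hypermethylation in tumors arising from that tissue, while broadly expressed
housekeeping-like genes resist it.

## Calling rules and their thresholds

All thresholds are exposed on `ClassifierParams`; the defaults are the
field-standard beta-value conventions for Infinium-style data:

| parameter | default | meaning |
|---|---|---|
| `unmeth_thr` | 0.3 | probe unmethylated when β < 0.3 (strict) |
| `meth_thr` | 0.3 | tumor methylated at a probe when β > 0.3 (strict; β = 0.3 is neither) |
| `freq_thr` | 0.20 | "frequent" needs ≥ 20% methylated among evaluable tumors |
| `cm_thr` | 0.05 | CM needs ≥ 5% in every type |
| `mean_beta_thr` | 0.5 | mean-beta rule variant |
| `min_normals` | 1 | non-missing normals required for evaluability |
| detection p | 0.01 | entries with p ≥ 0.01 are missing (conservative: the boundary fails) |
| TSS distance | 200 bp | inclusive (\|d\| ≤ 200), probe must also lie in a CGI (half-open BED intervals) |

Aberrant methylation is only defined against a clean baseline, so a probe is
evaluable for a type only when unmethylated in **all** non-missing normals of
that type; a gene with no evaluable qualifying probe is `not_evaluable`, and
resistance additionally requires evaluability in every type (a gene cannot
be "never methylated anywhere" if it could not be assessed somewhere).
Missing entries are excluded from both numerator and denominator of the
methylated fraction.

Gene-level aggregation is the maximum over evaluable probes. Membership in
the pan-cancer *frequent* and *never* lists is probe-wise, mirroring
probe-level array practice: a gene can enter the frequent list through one
probe and the never list through another, in which case it is excluded as
ambiguous. With max-aggregation alone the two lists could never intersect
and the exclusion rule would be vacuous; the probe-wise construction is what
makes it meaningful.

Equidistant probe-to-gene ties are dropped as ambiguous (the natural
extension of the multi-gene ambiguity rule to the one tie case the mapping
can produce). Quintile assignment sends the remainder to the
lowest-specificity groups and breaks score ties by gene id, so grouping is
deterministic.

### Exact tests

Rank-sum tests use the exact null distribution (inclusive convention,
p = P(U ≥ u_obs)) for combined n ≤ 20 without ties, and the normal
approximation with continuity and tie correction otherwise; all values tied
gives p = 1. Fisher tests are two-sided exact probabilities. The unit of the
repeat-density Fisher test is genes (with/without ≥ 1 repeat of a class
within ±2 kb), not raw repeat counts: gene-level 2×2 tables keep the
independence assumptions defensible, whereas pooled repeat counts across
genes are not exchangeable units. Benjamini–Hochberg adjustment is the
standard step-up.

### Sequencing-based calling

CGI read counts are normalized to RPKM (count / kb of CGI / million mapped
reads), averaging replicate lanes of a sample first. The paired caller
requires strictly greater tumor RPKM ("higher" with ties not counting) in at
least two pairs, within the set of CGIs unmethylated in all normals. No
numeric rule exists in the literature for that input set; the package's
default takes the per-CGI maximum RPKM across normals and keeps the CGIs at
or below its 25th percentile — i.e. the quarter of CGIs that are
consistently lowest in every normal. The rank-sum caller defines no
resistant set (absence of evidence for elevation is not evidence of
consistent absence under that test).

## The synthetic-data generator

`SynthConfig` defaults define the study conditions used everywhere: 3 cancer
types, 40 tumors and 8 normals per type, 2,000 genes, 1–3 qualifying probes
per gene, planted per-type methylation frequency 0.35 for susceptible genes,
1% missingness, 9 expression tissues, 8-fold repression, and a
beta-concentration of 50 around means 0.10 (unmethylated) / 0.50
(methylated, population average).

Planted structure:

- **Classes.** Exact counts: 30% resistant, 6% CM, 12% VM (prone = CM ∪ VM),
  remainder background. VM genes get a proper nonempty susceptible subset of
  types; CM genes are susceptible everywhere. Background genes are planted
  methylated in normal tissue (β ≈ 0.75 in every sample), so they fail the
  evaluability filter — a background gene left unmethylated everywhere would
  be indistinguishable from a resistant gene and the recovery oracle would
  contradict itself. A few probes per bundle are planted non-qualifying
  (inside the CGI beyond 200 bp, or outside the CGI) and carry methylated
  values everywhere, so a filter defect surfaces downstream instead of
  vanishing.
- **Load factor.** Each tumor carries a latent methylation load. Within a
  type the loads are a shuffled grid of normal quantiles (every cohort spans
  the same load spectrum, as real tumor panels do); a gene susceptible at
  frequency f is methylated in a tumor when
  √ρ·Z_t + √(1−ρ)·ε < Φ⁻¹(f), with ρ = 0.9 by default, so each gene's
  methylated-tumor count stays centered on f while indicators are strongly
  correlated within a tumor. The mean β of methylated entries also rises
  with load (a tumor-purity admixture effect: methylated probes in admixed
  tumors show intermediate betas). Together these plant a dominant global
  load factor: PC1 of the tumor methylomes captures >50% of variance and
  tracks median prone-gene methylation, while the type structure lands on
  PCs 2–4. Setting `load_correlation=0` removes the factor.
- **Expression linkage.** One tissue is matched 1:1 to each cancer type; a
  gene susceptible in a type is repressed (active level / `repression_fold`)
  in the matched tissue — the premise invariant, checked at generation time.
  CM genes are active in the fewest tissues, VM genes in more (their
  non-susceptible matched tissues plus a few others), resistant genes
  everywhere; the planted specificity ordering median S(CM) > S(VM) >
  S(resistant) follows. About 2% of background genes are unexpressed
  everywhere (all-zero, absent in presence calls) to exercise the
  removal rule. A replicate matrix (4 per tissue, log-normal noise) feeds
  the Welch-t differential-expression path.
- **Genome features.** Repeats follow a homogeneous point process at
  0.2/kb within ±2 kb of prone TSSs vs 0.8/kb elsewhere (class drawn
  uniformly from LINE/SINE/LTR); conservation is 0.6 vs 0.2 (±0.03 noise) in
  100 bp bins; indel-purified elements cover ~50% vs ~15% of each 500 bp
  window; lincRNAs are placed adjacent to 35% of prone vs 10% of resistant
  genes. Coordinates are 0-based half-open, one chromosome per 100 genes,
  TSSs 100 kb apart, strands alternating to exercise strand-aware windows.
- **CGI counts.** A 5-pair tumor/normal MBD-seq-like experiment for the
  first cancer type: elevated CGIs (genes susceptible in that type) get
  ~4-fold tumor counts in most pairs; unelevated tumor counts are copied
  from the matched normal (no methylation difference and ties are not
  elevation); background CGIs are high in both. One normal is provided as
  two replicate lanes.

Identical config + seed ⇒ byte-identical serialized bundles (per-stage RNG
streams spawned from one seed; fixed float formatting on write).

### What the generator does not emulate

Probe-level chemistry (type I/II probe bias, batch effects), copy-number
artifacts, correlated missingness, CIMP-like discrete subgroups within a
type, multi-transcript TSSs, overlapping genes, and realistic genome
geometry. Passing tests therefore demonstrate that the implementation of the
calling rules, tests and decompositions is correct and well-calibrated under
the declared statistical structure — not that the biological conclusions
would replicate on any particular real dataset.

## Numerical and calibration choices

- Test-suite null calibrations run 200 seeded replicates on reduced problem
  sizes (250 genes / 40% VM for the expression null; 200 genes with all
  feature effects nulled for the type-I study), since the null properties
  under test are size-free. The uniformity of the susceptibility test's
  p-values is checked by Kolmogorov–Smirnov; feature-test type-I counts are
  checked against exact binomial bounds at the nominal level, with the two
  Fisher-based tests held to the upper bound only because exact conditional
  tests on discrete 2×2 tables are conservative by construction.
- The generator's realized-frequency check uses family-wise (Bonferroni)
  exact binomial bounds across all susceptible gene×type pairs; with ~700
  simultaneous checks, per-pair 99% intervals would reject a correct
  generator almost surely. The stratified load makes per-gene counts
  under-dispersed relative to Binomial(n, f), which only tightens them
  inside those bounds.
- PCA imputes missing gene-level betas with the per-gene median before
  centering (deterministic, scale-preserving); variables are centered, never
  scaled, and the PC1 sign is arbitrary, so correlations are reported with
  their magnitude alongside the signed value.
- GO enrichment reports the ratio-form percent change
  100·(pct_set − pct_bg)/pct_bg as primary and the percentage-point
  difference alongside; terms under 10 background genes are dropped; raw
  Fisher p-values are reported without cross-term correction (the
  enrichment tables are descriptive).
- lincRNA adjacency assigns each lincRNA to the gene whose TSS is nearest
  its midpoint — a deterministic stand-in for inherited assignments that
  external annotation pipelines provide.
- Degenerate inputs: all-tied rank tests give p = 1; zero-variance
  equal-mean Welch comparisons give p = 1 (0 when means differ);
  constant vectors make correlations "not testable" rather than NaN
  surprises; an empty test side is flagged `not_testable`.

## Known limitations

The classifier's probe-wise never-list rule requires a probe evaluable in
*every* type, which on sparse panels (many missing normals) shrinks the
resistant set faster than the prone set. The mean-beta mode does not produce
a probe-level table, so its ambiguity exclusion can only act at gene level.
The sequencing callers assume the normal-unmethylated input set is
trustworthy; with very few normals the quantile rule degrades. Window
profiles treat the reflected half-open interval of a minus-strand window as
half-open on the genome (a 1 bp convention at window edges).
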