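# lineage-methylome

Analysis of CpG-island (CGI) promoter hypermethylation across cancer types,
built around the observation that tumors preferentially hypermethylate genes
that are already repressed in their tissue of origin.

The package is for computational epigenomics work on Infinium-style beta
matrices (and MBD-seq/WGBS-style CGI counts): it calls which genes are prone
to or resistant to promoter hypermethylation per cancer type, splits prone
genes into consistently (CM) and variably (VM) methylated subsets, links VM
susceptibility to expression in the matched normal tissue, profiles promoter
genome features, and summarizes tumor methylome structure by PCA. A seeded
synthetic-data generator with planted ground truth makes the whole analysis
testable offline.

## The method

**Gene calling.** Beta values β = I_meth / (I_meth + I_unmeth) ∈ [0,1];
entries with detection p ≥ 0.01 are treated as missing. Only probes inside a
CGI and within 200 bp of their nearest gene's TSS qualify (probes equidistant
to two genes are dropped). Per cancer type, a probe is *evaluable* when
β < 0.3 in every available normal; a tumor is *methylated* at a probe when
β > 0.3. A gene is **frequently hypermethylated** in a type when its
methylated tumor fraction (max over evaluable probes) is ≥ 20%, **never
methylated** when it is 0. Across types:

- **prone** = frequently hypermethylated in ≥ 1 type,
- **resistant** = evaluable in every type and never methylated in any tumor,
- genes reaching both lists through different probes are excluded as
  ambiguous,
- **CM** = prone genes methylated in ≥ 5% of tumors of *every* type,
- **VM** = prone genes never methylated in ≥ 1 type.

A mean-beta rule variant (gene methylated in a tumor when its mean
qualifying-probe β > 0.5) and a 10–50% frequency-threshold sweep are provided,
as are the three sequencing-based callers (paired tumor-vs-matched-normal RPKM
elevation in ≥ 2 pairs; one-sided Wilcoxon rank-sum on CGI RPKM; overlap of
the CGI TSS with pre-defined prone/resistant regions).

**Tissue specificity.** For expression x over N tissues, with
p_t = x_t / Σ_u x_u and Shannon entropy H = −Σ p_t log2 p_t, the specificity
score is S = log2 N − H (0 = uniform, log2 N = single-tissue). Set
comparisons use Wilcoxon rank-sum tests; differential expression uses Welch's
t with Benjamini–Hochberg FDR control; specificity vs. the number of
susceptible tumor types uses Spearman correlation.

**Promoter features.** Non-overlapping transcription-direction windows around
each TSS (1 kb for repeat presence, 500 bp for conservation and
indel-purified coverage); Fisher exact tests on gene-level repeat presence
within ±2 kb, rank-sum tests on regional conservation means, and a Fisher
test on lincRNA nearest-neighbor adjacency.

**Structure.** PCA of tumor methylomes (samples as observations, per-gene
max qualifying-probe β as variables, centered, SVD) over the prone gene set,
plus the Pearson correlation of PC1 with each tumor's median prone-gene
methylation.

## Worked example

```sh
lineage-methylome run --seed 1 --out out/
```

generates the default synthetic study (3 cancer types, 40 tumors + 8 normals
each, 2,000 genes, planted methylation frequency 0.35), runs the full
analysis and prints the recovered set sizes:

```
{"prone": 360, "resistant": 597, "ambiguous": 0, "cm": 119, "vm": 238}
```

`out/report.json` then contains, among others:

- `set_sizes` — as above; 119 of the 360 prone genes are frequent in a
  single cancer type only;
- `recovery` — agreement with the planted truth (here prone F1 = 1.0,
  VM sensitivity 0.992);
- `pca` — PC1 explains 54.5% of tumor-methylome variance and correlates
  with median prone-gene methylation at |r| = 0.95, while PCs 2–4 (26.9%)
  carry the cancer-type separation;
- `expression_tests.susceptibility_expression` — per type, VM genes
  frequently methylated in that type are expressed far lower in the matched
  normal tissue than VM genes never methylated in it (p ≪ 0.01);
- `feature_tests` — repeat depletion (odds ratios < 1), conservation
  elevation and lincRNA adjacency at prone vs. resistant promoters.

The same stages are available as library calls (`HypermethylationCaller`,
`TissueSpecificityScorer`, `MethylomePCA`, and the functions in
`lineage_methylome.features` / `.seqmeth` / `.enrichment`) and as individual
subcommands (`simulate`, `annotate`, `classify`, `seqcall`, `specificity`,
`enrich`, `pca`).

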