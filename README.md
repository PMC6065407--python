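# concord

Tumor–organoid concordance and clonal-dynamics analysis for paired cancer
cohorts — built around esophageal adenocarcinoma organoid panels, where the
central question is whether a patient-derived culture faithfully carries its
donor tumor's mutations, copy-number landscape, mutational signatures,
subclonal architecture, expression program and drug sensitivities.

The package is a library: you drive it from Python (see `examples/`), and a
synthetic paired-cohort generator with known ground truth backs every stage,
so the whole pipeline runs and is tested without any sequencing download.

## What it computes

**Variant concordance with pooled rescue.** Somatic variants observed in a
tumor and its matched organoid are partitioned into shared / tumor-only /
organoid-only. Because tumors are impure (purity 33–78% in this setting)
while organoids are essentially pure tumor, real variants are often missed
in the tumor; a variant called in one sample is *rescued* as shared when the
pooled tumor+organoid evidence calls it and the other sample shows at least
one alternate read.

**Mutational-signature exposures.** A genome's 96-channel trinucleotide
spectrum `c` is decomposed over a six-signature catalog `P` by constrained
quadratic programming,

```
min ‖Pᵀe − c‖²  subject to  e ≥ 0,
```

solved as non-negative least squares. Subtypes follow the dominant
contribution, with S17A+S17B pooled into one "mutagenic" candidate.

**Ploidy-relative copy number and SV filtering.** With sample average ploidy
`p_s`: deletion (cn = 0), amplification (cn ≥ 2·p_s), gain (cn > 1.25·p_s),
loss (cn < 0.75·p_s), else neutral; gene families are classified on their
mean copy number. Structural variants lose blacklist-overlapping calls,
sub-1-kb deletions without read support, and sub-10-kb inversions.

**Subclonal reconstruction.** Per-site cancer cell fractions
`CCF = vaf·(purity·cn + (1−purity)·2)/(purity·m)` are clustered across all
samples jointly with a Dirichlet-process binomial mixture (Gibbs-sampled),
clusters pass three QC filters (≥1% of mutations; member-median CCF within
0.2 of the process CCF; ≤50% of members on one chromosome), and the sum and
crossing rules arrange them into a clone tree. Clone-CCF trajectories across
serial passages are classified as stable, rapid-then-static, or gradual.

**Expression concordance.** Counts are normalized by median-of-ratios size
factors; expressed mutations need RNA depth ≥ 4 and VAF > 0; patient-specific
signature genes pass a three-step selection (tumor-vs-normal, minus general
tumor-vs-organoid culture effects, plus a per-patient one-vs-all shift capped
at the top-50 by base mean); tumors × organoids Pearson correlations over the
gene-set union are clustered with complete linkage.

**Drug response.** Seven-point half-log viability curves are fitted with a
two-parameter logistic on log10 dose; AUC is the mean fitted viability over
the tested doses so sensitivity = 1 − AUC ∈ [0, 1]; IC50s outside the tested
range are censored at the edge; plate quality uses the Z-factor
`1 − 3(σ₊+σ₋)/|μ₊−μ₋|`; anchored chemotherapy combinations fix cisplatin at
4 µM and 5-fluorouracil at 10 µM while titrating epirubicin.

## Worked example

```bash
python examples/variant_concordance.py
```

```
variants present in either sample: 432
without rescue: {'shared': 0.822, 'tumor_only': 0.134, 'organoid_only': 0.044}
with rescue:    {'shared': 0.972, 'tumor_only': 0.021, 'organoid_only': 0.007} (65 variants rescued)
```

A tumor simulated at 40% purity hides many truncal variants below the caller
threshold; pooling the evidence with the pure organoid rescues 65 of them,
raising the shared fraction from 0.82 to 0.97 — the same mechanism that makes
organoid sequencing a sharper lens on the donor tumor than the biopsy itself.

The other scripts in `examples/` walk through signature fitting and subtype
assignment, copy-number/SV classification, subclone reconstruction with
clone-tree rules, expression-signature matching (ten simulated patients, all
tumors correlate best with their own organoid, mean r ≈ 0.6), and a drug
screen with sensitivity clustering.

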