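# Methods

This note documents the models behind each analysis stage, the synthetic
cohort that exercises them, the numerical choices, and the limits of what
the synthetic validation shows.

## Variant concordance and pooled rescue

Variants carry per-sample alternate/total read counts and a caller flag.
Because re-running a somatic caller on merged alignments is out of scope,
pooled calling is modelled at the allele-count level: the detection rule is
applied to the summed alt counts and depths of tumor + organoid. Summing is
exactly the effect merging alignments has on the evidence at a locus, which
is why pooling raises borderline variants above threshold. The detection
rule itself (called iff alt ≥ 3 and VAF ≥ 0.05, configurable) is a surrogate
for a caller-plus-filters stack that has no closed-form description; it
reproduces the qualitative behaviour that matters here — loss of low-VAF
variants in impure tumors. Rescue requires the pooled call plus ≥ 1 alt read
in the other sample ("the variant allele is represented" read literally;
the threshold is configurable). Multi-passage cohorts generalize pairwise
status per passage, with shared meaning tumor + at least one passage.

## Signature exposures

Exposures solve `min ‖Pᵀe − c‖², e ≥ 0` by NNLS on raw counts — the
standard constrained-QP formulation, with no Poisson weighting and no
sum-to-total constraint; proportions are normalized afterwards. The solver
is deterministic, scale-equivariant, and is checked in the tests against a
dense simplex grid search with closed-form optimal scaling per direction.
The six-signature catalog is an input file (COSMIC-style channel × signature
TSV); the packaged default for simulations is a seeded sparse random
catalog, because the genuine esophageal signature vectors live in an
external supplement and copying them is neither needed for validation nor
appropriate. Subtype assignment pools every signature mapped to "mutagenic"
(S17A and S17B in the default map) into a single candidate before taking
the maximum; exact ties break by catalog order with a warning.

## Copy-number and structural-variant rules

The cut-offs (deletion cn = 0; amplification cn ≥ 2·p_s; gain > 1.25·p_s;
loss < 0.75·p_s) are transcribed with their stated inclusive/strict
boundaries, and gain is bounded above at 2·p_s so the five classes
partition the axis — necessary for class matrices and fraction-altered
summaries. Family averages use total copy number (the major-allele variant
is a plausible alternative but is not what a total-CN matrix supports).
Genome-fraction-altered is length-weighted over profiled segments only.
"Extreme read depth" and similar problematic regions are supplied as a
blacklist file rather than recomputed, since they have no numeric
definition independent of a sequencing run.

## CCF estimation and Dirichlet-process clustering

The estimator is the standard purity/copy-number correction with
multiplicity `m = clip(round(vaf/purity·D), 1, max(cn,1))`,
`D = purity·cn + (1−purity)·2`, and `CCF = vaf·D/(purity·m)` clipped to
[0, 1.5] with clip events flagged.

Clustering is a truncated stick-breaking Dirichlet-process mixture
(concentration α = 1, truncation 12 components, 2000 Gibbs sweeps of which
500 are warm-up, seeded) over S-dimensional CCF space. Cluster positions
live on a uniform CCF grid (step 0.01); because site likelihoods factorize
over samples, all grid log-likelihoods are precomputed once and each sweep
reduces to gathers and one matrix product, keeping a 600-mutation,
two-sample run under two seconds. Truncated samplers leave duplicate and
tail atoms on single mixture components, so the final partition is
consolidated by greedy pairwise merging under the collapsed posterior: two
clusters merge when grid-marginalized likelihood plus the
Chinese-restaurant partition prior (Γ(n) occupancy terms and one factor α
per component) favors one component over two. This absorbs sampling-tail
fragments while leaving genuinely separated clones (likelihood gaps of
hundreds of log units at depth 100) untouched. Cluster centers are the
per-sample medians of the conditional grid posterior of the merged member
set; the process CCF used by QC rule 2 is the posterior mean.

QC keeps a cluster only if it holds ≥ 1% of all mutations (union across
samples — the per-sample reading is available via the threshold argument),
its member-median CCF stays within 0.2 of the process CCF in every sample,
and no chromosome carries more than half its members.

The sum/crossing tree rules use tolerance τ = 0.05, about twice the center
standard error at depth 100. Construction attaches clusters in descending
mean CCF as high in the tree as possible; a pigeonhole sum-rule violation
with an enclosing sibling pushes the smaller cluster inside the larger,
crossing CCFs force disjoint branches, and sibling pairs that could also
nest are flagged ambiguous rather than silently resolved. Cross-passage
cluster identity uses member-set Jaccard ≥ 0.5 when passages are clustered
separately; joint multi-sample clustering is the default. Trajectories are
classified stable (no clone's CCF range exceeds 0.1), rapid-then-static
(≥ 70% of total absolute CCF change at the derivation step) or gradual;
both thresholds are arguments.

## Expression concordance

Normalization uses median-of-ratios size factors with log2(x/sf + 1)
values — a variance-flattening approximation to a full variance-stabilizing
transform that preserves the orderings the selection steps depend on. The
internal differential-expression engine is a per-gene Welch t-test on
normalized values (log2 fold change = difference of group means; base mean
= mean normalized count); the three-step selection procedure, not the test
engine, is the scientific content, and the engine is pluggable.

The three steps use the quoted thresholds (step 1: p ≤ 0.01, normal-minus-
tumor log2FC ≤ −1; step 2 discard: p ≤ 0.01, |log2FC| ≥ 1; step 3: one-vs-
all organoids, p ≤ 0.05 and |log2FC| ≤ 1, with a switch to ≥ 1 since the
stated cap conflicts with "specifically up- or downregulated" and no intent
is guessed). The top-50-by-base-mean cap is applied per patient within the
genes that survive steps 1–2 and that patient's step-3 test: a single
global top-50 would cap the union of all patients' signatures at 50 genes,
which cannot express per-patient signatures at cohort scale. Both scopes
are available (`top50_scope`).

## Drug response

The two-parameter logistic `v(x) = 1/(1 + exp((x − x₀)/s))` on
x = log10 molar dose fixes the asymptotes at 1 and 0, which is identifiable
from seven points; multi-level curve families are out of scope. Fits use
deterministic initialization (midpoint from the dose nearest viability 0.5,
slope a quarter of the tested range) with bounded least squares, so
identical data give identical fits; non-convergence falls back to a
normalized trapezoid on the raw points and is flagged. AUC is the mean
fitted viability over the seven tested doses, making 1 − AUC a [0, 1]
sensitivity score; IC50s beyond the tested range are censored at the edge,
which is equivalent to fitted viability at the extreme dose crossing 0.5.
Censored IC50s rank at the range edge in replicate correlations and are
excluded from threshold counts. Viability is defined as signal over the
median negative-control signal and values above 1 are kept for fitting.

## The synthetic cohort

The generator plants the truth each stage must recover and mirrors the
study conditions: tumors at 50× depth with purity defaulting to 0.6
(cohort range roughly 0.33–0.78), organoid passages pure at 30×, a toy
genome of 22 chromosomes × 10 Mb, multiplicity 1 by default (per-mutation
multiplicity is available for amplified segments).

Clone trees give every node Dirichlet-like allocation logits over
self-retained versus child CCF mass, guaranteeing the children-sum
invariant by construction. Between consecutive samples the logits receive
Gaussian perturbations of amplitude `selection_shift · 3 · 0.35^(j−1)` for
transition j, so the derivation step dominates compositional change and
later passages stabilize — a bottleneck-selection schedule; the magnitude
is a free parameter because no quantitative bottleneck model is available.
Mutation channels come from exposure-weighted catalog mixtures; allele
counts follow the VAF law with Poisson depth and binomial sampling, and
zero-alt sites are emitted as caller-missed observations.

Subclone-recovery experiments redraw trees until all clone pairs are
separated by ≥ 0.25 CCF in some sample and every clone is detectable
(CCF ≥ 0.15 somewhere): clones closer than the ±0.1 recovery tolerance are
statistically indistinguishable at depth 100, so unidentifiable draws would
test nothing.

Expression counts are negative-binomial (gamma-Poisson) with dispersion 0.1
(typical bulk RNA-seq) around log2 baselines N(6, 1.5), with per-sample
library-size factors. Three planted programs drive the concordance
analysis: a tumor program (150 genes, +1.5–3 log2 in tumors and organoids
versus normal squamous), a culture-environment program (150 genes, ±1.5–3
log2 in all organoids), and 50 patient-specific marker genes per patient,
shifted ±0.8–0.95 log2 in that patient's tumor and organoids only. Marker
genes sit on high, tight baselines (log2 ≈ N(9, 0.3)) plus a uniform +2
tumor effect so they pass the tumor-versus-normal step and survive the
base-mean ranking. The defaults come from a power calculation against the
quoted selection thresholds: with four organoid passages per patient,
Welch one-vs-all tests at NB dispersion 0.1 have per-gene power around
0.6–0.8 at effect 0.85 log2 while the |log2FC| ≤ 1 cap still retains most
estimates, leaving ≈ 20–50 signature genes per patient — enough signal for
matched-pair recovery without making the task trivial. Effects below
≈ 0.5 log2, two passages per patient, or dispersion ≳ 0.3 would starve
step 3 of power under the quoted thresholds.

Viability plates evaluate the logistic at the half-log ladder, add Gaussian
noise (default σ = 0.05, clipped at zero), and append 16 negative and 16
positive control wells.

## What the synthetic validation does and does not show

The generators reproduce the statistical structure the analyses assume —
binomial allele counts at known CCFs, NB counts with planted programs,
logistic viability — so passing tests demonstrate that each stage recovers
its planted truth at the stated tolerances and that every filtering rule
matches its definition exactly. They do not emulate alignment artefacts,
caller-specific error modes, copy-number mis-segmentation, stromal
contamination of expression profiles, batch effects, or assay drift; on
real cohorts those error sources widen every tolerance, and the clustering
depends on reasonably accurate purity and copy-number inputs. Problem
sizes in the tests and the acceptance script (600-mutation clone trees,
2,000-gene expression panels, 30-pair screens, 50-run recovery sweeps) are
the package's validation scale, chosen to exercise every code path with
tight planted-truth checks.

## Known limitations

De novo signature extraction, haplotype-aware copy-number calling,
mutation timing, whole-genome-duplication detection and biomarker–response
association are out of scope. The DP sampler uses a fixed truncation (12
components) and a grid prior on CCFs; both are adequate for the clone
counts organoid cohorts exhibit but would need widening for highly
polyclonal tissues. The rescue model operates on allele counts, not reads,
so it cannot reproduce mapping-level rescue failures.
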