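"""Expression normalization, expressed-SNV calls and patient-specific
signature concordance.

Bulk RNA-seq counts from tumors, adjacent normal squamous esophagus and
organoid cultures are normalized by median-of-ratios size factors and
log2-transformed (a variance-flattening stand-in for a full variance
stabilizing transform). Somatic mutations are classified as expressed from
RNA read counts at the DNA-called loci: a site needs depth >= 4, and any
alternate read (VAF > 0) marks the mutant allele as expressed.

Patient-specific signature genes are selected in three steps:

1. keep genes under-expressed in normals vs tumors (p <= 0.01, log2FC <= -1
   with the contrast oriented normal minus tumor);
2. discard genes differentially expressed between tumors and organoids in
   general (p <= 0.01, |log2FC| >= 1) — culture-environment effects;
3. per patient, keep genes specifically shifted in that patient's organoids
   (one-vs-all other organoids, p <= 0.05 and |log2FC| <= 1 as quoted; a
   switch to >= 1 is provided) that rank in the top 50 by base mean.

The tumor x organoid Pearson-correlation matrix over the union of selected
genes, with complete-linkage Euclidean clustering of both axes, summarizes
how well each organoid recapitulates its donor tumor's expression program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

SAMPLE_CLASSES = ("tumor", "normal", "organoid")

EXPRESSED_SNV_STATUSES = ("not_expressed", "reference_expressed", "alternative_expressed")


def classify_expressed_snv(rna_depth: int, rna_alt_count: int) -> str:
    """Expressed-mutation call from RNA counts at a DNA-mutated locus."""
    if rna_depth < 0 or rna_alt_count < 0:
        raise ValueError("counts must be non-negative")
    if rna_alt_count > rna_depth:
        raise ValueError("alt count cannot exceed depth")
    if rna_depth < 4:
        return "not_expressed"
    if rna_alt_count == 0:
        return "reference_expressed"
    return "alternative_expressed"


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts with per-sample class and patient labels."""

    counts: pd.DataFrame
    classes: pd.Series  # sample -> tumor | normal | organoid
    patients: pd.Series  # sample -> patient label ("" for unmatched normals)

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        if list(self.classes.index) != samples or list(self.patients.index) != samples:
            self.classes = self.classes.reindex(samples)
            self.patients = self.patients.reindex(samples)
        if self.classes.isna().any() or self.patients.isna().any():
            raise ValueError("every sample needs a class and a patient label")
        bad = set(self.classes) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, cls: str, patient: str | None = None) -> list[str]:
        mask = self.classes == cls
        if patient is not None:
            mask &= self.patients == patient
        return list(self.classes.index[mask])


def normalize_counts(counts: pd.DataFrame):
    """Median-of-ratios size factors and log2(count / sf + 1) matrix.

    The reference is the per-gene geometric mean over genes expressed in
    every sample; a sample sharing no such genes is an input error.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization requires >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no genes expressed in all samples; cannot form reference")
    ref = np.exp(np.mean(np.log(mat[everywhere]), axis=1))
    size_factors = np.median(mat[everywhere] / ref[:, None], axis=0)
    if np.any(size_factors <= 0):
        raise ValueError("non-positive size factor; sample shares no expressed genes")
    normalized = np.log2(mat / size_factors[None, :] + 1.0)
    return (
        pd.DataFrame(normalized, index=counts.index, columns=counts.columns),
        pd.Series(size_factors, index=counts.columns, name="size_factor"),
    )


@dataclass
class DEResult:
    """Per-gene differential-expression table."""

    table: pd.DataFrame  # columns: log2fc, pvalue, base_mean

    def passing(self, max_p: float, min_abs_lfc: float = 0.0,
                direction: str | None = None) -> pd.Index:
        t = self.table
        mask = t["pvalue"] <= max_p
        if direction == "down":
            mask &= t["log2fc"] <= -min_abs_lfc
        elif direction == "up":
            mask &= t["log2fc"] >= min_abs_lfc
        else:
            mask &= t["log2fc"].abs() >= min_abs_lfc
        return t.index[mask]


def differential_expression(normalized: pd.DataFrame, group_a, group_b,
                            counts_scale: pd.DataFrame | None = None) -> DEResult:
    """Welch t-test per gene on normalized log2 values.

    log2 fold change is mean(group_a) - mean(group_b) on the log2 scale;
    base mean is the mean normalized count (2**value - 1) over both groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = normalized[group_a].to_numpy()
    b = normalized[group_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    base = (2.0 ** normalized[group_a + group_b].to_numpy() - 1.0).mean(axis=1)
    return DEResult(pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals, "base_mean": base},
        index=normalized.index,
    ))


@dataclass
class SignatureGeneParams:
    """Thresholds of the three-step signature-gene selection (all quoted
    defaults; every threshold is configurable)."""

    step1_p: float = 0.01
    step1_lfc: float = -1.0  # normal-minus-tumor contrast, "less in normals"
    step2_p: float = 0.01
    step2_abs_lfc: float = 1.0
    step3_p: float = 0.05
    step3_abs_lfc: float = 1.0
    step3_lfc_mode: str = "le"  # "le" as quoted; "ge" alternative reading
    top_n: int = 50
    top50_scope: str = "within_selected"  # or "within_survivors"


def select_signature_genes(em: ExpressionMatrix, patient: str,
                           normalized: pd.DataFrame | None = None,
                           params: SignatureGeneParams | None = None) -> list[str]:
    """Patient-specific signature genes by the three-step selection."""
    params = params or SignatureGeneParams()
    for cls in SAMPLE_CLASSES:
        if not em.samples_of(cls):
            raise ValueError(f"missing sample class {cls!r}")
    if normalized is None:
        normalized, _ = normalize_counts(em.counts)

    tumors = em.samples_of("tumor")
    normals = em.samples_of("normal")
    organoids = em.samples_of("organoid")
    own_organoids = em.samples_of("organoid", patient)
    other_organoids = [s for s in organoids if s not in own_organoids]
    if not own_organoids:
        raise ValueError(f"patient {patient!r} has no organoid samples")

    # Step 1: tumor-associated genes (under-expressed in normals).
    de_nt = differential_expression(normalized, normals, tumors)
    step1 = set(de_nt.passing(params.step1_p, abs(params.step1_lfc), direction="down"))

    # Step 2: drop general culture-environment genes.
    de_to = differential_expression(normalized, tumors, organoids)
    culture = set(de_to.passing(params.step2_p, params.step2_abs_lfc))
    survivors = step1 - culture

    # Step 3: patient-specific shift among organoids, capped by base mean rank.
    de_own = differential_expression(normalized, own_organoids, other_organoids)
    t = de_own.table
    sig = t["pvalue"] <= params.step3_p
    if params.step3_lfc_mode == "le":
        sig &= t["log2fc"].abs() <= params.step3_abs_lfc
    elif params.step3_lfc_mode == "ge":
        sig &= t["log2fc"].abs() >= params.step3_abs_lfc
    else:
        raise ValueError("step3_lfc_mode must be 'le' or 'ge'")
    specific = set(t.index[sig]) & survivors

    base_mean = de_nt.table["base_mean"]
    if params.top50_scope == "within_selected":
        pool = specific
    elif params.top50_scope == "within_survivors":
        pool = survivors
    else:
        raise ValueError("top50_scope must be 'within_selected' or 'within_survivors'")
    top = set(base_mean.loc[sorted(pool)].nlargest(params.top_n).index)
    return sorted(specific & top)


@dataclass
class CorrelationResult:
    """Tumor x organoid Pearson matrix with clustering and pair recovery."""

    matrix: pd.DataFrame  # tumors (rows) x organoids (columns)
    row_order: list
    col_order: list
    matched_argmax: pd.Series  # per tumor row: argmax column is patient-matched
    summary: dict = field(default_factory=dict)


def correlation_matrix(em: ExpressionMatrix, gene_sets: dict[str, list[str]],
                       normalized: pd.DataFrame | None = None) -> CorrelationResult:
    """Pearson correlations between tumor and organoid profiles over the
    union of per-patient signature genes, with complete-linkage Euclidean
    clustering of rows and columns."""
    if normalized is None:
        normalized, _ = normalize_counts(em.counts)
    genes = sorted(set().union(*gene_sets.values())) if gene_sets else []
    if not genes:
        raise ValueError("union of signature gene sets is empty")
    tumors = em.samples_of("tumor")
    organoids = em.samples_of("organoid")
    if len(tumors) < 2 or len(organoids) < 2:
        raise ValueError("correlation matrix requires >= 2 tumors and >= 2 organoids")

    sub = normalized.loc[genes]
    flagged = [s for s in tumors + organoids if sub[s].std() == 0]
    if flagged:
        raise ValueError(f"zero-variance profiles over signature genes: {flagged}")
    corr = pd.DataFrame(
        np.corrcoef(sub[tumors].to_numpy().T, sub[organoids].to_numpy().T)
        [: len(tumors), len(tumors):],
        index=tumors, columns=organoids,
    )

    def _order(frame: pd.DataFrame) -> list:
        if len(frame) < 2:
            return list(frame.index)
        link = hierarchy.linkage(frame.to_numpy(), method="complete",
                                 metric="euclidean")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    matched = pd.Series({
        t: em.patients[corr.loc[t].idxmax()] == em.patients[t] for t in tumors
    })
    vals = corr.to_numpy().ravel()
    return CorrelationResult(
        matrix=corr,
        row_order=_order(corr),
        col_order=_order(corr.T),
        matched_argmax=matched,
        summary={
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "range": (float(vals.min()), float(vals.max())),
            "matched_fraction": float(matched.mean()),
        },
    )
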