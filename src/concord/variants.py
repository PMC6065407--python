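"""Tumor-organoid somatic-variant concordance with pooled-call rescue.

Somatic SNVs/InDels observed in a tumor and its matched organoid are
partitioned into shared / tumor-only / organoid-only. Because primary tumors
are impure (purity 33-78% in this cohort) while organoids are essentially
pure, real variants are often called only in the organoid; the rescue rule
recovers them: a variant called in exactly one sample counts as shared if it
is called from the pooled tumor+organoid evidence AND the variant allele is
represented (>= 1 alt read by default) in the other sample.

Pooled calling is modelled at the allele-count level: the detection rule is
applied to the summed alt counts and summed depths of the two samples, which
reproduces the read-count-boosting effect of merging the alignments.
Coordinates are 1-based; gene intervals are half-open [start, end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

STATUSES = ("shared", "tumor_only", "organoid_only", "absent")


@dataclass(frozen=True)
class DetectionRule:
    """Caller-behaviour surrogate: a variant is 'called' in a sample iff
    alt_count >= min_alt and VAF >= min_vaf."""

    min_alt: int = 3
    min_vaf: float = 0.05

    def __call__(self, alt_count: int, depth: int) -> bool:
        if depth <= 0:
            return False
        return alt_count >= self.min_alt and alt_count / depth >= self.min_vaf


DEFAULT_DETECTION = DetectionRule()


def compute_vaf(alt_count: int, depth: int) -> float:
    """Variant allele fraction alt/depth; NaN when depth is 0 (undefined)."""
    if alt_count < 0 or depth < 0:
        raise ValueError("counts must be non-negative")
    if alt_count > depth:
        raise ValueError("alt_count cannot exceed depth")
    if depth == 0:
        return math.nan
    return alt_count / depth


@dataclass
class VariantObservation:
    """One somatic variant in one sample, with allele counts and call flag."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    called: bool = False
    sample: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based (pos >= 1)")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")
        if self.alt_count < 0 or self.depth < 0:
            raise ValueError("counts must be non-negative")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return compute_vaf(self.alt_count, self.depth)


@dataclass
class VariantTrio:
    """Matched tumor/organoid observations of one variant plus the pooled call."""

    tumor: VariantObservation
    organoid: VariantObservation
    pooled_called: bool

    def __post_init__(self) -> None:
        if self.tumor.key != self.organoid.key:
            raise ValueError("tumor and organoid observations must share the variant key")

    @property
    def key(self) -> tuple:
        return self.tumor.key


class RescueResult(NamedTuple):
    status: str
    rescued: bool


def rescue_status(trio: VariantTrio, min_rescue_alt: int = 1,
                  rescue: bool = True) -> RescueResult:
    """Classify one variant trio as shared / tumor_only / organoid_only / absent.

    With ``rescue`` enabled, a variant called in exactly one sample becomes
    shared when the pooled call succeeded and the other sample shows at
    least ``min_rescue_alt`` alternate reads.
    """
    t, o = trio.tumor.called, trio.organoid.called
    if t and o:
        return RescueResult("shared", False)
    if not t and not o:
        return RescueResult("absent", False)
    other = trio.organoid if t else trio.tumor
    if rescue and trio.pooled_called and other.alt_count >= min_rescue_alt:
        return RescueResult("shared", True)
    return RescueResult("tumor_only" if t else "organoid_only", False)


@dataclass
class ConcordanceSummary:
    """Counts and proportions of the shared/unique variant partition."""

    n_shared: int
    n_tumor_only: int
    n_organoid_only: int
    n_rescued: int = 0

    @property
    def n_present(self) -> int:
        return self.n_shared + self.n_tumor_only + self.n_organoid_only

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_present
        return {
            "shared": self.n_shared / n,
            "tumor_only": self.n_tumor_only / n,
            "organoid_only": self.n_organoid_only / n,
        }


def summarize_concordance(trios, min_rescue_alt: int = 1,
                          rescue: bool = True) -> ConcordanceSummary:
    """Partition variants and report proportions over the present union.

    Variants called in neither sample (and not rescued) are excluded from
    the denominator.
    """
    trios = list(trios)
    if not trios:
        raise ValueError("summarize_concordance requires at least one trio")
    counts = {s: 0 for s in STATUSES}
    n_rescued = 0
    for trio in trios:
        status, rescued = rescue_status(trio, min_rescue_alt=min_rescue_alt, rescue=rescue)
        counts[status] += 1
        n_rescued += rescued
    if counts["shared"] + counts["tumor_only"] + counts["organoid_only"] == 0:
        raise ValueError("no present variants to summarize")
    return ConcordanceSummary(
        n_shared=counts["shared"],
        n_tumor_only=counts["tumor_only"],
        n_organoid_only=counts["organoid_only"],
        n_rescued=n_rescued,
    )


def make_trios(tumor_obs, organoid_obs,
               detection: DetectionRule = DEFAULT_DETECTION) -> list[VariantTrio]:
    """Join per-sample observations on the variant key and model the pooled call.

    Variants observed in only one table get a zero-count placeholder in the
    other; the pooled call applies the detection rule to summed counts.
    """
    tumor_by_key = {o.key: o for o in tumor_obs}
    organoid_by_key = {o.key: o for o in organoid_obs}
    trios = []
    for key in sorted(set(tumor_by_key) | set(organoid_by_key)):
        chrom, pos, ref, alt = key
        t = tumor_by_key.get(key) or VariantObservation(chrom, pos, ref, alt, 0, 0)
        o = organoid_by_key.get(key) or VariantObservation(chrom, pos, ref, alt, 0, 0)
        pooled = detection(t.alt_count + o.alt_count, t.depth + o.depth)
        trios.append(VariantTrio(tumor=t, organoid=o, pooled_called=pooled))
    return trios


@dataclass(frozen=True)
class GeneInterval:
    """Half-open gene interval [start, end), 1-based start."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def driver_overlay(trios, gene_intervals) -> pd.DataFrame:
    """Per-(gene, sample) presence/VAF table for driver-gene visualization.

    A variant is assigned to every interval containing its position; one row
    per (gene, sample, variant) with the rescue-aware status and the VAF in
    that sample.
    """
    rows = []
    for trio in trios:
        chrom, pos, ref, alt = trio.key
        hits = [gi for gi in gene_intervals if gi.contains(chrom, pos)]
        if not hits:
            continue
        status, rescued = rescue_status(trio)
        for gi in hits:
            for sample, obs in (("tumor", trio.tumor), ("organoid", trio.organoid)):
                rows.append({
                    "gene": gi.gene, "sample": sample,
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "status": status, "rescued": rescued, "vaf": obs.vaf,
                })
    return pd.DataFrame(
        rows, columns=["gene", "sample", "chrom", "pos", "ref", "alt",
                       "status", "rescued", "vaf"])


def concordance_table(summary: ConcordanceSummary) -> pd.DataFrame:
    """Stacked-proportion table (one row per category) for plotting."""
    props = summary.proportions
    return pd.DataFrame({
        "category": list(props),
        "count": [summary.n_shared, summary.n_tumor_only, summary.n_organoid_only],
        "proportion": list(props.values()),
    })
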