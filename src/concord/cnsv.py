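"""Ploidy-relative copy-number classification and structural-variant filtering.

Copy-number calls are classified relative to the sample's average ploidy
``p_s`` rather than a fixed diploid baseline, because esophageal
adenocarcinomas are frequently polyploid:

* deletion       total copy number exactly 0
* amplification  cn >= 2 * p_s
* gain           1.25 * p_s < cn < 2 * p_s
* loss           0 < cn < 0.75 * p_s
* neutral        otherwise

The ">=" / ">" / "<" boundary semantics are deliberate and exercised by the
tests; gain is bounded above at 2*p_s so the five classes partition the
copy-number axis. Gene families (e.g. RAS = HRAS/KRAS/NRAS) are summarized
by the arithmetic mean of member total copy numbers, classified with the
same cut-offs.

Structural variants are filtered by breakpoint overlap with a blacklist of
problematic regions plus two size rules: deletions under 1 kb with no
supporting read, and inversions under 10 kb, are discarded as likely
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CN_CLASSES = ("deletion", "loss", "neutral", "gain", "amplification")

SV_TYPES = ("deletion", "duplication", "inversion", "translocation")

# SV filter constants (bp).
MIN_DELETION_SIZE = 1000
MIN_INVERSION_SIZE = 10_000


def classify_segment(total_cn: float, ploidy: float) -> str:
    """Classify a total copy number relative to sample average ploidy."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if total_cn < 0:
        raise ValueError("copy number must be non-negative")
    if total_cn == 0:
        return "deletion"
    if total_cn >= 2 * ploidy:
        return "amplification"
    if total_cn > 1.25 * ploidy:
        return "gain"
    if total_cn < 0.75 * ploidy:
        return "loss"
    return "neutral"


def family_average(gene_cns, ploidy: float) -> tuple[float, str]:
    """Mean total copy number of a gene family and its ploidy-relative class."""
    cns = np.asarray(list(gene_cns), dtype=float)
    if cns.size == 0:
        raise ValueError("gene family must contain at least one gene")
    mean_cn = float(cns.mean())
    return mean_cn, classify_segment(mean_cn, ploidy)


@dataclass
class CNSegment:
    """Allele-specific copy-number segment (1-based, half-open [start, end))."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.minor_cn > self.total_cn:
            raise ValueError("minor copy number cannot exceed total")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


def loh_flag(segment: CNSegment) -> bool:
    """Loss of heterozygosity: minor allele lost but total copy retained."""
    return segment.minor_cn == 0 and segment.total_cn > 0


@dataclass
class SampleCNProfile:
    """All CN segments of one sample plus its average ploidy p_s."""

    segments: list
    ploidy: float

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segments on {a.chrom}")


def genome_fraction_altered(profile: SampleCNProfile) -> dict[str, float]:
    """Length-weighted fractions of the profiled genome that are amplified,
    deleted, or under LOH (denominator: total segment length)."""
    if not profile.segments:
        raise ValueError("profile has no segments")
    total = sum(s.length for s in profile.segments)
    if total == 0:
        raise ValueError("profile has zero total segment length")
    out = {"amplified": 0.0, "deleted": 0.0, "loh": 0.0}
    for seg in profile.segments:
        cls = classify_segment(seg.total_cn, profile.ploidy)
        if cls == "amplification":
            out["amplified"] += seg.length
        elif cls == "deletion":
            out["deleted"] += seg.length
        if loh_flag(seg):
            out["loh"] += seg.length
    return {k: v / total for k, v in out.items()}


@dataclass
class SVCall:
    """One structural-variant call (breakpoints 1-based)."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    size: int | None = None
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type != "translocation":
            if self.size is None or self.size <= 0:
                raise ValueError("intra-chromosomal SVs require a positive size")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be non-negative")

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom1, self.pos1), (self.chrom2, self.pos2))


@dataclass
class Blacklist:
    """Half-open genomic intervals covering problematic regions (gaps,
    satellites, long simple repeats, extreme-depth regions)."""

    intervals: list = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError("blacklist interval end must exceed start")
            self._by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        for segs in self._by_chrom.values():
            segs.sort()

    def contains(self, chrom: str, pos: int) -> bool:
        for start, end in self._by_chrom.get(str(chrom), ()):
            if start <= pos < end:
                return True
            if start > pos:
                break
        return False

    @classmethod
    def from_bed(cls, path) -> "Blacklist":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end"], usecols=[0, 1, 2])
        return cls(intervals=list(df.itertuples(index=False, name=None)))


def filter_svs(svs, blacklist: Blacklist | None = None):
    """Apply the blacklist and size-based artefact filters to SV calls.

    Returns ``(retained, reasons)`` where ``reasons`` is a list aligned to
    the input with ``None`` for retained calls and a short reject reason
    otherwise. Order-independent and idempotent.
    """
    blacklist = blacklist or Blacklist()
    retained: list[SVCall] = []
    reasons: list[str | None] = []
    for sv in svs:
        reason = None
        if any(blacklist.contains(c, p) for c, p in sv.breakpoints):
            reason = "blacklist_overlap"
        elif (sv.sv_type == "deletion" and sv.size is not None
              and sv.size < MIN_DELETION_SIZE and sv.supporting_reads < 1):
            reason = "small_unsupported_deletion"
        elif (sv.sv_type == "inversion" and sv.size is not None
              and sv.size < MIN_INVERSION_SIZE):
            reason = "small_inversion"
        reasons.append(reason)
        if reason is None:
            retained.append(sv)
    return retained, reasons


def family_class_matrix(gene_cn_table: pd.DataFrame, families: dict[str, list[str]],
                        ploidies: dict[str, float]) -> pd.DataFrame:
    """Per-sample gene-family copy-number class matrix.

    ``gene_cn_table``: genes x samples total copy numbers. ``families`` maps a
    family label to its member genes; singletons are allowed.
    """
    rows = {}
    for fam, genes in families.items():
        missing = [g for g in genes if g not in gene_cn_table.index]
        if missing:
            raise KeyError(f"genes absent from table: {missing}")
        rows[fam] = {
            sample: family_average(gene_cn_table.loc[genes, sample], ploidies[sample])[1]
            for sample in gene_cn_table.columns
        }
    return pd.DataFrame(rows).T[list(gene_cn_table.columns)]


def read_cn_bed(path, sample: str = "", ploidy: float | None = None):
    """Read a BED-like TSV (chrom, start, end, total_cn, minor_cn) into segments."""
    df = pd.read_csv(path, sep="\t")
    segs = [
        CNSegment(str(r.chrom), int(r.start), int(r.end),
                  float(r.total_cn), float(r.minor_cn), sample)
        for r in df.itertuples(index=False)
    ]
    if ploidy is not None:
        return SampleCNProfile(segments=segs, ploidy=ploidy)
    return segs


def write_cn_bed(segments, path) -> None:
    pd.DataFrame(
        [{"chrom": s.chrom, "start": s.start, "end": s.end,
          "total_cn": s.total_cn, "minor_cn": s.minor_cn} for s in segments]
    ).to_csv(path, sep="\t", index=False)
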