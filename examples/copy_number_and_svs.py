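"""Ploidy-relative copy-number classes, gene families, and SV filtering.

Classifies copy numbers against the sample's average ploidy, averages a
gene family, computes genome-fraction-altered, and applies the structural-
variant artefact filters.
"""

from concord.cnsv import (
    Blacklist,
    CNSegment,
    SampleCNProfile,
    SVCall,
    classify_segment,
    family_average,
    filter_svs,
    genome_fraction_altered,
)

ploidy = 3.1  # polyploid tumor: thresholds scale with ploidy
for cn in (0, 2, 4, 7):
    print(f"total CN {cn} at ploidy {ploidy}: {classify_segment(cn, ploidy)}")

mean_cn, cls = family_average([2, 6, 2], ploidy=2.0)
print(f"RAS family (HRAS=2, KRAS=6, NRAS=2): mean {mean_cn:.2f} -> {cls}")

profile = SampleCNProfile([
    CNSegment("1", 1, 5_000_001, total_cn=8, minor_cn=2),
    CNSegment("2", 1, 5_000_001, total_cn=2, minor_cn=0),
    CNSegment("3", 1, 10_000_001, total_cn=2, minor_cn=1),
], ploidy=2.0)
print("genome fraction altered:",
      {k: round(v, 3) for k, v in genome_fraction_altered(profile).items()})

svs = [
    SVCall("deletion", "1", 5000, "1", 5800, size=800, supporting_reads=0),
    SVCall("inversion", "2", 1000, "2", 6000, size=5000, supporting_reads=20),
    SVCall("deletion", "3", 5000, "3", 5800, size=800, supporting_reads=3),
]
retained, reasons = filter_svs(svs, Blacklist())
print("SV filter reasons:", reasons,
      f"-> {len(retained)} of {len(svs)} calls retained")
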