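"""Generate a full synthetic paired cohort and write its interchange files.

Produces one patient's clone tree, signature-mixture mutations, and
per-sample allele counts for a tumor plus two organoid passages, then
writes the VCF-like variant tables. The same generators back every test in
the package, so the written files are exactly what the analysis stages read.
"""

from pathlib import Path

from concord.cohort import CohortConfig, simulate_cohort, write_variants_tsv

out = Path("scratch_cohort")
out.mkdir(exist_ok=True)

config = CohortConfig(n_clones=4, n_samples=3, selection_shift=0.6,
                      n_mutations=600, tumor_purity=0.6)
cohort = simulate_cohort(config, seed=42)

print("samples:", cohort.samples)
print("planted clone CCFs:")
print(cohort.truth.tree.ccf_table().round(3))
print(f"{len(cohort.mutations)} mutations over "
      f"{cohort.mutations['chrom'].nunique()} chromosomes")

for sample in cohort.samples:
    path = out / f"{sample}.variants.tsv"
    write_variants_tsv(cohort.observations[sample], path)
    called = int(cohort.observations[sample]["called"].sum())
    print(f"wrote {path} ({called} called variants; uncalled sites kept "
          "for rescue and CCF analysis)")
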