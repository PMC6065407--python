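"""Mutational-signature exposures, subtype, and stability across passages.

Builds a 96-channel spectrum from a known two-signature mixture, fits
exposures by non-negative least squares, assigns the subtype (S17A/S17B
pool toward "mutagenic"), and shows that resampled passages keep exposure
proportions stable.
"""

import numpy as np

from concord.signatures import SignatureCatalog, assign_subtype, exposure_trajectory, fit_exposures

rng = np.random.default_rng(1)
catalog = SignatureCatalog.random(seed=7)

# Genome with 70% S17A + 30% S3 mutations (20,000 total).
mix = 0.7 * catalog.matrix[3] + 0.3 * catalog.matrix[2]
counts = rng.multinomial(20000, mix / mix.sum())

ev = fit_exposures(counts, catalog)
print("fitted proportions:",
      dict(zip(ev.names, np.round(ev.proportions, 3))))
print("subtype:", assign_subtype(ev, catalog),
      "(S17A alone dominates, and pooling S17A+S17B only strengthens it)")

passages = [rng.multinomial(15000, mix / mix.sum()) for _ in range(5)]
_, drift, per_signature = exposure_trajectory(passages, catalog)
print(f"max proportion drift across 5 passages: {drift:.3f} "
      "(pure resampling noise; real exposure switches would exceed it)")
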