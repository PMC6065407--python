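"""Dose-response screening: curve fits, sensitivity matrix and plate QC.

Simulates viability plates for four organoids x three compounds on the
7-point half-log ladder, fits logistic curves, summarizes 1-AUC
sensitivities with IC50 threshold counts, checks plate quality with the
Z-factor, and prints the anchored chemotherapy-combination design.
"""

import numpy as np

from concord.drugs import (
    anchored_combination_layout,
    fit_curve,
    sensitivity_matrix,
    z_factor,
)
from concord.synthetic import simulate_plate

rng = np.random.default_rng(1)
fits = []
for o, organoid in enumerate(["org1", "org2", "org3", "org4"]):
    for c, compound in enumerate(["trametinib", "afatinib", "nutlin-3a"]):
        true_ic50 = 10 ** rng.uniform(-8, -5)
        plate = simulate_plate(true_ic50, 0.3, 1e-5, noise_sd=0.05,
                               seed=100 * o + c, organoid=organoid,
                               compound=compound)
        wells = plate[plate.role == "sample"]
        fit = fit_curve(wells.concentration_M, wells.viability,
                        organoid=organoid, compound=compound)
        fits.append(fit)
        if o == 0:
            qc = z_factor(
                plate.loc[plate.role == "neg_ctrl", "viability"],
                plate.loc[plate.role == "pos_ctrl", "viability"],
            )
            print(f"{organoid}/{compound}: true IC50 {true_ic50:.2e} M, "
                  f"fitted {fit.ic50:.2e} M "
                  f"(censored={fit.censored}), Z-factor {qc.z_factor:.2f}")

summary = sensitivity_matrix(fits)
print("\n1-AUC sensitivity matrix (clustered row order):")
print(summary.matrix.loc[summary.row_order].round(2))
print("\ncompounds with IC50 below 1 uM / 0.1 uM per organoid:")
print(summary.ic50_counts)

print("\nanchored combination design (fixed cisplatin + 5-FU, titrated epirubicin):")
print(anchored_combination_layout().round(10).to_string(index=False))
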