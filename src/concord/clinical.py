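"""Cohort-level clinical bookkeeping.

The donor summary of the esophageal-adenocarcinoma organoid cohort:
10 cultures were established from 32 attempted derivations, and 9 of the 10
sustained long-term growth (>6 months, >=25 passages). The donor table
carries tumor regression grade (TRG; 1 = complete regression after
neoadjuvant chemotherapy, 5 = no regression) and differentiation status.
"""

from __future__ import annotations

import pandas as pd

#: Derivation attempts and outcomes.
N_ATTEMPTED = 32
N_ESTABLISHED = 10
N_LONG_TERM = 9

#: Reasons derivations failed (count of cultures).
FAILURE_REASONS = {
    "no_growth_from_initiation": 11,
    "infection": 5,
    "fibroblast_overgrowth": 4,
    "arrested_growth": 2,
}

#: Clinical characteristics of the 10 donors, ranked by TRG.
DONORS = pd.DataFrame([
    ("CAM298", 58, "M", "ypT1bN0M0", "ECX", "2", "Well"),
    ("CAM388", 78, "M", "ypT2N0M0", "ECX", "4", "Moderate to poor"),
    ("CAM247", 67, "M", "ypT2N2M0", "ECX", "4", "Moderate"),
    ("CAM292", 66, "F", "ypT3N1MX", "ECX", "4", "Moderate to poor"),
    ("CAM296", 72, "M", "ypT3N3MX", "ECF", "4", "Moderate to poor"),
    ("CAM338", 51, "F", "ypT3N1MX", "ECX", "5", "Moderate to poor"),
    ("CAM401", 77, "F", "ypT4aN2M0", "CF", "5", "Poor"),
    ("CAM412", 52, "F", "cT1bN0M0", "none", "no chemotherapy", "Poor"),
    ("CAM277", 80, "F", "cT3N2M0", "none", "no chemotherapy", "Poor"),
    ("CAM408", 60, "M", "cT1aN0M0", "none", "no chemotherapy", "Moderate"),
], columns=["id", "age", "sex", "stage", "regimen", "trg", "differentiation"])


def derivation_efficiency(n_established: int = N_ESTABLISHED,
                          n_attempted: int = N_ATTEMPTED) -> float:
    """Derivation success rate as a percentage."""
    if n_attempted <= 0:
        raise ValueError("n_attempted must be positive")
    if not 0 <= n_established <= n_attempted:
        raise ValueError("n_established must lie in [0, n_attempted]")
    return 100.0 * n_established / n_attempted


def long_term_growth_rate(n_long_term: int = N_LONG_TERM,
                          n_established: int = N_ESTABLISHED) -> float:
    """Fraction of established cultures with long-term growth, in percent."""
    if n_established <= 0:
        raise ValueError("n_established must be positive")
    return 100.0 * n_long_term / n_established
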