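"""Mutational-signature exposure fitting and subtype assignment.

A tumor genome's 96-channel trinucleotide substitution spectrum is modelled
as a non-negative mixture of a small catalog of signatures (here six, the
number recurrently observed in esophageal adenocarcinoma). Exposures are the
mutation counts attributed to each signature; they are obtained by
constrained quadratic programming,

    minimize ||P^T e - c||^2   subject to  e >= 0,

where ``P`` is the 6 x 96 catalog and ``c`` the observed channel counts.
This is exactly non-negative least squares and is solved with
:func:`scipy.optimize.nnls` (deterministic, no tuning). Subtype assignment
follows the dominant-signature rule with the two S17 signatures pooled into
a single "mutagenic" candidate before comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

N_CHANNELS = 96

#: The three signature subtypes used for patient stratification.
SUBTYPES = ("mutagenic", "DDR impaired", "C>A/T dominant")

DEFAULT_NAMES = ("S1", "S2", "S3", "S17A", "S17B", "S18")

#: Default signature -> subtype map. S17A/S17B jointly define the mutagenic
#: subtype; S3 is the BRCA-like DNA-damage-repair signature.
DEFAULT_SUBTYPE_MAP = {
    "S1": "C>A/T dominant",
    "S2": "C>A/T dominant",
    "S3": "DDR impaired",
    "S17A": "mutagenic",
    "S17B": "mutagenic",
    "S18": "C>A/T dominant",
}


def channel_labels() -> list[str]:
    """The 96 trinucleotide channels in COSMIC lexicographic order.

    Substitution classes C>A, C>G, C>T, T>A, T>C, T>G, each with the 16
    flanking-base contexts ordered A, C, G, T on either side.
    """
    labels = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five, three in itertools.product("ACGT", "ACGT"):
                labels.append(f"{five}[{ref}>{alt}]{three}")
    return labels


def channel_ref_alt(channel: int) -> tuple[str, str]:
    """Reference and alternate base of a channel index (pyrimidine strand)."""
    label = channel_labels()[channel]
    return label[2], label[4]


@dataclass
class SignatureCatalog:
    """Six signatures as 96-channel probability vectors plus a subtype map."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (n_signatures, 96)
    subtype_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MAP))

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.names), N_CHANNELS):
            raise ValueError(
                f"catalog matrix must be {len(self.names)} x {N_CHANNELS}, got {self.matrix.shape}"
            )
        if np.any(self.matrix < 0):
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each catalog row must sum to 1 (probability vector)")
        missing = set(self.names) - set(self.subtype_map)
        if missing:
            raise ValueError(f"subtype_map missing signatures: {sorted(missing)}")
        bad = {s for s in self.names if self.subtype_map[s] not in SUBTYPES}
        if bad:
            raise ValueError(f"unknown subtype for signatures: {sorted(bad)}")
        for s17 in ("S17A", "S17B"):
            if s17 in self.names and self.subtype_map[s17] != "mutagenic":
                raise ValueError(f"{s17} must map to the mutagenic subtype")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    @classmethod
    def random(cls, seed: int, names: tuple[str, ...] = DEFAULT_NAMES,
               sparsity: float = 0.75) -> "SignatureCatalog":
        """Seeded random sparse catalog for tests and simulations.

        Each signature concentrates its mass on a random subset of channels
        (fraction ``1 - sparsity`` of the 96), which keeps the signatures
        mutually distinguishable the way real catalogs are.
        """
        rng = np.random.default_rng(seed)
        k = max(4, int(round((1.0 - sparsity) * N_CHANNELS)))
        rows = []
        for _ in names:
            active = rng.choice(N_CHANNELS, size=k, replace=False)
            row = np.full(N_CHANNELS, 1e-4)
            row[active] += rng.gamma(2.0, 1.0, size=k)
            rows.append(row / row.sum())
        return cls(names=tuple(names), matrix=np.array(rows))

    @classmethod
    def from_tsv(cls, path, subtype_map: dict[str, str] | None = None) -> "SignatureCatalog":
        """Read a COSMIC-style matrix TSV: rows = 96 channels, columns = signatures."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        expected = channel_labels()
        if list(df.index) != expected:
            raise ValueError("catalog TSV rows must be the 96 channels in COSMIC order")
        return cls(
            names=tuple(df.columns),
            matrix=df.to_numpy().T,
            subtype_map=subtype_map or dict(DEFAULT_SUBTYPE_MAP),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix.T, index=channel_labels(), columns=self.names).to_csv(
            path, sep="\t"
        )


@dataclass
class ExposureVector:
    """Fitted per-signature exposures (attributed mutation counts)."""

    names: tuple[str, ...]
    exposures: np.ndarray

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if np.any(self.exposures < 0):
            raise ValueError("exposures must be non-negative")
        if len(self.exposures) != len(self.names):
            raise ValueError("exposures/names length mismatch")

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    @property
    def defined(self) -> bool:
        """False when the total exposure is zero (proportions undefined)."""
        return self.total > 0

    @property
    def proportions(self) -> np.ndarray:
        """Exposures normalized to sum to one; NaN when total is zero."""
        if not self.defined:
            return np.full_like(self.exposures, np.nan)
        return self.exposures / self.total

    def as_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=list(self.names))


def _validate_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_CHANNELS,):
        raise ValueError(f"spectrum must have {N_CHANNELS} channels, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("spectrum counts must be non-negative")
    return c


def fit_exposures(counts, catalog: SignatureCatalog) -> ExposureVector:
    """Fit non-negative signature exposures to a 96-channel spectrum.

    Solves ``min ||P^T e - c||^2, e >= 0`` by non-negative least squares on
    raw counts (no Poisson weighting, no sum constraint); proportions are
    obtained post hoc by normalization.
    """
    c = _validate_counts(counts)
    e, _ = nnls(catalog.matrix.T, c)
    return ExposureVector(names=catalog.names, exposures=e)


def assign_subtype(exposure: ExposureVector, catalog: SignatureCatalog) -> str:
    """Assign the subtype of the most prevalent signature contribution.

    Signatures mapped to "mutagenic" (S17A and S17B in the default catalog)
    are pooled: their summed contribution competes as a single candidate.
    Exact ties are broken by catalog order with a warning.

    Raises
    ------
    ValueError
        If the total exposure is zero (subtype undefined).
    """
    if not exposure.defined:
        raise ValueError("subtype undefined: total exposure is zero")
    props = exposure.proportions
    mutagenic_total = sum(
        p for name, p in zip(exposure.names, props)
        if catalog.subtype_map[name] == "mutagenic"
    )
    # Candidates in catalog order; the pooled mutagenic candidate takes the
    # slot of the first mutagenic signature.
    candidates: list[tuple[str, float]] = []
    pooled = False
    for name, p in zip(exposure.names, props):
        if catalog.subtype_map[name] == "mutagenic":
            if not pooled:
                candidates.append(("mutagenic", mutagenic_total))
                pooled = True
        else:
            candidates.append((catalog.subtype_map[name], float(p)))
    best = max(candidates, key=lambda t: t[1])
    ties = [c for c in candidates if c[1] == best[1]]
    if len(ties) > 1:
        warnings.warn(
            "exact tie between signature contributions; "
            "breaking by catalog order", stacklevel=2,
        )
        best = ties[0]
    return best[0]


def exposure_trajectory(series, catalog: SignatureCatalog):
    """Fit exposures for a series of passages and measure proportion drift.

    Parameters
    ----------
    series : sequence of 96-channel count vectors, one per passage (>= 2).

    Returns
    -------
    (fits, drift, per_signature) where ``fits`` is a list of
    :class:`ExposureVector`, ``per_signature`` the max-minus-min proportion
    of each signature across passages, and ``drift`` its maximum.
    """
    series = list(series)
    if len(series) < 2:
        raise ValueError("exposure_trajectory requires at least 2 passages")
    fits = [fit_exposures(c, catalog) for c in series]
    props = np.array([f.proportions for f in fits])
    per_signature = pd.Series(
        props.max(axis=0) - props.min(axis=0), index=list(catalog.names)
    )
    return fits, float(per_signature.max()), per_signature


def exposures_table(samples: dict, catalog: SignatureCatalog) -> pd.DataFrame:
    """Exposure/proportion/subtype table for several samples (CSV-ready)."""
    rows = []
    for sample, counts in samples.items():
        ev = fit_exposures(counts, catalog)
        subtype = assign_subtype(ev, catalog) if ev.defined else "undefined"
        for name, e, p in zip(ev.names, ev.exposures, ev.proportions):
            rows.append({
                "sample": sample, "signature": name,
                "exposure": e, "proportion": p, "subtype": subtype,
            })
    return pd.DataFrame(rows)
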