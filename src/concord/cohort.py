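"""End-to-end synthetic paired-cohort assembly.

Chains the generators into one reproducible object: a clone tree with
per-sample CCFs, mutations drawn from signature mixtures, binomial allele
counts per sample under purity and copy number, and matched tumor/organoid
variant trios ready for the concordance and clonality stages. The defaults
emulate the study conditions: a 50x tumor of intermediate purity plus pure
organoid passages at 30x, with the strongest clonal shift at derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .clonality import CCFObservation
from .signatures import SignatureCatalog
from .variants import DEFAULT_DETECTION, DetectionRule, VariantObservation, make_trios


@dataclass
class CohortConfig:
    """Knobs of the genomic side of a synthetic cohort."""

    n_clones: int = 4
    n_samples: int = 2  # tumor + passages
    selection_shift: float = 0.5
    n_mutations: int = 600
    tumor_purity: float = 0.6  # cohort tumors ranged ~0.33-0.78
    tumor_depth: float = 50.0
    organoid_depth: float = 30.0
    ploidy: float = 2.0
    exposures: np.ndarray | None = None  # signature mixture for all clones
    clone_weights: np.ndarray | None = None
    detection: DetectionRule = field(default_factory=lambda: DEFAULT_DETECTION)


@dataclass
class SyntheticCohort:
    """One simulated patient: truth plus per-sample variant tables."""

    config: CohortConfig
    truth: synthetic.GroundTruth
    catalog: SignatureCatalog
    mutations: pd.DataFrame
    observations: dict  # sample -> read-count DataFrame

    @property
    def samples(self) -> list:
        return self.truth.tree.samples

    def variant_observations(self, sample: str) -> list:
        df = self.observations[sample]
        return [
            VariantObservation(
                chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
                alt_count=int(r.alt_count), depth=int(r.depth),
                called=bool(r.called), sample=sample,
            )
            for r in df.itertuples(index=False)
        ]

    def trios(self, organoid_sample: str | None = None) -> list:
        organoid_sample = organoid_sample or self.samples[1]
        return make_trios(
            self.variant_observations("tumor"),
            self.variant_observations(organoid_sample),
            detection=self.config.detection,
        )

    def ccf_observations(self, samples=None, min_alt: int = 0) -> list:
        """Per-mutation multi-sample CCF observations for clustering.

        Sites with zero depth in any requested sample are dropped;
        ``min_alt`` additionally requires that many alt reads in at least
        one sample (mimicking a somatic call set).
        """
        samples = list(samples or self.samples)
        frames = [self.observations[s].set_index("mutation_id") for s in samples]
        obs = []
        for mid in frames[0].index:
            alt = np.array([f.loc[mid, "alt_count"] for f in frames], dtype=float)
            dep = np.array([f.loc[mid, "depth"] for f in frames], dtype=float)
            if np.any(dep <= 0) or alt.max() < min_alt:
                continue
            obs.append(CCFObservation(
                mutation_id=mid, alt_count=alt, depth=dep,
                purity=np.array([self.truth.purity[s] for s in samples]),
                total_cn=self.config.ploidy,
                chrom=int(frames[0].loc[mid, "chrom"]),
            ))
        return obs


def simulate_cohort(config: CohortConfig, seed: int,
                    catalog: SignatureCatalog | None = None) -> SyntheticCohort:
    """Generate one patient's paired tumor/organoid-passage dataset."""
    rng = np.random.default_rng(seed)
    catalog = catalog or SignatureCatalog.random(int(rng.integers(2 ** 31)))
    tree = synthetic.simulate_clone_tree(
        config.n_clones, config.n_samples, config.selection_shift,
        seed=int(rng.integers(2 ** 31)),
    )
    exposures = config.exposures
    if exposures is None:
        exposures = rng.dirichlet(np.ones(catalog.n_signatures))
    purity = {s: (config.tumor_purity if s == "tumor" else 1.0) for s in tree.samples}
    depth = {s: (config.tumor_depth if s == "tumor" else config.organoid_depth)
             for s in tree.samples}
    truth = synthetic.GroundTruth(
        tree=tree,
        exposures={c.clone_id: np.asarray(exposures, dtype=float) for c in tree.clones},
        purity=purity,
        ploidy={s: config.ploidy for s in tree.samples},
        mean_depth=depth,
        seed=seed,
    )
    mutations = synthetic.simulate_mutations(
        tree, catalog, exposures, config.n_mutations,
        seed=int(rng.integers(2 ** 31)), clone_weights=config.clone_weights,
    )
    observations = {
        s: synthetic.simulate_read_counts(
            mutations, tree, truth, s, seed=int(rng.integers(2 ** 31)),
            total_cn=config.ploidy, detection=config.detection,
        )
        for s in tree.samples
    }
    return SyntheticCohort(config=config, truth=truth, catalog=catalog,
                           mutations=mutations, observations=observations)


VARIANT_COLUMNS = ["CHROM", "POS", "REF", "ALT", "ALT_COUNT", "DEPTH",
                   "FILTER", "SAMPLE"]


def write_variants_tsv(observations: pd.DataFrame, path) -> None:
    """Write a read-count table in the VCF-like TSV interchange format."""
    out = pd.DataFrame({
        "CHROM": observations["chrom"],
        "POS": observations["pos"],
        "REF": observations["ref"],
        "ALT": observations["alt"],
        "ALT_COUNT": observations["alt_count"],
        "DEPTH": observations["depth"],
        "FILTER": np.where(observations["called"], "PASS", "LOWSUPPORT"),
        "SAMPLE": observations["sample"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    """Read the VCF-like TSV back into VariantObservation objects."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return [
        VariantObservation(
            chrom=str(r.CHROM), pos=int(r.POS), ref=str(r.REF), alt=str(r.ALT),
            alt_count=int(r.ALT_COUNT), depth=int(r.DEPTH),
            called=(r.FILTER == "PASS"), sample=str(r.SAMPLE),
        )
        for r in df.itertuples(index=False)
    ]


def write_expression_csv(em, counts_path, samples_path) -> None:
    """Write genes x samples counts plus the class/patient sample sheet."""
    em.counts.to_csv(counts_path)
    pd.DataFrame({
        "sample": em.classes.index,
        "class": em.classes.to_numpy(),
        "patient": em.patients.to_numpy(),
    }).to_csv(samples_path, index=False)


def read_expression_csv(counts_path, samples_path):
    from .expression import ExpressionMatrix

    counts = pd.read_csv(counts_path, index_col=0)
    sheet = pd.read_csv(samples_path).set_index("sample")
    return ExpressionMatrix(
        counts=counts,
        classes=sheet["class"],
        patients=sheet["patient"].fillna(""),
    )
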