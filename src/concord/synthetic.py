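"""Synthetic paired tumor/organoid cohort generator with known ground truth.

Every downstream stage of the pipeline (variant concordance, signature
fitting, CCF clustering, expression concordance, drug screening) is
exercised against data produced here, so each generator plants a truth the
corresponding analysis must recover:

* ``simulate_clone_tree`` builds a clone hierarchy with per-sample cancer
  cell fractions. The trunk is fully clonal everywhere; subclone CCFs drift
  between consecutive samples with the largest shift at the point of
  organoid derivation (tumor -> first passage) and geometrically decaying
  shifts afterwards, mirroring the derivation-bottleneck selection observed
  in serially passaged cultures.
* ``simulate_mutations`` assigns mutations to clones and draws their
  96-channel substitution types from an exposure-weighted signature mixture.
* ``simulate_read_counts`` emits allele counts per sample under the VAF law
  vaf = purity * m * CCF / (purity * cn_t + (1 - purity) * 2), binomial
  sampling at Poisson depth, including caller-missed zero-alt sites.
* ``simulate_expression`` produces negative-binomial counts with a tumor
  program (up in tumors and organoids vs normal squamous), a
  culture-environment program (shifted in all organoids) and per-patient
  marker programs shared only within a patient's tumor-organoid pair.
* ``simulate_plate`` produces sigmoidal viability with Gaussian noise plus
  control wells for a 7-point half-log dose ladder.

All generators are bit-reproducible given (parameters, seed). Positions are
drawn over a toy genome of 22 chromosomes x 10 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .signatures import N_CHANNELS, SignatureCatalog, channel_ref_alt
from .variants import DEFAULT_DETECTION, DetectionRule

N_CHROMOSOMES = 22
CHROM_LENGTH = 10_000_000


@dataclass
class Clone:
    clone_id: int
    parent_id: int | None
    ccf: np.ndarray  # per-sample CCF in [0, 1]


@dataclass
class CloneTree:
    """Clone hierarchy with per-sample cancer cell fractions."""

    clones: list
    samples: list

    def __post_init__(self) -> None:
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root (trunk)")
        if not np.allclose(roots[0].ccf, 1.0):
            raise ValueError("trunk CCF must be 1.0 in every sample")
        for c in self.clones:
            if np.any(c.ccf < 0) or np.any(c.ccf > 1):
                raise ValueError("CCFs must lie in [0, 1]")
        by_id = {c.clone_id: c for c in self.clones}
        for c in self.clones:
            child_sum = sum(
                (k.ccf for k in self.clones if k.parent_id == c.clone_id),
                np.zeros(len(self.samples)),
            )
            if np.any(child_sum > c.ccf + 1e-9):
                raise ValueError("children CCFs exceed parent CCF")
        self._by_id = by_id

    @property
    def trunk(self) -> Clone:
        return next(c for c in self.clones if c.parent_id is None)

    def clone(self, clone_id: int) -> Clone:
        return self._by_id[clone_id]

    def ccf(self, clone_id: int, sample: str) -> float:
        return float(self._by_id[clone_id].ccf[self.samples.index(sample)])

    def ccf_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c.clone_id: c.ccf for c in self.clones}, index=self.samples
        ).T


def simulate_clone_tree(n_clones: int, n_samples: int, selection_shift: float,
                        seed: int, drift_decay: float = 0.35,
                        derivation_amplitude: float = 3.0) -> CloneTree:
    """Random clone tree whose subclone CCFs drift across serial samples.

    Sample 0 is the tumor; samples 1..k are organoid passages. Between
    samples ``j`` and ``j+1`` each node's allocation logits receive Gaussian
    perturbations of amplitude
    ``selection_shift * derivation_amplitude * drift_decay**j``, so the
    derivation step carries the largest compositional change and later
    passages progressively stabilize. ``selection_shift = 0`` freezes the
    composition exactly.
    """
    if n_clones < 1 or n_samples < 2:
        raise ValueError("need n_clones >= 1 and n_samples >= 2 (tumor + passage)")
    if not 0.0 <= selection_shift <= 1.0:
        raise ValueError("selection_shift must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    parents: list[int | None] = [None] + [
        int(rng.integers(0, i)) for i in range(1, n_clones)
    ]
    children: dict[int, list[int]] = {i: [] for i in range(n_clones)}
    for i, p in enumerate(parents):
        if p is not None:
            children[p].append(i)

    # Per node: allocation logits over [retained-by-self, child_1, ...].
    logits = {
        i: rng.normal(0.0, 1.0, size=1 + len(children[i])) for i in range(n_clones)
    }
    ccf = np.zeros((n_clones, n_samples))
    for j in range(n_samples):
        if j > 0:
            amp = selection_shift * derivation_amplitude * drift_decay ** (j - 1)
            for i in range(n_clones):
                # Draw even when amp == 0 to keep the stream aligned across
                # selection_shift values; amp scales the step to exactly 0.
                logits[i] = logits[i] + amp * rng.normal(0.0, 1.0, size=logits[i].size)
        ccf[0, j] = 1.0
        for i in range(n_clones):  # parents precede children by construction
            w = np.exp(logits[i] - logits[i].max())
            w = w / w.sum()
            for slot, child in enumerate(children[i], start=1):
                ccf[child, j] = ccf[i, j] * w[slot]
    clones = [Clone(i, parents[i], ccf[i].copy()) for i in range(n_clones)]
    samples = ["tumor"] + [f"P{j}" for j in range(1, n_samples)]
    return CloneTree(clones=clones, samples=samples)


@dataclass
class GroundTruth:
    """Everything the synthetic cohort knows about itself."""

    tree: CloneTree
    exposures: dict  # clone_id -> exposure array (len = n signatures)
    purity: dict  # sample -> purity in (0, 1]
    ploidy: dict  # sample -> average ploidy
    mean_depth: dict  # sample -> mean sequencing depth
    seed: int

    def __post_init__(self) -> None:
        for sample in self.tree.samples:
            p = self.purity[sample]
            if not 0 < p <= 1:
                raise ValueError("purity must lie in (0, 1]")
            if sample != "tumor" and p != 1.0:
                raise ValueError("organoid samples must have purity 1.0")
            if self.mean_depth[sample] <= 0:
                raise ValueError("mean depth must be positive")
            if self.ploidy[sample] <= 0:
                raise ValueError("ploidy must be positive")


def simulate_mutations(tree: CloneTree, catalog: SignatureCatalog, exposures,
                       n_mutations: int, seed: int,
                       clone_weights=None) -> pd.DataFrame:
    """Assign mutations to clones and draw trinucleotide channels.

    Channels come from the exposure-weighted mixture of catalog rows; clone
    assignment is multinomial with the given per-clone budgets (uniform by
    default). Positions are unique over the toy genome.
    """
    e = np.asarray(exposures, dtype=float)
    if np.any(e < 0):
        raise ValueError("exposures must be non-negative")
    if e.sum() == 0:
        raise ValueError("exposures are all zero; mutation spectrum undefined")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    rng = np.random.default_rng(seed)
    cols = ["mutation_id", "clone_id", "channel", "chrom", "pos"]
    if n_mutations == 0:
        return pd.DataFrame(columns=cols)

    channel_probs = (e / e.sum()) @ catalog.matrix
    channel_probs = channel_probs / channel_probs.sum()
    channels = rng.choice(N_CHANNELS, size=n_mutations, p=channel_probs)

    n_clones = len(tree.clones)
    if clone_weights is None:
        w = np.full(n_clones, 1.0 / n_clones)
    else:
        w = np.asarray(clone_weights, dtype=float)
        w = w / w.sum()
    clone_ids = np.array([c.clone_id for c in tree.clones])
    assigned = rng.choice(clone_ids, size=n_mutations, p=w)

    genome = N_CHROMOSOMES * CHROM_LENGTH
    sites: np.ndarray = np.unique(rng.integers(0, genome, size=n_mutations))
    while sites.size < n_mutations:  # collisions are rare at toy-genome scale
        extra = rng.integers(0, genome, size=n_mutations - sites.size)
        sites = np.unique(np.concatenate([sites, extra]))
    sites = rng.permutation(sites)[:n_mutations]

    return pd.DataFrame({
        "mutation_id": [f"mut{i:06d}" for i in range(n_mutations)],
        "clone_id": assigned,
        "channel": channels,
        "chrom": (sites // CHROM_LENGTH + 1).astype(int),
        "pos": (sites % CHROM_LENGTH + 1).astype(int),
    })


def expected_vaf(purity: float, ccf, total_cn=2.0, multiplicity=1.0):
    """VAF law: purity * m * CCF / (purity * cn_t + (1 - purity) * 2)."""
    ccf = np.asarray(ccf, dtype=float)
    return purity * multiplicity * ccf / (purity * np.asarray(total_cn, dtype=float)
                                          + (1.0 - purity) * 2.0)


def simulate_read_counts(mutations: pd.DataFrame, tree: CloneTree,
                         truth: GroundTruth, sample: str, seed: int,
                         total_cn: float = 2.0, multiplicity: float = 1.0,
                         detection: DetectionRule = DEFAULT_DETECTION,
                         fixed_depth: int | None = None) -> pd.DataFrame:
    """Sequencing-style allele counts for one sample.

    Depth is Poisson around the sample's mean (or forced to ``fixed_depth``);
    alt counts are binomial at the expected VAF. Variants with zero alt
    reads are still emitted (caller-missed), with ``called`` False.
    """
    if sample not in tree.samples:
        raise ValueError(f"unknown sample {sample!r}")
    rng = np.random.default_rng(seed)
    s_idx = tree.samples.index(sample)
    purity = truth.purity[sample]
    ccf = np.array([tree.clone(cid).ccf[s_idx] for cid in mutations["clone_id"]])
    vaf = expected_vaf(purity, ccf, total_cn, multiplicity)

    n = len(mutations)
    if fixed_depth is not None:
        depth = np.full(n, int(fixed_depth))
    else:
        depth = rng.poisson(truth.mean_depth[sample], size=n)
    alt = rng.binomial(depth, np.clip(vaf, 0.0, 1.0))
    called = np.array([detection(a, d) for a, d in zip(alt, depth)])

    ref_alt = [channel_ref_alt(int(ch)) for ch in mutations["channel"]]
    return pd.DataFrame({
        "mutation_id": mutations["mutation_id"].to_numpy(),
        "chrom": mutations["chrom"].to_numpy(),
        "pos": mutations["pos"].to_numpy(),
        "ref": [ra[0] for ra in ref_alt],
        "alt": [ra[1] for ra in ref_alt],
        "alt_count": alt,
        "depth": depth,
        "called": called,
        "sample": sample,
        "true_ccf": ccf,
        "expected_vaf": vaf,
    })


def planted_subclone_dataset(n_clones: int, seed: int,
                             mutations_per_clone: int = 150,
                             depth: int = 100, n_samples: int = 2,
                             tumor_purity: float = 0.7,
                             min_separation: float = 0.25,
                             min_detectable_ccf: float = 0.15,
                             selection_shift: float = 0.6):
    """An identifiable planted subclone-recovery experiment.

    Draws clone trees until every pair of clones is separated by at least
    ``min_separation`` CCF in some sample and every clone reaches
    ``min_detectable_ccf`` somewhere (clones closer than the recovery
    tolerance are not statistically distinguishable at finite depth, so an
    unidentifiable draw would test nothing). Emits per-sample fixed-depth
    allele counts with equal mutation budgets per clone.

    Returns ``(tree, truth, observations)`` where observations maps samples
    to read-count tables.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        tree = simulate_clone_tree(n_clones, n_samples, selection_shift,
                                   seed=int(rng.integers(2 ** 31)))
        ccf = np.array([c.ccf for c in tree.clones])
        separated = all(
            np.max(np.abs(ccf[i] - ccf[j])) >= min_separation
            for i in range(n_clones) for j in range(i + 1, n_clones)
        )
        detectable = bool(np.all(ccf.max(axis=1) >= min_detectable_ccf))
        if separated and detectable:
            break
    else:
        raise RuntimeError("could not draw an identifiable clone tree")
    catalog = SignatureCatalog.random(int(rng.integers(2 ** 31)))
    purity = {s: (tumor_purity if s == "tumor" else 1.0) for s in tree.samples}
    truth = GroundTruth(
        tree=tree,
        exposures={c.clone_id: np.ones(catalog.n_signatures) for c in tree.clones},
        purity=purity,
        ploidy={s: 2.0 for s in tree.samples},
        mean_depth={s: float(depth) for s in tree.samples},
        seed=seed,
    )
    mutations = simulate_mutations(
        tree, catalog, np.ones(catalog.n_signatures),
        n_mutations=mutations_per_clone * n_clones,
        seed=int(rng.integers(2 ** 31)),
        clone_weights=np.ones(n_clones),
    )
    observations = {
        s: simulate_read_counts(mutations, tree, truth, s,
                                seed=int(rng.integers(2 ** 31)),
                                fixed_depth=depth)
        for s in tree.samples
    }
    return tree, truth, observations


@dataclass
class ExpressionTruth:
    """Planted gene programs of a synthetic expression cohort."""

    tumor_program: list
    culture_program: list
    patient_programs: dict  # patient -> list of genes
    patient_effects: pd.DataFrame  # gene x patient signed log2 effects


@dataclass
class ExpressionParams:
    """Defaults chosen to emulate bulk RNA-seq of this cohort: moderate
    library-size variation, NB dispersion 0.1, strong tumor and
    culture-environment programs, and subtle (|log2FC| < 1) but consistent
    patient-specific marker shifts carried by highly expressed genes."""

    n_genes: int = 2000
    organoid_replicates: int = 4  # serial passages profiled per patient
    dispersion: float = 0.1
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    n_tumor_program: int = 150
    tumor_effect_range: tuple[float, float] = (1.5, 3.0)
    n_culture_program: int = 150
    culture_effect_range: tuple[float, float] = (1.5, 3.0)
    n_patient_program: int = 50
    patient_effect_range: tuple[float, float] = (0.8, 0.95)
    marker_baseline_log2_mean: float = 9.0
    marker_baseline_log2_sd: float = 0.3
    marker_tumor_effect: float = 2.0
    library_size_log2_sd: float = 0.25


def simulate_expression(n_genes: int, patients, seed: int,
                        params: ExpressionParams | None = None):
    """Synthetic tumor/normal/organoid count matrix with planted programs.

    Per patient: one tumor, one adjacent-normal and ``organoid_replicates``
    organoid passage samples. Returns ``(ExpressionMatrix, ExpressionTruth)``.
    """
    params = params or ExpressionParams()
    patients = list(patients)
    if len(patients) < 2:
        raise ValueError("simulate_expression requires >= 2 patients")
    n_program = (params.n_tumor_program + params.n_culture_program
                 + params.n_patient_program * len(patients))
    if n_genes < n_program:
        raise ValueError(
            f"n_genes={n_genes} smaller than total program size {n_program}")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples, classes, pat_labels = [], [], []
    for p in patients:
        samples.append(f"{p}_T")
        classes.append("tumor")
        pat_labels.append(p)
        samples.append(f"{p}_N")
        classes.append("normal")
        pat_labels.append(p)
        for r in range(params.organoid_replicates):
            samples.append(f"{p}_O{r + 1}")
            classes.append("organoid")
            pat_labels.append(p)

    base = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_genes)
    idx = rng.permutation(n_genes)
    cut1 = params.n_tumor_program
    cut2 = cut1 + params.n_culture_program
    tumor_idx = idx[:cut1]
    culture_idx = idx[cut1:cut2]
    patient_idx = {
        p: idx[cut2 + k * params.n_patient_program:
               cut2 + (k + 1) * params.n_patient_program]
        for k, p in enumerate(patients)
    }
    # Patient markers: highly and uniformly expressed so they survive the
    # base-mean ranking of the selection procedure.
    for p in patients:
        base[patient_idx[p]] = rng.normal(
            params.marker_baseline_log2_mean, params.marker_baseline_log2_sd,
            params.n_patient_program,
        )

    tumor_eff = np.zeros(n_genes)
    tumor_eff[tumor_idx] = rng.uniform(*params.tumor_effect_range, cut1)
    tumor_eff[np.concatenate(list(patient_idx.values()))] = params.marker_tumor_effect
    culture_eff = np.zeros(n_genes)
    culture_eff[culture_idx] = (
        rng.uniform(*params.culture_effect_range, params.n_culture_program)
        * rng.choice([-1.0, 1.0], params.n_culture_program)
    )
    patient_eff = np.zeros((n_genes, len(patients)))
    for k, p in enumerate(patients):
        lo, hi = params.patient_effect_range
        patient_eff[patient_idx[p], k] = (
            rng.uniform(lo, hi, params.n_patient_program)
            * rng.choice([-1.0, 1.0], params.n_patient_program)
        )

    lib = rng.normal(0.0, params.library_size_log2_sd, len(samples))
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, (cls, p) in enumerate(zip(classes, pat_labels)):
        log2_mu = base + lib[j]
        if cls in ("tumor", "organoid"):
            log2_mu = log2_mu + tumor_eff + patient_eff[:, patients.index(p)]
        if cls == "organoid":
            log2_mu = log2_mu + culture_eff
        mu = 2.0 ** log2_mu
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)

    em = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        classes=pd.Series(classes, index=samples),
        patients=pd.Series(pat_labels, index=samples),
    )
    truth = ExpressionTruth(
        tumor_program=[genes[i] for i in tumor_idx],
        culture_program=[genes[i] for i in culture_idx],
        patient_programs={p: [genes[i] for i in patient_idx[p]] for p in patients},
        patient_effects=pd.DataFrame(patient_eff, index=genes, columns=patients),
    )
    return em, truth


def simulate_plate(true_ic50: float, slope: float, max_conc: float, seed: int,
                   n_points: int = 7, noise_sd: float = 0.05,
                   n_controls: int = 16, organoid: str = "",
                   compound: str = "") -> pd.DataFrame:
    """Long-format viability plate for one (organoid, compound) pair.

    Viability follows the two-parameter logistic at the half-log dose
    ladder plus Gaussian noise (clipped at 0); negative controls sit near 1
    and positive controls near 0.
    """
    if true_ic50 <= 0 or max_conc <= 0:
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    doses = max_conc * 10.0 ** (-0.5 * np.arange(n_points))
    x = np.log10(doses)
    viab = 1.0 / (1.0 + np.exp((x - np.log10(true_ic50)) / slope))
    viab = np.clip(viab + rng.normal(0.0, noise_sd, n_points), 0.0, None)
    neg = np.clip(1.0 + rng.normal(0.0, noise_sd, n_controls), 0.0, None)
    pos = np.clip(rng.normal(0.0, noise_sd, n_controls), 0.0, None)

    rows = [
        {"organoid": organoid, "compound": compound, "role": "sample",
         "concentration_M": d, "viability": v}
        for d, v in zip(doses, viab)
    ]
    rows += [{"organoid": organoid, "compound": compound, "role": "neg_ctrl",
              "concentration_M": 0.0, "viability": v} for v in neg]
    rows += [{"organoid": organoid, "compound": compound, "role": "pos_ctrl",
              "concentration_M": 0.0, "viability": v} for v in pos]
    return pd.DataFrame(rows)
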