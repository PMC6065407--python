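import numpy as np
import pytest

from concord.cohort import CohortConfig, simulate_cohort
from concord.signatures import SignatureCatalog


@pytest.fixture(scope="session")
def catalog():
    return SignatureCatalog.random(seed=7)


@pytest.fixture(scope="session")
def low_purity_cohort():
    """Paired tumor/organoid simulation at tumor purity 0.4."""
    return simulate_cohort(CohortConfig(tumor_purity=0.4), seed=1)


def subclone_observations(tree, truth, observations):
    """Convert per-sample read-count tables to multi-sample CCF observations."""
    from concord.clonality import CCFObservation

    samples = tree.samples
    frames = [observations[s].set_index("mutation_id") for s in samples]
    purity = np.array([truth.purity[s] for s in samples])
    alt = np.column_stack([f["alt_count"].to_numpy() for f in frames]).astype(float)
    dep = np.column_stack([f["depth"].to_numpy() for f in frames]).astype(float)
    chroms = frames[0]["chrom"].to_numpy()
    ids = frames[0].index.to_numpy()
    keep = (dep > 0).all(axis=1)
    return [
        CCFObservation(ids[i], alt[i], dep[i], purity, 2.0, chrom=int(chroms[i]))
        for i in np.flatnonzero(keep)
    ]
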