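"""Cancer-cell-fraction estimation, subclone clustering, QC and tree rules.

The fraction of cancer cells carrying a mutation (CCF) is estimated from
allele counts after correcting for sample purity and local copy number:

    m   = clip(round(vaf / purity * D), 1, max(cn_t, 1)),  D = purity*cn_t + (1-purity)*2
    CCF = vaf * D / (purity * m)

clipped to [0, 1.5] with clip events flagged. Mutations are then clustered
across all samples jointly with a truncated stick-breaking Dirichlet-process
mixture of binomials: each cluster is a point in S-dimensional CCF space, a
mutation's alt count in sample s is Binomial(depth, c_s * CCF_s) with
c_s = purity*m/D the purity/copy-number attenuation, and cluster positions
are Gibbs-sampled on a fine CCF grid. Cluster centers are posterior medians.

Clusters pass three QC filters (fewer than 1% of all mutations; member
median CCF deviating more than 0.2 from the process CCF in any sample; more
than half the members on one chromosome) before the 'sum' and 'crossing'
phylogenetic rules arrange them into a clone tree: crossing CCFs in
different samples force disjoint branches, while a pigeonhole violation of
the sum rule forces the larger cluster to contain the smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_MUTATIONS = 20
CCF_CAP = 1.5


def estimate_ccf(alt_count, depth, purity, total_cn=2.0):
    """Per-site CCF point estimate with multiplicity rounding.

    Returns ``(ccf, multiplicity, clipped)``; accepts scalars or arrays.
    """
    alt = np.asarray(alt_count, dtype=float)
    dep = np.asarray(depth, dtype=float)
    if np.any(dep <= 0):
        raise ValueError("depth must be positive")
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    cn = np.asarray(total_cn, dtype=float)
    vaf = alt / dep
    denom = purity * cn + (1.0 - purity) * 2.0
    m = np.clip(np.round(vaf / purity * denom), 1.0, np.maximum(cn, 1.0))
    ccf = vaf * denom / (purity * m)
    clipped = ccf > CCF_CAP
    ccf = np.clip(ccf, 0.0, CCF_CAP)
    if np.isscalar(alt_count):
        return float(ccf), float(m), bool(clipped)
    return ccf, m, clipped


@dataclass
class CCFObservation:
    """One mutation's per-sample allele counts and local context."""

    mutation_id: str
    alt_count: np.ndarray  # (S,)
    depth: np.ndarray  # (S,)
    purity: np.ndarray  # (S,)
    total_cn: np.ndarray | float = 2.0
    chrom: str | int | None = None

    def __post_init__(self) -> None:
        self.alt_count = np.atleast_1d(np.asarray(self.alt_count, dtype=float))
        self.depth = np.atleast_1d(np.asarray(self.depth, dtype=float))
        self.purity = np.atleast_1d(np.asarray(self.purity, dtype=float))
        if np.isscalar(self.total_cn):
            self.total_cn = np.full_like(self.depth, float(self.total_cn))
        else:
            self.total_cn = np.atleast_1d(np.asarray(self.total_cn, dtype=float))
        if np.any(self.depth <= 0):
            raise ValueError("depth must be positive in every included sample")
        if np.any((self.purity <= 0) | (self.purity > 1)):
            raise ValueError("purity must lie in (0, 1]")


@dataclass
class SubcloneCluster:
    """A mutation cluster with per-sample CCFs."""

    cluster_id: int
    ccf: np.ndarray  # posterior median per sample, clipped to [0, 1]
    dp_ccf: np.ndarray  # posterior mean per sample (process CCF)
    member_ccf_median: np.ndarray  # median of member point-estimate CCFs
    members: list
    chrom_counts: dict = field(default_factory=dict)

    @property
    def n_mutations(self) -> int:
        return len(self.members)


def cluster_ccf(observations, seed: int, iterations: int = 2000,
                burn_in: int = 500, max_clusters: int = 12, alpha: float = 1.0,
                grid_points: int = 101) -> list:
    """Joint multi-sample CCF clustering by a truncated DP binomial mixture.

    Gibbs sampling alternates cluster assignments, stick-breaking weights
    and grid-sampled cluster CCFs (uniform prior on a CCF grid). Truncated
    stick-breaking chains leave duplicate or tail atoms on one mixture
    component, so the final partition is consolidated by greedy agglomerative
    merging under the collapsed posterior: two clusters are merged whenever
    the grid-marginalized likelihood plus the Chinese-restaurant partition
    prior favors the merged configuration. Each cluster's CCF is then
    summarized from the conditional grid posterior of its member set: the
    center is the posterior median, the process CCF the posterior mean.
    Clusters are reported in descending mean-CCF order (resolving label
    switching). Seeded and deterministic.
    """
    obs = list(observations)
    if len(obs) < MIN_MUTATIONS:
        raise ValueError(f"clustering requires >= {MIN_MUTATIONS} mutations")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    n = len(obs)
    n_samples = len(obs[0].depth)
    for o in obs:
        if len(o.depth) != n_samples:
            raise ValueError("all observations must cover the same samples")

    alt = np.array([o.alt_count for o in obs])  # (N, S)
    dep = np.array([o.depth for o in obs])
    purity = np.array([o.purity for o in obs])
    cn = np.array([o.total_cn for o in obs])
    vaf = alt / dep
    denom = purity * cn + (1.0 - purity) * 2.0
    mult = np.clip(np.round(vaf / purity * denom), 1.0, np.maximum(cn, 1.0))
    # Attenuation: expected vaf = c * CCF.
    c = purity * mult / denom
    point_ccf = np.clip(vaf * denom / (purity * mult), 0.0, 1.0)

    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_points)
    eps = 1e-9
    # Constant per-site grid log-likelihoods: (N, S, G).
    p = np.clip(c[:, :, None] * grid[None, None, :], eps, 1.0 - eps)
    loglik_grid = alt[:, :, None] * np.log(p) + (dep - alt)[:, :, None] * np.log1p(-p)

    K = max_clusters
    z = rng.integers(0, K, size=n)
    phi_idx = rng.integers(0, grid_points, size=(K, n_samples))
    rows = np.arange(n)

    for it in range(iterations):
        # 1. Stick-breaking weights from current occupancy.
        counts = np.bincount(z, minlength=K)
        tail = np.concatenate([np.cumsum(counts[::-1])[-2::-1], [0]])
        v = rng.beta(1.0 + counts, alpha + tail)
        v[-1] = 1.0
        logw = np.log(np.clip(v, 1e-300, None))
        logw[1:] += np.cumsum(np.log(np.clip(1.0 - v[:-1], 1e-300, None)))

        # 2. Assignments: gather each cluster's grid column, Gumbel-max draw.
        site_ll = loglik_grid[
            rows[:, None, None], np.arange(n_samples)[None, :, None],
            phi_idx.T[None, :, :],
        ].sum(axis=1)  # (N, K)
        gumbel = rng.gumbel(size=(n, K))
        z = np.argmax(logw[None, :] + site_ll + gumbel, axis=1)

        # 3. Cluster CCFs on the grid (uniform prior).
        onehot = np.zeros((n, K))
        onehot[rows, z] = 1.0
        cluster_ll = np.einsum("ik,isg->ksg", onehot, loglik_grid)
        gumbel = rng.gumbel(size=cluster_ll.shape)
        shifted = cluster_ll - cluster_ll.max(axis=2, keepdims=True)
        phi_idx = np.argmax(shifted + gumbel, axis=2)

    # Consolidate the final partition: greedily merge cluster pairs whenever
    # the collapsed posterior (grid-marginalized likelihood x CRP prior)
    # prefers one component to two.
    from scipy.special import gammaln, logsumexp

    log_g = np.log(grid_points)

    def _collapsed_score(ll_sums: np.ndarray, size: int) -> float:
        # ll_sums: (S, G) summed member log-likelihoods per sample.
        return float(logsumexp(ll_sums, axis=1).sum() - n_samples * log_g
                     + gammaln(size))

    groups = [np.flatnonzero(z == lab) for lab in np.unique(z)]
    ll_sums = [loglik_grid[g].sum(axis=0) for g in groups]
    scores = [_collapsed_score(ll, len(g)) for ll, g in zip(ll_sums, groups)]
    log_alpha = np.log(alpha)
    while len(groups) > 1:
        best_gain, best_pair = 0.0, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                merged_score = _collapsed_score(
                    ll_sums[i] + ll_sums[j], len(groups[i]) + len(groups[j]))
                gain = merged_score - scores[i] - scores[j] - log_alpha
                if gain > best_gain:
                    best_gain, best_pair = gain, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        groups[i] = np.concatenate([groups[i], groups[j]])
        ll_sums[i] = ll_sums[i] + ll_sums[j]
        scores[i] = _collapsed_score(ll_sums[i], len(groups[i]))
        del groups[j], ll_sums[j], scores[j]

    clusters = []
    for members in groups:
        # Conditional grid posterior of the merged member set, per sample.
        center = np.empty(n_samples)
        dp_mean = np.empty(n_samples)
        for s in range(n_samples):
            ll_s = loglik_grid[members, s, :].sum(axis=0)
            w = np.exp(ll_s - ll_s.max())
            w /= w.sum()
            center[s] = grid[np.searchsorted(np.cumsum(w), 0.5)]
            dp_mean[s] = float(w @ grid)
        member_median = np.median(point_ccf[members], axis=0)
        chroms = [obs[i].chrom for i in members if obs[i].chrom is not None]
        chrom_counts = pd.Series(chroms).value_counts().to_dict() if chroms else {}
        clusters.append(SubcloneCluster(
            cluster_id=-1,
            ccf=np.clip(center, 0.0, 1.0),
            dp_ccf=dp_mean,
            member_ccf_median=member_median,
            members=[obs[i].mutation_id for i in members],
            chrom_counts=chrom_counts,
        ))
    clusters.sort(key=lambda cl: -float(cl.ccf.mean()))
    for i, cl in enumerate(clusters):
        cl.cluster_id = i
    return clusters


def qc_clusters(clusters, total_mutations: int, min_fraction: float = 0.01,
                max_center_discrepancy: float = 0.2,
                max_chrom_fraction: float = 0.5):
    """Apply the three subclone-cluster QC filters.

    Rejects clusters that (1) hold fewer than ``min_fraction`` of all
    mutations, (2) whose member-median CCF deviates from the process CCF by
    more than ``max_center_discrepancy`` in any sample, or (3) with more
    than ``max_chrom_fraction`` of members on a single chromosome. Returns
    ``(retained, reasons)`` with per-cluster rejection reasons.
    """
    if total_mutations <= 0:
        raise ValueError("total_mutations must be positive")
    retained, reasons = [], {}
    for cl in clusters:
        why = []
        if cl.n_mutations < min_fraction * total_mutations:
            why.append("too_few_mutations")
        if np.any(np.abs(cl.member_ccf_median - cl.dp_ccf) > max_center_discrepancy):
            why.append("ccf_discrepancy")
        if cl.chrom_counts and cl.n_mutations > 0:
            if max(cl.chrom_counts.values()) > max_chrom_fraction * cl.n_mutations:
                why.append("chromosome_concentration")
        reasons[cl.cluster_id] = why
        if not why:
            retained.append(cl)
    return retained, reasons


def _crossing(a: np.ndarray, b: np.ndarray, tau: float) -> bool:
    return bool(np.any(a > b + tau) and np.any(a < b - tau))


def _encloses(a: np.ndarray, b: np.ndarray, tau: float) -> bool:
    """a can be an ancestor of b: no crossing and a >= b - tau everywhere."""
    return bool(np.all(a >= b - tau)) and not _crossing(a, b, tau)


@dataclass
class CloneTreeInferred:
    """Sum/crossing-rule clone tree over QC-passing clusters."""

    clusters: list
    parent: dict  # cluster_id -> parent cluster_id (trunk -> None)
    ambiguous_pairs: list = field(default_factory=list)
    unresolved_pairs: list = field(default_factory=list)

    def children(self, cluster_id) -> list:
        return [cid for cid, p in self.parent.items() if p == cluster_id]

    @property
    def trunk_id(self) -> int:
        return next(cid for cid, p in self.parent.items() if p is None)

    def is_ancestor(self, a, b) -> bool:
        node = self.parent.get(b)
        while node is not None:
            if node == a:
                return True
            node = self.parent.get(node)
        return False

    def to_dict(self) -> dict:
        by_id = {cl.cluster_id: cl for cl in self.clusters}
        return {
            "clones": [
                {"cluster_id": cid, "parent": p,
                 "ccf": [float(x) for x in by_id[cid].ccf],
                 "n_mutations": by_id[cid].n_mutations}
                for cid, p in self.parent.items()
            ],
            "ambiguous_pairs": self.ambiguous_pairs,
            "unresolved_pairs": self.unresolved_pairs,
        }


def build_tree(clusters, tau: float = 0.05,
               trunk_threshold: float = 0.9) -> CloneTreeInferred:
    """Arrange clusters into a clone tree using the sum and crossing rules.

    The cluster with CCF ~= 1 in all samples is the trunk. Each remaining
    cluster (descending mean CCF) attaches as high as possible; a sum-rule
    violation with an enclosing sibling pushes it inside that sibling, and a
    sum-rule violation with a crossing sibling is recorded as unresolved.
    Enclosing-but-unforced sibling pairs are flagged ambiguous.
    """
    clusters = sorted(clusters, key=lambda cl: -float(cl.ccf.mean()))
    if not clusters:
        raise ValueError("build_tree requires at least one cluster")
    trunk = clusters[0]
    if np.any(trunk.ccf < trunk_threshold):
        raise ValueError("no trunk-compatible cluster (CCF ~ 1 in all samples)")
    by_id = {cl.cluster_id: cl for cl in clusters}
    parent: dict = {trunk.cluster_id: None}
    ambiguous, unresolved = [], []

    for cl in clusters[1:]:
        node = trunk.cluster_id
        while True:
            siblings = [by_id[cid] for cid, p in parent.items() if p == node]
            parent_ccf = by_id[node].ccf
            forced = [
                s for s in siblings
                if _encloses(s.ccf, cl.ccf, tau)
                and np.any(s.ccf + cl.ccf > parent_ccf + tau)
            ]
            if forced:
                node = max(forced, key=lambda s: float(s.ccf.mean())).cluster_id
                continue
            for s in siblings:
                violates = np.any(s.ccf + cl.ccf > parent_ccf + tau)
                if violates and _crossing(s.ccf, cl.ccf, tau):
                    unresolved.append((s.cluster_id, cl.cluster_id))
                elif (not violates and _encloses(s.ccf, cl.ccf, tau)
                      and not _crossing(s.ccf, cl.ccf, tau)):
                    ambiguous.append((s.cluster_id, cl.cluster_id))
            break
        parent[cl.cluster_id] = node
    return CloneTreeInferred(clusters=clusters, parent=parent,
                             ambiguous_pairs=ambiguous,
                             unresolved_pairs=unresolved)


def match_clusters(clusters_a, clusters_b, min_jaccard: float = 0.5):
    """Match clusters between two runs by member-set Jaccard index.

    Returns ``(mapping, unmatched_a, unmatched_b)`` where mapping sends
    cluster ids of ``clusters_a`` to ids of ``clusters_b``.
    """
    mapping = {}
    used = set()
    for a in clusters_a:
        sa = set(a.members)
        best, best_j = None, min_jaccard
        for b in clusters_b:
            if b.cluster_id in used:
                continue
            sb = set(b.members)
            j = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
            if j >= best_j:
                best, best_j = b.cluster_id, j
        if best is not None:
            mapping[a.cluster_id] = best
            used.add(best)
    unmatched_a = [a.cluster_id for a in clusters_a if a.cluster_id not in mapping]
    unmatched_b = [b.cluster_id for b in clusters_b if b.cluster_id not in used]
    return mapping, unmatched_a, unmatched_b


DYNAMICS_CLASSES = ("stable", "rapid_then_static", "gradual")


def track_dynamics(clusters, samples, stable_max_change: float = 0.1,
                   rapid_fraction: float = 0.7):
    """Clone-fraction trajectories across serial passages and their regime.

    ``samples`` orders the columns (tumor first, then passages). A cohort is
    ``stable`` when no clone's CCF range exceeds ``stable_max_change``,
    ``rapid_then_static`` when at least ``rapid_fraction`` of the total
    absolute CCF change happens at the derivation step (first transition),
    and ``gradual`` otherwise. Returns ``(trajectory, classification)``.
    """
    if len(samples) < 2:
        raise ValueError("dynamics require >= 2 time points")
    traj = pd.DataFrame(
        {cl.cluster_id: cl.ccf for cl in clusters}, index=list(samples)
    ).T
    ranges = traj.max(axis=1) - traj.min(axis=1)
    if float(ranges.max()) < stable_max_change:
        return traj, "stable"
    deltas = traj.diff(axis=1).abs().iloc[:, 1:]
    total = float(deltas.to_numpy().sum())
    first = float(deltas.iloc[:, 0].sum())
    if total > 0 and first / total >= rapid_fraction:
        return traj, "rapid_then_static"
    return traj, "gradual"
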