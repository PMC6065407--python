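"""CCF estimation, DP clustering recovery, cluster QC rules, sum/crossing
tree construction and passage dynamics."""

import numpy as np
import pytest

from concord.clonality import (
    CCFObservation,
    SubcloneCluster,
    build_tree,
    cluster_ccf,
    estimate_ccf,
    match_clusters,
    qc_clusters,
    track_dynamics,
)
from concord.synthetic import planted_subclone_dataset
from conftest import subclone_observations


class TestEstimateCCF:
    @pytest.mark.parametrize("alt,depth,purity,cn,exp_ccf,exp_m", [
        (50, 100, 1.0, 2, 1.0, 1),    # clonal heterozygous diploid
        (25, 100, 0.5, 2, 1.0, 1),    # impurity-corrected clonal variant
        (50, 100, 1.0, 4, 1.0, 2),    # doubled multiplicity on a 4-copy segment
    ])
    def test_formula(self, alt, depth, purity, cn, exp_ccf, exp_m):
        ccf, m, clipped = estimate_ccf(alt, depth, purity, cn)
        assert ccf == pytest.approx(exp_ccf)
        assert m == exp_m
        assert not clipped

    def test_clipping_and_errors(self):
        ccf, _, clipped = estimate_ccf(90, 100, 0.5, 2)
        assert clipped and ccf == 1.5
        with pytest.raises(ValueError):
            estimate_ccf(5, 0, 1.0, 2)
        with pytest.raises(ValueError):
            estimate_ccf(5, 10, 0.0, 2)


def _binomial_obs(ccfs, n_per, seed, depth=100, purity=(1.0, 1.0)):
    rng = np.random.default_rng(seed)
    purity = np.asarray(purity, dtype=float)
    atten = purity / (purity * 2 + (1 - purity) * 2)
    obs = []
    for j, ccf in enumerate(ccfs):
        vaf = np.asarray(ccf) * atten
        for i in range(n_per):
            alt = rng.binomial(depth, vaf)
            obs.append(CCFObservation(
                f"c{j}_m{i}", alt, np.full(len(vaf), float(depth)), purity,
                2.0, chrom=int(rng.integers(1, 23)),
            ))
    return obs


class TestClustering:
    def test_single_planted_clone(self):
        obs = _binomial_obs([(1.0, 1.0)], 200, seed=1)
        clusters = cluster_ccf(obs, seed=1)
        retained, _ = qc_clusters(clusters, total_mutations=len(obs))
        assert len(retained) == 1
        assert np.all(np.abs(retained[0].ccf - 1.0) <= 0.05)

    def test_two_planted_clones(self):
        obs = _binomial_obs([(1.0, 1.0), (0.3, 0.9)], 200, seed=1)
        clusters = cluster_ccf(obs, seed=1)
        retained, _ = qc_clusters(clusters, total_mutations=len(obs))
        assert len(retained) == 2
        assert np.all(np.abs(retained[0].ccf - 1.0) <= 0.08)
        assert np.all(np.abs(retained[1].ccf - (0.3, 0.9)) <= 0.08)

    def test_seeded_determinism(self):
        obs = _binomial_obs([(1.0, 1.0), (0.4, 0.7)], 100, seed=3)
        a = cluster_ccf(obs, seed=5, iterations=400, burn_in=100)
        b = cluster_ccf(obs, seed=5, iterations=400, burn_in=100)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.members == cb.members
            assert np.allclose(ca.ccf, cb.ccf)

    def test_pure_organoid_trunk_near_one(self):
        """Clustering pure-culture samples puts the trunk within 0.03 of
        fully clonal, mirroring near-100% organoid purity."""
        obs = _binomial_obs([(1.0, 1.0)], 300, seed=2, depth=100)
        clusters = cluster_ccf(obs, seed=2)
        retained, _ = qc_clusters(clusters, total_mutations=len(obs))
        assert np.all(np.abs(retained[0].ccf - 1.0) <= 0.03)

    def test_minor_tumor_clone_expanded_in_organoid_is_detected(self):
        """A subclone at tumor CCF 0.08 that sweeps to 0.7 in culture must
        surface as its own cluster in the organoid dimension."""
        obs = _binomial_obs([(1.0, 1.0), (0.08, 0.7)], 200, seed=4)
        clusters = cluster_ccf(obs, seed=4)
        retained, _ = qc_clusters(clusters, total_mutations=len(obs))
        assert len(retained) == 2
        minor = retained[1]
        assert abs(minor.ccf[1] - 0.7) <= 0.08

    def test_minimum_input_size(self):
        obs = _binomial_obs([(1.0, 1.0)], 5, seed=1)
        with pytest.raises(ValueError, match=">= 20"):
            cluster_ccf(obs, seed=1)


def _cluster(cid, ccf, members, dp=None, member_median=None, chroms=None):
    ccf = np.asarray(ccf, dtype=float)
    return SubcloneCluster(
        cluster_id=cid, ccf=ccf,
        dp_ccf=np.asarray(dp if dp is not None else ccf, dtype=float),
        member_ccf_median=np.asarray(
            member_median if member_median is not None else ccf, dtype=float),
        members=[f"{cid}_{i}" for i in range(members)],
        chrom_counts=chroms or {},
    )


class TestQCRules:
    def test_small_cluster_rejected(self):
        small = _cluster(0, [0.5], members=4)
        _, reasons = qc_clusters([small], total_mutations=1000)
        assert reasons[0] == ["too_few_mutations"]

    def test_ccf_discrepancy_rejected(self):
        off = _cluster(0, [0.5], members=100, dp=[0.5], member_median=[0.75])
        _, reasons = qc_clusters([off], total_mutations=1000)
        assert reasons[0] == ["ccf_discrepancy"]
        borderline = _cluster(1, [0.5], members=100, dp=[0.5], member_median=[0.70])
        retained, _ = qc_clusters([borderline], total_mutations=1000)
        assert retained  # exactly 0.2 is not "more than 0.2"

    def test_chromosome_concentration_rejected(self):
        skew = _cluster(0, [0.5], members=100, chroms={"7": 60, "1": 40})
        _, reasons = qc_clusters([skew], total_mutations=1000)
        assert reasons[0] == ["chromosome_concentration"]
        even = _cluster(1, [0.5], members=100, chroms={"7": 50, "1": 50})
        retained, _ = qc_clusters([even], total_mutations=1000)
        assert retained  # exactly 50% is not "more than 50%"


class TestTreeRules:
    def test_sum_rule_satisfied_children_are_siblings(self):
        tree = build_tree([_cluster(0, [1.0], 100), _cluster(1, [0.6], 100),
                           _cluster(2, [0.3], 100)])
        assert tree.parent == {0: None, 1: 0, 2: 0}
        assert (1, 2) in tree.ambiguous_pairs

    def test_sum_rule_violation_forces_nesting(self):
        tree = build_tree([_cluster(0, [1.0], 100), _cluster(1, [0.7], 100),
                           _cluster(2, [0.6], 100)])
        assert tree.parent[2] == 1  # 0.7 + 0.6 > 1.0: pigeonhole nesting

    def test_crossing_rule_forces_disjoint_branches(self):
        tree = build_tree([_cluster(0, [1.0, 1.0], 100),
                           _cluster(1, [0.7, 0.2], 100),
                           _cluster(2, [0.2, 0.7], 100)])
        assert tree.parent[1] == 0 and tree.parent[2] == 0
        assert not tree.is_ancestor(1, 2) and not tree.is_ancestor(2, 1)

    def test_constructed_tree_never_violates_sum_rule(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ccfs = np.sort(rng.uniform(0, 0.8, size=(3, 2)), axis=0)[::-1]
            clusters = [_cluster(0, [1.0, 1.0], 100)] + [
                _cluster(i + 1, ccfs[i], 100) for i in range(3)
            ]
            tree = build_tree(clusters)
            by_id = {c.cluster_id: c for c in clusters}
            for parent_id in tree.parent.values():
                if parent_id is None:
                    continue
            for node, parent_id in tree.parent.items():
                if parent_id is None:
                    continue
                siblings = [c for c in tree.children(parent_id) if c != node]
                for sib in siblings:
                    bad = (by_id[node].ccf + by_id[sib].ccf
                           > by_id[parent_id].ccf + 0.05)
                    if np.any(bad):
                        pair = tuple(sorted((node, sib)))
                        assert pair in [tuple(sorted(p))
                                        for p in tree.unresolved_pairs]

    def test_no_trunk_raises(self):
        with pytest.raises(ValueError, match="trunk"):
            build_tree([_cluster(0, [0.5, 0.5], 100)])

    def test_roundtrip_dict(self):
        tree = build_tree([_cluster(0, [1.0], 100), _cluster(1, [0.4], 100)])
        d = tree.to_dict()
        assert {c["cluster_id"] for c in d["clones"]} == {0, 1}


class TestDynamics:
    def test_constant_ccfs_are_stable(self):
        clusters = [_cluster(0, [1.0, 1.0, 1.0], 100),
                    _cluster(1, [0.4, 0.44, 0.41], 100)]
        _, cls = track_dynamics(clusters, ["tumor", "P4", "P10"])
        assert cls == "stable"

    def test_derivation_jump_is_rapid_then_static(self):
        clusters = [_cluster(0, [1.0, 1.0, 1.0, 1.0], 100),
                    _cluster(1, [0.1, 0.75, 0.78, 0.8], 100)]
        _, cls = track_dynamics(clusters, ["tumor", "P4", "P10", "P16"])
        assert cls == "rapid_then_static"

    def test_linear_drift_is_gradual(self):
        clusters = [_cluster(0, [1.0] * 5, 100),
                    _cluster(1, [0.1, 0.25, 0.4, 0.55, 0.7], 100)]
        _, cls = track_dynamics(clusters, ["tumor", "P4", "P8", "P12", "P16"])
        assert cls == "gradual"

    def test_planted_derivation_selection_classified_from_inference(self):
        """End-to-end: a derivation-concentrated selection regime generated,
        clustered, and classified as rapid-then-static."""
        tree, truth, observations = planted_subclone_dataset(
            3, seed=123, n_samples=4, mutations_per_clone=150,
            selection_shift=0.9,
        )
        obs = subclone_observations(tree, truth, observations)
        clusters = cluster_ccf(obs, seed=11)
        retained, _ = qc_clusters(clusters, total_mutations=len(obs))
        traj, cls = track_dynamics(retained, tree.samples)
        # The generator concentrates drift at derivation; the truth regime
        # computed from planted CCFs must match the inferred one.
        _, truth_cls = track_dynamics(
            [_cluster(c.clone_id, c.ccf, 100) for c in tree.clones],
            tree.samples,
        )
        assert cls == truth_cls


def test_match_clusters_by_jaccard():
    a = [_cluster(0, [1.0], 100), _cluster(1, [0.4], 100)]
    b = [_cluster(10, [1.0], 100), _cluster(11, [0.4], 100)]
    b[0].members = a[0].members[:80] + ["x"] * 20
    b[1].members = ["y"] * 60
    mapping, unmatched_a, unmatched_b = match_clusters(a, b)
    assert mapping == {0: 10}
    assert unmatched_a == [1] and unmatched_b == [11]
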