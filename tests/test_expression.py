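"""Expression normalization, expressed-SNV rules, internal DE test,
three-step signature-gene selection and the correlation matrix."""

import numpy as np
import pandas as pd
import pytest

from concord.expression import (
    SignatureGeneParams,
    classify_expressed_snv,
    correlation_matrix,
    differential_expression,
    normalize_counts,
    select_signature_genes,
)
from concord.synthetic import simulate_expression


@pytest.fixture(scope="module")
def expression_cohort():
    patients = [f"P{i:02d}" for i in range(1, 11)]
    em, truth = simulate_expression(2000, patients, seed=1)
    norm, _ = normalize_counts(em.counts)
    return em, truth, norm


class TestNormalization:
    def test_identical_samples_unit_size_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        _, sf = normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_library_doubles_size_factor(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=500) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        norm, sf = normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(norm["a"], norm["b"])

    def test_all_zero_gene_stays_zero(self):
        counts = pd.DataFrame({"a": [0, 5, 9], "b": [0, 5, 9]})
        norm, _ = normalize_counts(counts)
        assert (norm.iloc[0] == 0).all()


class TestExpressedSNV:
    @pytest.mark.parametrize("depth,alt,expected", [
        (3, 1, "not_expressed"),          # depth below 4
        (10, 0, "reference_expressed"),   # covered, VAF not > 0
        (4, 1, "alternative_expressed"),  # both thresholds met at boundary
        (0, 0, "not_expressed"),
    ])
    def test_examples(self, depth, alt, expected):
        assert classify_expressed_snv(depth, alt) == expected

    def test_exhaustive_against_rule_transcription(self):
        for depth in range(0, 30):
            for alt in range(0, depth + 1):
                expected = (
                    "not_expressed" if depth < 4
                    else ("alternative_expressed" if alt / depth > 0
                          else "reference_expressed")
                )
                assert classify_expressed_snv(depth, alt) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            classify_expressed_snv(3, 4)


class TestDifferentialExpression:
    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(1)
        n = 300
        mu = rng.lognormal(4, 0.5, n)
        a = pd.DataFrame({f"a{i}": rng.poisson(mu * 4 ** (np.arange(n) == 0))
                          for i in range(5)})
        b = pd.DataFrame({f"b{i}": rng.poisson(mu) for i in range(5)})
        counts = pd.concat([a, b], axis=1)
        norm, _ = normalize_counts(counts)
        res = differential_expression(norm, a.columns, b.columns)
        assert res.table["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.5)
        assert res.table["pvalue"].iloc[0] <= 0.01

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        n = 2000
        mu = rng.lognormal(4, 0.5, n)
        counts = pd.DataFrame({f"s{i}": rng.poisson(mu) for i in range(10)})
        norm, _ = normalize_counts(counts)
        res = differential_expression(norm, [f"s{i}" for i in range(5)],
                                      [f"s{i}" for i in range(5, 10)])
        rate = float((res.table["pvalue"] <= 0.01).mean())
        assert 0.002 <= rate <= 0.03

    def test_group_size_guard(self):
        counts = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        norm, _ = normalize_counts(counts + 1)
        with pytest.raises(ValueError):
            differential_expression(norm, ["a"], ["b", "c"])


class TestSignatureSelection:
    def test_culture_effect_genes_discarded(self, expression_cohort):
        em, truth, norm = expression_cohort
        selected = set(select_signature_genes(em, "P01", normalized=norm))
        assert not selected & set(truth.culture_program)

    def test_markers_selected_for_own_patient_only(self, expression_cohort):
        em, truth, norm = expression_cohort
        own = set(select_signature_genes(em, "P01", normalized=norm))
        other = set(select_signature_genes(em, "P02", normalized=norm))
        markers = set(truth.patient_programs["P01"])
        assert len(own & markers) >= 5
        assert len(own & markers) > len(other & markers)

    def test_loosening_thresholds_never_shrinks_the_set(self, expression_cohort):
        em, _, norm = expression_cohort
        tight = set(select_signature_genes(em, "P03", normalized=norm))
        loose = set(select_signature_genes(
            em, "P03", normalized=norm,
            params=SignatureGeneParams(step1_p=0.05, step2_p=0.001,
                                       step3_p=0.2, step3_abs_lfc=2.0,
                                       top_n=200),
        ))
        assert tight <= loose

    def test_missing_class_rejected(self, expression_cohort):
        em, _, norm = expression_cohort
        from concord.expression import ExpressionMatrix

        keep = em.classes != "normal"
        sub = ExpressionMatrix(
            counts=em.counts.loc[:, keep],
            classes=em.classes[keep],
            patients=em.patients[keep],
        )
        with pytest.raises(ValueError, match="missing sample class"):
            select_signature_genes(sub, "P01")


class TestCorrelationMatrix:
    def test_identical_and_negated_profiles(self):
        rng = np.random.default_rng(3)
        from concord.expression import ExpressionMatrix

        base = rng.poisson(100, size=200)
        counts = pd.DataFrame({
            "t1": base, "t2": rng.poisson(100, 200),
            "o1": base, "o2": rng.poisson(100, 200),
            "n1": rng.poisson(100, 200), "n2": rng.poisson(100, 200),
        })
        em = ExpressionMatrix(
            counts=counts,
            classes=pd.Series(["tumor", "tumor", "organoid", "organoid",
                               "normal", "normal"], index=counts.columns),
            patients=pd.Series(["p1", "p2", "p1", "p2", "p1", "p2"],
                               index=counts.columns),
        )
        norm, _ = normalize_counts(counts)
        res = correlation_matrix(em, {"p1": list(counts.index[:100])},
                                 normalized=norm)
        assert res.matrix.loc["t1", "o1"] == pytest.approx(1.0)
        assert np.all(res.matrix.to_numpy() <= 1.0 + 1e-12)
        assert np.all(res.matrix.to_numpy() >= -1.0 - 1e-12)

        negated = norm.copy()
        negated["o1"] = 2 * norm["o1"].mean() - norm["o1"]
        res2 = correlation_matrix(em, {"p1": list(counts.index[:100])},
                                  normalized=negated)
        assert res2.matrix.loc["t1", "o1"] == pytest.approx(-1.0)

    def test_matched_pairs_recovered_on_default_cohort(self, expression_cohort):
        em, _, norm = expression_cohort
        gene_sets = {
            p: select_signature_genes(em, p, normalized=norm)
            for p in sorted(set(em.patients))
        }
        res = correlation_matrix(em, gene_sets, normalized=norm)
        assert res.summary["matched_fraction"] >= 0.8
        assert len(res.row_order) == res.matrix.shape[0]

    def test_union_order_invariance(self, expression_cohort):
        em, _, norm = expression_cohort
        gs = {"P01": select_signature_genes(em, "P01", normalized=norm),
              "P02": select_signature_genes(em, "P02", normalized=norm)}
        forward = correlation_matrix(em, gs, normalized=norm)
        backward = correlation_matrix(
            em, {"P02": gs["P02"], "P01": gs["P01"]}, normalized=norm)
        assert np.allclose(forward.matrix, backward.matrix)

    def test_empty_union_rejected(self, expression_cohort):
        em, _, norm = expression_cohort
        with pytest.raises(ValueError, match="empty"):
            correlation_matrix(em, {"P01": []}, normalized=norm)


def test_dna_rna_concordance_of_expressed_mutations(low_purity_cohort):
    """Alternative-allele-expressed sites coincide with DNA-shared variants
    when RNA counts are generated from the same clone structure."""
    rng = np.random.default_rng(5)
    coh = low_purity_cohort
    organoid = coh.observations["P1"]
    shared_dna = set(
        coh.observations["tumor"].loc[lambda d: d.called, "mutation_id"]
    ) & set(organoid.loc[lambda d: d.called, "mutation_id"])
    # RNA read counts at the organoid's called loci, driven by true CCFs.
    statuses = {}
    for row in organoid[organoid.called].itertuples():
        depth = rng.poisson(30)
        alt = rng.binomial(depth, min(1.0, row.expected_vaf))
        statuses[row.mutation_id] = classify_expressed_snv(depth, alt)
    alt_expressed = {m for m, s in statuses.items()
                     if s == "alternative_expressed"}
    overlap = len(alt_expressed & shared_dna) / max(len(alt_expressed), 1)
    assert overlap >= 0.95
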