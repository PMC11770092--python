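"""Presence rule, pan-cancer sets and the differential screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import pooled_t_pvalue
from lepscan.screen import (
    AbundanceMatrix,
    ScreenConfig,
    call_presence,
    differential_expression,
    identified_sets,
    length_histogram,
    pan_cancer_sets,
    read_abundance,
    write_presence_table,
)
from lepscan.simulate import MissingModel, gen_abundance_cohort, write_abundance_tsv

NO_MISSING = MissingModel(mnar_quantile=0.0, mnar_slope=0.0, mcar_rate=0.0)


def make_matrix(values: np.ndarray, n_tumor: int, n_nontumor: int, cohort="kidney"):
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_nontumor)]
    meta = pd.DataFrame(
        {"cohort": [cohort] * len(samples),
         "group": ["tumor"] * n_tumor + ["nontumor"] * n_nontumor},
        index=pd.Index(samples, name="sample_id"),
    )
    vals = pd.DataFrame(values, columns=samples,
                        index=[f"P{i}" for i in range(values.shape[0])])
    return AbundanceMatrix(vals, meta)


class TestPresence:
    def test_forty_percent_tumor_is_identified(self, single_cohort_matrix):
        calls = {c.protein: c for c in call_presence(single_cohort_matrix)}
        assert calls["P2"].frac_tumor == pytest.approx(0.4)
        assert calls["P2"].frac_nontumor == 0.0
        assert calls["P2"].identified

    def test_exactly_thirty_percent_is_not_identified(self, single_cohort_matrix):
        calls = {c.protein: c for c in call_presence(single_cohort_matrix)}
        assert calls["P3"].frac_tumor == pytest.approx(0.3)
        assert not calls["P3"].identified

    def test_cohort_without_samples_raises(self, single_cohort_matrix):
        with pytest.raises(ValueError, match="ghost"):
            call_presence(single_cohort_matrix, cohorts=["ghost"])

    def test_identification_rate_matches_binomial_closed_form(self, rng):
        """Per-sample detection probability pi=0.35, n=10 tumor samples:
        the fraction of proteins identified must match
        P(Binomial(10, 0.35) >= 4) within 3 standard errors."""
        n_prot, n, pi = 1000, 10, 0.35
        detected = rng.random((n_prot, n)) < pi
        vals = np.where(detected, 100.0, np.nan)
        m = make_matrix(vals, n_tumor=n, n_nontumor=0)
        frac = np.mean([c.identified for c in call_presence(m)])
        expected = float(stats.binom.sf(3, n, pi))  # X >= 4 <=> X/n > 0.3
        se = np.sqrt(expected * (1 - expected) / n_prot)
        assert abs(frac - expected) < 3 * se

    def test_monotone_in_presence_frac(self, rng):
        detected = rng.random((200, 12)) < 0.4
        vals = np.where(detected, 50.0, np.nan)
        m = make_matrix(vals, 6, 6)
        prev = None
        for frac in (0.1, 0.3, 0.5, 0.7):
            ident = {c.protein for c in call_presence(m, ScreenConfig(presence_frac=frac))
                     if c.identified}
            if prev is not None:
                assert ident <= prev
            prev = ident


class TestPanCancerSets:
    def test_single_cohort_core_equals_unique(self):
        core, unique, counts = pan_cancer_sets({"kidney": {"A", "B"}})
        assert core == unique["kidney"] == {"A", "B"}
        assert counts == {"kidney": 2}

    def test_disjoint_cohorts(self):
        core, unique, _ = pan_cancer_sets({"a": {"X"}, "b": {"Y"}})
        assert core == set()
        assert unique == {"a": {"X"}, "b": {"Y"}}

    def test_partition_identity(self, rng):
        """core, the unique sets and the shared-but-not-core remainder
        partition the union of identified sets."""
        universe = [f"P{i}" for i in range(40)]
        for _ in range(20):
            ident = {
                f"c{k}": {p for p in universe if rng.random() < 0.5}
                for k in range(int(rng.integers(2, 6)))
            }
            core, unique, _ = pan_cancer_sets(ident)
            union = set().union(*ident.values())
            uniq_all = set().union(*unique.values())
            shared_not_core = union - core - uniq_all
            # pairwise disjoint
            assert not core & uniq_all
            for a in unique:
                for b in unique:
                    if a != b:
                        assert not unique[a] & unique[b]
            assert core | uniq_all | shared_not_core == union

    def test_planted_core_recovered(self):
        design = {c: (10, 10) for c in ["a", "b", "c", "d", "e", "f", "g", "h", "i"]}
        m, truth = gen_abundance_cohort(42, design=design, n_proteins=120, n_core=3)
        core, unique, _ = pan_cancer_sets(identified_sets(call_presence(m)))
        assert core == truth.planted_core_leps
        assert len(core) == 3
        for c, planted in truth.planted_unique_leps.items():
            assert planted <= unique[c]


class TestDifferentialExpression:
    def test_below_fifty_percent_presence_excluded(self, single_cohort_matrix):
        res = {r.protein: r for r in differential_expression(single_cohort_matrix)}
        assert res["P4"].skip_reason == "below_de_presence_frac"
        assert res["P1"].skip_reason == ""

    def test_identical_groups_not_significant(self):
        vals = np.full((1, 12), 64.0)
        m = make_matrix(vals, 6, 6)
        (r,) = differential_expression(m)
        assert r.log2fc == 0.0
        assert not r.significant

    def test_label_symmetry(self, rng):
        vals = np.exp2(rng.normal(25, 1, size=(50, 16)))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = make_matrix(vals, 8, 8)
        flipped_meta = m.sample_meta.copy()
        flipped_meta["group"] = flipped_meta["group"].map(
            {"tumor": "nontumor", "nontumor": "tumor"}
        )
        m2 = AbundanceMatrix(m.values, flipped_meta)
        for r1, r2 in zip(differential_expression(m), differential_expression(m2)):
            assert r1.skip_reason == r2.skip_reason
            if not r1.skip_reason:
                assert r1.log2fc == pytest.approx(-r2.log2fc)
                assert r1.p_value == pytest.approx(r2.p_value)

    def test_fold_change_on_linear_scale_means(self, rng):
        vals = np.exp2(rng.normal(20, 0.3, size=(1, 12)))
        m = make_matrix(vals, 6, 6)
        (r,) = differential_expression(m)
        expected = np.log2(vals[0, :6].mean() / vals[0, 6:].mean())
        assert r.log2fc == pytest.approx(expected)

    def test_student_t_path_matches_independent_t(self, rng):
        """For proteins routed to the t-test, the p-value equals a from-
        scratch pooled-variance computation."""
        vals = np.exp2(rng.normal(24, 0.5, size=(40, 20)))
        m = make_matrix(vals, 10, 10)
        checked = 0
        for r in differential_expression(m):
            if r.test_used == "student_t":
                row = m.values.loc[r.protein]
                p = pooled_t_pvalue(np.log2(row[:10]), np.log2(row[10:]))
                assert r.p_value == pytest.approx(p)
                checked += 1
        assert checked > 10

    def test_nonnormal_data_routed_to_mann_whitney(self, rng):
        base = np.exp2(rng.normal(20, 0.2, size=(1, 24)))
        base[0, ::5] *= 2000  # heavy outliers break normality
        m = make_matrix(base, 12, 12)
        (r,) = differential_expression(m)
        assert r.test_used == "mann_whitney"

    def test_planted_effects_detected_with_signs(self):
        m, truth = gen_abundance_cohort(
            3, design={"kidney": (20, 20)}, n_proteins=150, de_fraction=0.2,
            effect_log2fc=1.0, sigma=0.5, missing=NO_MISSING,
        )
        res = {r.protein: r for r in differential_expression(m)}
        hits = [p for p, fc in truth.planted_de.items() if res[p].significant]
        assert len(hits) / len(truth.planted_de) >= 0.9
        for p, fc in truth.planted_de.items():
            if res[p].significant:
                assert np.sign(res[p].log2fc) == np.sign(fc)


class TestLengthHistogram:
    def test_empty_input_all_zero(self):
        counts, fracs = length_histogram([], [0, 50, 200])
        assert counts.tolist() == [0, 0]
        assert fracs.tolist() == [0.0, 0.0]

    def test_single_length_lands_in_bin(self):
        counts, fracs = length_histogram([92], [0, 50, 200, 1000])
        assert counts.tolist() == [0, 1, 0]
        assert fracs.tolist() == [0.0, 1.0, 0.0]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            length_histogram([10], [0, 200, 50])

    def test_mixture_fractions_recovered(self, rng):
        """Lengths from a 0.7/0.3 mixture of Uniform[50,200) and
        Uniform[200,500): bin fractions match weights within 3 SE."""
        n = 4000
        pick = rng.random(n) < 0.7
        lengths = np.where(pick, rng.integers(50, 200, n), rng.integers(200, 500, n))
        counts, fracs = length_histogram(lengths.tolist(), [0, 50, 200, 500])
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(fracs[1] - 0.7) < 3 * se
        assert counts.sum() == n
        assert fracs.sum() == pytest.approx(1.0)


def test_abundance_tsv_roundtrip(tmp_path):
    m, _ = gen_abundance_cohort(9, design={"kidney": (4, 4), "liver": (4, 4)},
                                n_proteins=30)
    write_abundance_tsv(m, tmp_path / "ab.tsv", tmp_path / "meta.tsv", seed=9)
    assert "# seed=9" in (tmp_path / "ab.tsv").read_text().splitlines()[0]
    m2 = read_abundance(tmp_path / "ab.tsv", tmp_path / "meta.tsv")
    pd.testing.assert_frame_equal(m.values, m2.values, check_exact=False, check_names=False)
    assert list(m2.sample_meta["group"]) == list(m.sample_meta["group"])
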