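"""VEP evaluation: coverage/intersection semantics, AUROC, Youden, kappa."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from idrbench import (
    VepBenchmark,
    VepScoreSet,
    auroc,
    binarize,
    cohens_kappa,
    confusion_at_threshold,
    filter_by_coverage,
    group_agreement,
    intersect_complete,
    orient_scores,
    region_thresholds,
    roc_curve,
    youden_threshold,
)


def auroc_bruteforce(scores, outcomes):
    """Pairwise Mann-Whitney count, ties one half."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_bruteforce(scores, outcomes):
    """Exhaustive max of J over candidate thresholds (observed scores + inf)."""
    best = None
    for t in sorted(set(scores)) + [math.inf]:
        sens, spec, _ = confusion_at_threshold(scores, outcomes, t)
        J = sens + spec - 1
        if best is None or J > best[0] + 1e-12:
            best = (J, sens, t)
        elif abs(J - best[0]) <= 1e-12 and sens > best[1] + 1e-12:
            best = (J, sens, t)
    return best


def key(i):
    return ("P1", i, "A", "V")


def make_variants(n_path, n_ben, regions=None):
    n = n_path + n_ben
    regions = regions or ["ordered"] * n
    return pd.DataFrame(
        {
            "protein_id": "P1",
            "gene": "G",
            "position": range(1, n + 1),
            "ref_aa": "A",
            "alt_aa": "V",
            "class_label": ["clinvar_pathogenic"] * n_path + ["gnomad_benign"] * n_ben,
            "region": regions,
        }
    )


class TestCoverageFilter:
    def test_075_boundary_inclusive(self):
        variants = make_variants(10, 10)
        sets = [
            VepScoreSet(f"v{i}", "population_free", True,
                        {key(j + 1): float(j) for j in range(cov)})
            for i, cov in enumerate([16, 15, 12])
        ]
        retained, coverage = filter_by_coverage(sets, variants, 0.75)
        assert [s.name for s in retained] == ["v0", "v1"]  # 0.80, 0.75 kept
        assert coverage == {"v0": 0.80, "v1": 0.75, "v2": 0.60}

    def test_complete_sets_all_retained(self):
        variants = make_variants(2, 2)
        sets = [VepScoreSet("v", "population_free", True,
                            {key(i): 0.0 for i in range(1, 5)})]
        retained, _ = filter_by_coverage(sets, variants, 1.0)
        assert len(retained) == 1

    def test_min_frac_one_drops_any_missing(self):
        variants = make_variants(2, 2)
        complete = VepScoreSet("c", "population_free", True,
                               {key(i): 0.0 for i in range(1, 5)})
        partial = VepScoreSet("p", "population_free", True,
                              {key(i): 0.0 for i in range(1, 4)})
        retained, _ = filter_by_coverage([complete, partial], variants, 1.0)
        assert [s.name for s in retained] == ["c"]

    def test_none_retained_errors(self):
        variants = make_variants(2, 2)
        empty = VepScoreSet("e", "population_free", True, {key(1): 0.0})
        with pytest.raises(ValueError, match="coverage"):
            filter_by_coverage([empty], variants, 0.9)


class TestIntersection:
    def test_keeps_only_shared_variants(self):
        variants = make_variants(2, 2)
        a = VepScoreSet("a", "population_free", True,
                        {key(i): float(i) for i in range(1, 5)})
        b = VepScoreSet("b", "population_free", True,
                        {key(i): float(i) for i in (1, 2, 4)})
        ds = intersect_complete(variants, [a, b])
        assert ds.variants["position"].tolist() == [1, 2, 4]
        assert list(ds.scores.columns) == ["a", "b"]

    def test_order_of_operations_is_normative(self):
        # VEP coverage filter first, then variant intersection.  Reversing the
        # order (intersect variants shared by ALL supplied VEPs, then filter)
        # gives a different retained set on this toy.
        variants = make_variants(10, 10)
        variants["class_label"] = [
            "clinvar_pathogenic" if i % 2 else "gnomad_benign" for i in range(20)
        ]
        full = VepScoreSet("full", "population_free", True,
                           {key(i): float(i) for i in range(1, 21)})
        most = VepScoreSet("most", "population_free", True,
                           {key(i): float(i) for i in range(1, 16)})  # 75%
        sparse = VepScoreSet("sparse", "population_free", True,
                             {key(i): float(i) for i in range(1, 11)})  # 50%
        retained, _ = filter_by_coverage([full, most, sparse], variants, 0.75)
        ds = intersect_complete(variants, retained)
        assert [s.name for s in retained] == ["full", "most"]
        assert len(ds.variants) == 15
        # reversed order: intersection over all three first -> only 10 variants,
        # on which every VEP is complete, so sparse would survive
        ds_wrong = intersect_complete(variants, [full, most, sparse])
        assert len(ds_wrong.variants) == 10
        retained_wrong, _ = filter_by_coverage(
            [full, most, sparse], ds_wrong.variants, 0.75
        )
        assert len(retained_wrong) == 3  # differs from the normative result

    def test_class_vanishing_errors(self):
        variants = make_variants(2, 2)
        only_benign = VepScoreSet("x", "population_free", True,
                                  {key(3): 1.0, key(4): 0.0})
        with pytest.raises(ValueError, match="class"):
            intersect_complete(variants, [only_benign])


class TestOrientation:
    def test_identity_when_higher_is_pathogenic(self):
        s = VepScoreSet("v", "population_free", True, {key(1): 2.0})
        assert orient_scores(s).scores[key(1)] == 2.0

    def test_negation_preserves_auroc(self):
        scores = [3.0, 1.0, 2.0, 0.0]
        outcomes = [1, 1, 0, 0]
        flipped = VepScoreSet("v", "population_free", False,
                              {key(i + 1): -s for i, s in enumerate(scores)})
        oriented = orient_scores(flipped)
        recovered = [oriented.scores[key(i + 1)] for i in range(4)]
        assert auroc(recovered, outcomes) == auroc(scores, outcomes)

    def test_audit_warns_never_flips(self, caplog):
        s = VepScoreSet("v", "population_free", True,
                        {key(1): 0.0, key(2): 1.0})
        outcomes = {key(1): 1, key(2): 0}  # anti-correlated: AUROC 0
        with caplog.at_level("WARNING"):
            out = orient_scores(s, outcomes, audit=True)
        assert out.scores == s.scores
        assert any("AUROC" in r.message for r in caplog.records)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,outcomes,expected",
        [
            ([3, 4, 1, 2], [1, 1, 0, 0], 1.0),     # perfect separation
            ([5, 5, 5, 5], [1, 1, 0, 0], 0.5),     # all ties at one half
            ([3, 1, 2, 0], [1, 1, 0, 0], 0.75),    # 3 of 4 pairs won
        ],
    )
    def test_known_values(self, scores, outcomes, expected):
        assert auroc(scores, outcomes) == pytest.approx(expected, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_and_sklearn(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(st.integers(-5, 5).map(float), min_size=n, max_size=n)
        )
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        a = auroc(scores, outcomes)
        assert a == pytest.approx(auroc_bruteforce(scores, outcomes), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-9)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(
            st.lists(st.integers(-20, 20).map(float), min_size=n, max_size=n)))
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        transformed = np.exp(scores / 10.0)  # strictly increasing
        assert auroc(scores, outcomes) == pytest.approx(
            auroc(transformed, outcomes), abs=1e-12
        )
        t0 = youden_threshold(scores, outcomes)
        t1 = youden_threshold(transformed, outcomes)
        assert (t0.sensitivity, t0.specificity) == (t1.sensitivity, t1.specificity)
        if math.isfinite(t0.threshold):
            assert t1.threshold == pytest.approx(math.exp(t0.threshold / 10.0))

    def test_roc_curve_endpoints_monotone(self):
        curve = roc_curve([3, 1, 2, 0, 2], [1, 1, 0, 0, 1])
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_trapezoid_equals_rank_auroc(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 6, size=40).astype(float)
        outcomes = rng.integers(0, 2, size=40)
        outcomes[:2] = [0, 1]
        curve = roc_curve(scores, outcomes)
        area = np.trapezoid(curve[:, 1], curve[:, 0])
        assert area == pytest.approx(auroc(scores, outcomes), abs=1e-12)


class TestYouden:
    def test_perfect_separation(self):
        res = youden_threshold([3, 4, 1, 2], [1, 1, 0, 0])
        assert (res.threshold, res.J) == (3.0, 1.0)
        assert (res.sensitivity, res.specificity) == (1.0, 1.0)

    def test_all_identical_prefers_sensitivity(self):
        res = youden_threshold([5, 5, 5, 5], [1, 1, 0, 0])
        assert res.J == 0.0
        assert res.threshold == 5.0  # sens 1/spec 0 preferred over sens 0/spec 1
        assert res.sensitivity == 1.0

    def test_tie_breaks_to_lower_threshold(self):
        res = youden_threshold([1, 3, 0, 2], [1, 1, 0, 0])
        assert res.threshold == 1.0
        assert (res.J, res.sensitivity, res.specificity) == (0.5, 1.0, 0.5)

    def test_J_identity(self):
        res = youden_threshold([3, 1, 2, 0], [1, 1, 0, 0])
        assert res.J == pytest.approx(res.sensitivity + res.specificity - 1)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_scan(self, data):
        n = data.draw(st.integers(4, 40))
        scores = data.draw(
            st.lists(st.integers(-4, 4).map(float), min_size=n, max_size=n))
        outcomes = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        res = youden_threshold(scores, outcomes)
        J, sens, t = youden_bruteforce(scores, outcomes)
        assert res.J == pytest.approx(J, abs=1e-12)
        assert res.sensitivity == pytest.approx(sens, abs=1e-12)
        assert res.threshold == t


class TestConfusion:
    def test_extreme_thresholds(self):
        scores, outcomes = [1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1]
        assert confusion_at_threshold(scores, outcomes, 0.0)[:2] == (1.0, 0.0)
        assert confusion_at_threshold(scores, outcomes, 10.0)[:2] == (0.0, 1.0)

    def test_hand_count(self):
        sens, spec, counts = confusion_at_threshold([3, 1, 2, 0], [1, 1, 0, 0], 2.0)
        assert (sens, spec) == (0.5, 0.5)
        assert counts == {"tp": 1, "fp": 1, "tn": 1, "fn": 1}

    def test_no_pathogenic_flagged_nan(self):
        sens, spec, _ = confusion_at_threshold([1.0, 2.0], [0, 0], 1.5)
        assert math.isnan(sens) and spec == 0.5


class TestBinarize:
    def test_ge_rule(self):
        assert binarize([1, 2, 3], 2.0).tolist() == [0, 1, 1]

    def test_infinite_threshold(self):
        assert binarize([1, 2, 3], math.inf).tolist() == [0, 0, 0]


class TestKappa:
    def test_identical_is_one(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_printed_contingency_table(self):
        # agreement table [[40, 10], [10, 40]]: p_o = 0.8, p_e = 0.5 -> 0.6
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_complementary_balanced_is_minus_one(self):
        a = [0] * 50 + [1] * 50
        b = [1] * 50 + [0] * 50
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_constant_vector_edge_cases(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        assert cohens_kappa([1, 1, 1], [0, 0, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([0, 1], [0])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounds_symmetry_and_sklearn(self, data):
        n = data.draw(st.integers(2, 60))
        a = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        k = cohens_kappa(a, b)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        assert k == pytest.approx(cohens_kappa(b, a), abs=1e-12)
        if len(set(a)) == 2 and len(set(b)) == 2:
            assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)


class TestGroupAgreement:
    def test_mean_and_sem_over_pairs(self):
        rng = np.random.default_rng(11)
        calls = {f"v{i}": rng.integers(0, 2, size=200) for i in range(3)}
        groups = {f"v{i}": "population_free" for i in range(3)}
        (res,) = group_agreement(calls, groups)
        pair_ks = [
            cohens_kappa(calls[a], calls[b])
            for a, b in itertools.combinations(sorted(calls), 2)
        ]
        assert res.n_pairs == 3
        assert res.mean_kappa == pytest.approx(np.mean(pair_ks))
        assert res.sem == pytest.approx(np.std(pair_ks, ddof=1) / math.sqrt(3))

    def test_two_singleton_groups(self):
        calls = {"a": np.array([0, 1, 1]), "b": np.array([0, 1, 0])}
        groups = {"a": "clinical_trained", "b": "population_free"}
        results = group_agreement(calls, groups)
        assert len(results) == 1  # only the between-group entry
        assert results[0].group_pair == ("clinical_trained", "population_free")
        assert results[0].sem is None  # single pair: SEM undefined, flagged

    def test_identical_calls_mean_one_sem_zero(self):
        vec = np.array([0, 1, 0, 1, 1])
        calls = {f"v{i}": vec.copy() for i in range(3)}
        groups = {f"v{i}": "population_free" for i in range(3)}
        (res,) = group_agreement(calls, groups)
        assert res.mean_kappa == 1.0 and res.sem == 0.0


class TestRegionThresholds:
    def test_identical_regions_identical_thresholds(self):
        scores = [0.0, 1.0, 2.0, 3.0]
        outcomes = [0, 0, 1, 1]
        regions = []
        all_scores, all_outcomes = [], []
        for region in ("disordered", "intermediate", "ordered"):
            regions += [region] * 4
            all_scores += scores
            all_outcomes += outcomes
        n = len(regions)
        variants = make_variants(0, 0) if False else pd.DataFrame(
            {
                "protein_id": "P1", "gene": "G", "position": range(1, n + 1),
                "ref_aa": "A", "alt_aa": "V",
                "class_label": ["clinvar_pathogenic" if y else "gnomad_benign"
                                for y in all_outcomes],
                "region": regions,
            }
        )
        s = VepScoreSet("v", "population_free", True,
                        {key(i + 1): all_scores[i] for i in range(n)})
        ds = intersect_complete(variants, [s])
        results = region_thresholds(ds, "v")
        thresholds = {r.scope: r.threshold for r in results}
        assert len(thresholds) == 4
        assert len(set(thresholds.values())) == 1

    def test_single_class_region_skipped(self, caplog):
        variants = make_variants(2, 2, regions=["ordered"] * 3 + ["disordered"])
        s = VepScoreSet("v", "population_free", True,
                        {key(i): float(i) for i in range(1, 5)})
        ds = intersect_complete(variants, [s])
        with caplog.at_level("WARNING"):
            results = region_thresholds(ds, "v")
        assert {r.scope for r in results} == {"global", "ordered"}


class TestVepBenchmark:
    def test_fit_and_summary(self, toy_variants):
        keys = [
            (r.protein_id, int(r.position), r.ref_aa, r.alt_aa)
            for r in toy_variants.itertuples(index=False)
        ]
        rng = np.random.default_rng(3)
        scoresets = [
            VepScoreSet(name, group, True,
                        {k: float(5 * (toy_variants["class_label"][i] == "clinvar_pathogenic")
                                  + rng.normal()) for i, k in enumerate(keys)})
            for name, group in [("a", "clinical_trained"), ("b", "clinical_trained"),
                                ("c", "population_free"), ("d", "population_free")]
        ]
        results = VepBenchmark(toy_variants, scoresets).fit()
        assert set(results.metrics["vep"]) == {"a", "b", "c", "d"}
        assert (results.metrics["auroc"] >= 0).all()
        text = results.summary()
        assert "AUROC" in text and "kappa" in text
        # global scope reported for every VEP
        assert (results.metrics["scope"] == "global").sum() == 4

    def test_min_coverage_validation(self, toy_variants):
        with pytest.raises(ValueError):
            VepBenchmark(toy_variants, [], min_coverage=1.5)
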