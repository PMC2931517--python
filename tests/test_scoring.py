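"""Scoring functions: worked examples, naive-oracle equivalence, invariants."""

import math
import random

import pytest

from fact.architecture_model import (
    ClanProfile,
    CountProfile,
    FeatureArchitecture,
    FeatureCatalog,
    FeatureInstance,
    clan_profile,
    count_profile,
    position_profile,
)
from fact.annotation_io import Proteome
from fact.scoring import (
    ScoreWeights,
    WeightVector,
    clan_similarity,
    fact_score,
    mls,
    multiplicity_similarity,
    positional_similarity,
    proteome_weights,
    uniform_weights,
)
from conftest import random_architecture


# ---------------------------------------------------------------------------
# Naive reference implementation: plain loops straight from the score
# definitions, sharing no code with the production module.


def naive_mls(p: dict, q: dict, jc=0.365, dc=0.635) -> float:
    union = sorted(set(p) | set(q))
    if not union:
        return 0.0
    shared = [f for f in union if f in p and f in q]
    jaccard = len(shared) / (len(p) + len(q) - len(shared))
    diff = 0.0
    nmax = 0.0
    for f in union:
        diff += abs(p.get(f, 0) - q.get(f, 0))
        nmax += max(p.get(f, 0), q.get(f, 0))
    return jc * jaccard + dc * math.exp(-diff / nmax)


def naive_ms(p: dict, q: dict, w: dict) -> float:
    total = 0.0
    for f in q:
        if f in p:
            total += w.get(f, 0.0) * (p[f] * q[f]) / max(p[f], q[f]) ** 2
    return total


def naive_cs(cp: dict, cq: dict) -> float:
    if not cq:
        return 0.0
    total = 0.0
    for c in cq:
        if c in cp:
            total += (cp[c] * cq[c]) / max(cp[c], cq[c]) ** 2
    return total / len(cq)


def naive_ps(pp: dict, pq: dict, counts_q: dict, w: dict) -> float:
    total = 0.0
    for f in pq:
        if f not in pp or not pp[f]:
            continue
        inner = 0.0
        for qc in pq[f]:
            inner += 1.0 - min(abs(qc - pc) for pc in pp[f])
        total += (w.get(f, 0.0) / counts_q[f]) * inner
    return total


def naive_proteome_weights(q: dict, totals: dict) -> dict:
    denom = sum(totals.get(f, 0) for f in q)
    if denom == 0:
        return {f: 0.0 for f in q}
    return {f: totals.get(f, 0) / denom for f in q}


# ---------------------------------------------------------------------------
# Worked examples, evaluated by hand from the score definitions.


class TestMLS:
    def test_identical_single_feature(self):
        assert mls(CountProfile({"A": 1}), CountProfile({"A": 1})) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_hand_worked_example(self):
        # 0.365·(2/4) + 0.635·exp(−7/9)
        p, q = CountProfile({"A": 2, "B": 1, "D": 5}), CountProfile(
            {"A": 1, "B": 1, "C": 1}
        )
        expected = 0.365 * 0.5 + 0.635 * math.exp(-7 / 9)
        assert mls(p, q) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4742, abs=5e-5)

    def test_disjoint_profiles_score_positive(self):
        # 0.635·e^−1: disjoint architectures still score > 0 under MLS
        got = mls(CountProfile({"X": 1}), CountProfile({"A": 1}))
        assert got == pytest.approx(0.635 * math.exp(-1), abs=1e-12)
        assert got == pytest.approx(0.2336, abs=5e-5)

    def test_both_empty_is_zero(self):
        assert mls(CountProfile({}), CountProfile({})) == 0.0

    def test_symmetric(self):
        rng = random.Random(2)
        for _ in range(100):
            p = {f: rng.randint(1, 5) for f in rng.sample("ABCDEFG", rng.randint(0, 5))}
            q = {f: rng.randint(1, 5) for f in rng.sample("ABCDEFG", rng.randint(0, 5))}
            assert mls(CountProfile(p), CountProfile(q)) == mls(
                CountProfile(q), CountProfile(p)
            )


class TestWeights:
    def test_uniform_three_features(self):
        wv = uniform_weights(CountProfile({"A": 1, "B": 2, "C": 1}))
        assert wv.weights == {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}

    def test_uniform_single_feature(self):
        assert uniform_weights(CountProfile({"A": 4}))["A"] == 1.0

    def test_uniform_empty_query_flagged(self):
        wv = uniform_weights(CountProfile({}))
        assert wv.degenerate and wv.weights == {}

    def _ref(self):
        return Proteome(
            [
                FeatureArchitecture(
                    "P1",
                    100,
                    [
                        FeatureInstance("A", 1, 10),
                        FeatureInstance("A", 20, 30),
                        FeatureInstance("B", 40, 50),
                    ],
                ),
                FeatureArchitecture(
                    "P2",
                    100,
                    [
                        FeatureInstance("A", 1, 10),
                        FeatureInstance("C", 20, 30),
                        FeatureInstance("C", 40, 50),
                        FeatureInstance("C", 60, 70),
                    ],
                ),
            ]
        )

    def test_proteome_frequency_hand_example(self):
        # totals A=3, B=1 over the two-protein reference → 3/4 and 1/4
        wv = proteome_weights(CountProfile({"A": 1, "B": 1}), self._ref())
        assert wv["A"] == pytest.approx(0.75, abs=1e-12)
        assert wv["B"] == pytest.approx(0.25, abs=1e-12)

    def test_absent_feature_gets_zero_weight(self):
        wv = proteome_weights(CountProfile({"A": 1, "Z": 1}), self._ref())
        assert wv["Z"] == 0.0
        assert sum(wv.weights.values()) == pytest.approx(1.0)

    def test_all_absent_flags_degenerate(self):
        wv = proteome_weights(CountProfile({"Y": 1, "Z": 1}), self._ref())
        assert wv.degenerate
        assert set(wv.weights.values()) == {0.0}

    def test_inverse_scheme_prefers_rare_features(self):
        wv = proteome_weights(
            CountProfile({"A": 1, "B": 1}), self._ref(), scheme="inverse"
        )
        # totals A=3, B=1 → inverse 1/3 : 1 → normalised 1/4 : 3/4
        assert wv["A"] == pytest.approx(0.25, abs=1e-12)
        assert wv["B"] == pytest.approx(0.75, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            proteome_weights(CountProfile({"A": 1}), Proteome())


class TestMultiplicitySimilarity:
    def test_identical_profiles_uniform(self):
        q = CountProfile({"A": 2, "B": 1})
        assert multiplicity_similarity(q, q, uniform_weights(q)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_hand_worked_example(self):
        # (1/3)(2·1/2² + 1·1/1²) = 0.5
        p = CountProfile({"A": 2, "B": 1, "D": 5})
        q = CountProfile({"A": 1, "B": 1, "C": 1})
        assert multiplicity_similarity(p, q, uniform_weights(q)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_disjoint_profiles(self):
        p, q = CountProfile({"X": 1}), CountProfile({"A": 1})
        assert multiplicity_similarity(p, q, uniform_weights(q)) == 0.0

    def test_uniform_sum_bounded_by_shared_fraction(self):
        # with ω = 1/N^Q over shared features only, the score tops out at
        # N^PQ / N^Q, reaching 1 only when all of Q's features are shared
        p = CountProfile({"A": 1})
        q = CountProfile({"A": 1, "B": 1})
        assert multiplicity_similarity(p, q, uniform_weights(q)) == pytest.approx(
            0.5, abs=1e-12
        )


class TestClanSimilarity:
    def test_hand_worked_example(self):
        # Q clan X with 2 instances, P with 1 → (1/1)·(2/4)
        assert clan_similarity(
            ClanProfile({"X": 1}), ClanProfile({"X": 2})
        ) == pytest.approx(0.5, abs=1e-12)

    def test_identical_clan_profiles(self):
        c = ClanProfile({"X": 2, "Y": 1})
        assert clan_similarity(c, c) == pytest.approx(1.0, abs=1e-12)

    def test_query_without_clans_scores_zero(self):
        assert clan_similarity(ClanProfile({"X": 3}), ClanProfile({})) == 0.0


class TestPositionalSimilarity:
    def make(self, q_centers, p_centers):
        from fact.architecture_model import PositionProfile

        pq = PositionProfile({"A": sorted(q_centers)})
        pp = PositionProfile({"A": sorted(p_centers)})
        counts_q = CountProfile({"A": len(q_centers)})
        return pp, pq, counts_q

    def test_identical_centers(self):
        pp, pq, cq = self.make([0.3], [0.3])
        assert positional_similarity(
            pp, pq, cq, WeightVector({"A": 1.0})
        ) == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_example(self):
        # (1/2)((1−0.05) + (1−0.1)) = 0.925
        pp, pq, cq = self.make([0.2, 0.8], [0.25, 0.9])
        assert positional_similarity(
            pp, pq, cq, WeightVector({"A": 1.0})
        ) == pytest.approx(0.925, abs=1e-12)

    def test_maximal_displacement(self):
        pp, pq, cq = self.make([0.0], [1.0])
        assert positional_similarity(
            pp, pq, cq, WeightVector({"A": 1.0})
        ) == pytest.approx(0.0, abs=1e-12)


class TestCompositeScore:
    def test_identical_clan_bearing_architectures(self, gst_pair, gst_catalog):
        _, subject = gst_pair
        ref = Proteome([subject])
        b = fact_score(subject, subject, ref, gst_catalog)
        assert b.fact == pytest.approx(1.0, abs=1e-12)
        assert (b.ms_uni, b.ms_st, b.cs, b.ps, b.mls) == pytest.approx(
            (1.0,) * 5, abs=1e-12
        )

    def test_identical_architectures_without_pfam(self):
        a = FeatureArchitecture(
            "P", 100, [FeatureInstance("tmhmm:TM", 10, 30)]
        )
        ref = Proteome([a])
        b = fact_score(a, a, ref, FeatureCatalog())
        # CS = 0 by convention → 0.6·1 + 0.2·0 + 0.2·1
        assert b.cs == 0.0
        assert b.fact == pytest.approx(0.8, abs=1e-12)

    def test_linear_combination(self):
        w = ScoreWeights()
        assert w.alpha * 0.5 + w.beta * 0.5 + w.gamma * 0.925 == pytest.approx(
            0.585, abs=1e-12
        )

    def test_breakdown_satisfies_composite_identity(self, random_pair_factory):
        cat = FeatureCatalog({"pfam:PF1": "CLX", "pfam:PF2": "CLX"})
        for seed in range(50):
            p, q, ref = random_pair_factory(seed)
            b = fact_score(p, q, ref, cat)
            assert b.fact == pytest.approx(
                0.6 * b.ms_st + 0.2 * b.cs + 0.2 * b.ps, abs=1e-12
            )

    def test_featureless_pair_degenerate(self):
        a = FeatureArchitecture("P", 50)
        q = FeatureArchitecture("Q", 50, [FeatureInstance("A", 1, 10)])
        ref = Proteome([a, q])
        b = fact_score(a, q, ref, FeatureCatalog())
        assert b.degenerate and b.fact == 0.0

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ScoreWeights(alpha=0.5, beta=0.5, gamma=0.5)


class TestOracleEquivalence:
    """Production scorer vs the naive plain-loop reference, random pairs."""

    def test_agreement_within_1e_12(self, random_pair_factory):
        cat = FeatureCatalog({"pfam:PF1": "CLX", "pfam:PF2": "CLY"})
        for seed in range(250):
            p, q, ref = random_pair_factory(seed)
            b = fact_score(p, q, ref, cat)
            cp, cq = count_profile(p).counts, count_profile(q).counts
            if not cp or not cq:
                assert b.fact == 0.0 and b.degenerate
                continue
            w_st = naive_proteome_weights(cq, ref.feature_totals)
            w_uni = {f: 1.0 / len(cq) for f in cq}
            clp = clan_profile(p, cat).counts
            clq = clan_profile(q, cat).counts
            ppp = position_profile(p).positions
            ppq = position_profile(q).positions
            assert b.mls == pytest.approx(naive_mls(cp, cq), abs=1e-12)
            assert b.ms_uni == pytest.approx(naive_ms(cp, cq, w_uni), abs=1e-12)
            assert b.ms_st == pytest.approx(naive_ms(cp, cq, w_st), abs=1e-12)
            assert b.cs == pytest.approx(naive_cs(clp, clq), abs=1e-12)
            assert b.ps == pytest.approx(
                naive_ps(ppp, ppq, cq, w_st), abs=1e-12
            )
            expected_fact = (
                0.6 * naive_ms(cp, cq, w_st)
                + 0.2 * naive_cs(clp, clq)
                + 0.2 * naive_ps(ppp, ppq, cq, w_st)
            )
            assert b.fact == pytest.approx(expected_fact, abs=1e-12)


class TestRangeAndMonotonicity:
    def test_all_scores_in_unit_interval(self, random_pair_factory):
        cat = FeatureCatalog({"pfam:PF1": "CLX", "pfam:PF2": "CLX"})
        for seed in range(400):
            p, q, ref = random_pair_factory(seed)
            b = fact_score(p, q, ref, cat)
            for name in ("ms_uni", "ms_st", "cs", "ps", "mls", "fact"):
                assert 0.0 <= b.score(name) <= 1.0 + 1e-12, (seed, name)

    def test_adding_p_only_feature_decreases_mls_only(self, random_pair_factory):
        """A subject-only feature (no clan, unshared) lowers MLS through both
        terms and leaves the shared-feature scores untouched."""
        cat = FeatureCatalog({"pfam:PF1": "CLX", "pfam:PF2": "CLX"})
        checked = 0
        for seed in range(200):
            p, q, ref = random_pair_factory(seed)
            cp, cq = count_profile(p), count_profile(q)
            if not set(cp.counts) & set(cq.counts):
                continue  # strict MLS decrease requires a shared feature
            before = fact_score(p, q, ref, cat)
            grown = FeatureArchitecture(
                p.protein_id,
                p.length,
                p.instances + [FeatureInstance("x:NOVEL", 1, min(10, p.length))],
            )
            after = fact_score(grown, q, ref, cat)
            assert after.mls < before.mls
            assert after.ms_uni == pytest.approx(before.ms_uni, abs=1e-12)
            assert after.ms_st == pytest.approx(before.ms_st, abs=1e-12)
            assert after.cs == pytest.approx(before.cs, abs=1e-12)
            assert after.ps == pytest.approx(before.ps, abs=1e-12)
            checked += 1
        assert checked > 50

    def test_ms_asymmetry_counterexample(self):
        # weights and normalisation follow the query, so swapping roles
        # changes the multiplicity similarity
        p = CountProfile({"A": 1})
        q = CountProfile({"A": 1, "B": 1})
        forward = multiplicity_similarity(p, q, uniform_weights(q))
        backward = multiplicity_similarity(q, p, uniform_weights(p))
        assert forward == pytest.approx(0.5) and backward == pytest.approx(1.0)
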