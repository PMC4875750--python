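import itertools

import numpy as np
import pandas as pd
import pytest

from perilink import (
    ComparisonVector,
    ComparisonVectors,
    EMParams,
    EpiLinkSpec,
    ProbabilityTable,
    em_fit,
    em_score,
    em_score_many,
    epilink_score,
    epilink_score_many,
    fs_score,
    fs_score_many,
    fs_weights,
)
from perilink.presets import BEST_GUESS, DATTANI, epilink_spec_from_table, get_preset
from published_values import PUBLISHED_WEIGHTS, printed_tolerance


class TestFSWeights:
    @pytest.mark.parametrize("preset,field,wm,wnm", PUBLISHED_WEIGHTS)
    def test_reproduces_published_weights(self, preset, field, wm, wnm):
        wt = fs_weights(get_preset(preset))
        assert wt.w_m[field] == pytest.approx(float(wm), abs=printed_tolerance(wm))
        assert wt.w_nm[field] == pytest.approx(float(wnm), abs=printed_tolerance(wnm))

    def test_equal_probabilities_give_zero_weights(self):
        wt = fs_weights(ProbabilityTable(m={"f": 0.95}, u={"f": 0.95}))
        assert wt.w_m["f"] == 0.0
        assert wt.w_nm["f"] == 0.0

    def test_sign_follows_m_vs_u(self):
        wt = fs_weights(ProbabilityTable(m={"a": 0.9, "b": 0.1}, u={"a": 0.1, "b": 0.9}))
        assert wt.w_m["a"] > 0 > wt.w_nm["a"]
        assert wt.w_m["b"] < 0 < wt.w_nm["b"]

    @pytest.mark.parametrize("m,u", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_boundary_probabilities_rejected(self, m, u):
        with pytest.raises(ValueError):
            ProbabilityTable(m={"f": m}, u={"f": u})


class TestFSScore:
    WT = fs_weights(BEST_GUESS)

    def _cv(self, outcomes):
        return ComparisonVector(pair=("c", "e"), outcomes=outcomes)

    def test_all_missing_scores_zero(self):
        cv = self._cv({f: None for f in BEST_GUESS.fields})
        assert fs_score(cv, self.WT).weight == 0.0

    def test_agreements_sum_published_weights(self):
        cv = self._cv({"date_of_birth": 1, "gestational_age": 1, "sex": None})
        assert fs_score(cv, self.WT).weight == pytest.approx(9.483, abs=5e-3)

    def test_mixed_agreement_hand_sum(self):
        cv = self._cv({"date_of_birth": 1, "sex": 0})
        assert fs_score(cv, self.WT).weight == pytest.approx(-0.4404, abs=5e-3)

    def test_additive_and_permutation_invariant(self):
        outcomes = {"date_of_birth": 1, "sex": 0, "birth_weight": 1, "ethnicity": None}
        scores = {
            fs_score(self._cv(dict(perm)), self.WT).weight
            for perm in itertools.permutations(outcomes.items())
        }
        assert len(scores) == 1
        partial = fs_score(self._cv({"date_of_birth": 1, "sex": 0}), self.WT).weight
        rest = fs_score(self._cv({"birth_weight": 1}), self.WT).weight
        assert partial + rest == pytest.approx(scores.pop())

    def test_m_equals_u_field_never_changes_score(self):
        base = {"date_of_birth": 1, "sex": 0}
        with_nb = dict(base, n_babies=1)
        with_nb_dis = dict(base, n_babies=0)
        s0 = fs_score(self._cv(base), self.WT).weight
        assert fs_score(self._cv(with_nb), self.WT).weight == s0
        assert fs_score(self._cv(with_nb_dis), self.WT).weight == s0


def _simulate_vectors(rng, n, fields, m, u, p):
    z = rng.random(n) < p
    k = len(fields)
    agree = np.where(
        z[:, None], rng.random((n, k)) < m, rng.random((n, k)) < u
    ).astype(float)
    return (
        ComparisonVectors(
            pairs=pd.DataFrame({"cohort_id": np.arange(n), "episode_id": np.arange(n)}),
            fields=list(fields),
            matrix=agree,
        ),
        z,
    )


class TestEM:
    FIELDS = [f"f{i}" for i in range(8)]

    def test_separable_limit(self):
        rng = np.random.default_rng(0)
        n = 2000
        z = np.arange(n) < n // 2
        matrix = np.where(z[:, None], 1.0, 0.0) * np.ones((n, len(self.FIELDS)))
        cvs = ComparisonVectors(
            pairs=pd.DataFrame({"cohort_id": np.arange(n), "episode_id": np.arange(n)}),
            fields=self.FIELDS,
            matrix=matrix,
        )
        params = em_fit(cvs, expected_matches=n // 2)
        assert params.converged
        assert params.p == pytest.approx(0.5, abs=1e-3)
        for f in self.FIELDS:
            assert params.m[f] > 0.99
            assert params.u[f] < 0.01

    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        cvs, _ = _simulate_vectors(rng, 20000, self.FIELDS, m=0.9, u=0.1, p=0.05)
        params = em_fit(cvs, expected_matches=1000)
        assert params.converged
        assert params.p == pytest.approx(0.05, abs=0.01)
        for f in self.FIELDS:
            assert params.m[f] == pytest.approx(0.9, abs=0.03)
            assert params.u[f] == pytest.approx(0.1, abs=0.01)

    def test_constant_patterns_do_not_converge(self):
        cvs = ComparisonVectors(
            pairs=pd.DataFrame({"cohort_id": range(50), "episode_id": range(50)}),
            fields=["a", "b"],
            matrix=np.ones((50, 2)),
        )
        params = em_fit(cvs)
        assert not params.converged
        assert "degenerate" in params.message

    def test_unconverged_params_refused_by_scorer(self):
        bad = EMParams(m={"a": 0.5}, u={"a": 0.5}, p=0.1, converged=False, iterations=0)
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": 1})
        with pytest.raises(ValueError, match="not converged"):
            em_score(cv, bad)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        cvs, _ = _simulate_vectors(rng, 3000, self.FIELDS[:5], m=0.85, u=0.15, p=0.1)
        params = em_fit(cvs, expected_matches=300)
        ll = np.array(params.loglik)
        assert (np.diff(ll) >= -1e-6).all()

    def test_em_score_matches_fs_with_same_table(self):
        params = EMParams(
            m=dict(BEST_GUESS.m), u=dict(BEST_GUESS.u), p=0.01, converged=True, iterations=3
        )
        cv = ComparisonVector(
            pair=("c", "e"), outcomes={"date_of_birth": 1, "sex": 0, "birth_weight": None}
        )
        em = em_score(cv, params)
        fs = fs_score(cv, fs_weights(BEST_GUESS))
        assert em.weight == pytest.approx(fs.weight, abs=1e-6)
        assert em.algorithm == "em"

    def test_three_field_hand_computation(self):
        params = EMParams(
            m={"a": 0.8, "b": 0.7, "c": 0.6},
            u={"a": 0.2, "b": 0.1, "c": 0.3},
            p=0.1,
            converged=True,
            iterations=1,
        )
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": 1, "b": 0, "c": None})
        expected = np.log(0.8 / 0.2) + np.log(0.3 / 0.9)
        assert em_score(cv, params).weight == pytest.approx(expected, abs=1e-9)


class TestEpiLink:
    def _spec(self, weights_by_field):
        # invert w = log2((1-e)/f) with e=0: f = 2^-w
        return EpiLinkSpec(
            error_rate={f: 0.0 for f in weights_by_field},
            avg_frequency={f: 2.0 ** -w for f, w in weights_by_field.items()},
        )

    def test_all_agree_scores_one(self):
        spec = self._spec({"a": 2.0, "b": 1.0})
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": 1, "b": 1})
        assert epilink_score(cv, spec).weight == pytest.approx(1.0)

    def test_all_disagree_scores_zero(self):
        spec = self._spec({"a": 2.0, "b": 1.0})
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": 0, "b": 0})
        assert epilink_score(cv, spec).weight == pytest.approx(0.0)

    def test_weighted_two_thirds(self):
        spec = self._spec({"a": 2.0, "b": 1.0})
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": 1, "b": 0})
        assert epilink_score(cv, spec).weight == pytest.approx(2.0 / 3.0)

    def test_all_missing_undefined(self):
        spec = self._spec({"a": 2.0})
        cv = ComparisonVector(pair=("c", "e"), outcomes={"a": None})
        with pytest.raises(ValueError, match="missing"):
            epilink_score(cv, spec)

    def test_invariant_to_weight_rescaling(self):
        outcomes = {"a": 1, "b": 0, "c": 1, "d": None}
        base = {"a": 3.0, "b": 1.5, "c": 0.5, "d": 2.0}
        cv = ComparisonVector(pair=("c", "e"), outcomes=outcomes)
        s1 = epilink_score(cv, self._spec(base)).weight
        s2 = epilink_score(cv, self._spec({f: 7.3 * w for f, w in base.items()})).weight
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_scores_bounded_and_bulk_matches_scalar(self, small_linked):
        from perilink.comparison import all_pairs, compare_pairs, default_specs

        cohort, episodes = small_linked.cohort, small_linked.episodes
        fields = [f for f in BEST_GUESS.fields if f in cohort.df.columns]
        cvs = compare_pairs(cohort, episodes, all_pairs(cohort, episodes), default_specs(fields))
        spec = epilink_spec_from_table(BEST_GUESS)
        bulk = epilink_score_many(cvs, spec)
        assert ((bulk["weight"] >= 0) & (bulk["weight"] <= 1)).all()
        lookup = bulk.set_index(["cohort_id", "episode_id"])["weight"]
        for cv in itertools.islice(iter(cvs), 25):
            assert epilink_score(cv, spec).weight == pytest.approx(lookup[cv.pair], abs=1e-9)


def test_threshold_nesting_property(small_linked):
    """Pairs above a higher cutoff are a subset of those above a lower one."""
    from perilink.comparison import all_pairs, compare_pairs, default_specs

    cohort, episodes = small_linked.cohort, small_linked.episodes
    fields = [f for f in BEST_GUESS.fields if f in cohort.df.columns]
    cvs = compare_pairs(cohort, episodes, all_pairs(cohort, episodes), default_specs(fields))
    scored = fs_score_many(cvs, fs_weights(BEST_GUESS))
    hi = set(map(tuple, scored[scored["weight"] > 15][["cohort_id", "episode_id"]].values))
    lo = set(map(tuple, scored[scored["weight"] > 5][["cohort_id", "episode_id"]].values))
    assert hi <= lo
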