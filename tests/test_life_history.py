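"""Leslie-matrix construction, fecundity back-calculation, eigen-analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvasim import (
    HYPOTHETICAL,
    T_LAMPROIDES,
    InfeasibleFecundityError,
    LifeHistorySpec,
    back_calculate_fecundity,
    build_leslie,
    cumulative_survivorship,
    dominant_eigenvalue,
    generation_time,
    get_preset,
    stable_age_distribution,
)

from conftest import PRINTED_FECUNDITIES, STUDY_COMBOS


class TestBuildLeslie:
    def test_structure_hypothetical(self):
        m = build_leslie(HYPOTHETICAL, 0.5)
        assert m.shape == (10, 10)
        assert np.all(m[0] == 0.5)
        assert np.all(np.diag(m, -1) == 0.5)
        assert m[9, 9] == 0.5
        # everything off the top row, sub-diagonal, and corner is zero
        mask = np.zeros_like(m, dtype=bool)
        mask[0] = True
        mask[np.arange(1, 10), np.arange(9)] = True
        mask[9, 9] = True
        assert np.all(m[~mask] == 0.0)

    def test_structure_snail(self):
        m = build_leslie(T_LAMPROIDES, 0.4630)
        assert np.all(m[0] == 0.4630)
        assert np.allclose(np.diag(m, -1), [0.4, 0.5, 0.8, 0.75])
        assert m[4, 4] == 0.7

    def test_zero_fecundity_reduces_to_survival_chain(self):
        m = build_leslie(T_LAMPROIDES, 0.0)
        assert np.all(m[0] == 0.0)
        # survival-only chain: spectral radius is the self-loop survival
        assert dominant_eigenvalue(m) == pytest.approx(0.7, abs=1e-10)

    def test_negative_fecundity_rejected(self):
        with pytest.raises(ValueError):
            build_leslie(HYPOTHETICAL, -0.1)


class TestBackCalculateFecundity:
    @pytest.mark.parametrize("spec,lam", STUDY_COMBOS, ids=lambda v: getattr(v, 'name', str(v)))
    def test_reproduces_printed_fecundities(self, spec, lam):
        f = back_calculate_fecundity(spec, lam)
        assert f == pytest.approx(PRINTED_FECUNDITIES[(spec.name, lam)], abs=5e-5)

    @pytest.mark.parametrize("spec,lam", STUDY_COMBOS, ids=lambda v: getattr(v, 'name', str(v)))
    def test_round_trip(self, spec, lam):
        f = back_calculate_fecundity(spec, lam)
        assert dominant_eigenvalue(build_leslie(spec, f)) == pytest.approx(
            lam, abs=1e-8
        )

    @given(lam=st.floats(0.9, 1.025))
    @settings(max_examples=25, deadline=None)
    def test_hypothetical_closed_form(self, lam):
        # equal survivals s with self-loop s collapse the renewal equation to a
        # geometric series, giving f = lambda - s exactly
        assert back_calculate_fecundity(HYPOTHETICAL, lam) == pytest.approx(
            lam - 0.5, abs=1e-10
        )

    def test_infeasible_target_raises(self):
        # below the fecundity-free spectral radius (snail self-loop 0.7)
        with pytest.raises(InfeasibleFecundityError):
            back_calculate_fecundity(T_LAMPROIDES, 0.65)

    @given(
        survival=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=8),
        lam=st.floats(0.9, 1.3),
    )
    @settings(max_examples=30, deadline=None)
    def test_round_trip_random_life_histories(self, survival, lam):
        spec = LifeHistorySpec(name="rand", survival=tuple(survival))
        if lam <= spec.composite_survival:
            return
        f = back_calculate_fecundity(spec, lam)
        assert f >= 0
        assert dominant_eigenvalue(build_leslie(spec, f)) == pytest.approx(
            lam, abs=1e-8
        )


class TestEigenAnalysis:
    def test_dominant_eigenvalue_printed_examples(self):
        assert dominant_eigenvalue(build_leslie(HYPOTHETICAL, 0.45)) == pytest.approx(
            0.95, abs=1e-8
        )
        assert dominant_eigenvalue(build_leslie(T_LAMPROIDES, 0.4947)) == pytest.approx(
            1.025, abs=5e-5
        )

    def test_single_class_matrix(self):
        assert dominant_eigenvalue(np.array([[0.7]])) == pytest.approx(0.7)

    @pytest.mark.parametrize("spec,lam", STUDY_COMBOS, ids=lambda v: getattr(v, 'name', str(v)))
    def test_stable_age_distribution_is_eigenvector(self, spec, lam):
        m = build_leslie(spec, back_calculate_fecundity(spec, lam))
        v = stable_age_distribution(m)
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        # one projection step multiplies every class by lambda
        assert np.allclose(m @ v, lam * v, rtol=1e-8)

    def test_stable_age_hand_derivation_hypothetical(self):
        # lambda = 1, s = 0.5: class k proportional to 0.5^(k-1) for k <= 9;
        # the composite class solves n10 = s n9 / (lambda - s) = n9
        v = stable_age_distribution(build_leslie(HYPOTHETICAL, 0.5))
        expected = np.array([0.5**k for k in range(9)] + [0.5**8])
        assert np.allclose(v, expected / expected.sum(), rtol=1e-8)

    def test_stable_age_matches_power_iteration(self):
        m = build_leslie(T_LAMPROIDES, back_calculate_fecundity(T_LAMPROIDES, 0.9))
        w = np.ones(5) / 5
        for _ in range(2000):
            w = m @ w
            w /= w.sum()
        assert np.allclose(stable_age_distribution(m), w, atol=1e-10)


class TestGenerationTime:
    @pytest.mark.parametrize("spec,lam", STUDY_COMBOS, ids=lambda v: getattr(v, 'name', str(v)))
    def test_three_generations_under_ten_years(self, spec, lam):
        m = build_leslie(spec, back_calculate_fecundity(spec, lam))
        assert 3 * generation_time(m) < 10.0

    def test_matches_direct_summation_oracle(self):
        # truncated direct sum of x f l_x / sum f l_x with the composite
        # class expanded year by year
        for spec, lam in [(HYPOTHETICAL, 1.0), (T_LAMPROIDES, 0.9)]:
            f = back_calculate_fecundity(spec, lam)
            m = build_leslie(spec, f)
            s = np.asarray(spec.survival)
            lx, num, den = 1.0, 0.0, 0.0
            for x in range(1, 600):
                num += x * f * lx
                den += f * lx
                lx *= s[min(x - 1, len(s) - 1)]
            assert generation_time(m) == pytest.approx(num / den, rel=1e-10)

    def test_hypothetical_closed_form(self):
        # l_x = 0.5^(x-1) for all x: T = sum x 2^-x / sum 2^-x = 2
        m = build_leslie(HYPOTHETICAL, 0.5)
        assert generation_time(m) == pytest.approx(2.0, rel=1e-12)

    def test_discounted_variant_uses_growth_rate(self):
        m = build_leslie(HYPOTHETICAL, 0.4)  # lambda = 0.9
        t_cohort = generation_time(m)
        t_disc = generation_time(m, discounted=True)
        assert t_disc > t_cohort  # lambda < 1 upweights older mothers


def test_cumulative_survivorship_rounds_to_printed_value():
    # ten consecutive annual survivals of 0.5
    p10 = cumulative_survivorship(HYPOTHETICAL, 10)
    assert p10 == pytest.approx(0.5**10)
    assert round(p10, 3) == 0.001


def test_preset_lookup():
    assert get_preset("hypothetical") is HYPOTHETICAL
    assert get_preset("t_lamproides").pe_cv_grid[-1] == 0.45
    with pytest.raises(KeyError):
        get_preset("wolpertinger")


def test_spec_validation():
    with pytest.raises(ValueError):
        LifeHistorySpec(name="bad", survival=(0.5,))
    with pytest.raises(ValueError):
        LifeHistorySpec(name="bad", survival=(0.5, 1.2))
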