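"""KL divergence, dot categories and canonical-fraction grid estimation."""

import math

import numpy as np
import pytest

from teloend import (
    CANONICAL_LABEL,
    PERMUTATION_LABELS,
    CanonicalMixtureModel,
    dot_category,
    estimate_canonical_fraction,
    kl_divergence,
    mixture_distribution,
)
from teloend.ends import EndMotifDistribution


def hand_kl_bits(p_vec, q_vec, epsilon):
    """Independent direct evaluation of sum p log2(p/q) with pseudocounts."""
    p = [v + epsilon for v in p_vec]
    q = [v + epsilon for v in q_vec]
    p = [v / sum(p) for v in p]
    q = [v / sum(q) for v in q]
    return sum(pi * math.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0)


class TestKlDivergence:
    def test_identity_is_zero(self, rng):
        counts = {l: float(c) for l, c in zip(PERMUTATION_LABELS, rng.integers(1, 100, 6))}
        dist = EndMotifDistribution(dict(counts))
        assert kl_divergence(dist, dist) == pytest.approx(0.0, abs=1e-6)

    def test_point_vs_uniform_approaches_log2_six(self):
        point = mixture_distribution(1.0)
        uniform = mixture_distribution(0.0)
        d = kl_divergence(point, uniform, epsilon=1e-12)
        assert d == pytest.approx(math.log2(6), abs=1e-6)

    def test_uniform_vs_point_dominated_by_empty_cells(self):
        """Hand-computed oracle: five reference cells hold only the 1e-9
        pseudocount, so the divergence blows past 10 bits."""
        uniform = mixture_distribution(0.0)
        point = mixture_distribution(1.0)
        d = kl_divergence(uniform, point, epsilon=1e-9)
        expected = hand_kl_bits([1 / 6] * 6, [1, 0, 0, 0, 0, 0], 1e-9)
        assert d == pytest.approx(expected, rel=1e-9)
        assert d > 10.0

    def test_other_category_dropped_and_renormalized(self):
        with_other = EndMotifDistribution(
            {CANONICAL_LABEL: 50.0, "CAATCC": 50.0, "OTHER": 900.0}
        )
        without = EndMotifDistribution({CANONICAL_LABEL: 5.0, "CAATCC": 5.0})
        assert kl_divergence(with_other, without) == pytest.approx(0.0, abs=1e-6)

    def test_zero_total_errors(self):
        ok = mixture_distribution(0.5)
        with pytest.raises(ValueError):
            kl_divergence({l: 0.0 for l in PERMUTATION_LABELS}, ok)

    def test_asymmetry_and_nonnegativity(self, rng):
        a = mixture_distribution(0.9)
        b = mixture_distribution(0.2)
        assert kl_divergence(a, b) >= 0
        assert kl_divergence(a, b) != pytest.approx(kl_divergence(b, a))


class TestDotCategory:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.10, "ns"),
            (0.30, "●●"),
            (0.40, "●●●"),
            (0.125, "●"),  # boundary goes to the higher category
            (0.25, "●●"),
            (0.375, "●●●"),
            (0.0, "ns"),
        ],
    )
    def test_banding(self, value, expected):
        assert dot_category(value) == expected

    def test_negative_divergence_errors(self):
        with pytest.raises(ValueError):
            dot_category(-0.01)


class TestMixtureDistribution:
    def test_pure_canonical(self):
        freqs = mixture_distribution(1.0).frequencies
        assert freqs[CANONICAL_LABEL] == 1.0

    def test_fully_randomized_is_uniform(self):
        freqs = mixture_distribution(0.0).frequencies
        for label in PERMUTATION_LABELS:
            assert freqs[label] == pytest.approx(1 / 6)

    def test_partial_mixture_arithmetic(self):
        freqs = mixture_distribution(0.7).frequencies
        assert freqs[CANONICAL_LABEL] == pytest.approx(0.75)
        for label in PERMUTATION_LABELS:
            if label != CANONICAL_LABEL:
                assert freqs[label] == pytest.approx(0.05)

    def test_out_of_range_errors(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                mixture_distribution(bad)


class TestEstimateCanonicalFraction:
    def test_exact_recovery_on_every_grid_point(self):
        """Noiseless mixtures recover their generating p across the grid."""
        for p in np.round(np.arange(0.0, 1.001, 0.01), 2):
            estimate = estimate_canonical_fraction(mixture_distribution(float(p)))
            assert estimate.p_hat == pytest.approx(float(p), abs=1e-9)
            assert estimate.kl_at_min == pytest.approx(0.0, abs=1e-6)

    def test_point_mass_gives_one(self, make_read):
        from teloend import end_distribution

        dist = end_distribution([make_read("CTAACC" * 5)] * 200)
        assert estimate_canonical_fraction(dist).p_hat == 1.0

    def test_monotone_randomization(self):
        """Divergence of mixture(p) from the pure-canonical reference strictly
        decreases as p rises toward 1."""
        reference = mixture_distribution(1.0)
        values = [
            kl_divergence(mixture_distribution(p), reference)
            for p in np.arange(0.0, 1.0, 0.05)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_profile_covers_the_grid(self):
        estimate = estimate_canonical_fraction(mixture_distribution(0.45))
        assert len(estimate.profile) == 101
        assert estimate.kl_at_min == min(estimate.profile.values())
        assert estimate.profile[estimate.p_hat] == estimate.kl_at_min


class TestCanonicalMixtureModel:
    def test_fit_matches_function_and_summary_prints(self, rng):
        counts = {
            label: float(c)
            for label, c in zip(
                PERMUTATION_LABELS, rng.multinomial(5000, [0.75] + [0.05] * 5)
            )
        }
        dist = EndMotifDistribution(counts)
        results = CanonicalMixtureModel(dist).fit(n_boot=25, seed=11)
        assert results.p_hat == estimate_canonical_fraction(dist).p_hat
        assert abs(results.p_hat - 0.70) <= 0.05
        assert results.se_p is not None and results.se_p < 0.05
        lo, hi = results.conf_int
        assert lo <= results.p_hat <= hi
        text = results.summary()
        assert "p_hat" in text and "KL" in text
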