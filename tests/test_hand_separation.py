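"""Second-peak distances, separation flags, symptom load and C-L stats."""

import numpy as np
import pytest

from tremorindex.distribution_stats import BinnedPDF
from tremorindex.errors import (
    DegenerateDistributionError,
    EmptyDataError,
    ValidationError,
)
from tremorindex.hand_separation import (
    ClinicalScores,
    associate,
    hand_distance,
    second_peak_bin,
    separate_hands,
    separated_count,
    symptom_load,
)


def pdf(probabilities, centers=None):
    p = np.asarray(probabilities, dtype=float)
    c = np.asarray(centers if centers is not None else
                   2 * np.arange(len(p)) + 1, dtype=float)
    w = np.diff(c).mean() if len(c) > 1 else 1.0
    return BinnedPDF(edges=np.concatenate([[c[0] - w / 2], c + w / 2]),
                     centers=c, probabilities=p, n=100)


class TestSecondPeak:
    def test_plain_second_largest(self):
        assert second_peak_bin(pdf([0.6, 0.3, 0.1], [1, 3, 5])) == 3

    def test_tie_breaks_to_lower_ti(self):
        assert second_peak_bin(pdf([0.3, 0.3, 0.4], [1, 3, 5])) == 1

    def test_single_occupied_bin_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            second_peak_bin(pdf([1.0, 0.0, 0.0]))


class TestHandDistance:
    def test_decade_apart_gives_one(self):
        d, bt, bnt = hand_distance(
            pdf([0.6, 0.4], [5, 10]), pdf([0.6, 0.4], [0.5, 1.0])
        )
        assert d == pytest.approx(1.0)
        assert (bt, bnt) == (10, 1.0)

    def test_identical_pdfs_give_zero(self):
        a = pdf([0.5, 0.3, 0.2])
        assert hand_distance(a, a)[0] == 0.0

    def test_antisymmetry(self):
        a, b = pdf([0.6, 0.4], [5, 10]), pdf([0.7, 0.3], [1, 2])
        assert hand_distance(a, b)[0] == pytest.approx(-hand_distance(b, a)[0])


class TestSeparatedCount:
    def test_no_distance_no_count(self):
        dists = {f: (0.0, 5.0, 5.0) for f in range(3, 13)}
        res = separated_count(dists, {f: 100.0 for f in range(3, 13)})
        assert res.C == 0

    def test_boundary_counts_as_separated(self):
        dists = {5: (1.0, 40.0, 10.0)}
        res = separated_count(dists, {5: 100.0})  # 30 >= 0.3*100 exactly
        assert res.c_f[5] == 1 and res.C == 1

    def test_below_threshold_not_separated(self):
        res = separated_count({5: (1.0, 39.0, 10.0)}, {5: 100.0})
        assert res.C == 0

    def test_literal_rule_uses_log_distance(self):
        dists = {5: (2.0, 40.0, 0.4)}
        linear = separated_count(dists, {5: 1000.0}, rule="linear")
        literal = separated_count(dists, {5: 1000.0}, rule="literal")
        assert linear.C == 0  # 39.6 < 300
        assert literal.C == 0  # 2.0 < 300
        tiny_max = separated_count(dists, {5: 5.0}, rule="literal")
        assert tiny_max.C == 1  # 2.0 >= 1.5
        assert "literal" in tiny_max.threshold_rule

    def test_missing_frequency_excluded_with_warning(self):
        dists = {5: (1.0, 40.0, 10.0), 6: None}
        with pytest.warns(UserWarning, match="f=6"):
            res = separated_count(dists, {5: 100.0, 6: 100.0})
        assert res.skipped == [6]
        assert 6 not in res.c_f

    def test_invariant_under_beta_rescaling(self, rng):
        """TI units cancel: scaling all values scales bins and threshold."""
        ti_t = {5: np.concatenate([rng.uniform(0, 1, 80),
                                   rng.uniform(50, 60, 20)])}
        ti_nt = {5: rng.uniform(0, 1, 100)}
        base = separate_hands(ti_t, ti_nt)
        scaled = separate_hands({5: 7.5 * ti_t[5]}, {5: 7.5 * ti_nt[5]})
        assert base.c_f == scaled.c_f


class TestSymptomLoad:
    def test_direct_formula(self):
        assert symptom_load(ClinicalScores(postural=1, kinetic=0, rest=2)) == 6

    def test_extremes(self):
        assert symptom_load(ClinicalScores()) == 0
        assert symptom_load(ClinicalScores(4, 4, 4)) == 36

    def test_intensity_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ClinicalScores(postural=5)
        with pytest.raises(ValidationError):
            ClinicalScores(rest=-1)


class TestAssociate:
    def test_identical_after_normalization(self):
        c = [0, 5, 10]
        l = [0, 18, 36]  # l * 10/36 == c * 10/10
        res = associate(c, l, freq_count=10)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert res.ci95[0] <= 0 <= res.ci95[1]
        assert res.ttest_p == pytest.approx(1.0)

    def test_anti_ordered_negative(self):
        res = associate([0, 5, 10], [36, 18, 0])
        assert res.pearson_r < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(EmptyDataError):
            associate([3, 3, 3], [0, 18, 36])

    def test_participant_relabelling_invariance(self, rng):
        c = [1, 4, 7, 9]
        l = [2, 10, 20, 30]
        perm = [2, 0, 3, 1]
        a = associate(c, l)
        b = associate([c[i] for i in perm], [l[i] for i in perm])
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.mean_diff == pytest.approx(b.mean_diff)
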