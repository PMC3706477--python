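"""Seed-site scanning, MRE windows, conservation profiles, Wilcoxon test."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirscreen import mre_conservation as mre
from mirscreen.errors import ConfigError, InputError

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"


class TestSeedComplement:
    def test_full_eight_nt_seed(self):
        # seed 1-8 = UAGCUUAU -> site = reverse complement ATAAGCTA
        assert mre.seed_complement(MIR21) == "ATAAGCTA"

    def test_seven_nt_seed_variant(self):
        assert mre.seed_complement(MIR21, seed_span=(2, 8)) == "ATAAGCT"

    def test_palindromic_seed_is_own_reverse_complement(self):
        pal = "GGATATCC"  # reverse complement of GGATATCC is itself
        assert mre.seed_complement(pal + "A" * 14) == pal

    def test_short_mirna_rejected(self):
        with pytest.raises(InputError):
            mre.seed_complement("UAGCUUA")

    def test_illegal_characters_rejected(self):
        with pytest.raises(InputError):
            mre.seed_complement("UAGCNUAU" + "A" * 14)


class TestSeedSiteScan:
    def test_utr_equal_to_motif(self):
        assert mre.seed_site_scan("ATAAGCTA", "ATAAGCTA") == [(0, 8)]

    def test_absent_motif(self):
        assert mre.seed_site_scan("CCCCCCCCCC", "ATAAGCTA") == []

    def test_overlapping_occurrences_kept(self):
        assert mre.seed_site_scan("A" * 7, "A" * 6) == [(0, 6), (1, 7)]

    def test_short_motif_rejected(self):
        with pytest.raises(InputError):
            mre.seed_site_scan("ACGTACGT", "ACGTA")

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        utr = "".join(rng.choice(list("ACGT"), size=60))
        motif = "".join(rng.choice(list("ACG"), size=6))  # 3-letter: more matches
        expected = [
            (i, i + len(motif))
            for i in range(len(utr) - len(motif) + 1)
            if utr[i : i + len(motif)] == motif
        ]
        assert mre.seed_site_scan(utr, motif) == expected


class TestExtractWindow:
    def test_default_flanks_give_42_nt_window(self):
        utr = "A" * 60
        w = mre.extract_window(utr, (10, 18))
        assert (w.window_start, w.window_end) == (0, 42)
        assert len(w.sequence) == 42

    def test_boundary_violation_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            w = mre.extract_window("A" * 60, (5, 13))
        assert w is None
        assert "dropped" in caplog.text

    def test_zero_flanks_reduce_to_site(self):
        w = mre.extract_window("ACGTACGTACGT", (2, 10), flank5=0, flank3=0)
        assert (w.window_start, w.window_end) == (2, 10)
        assert w.sequence == "GTACGTAC"

    def test_position_labels_site_relative(self):
        utr = "A" * 60
        scores = np.zeros(60)
        w = mre.extract_window(utr, (10, 18), scores=scores)
        labels = w.position_labels
        assert labels[0] == -9  # first 5'-flank base
        assert labels[10] == 1  # site start
        assert labels[-1] == 32  # last 3'-flank base


class TestWindowScores:
    def _window(self, scores):
        n = len(scores)
        return mre.MREWindow("g", "m", 10, 18, 0, n, "A" * n, np.asarray(scores, float))

    def test_flat_track(self):
        assert mre.window_mean_score(self._window([0.5] * 42)) == pytest.approx(0.5)

    def test_half_low_half_high(self):
        assert mre.window_mean_score(self._window([0.2] * 21 + [0.8] * 21)) == pytest.approx(0.5)

    def test_missing_scores_drop_window(self, caplog):
        scores = [0.5] * 42
        scores[3] = np.nan
        with caplog.at_level("WARNING"):
            assert mre.window_mean_score(self._window(scores)) is None

    def test_profile_of_single_window_is_its_scores(self):
        w = self._window(np.linspace(0, 1, 42))
        labels, profile = mre.positional_profile([w])
        assert np.allclose(profile, w.scores)
        assert labels[10] == 1

    def test_profile_conserves_mass(self, rng):
        windows = [self._window(rng.uniform(0, 1, size=42)) for _ in range(25)]
        _, profile = mre.positional_profile(windows)
        window_means = [mre.window_mean_score(w) for w in windows]
        assert profile.mean() == pytest.approx(np.mean(window_means))

    def test_mixed_lengths_rejected(self):
        with pytest.raises(InputError):
            mre.positional_profile([self._window([0.5] * 42), self._window([0.5] * 41)])


class TestWilcoxon:
    def test_identical_multisets(self):
        w, p = mre.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_separated_triplets(self):
        # all A-ranks minimal: only 2 of C(6,3)=20 splits are as extreme
        _, p = mre.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], method="exact")
        assert p == pytest.approx(0.1)

    def test_extreme_shift_gives_extreme_w(self):
        a = [1.0, 2.0, 3.0]
        w_lo, _ = mre.wilcoxon_rank_sum(a, [10.0, 11.0, 12.0])
        assert w_lo == 1 + 2 + 3  # minimal possible rank sum for A

    @given(st.integers(min_value=0, max_value=200))
    def test_edgeworth_tracks_exact_for_small_groups(self, seed):
        """The Edgeworth-refined approximation stays within 0.02 of exact
        enumeration for tie-free groups of 3-6 (the 0.0195 worst case sits
        at 3+3 where the exact p has only five atoms), and within 0.01 once
        both groups reach 5."""
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(3, 7))
        n_b = int(rng.integers(3, 7))
        a = rng.normal(size=n_a)
        b = rng.normal(loc=0.8, size=n_b)
        _, p_exact = mre.wilcoxon_rank_sum(a, b, method="exact")
        _, p_edge = mre.wilcoxon_rank_sum(a, b, method="edgeworth")
        assert abs(p_exact - p_edge) <= 0.02
        if min(n_a, n_b) >= 5:
            assert abs(p_exact - p_edge) <= 0.01

    def test_calibration_sweep_small_sizes(self):
        """Exhaustive tie-free sweep over every achievable rank split for
        group sizes 3..6: the Edgeworth route's worst-case error against
        exact enumeration is 0.0195 (at 3+3, whose exact p has only five
        atoms) and at most half the plain cc-normal's (0.0375)."""
        worst_edge = worst_norm = 0.0
        for n_a in range(3, 7):
            for n_b in range(n_a, 7):
                vals = np.arange(n_a + n_b, dtype=float)
                seen = set()
                for combo in itertools.combinations(range(n_a + n_b), n_a):
                    if sum(combo) in seen:
                        continue
                    seen.add(sum(combo))
                    a = vals[list(combo)]
                    b = np.delete(vals, list(combo))
                    _, p_exact = mre.wilcoxon_rank_sum(a, b, method="exact")
                    _, p_edge = mre.wilcoxon_rank_sum(a, b, method="edgeworth")
                    _, p_norm = mre.wilcoxon_rank_sum(a, b, method="normal")
                    worst_edge = max(worst_edge, abs(p_edge - p_exact))
                    worst_norm = max(worst_norm, abs(p_norm - p_exact))
        assert worst_edge == pytest.approx(0.0195, abs=5e-4)
        assert worst_norm == pytest.approx(0.0375, abs=5e-4)
        assert worst_edge <= worst_norm / 1.9

    def test_edgeworth_beats_plain_normal_at_separation(self):
        # exact p = 0.1; plain cc-normal 0.081, Edgeworth 0.0805 -> both
        # below, but over the full support the Edgeworth max error is half
        # the plain normal's; spot-check a central point where it matters
        a = [1.0, 2.0, 4.0]
        b = [3.0, 5.0, 6.0]
        _, p_exact = mre.wilcoxon_rank_sum(a, b, method="exact")
        _, p_edge = mre.wilcoxon_rank_sum(a, b, method="edgeworth")
        _, p_norm = mre.wilcoxon_rank_sum(a, b, method="normal")
        assert abs(p_edge - p_exact) <= abs(p_norm - p_exact) + 1e-12

    @given(st.integers(min_value=0, max_value=100))
    def test_normal_route_matches_scipy(self, seed):
        """Independent cross-check of the large-sample route against
        scipy's Mann-Whitney asymptotic p (same tie correction and
        continuity correction)."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=15)
        b = rng.normal(loc=0.4, size=18)
        _, p_norm = mre.wilcoxon_rank_sum(a, b, method="normal")
        p_scipy = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert p_norm == pytest.approx(p_scipy, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mre.wilcoxon_rank_sum([], [1.0])

    def test_boosted_group_detected(self, rng):
        base = rng.uniform(0.2, 0.6, size=40)
        boosted = rng.uniform(0.2, 0.6, size=25) + 0.3
        _, p = mre.wilcoxon_rank_sum(boosted, base)
        assert p < 0.05


class TestAssignGroups:
    def _hits(self, **kw):
        import pandas as pd

        defaults = dict(mirna_id=["m1"], reporter_id=["g1"], positive=[False],
                        ssmd=[0.0])
        defaults.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(defaults)

    @pytest.mark.parametrize(
        "ssmd,expected", [(-3.2, "positive"), (-3.0, "positive"), (-2.5, "negative")]
    )
    def test_ssmd3_mode_threshold(self, ssmd, expected):
        groups = mre.assign_groups(self._hits(ssmd=ssmd), mode="ssmd3")
        assert groups[("m1", "g1")] == expected

    def test_pvalue_mode_uses_positive_flag(self):
        groups = mre.assign_groups(self._hits(positive=True), mode="pvalue")
        assert groups[("m1", "g1")] == "positive"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            mre.assign_groups(self._hits(), mode="bonferroni")
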