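"""Synthetic screen generator: construction guarantees and recoverability."""

import numpy as np
import pandas as pd
import pytest

from mirscreen import mre_conservation as mre
from mirscreen import pipeline, synthetic_data as syn
from mirscreen.errors import ConfigError, InputError

MIRNAS = [
    "UAGCUUAUCAGACUGAUGUUGA",
    "UGAGGUAGUAGGUUGUAUAGUU",
    "AAAGUGCUUACAGUGCAGGUAG",
]


class TestGenScreen:
    def test_fixed_seed_is_byte_identical(self):
        cfg = syn.ScreenSimConfig(n_mirnas=40, rng_seed=1)
        w1, t1 = syn.gen_screen(cfg)
        w2, t2 = syn.gen_screen(cfg)
        assert w1.to_csv(index=False) == w2.to_csv(index=False)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_hit_count_is_exact_by_construction(self):
        cfg = syn.ScreenSimConfig(
            n_mirnas=100, hit_fraction=0.1, effect_fold=0.5, noise_cv=0.1, rng_seed=1
        )
        _, truth = syn.gen_screen(cfg)
        assert int(truth["is_hit"].sum()) == 10

    def test_noise_free_null_normalizes_to_exactly_one(self):
        cfg = syn.ScreenSimConfig(n_mirnas=20, hit_fraction=0.0, noise_cv=0.0)
        wells, _ = syn.gen_screen(cfg)
        from mirscreen.screen_core import normalize_screen

        out = normalize_screen(wells)
        assert (out["normalized_ratio"] == 1.0).all()

    def test_every_plate_carries_its_controls(self):
        cfg = syn.ScreenSimConfig(n_mirnas=100, controls_per_plate=6, rng_seed=2)
        wells, _ = syn.gen_screen(cfg)
        per_plate = wells[wells["role"] == "control"].groupby("plate_id").size()
        assert (per_plate == 6).all()
        assert per_plate.index.equals(pd.Index(sorted(wells["plate_id"].unique())))

    def test_each_interaction_has_exact_replicates(self):
        cfg = syn.ScreenSimConfig(n_mirnas=33, replicates_per_interaction=3, rng_seed=3)
        wells, truth = syn.gen_screen(cfg)
        counts = wells[wells["role"] == "test"].groupby(["mirna_id", "reporter_id"]).size()
        assert (counts == 3).all()
        assert len(counts) == len(truth)

    def test_truth_invariant_hit_iff_effect_below_one(self):
        _, truth = syn.gen_screen(syn.ScreenSimConfig(n_mirnas=60, rng_seed=4))
        assert (truth["is_hit"] == (truth["true_effect"] < 1.0)).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hit_fraction": 1.5},
            {"effect_fold": 0.0},
            {"noise_cv": -0.1},
            {"controls_per_plate": 1},
            {"wells_per_plate": 4, "controls_per_plate": 3},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            syn.ScreenSimConfig(**kwargs)

    def test_parameter_recovery_on_design_conditions(self):
        """A screen at the design conditions (200 interactions, 10% hits at
        0.5-fold, CV 0.1, triplicates) is recoverable: t-test sensitivity
        >= 0.9 and SSMD <= -2 marks >= 80% of true hits."""
        cfg = syn.ScreenSimConfig(
            n_mirnas=200, n_reporters=1, hit_fraction=0.1, effect_fold=0.5,
            noise_cv=0.1, rng_seed=11,
        )
        wells, truth = syn.gen_screen(cfg)
        _, hits = pipeline.analyze_screen(wells)
        merged = hits.merge(truth, on=["mirna_id", "reporter_id"])
        true_hits = merged[merged["is_hit"]]
        assert len(true_hits) == 20
        assert true_hits["positive"].mean() >= 0.9
        assert (true_hits["ssmd"] <= -2).mean() >= 0.8


class TestGenSequences:
    def test_embedded_site_is_found_by_scan(self):
        mirnas, utrs, truth = syn.gen_sequences(
            n_utrs=1, utr_length=120, mirnas=[MIRNAS[0]], sites_per_positive=1,
            rng_seed=5,
        )
        assert len(truth) == 1
        row = truth.iloc[0]
        motif = mre.seed_complement(mirnas[row["mirna_id"]])
        sites = mre.seed_site_scan(utrs[row["utr_id"]], motif)
        assert (row["site_start"], row["site_end"]) in sites

    def test_recorded_coordinates_carry_the_exact_motif(self):
        mirnas, utrs, truth = syn.gen_sequences(
            n_utrs=8, utr_length=200, mirnas=MIRNAS, sites_per_positive=2, rng_seed=6
        )
        for row in truth.itertuples(index=False):
            motif = mre.seed_complement(mirnas[row.mirna_id])
            assert utrs[row.utr_id][row.site_start : row.site_end] == motif

    def test_zero_sites_gives_empty_truth(self):
        _, _, truth = syn.gen_sequences(
            n_utrs=4, utr_length=100, mirnas=MIRNAS, sites_per_positive=0, rng_seed=7
        )
        assert truth.empty

    def test_fixed_seed_reproduces_sequences(self):
        a = syn.gen_sequences(6, 150, MIRNAS, rng_seed=8)
        b = syn.gen_sequences(6, 150, MIRNAS, rng_seed=8)
        assert a[1] == b[1]
        assert a[0] == b[0]

    def test_short_mirna_rejected(self):
        with pytest.raises(InputError):
            syn.gen_sequences(2, 100, ["ACGUACG"], rng_seed=0)


class TestGenConservationTrack:
    def test_zero_boost_is_flat_baseline(self):
        _, utrs, truth = syn.gen_sequences(4, 100, MIRNAS, rng_seed=9)
        tracks = syn.gen_conservation_track(
            utrs, truth, base_level=0.1, site_boost=0.0, rng_seed=9
        )
        all_scores = np.concatenate(list(tracks.values()))
        assert all_scores.mean() == pytest.approx(0.1, abs=0.01)
        assert all_scores.std() < 0.05

    def test_peak_positions_reach_boosted_level(self):
        """Monte-Carlo averaging oracle: scores at seed-peak positions of
        true sites average base + boost."""
        _, utrs, truth = syn.gen_sequences(
            40, 150, MIRNAS, sites_per_positive=1, rng_seed=10
        )
        tracks = syn.gen_conservation_track(
            utrs, truth, base_level=0.1, site_boost=0.5, rng_seed=10
        )
        peak_scores, off_scores = [], []
        for row in truth.itertuples(index=False):
            track = tracks[row.utr_id]
            # seed-peak labels 2-8 -> UTR offsets site_start+1 .. site_start+7
            peak_scores.extend(track[row.site_start + 1 : row.site_start + 8])
            off_scores.extend(track[: max(row.site_start - 15, 0)])
        assert np.mean(peak_scores) == pytest.approx(0.6, abs=0.02)
        assert np.mean(off_scores) == pytest.approx(0.1, abs=0.02)

    def test_empty_site_table_is_noisy_baseline(self):
        utrs = {"u1": "ACGT" * 30}
        tracks = syn.gen_conservation_track(
            utrs, pd.DataFrame(columns=["utr_id", "mirna_id", "site_start", "site_end"]),
            base_level=0.3, site_boost=0.4, rng_seed=11,
        )
        assert tracks["u1"].mean() == pytest.approx(0.3, abs=0.02)

    def test_out_of_range_levels_rejected(self):
        with pytest.raises(ConfigError):
            syn.gen_conservation_track({}, pd.DataFrame(), base_level=0.6, site_boost=0.5)

    def test_scores_stay_in_unit_interval(self):
        _, utrs, truth = syn.gen_sequences(10, 120, MIRNAS, rng_seed=12)
        tracks = syn.gen_conservation_track(
            utrs, truth, base_level=0.5, site_boost=0.5, rng_seed=12
        )
        for t in tracks.values():
            assert (t >= 0).all() and (t <= 1).all()
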