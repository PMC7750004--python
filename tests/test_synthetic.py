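"""Latin-square balance, generative closed forms, and planted ground truths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partikel.cloze import compute_cloze_statistics, select_items
from partikel.synthetic import (
    ClozeGenConfig,
    DesignError,
    ExperimentDesign,
    GenerativeParams,
    build_latin_square,
    draw_item_entropies,
    generate_cloze_responses,
    generate_et_trials,
    generate_spr_trials,
)


class TestLatinSquare:
    def test_paper_design_six_targets_per_condition(self):
        df = build_latin_square(ExperimentDesign(seed=1))
        targets = df[~df["is_filler"]]
        per = targets.groupby(["participant", "set_size", "distance"]).size()
        assert (per == 6).all()
        assert targets.groupby("participant").size().eq(24).all()

    def test_each_participant_sees_each_item_once(self):
        df = build_latin_square(ExperimentDesign(seed=2))
        targets = df[~df["is_filler"]]
        assert (
            targets.groupby(["participant", "item"]).size() == 1
        ).all()

    def test_item_rotates_through_all_conditions_across_lists(self):
        df = build_latin_square(ExperimentDesign(seed=3))
        targets = df[~df["is_filler"]]
        by_list = targets[targets["item"] == "i07"].drop_duplicates(
            subset=["list", "set_size", "distance"]
        )
        assert len(by_list[["set_size", "distance"]].drop_duplicates()) == 4

    def test_minimal_design_one_per_condition(self):
        df = build_latin_square(
            ExperimentDesign(n_participants=4, n_items=4, n_fillers=0, seed=4)
        )
        per = df.groupby(["participant", "set_size", "distance"]).size()
        assert (per == 1).all()

    def test_indivisible_item_count_rejected(self):
        with pytest.raises(DesignError):
            ExperimentDesign(n_items=10)

    @given(
        n_quads=st.integers(min_value=1, max_value=8),
        n_participants=st.integers(min_value=1, max_value=12),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_balance_invariants_hold_for_any_divisible_config(
        self, n_quads, n_participants, seed
    ):
        design = ExperimentDesign(
            n_participants=n_participants, n_items=4 * n_quads, n_fillers=3,
            seed=seed,
        )
        targets = build_latin_square(design)
        targets = targets[~targets["is_filler"]]
        per = targets.groupby(["participant", "set_size", "distance"]).size()
        assert (per == n_quads).all()
        assert (targets.groupby(["participant", "item"]).size() == 1).all()


class TestSPRGeneration:
    def test_noise_free_reading_time_is_reciprocal_of_intercept(self):
        design = ExperimentDesign(n_participants=4, n_items=4, n_fillers=0,
                                  seed=1)
        params = GenerativeParams.spr_defaults(
            effect_set_size=0.0, effect_distance=0.0, effect_interaction=0.0,
            participant_sds=(0, 0, 0, 0), item_sds=(0, 0, 0, 0),
            residual_sd=1e-9, sub100_fraction=0.0, seed=2,
        )
        trials = generate_spr_trials(design, params)
        assert np.allclose(trials["rt_ms"], 400.0, atol=1e-5)

    def test_cell_means_follow_closed_form(self):
        design = ExperimentDesign(n_participants=8, n_items=8, n_fillers=0,
                                  seed=3)
        params = GenerativeParams.spr_defaults(
            effect_set_size=0.07, effect_distance=0.0,
            effect_interaction=0.0, participant_sds=(0, 0, 0, 0),
            item_sds=(0, 0, 0, 0), residual_sd=1e-9, sub100_fraction=0.0,
            seed=4,
        )
        trials = generate_spr_trials(design, params)
        means = trials.groupby("set_size")["rt_ms"].mean()
        assert means["large"] == pytest.approx(1000 / 2.535, abs=1e-4)
        assert means["small"] == pytest.approx(1000 / 2.465, abs=1e-4)

    def test_grand_mean_speed_matches_intercept(self, paper_design):
        params = GenerativeParams.spr_defaults(sub100_fraction=0.0, seed=5)
        trials = generate_spr_trials(paper_design, params)
        speed = 1000.0 / trials["rt_ms"]
        se = speed.std() / np.sqrt(len(speed))
        # participant/item random intercepts inflate the SE of the grand mean
        cluster_se = np.sqrt(
            se**2 + 0.3**2 / paper_design.n_participants
            + 0.1**2 / paper_design.n_items
        )
        assert abs(speed.mean() - 2.5) < 3 * cluster_se

    def test_sub_100ms_contamination_rate(self, paper_design):
        params = GenerativeParams.spr_defaults(sub100_fraction=0.1, seed=6)
        trials = generate_spr_trials(paper_design, params)
        frac = (trials["rt_ms"] < 100).mean()
        assert frac == pytest.approx(0.1, abs=0.03)

    def test_accuracy_near_configured_rate(self, paper_design):
        params = GenerativeParams.spr_defaults(seed=7)
        trials = generate_spr_trials(paper_design, params)
        acc = trials["question_correct"].mean()
        assert 0.92 <= acc <= 0.97

    def test_invalid_params_rejected(self):
        with pytest.raises(DesignError):
            GenerativeParams.spr_defaults(residual_sd=0.0)
        with pytest.raises(DesignError):
            GenerativeParams.spr_defaults(accuracy=1.2)
        with pytest.raises(DesignError):
            generate_et_trials(
                ExperimentDesign(seed=1), GenerativeParams.spr_defaults()
            )


class TestETGeneration:
    def test_no_increments_collapses_all_measures(self):
        design = ExperimentDesign(n_participants=6, n_items=4, n_fillers=0,
                                  seed=8)
        params = GenerativeParams.et_defaults(
            p_refix=0.0, p_reread=0.0, p_regress=0.0, seed=9
        )
        trials = generate_et_trials(design, params)
        assert np.allclose(trials["ffd_ms"], trials["fprt_ms"])
        assert np.allclose(trials["fprt_ms"], trials["tft_ms"])
        assert np.allclose(trials["fprt_ms"], trials["rpd_ms"])

    def test_median_ffd_matches_log_intercept(self):
        design = ExperimentDesign(n_participants=60, n_items=24, seed=10)
        params = GenerativeParams.et_defaults(
            intercept=5.7, effect_set_size=0.0, effect_distance=0.0,
            effect_interaction=0.0, participant_sds=(0, 0, 0, 0),
            item_sds=(0, 0, 0, 0), seed=11,
        )
        trials = generate_et_trials(design, params)
        # median of a lognormal is exp(mu); SE of log-median ~ sd*sqrt(pi/(2n))
        tol = 3 * 0.25 * np.sqrt(np.pi / (2 * len(trials)))
        assert abs(np.log(np.median(trials["ffd_ms"])) - 5.7) < tol

    def test_containment_holds_on_generated_corpus(self, paper_design):
        params = GenerativeParams.et_defaults(seed=12)
        trials = generate_et_trials(paper_design, params)
        assert (trials["ffd_ms"] <= trials["fprt_ms"] + 1e-12).all()
        assert (trials["fprt_ms"] <= trials["tft_ms"] + 1e-12).all()
        assert (trials["fprt_ms"] <= trials["rpd_ms"] + 1e-12).all()

    def test_entropy_components_overlap_with_higher_large_mean(self):
        design = ExperimentDesign(n_participants=4, n_items=200, n_fillers=0,
                                  seed=13)
        rng = np.random.default_rng(14)
        ent = draw_item_entropies(design, GenerativeParams.et_defaults(), rng)
        small = ent[ent["set_size"] == "small"]["entropy_bits"]
        large = ent[ent["set_size"] == "large"]["entropy_bits"]
        assert large.mean() > small.mean()
        # overlap: each category contains values beyond the other's mean
        assert (small > large.mean()).any()
        assert (large < small.mean()).any()


class TestClozeGeneration:
    def test_tiny_concentration_gives_near_zero_entropy(self):
        cfg = ClozeGenConfig(n_items=12, concentration_small=0.01,
                             concentration_large=0.01, nonparticle_rate=0.0,
                             seed=1)
        responses, targets = generate_cloze_responses(cfg)
        ents = [
            compute_cloze_statistics(r, targets[r.item_id]).entropy_bits
            for r in responses
        ]
        assert np.mean(ents) < 0.25

    def test_symmetric_concentration_approaches_uniform_entropy(self):
        cfg = ClozeGenConfig(n_items=12, small_inventory=4,
                             concentration_small=500.0,
                             concentration_large=500.0,
                             n_respondents=4000, nonparticle_rate=0.0, seed=2)
        responses, targets = generate_cloze_responses(cfg)
        small = [
            compute_cloze_statistics(r, targets[r.item_id]).entropy_bits
            for r in responses if r.set_size == "small"
        ]
        assert np.mean(small) == pytest.approx(2.0, abs=0.1)

    def test_planted_selection_structure_recovered_exactly(self):
        fail = list(range(0, 48, 2))  # exactly half the pool
        cfg = ClozeGenConfig(
            n_items=48, n_respondents=200, concentration_large=10.0,
            nonparticle_rate=0.0, seed=3,
        )
        responses, targets = generate_cloze_responses(
            cfg, planted_fail_items=fail
        )
        stats = [
            compute_cloze_statistics(r, targets[r.item_id]) for r in responses
        ]
        by_item = {}
        for s in stats:
            by_item.setdefault(s.item_id, []).append(s)
        result = select_items(by_item)
        expected = {f"c{i + 1:02d}" for i in range(48) if i not in fail}
        assert set(result.retained) == expected
        assert len(result.retained) == 24

    def test_inventory_bounds_enforced(self):
        with pytest.raises(DesignError):
            ClozeGenConfig(small_inventory=8)
        with pytest.raises(DesignError):
            ClozeGenConfig(large_inventory=8)

    def test_cloze_list_composition(self):
        cfg = ClozeGenConfig()
        assert cfg.sentences_per_list == 111
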