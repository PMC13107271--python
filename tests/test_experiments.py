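import numpy as np
import pandas as pd
import pytest

from dielcorrect import (
    SamplerSettings,
    make_scenario,
    min_verification,
    run_replicates,
    run_single_scenario,
    sweep_grid,
)
from dielcorrect.experiments import IncompleteGridError

FAST = SamplerSettings(thin=2)


class TestRunSingleScenario:
    def test_identical_seed_gives_identical_result(self):
        config, spec = make_scenario("unimodal", "uniform", 0.1, 0.1, 500, seed=4)
        a = run_single_scenario(config, spec, FAST)
        b = run_single_scenario(config, spec, FAST)
        assert a == b

    def test_error_free_data_recovers_pattern(self):
        config, spec = make_scenario("unimodal", "uniform", 0.0, 0.0, 4000, seed=5)
        res = run_single_scenario(config, spec, comparator="theoretical")
        assert res.delta_uncorrected >= 0.95
        assert res.delta_corrected >= 0.94

    def test_unknown_comparator_rejected(self):
        config, spec = make_scenario(seed=1)
        with pytest.raises(ValueError, match="comparator"):
            run_single_scenario(config, spec, FAST, comparator="smoothed")

    def test_correction_helps_under_night_skewed_errors(self):
        wins = 0
        for s in range(8):
            config, spec = make_scenario("skewed_true", "skewed", 0.30, 0.20, 2000, seed=700 + s)
            res = run_single_scenario(config, spec)
            wins += res.delta_corrected >= res.delta_uncorrected - 0.02
        assert wins >= 7


class TestRunReplicates:
    def test_summary_is_bookkeeping_of_replicates(self):
        config, spec = make_scenario("unimodal", "uniform", 0.1, 0.2, 500, seed=0)
        mean, sd, results = run_replicates(
            config, spec, n_replicates=5, master_seed=3, settings=FAST
        )
        deltas = [r.delta_corrected for r in results]
        assert mean == pytest.approx(np.mean(deltas), abs=1e-12)
        assert sd == pytest.approx(np.std(deltas, ddof=1), abs=1e-12)

    def test_replicate_seeds_differ_and_are_stable(self):
        from dielcorrect.experiments import replicate_seeds

        seeds = replicate_seeds(42, 10)
        assert len(set(seeds.tolist())) == 10
        np.testing.assert_array_equal(seeds, replicate_seeds(42, 10))
        assert seeds.max() < 2**31

    def test_requires_at_least_two_replicates(self):
        config, spec = make_scenario(seed=0)
        with pytest.raises(ValueError):
            run_replicates(config, spec, n_replicates=1)


class TestSweepGrid:
    def test_sub_grid_row_count_and_bounds(self):
        table = sweep_grid(
            shapes=["unimodal"],
            fp_rates=[0.05],
            verification_fractions=[0.0, 0.05],
            structures=["uniform"],
            n_detections=500,
            n_replicates=3,
            master_seed=7,
            settings=FAST,
        )
        assert len(table) == 2
        assert table["mean_delta"].between(0, 1).all()
        assert (table["n_replicates"] >= 1).all()

    def test_bit_reproducible_under_fixed_master_seed(self):
        kwargs = dict(
            shapes=["bimodal"],
            fp_rates=[0.1],
            verification_fractions=[0.1],
            structures=["uniform"],
            n_detections=500,
            n_replicates=3,
            master_seed=11,
            settings=FAST,
        )
        a, b = sweep_grid(**kwargs), sweep_grid(**kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_dimension_rejected(self):
        with pytest.raises(ValueError):
            sweep_grid(shapes=[], n_replicates=2)


class TestMinVerification:
    @staticmethod
    def ladder_table(means, structure="uniform", shape="unimodal", rate=0.05):
        fractions = [0.0, 0.05, 0.10, 0.15][: len(means)]
        return pd.DataFrame(
            {
                "fp_structure": structure,
                "shape": shape,
                "fp_rate": rate,
                "verification_fraction": fractions,
                "mean_delta": means,
                "sd_delta": 0.01,
                "n_replicates": 100,
            }
        )

    def test_first_rung_meeting_threshold_selected(self):
        table = self.ladder_table([0.90, 0.94, 0.96, 0.97])
        out = min_verification(table)
        assert len(out) == 1
        assert out.loc[0, "min_verification_fraction"] == 0.10
        assert out.loc[0, "mean_delta"] == 0.96
        assert bool(out.loc[0, "achieved"])

    def test_unachievable_threshold_reported_as_such(self):
        out = min_verification(self.ladder_table([0.80, 0.85, 0.90, 0.92]))
        assert not bool(out.loc[0, "achieved"])
        assert np.isnan(out.loc[0, "min_verification_fraction"])

    def test_missing_ladder_rung_rejected(self):
        full = self.ladder_table([0.90, 0.94, 0.96, 0.97])
        partial = self.ladder_table([0.9, 0.96], shape="bimodal").iloc[:2]
        table = pd.concat([full, partial], ignore_index=True)
        with pytest.raises(IncompleteGridError):
            min_verification(table)
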