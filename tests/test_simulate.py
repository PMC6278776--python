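"""Generative model: somatic trajectories, small-pool observation, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somamosaic import (
    generate_reference_cohort,
    generate_study_cohort,
    read_allele_table,
    sample_small_pool,
    simulate_trajectory,
    write_allele_table,
)
from somamosaic.models import DEFAULT_SPECS, RepeatRegression
from somamosaic.compare import study_rows
from somamosaic.simulate import SimulationConfig


class TestTrajectory:
    def test_age_zero_identity(self, fast_sim):
        pop = simulate_trajectory(fast_sim, 300.0, 0.0)
        assert np.all(pop == 300.0)
        assert pop.size == fast_sim.n_lineages

    def test_invalid_inputs(self, fast_sim):
        with pytest.raises(ValueError):
            simulate_trajectory(fast_sim, 300.0, -1.0)
        with pytest.raises(ValueError):
            simulate_trajectory(fast_sim, 10.0, 20.0)  # below 50 repeats

    def test_stabilization_reduces_growth(self, fast_sim):
        # f = 1 vs f = 0.3, paired seed streams, 200 replicates
        wins = 0
        for rep in range(200):
            pop_f1 = simulate_trajectory(
                fast_sim, 300.0, 40.0,
                rng=np.random.default_rng(1000 + rep), stabilization=1.0,
            )
            pop_f03 = simulate_trajectory(
                fast_sim, 300.0, 40.0,
                rng=np.random.default_rng(1000 + rep), stabilization=0.3,
            )
            if pop_f1.mean() > pop_f03.mean():
                wins += 1
        assert wins >= 195

    def test_mean_length_monotone_in_age(self, fast_sim):
        means = []
        for age in (10.0, 30.0, 50.0):
            reps = [
                simulate_trajectory(
                    fast_sim, 300.0, age,
                    rng=np.random.default_rng(2000 + r),
                ).mean()
                for r in range(60)
            ]
            means.append(np.mean(reps))
        assert means[0] < means[1] < means[2]


class TestSmallPool:
    def test_noise_free_subsample(self, fast_sim):
        from dataclasses import replace

        cfg = replace(fast_sim, sizing_cv=0.0, poisson_lambda=50.0)
        population = np.random.default_rng(0).uniform(100, 500, 200)
        sizes = sample_small_pool(
            population, cfg, rng=np.random.default_rng(1)
        )
        assert sizes.size >= cfg.target_alleles
        assert np.isin(sizes, population).all()

    def test_p10_consistency(self, fast_sim):
        from dataclasses import replace

        cfg = replace(fast_sim, sizing_cv=0.0, target_alleles=5000,
                      min_detectable=1.0)
        population = np.random.default_rng(2).lognormal(5.7, 0.35, 500)
        sizes = sample_small_pool(
            population, cfg, rng=np.random.default_rng(3)
        )
        assert np.percentile(sizes, 10) == pytest.approx(
            np.percentile(population, 10), rel=0.03
        )

    def test_detection_filter(self, fast_sim):
        from dataclasses import replace

        cfg = replace(fast_sim, sizing_cv=0.0, min_detectable=60.0,
                      target_alleles=2000)
        population = np.random.default_rng(4).uniform(40, 140, 1000)
        sizes = sample_small_pool(
            population, cfg, rng=np.random.default_rng(5)
        )
        assert sizes.min() >= 60.0
        # kept sample follows the truncated population: 1/4 of kept mass
        # lies in [60, 80)
        frac = np.mean(sizes < 80.0)
        se = np.sqrt(0.25 * 0.75 / sizes.size)
        assert frac == pytest.approx(0.25, abs=4 * se)

    def test_entirely_undetectable_raises(self, fast_sim):
        with pytest.raises(ValueError, match="detection limit"):
            sample_small_pool(np.full(50, 20.0), fast_sim)


class TestCohorts:
    def test_reference_determinism(self, fast_sim, fast_cohort_spec):
        a = generate_reference_cohort(fast_cohort_spec, fast_sim, seed=5)
        b = generate_reference_cohort(fast_cohort_spec, fast_sim, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_reference_cohort(fast_cohort_spec, fast_sim, seed=6)
        assert not a.equals(c)

    def test_reference_layout(self, fast_sim, fast_cohort_spec):
        frame = generate_reference_cohort(fast_cohort_spec, fast_sim, seed=1)
        n = fast_cohort_spec.n_subjects
        assert len(frame) == 2 * n
        assert set(frame.timepoint) == {"t1", "t2"}
        per_tp = frame[frame.timepoint == "t1"]
        assert per_tp.age_at_onset.notna().sum() == fast_cohort_spec.n_symptomatic
        assert (frame.si > 0).all()
        assert (frame.epal > 0).all()

    def test_afd_right_skew(self, fast_sim, fast_cohort_spec):
        _, samples = generate_reference_cohort(
            fast_cohort_spec, fast_sim, seed=2, return_samples=True
        )
        skews = [stats.skew(s.sizes) for s in samples
                 if s.age_at_sampling >= 10]
        assert np.mean(np.array(skews) > 0) >= 0.9

    def test_study_cohort_round_trip(self, tmp_path, fast_sim,
                                     fast_cohort_spec, fast_study_spec):
        records, samples = generate_study_cohort(
            fast_cohort_spec, fast_study_spec, fast_sim, seed=3
        )
        assert sum(r.group == "interrupted" for r in records.values()) == 7
        assert sum(r.group == "control" for r in records.values()) == 4
        path = tmp_path / "alleles.tsv"
        write_allele_table(samples, path)
        back = {s.key: s for s in read_allele_table(path)}
        assert set(back) == {s.key for s in samples}
        for s in samples:
            np.testing.assert_allclose(np.sort(back[s.key].sizes),
                                       np.sort(s.sizes))

    def test_interrupted_patients_carry_patterns(self, fast_sim,
                                                 fast_cohort_spec,
                                                 fast_study_spec):
        records, _ = generate_study_cohort(
            fast_cohort_spec, fast_study_spec, fast_sim, seed=3
        )
        for rec in records.values():
            if rec.group == "interrupted":
                assert not rec.pattern.is_pure
                assert rec.interrupted_block_override is not None
            else:
                assert rec.pattern.is_pure

    def test_stabilized_group_has_negative_residuals(
        self, fast_sim, fast_cohort_spec, fast_study_spec
    ):
        # with f = 0.3, interrupted subjects should sit below the fitted
        # instability surface in nearly every replicate
        from dataclasses import replace

        cfg = replace(fast_sim, stabilization_factor=0.3)
        study_spec = replace(fast_study_spec, n_buccal_interrupted=0,
                             n_buccal_control=0)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            ref = generate_reference_cohort(fast_cohort_spec, cfg,
                                            seed=3000 + seed)
            records, _ = generate_study_cohort(
                fast_cohort_spec, study_spec, cfg, seed=7000 + seed
            )
            rows = study_rows(records, "t1")
            combined = pd.concat([
                ref[ref.timepoint == "t1"].set_index("patient_id")
                .assign(group="reference")[
                    ["group", "epal", "age_at_sampling", "si"]],
                rows[["group", "epal", "age_at_sampling", "si"]],
            ])
            fit = RepeatRegression(DEFAULT_SPECS["M8"], combined).fit()
            resid = fit.std_residuals
            interrupted = resid[combined["group"] == "interrupted"]
            if interrupted.median() < 0:
                hits += 1
        assert hits >= n_seeds - 1


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(stabilization_factor=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(contraction_fraction=0.6)
    with pytest.raises(ValueError):
        SimulationConfig(expansion_rate=-1.0)
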