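import dataclasses

import numpy as np
import pytest

from nutrigeo.diets import make_2d_diet, reference_designs
from nutrigeo.intake import summarize_experiments
from nutrigeo.simulate import (
    GeneratorConfig,
    InfeasibleTargetError,
    experiments_to_frames,
    gen_choice_experiment,
    gen_nochoice_experiment,
    gen_rmt_experiment,
    generate,
    read_fixture,
    write_fixture,
    _mixing_masses,
)

from conftest import small_design


class TestDeterminism:
    @pytest.mark.parametrize("kind", ["choice_2d", "nochoice_2d", "nochoice_3d"])
    def test_same_seed_identical(self, designs, kind):
        d = small_design(designs, kind, 3)
        cfg = GeneratorConfig(design=d, seed=42, n_bins=4)
        a_days, a_end = experiments_to_frames(generate(cfg))
        b_days, b_end = experiments_to_frames(generate(cfg))
        assert a_days.equals(b_days) and a_end.equals(b_end)

    def test_distinct_seeds_differ(self, designs):
        d = small_design(designs, "choice_2d", 3)
        a, _ = experiments_to_frames(
            generate(GeneratorConfig(design=d, seed=1))
        )
        b, _ = experiments_to_frames(
            generate(GeneratorConfig(design=d, seed=2))
        )
        assert not a.equals(b)


class TestChoiceGenerator:
    def test_zero_noise_hits_target_exactly(self, quiet_config):
        exps = gen_choice_experiment(quiet_config)
        recipes = quiet_config.design.diets()
        for s in summarize_experiments(exps, recipes):
            assert s.protein_consumed == pytest.approx(40.0, rel=1e-9)
            assert s.carb_consumed == pytest.approx(60.0, rel=1e-9)
            assert s.consumed == pytest.approx(s.harvested, rel=1e-9)

    def test_mixing_solve_against_substitution(self):
        # target (20, 30) split between the 1:6 and 3:1 diets
        d1, d2 = make_2d_diet(1, 6), make_2d_diet(3, 1)
        m = _mixing_masses(np.array([20.0, 30.0]), d1, d2)
        p = m[0] * d1.protein_mass_fraction + m[1] * d2.protein_mass_fraction
        c = m[0] * d1.carb_mass_fraction + m[1] * d2.carb_mass_fraction
        assert (p, c) == pytest.approx((20.0, 30.0), rel=1e-12)
        assert (m >= 0).all()

    def test_infeasible_target_raises(self, designs):
        d = small_design(designs, "choice_2d", 2)
        cfg = GeneratorConfig(design=d, intake_target=(100.0, 1.0), seed=0)
        with pytest.raises(InfeasibleTargetError):
            gen_choice_experiment(cfg)

    def test_mass_conservation(self, designs):
        cfg = GeneratorConfig(design=designs["choice_2d"], seed=3)
        for e in gen_choice_experiment(cfg):
            recipes = cfg.design.diets()
            s = summarize_experiments([e], recipes)[0]
            assert s.consumed + s.hoarded + s.scattered == pytest.approx(
                s.harvested, rel=1e-12
            )


class TestNochoiceGenerator:
    def _quiet(self, designs, rule):
        return GeneratorConfig(
            design=designs["nochoice_2d"],
            rule=rule,
            total_intake_cv=0.0,
            hoard_frac=0.0,
            hoard_sd=0.0,
            scatter_frac=0.0,
            scatter_sd=0.0,
            intake_target=(20.0, 30.0),
            death_hazard_fn=lambda p, c: 0.0,
            seed=5,
        )

    def test_equal_distance_gives_constant_total(self, designs):
        cfg = self._quiet(designs, "equal_distance")
        summaries = summarize_experiments(
            gen_nochoice_experiment(cfg), cfg.design.diets()
        )
        totals = {s.treatment: s.consumed for s in summaries}
        assert all(t == pytest.approx(50.0, rel=1e-9) for t in totals.values())

    def test_closest_distance_projects_onto_rail(self, designs):
        cfg = self._quiet(designs, "closest_distance")
        summaries = summarize_experiments(
            gen_nochoice_experiment(cfg), cfg.design.diets()
        )
        on_diag = [s for s in summaries if s.treatment == "1:1"]
        for s in on_diag:
            assert (s.protein_consumed, s.carb_consumed) == pytest.approx(
                (25.0, 25.0), rel=1e-9
            )

    def test_zero_hazard_keeps_all_workers(self, designs):
        cfg = self._quiet(designs, "equal_distance")
        assert all(
            e.final_workers == 200 for e in gen_nochoice_experiment(cfg)
        )


class TestRmtGenerator:
    def test_flat_surface_gives_equal_consumption(self, designs):
        cfg = GeneratorConfig(
            design=designs["nochoice_3d"],
            surface_coeffs=(50.0, 0, 0, 0, 0, 0),
            surface_noise_sd=0.0,
            hoard_frac=0.0,
            hoard_sd=0.0,
            scatter_frac=0.0,
            scatter_sd=0.0,
            seed=6,
            n_bins=8,
        )
        summaries = summarize_experiments(
            gen_rmt_experiment(cfg), cfg.design.diets()
        )
        for s in summaries:
            assert s.consumed == pytest.approx(50.0, rel=1e-9)

    def test_death_rate_matches_logistic_hazard(self, designs):
        # without bin effects, the 14-day death fraction has the closed form
        # 1 - (1 - h)^14; the empirical rate must sit within 3 SE of it
        hazard = lambda p, c: 0.02 + 0.0005 * p
        d = small_design(designs, "nochoice_3d", 30)
        cfg = GeneratorConfig(
            design=d, death_hazard_fn=hazard, bin_effect_sd=0.0, seed=7, n_bins=8
        )
        exps = gen_rmt_experiment(cfg)
        by_diet = {}
        for e in exps:
            by_diet.setdefault(e.treatment, []).append(
                1.0 - e.final_workers / e.n_workers_initial
            )
        for diet in d.treatments:
            h = hazard(diet.p_frac, diet.c_frac)
            expected = 1.0 - (1.0 - h) ** 14
            rates = by_diet[diet.label]
            n_workers = len(rates) * 200
            se = np.sqrt(expected * (1 - expected) / n_workers)
            assert abs(np.mean(rates) - expected) < 3 * se

    def test_poisson_eggs_seeded(self, designs):
        cfg = GeneratorConfig(design=designs["nochoice_3d"], seed=8, n_bins=8)
        eggs = [e.eggs for e in gen_rmt_experiment(cfg)]
        assert all(x >= 0 for x in eggs) and np.mean(eggs) > 0


class TestFixtureIO:
    def test_round_trip(self, tmp_path, designs):
        cfg = GeneratorConfig(design=small_design(designs, "choice_2d", 3), seed=9)
        exps = generate(cfg)
        write_fixture(exps, tmp_path, cfg)
        back = read_fixture(tmp_path)
        assert len(back) == len(exps)
        for a, b in zip(exps, back):
            assert a.records == b.records
            assert a.hoarded_by_diet == pytest.approx(b.hoarded_by_diet)
            assert (a.final_workers, a.eggs, a.bin_id) == (
                b.final_workers, b.eggs, b.bin_id,
            )

    def test_empty_experiment_list(self, tmp_path, designs):
        cfg = GeneratorConfig(design=designs["choice_2d"], seed=0)
        write_fixture([], tmp_path, cfg)
        assert (tmp_path / "colony_days.csv").read_text().startswith("colony_id")
        assert read_fixture(tmp_path) == []

    def test_full_3d_design_record_count(self, tmp_path, designs):
        cfg = GeneratorConfig(design=designs["nochoice_3d"], seed=1, n_bins=8)
        exps = generate(cfg)
        days, end = experiments_to_frames(exps)
        assert len(exps) == 35
        assert len(days) == 35 * 14
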