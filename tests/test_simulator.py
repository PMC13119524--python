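"""Simulator dynamics: closed forms, bookkeeping and measurement layers."""

import numpy as np
import pytest

import phagesteer as ps
from phagesteer.simulator import (
    ExtinctPopulationError,
    PopulationState,
    StepSizeError,
    Trajectory,
    cross_resistant_labels,
    first_majority_day,
)

from conftest import analytic_params


def single_genotype_state(count, phage=None):
    return PopulationState(0.0, {"sensitive": count}, phage or {"T2": 0, "LAMBDA": 0})


class TestGrowAndInfect:
    def test_deterministic_exponential_growth(self):
        """No phage, no mutation, N << K: one hour multiplies N by e^r."""
        params = analytic_params(K=1e30)
        out = ps.grow_and_infect(single_genotype_state(10**6), params, 1.0)
        assert out.cells["sensitive"] / 1e6 == pytest.approx(np.exp(params.r), rel=1e-6)

    def test_deterministic_constant_phage_killing(self):
        """r = 0, burst = 1 (each adsorption replaced): N(t) = N0 exp(-phi P t / V)."""
        params = analytic_params(
            r=0.0, phi={"T2": 1e-8, "LAMBDA": 0.0}, burst={"T2": 1, "LAMBDA": 1}
        )
        state = single_genotype_state(10**6, {"T2": 10**8, "LAMBDA": 0})
        out = ps.grow_and_infect(state, params, 0.5)
        expected = 1e6 * np.exp(-1e-8 * (1e8 / params.volume_ml) * 0.5)
        assert out.cells["sensitive"] == pytest.approx(expected, rel=1e-4)

    def test_deterministic_logistic_matches_closed_form(self):
        """mu = 0, no phage: total cells track the logistic solution within 1%
        at dt = 0.01 h over a full day."""
        params = analytic_params(dt_hours=0.01)
        n0 = 9e4
        out = ps.grow_and_infect(single_genotype_state(int(n0)), params, 24.0)
        kv = params.K * params.volume_ml
        g = np.exp(params.r * 24.0)
        exact = kv * n0 * g / (kv + n0 * (g - 1.0))
        assert out.cells["sensitive"] == pytest.approx(exact, rel=0.01)

    def test_full_resistance_matches_no_phage_trajectory(self):
        """s = 0 for every phage present: cells follow the phage-free path."""
        resistant = ps.Genotype("res", {"T2": 0.0, "LAMBDA": 0.0})
        params = analytic_params(genotypes=(resistant,))
        with_phage = PopulationState(0.0, {"res": 10**5}, {"T2": 10**9, "LAMBDA": 0})
        without = PopulationState(0.0, {"res": 10**5}, {"T2": 0, "LAMBDA": 0})
        a = ps.grow_and_infect(with_phage, params, 6.0)
        b = ps.grow_and_infect(without, params, 6.0)
        assert a.cells == b.cells

    def test_phage_bookkeeping_single_step(self):
        """Over one step with r = 0 and no decay, the phage gain equals
        (cells lysed) x (burst - 1)."""
        params = ps.SimParams(
            r=0.0,
            phi={"T2": 1e-7, "LAMBDA": 0.0},
            burst={"T2": 50, "LAMBDA": 1},
            decay={"T2": 0.0, "LAMBDA": 0.0},
            refuge_cells=0.0,
            dormant_on=0.0,
            dormant_off=0.0,
            mutations={},
        )
        state = single_genotype_state(10**6, {"T2": 10**7, "LAMBDA": 0})
        out = ps.grow_and_infect(state, params, params.dt_hours, rng_seed=1)
        lysed = state.cells["sensitive"] - out.cells["sensitive"]
        assert lysed > 0
        assert out.phage["T2"] - state.phage["T2"] == lysed * (50 - 1)

    def test_stochastic_killing_matches_closed_form_within_mc_error(self):
        """Binomial thinning reproduces exp(-phi P t / V) survival on average."""
        params = ps.SimParams(
            r=0.0,
            phi={"T2": 1e-8, "LAMBDA": 0.0},
            burst={"T2": 1, "LAMBDA": 1},
            decay={"T2": 0.0, "LAMBDA": 0.0},
            refuge_cells=0.0,
            dormant_on=0.0,
            dormant_off=0.0,
            mutations={},
        )
        n0, reps = 10**6, 20
        state = single_genotype_state(n0, {"T2": 10**8, "LAMBDA": 0})
        rng = np.random.default_rng(0)
        survivors = [
            ps.grow_and_infect(state, params, 0.5, rng).cells["sensitive"]
            for _ in range(reps)
        ]
        p_surv = np.exp(-1e-8 * (1e8 / params.volume_ml) * 0.5)
        se = np.sqrt(n0 * p_surv * (1 - p_surv) / reps)
        assert abs(np.mean(survivors) - n0 * p_surv) < 4 * se

    def test_refuge_floor_shields_cells(self):
        """Below the wall-refuge floor no cell is exposed to phage."""
        params = analytic_params(
            r=0.0, phi={"T2": 1e-6, "LAMBDA": 0.0}, burst={"T2": 1, "LAMBDA": 1},
            refuge_cells=1e6,
        )
        state = single_genotype_state(10**5, {"T2": 10**10, "LAMBDA": 0})
        out = ps.grow_and_infect(state, params, 2.0)
        assert out.cells["sensitive"] == 10**5

    def test_step_size_guard(self):
        params = ps.SimParams(r=1.2, dt_hours=0.1)
        with pytest.raises(StepSizeError, match="dt_hours"):
            ps.grow_and_infect(single_genotype_state(1000), params, 1.0, rng_seed=0)

    def test_no_spontaneous_genotypes_without_mutation(self):
        """mu = 0: genotype classes absent at t = 0 never appear."""
        params = ps.SimParams(mutations={})
        spec = ps.TreatmentSpec("monophage", "T2", "none", "NONE", 1)
        for seed in range(5):
            traj = ps.run_population(spec, params, seed=seed, population_id=f"m{seed}")
            seen = set().union(*(f.keys() for f in traj.genotype_frequencies if f))
            assert seen <= {"sensitive"}


class TestTransferAndDose:
    def test_transfer_of_zero_is_zero(self, default_params):
        out = ps.daily_transfer(
            PopulationState(0.0, {"sensitive": 0}, {"T2": 0, "LAMBDA": 0}),
            default_params,
            rng_seed=0,
        )
        assert out.cells["sensitive"] == 0

    def test_transfer_deterministic_rounding(self):
        params = analytic_params()
        out = ps.daily_transfer(single_genotype_state(4_000_000_000), params)
        assert out.cells["sensitive"] == 40_000_000  # 1% of the culture

    def test_transfer_mean_matches_binomial(self, default_params):
        """Monte-Carlo mean of the transfer equals D x count within 3 SE."""
        count, reps = 1000, 10_000
        rng = np.random.default_rng(1)
        total = sum(
            ps.daily_transfer(single_genotype_state(count), default_params, rng).cells[
                "sensitive"
            ]
            for _ in range(reps)
        )
        d = default_params.dilution
        se = np.sqrt(count * d * (1 - d) / reps)
        assert abs(total / reps - count * d) < 3 * se

    def test_zero_dose_is_identity(self):
        state = single_genotype_state(1000, {"T2": 5, "LAMBDA": 0})
        out, moi = ps.apply_dose(state, ps.DoseEvent(0, {}))
        assert out.cells == state.cells and out.phage == state.phage
        assert moi == 0.0

    def test_dose_moi_logged(self):
        state = single_genotype_state(90_000)
        out, moi = ps.apply_dose(state, ps.DoseEvent(0, {"T2": 1e6}))
        assert out.phage["T2"] == 1_000_000
        assert moi == pytest.approx(1e6 / 9e4, rel=1e-12)  # ~11.1

    def test_both_dose_split(self):
        spec = ps.TreatmentSpec("cocktail", "BOTH", "late", "BOTH", 3)
        event = ps.dose_schedule(spec, 1e6)[0]
        state, _ = ps.apply_dose(single_genotype_state(1000), event)
        assert state.phage == {"T2": 500_000, "LAMBDA": 500_000}


class TestRunPopulation:
    def test_control_rises_monotonically_to_plateau(self, default_params):
        spec = ps.TreatmentSpec("control", n_replicates=1)
        traj = ps.run_population(spec, default_params, seed=0)
        assert traj.od600[0] > 0.9  # saturates within the first day
        assert np.all(np.diff(traj.od600) > -0.01)
        plateau = ps.cfu_to_od(default_params.K, default_params)
        assert traj.od600[-1] == pytest.approx(plateau, rel=0.02)

    def test_t2_only_suppressed_below_detection(self, default_params):
        """T2 alone keeps OD below the optical detection limit for at least
        three recorded days in a majority of seeds."""
        spec = ps.TreatmentSpec("monophage", "T2", "none", "NONE", 1)
        wins = 0
        for seed in range(15):
            traj = ps.run_population(spec, default_params, seed=seed, population_id=f"t{seed}")
            wins += int(np.sum(traj.censored) >= 3)
        assert wins > 15 / 2

    def test_identical_seeds_identical_trajectories(self, default_params):
        spec = ps.TreatmentSpec("sequential", "LAMBDA", "late", "T2", 1)
        a = ps.run_population(spec, default_params, seed=42)
        b = ps.run_population(spec, default_params, seed=42)
        assert np.array_equal(a.od600, b.od600)
        assert np.array_equal(a.censored, b.censored)
        assert a.genotype_frequencies == b.genotype_frequencies
        c = ps.run_population(spec, default_params, seed=43)
        assert a.genotype_frequencies != c.genotype_frequencies

    def test_dose_log_records_moi(self, default_params):
        spec = ps.TreatmentSpec("sequential", "T2", "late", "LAMBDA", 1)
        traj = ps.run_population(spec, default_params, seed=0)
        assert [d["day"] for d in traj.dose_log] == [0, 3]
        assert traj.dose_log[0]["moi"] == pytest.approx(1e6 / 9e4, rel=1e-9)

    def test_collateral_sensitivity_draw(self, default_params):
        """A T2-specific genotype with ancestral lambda susceptibility is
        drawn collaterally hypersensitive with the configured probability."""
        from dataclasses import replace

        genotypes = (
            ps.Genotype("sensitive", {"T2": 1.0, "LAMBDA": 1.0}),
            ps.Genotype("t2_resistant", {"T2": 0.0, "LAMBDA": 1.0}),
        )
        base = replace(
            default_params, genotypes=genotypes,
            mutations={("sensitive", "t2_resistant"): 1e-8},
        )
        spec = ps.TreatmentSpec("monophage", "T2", "none", "NONE", 1, duration_days=1)
        t = ps.run_population(spec, replace(base, collateral_prob=1.0), seed=0)
        assert t.genotypes[1].susceptibility["LAMBDA"] == base.collateral_s_lambda
        t = ps.run_population(spec, replace(base, collateral_prob=0.0), seed=0)
        assert t.genotypes[1].susceptibility["LAMBDA"] == 1.0
        # the default lattice's T2-specific genotype is already hypersensitive
        # and is left untouched by the draw
        t = ps.run_population(spec, replace(default_params, collateral_prob=1.0), seed=0)
        assert t.genotypes[1].susceptibility["LAMBDA"] == 6.0


class TestCalibrationAndPresence:
    def test_od_limits(self, default_params):
        assert ps.cfu_to_od(0.0, default_params) == 0.0
        assert ps.cfu_to_od(default_params.n_half, default_params) == pytest.approx(
            default_params.od_max / 2
        )

    def test_round_trip(self, default_params):
        for n in (1e3, 1e6, 1e9, 5e9):
            od = ps.cfu_to_od(n, default_params)
            assert ps.od_to_cfu(od, default_params) == pytest.approx(n, rel=1e-6)

    def test_od_monotone(self, default_params):
        ns = np.logspace(2, 10, 30)
        ods = ps.cfu_to_od(ns, default_params)
        assert np.all(np.diff(ods) > 0)

    def test_inverse_domain(self, default_params):
        with pytest.raises(ValueError):
            ps.od_to_cfu(default_params.od_max, default_params)

    @pytest.mark.parametrize(
        "pfu, present", [(0, False), (3999, False), (4000, True), (10**7, True)]
    )
    def test_presence_threshold(self, default_params, pfu, present):
        # threshold 1e3 PFU/mL x 4 mL = 4000 particles
        state = PopulationState(0.0, {"sensitive": 1}, {"T2": pfu, "LAMBDA": 0})
        assert ps.phage_presence(state, default_params)["T2"] is present
        assert ps.phage_presence(state, default_params)["LAMBDA"] is False


class TestAssaysAndCurves:
    def test_fully_resistant_isolate_unkilled(self, default_params):
        rng = np.random.default_rng(0)
        ratios = [
            r.iso_p / r.iso_np
            for r in (
                ps.simulate_killing_assay(
                    ps.Genotype("res", {"T2": 0.0, "LAMBDA": 1.0}), "T2", default_params, rng
                )
                for _ in range(10)
            )
        ]
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.1)  # counting noise only

    def test_ancestral_isolate_matches_wt(self, default_params):
        rng = np.random.default_rng(2)
        ratios = []
        for i in range(30):
            rec = ps.simulate_killing_assay(
                ps.Genotype("wt", {"T2": 1.0, "LAMBDA": 1.0}), "T2", default_params, rng
            )
            ratios.append((rec.iso_p / rec.iso_np) / (rec.wt_p / rec.wt_np))
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.15)

    def test_survival_fraction_closed_form(self, default_params):
        """Mean survival over replicate assays matches exp(-phi s P t / V)."""
        genotype = ps.Genotype("partial", {"T2": 0.3, "LAMBDA": 1.0})
        rng = np.random.default_rng(3)
        fracs = [
            r.iso_p / r.iso_np
            for r in (
                ps.simulate_killing_assay(genotype, "T2", default_params, rng)
                for _ in range(300)
            )
        ]
        p_ml = default_params.assay_lysate_pfu / default_params.assay_volume_ml
        expected = np.exp(-default_params.phi["T2"] * 0.3 * p_ml * 0.5)
        assert np.mean(fracs) == pytest.approx(expected, rel=0.1)

    def test_unknown_phage_rejected(self, default_params):
        with pytest.raises(ValueError, match="unknown phage"):
            ps.simulate_killing_assay(
                ps.Genotype("x", {"T2": 1.0}), "T4", default_params, seed=0
            )

    def test_growth_curve_slope_equals_growth_rate(self, default_params):
        """Noiseless early-phase slope of ln OD recovers r, and a 15% cost
        scales it by 0.85."""
        for cost, factor in [(0.0, 1.0), (0.15, 0.85)]:
            genotype = ps.Genotype("g", {"T2": 1, "LAMBDA": 1}, growth_cost=cost)
            t, od = ps.simulate_growth_curve(genotype, default_params, noise_sd=0.0)
            early = slice(0, 13)
            slope = np.polyfit(t[early] / 60.0, np.log(od[early]), 1)[0]
            assert slope == pytest.approx(default_params.r * factor, rel=0.02)

    def test_growth_curve_shape_and_determinism(self, default_params):
        genotype = ps.Genotype("g", {"T2": 1, "LAMBDA": 1})
        t1, od1 = ps.simulate_growth_curve(genotype, default_params, noise_sd=0.02, seed=9)
        t2, od2 = ps.simulate_growth_curve(genotype, default_params, noise_sd=0.02, seed=9)
        assert len(t1) == 289 and t1[-1] == 288 * 5.0
        assert np.array_equal(od1, od2)


class TestSampleIsolates:
    def make_trajectory(self, freqs, genotypes):
        days = np.array([1])
        return Trajectory(
            population_id="p",
            seed=0,
            days=days,
            od600=np.array([0.5]),
            censored=np.array([False]),
            phage_present={"T2": np.array([True]), "LAMBDA": np.array([False])},
            genotype_frequencies=[freqs],
            extinction_day=None,
            dose_log=[],
            genotypes=genotypes,
        )

    def test_single_genotype_all_identical(self):
        genos = (ps.Genotype("only", {"T2": 0, "LAMBDA": 1}),)
        traj = self.make_trajectory({"only": 1.0}, genos)
        isolates = ps.sample_isolates(traj, 1, 5, seed=0)
        assert all(g.label == "only" for g in isolates)

    def test_balanced_frequencies_sampled_binomially(self):
        genos = (
            ps.Genotype("a", {"T2": 1, "LAMBDA": 1}),
            ps.Genotype("b", {"T2": 0, "LAMBDA": 0}),
        )
        traj = self.make_trajectory({"a": 0.5, "b": 0.5}, genos)
        n = 10_000
        isolates = ps.sample_isolates(traj, 1, n, seed=0)
        count_a = sum(g.label == "a" for g in isolates)
        se = np.sqrt(n * 0.25)
        assert abs(count_a - n / 2) < 3 * se

    def test_extinct_day_raises(self):
        genos = (ps.Genotype("a", {"T2": 1, "LAMBDA": 1}),)
        traj = self.make_trajectory({}, genos)
        with pytest.raises(ExtinctPopulationError):
            ps.sample_isolates(traj, 1, 3, seed=0)


class TestCrossResistanceSummaries:
    def test_cross_resistant_labels_default_lattice(self, default_params):
        labels = cross_resistant_labels(default_params.genotypes)
        assert set(labels) == {"cross_resistant", "mucoid"}

    def test_first_majority_day(self):
        genos = (
            ps.Genotype("sensitive", {"T2": 1, "LAMBDA": 1}),
            ps.Genotype("cross_resistant", {"T2": 0, "LAMBDA": 0}),
        )
        traj = Trajectory(
            population_id="p",
            seed=0,
            days=np.array([1, 2, 3]),
            od600=np.array([0.01, 0.2, 0.9]),
            censored=np.array([True, False, False]),
            phage_present={"T2": np.array([1, 1, 1], bool), "LAMBDA": np.array([0, 0, 0], bool)},
            genotype_frequencies=[
                {"sensitive": 1.0},
                {"sensitive": 0.6, "cross_resistant": 0.4},
                {"sensitive": 0.1, "cross_resistant": 0.9},
            ],
            extinction_day=None,
            dose_log=[],
            genotypes=genos,
        )
        assert first_majority_day(traj) == 3
        assert first_majority_day(traj, threshold=0.3) == 2
        assert first_majority_day(traj, labels=["sensitive"]) == 1
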