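"""LRA estimators: free energy, reorganization energies, block analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from hemepath import EV_TO_KCAL_MOL, KB_EV
from hemepath import synthetic_data as syn
from hemepath.marcus_estimators import (
    GapSeries,
    InnerSphereEnergies,
    block_analysis,
    decompose_gap,
    ergodicity_factor,
    estimate_parameters,
    inner_sphere_lambda,
    load_gap_series,
    reaction_free_energy,
    running_average,
    stokes_reorganization,
    total_reorganization,
    variance_reorganization,
)


def make_series(gaps, state="initial", times=None, **kw):
    gaps = np.asarray(gaps, dtype=float)
    if times is None:
        times = np.arange(len(gaps), dtype=float)
    return GapSeries(times=times, gaps=gaps, state=state, **kw)


class TestPointEstimators:
    def test_reaction_free_energy_arithmetic(self):
        assert reaction_free_energy(0.8, -1.4) == pytest.approx(-0.3)

    def test_self_exchange_is_thermoneutral(self):
        lam = 1.1
        assert reaction_free_energy(lam, -lam) == 0.0

    def test_stokes_arithmetic(self):
        assert stokes_reorganization(0.8, -1.4) == pytest.approx(1.1)
        assert stokes_reorganization(0.5, 0.5) == 0.0

    def test_negative_stokes_warns(self):
        with pytest.warns(UserWarning, match="LRA"):
            stokes_reorganization(-1.0, 1.0)

    def test_variance_reorganization_constant_series(self):
        series = make_series([0.5, 0.5, 0.5])
        assert variance_reorganization(series, 310.0) == 0.0

    def test_variance_reorganization_known_variance(self):
        # population variance 2 * 1.1 * kB * 310 corresponds to 1.1 eV
        target_var = 2.0 * 1.1 * KB_EV * 310.0
        x = np.array([-1.0, 1.0]) * math.sqrt(target_var)  # var = target
        series = make_series(x)
        assert variance_reorganization(series, 310.0) == pytest.approx(1.1)

    def test_variance_needs_two_samples(self):
        with pytest.raises(ValueError):
            variance_reorganization(make_series([1.0]), 310.0)

    def test_ergodicity_factor(self):
        assert ergodicity_factor(1.0, 1.0, 1.0) == 1.0
        assert ergodicity_factor(1.5, 1.5, 1.0) == 1.5
        with pytest.raises(ValueError):
            ergodicity_factor(1.0, 1.0, 0.0)

    def test_mean_identities_reconstruct_inputs(self):
        # <dE>_i = dA0 + lambda_St and <dE>_f = dA0 - lambda_St exactly
        mi, mf = 0.73, -1.21
        da = reaction_free_energy(mi, mf)
        lam = stokes_reorganization(mi, mf)
        assert da + lam == pytest.approx(mi, abs=1e-15)
        assert da - lam == pytest.approx(mf, abs=1e-15)


class TestLoadGapSeries:
    def test_ev_file_unchanged(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("time,gap\n0,0.1\n1,0.2\n2,0.3\n")
        s = load_gap_series(p, state="initial")
        assert np.allclose(s.gaps, [0.1, 0.2, 0.3])

    def test_kcal_per_mol_conversion(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(f"time,gap\n0,{EV_TO_KCAL_MOL}\n1,0\n")
        s = load_gap_series(p, units="kcal/mol", state="initial")
        assert s.gaps[0] == pytest.approx(1.0)

    def test_component_columns_accepted(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "time\tgap\tTM\tDH\tenv\tcof\n"
            "0\t1.0\t0.4\t0.1\t0.3\t0.2\n"
            "1\t0.5\t0.2\t0.05\t0.15\t0.1\n"
        )
        s = load_gap_series(p, state="initial")
        assert list(s.components.columns) == ["TM", "DH", "env", "cof"]

    def test_mismatched_components_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("time,gap,TM,DH\n0,1.0,0.9,0.2\n")
        with pytest.raises(ValueError, match="sum"):
            load_gap_series(p, state="initial")

    def test_state_column_splits_series(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(
            "time,gap,state\n0,0.8,initial\n1,0.9,initial\n"
            "0,-1.3,final\n1,-1.5,final\n"
        )
        both = load_gap_series(p)
        assert set(both) == {"initial", "final"}
        assert both["final"].mean() == pytest.approx(-1.4)

    def test_non_monotonic_times_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("time,gap\n1,0.1\n0,0.2\n")
        with pytest.raises(ValueError):
            load_gap_series(p, state="initial")


class TestGeneratorRecovery:
    """Estimators recover the generator's parameters on LRA data."""

    N = 100_000
    DELTA_A = -0.28
    LAM = 1.04

    @pytest.fixture(scope="class")
    @staticmethod
    def params():
        spec = syn.LRAGeneratorSpec(
            delta_A=TestGeneratorRecovery.DELTA_A,
            lam=TestGeneratorRecovery.LAM, temperature=310.0,
            n_samples=TestGeneratorRecovery.N, seed=20,
        )
        ini, fin = syn.generate_lra_gaps(spec)
        return estimate_parameters(ini, fin)

    def test_free_energy_within_three_sigma(self, params):
        sigma2 = 2 * self.LAM * KB_EV * 310.0
        se = math.sqrt(sigma2 / (2 * self.N))
        assert abs(params.delta_A0 - self.DELTA_A) < 3 * se

    def test_stokes_within_three_sigma(self, params):
        sigma2 = 2 * self.LAM * KB_EV * 310.0
        se = math.sqrt(sigma2 / (2 * self.N))
        assert abs(params.lambda_St - self.LAM) < 3 * se

    def test_variance_lambdas_within_three_sigma(self, params):
        se = self.LAM * math.sqrt(2.0 / self.N)
        assert abs(params.lambda_var_initial - self.LAM) < 3 * se
        assert abs(params.lambda_var_final - self.LAM) < 3 * se

    def test_chi_g_near_unity(self, params):
        assert 0.97 < params.chi_G < 1.03

    def test_bimodal_gaps_inflate_chi_g(self):
        # two regimes 0.8 eV apart, switching slowly: variance estimators
        # see the mixture, the Stokes estimator only the mean difference
        a = syn.LRAGeneratorSpec(delta_A=-0.7, lam=1.1, n_samples=40_000)
        b = syn.LRAGeneratorSpec(delta_A=0.1, lam=1.1, n_samples=40_000)
        ini = syn.generate_bimodal_gaps(a, b, switch_prob=1e-3, state="initial",
                                        seed=5)
        fin = syn.generate_bimodal_gaps(a, b, switch_prob=1e-3, state="final",
                                        seed=6)
        p = estimate_parameters(ini, fin)
        assert p.chi_G > 1.0


class TestBlockAnalysis:
    def _segment(self, seed, delta_a=-0.3, lam=1.1, n=4000):
        spec = syn.LRAGeneratorSpec(
            delta_A=delta_a, lam=lam, n_samples=n, seed=seed, dt_ps=10.0,
        )
        return syn.generate_lra_gaps(spec)

    def test_identical_segments_zero_uncertainty(self):
        seg = self._segment(1)
        out = block_analysis([seg] * 5, equilibration_discard=0.0)
        assert out.uncertainties["delta_A0"] == 0.0
        assert out.n_blocks == 5

    def test_two_block_hand_arithmetic(self):
        # blocks with dA0 estimates a and b: mean (a+b)/2, 2*SEM = |a-b|/sqrt(2) * ...
        s1 = (make_series([0.7, 0.9]), make_series([-1.3, -1.5], state="final"))
        s2 = (make_series([0.5, 0.7]), make_series([-1.1, -1.3], state="final"))
        out = block_analysis([s1, s2], equilibration_discard=0.0)
        # per-block dA0: (0.8 - 1.4)/2 = -0.3 and (0.6 - 1.2)/2 = -0.3
        assert out.delta_A0 == pytest.approx(-0.3)
        # per-block estimates differ by 0: uncertainty 0
        assert out.uncertainties["delta_A0"] == pytest.approx(0.0, abs=1e-15)

    def test_two_value_uncertainty_formula(self):
        # dA0 block values -0.2 and -0.4: mean -0.3, 2*SEM = 0.2
        s1 = (make_series([0.9]* 2 + [0.9] * 0), make_series([-1.3, -1.3],
                                                             state="final"))
        s2 = (make_series([0.7, 0.7]), make_series([-1.5, -1.5], state="final"))
        out = block_analysis([s1, s2], equilibration_discard=0.0)
        assert out.delta_A0 == pytest.approx(-0.3)
        assert out.uncertainties["delta_A0"] == pytest.approx(0.2)

    def test_generator_blocks_recover_truth(self):
        segments = [self._segment(seed) for seed in range(5)]
        out = block_analysis(segments, equilibration_discard=2000.0)
        # block SEM is data-driven; truth must lie within ~3x SEM
        sem = out.uncertainties["delta_A0"] / 2.0
        assert abs(out.delta_A0 - (-0.3)) < 3 * max(sem, 1e-3)
        sem_l = out.uncertainties["lambda_St"] / 2.0
        assert abs(out.lambda_St - 1.1) < 3 * max(sem_l, 1e-3)

    def test_equilibration_discard_is_applied(self):
        ini, fin = self._segment(3)
        shifted = GapSeries(
            times=ini.times, gaps=ini.gaps + np.where(ini.times < 10_000, 5.0, 0.0),
            state="initial", temperature=ini.temperature,
        )
        out = block_analysis(
            [(shifted, fin), (shifted, fin)], equilibration_discard=10_000.0
        )
        clean = block_analysis(
            [(ini, fin), (ini, fin)], equilibration_discard=10_000.0
        )
        assert out.delta_A0 == pytest.approx(clean.delta_A0)

    def test_segment_shorter_than_discard_raises(self):
        seg = self._segment(4, n=100)  # 1000 ps long
        with pytest.raises(ValueError, match="discard"):
            block_analysis([seg, seg], equilibration_discard=20_000.0)


class TestDecomposition:
    def test_single_component_equals_total(self):
        comp = {"all": (1.0, 1.0)}
        spec = syn.LRAGeneratorSpec(delta_A=-0.3, lam=1.1, n_samples=2000,
                                    seed=7, components=comp)
        ini, fin = syn.generate_lra_gaps(spec)
        table = decompose_gap(ini, fin)
        assert table.loc["all", "delta_A0"] == pytest.approx(
            table.loc["total", "delta_A0"]
        )

    def test_contributions_sum_to_total(self):
        comp = {"TM": (0.5, 0.4), "env": (0.3, 0.35), "cof": (0.2, 0.25)}
        spec = syn.LRAGeneratorSpec(delta_A=-0.3, lam=1.1, n_samples=5000,
                                    seed=8, components=comp)
        ini, fin = syn.generate_lra_gaps(spec)
        table = decompose_gap(ini, fin)
        parts = table.drop(index="total")
        assert parts["delta_A0"].sum() == pytest.approx(
            table.loc["total", "delta_A0"], abs=1e-9
        )
        assert parts["lambda_St"].sum() == pytest.approx(
            table.loc["total", "lambda_St"], abs=1e-9
        )

    def test_component_free_energies_recovered(self):
        # free-energy contributions patterned on a membrane-protein balance:
        # protein core and membrane oppose transfer, water and ions drive it
        truth = {"TM": 1.52, "membrane": 0.60, "water": -0.27, "ions": -1.42,
                 "rest": -0.71}
        delta_a = sum(truth.values())  # -0.28 eV
        comp = {
            name: (value / delta_a, 0.2) for name, value in truth.items()
        }
        spec = syn.LRAGeneratorSpec(
            delta_A=delta_a, lam=1.04, n_samples=60_000, seed=9,
            components=comp,
        )
        ini, fin = syn.generate_lra_gaps(spec)
        table = decompose_gap(ini, fin)
        sigma2 = 2 * 0.2 * 1.04 * KB_EV * 310.0  # per-component variance
        se = math.sqrt(sigma2 / (2 * 60_000))
        for name, value in truth.items():
            assert abs(table.loc[name, "delta_A0"] - value) < 4 * se
            assert np.sign(table.loc[name, "delta_A0"]) == np.sign(value)

    def test_mismatched_component_sets_rejected(self):
        c1 = pd.DataFrame({"a": [1.0, 1.0]})
        c2 = pd.DataFrame({"b": [1.0, 1.0]})
        ini = make_series([1.0, 1.0], components=c1)
        fin = make_series([1.0, 1.0], state="final", components=c2)
        with pytest.raises(ValueError, match="component"):
            decompose_gap(ini, fin)


class TestInnerSphere:
    def test_reported_magnitude_case(self):
        e = InnerSphereEnergies(e_gR_O=0.05, e_gR_R=0.0, e_gO_R=0.05,
                                e_gO_O=0.0)
        assert inner_sphere_lambda(e) == pytest.approx(0.10)

    def test_all_equal_energies_give_zero(self):
        e = InnerSphereEnergies(0.3, 0.3, 0.3, 0.3)
        assert inner_sphere_lambda(e) == 0.0

    def test_two_parabola_closed_form(self):
        # identical harmonic wells (force constant k) displaced by d: each
        # state's relaxation energy is k d^2 / 2, and the two-cofactor
        # self-exchange total is their sum, k d^2
        k, d = 3.0, 0.4

        def e_red(x):
            return 0.5 * k * x**2

        def e_ox(x):
            return 0.5 * k * (x - d) ** 2 - 0.2  # arbitrary offset cancels

        e = InnerSphereEnergies(
            e_gR_O=e_ox(0.0), e_gR_R=e_red(0.0),
            e_gO_R=e_red(d), e_gO_O=e_ox(d),
        )
        assert inner_sphere_lambda(e) == pytest.approx(k * d**2)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            InnerSphereEnergies(e_gR_O=-0.1, e_gR_R=0.0, e_gO_R=0.05,
                                e_gO_O=0.0)

    def test_total_reorganization(self):
        assert total_reorganization(0.10, 1.04) == pytest.approx(1.14)
        assert total_reorganization(0.0, 0.9) == 0.9
        assert total_reorganization(0.3, 0.7) == total_reorganization(0.7, 0.3)
        with pytest.raises(ValueError):
            total_reorganization(-0.1, 1.0)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        out = running_average(np.full(10, 2.5), 4)
        assert np.allclose(out, 2.5)

    def test_window_one_is_identity(self):
        x = np.arange(6, dtype=float)
        assert np.array_equal(running_average(x, 1), x)

    def test_linear_ramp_interior_preserved(self):
        x = np.arange(20, dtype=float)
        out = running_average(x, 5)
        # centered mean of a linear ramp equals the center value
        assert np.allclose(out, x[2:-2])

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError):
            running_average(np.ones(3), 4)
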