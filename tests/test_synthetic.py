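"""The forward simulator: isotherms, mass balance, intensity model, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind.errors import ValidationError
from quenchbind.synthetic import (
    GroundTruth,
    PanelDesign,
    free_ligand,
    generate_panel,
    k_from_thermo,
    observe,
    site_occupancy,
    true_intensity,
    write_panel,
)
from quenchbind.thermodynamics import vant_hoff

from conftest import bisection_free_ligand


class TestSiteOccupancy:
    def test_zero_affinity_never_occupied(self):
        assert site_occupancy(0.0, 1e-3) == 0.0

    def test_half_saturation_at_reciprocal_affinity(self):
        assert site_occupancy(2.5e5, 1 / 2.5e5) == pytest.approx(0.5)

    def test_hand_evaluated_point(self):
        assert site_occupancy(1e6, 9e-6) == pytest.approx(0.9)

    @given(K=st.floats(0, 1e8), Q=st.floats(0, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, K, Q):
        assert 0.0 <= site_occupancy(K, Q) <= 1.0


class TestFreeLigand:
    def test_no_binding_returns_total(self):
        assert free_ligand(0.0, 0.0, 3e-6, 5e-6) == 5e-6

    def test_no_protein_returns_total(self):
        assert free_ligand(1e6, 1e5, 0.0, 5e-6) == 5e-6

    def test_worked_example_against_bisection(self):
        got = free_ligand(1e6, 0.0, 3e-6, 5e-6)
        assert got == pytest.approx(2.79e-6, rel=1e-2)
        assert got == pytest.approx(bisection_free_ligand(1e6, 0.0, 3e-6, 5e-6), rel=1e-12)

    def test_residual_below_tolerance_on_random_draws(self):
        """Mass-balance residual < 1e-12 * max(Q_total, 1e-9) on 100 draws."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            K1 = 10 ** rng.uniform(2, 7)
            K2 = K1 * rng.uniform(0.001, 0.99)
            P = 10 ** rng.uniform(-7, -5)
            Qt = 10 ** rng.uniform(-8, -4)
            qf = free_ligand(K1, K2, P, Qt)
            resid = qf + P * (site_occupancy(K1, qf) + site_occupancy(K2, qf)) - Qt
            assert abs(resid) < 1e-12 * max(Qt, 1e-9)
            assert qf == pytest.approx(bisection_free_ligand(K1, K2, P, Qt), rel=1e-9)


class TestTrueIntensity:
    def test_zero_quencher_returns_f0(self, noiseless_truth):
        assert true_intensity(noiseless_truth, 0.0, 298.15) == noiseless_truth.f0

    def test_saturating_single_site_halves_intensity(self):
        gt = GroundTruth(q1=0.5, q2=0.0, noise_cv=0.0)
        assert true_intensity(gt, 1.0, 298.15) == pytest.approx(gt.f0 / 2, rel=1e-4)

    def test_both_sites_saturated_additive_efficiencies(self):
        gt = GroundTruth(q1=0.6, q2=0.2, noise_cv=0.0)
        assert true_intensity(gt, 10.0, 298.15) == pytest.approx(0.2 * gt.f0, rel=1e-3)

    def test_monotone_nonincreasing_in_quencher(self, noiseless_truth):
        q = np.linspace(0, 2e-5, 60)
        f = [true_intensity(noiseless_truth, qi, 298.15) for qi in q]
        assert np.all(np.diff(f) <= 0)

    def test_stern_volmer_ratios_concave_downward(self, noiseless_truth):
        """Second differences of F0/F over an even grid are <= 0 for q2 < q1."""
        q = np.arange(0, 11) * 1e-6
        f = np.array([true_intensity(noiseless_truth, qi, 298.15) for qi in q])
        ratios = f[0] / f
        assert np.all(np.diff(ratios, 2) <= 1e-12)

    def test_thermo_consistency_exact_vant_hoff(self, noiseless_truth):
        """K1(T) from (dH1, dS1) is exactly Van't Hoff-linear: regression on
        noiseless constants returns the generator's inputs to machine precision."""
        temps = (288.15, 298.15, 308.15, 318.15)
        res = vant_hoff({T: noiseless_truth.k1_at(T) for T in temps})
        assert res.delta_H == pytest.approx(noiseless_truth.delta_H1, rel=1e-12)
        assert res.delta_S == pytest.approx(noiseless_truth.delta_S1, rel=1e-12)

    def test_reference_constants_hit_calibration(self, noiseless_truth):
        assert noiseless_truth.K1 == pytest.approx(5.9e5, rel=1e-12)
        assert noiseless_truth.K2 == pytest.approx(1.9e3, rel=1e-12)
        assert k_from_thermo(-47.4, noiseless_truth.delta_S1, 298.15) == pytest.approx(
            5.9e5, rel=1e-12
        )

    def test_exact_depletion_lowers_effective_quenching(self):
        free = GroundTruth(noise_cv=0.0)
        depleted = GroundTruth(noise_cv=0.0, ligand_depletion="exact")
        assert true_intensity(depleted, 2e-6, 298.15) > true_intensity(free, 2e-6, 298.15)


class TestObserve:
    def test_no_extinction_no_noise_is_identity(self):
        gt = GroundTruth(
            noise_cv=0.0, epsilon_ex=0.0, epsilon_em=0.0, baseline_ex=0.0
        )
        p = observe(gt, 123.0, 5e-6, np.random.default_rng(0))
        assert p.intensity == pytest.approx(123.0)

    def test_absorbances_attached(self):
        gt = GroundTruth(noise_cv=0.0)
        p = observe(gt, 100.0, 5e-6, np.random.default_rng(0))
        assert p.absorbance_ex == pytest.approx(gt.epsilon_ex * 5e-6 + gt.baseline_ex)
        assert p.absorbance_em == pytest.approx(gt.epsilon_em * 5e-6)


class TestGeneratePanel:
    def test_default_design_row_count(self, noiseless_panel):
        tit, absorb, _ = noiseless_panel
        assert len(tit) == 11 * 3 * 5
        assert len(absorb) == 11 * 3 * 5

    def test_same_seed_byte_identical_files(self, tmp_path):
        gt = GroundTruth(noise_cv=0.01, seed=42)
        p1 = write_panel(gt, out_dir=tmp_path / "a")
        p2 = write_panel(gt, out_dir=tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_changes_noise_not_grid(self):
        t1, _, _ = generate_panel(GroundTruth(seed=1))
        t2, _, _ = generate_panel(GroundTruth(seed=2))
        assert (t1["quencher_total_M"] == t2["quencher_total_M"]).all()
        assert not np.allclose(t1["intensity"], t2["intensity"])

    def test_adding_a_condition_does_not_perturb_others(self):
        full = PanelDesign()
        reduced = PanelDesign(conditions=("free", "hemin"))
        t_full, _, _ = generate_panel(GroundTruth(seed=3), full)
        t_red, _, _ = generate_panel(GroundTruth(seed=3), reduced)
        for cond in ("free", "hemin"):
            a = t_full[t_full.condition == cond]["intensity"].to_numpy()
            b = t_red[t_red.condition == cond]["intensity"].to_numpy()
            assert np.array_equal(a, b)

    def test_invalid_efficiencies_rejected(self):
        with pytest.raises(ValidationError):
            GroundTruth(q1=0.7, q2=0.5)

    def test_ground_truth_sidecar_carries_design(self, noiseless_panel):
        _, _, truth = noiseless_panel
        assert truth["design"]["conditions"][0] == "free"
        assert truth["K1_25C"] == pytest.approx(5.9e5)
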