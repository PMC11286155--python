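"""CSA protocol, force conversion, growth regression, force vectors."""

import numpy as np
import pytest

from cranioload import (
    CohortParams,
    MuscleConstants,
    SectioningProtocol,
    build_vectors,
    csa_asymmetry,
    csa_max,
    fit_growth,
    generate_csa_cohort,
    growth_curve,
    make_muscle_mask,
    peak_force,
    vectors_to_loads,
)
from cranioload.anatomy import MuscleMaskVolume
from cranioload.errors import (
    DegenerateDirectionError,
    DomainError,
    EmptySectionError,
    FitError,
)

from conftest import FORCES_48


class TestCsaMax:
    def test_elliptic_cylinder_analytic(self):
        vol = make_muscle_mask("elliptic_cylinder", (10.0, 5.0, 30.0), 0.25)
        area = csa_max(vol, SectioningProtocol(p1_offset_mm=10.0))
        assert area == pytest.approx(np.pi * 10 * 5 / 100.0, rel=0.02)

    def test_cone_two_plane_mean_matches_midpoint(self):
        # the area of a cone varies smoothly; the two-plane average equals
        # the area midway between P1 and P2 up to discretization + curvature
        vol = make_muscle_mask("cone", (12.0, 12.0, 40.0), 0.25)
        prot = SectioningProtocol(p1_offset_mm=19.0)
        expected = np.pi * 12.0**2 * (1 - 20.0 / 40.0) ** 2 / 100.0
        assert csa_max(vol, prot) == pytest.approx(expected, rel=0.01)

    def test_plane_missing_mask_raises(self):
        vol = make_muscle_mask("prism", (10.0, 10.0, 10.0), 0.5)
        with pytest.raises(EmptySectionError):
            csa_max(vol, SectioningProtocol(p1_offset_mm=200.0))

    def test_non_unit_normal_rejected(self):
        with pytest.raises(DomainError):
            SectioningProtocol(normal=(0.0, 0.0, 2.0))

    def test_p2_spacing_is_two_mm(self):
        prot = SectioningProtocol(p1_offset_mm=5.0)
        assert prot.p2_offset_mm - prot.p1_offset_mm == 2.0

    def test_translation_in_plane_invariance(self):
        vol = make_muscle_mask("elliptic_cylinder", (8.0, 4.0, 20.0), 0.25)
        shifted = MuscleMaskVolume(
            mask=np.pad(vol.mask, ((7, 0), (0, 0), (0, 0))), pitch=vol.pitch
        )
        prot = SectioningProtocol(p1_offset_mm=8.0)
        assert csa_max(vol, prot) == pytest.approx(csa_max(shifted, prot), rel=1e-9)

    def test_symmetric_mask_has_no_side_asymmetry(self):
        vol = make_muscle_mask("elliptic_cylinder", (8.0, 4.0, 20.0), 0.5)
        assert csa_asymmetry(vol, SectioningProtocol(p1_offset_mm=8.0)) < 0.05


class TestPeakForce:
    @pytest.mark.parametrize(
        "csa,expected", [(1.0, 37.0), (0.0, 0.0), (1.5, 55.5)]
    )
    def test_stress_factor_conversion(self, csa, expected):
        assert peak_force(csa) == pytest.approx(expected, abs=1e-12)

    def test_linearity(self):
        a, b = 0.7314, 1.2086
        assert peak_force(a + b) == pytest.approx(peak_force(a) + peak_force(b), abs=1e-9)

    def test_negative_csa(self):
        with pytest.raises(DomainError):
            peak_force(-0.1)

    def test_vector_count_validation(self):
        with pytest.raises(DomainError):
            MuscleConstants(vectors_per_side=0)
        with pytest.raises(DomainError):
            MuscleConstants(fascia_vectors_total=5)


class TestFitGrowth:
    def test_noise_free_recovery_exact(self, cohort_noisefree):
        model = fit_growth(cohort_noisefree, n_boot=0)
        params = CohortParams(cv=0.0)
        for m in ("temporalis", "masseter", "medial_pterygoid"):
            for age in (3, 6, 12, 24, 36, 48):
                truth = float(growth_curve(params, m)(age)) * 37.0
                assert model.predict(m, age) == pytest.approx(truth, rel=1e-6)

    def test_single_age_cohort_rejected(self, cohort_noisefree):
        one_age = cohort_noisefree[cohort_noisefree.age_months == 48.0]
        with pytest.raises(FitError):
            fit_growth(one_age, n_boot=0)

    def test_nonpositive_rows_counted(self, cohort_noisefree):
        bad = cohort_noisefree.copy()
        bad.loc[bad.index[:4], "csa_cm2"] = -1.0
        model = fit_growth(bad, n_boot=0)
        assert model.n_rejected == 4

    def test_bootstrap_bands_bracket_mean(self, cohort_default):
        model = fit_growth(cohort_default, n_boot=40, seed=5)
        frame = model.to_frame()
        ok = frame.dropna()
        assert len(ok) > 0
        assert (ok["ci_lo"] <= ok["mean_force_N"] + 1e-9).all()
        assert (ok["ci_hi"] >= ok["mean_force_N"] - 1e-9).all()

    def test_prediction_positive_and_monotone(self, growth_default):
        ages = np.linspace(0, 48, 33)
        for m in ("temporalis", "masseter", "medial_pterygoid"):
            f = growth_default.predict(m, ages)
            assert (f > 0).all()
            assert (np.diff(f) >= -1e-9).all()


class TestBuildVectors:
    def test_force_division_and_conservation(self, skull48):
        vs = build_vectors(skull48, dict(FORCES_48))
        for muscle, f_side in FORCES_48.items():
            for side in ("L", "R"):
                mags = [
                    v.magnitude for v in vs.vectors if v.tag == muscle and v.side == side
                ]
                assert len(mags) == 3
                assert mags[0] == pytest.approx(f_side / 3.0, abs=1e-12)
                assert sum(mags) == pytest.approx(f_side, abs=1e-9)

    def test_left_right_mirror(self, skull48):
        vs = build_vectors(skull48, dict(FORCES_48), include_fascia=True,
                           fascia_force_per_side=10.0)
        left = {(v.tag, v.index % 3): v for v in vs.vectors if v.side == "L"}
        right = {(v.tag, v.index % 3): v for v in vs.vectors if v.side == "R"}
        mirror = skull48.mirror_node_map()
        for v_l in left.values():
            twins = [
                v_r for v_r in right.values()
                if v_r.tag == v_l.tag
                and np.array_equal(
                    np.sort(mirror[v_l.nodes]), np.sort(np.asarray(v_r.nodes))
                )
            ]
            assert len(twins) == 1
            v_r = twins[0]
            assert v_r.magnitude == pytest.approx(v_l.magnitude, abs=1e-12)
            assert v_r.direction[0] == pytest.approx(-v_l.direction[0], abs=1e-12)
            assert np.allclose(v_r.direction[1:], v_l.direction[1:], atol=1e-12)

    def test_total_load_matches_vector_sum(self, skull48):
        vs = build_vectors(skull48, dict(FORCES_48))
        loads = vectors_to_loads(skull48, vs)
        expected = sum(v.magnitude * v.direction for v in vs.vectors)
        assert np.allclose(loads.sum(axis=0), expected, atol=1e-9)

    def test_degenerate_direction(self, skull48):
        import copy

        broken = copy.copy(skull48)
        broken.landmarks = skull48.landmarks.copy()
        broken.landmarks[3:6] = broken.landmarks[0:3]  # insertions == origins
        with pytest.raises(DegenerateDirectionError):
            build_vectors(broken, {"temporalis": 10.0})

    def test_fascia_eight_vector_variant_conserves_force(self, skull48):
        constants = MuscleConstants(fascia_vectors_total=8)
        vs = build_vectors(
            skull48, {}, constants, include_fascia=True, fascia_force_per_side=12.0
        )
        for side in ("L", "R"):
            assert vs.total("temporal_fascia", side) == pytest.approx(12.0, abs=1e-9)
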