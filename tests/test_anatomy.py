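"""Synthetic anatomy: surrogate meshes, suture schedule, cohort, masks."""

import numpy as np
import pandas as pd
import pytest

from cranioload import (
    CohortParams,
    SkullParams,
    SuturePatencySchedule,
    build_skull_mesh,
    default_schedule,
    generate_csa_cohort,
    growth_curve,
    make_muscle_mask,
)
from cranioload.anatomy import head_scale
from cranioload.errors import DomainError, ResolutionError
from cranioload.mesh import SUTURE_LABELS

from conftest import COARSE


class TestSkullMesh:
    def test_no_sutures_from_24_months(self):
        mesh = build_skull_mesh(SkullParams(age_months=24, **COARSE))
        assert int(mesh.is_suture().sum()) == 0

    def test_all_joint_classes_open_at_3_months(self):
        mesh = build_skull_mesh(SkullParams(age_months=3, **COARSE))
        present = set(mesh.region_names())
        assert {"facial_suture", "base_joint", "metopic", "coronal"} <= present

    def test_deterministic_rebuild(self):
        p = SkullParams(age_months=36, **COARSE)
        a, b = build_skull_mesh(p), build_skull_mesh(p)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.region, b.region)

    def test_default_element_count_band(self, skull48):
        # frozen from the first build of the calibrated default geometry
        assert 50_000 <= skull48.n_elements <= 80_000

    def test_mirror_symmetry_of_mesh_and_node_sets(self, skull48):
        m = skull48.mirror_node_map()
        assert np.allclose(skull48.nodes[m][:, 0], -skull48.nodes[:, 0])
        assert np.allclose(skull48.nodes[m][:, 1:], skull48.nodes[:, 1:])
        for left, right in [
            ("bite_molar_L", "bite_molar_R"),
            ("tmj_L", "tmj_R"),
            ("arch_mid_L", "arch_mid_R"),
            ("fascia_ori_L", "fascia_ori_R"),
        ]:
            assert np.array_equal(
                np.sort(m[skull48.node_sets[left]]), np.sort(skull48.node_sets[right])
            )

    def test_positive_volumes_and_single_labels(self, skull48):
        assert (skull48.volumes() > 0).all()
        assert skull48.region.shape == (skull48.n_elements,)

    def test_bite_points_inferior_anterior_to_tmj(self, skull48):
        bite = skull48.nodes[skull48.node_sets["bite_molar_L"]]
        tmj = skull48.nodes[skull48.node_sets["tmj_L"]]
        assert bite[:, 2].max() < tmj[:, 2].min()  # inferior
        assert bite[:, 1].min() > tmj[:, 1].max()  # anterior

    @pytest.mark.parametrize("ages", [(3, 12), (12, 24), (24, 48)])
    def test_monotone_growth_and_patency(self, ages):
        meshes = [build_skull_mesh(SkullParams(age_months=a, **COARSE)) for a in ages]
        for axis in range(3):
            spans = [np.ptp(m.nodes[:, axis]) for m in meshes]
            assert spans[0] <= spans[1] + 1e-9
        sut = [int(m.is_suture().sum()) for m in meshes]
        assert sut[0] >= sut[1]

    def test_age_out_of_domain(self):
        with pytest.raises(DomainError):
            build_skull_mesh(SkullParams(age_months=2.0))

    def test_pitch_too_coarse(self):
        with pytest.raises(ResolutionError):
            SkullParams(voxel_pitch=5.0, shell_thickness=7.0).validate()

    def test_schedule_must_be_monotone(self):
        with pytest.raises(DomainError):
            SuturePatencySchedule(stages={3: set(), 6: {"metopic"}})

    def test_default_schedule_monotone_and_complete(self):
        sched = default_schedule()
        assert sched.active(3) == frozenset(SUTURE_LABELS)
        assert sched.active(12) == frozenset({"anterior_fontanelle"})
        assert sched.active(48) == frozenset()

    def test_head_scale_monotone(self):
        ages = np.linspace(3, 48, 50)
        s = np.array([head_scale(a) for a in ages])
        assert (np.diff(s) >= 0).all() and 0.7 < s[0] < s[-1] == 1.0


class TestCohort:
    def test_zero_noise_lies_on_curve(self, cohort_noisefree):
        params = CohortParams(cv=0.0)
        for m, grp in cohort_noisefree.groupby("muscle"):
            expected = growth_curve(params, m)(grp["age_months"].to_numpy())
            assert np.allclose(grp["csa_cm2"].to_numpy(), expected, rtol=1e-12)

    def test_temporalis_anchor_is_printed_force_over_stress_factor(self):
        cohort = generate_csa_cohort(CohortParams(cv=0.0))
        at48 = cohort[(cohort.muscle == "temporalis") & (cohort.age_months == 48.0)]
        assert at48["csa_cm2"].iloc[0] == pytest.approx(87.0 / 37.0, rel=1e-12)

    def test_same_seed_reproduces_table(self):
        a = generate_csa_cohort(CohortParams(seed=7))
        b = generate_csa_cohort(CohortParams(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_noise_perturbs_but_preserves_scale(self, cohort_default, cohort_noisefree):
        merged = cohort_default.merge(
            cohort_noisefree, on=["individual_id", "muscle"], suffixes=("", "_clean")
        )
        ratio = merged["csa_cm2"] / merged["csa_cm2_clean"]
        assert ratio.std() == pytest.approx(0.10, abs=0.03)
        assert ratio.mean() == pytest.approx(1.0, abs=0.03)

    def test_invalid_params(self):
        with pytest.raises(DomainError):
            CohortParams(n=1).validate()
        with pytest.raises(DomainError):
            CohortParams(cv=-0.1).validate()


class TestMuscleMasks:
    def test_elliptic_cylinder_slice_area(self):
        vol = make_muscle_mask("elliptic_cylinder", (10.0, 5.0, 30.0), 0.25)
        areas = vol.mask.sum(axis=(0, 1)) * vol.pitch[0] * vol.pitch[1]
        mid = areas[areas > 0]
        assert np.allclose(mid, np.pi * 10 * 5, rtol=0.02)

    def test_prism_slice_area_exact_to_voxel_ring(self):
        vol = make_muscle_mask("prism", (10.0, 10.0, 12.0), 0.5)
        areas = vol.mask.sum(axis=(0, 1)) * vol.pitch[0] * vol.pitch[1]
        ring = 4 * 10 * 0.5  # one boundary voxel ring
        assert np.all(np.abs(areas[areas > 0] - 100.0) <= ring)

    def test_pitch_larger_than_smallest_dim(self):
        with pytest.raises(DomainError):
            make_muscle_mask("elliptic_cylinder", (10.0, 5.0, 30.0), pitch=6.0)

    def test_unknown_shape(self):
        with pytest.raises(DomainError):
            make_muscle_mask("torus", (5, 5, 5), 0.5)
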