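"""Generator contracts: nesting, determinism, calibration, longitudinal pairs."""

import numpy as np
import pytest

from izmap.regions import area_mm2, percent_overlap
from izmap.synthetic import (
    GROUP_TARGETS,
    LongitudinalParams,
    SceneParams,
    generate_cohort,
    generate_longitudinal,
    generate_scene,
    invert_field,
    longitudinal_scene_params,
    sample_positive,
    sample_truth,
)

SCALE = 3 / 304


class TestSceneGeneration:
    def test_zero_area_targets_give_empty_truth_and_flat_slab(self):
        p = SceneParams(
            target_areas_mm2={"attn": (0, 0), "izloss": (0, 0), "ezloss": (0, 0)},
            telangiectasia_area_mm2=(0, 0),
            overlap_fractions={"attn": (0, 0), "izloss": (0, 0), "ezloss": (0, 0)},
            noise_level=0.0,
            seed=3,
        )
        scene = generate_scene(p)
        t = scene.truth
        assert not t.region_combined_A.any()
        assert not t.telangiectasia.any()
        # slab has no depressed region: constant at baseline level
        assert np.unique(scene.slab.data).size == 1

    def test_nesting_holds_for_every_group(self):
        for group in GROUP_TARGETS:
            t = sample_truth(SceneParams(stage_group=group, seed=21))
            assert (t.region_ez_C <= t.region_combined_B).all()
            assert (t.region_combined_B <= t.region_combined_A).all()

    def test_same_seed_is_bit_identical(self):
        a = generate_scene(SceneParams(stage_group="advanced", seed=9))
        b = generate_scene(SceneParams(stage_group="advanced", seed=9))
        assert np.array_equal(a.dcp.data, b.dcp.data)
        assert np.array_equal(a.scp.data, b.scp.data)
        assert np.array_equal(a.slab.data, b.slab.data)
        assert np.array_equal(a.truth.telangiectasia, b.truth.telangiectasia)

    def test_slab_depressions_are_ordered_and_exceed_speckle(self):
        scene = generate_scene(SceneParams(stage_group="advanced", seed=5, noise_level=0.15))
        t = scene.truth
        slab = scene.slab.data
        outside = ~t.region_combined_A
        m_out = slab[outside].mean()
        m_attn = slab[t.attn_only].mean()
        m_iz = slab[t.izloss_only].mean()
        m_ez = slab[t.region_ez_C].mean()
        assert m_out > m_attn > m_iz > m_ez
        speckle_sd = slab[outside].std()
        assert m_out - m_attn > speckle_sd

    def test_advanced_group_mean_areas_converge_to_targets(self):
        # 200 seeds of truth sampling; compare to the configured means
        # within twice the configured standard error
        tels, ezs = [], []
        for s in range(200):
            t = sample_truth(SceneParams(stage_group="advanced", seed=60000 + s))
            tels.append(area_mm2(t.telangiectasia, SCALE))
            ezs.append(area_mm2(t.region_ez_C, SCALE))
        for vals, (mean, sd) in [(tels, GROUP_TARGETS["advanced"]["tel"]),
                                 (ezs, GROUP_TARGETS["advanced"]["ezloss"])]:
            se = sd / np.sqrt(len(vals))
            assert abs(np.mean(vals) - mean) < 2 * se

    def test_excessive_targets_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SceneParams(target_areas_mm2={"attn": (10.0, 0), "izloss": (0, 0), "ezloss": (0, 0)}).resolved()

    def test_moment_matched_sampler_hits_target_mean(self, rng):
        draws = [sample_positive(rng, 0.15, 0.149) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.15, abs=3 * 0.149 / np.sqrt(4000))


class TestLongitudinal:
    def test_identity_pair_reproduces_baseline_exactly(self):
        base = generate_scene(longitudinal_scene_params(3, grid_size=128))
        pair = generate_longitudinal(
            base,
            LongitudinalParams(
                deformation_amplitude_px=0,
                new_ez_area_mm2=(0, 0),
                recovery_area_mm2=(0, 0),
                seed=3,
            ),
        )
        assert np.array_equal(pair.followup.truth.region_ez_C, base.truth.region_ez_C)
        assert not pair.new_ez_truth.any() and not pair.recovery_truth.any()

    def test_full_containment_places_all_new_loss_in_iz_class(self):
        base = generate_scene(longitudinal_scene_params(4, grid_size=160))
        pair = generate_longitudinal(
            base,
            LongitudinalParams(containment_range=(1.0, 1.0), deformation_amplitude_px=0, seed=4),
        )
        iz_only = base.truth.izloss_only
        assert (pair.new_ez_truth <= iz_only).all()

    def test_new_loss_mean_area_converges(self):
        base = generate_scene(longitudinal_scene_params(7, grid_size=160))
        areas = []
        scale = base.scp.scale_mm_per_px
        for s in range(100):
            pair = generate_longitudinal(base, LongitudinalParams(seed=70000 + s))
            areas.append(area_mm2(pair.new_ez_truth, scale))
        se = 0.022 / np.sqrt(len(areas))
        assert abs(np.mean(areas) - 0.052) < 2.5 * se

    def test_warp_roundtrip_recovers_mask(self):
        base = generate_scene(longitudinal_scene_params(8, grid_size=160))
        pair = generate_longitudinal(
            base,
            LongitudinalParams(new_ez_area_mm2=(0, 0), recovery_area_mm2=(0, 0), seed=8),
        )
        from izmap.longitudinal import warp_mask

        # without EZ change, mapping the follow-up EZ back through the true
        # inverse field must reproduce the baseline EZ up to resampling
        back = warp_mask(pair.followup.truth.region_ez_C, pair.true_field)
        ref = base.truth.region_ez_C
        agree = np.count_nonzero(back == ref) / ref.size
        assert agree >= 0.99

    def test_inverse_field_is_numerical_inverse(self, rng):
        from izmap.synthetic import _smooth_displacement
        from izmap.longitudinal import warp_mask

        n = 128
        e = _smooth_displacement(rng, n, amplitude=3.0)
        inv = invert_field(e)
        mask = np.zeros((n, n), dtype=bool)
        mask[40:90, 30:100] = True
        # warp with e then with its inverse: >= 99% agreement
        m1 = warp_mask(mask, e)
        m2 = warp_mask(m1, inv)
        agree = np.count_nonzero(m2 == mask) / mask.size
        assert agree >= 0.99

    def test_impossible_containment_raises(self):
        base = generate_scene(
            SceneParams(
                grid_size=128,
                target_areas_mm2={"attn": (0.3, 0), "izloss": (0.001, 0), "ezloss": (0.05, 0)},
                telangiectasia_area_mm2=(0.05, 0),
                seed=2,
            )
        )
        with pytest.raises(ValueError, match="containment"):
            generate_longitudinal(
                base,
                LongitudinalParams(
                    containment_range=(1.0, 1.0), new_ez_area_mm2=(0.5, 0), seed=2
                ),
            )


class TestCohort:
    def test_minimal_cohort_spans_three_groups(self):
        eyes = generate_cohort(1, seed=0)
        assert len(eyes) == 3
        assert {e.pooled_group for e in eyes} == {"early", "moderate", "advanced"}

    def test_two_eyes_of_one_patient_share_patient_id(self):
        eyes = generate_cohort(10, seed=1)
        by_patient = {}
        for e in eyes:
            by_patient.setdefault(e.patient_id, []).append(e)
        assert all(len(v) <= 2 for v in by_patient.values())
        assert any(len(v) == 2 for v in by_patient.values())
        for v in by_patient.values():
            if len(v) == 2:
                assert v[0].laterality != v[1].laterality

    def test_cohort_is_reproducible(self):
        a = generate_cohort(5, seed=3)
        b = generate_cohort(5, seed=3)
        assert [(e.patient_id, e.stage, e.params.seed) for e in a] == [
            (e.patient_id, e.stage, e.params.seed) for e in b
        ]

    def test_stages_consistent_with_pooled_group(self):
        from izmap.stats import pool_stage

        for e in generate_cohort(8, seed=5):
            assert pool_stage(e.stage) == e.pooled_group
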