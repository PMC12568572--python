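"""Synthetic scene generator: trees, rendering, cohorts, and their truth."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from retinavasc.simulate import (
    CohortSpec,
    DiscSpec,
    TreeSpec,
    build_scene,
    draw_cohort_parameters,
    generate_cohort,
    generate_tree,
    render_fundus,
)

DISC = DiscSpec(center=(512.0, 512.0))


def make_tree(**kw):
    spec = TreeSpec(**kw)
    return generate_tree(spec, DISC, kind="artery", root_angle_deg=200.0)


class TestTreeSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"trunk_caliber_artery": 16.0, "trunk_caliber_vein": 15.0},
            {"trunk_caliber_artery": -1.0, "trunk_caliber_vein": 2.0},
            {"depth": 0},
            {"branch_angle_mean": 0.0},
            {"branch_angle_mean": 185.0},
            {"tortuosity_wavelength": 0.0},
            {"split_ratio": 0.0},
            {"segment_taper": 1.2},
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            TreeSpec(**kw)

    def test_invalid_disc_rejected(self):
        with pytest.raises(ValueError):
            DiscSpec(disc_radius=40.0, cup_radius=50.0)
        with pytest.raises(ValueError):
            DiscSpec(pixel_pitch=0.0)


class TestGenerateTree:
    def test_zero_amplitude_gives_exactly_straight_segments(self):
        g = make_tree(tortuosity_amplitude=0.0, seed=1)
        assert len(g.segment_truth) > 0
        for rec in g.segment_truth.values():
            assert rec["tortuosity"] == 0.0
        for s in g.segments:
            # all points collinear with the chord
            v = s.points[-1] - s.points[0]
            rel = s.points - s.points[0]
            cross = np.abs(v[0] * rel[:, 1] - v[1] * rel[:, 0])
            assert cross.max() / max(np.linalg.norm(v), 1e-9) < 1e-9

    def test_murray_symmetric_split_matches_numeric_root(self):
        # independent oracle: solve w_p^3 = 2 w_c^3 for w_p = 8
        w_c = brentq(lambda w: 8.0**3 - 2.0 * w**3, 1.0, 8.0)
        assert w_c == pytest.approx(6.3496, abs=1e-4)
        g = make_tree(
            trunk_caliber_artery=8.0,
            trunk_caliber_vein=8.0,
            split_ratio=1.0,
            segment_taper=1.0,
            depth=2,
            branch_angle_sd=0.0,
            seed=2,
        )
        daughters = [s for s in g.segments if s.nodes[0] != 0]
        assert len(daughters) == 2
        for s in daughters:
            assert 2.0 * s.radii[0] == pytest.approx(w_c, rel=1e-9)

    def test_murray_conservation_at_every_bifurcation(self):
        spec = TreeSpec(seed=3)
        g = generate_tree(spec, DISC, kind="vein", root_angle_deg=140.0)
        e = spec.taper_exponent
        for node in g.bifurcations():
            inc = g.incident_segments(node.id)
            parent = [s for s in inc if s.nodes[1] == node.id]
            children = [s for s in inc if s.nodes[0] == node.id]
            assert len(parent) == 1 and len(children) == 2
            w_p = 2.0 * parent[0].radii[-1]
            resid = abs(w_p**e - sum((2.0 * c.radii[0]) ** e for c in children))
            assert resid < 1e-6

    def test_degenerate_angle_distribution_without_radial_bias(self):
        g = make_tree(branch_angle_mean=60.0, branch_angle_sd=0.0, radial_bias=0.0, seed=4)
        assert len(g.branch_truth) > 0
        for rec in g.branch_truth.values():
            assert rec["angle_deg"] == pytest.approx(60.0, abs=1e-9)

    def test_recorded_angles_match_daughter_chord_directions(self):
        g = make_tree(seed=5)
        for nid, rec in g.branch_truth.items():
            children = [s for s in g.segments if s.nodes[0] == nid]
            assert len(children) == 2
            dirs = []
            for s in children:
                v = s.points[-1] - s.points[0]
                dirs.append(v / np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(np.dot(dirs[0], dirs[1]), -1, 1)))
            assert ang == pytest.approx(rec["angle_deg"], abs=1e-9)

    def test_frame_escape_truncates_and_excludes(self):
        # a disc close to the aperture edge forces truncation
        disc = DiscSpec(center=(220.0, 512.0))
        spec = TreeSpec(seed=6, depth=6)
        g = generate_tree(spec, disc, kind="artery", root_angle_deg=180.0)
        excluded = [s for s in g.segments if s.excluded]
        assert excluded, "expected at least one truncated segment"
        assert all(s.id not in g.segment_truth for s in excluded)


class TestRenderFundus:
    def test_constant_radius_mask_matches_distance_oracle(self):
        from retinavasc.graph import Node, Segment, VesselGraph

        pts = np.column_stack([np.linspace(300.0, 700.0, 401), np.full(401, 512.0)])
        g = VesselGraph(
            nodes=[Node(0, (300.0, 512.0), 1, "endpoint"), Node(1, (700.0, 512.0), 1, "endpoint")],
            segments=[Segment(0, pts, np.full(401, 4.0), "artery", (0, 1))],
        )
        _, truth = render_fundus([g], DISC, noise_level=0.0, seed=0)
        yy, xx = np.mgrid[0:1024, 0:1024]
        # brute force: pixel centers within distance 4 of the centerline segment
        t = np.clip((xx - 300.0) / 400.0, 0, 1)
        d2 = (xx - (300.0 + 400.0 * t)) ** 2 + (yy - 512.0) ** 2
        oracle = d2 <= 16.0
        assert np.array_equal(truth.vessel_mask, oracle)

    def test_truth_masks_independent_of_noise_seed(self):
        tree = make_tree(seed=7)
        _, t1 = render_fundus([tree], DISC, noise_level=0.05, seed=1)
        img2, t2 = render_fundus([tree], DISC, noise_level=0.05, seed=2)
        img1, _ = render_fundus([tree], DISC, noise_level=0.05, seed=1)
        assert np.array_equal(t1.vessel_mask, t2.vessel_mask)
        assert np.array_equal(t1.artery_mask, t2.artery_mask)
        img3, _ = render_fundus([tree], DISC, noise_level=0.05, seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(img2.pixels, img3.pixels)

    def test_vein_only_scene_has_empty_artery_mask(self):
        spec = TreeSpec(seed=8)
        vein = generate_tree(spec, DISC, kind="vein", root_angle_deg=220.0)
        _, truth = render_fundus([vein], DISC, noise_level=0.0, seed=0)
        assert not truth.artery_mask.any()
        assert truth.vein_mask.sum() == truth.vessel_mask.sum()

    def test_zero_radius_segment_rejected(self):
        tree = make_tree(seed=9)
        tree.segments[0].radii[3] = 0.0
        with pytest.raises(ValueError, match="zero-radius"):
            render_fundus([tree], DISC, noise_level=0.0, seed=0)

    def test_empty_tree_list_rejected(self):
        with pytest.raises(ValueError):
            render_fundus([], DISC)

    def test_truth_invariants(self, scene0):
        _, truth = scene0
        truth.validate()
        # every non-excluded centerline point lies inside the vessel mask
        for s in truth.graph.segments:
            if s.excluded:
                continue
            xs = np.round(s.points[:, 0]).astype(int)
            ys = np.round(s.points[:, 1]).astype(int)
            assert truth.vessel_mask[ys, xs].all()


class TestCohort:
    def test_scene_determinism(self):
        a = build_scene(TreeSpec(seed=11), DISC, seed=11)
        b = build_scene(TreeSpec(seed=11), DISC, seed=11)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].vessel_mask, b[1].vessel_mask)
        assert a[1].graph.to_json() == b[1].graph.to_json()

    def test_both_eyes_share_subject_covariates(self):
        df = draw_cohort_parameters(CohortSpec(n_per_group=10, seed=1))
        assert len(df) == 40  # 2 groups x 10 subjects x 2 eyes
        per_subj = df.groupby("subject_id")[["age", "sex", "axl_mm", "group"]].nunique()
        assert (per_subj == 1).all().all()

    def test_single_eye_mode(self):
        df = draw_cohort_parameters(CohortSpec(n_per_group=5, eyes_per_subject=1, seed=1))
        assert len(df) == 10
        assert set(df["eye"]) == {"OD"}

    def test_caliber_offset_recovered_over_replicates(self):
        # Monte-Carlo oracle: the generated HLC-LLC true-caliber difference,
        # adjusted for the axial-length confound, recenters on the injected
        # -4 um offset over many replicates
        diffs = []
        spec = CohortSpec(n_per_group=40)
        for s in range(60):
            df = draw_cohort_parameters(dataclasses.replace(spec, seed=s))
            d = df.groupby("group")["vc_true_um"].mean()
            a = df.groupby("group")["axl_mm"].mean()
            slope = spec.vc_axl_slope_um_per_mm
            diffs.append((d["HLC"] - d["LLC"]) - slope * (a["HLC"] - a["LLC"]))
        mean_diff = np.mean(diffs)
        sem = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean_diff - (-4.0)) < 3 * sem + 0.3

    def test_zero_effects_give_matched_groups(self):
        spec = CohortSpec(
            n_per_group=200,
            group_effects={k: 0.0 for k in ("caliber_um", "branch_angle_deg", "disc_area_mm2", "cup_area_mm2")},
            covariate_dists={
                g: {"age_mean": 8.4, "age_sd": 0.5, "male_prop": 0.5, "axl_mean": 23.0, "axl_sd": 1.0}
                for g in ("HLC", "LLC")
            },
            seed=2,
        )
        df = draw_cohort_parameters(spec)
        d = df.groupby("group")["vba_true_deg"].mean()
        assert abs(d["HLC"] - d["LLC"]) < 1.5

    def test_generate_cohort_render_false_returns_table_only(self):
        imgs, truths, df = generate_cohort(CohortSpec(n_per_group=2, seed=3), render=False)
        assert imgs == [] and truths == []
        assert len(df) == 8

    def test_cohort_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group=1)
        with pytest.raises(ValueError):
            CohortSpec(eyes_per_subject=3)
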