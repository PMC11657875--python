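import numpy as np
import pytest

from spinemorph import synth
from spinemorph.io import PlaneOutline, SpineAnnotation, SpineSkeleton
from spinemorph.morphometry import (
    MorphometryError,
    WidthProfile,
    arc_length_3d,
    compute_descriptors,
    compute_width_profile,
    polyline_samples,
)
from tests.conftest import raster_chord_oracle


def straight_annotation(width_fn, length=2000.0, spine_id="s", labels=None):
    """Spine along +x in one plane with an explicit top/bottom outline."""
    xs = np.linspace(-5.0, length + 5.0, 200)
    half = np.array([width_fn(x) / 2.0 for x in xs])
    vertices = np.vstack(
        [np.column_stack([xs, half]), np.column_stack([xs, -half])[::-1]]
    )
    n_nodes = max(2, int(length // 200) + 1)
    nodes = np.column_stack(
        [np.linspace(0, length, n_nodes), np.zeros(n_nodes), np.zeros(n_nodes)]
    )
    if labels is None:
        labels = ["unlabeled"] * n_nodes
    skel = SpineSkeleton(nodes=nodes, region_labels=labels, spine_id=spine_id)
    return SpineAnnotation(
        skeleton=skel, outlines=[PlaneOutline(z=0.0, vertices=vertices)]
    )


class TestArcLength:
    def test_in_plane(self):
        assert arc_length_3d(np.array([[0, 0, 0], [400, 0, 0]])) == pytest.approx(400)

    def test_3_4_5_across_planes(self):
        assert arc_length_3d(np.array([[0, 0, 0], [400, 0, 300]])) == pytest.approx(500)

    def test_refinement_convergence(self):
        t_coarse = np.linspace(0, np.pi, 20)
        t_fine = np.linspace(0, np.pi, 400)
        curve = lambda t: np.column_stack(
            [1000 * np.cos(t), 1000 * np.sin(t), np.zeros_like(t)]
        )
        coarse = arc_length_3d(curve(t_coarse))
        fine = arc_length_3d(curve(t_fine))
        assert abs(fine - coarse) / fine < 0.01


class TestComputeWidthProfile:
    def test_constant_cylinder(self):
        ann = straight_annotation(lambda x: 400.0, length=2000.0)
        profile = compute_width_profile(ann)
        assert 95 <= len(profile.s) <= 105
        np.testing.assert_allclose(profile.d, 400.0, atol=0.5)

    def test_linear_cone(self):
        # width 600 at s=0 tapering to 0 at s=2000; skeleton stops at 1900
        ann = straight_annotation(
            lambda x: max(1.0, 600.0 * (1 - x / 2000.0)), length=1900.0
        )
        profile = compute_width_profile(ann)
        d_mid = profile.d[np.argmin(np.abs(profile.s - 1000.0))]
        assert d_mid == pytest.approx(300.0, abs=10.0)

    def test_skeleton_outside_outline_errors(self):
        ann = straight_annotation(lambda x: 300.0, length=1000.0)
        ann.skeleton.nodes[:, 1] += 500.0  # shift skeleton off the ribbon
        ann.outlines[0].vertices[:, 1] += 0.0
        with pytest.raises(MorphometryError, match="outside its outline"):
            compute_width_profile(ann)

    def test_missing_plane_errors(self):
        ann = straight_annotation(lambda x: 300.0, length=1000.0)
        ann.outlines[0].z = 0.0
        ann.skeleton.nodes[:, 2] = 600.0  # nodes on a plane with no outline
        with pytest.raises(MorphometryError, match="no outline"):
            compute_width_profile(ann)

    def test_incomplete_spine_rejected(self):
        ann = straight_annotation(lambda x: 300.0, length=1000.0)
        ann.complete = False
        with pytest.raises(MorphometryError, match="excluded"):
            compute_width_profile(ann)

    def test_sample_spacing_bounded(self, archetypes, rng):
        for a in archetypes:
            ann = synth.sample_spine(a, rng)
            profile = compute_width_profile(ann, step_nm=20.0)
            assert np.all(np.diff(profile.s) <= 1.5 * 20.0)

    def test_matches_rasterization_oracle(self, archetypes, rng):
        for a in archetypes:
            for _ in range(3):
                ann = synth.sample_spine(a, rng)
                profile = compute_width_profile(ann)
                s, points, tangents = polyline_samples(ann.skeleton.nodes)
                zs = np.array([o.z for o in ann.outlines])
                for k in range(len(s)):
                    if not profile.measured[k]:
                        continue
                    iz = int(np.argmin(np.abs(zs - points[k, 2])))
                    normal = np.array([-tangents[k, 1], tangents[k, 0]])
                    oracle = raster_chord_oracle(
                        ann.outlines[iz].vertices, points[k, :2], normal
                    )
                    assert oracle is not None
                    assert abs(profile.d[k] - oracle) <= 2.0


class TestRegions:
    def test_nearest_labelled_node(self):
        labels = ["unlabeled", "neck", "neck", "head", "head"]
        ann = straight_annotation(lambda x: 300.0, length=800.0, labels=labels)
        profile = compute_width_profile(ann)
        # node arcs at 0,200,...,800; neck nodes at 200/400, head at 600/800
        assert profile.region[0] == "neck"  # nearest labelled node is at 200
        assert profile.region[-1] == "head"
        switch = profile.s[np.argmax(profile.region == "head")]
        assert 400 < switch <= 520

    def test_no_labels_gives_other(self):
        ann = straight_annotation(lambda x: 300.0, length=800.0)
        profile = compute_width_profile(ann)
        assert set(profile.region) == {"other"}


class TestDescriptors:
    def make_profile(self, s, d, region):
        return WidthProfile(
            s=np.asarray(s, float),
            d=np.asarray(d, float),
            region=np.asarray(region, dtype=object),
            spine_id="p",
        )

    def test_constant_profile(self):
        s = np.arange(0.0, 2001.0, 20.0)
        region = np.where(s < 1000, "neck", "head")
        desc = compute_descriptors(self.make_profile(s, np.full(len(s), 400.0), region))
        assert desc.spine_area == pytest.approx(800_000.0)
        assert desc.cv_spine == pytest.approx(0.0)
        assert desc.head_neck_ratio == pytest.approx(1.0)
        assert desc.spine_length == pytest.approx(2000.0)

    def test_min_max_selection(self):
        s = np.arange(0.0, 6 * 20.0, 20.0)
        d = [120, 100, 140, 350, 400, 380]
        region = ["neck"] * 3 + ["head"] * 3
        desc = compute_descriptors(self.make_profile(s, d, region))
        assert desc.neck_diameter == 100
        assert desc.head_diameter == 400
        assert desc.head_neck_ratio == pytest.approx(4.0)

    def test_triangular_area(self):
        s = np.arange(0.0, 2000.0 + 1, 20.0)
        d = np.maximum(600.0 * (1 - s / 2000.0), 1e-9) + 1e-9
        desc = compute_descriptors(
            self.make_profile(s, d, ["other"] * len(s))
        )
        assert desc.spine_area == pytest.approx(600_000.0, rel=0.01)

    def test_missing_regions_flagged(self):
        s = np.arange(0.0, 200.0, 20.0)
        desc = compute_descriptors(
            self.make_profile(s, np.full(len(s), 300.0), ["other"] * len(s))
        )
        assert np.isnan(desc.neck_diameter)
        assert np.isnan(desc.head_diameter)
        assert np.isnan(desc.cv_head)
        assert np.isfinite(desc.spine_area)
        assert np.isfinite(desc.cv_spine)

    def test_region_additivity(self, archetypes, rng):
        # neck/head cover every sample on generator spines (nearest labelled
        # node tagging) -> areas partition exactly
        for a in archetypes:
            ann = synth.sample_spine(a, rng)
            profile = compute_width_profile(ann)
            desc = compute_descriptors(profile)
            assert desc.neck_area + desc.head_area == pytest.approx(
                desc.spine_area, rel=1e-9
            )


class TestScalingProperty:
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_outline_scaling(self, c):
        widths = lambda x: 300.0 + 100.0 * np.sin(x / 300.0)
        ann = straight_annotation(widths, length=1500.0,
                                  labels=None)
        base = compute_width_profile(ann)
        scaled_ann = straight_annotation(lambda x: c * widths(x), length=1500.0)
        scaled = compute_width_profile(scaled_ann)
        np.testing.assert_allclose(scaled.d, c * base.d, rtol=1e-6)
        db = compute_descriptors(base)
        ds = compute_descriptors(scaled)
        assert ds.spine_area == pytest.approx(c * db.spine_area, rel=1e-6)
        assert ds.cv_spine == pytest.approx(db.cv_spine, rel=1e-6)
        assert ds.spine_length == pytest.approx(db.spine_length)


class TestDescriptorOracle:
    def test_straight_noise_free_matches_template(self, archetypes, rng):
        # straight single-plane spines: descriptors computed from the
        # measured profile must match values computed directly from the
        # archetype template
        grid = np.linspace(0, 1, 100)
        for a in archetypes:
            ann = synth.sample_spine(a, rng, noise_cv=0.0, straight=True)
            profile = compute_width_profile(ann)
            desc = compute_descriptors(profile)
            length = ann.notes["true_length_nm"]
            assert desc.spine_length == pytest.approx(length, rel=1e-6)
            fine_u = np.linspace(0, 1, 4000)
            area_oracle = np.trapezoid(a.diameter_at(fine_u), fine_u * length)
            assert desc.spine_area == pytest.approx(area_oracle, rel=0.02)
            head = grid >= a.head_span[0]
            assert desc.head_diameter == pytest.approx(
                a.template_profile[head].max(), rel=0.02
            )
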