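"""Systematic field placement and counting-frame geometry."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from nervestereo import (
    DesignError,
    SamplingDesign,
    attach_reference_areas,
    em_design,
    frame_reference_area,
    lm_design,
    make_frames,
    place_fields,
)
from nervestereo.synthetic import generate_section

from conftest import tiny_phenotype


@pytest.fixture(scope="module")
def nerve100():
    return generate_section(tiny_phenotype(50), nerve_radius=100.0, seed=2)


class TestPlaceFields:
    def test_requested_number_of_fields(self, nerve100):
        design = SamplingDesign("LM", 4, 60.0, 60.0, 2, 10.0)
        fields = place_fields(nerve100, design, seed=7)
        assert len(fields) == 4
        for f in fields:
            assert f.intersects_disk(0.0, 0.0, 100.0)

    def test_pairwise_spacing_at_least_field_size(self, nerve100):
        design = SamplingDesign("LM", 4, 60.0, 60.0, 2, 10.0)
        for seed in range(10):
            fields = place_fields(nerve100, design, seed=seed)
            for i, a in enumerate(fields):
                for b in fields[i + 1:]:
                    dist = math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
                    assert dist >= 60.0 - 1e-9

    def test_single_field(self, nerve100):
        fields = place_fields(nerve100, SamplingDesign("LM", 1, 60.0, 60.0, 2, 10.0))
        assert len(fields) == 1

    def test_too_many_fields_is_design_error(self, nerve100):
        design = SamplingDesign("EM", 10_000, 12.2, 16.2, 1)
        with pytest.raises(DesignError):
            place_fields(nerve100, design, seed=0)

    def test_determinism(self, nerve100):
        design = lm_design(n_fields=10, placement_seed=99)
        a = place_fields(nerve100, design)
        b = place_fields(nerve100, design)
        assert a == b

    def test_uniform_coverage_of_interior_points(self):
        """Unbiasedness precondition: over many placements, a fixed point is
        covered by the LM frames with probability equal to the expected
        sampled-area fraction of the nerve."""
        section = generate_section(tiny_phenotype(1), nerve_radius=160.0, seed=0)
        design = lm_design()
        points = np.array([[0.0, 0.0], [50.0, -30.0], [-80.0, 60.0]])
        n_seeds = 1000
        hits = np.zeros(len(points))
        sampled_fraction = 0.0
        for seed in range(n_seeds):
            fields = place_fields(section, design, seed=seed)
            frames = attach_reference_areas(make_frames(fields, design), section)
            sampled_fraction += sum(f.reference_area for f in frames)
            for k, (px, py) in enumerate(points):
                if any(f.contains(px, py) for f in frames):
                    hits[k] += 1
        expected = sampled_fraction / n_seeds / section.cross_sectional_area
        se = math.sqrt(expected * (1 - expected) / n_seeds)
        for k in range(len(points)):
            assert abs(hits[k] / n_seeds - expected) < 3.5 * se


class TestMakeFrames:
    def test_em_frame_matches_screen_area(self):
        design = em_design(n_fields=1)
        section = generate_section(tiny_phenotype(1), nerve_radius=50.0, seed=0)
        fields = place_fields(section, design, seed=0)
        frames = make_frames(fields, design)
        assert len(frames) == 1
        assert frames[0].area == pytest.approx(197.64)

    def test_lm_two_circles_geometry(self):
        design = SamplingDesign("LM", 1, 60.0, 60.0, 2, 10.0)
        section = generate_section(tiny_phenotype(1), nerve_radius=50.0, seed=0)
        frames = make_frames(place_fields(section, design, seed=1), design)
        assert len(frames) == 2
        a, b = frames
        assert math.hypot(a.center_x - b.center_x, a.center_y - b.center_y) == (
            pytest.approx(30.0)
        )
        assert sum(f.area for f in frames) == pytest.approx(2 * math.pi * 100.0)

    def test_oversized_circles_rejected(self):
        with pytest.raises(DesignError):
            design = SamplingDesign("LM", 1, 60.0, 60.0, 2, 20.0)
            section = generate_section(tiny_phenotype(1), nerve_radius=50.0, seed=0)
            make_frames(place_fields(section, design, seed=0), design)

    @pytest.mark.parametrize(
        "maker",
        [lambda **kw: lm_design(n_fields=10, **kw), lambda **kw: em_design(n_fields=40, **kw)],
        ids=["LM", "EM"],
    )
    def test_frames_inside_parent_fields_and_disjoint(self, maker, nerve100):
        design = maker(placement_seed=4)
        fields = place_fields(nerve100, design)
        frames = make_frames(fields, design)
        by_id = {f.field_id: f for f in fields}
        for fr in frames:
            parent = by_id[fr.parent_field_id]
            if fr.shape == "circle":
                assert fr.center_x - fr.radius >= parent.x_min - 1e-9
                assert fr.center_x + fr.radius <= parent.x_max + 1e-9
                assert fr.center_y - fr.radius >= parent.y_min - 1e-9
                assert fr.center_y + fr.radius <= parent.y_max + 1e-9
        # LM circles within one field are disjoint
        if design.modality == "LM":
            for i in range(0, len(frames), 2):
                a, b = frames[i], frames[i + 1]
                d = math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
                assert d >= a.radius + b.radius - 1e-9

    def test_total_frame_area_exact(self, nerve100):
        design = lm_design(n_fields=10, placement_seed=0)
        frames = make_frames(place_fields(nerve100, design), design)
        total = sum(f.area for f in frames)
        assert total == pytest.approx(10 * 2 * math.pi * design.frame_radius**2)


class TestReferenceArea:
    def test_interior_frames_keep_full_area(self, nerve100):
        design = lm_design(n_fields=10, placement_seed=3)
        frames = attach_reference_areas(
            make_frames(place_fields(nerve100, design), design), nerve100
        )
        for fr in frames:
            dist = math.hypot(fr.center_x, fr.center_y)
            if dist + fr.radius <= nerve100.nerve_radius:
                assert fr.reference_area == pytest.approx(fr.area)
            else:
                assert fr.reference_area < fr.area

    @pytest.mark.parametrize(
        "shape,center",
        [("circle", (95.0, 0.0)), ("circle", (0.0, 0.0)), ("circle", (120.0, 0.0)),
         ("rectangle", (98.0, 10.0)), ("rectangle", (0.0, -99.0)),
         ("rectangle", (200.0, 0.0))],
    )
    def test_overlap_area_matches_polygon_clipping(self, nerve100, shape, center):
        from nervestereo.sampling import CountingFrame

        if shape == "circle":
            frame = CountingFrame(0, 0, "circle", *center, radius=10.0)
            geom = Point(*center).buffer(10.0, quad_segs=512)
        else:
            frame = CountingFrame(0, 0, "rectangle", *center, width=12.2, height=16.2)
            geom = box(center[0] - 6.1, center[1] - 8.1, center[0] + 6.1, center[1] + 8.1)
        nerve = Point(0, 0).buffer(nerve100.nerve_radius, quad_segs=512)
        expected = geom.intersection(nerve).area
        assert frame_reference_area(frame, nerve100) == pytest.approx(
            expected, rel=1e-3, abs=1e-6
        )
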