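import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rostrabeam import phantom_forge as pf
from rostrabeam import section_engine as se


def _section(mask, pixel=(1e-3, 1e-3)):
    return se.CrossSection(mask=np.asarray(mask, dtype=bool), pixel_size=pixel)


def _annulus(r_out=20, r_in=12, pad=3):
    n = 2 * r_out + 2 * pad + 1
    off = np.arange(n) - (n - 1) / 2
    yy, xx = np.meshgrid(off, off, indexing="ij")
    rr = xx**2 + yy**2
    return (rr <= r_out**2) & (rr > r_in**2)


nonempty_masks = hnp.arrays(
    dtype=bool, shape=st.tuples(st.integers(2, 12), st.integers(2, 12))
).filter(lambda m: m.any())


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


class TestThresholdMask:
    def test_constant_image_inclusive_window(self):
        img = np.full((5, 5), 42.0)
        sec = se.threshold_mask(img, 42, 42)
        assert sec.mask.all()

    def test_excluding_window_warns_and_is_empty(self):
        img = np.full((5, 5), 42.0)
        with pytest.warns(UserWarning, match="no pixels"):
            sec = se.threshold_mask(img, 100, 200)
        assert not sec.mask.any()

    def test_round_trips_phantom_render(self, tube_volume):
        rendered = tube_volume.mask[3].astype(np.uint8) * 255
        sec = se.threshold_mask(rendered, 128, 255)
        assert np.array_equal(sec.mask, tube_volume.mask[3])

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            se.threshold_mask(np.zeros((3, 3)), 10, 5)


# ---------------------------------------------------------------------------
# closed-section preparation
# ---------------------------------------------------------------------------


class TestCloseSection:
    def test_annulus_becomes_solid_disc(self):
        sec = _section(_annulus())
        closed = se.close_section(sec)
        n = sec.mask.shape[0]
        off = np.arange(n) - (n - 1) / 2
        yy, xx = np.meshgrid(off, off, indexing="ij")
        assert np.array_equal(closed.mask, xx**2 + yy**2 <= 20**2)

    def test_open_c_shape_unchanged(self):
        mask = _annulus()
        mask[: mask.shape[0] // 2, mask.shape[1] // 2] = False  # breach to border
        # carve a channel from cavity to image edge
        mid = mask.shape[1] // 2
        mask[: mask.shape[0] // 2, mid - 1 : mid + 2] = False
        sec = _section(mask)
        closed = se.close_section(sec)
        assert np.array_equal(closed.mask, mask)

    def test_two_disjoint_rings_both_filled(self):
        ring = _annulus(r_out=8, r_in=5, pad=2)
        n = ring.shape[0]
        mask = np.zeros((n, 2 * n + 3), dtype=bool)
        mask[:, :n] = ring
        mask[:, n + 3 :] = ring
        closed = se.close_section(_section(mask))
        assert closed.mask[:, :n].sum() == closed.mask[:, n + 3 :].sum()
        assert closed.mask.sum() > mask.sum()
        # each ring independently becomes a disc
        disc = se.close_section(_section(ring)).mask
        assert np.array_equal(closed.mask[:, :n], disc)


# ---------------------------------------------------------------------------
# mirror completion
# ---------------------------------------------------------------------------


class TestMirrorComplete:
    def test_symmetric_input_idempotent(self):
        mask = _annulus()
        col = (mask.shape[1] - 1) // 2
        sec = _section(mask)
        for side in ("left", "right"):
            out = se.mirror_complete(sec, col, side)
            assert np.array_equal(out.mask, mask)

    def test_half_disc_restored_to_full_disc(self):
        n = 41
        off = np.arange(n) - (n - 1) / 2
        yy, xx = np.meshgrid(off, off, indexing="ij")
        disc = xx**2 + yy**2 <= 15**2
        col = (n - 1) // 2
        half = disc.copy()
        half[:, col + 1 :] = False
        out = se.mirror_complete(_section(half), col, "left")
        assert np.array_equal(out.mask, disc)

    def test_mirror_preserves_iy_of_symmetric_mask(self):
        mask = _annulus(r_out=18, r_in=10)
        col = (mask.shape[1] - 1) // 2
        original = se.section_properties(_section(mask))
        mirrored = se.mirror_complete(_section(mask), col, "right")
        rebuilt = se.section_properties(mirrored)
        assert rebuilt.Iy == pytest.approx(original.Iy, rel=1e-12)
        assert rebuilt.Ix == pytest.approx(original.Ix, rel=1e-12)

    def test_empty_half_errors(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 7] = True
        with pytest.raises(se.EmptySectionError):
            se.mirror_complete(_section(mask), 2, "left")

    def test_column_outside_image_errors(self):
        with pytest.raises(ValueError, match="outside"):
            se.mirror_complete(_section(np.ones((4, 4))), 10, "left")


# ---------------------------------------------------------------------------
# section properties
# ---------------------------------------------------------------------------


class TestSectionProperties:
    def test_single_pixel_has_zero_moments(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        p = se.section_properties(_section(mask))
        assert p.Ix == 0.0 and p.Iy == 0.0 and p.J == 0.0
        assert p.area == pytest.approx(1e-6)

    def test_rasterized_circle_matches_closed_form(self, disc_section):
        p = se.section_properties(disc_section)
        r = 200 * 1e-3
        expected = math.pi * r**4 / 4
        assert p.Ix == pytest.approx(expected, rel=0.01)
        assert p.Iy == pytest.approx(expected, rel=0.01)

    def test_empty_mask_names_slice(self):
        sec = se.CrossSection(
            np.zeros((4, 4), dtype=bool), (1e-3, 1e-3), axial_position=0.16
        )
        with pytest.raises(se.EmptySectionError, match="0.16"):
            se.section_properties(sec)

    @given(mask=nonempty_masks)
    @settings(max_examples=50, deadline=None)
    def test_j_identity_exact(self, mask):
        p = se.section_properties(_section(mask))
        assert p.J == p.Ix + p.Iy

    @given(mask=nonempty_masks, dy=st.integers(1, 4), dx=st.integers(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, mask, dy, dx):
        padded = np.pad(mask, ((dy, 0), (dx, 0)))
        p0 = se.section_properties(_section(mask))
        p1 = se.section_properties(_section(padded))
        assert p1.Ix == pytest.approx(p0.Ix, rel=1e-9, abs=1e-18)
        assert p1.Iy == pytest.approx(p0.Iy, rel=1e-9, abs=1e-18)
        assert p1.centroid != p0.centroid or (dy, dx) == (0, 0)

    @given(mask=nonempty_masks)
    @settings(max_examples=50, deadline=None)
    def test_rotation_swaps_ix_iy(self, mask):
        p0 = se.section_properties(_section(mask))
        p90 = se.section_properties(_section(np.rot90(mask)))
        assert p90.Ix == pytest.approx(p0.Iy, rel=1e-9, abs=1e-18)
        assert p90.Iy == pytest.approx(p0.Ix, rel=1e-9, abs=1e-18)
        assert p90.J == pytest.approx(p0.J, rel=1e-9, abs=1e-18)

    def test_disjoint_components_pooled_about_common_centroid(self):
        mask = np.zeros((3, 11), dtype=bool)
        mask[1, 0] = mask[1, 10] = True
        p = se.section_properties(_section(mask))
        # two point masses 10 px apart: Iy = 2 * (5 dx)^2 * dA
        assert p.Iy == pytest.approx(2 * (5e-3) ** 2 * 1e-6, rel=1e-12)
        assert p.Ix == 0.0
        per_comp = se.section_properties_per_component(_section(mask))
        assert len(per_comp) == 2
        assert all(c.Iy == 0.0 for c in per_comp)

    def test_equal_area_annulus_beats_disc_on_rasters(self):
        # Rasterized counterpart of the thin-tube advantage
        annulus = _annulus(r_out=120, r_in=80, pad=4)
        area = annulus.sum()
        r_disc = math.sqrt(area / math.pi)
        n = annulus.shape[0]
        off = np.arange(n) - (n - 1) / 2
        yy, xx = np.meshgrid(off, off, indexing="ij")
        disc = xx**2 + yy**2 <= r_disc**2
        pa = se.section_properties(_section(annulus))
        pd = se.section_properties(_section(disc))
        assert abs(pa.area - pd.area) / pd.area < 0.01
        assert pa.Ix > pd.Ix and pa.Iy > pd.Iy and pa.J > pd.J


class TestStiffness:
    def test_unit_moduli_identity(self, disc_section):
        p = se.section_properties(disc_section)
        mat = se.MaterialProperties(1.0, 1.0)
        assert se.stiffness(p, mat) == (p.Ix, p.Iy, p.J)

    def test_doubling_E_scales_flexural_only(self, disc_section):
        p = se.section_properties(disc_section)
        f1 = se.stiffness(p, se.MaterialProperties(2e9, 5e8))
        f2 = se.stiffness(p, se.MaterialProperties(4e9, 5e8))
        assert f2[0] == 2 * f1[0] and f2[1] == 2 * f1[1]
        assert f2[2] == f1[2]

    def test_ten_gpa_arithmetic(self, disc_section):
        p = se.section_properties(disc_section)
        fx, fy, tz = se.stiffness(p, se.MaterialProperties(1e10, 4e9))
        assert fx == pytest.approx(1e10 * p.Ix, rel=1e-15)

    def test_invalid_moduli(self):
        with pytest.raises(ValueError):
            se.MaterialProperties(-1.0, 1.0)


# ---------------------------------------------------------------------------
# slice placement
# ---------------------------------------------------------------------------


class TestPlaceSlices:
    def test_scheme_a_posterior_anchored_anchors(self):
        pos = se.place_slices("A", 1.0, 25)
        assert pos[3] == pytest.approx(0.16)
        assert pos[1] == pytest.approx(0.08)
        assert pos[5] == pytest.approx(0.24)
        assert pos[-1] == pytest.approx(1.0)
        assert len(pos) == 25

    def test_scheme_b_tip_anchored_span(self):
        pos = se.place_slices("B", 0.185, 8)
        assert pos[0] == 0.0
        assert pos[-1] == pytest.approx(0.185)
        assert len(pos) == 8
        steps = np.diff(pos)
        assert np.allclose(steps, steps[0])

    @pytest.mark.parametrize("count", [0, 1])
    def test_count_too_small(self, count):
        with pytest.raises(ValueError):
            se.place_slices("A", 1.0, count)

    @pytest.mark.parametrize("span", [0.0, 1.5, -0.2])
    def test_bad_span(self, span):
        with pytest.raises(ValueError):
            se.place_slices("B", span, 8)


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------


class TestExtractProfile:
    def test_uniform_tube_flat_ix(self, tube_volume):
        pos = se.place_slices("A", 1.0, 25)
        prof = se.extract_profile(tube_volume, pos, taxon="tube", skull_length=1.0)
        ix = prof.measure("Ix")
        assert ix.max() / ix.min() <= 1.02

    def test_tapering_phantom_area_decreases_toward_tip(self):
        spec = pf.MorphotypeSpec(
            "taper", 1.0, 0.1,
            width_profile=pf.piecewise_linear([(0.0, 0.008), (1.0, 0.03)]),
            height_profile=pf.piecewise_linear([(0.0, 0.008), (1.0, 0.03)]),
            wall_thickness_profile=pf.constant(0.004),
        )
        vol = pf.generate_rostrum_volume(spec, 0.0005)
        pos = se.place_slices("A", 1.0, 10)
        prof = se.extract_profile(vol, pos, taxon="taper")
        area = prof.measure("area")
        assert np.all(np.diff(area) > 0)  # grows away from the tip

    def test_too_many_positions_for_stack(self, tube_volume):
        coarse = pf.VoxelVolume(
            mask=tube_volume.mask[::20],  # 11 stored slices
            voxel_spacing=(0.01, 0.0005, 0.0005),
            origin_landmarks=(0, tube_volume.mask[::20].shape[0] - 1),
        )
        with pytest.raises(se.SliceGridError, match="finer"):
            se.extract_profile(coarse, se.place_slices("A", 1.0, 25))

    def test_actual_positions_recorded(self, tube_volume):
        pos = se.place_slices("B", 0.185, 8)
        prof = se.extract_profile(tube_volume, pos)
        assert prof.slice_positions[0] == 0.0
        assert prof.slice_positions[-1] == pytest.approx(0.185, abs=0.01)


# ---------------------------------------------------------------------------
# size correction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tube_profile(tube_volume):
    pos = se.place_slices("A", 1.0, 10)
    return se.extract_profile(
        tube_volume, pos, taxon="tube", skull_length=0.217,
        prep=se.PrepOptions(keep_sections=True),
    )


class TestSizeCorrect:
    def test_identity_at_s_one(self, tube_profile):
        out = se.size_correct(tube_profile, 0.217, "analytic")
        for p0, p1 in zip(tube_profile.properties, out.properties):
            assert p1.J == pytest.approx(p0.J, rel=1e-15)
        assert out.treatment == "size_corrected"

    def test_s_two_gives_sixteenfold_j(self, tube_profile):
        out = se.size_correct(tube_profile, 2 * 0.217, "analytic")
        for p0, p1 in zip(tube_profile.properties, out.properties):
            assert p1.J == p0.J * 16.0
            assert p1.area == p0.area * 4.0

    def test_analytic_vs_resample_agree(self, tube_profile):
        s_ref = 0.86  # scale 21.7 cm -> 86 cm
        analytic = se.size_correct(tube_profile, s_ref, "analytic")
        resampled = se.size_correct(tube_profile, s_ref, "resample")
        for pa, pr in zip(analytic.properties, resampled.properties):
            assert pr.Ix == pytest.approx(pa.Ix, rel=0.02)
            assert pr.Iy == pytest.approx(pa.Iy, rel=0.02)
            assert pr.J == pytest.approx(pa.J, rel=0.02)
            assert pr.area == pytest.approx(pa.area, rel=0.02)

    def test_nonpositive_reference_rejected(self, tube_profile):
        with pytest.raises(ValueError):
            se.size_correct(tube_profile, 0.0)

    def test_resample_requires_masks(self, tube_volume):
        prof = se.extract_profile(
            tube_volume, [0.1, 0.5, 0.9],
            prep=se.PrepOptions(keep_sections=False),
        )
        with pytest.raises(ValueError, match="masks"):
            se.size_correct(prof, 2.0, "resample")


def test_morphotype_ordering_flat_vs_tall():
    # matched skull length: flat-wide favours Iy, tall-narrow favours Ix
    L = 0.86
    flat = pf.generate_rostrum_volume(pf.flat_wide_morphotype(L), 0.003)
    tall = pf.generate_rostrum_volume(pf.tall_narrow_morphotype(L), 0.003)
    pos = se.place_slices("A", 1.0, 10)
    pf_flat = se.extract_profile(flat, pos, taxon="flat", skull_length=L)
    pf_tall = se.extract_profile(tall, pos, taxon="tall", skull_length=L)
    assert np.all(pf_flat.measure("Iy") > pf_flat.measure("Ix"))
    assert np.all(pf_tall.measure("Ix") > pf_tall.measure("Iy"))


class TestProfileCSV:
    def test_round_trip(self, tmp_path, tube_volume):
        prof = se.extract_profile(
            tube_volume, se.place_slices("A", 1.0, 10),
            taxon="tube", skull_length=1.0,
        )
        path = tmp_path / "tube.csv"
        se.write_profile_csv(prof, path)
        back = se.read_profile_csv(path)
        assert back.taxon == "tube"
        assert back.treatment == "raw"
        assert back.slice_positions == pytest.approx(prof.slice_positions)
        np.testing.assert_allclose(back.measure("J"), prof.measure("J"))
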