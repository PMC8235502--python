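"""Macro-tumor outlining, stroma definition, exclusion zones, TIL filter."""

import numpy as np
import pytest

from conftest import oracle_dilate
from stilquant.geometry import (
    AuditCode,
    EmptyMacroTumorError,
    GeometryParams,
    build_partition,
    connected_components,
    exclusion_zone,
    filter_tils,
    macro_tumor_outline,
    tumor_associated_stroma,
)
from stilquant.raster import (
    BinaryMask,
    Calibration,
    CellClass,
    CellDetections,
    LabelMask,
    TissueClass,
    disk_kernel_fraction,
    morph_close_open,
)


def _labels_with_discs(shape, mpp, discs, base=TissueClass.STROMA):
    """discs: list of (cx_px, cy_px, r_px, TissueClass)."""
    raster = np.full(shape, int(base), dtype=np.uint8)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy, r, cls in discs:
        raster[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = int(cls)
    cal = Calibration(mpp, shape[1], shape[0])
    return LabelMask(raster, cal)


class TestMacroTumorOutline:
    def test_solid_disc_covered_and_connected(self):
        # 4×4 mm at 10 µm/px; tumor disc radius 2000 µm
        labels = _labels_with_discs((400, 400), 10.0, [(200, 200, 200, TissueClass.TUMOR)])
        macro, ok = macro_tumor_outline(labels, GeometryParams())
        assert ok
        tumor = labels.class_mask(TissueClass.TUMOR)
        assert np.all(macro.raster | ~tumor.raster)  # macro ⊇ disc
        assert connected_components(macro) == 1

    def test_no_tumor_gives_empty_and_flag(self):
        labels = _labels_with_discs((100, 100), 10.0, [])
        macro, ok = macro_tumor_outline(labels, GeometryParams())
        assert not ok and macro.is_empty()
        with pytest.raises(EmptyMacroTumorError):
            tumor_associated_stroma(labels, macro, GeometryParams())

    def test_two_blobs_bridged_across_800um_gap(self):
        # blobs radius 600 µm, edge-to-edge gap 800 µm at default params
        labels = _labels_with_discs(
            (400, 400),
            10.0,
            [(130, 200, 60, TissueClass.TUMOR), (330, 200, 60, TissueClass.TUMOR)],
        )
        params = GeometryParams()
        macro, ok = macro_tumor_outline(labels, params)
        assert ok
        assert connected_components(macro) == 1
        # oracle: explicit composition of the raster primitives
        tumor = labels.class_mask(TissueClass.TUMOR)
        frac = disk_kernel_fraction(tumor, params.kernel_radius_um)
        core = BinaryMask(frac >= params.tumor_fraction_threshold, labels.calibration)
        expected = morph_close_open(core, params.morph_radius_um) & labels.tissue_mask()
        assert np.array_equal(macro.raster, expected.raster)

    def test_monotone_in_fraction_threshold(self):
        labels = _labels_with_discs((300, 300), 10.0, [(150, 150, 80, TissueClass.TUMOR)])
        lo, _ = macro_tumor_outline(labels, GeometryParams(tumor_fraction_threshold=0.05))
        hi, _ = macro_tumor_outline(labels, GeometryParams(tumor_fraction_threshold=0.30))
        assert np.all(lo.raster | ~hi.raster)  # lower threshold → superset


class TestTumorAssociatedStroma:
    def _setup(self):
        labels = _labels_with_discs((400, 400), 10.0, [(200, 200, 100, TissueClass.TUMOR)])
        macro, _ = macro_tumor_outline(labels, GeometryParams())
        return labels, macro

    def test_margin_zero_strictly_inside_macro(self):
        labels, macro = self._setup()
        stroma = tumor_associated_stroma(labels, macro, GeometryParams(margin_um=0.0))
        assert np.all(macro.raster | ~stroma.raster)

    def test_probe_points_at_200_and_300_um_outside_macro(self):
        # distance-transform oracle for the 250 µm margin rule
        from scipy.ndimage import distance_transform_edt

        labels, macro = self._setup()
        stroma = tumor_associated_stroma(labels, macro, GeometryParams())
        dist_um = distance_transform_edt(~macro.raster) * 10.0
        probe_in = (dist_um > 150) & (dist_um <= 200) & (labels.raster == int(TissueClass.STROMA))
        probe_out = (dist_um >= 300) & (labels.raster == int(TissueClass.STROMA))
        assert probe_in.any() and probe_out.any()
        assert np.all(stroma.raster[probe_in])
        assert not stroma.raster[probe_out].any()

    def test_all_tumor_inside_macro_gives_empty_stroma(self):
        labels = _labels_with_discs((200, 200), 10.0, [], base=TissueClass.TUMOR)
        macro, _ = macro_tumor_outline(labels, GeometryParams())
        stroma = tumor_associated_stroma(labels, macro, GeometryParams(margin_um=0.0))
        assert stroma.is_empty()


class TestExclusionZone:
    def test_empty_when_no_excludable_classes(self):
        labels = _labels_with_discs((50, 50), 10.0, [])
        assert exclusion_zone(labels, GeometryParams()).is_empty()

    def test_dcis_blob_dilated_by_150um_against_oracle(self):
        labels = _labels_with_discs(
            (60, 60), 10.0, [(30, 30, 5, TissueClass.NONINVASIVE_EPITHELIUM)]
        )
        zone = exclusion_zone(labels, GeometryParams())
        epi = labels.raster == int(TissueClass.NONINVASIVE_EPITHELIUM)
        assert np.array_equal(zone.raster, oracle_dilate(epi, 15.0))

    def test_monotone_in_buffer(self):
        labels = _labels_with_discs(
            (60, 60), 10.0, [(30, 30, 5, TissueClass.NONINVASIVE_EPITHELIUM)]
        )
        z150 = exclusion_zone(labels, GeometryParams(epi_exclusion_um=150))
        z300 = exclusion_zone(labels, GeometryParams(epi_exclusion_um=300))
        assert np.all(z300.raster >= z150.raster)
        assert z300.raster.sum() > z150.raster.sum()


class TestFilterTils:
    def test_all_other_labeled(self, small_render):
        cells = small_render.cells
        others = CellDetections(
            cells.points, np.zeros(len(cells), np.int64), cells.calibration
        )
        p = small_render.partition
        out = filter_tils(others, p.tumor_associated_stroma, p.exclusion_zone, small_render.labels)
        assert len(out.kept) == 0
        assert (out.codes == int(AuditCode.NOT_TIL)).all()

    def test_counts_conserve_and_codes_unique(self, small_render):
        p = small_render.partition
        out = filter_tils(
            small_render.cells, p.tumor_associated_stroma, p.exclusion_zone, small_render.labels
        )
        n_til = small_render.cells.n_til
        excluded = sum(
            out.count(c)
            for c in (
                AuditCode.IN_TUMOR,
                AuditCode.IN_NECROSIS,
                AuditCode.NEAR_EPI,
                AuditCode.OUTSIDE_STROMA,
            )
        )
        assert len(out.kept) + excluded == n_til
        assert out.count(AuditCode.NOT_TIL) == small_render.cells.n_other
        assert len(out.codes) == len(small_render.cells)

    def test_matches_generator_ground_truth_exactly(self, small_render):
        p = small_render.partition
        out = filter_tils(
            small_render.cells, p.tumor_associated_stroma, p.exclusion_zone, small_render.labels
        )
        assert np.array_equal(out.codes, small_render.compartments)

    def test_dcis_proximity_flip_at_149_vs_151_um(self):
        # single-pixel DCIS at 1 µm/px; a TIL at 149 µm is excluded (NEAR_EPI),
        # at 151 µm it is kept — moving the blob by 2 µm flips exactly that flag
        labels = _labels_with_discs(
            (800, 800),
            1.0,
            [(400, 400, 150, TissueClass.TUMOR), (100, 200, 0, TissueClass.NONINVASIVE_EPITHELIUM)],
        )
        partition = build_partition(labels, GeometryParams())
        cal = labels.calibration
        cells = CellDetections(
            np.array([[100 + 149.0, 200.0], [100 + 151.0, 200.0]]),
            np.array([int(CellClass.TIL)] * 2),
            cal,
        )
        out = filter_tils(
            cells, partition.tumor_associated_stroma, partition.exclusion_zone, labels
        )
        assert out.codes.tolist() == [int(AuditCode.NEAR_EPI), int(AuditCode.KEPT)]
        # move the DCIS pixel 2 µm toward the second TIL: both TILs now ≤150 µm
        labels2 = _labels_with_discs(
            (800, 800),
            1.0,
            [(400, 400, 150, TissueClass.TUMOR), (102, 200, 0, TissueClass.NONINVASIVE_EPITHELIUM)],
        )
        partition2 = build_partition(labels2, GeometryParams())
        out2 = filter_tils(
            cells, partition2.tumor_associated_stroma, partition2.exclusion_zone, labels2
        )
        assert out2.codes.tolist() == [int(AuditCode.NEAR_EPI), int(AuditCode.NEAR_EPI)]

    def test_precedence_tumor_over_near_epi(self):
        # a TIL on a tumor pixel inside the epithelial buffer reports IN_TUMOR
        labels = _labels_with_discs(
            (800, 800),
            1.0,
            [
                (400, 400, 150, TissueClass.TUMOR),
                (400, 200, 10, TissueClass.NONINVASIVE_EPITHELIUM),
            ],
        )
        partition = build_partition(labels, GeometryParams())
        cal = labels.calibration
        # 50 µm from the DCIS edge (in the 150 µm buffer), 140 µm from tumor
        # center → tumor-class pixel
        cells = CellDetections(np.array([[400.0, 260.0]]), np.array([int(CellClass.TIL)]), cal)
        out = filter_tils(
            cells, partition.tumor_associated_stroma, partition.exclusion_zone, labels
        )
        assert out.codes.tolist() == [int(AuditCode.IN_TUMOR)]


class TestPartition:
    def test_partition_masks_disjoint_and_calibrated(self, small_render):
        p = small_render.partition
        assert not (p.tumor_associated_stroma.raster & p.exclusion_zone.raster).any()
        assert np.all(p.raw_stroma.raster | ~p.tumor_associated_stroma.raster)

    def test_translation_invariance_modulo_border(self):
        # whole-pixel shift of the tumor shifts the macro mask identically in
        # the interior (≥ kernel+morph radius away from every border)
        labels = _labels_with_discs((300, 300), 10.0, [(150, 150, 50, TissueClass.TUMOR)])
        shifted = _labels_with_discs((300, 300), 10.0, [(160, 155, 50, TissueClass.TUMOR)])
        m1, _ = macro_tumor_outline(labels, GeometryParams())
        m2, _ = macro_tumor_outline(shifted, GeometryParams())
        a = m1.raster[105:190, 105:190]
        b = m2.raster[110:195, 115:200]
        assert a.any()
        assert np.array_equal(a, b)
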