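"""Nuclear/nucleolar segmentation and per-nucleus morphometry."""

import math

import numpy as np
import pytest

import nucleoquant as nq
from nucleoquant.datatypes import LabelMask, MultiChannelImage
from nucleoquant.errors import ChannelNotFound, MaskMismatch
from nucleoquant.nucleoli import measures_to_frame

from conftest import match_to_truth


def _two_channel(dna, marker):
    return MultiChannelImage(np.stack([dna, marker], axis=-1), ["dna", "marker"])


class TestSegmentNuclei:
    def test_disk_count_and_areas(self):
        spec = nq.NucleolarSceneSpec(n_nuclei=5, noise_sd=0.0, seed=3)
        scene = nq.gen_nucleolar_scene(spec)
        nuclei = nq.segment_nuclei(scene.image, "dna", min_area_px=200)
        assert nuclei.ids.size == 5
        truth_areas = sorted(scene.truth.nuclear_area_px)
        seg_areas = sorted(int((nuclei.labels == i).sum()) for i in nuclei.ids)
        for got, want in zip(seg_areas, truth_areas):
            assert abs(got - want) / want < 0.02

    def test_blank_image_yields_no_labels(self):
        img = _two_channel(np.full((64, 64), 9.0), np.zeros((64, 64)))
        assert nq.segment_nuclei(img, "dna").ids.size == 0

    def test_border_object_excluded_by_default(self):
        dna = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        dna[(yy - 0) ** 2 + (xx - 32) ** 2 <= 100] = 100.0    # clipped by edge
        dna[(yy - 40) ** 2 + (xx - 32) ** 2 <= 100] = 100.0   # interior
        img = _two_channel(dna, np.zeros_like(dna))
        assert nq.segment_nuclei(img, "dna", min_area_px=10).ids.size == 1
        both = nq.segment_nuclei(img, "dna", min_area_px=10,
                                 exclude_border=False)
        assert both.ids.size == 2

    def test_missing_channel_raises(self, nucleolar_scene):
        with pytest.raises(ChannelNotFound):
            nq.segment_nuclei(nucleolar_scene.image, "hoechst")


class TestSegmentNucleoli:
    @staticmethod
    def _nucleus_with_blobs(gap_px):
        """One 60x60 nucleus holding two 6x6 bright squares gap_px apart."""
        dna = np.zeros((80, 80))
        marker = np.full((80, 80), 1.0)
        dna[10:70, 10:70] = 100.0
        marker[10:70, 10:70] = 100.0
        marker[30:36, 20:26] = 200.0
        marker[30:36, 26 + gap_px:32 + gap_px] = 200.0
        return _two_channel(dna, marker)

    def test_adjacent_fragments_merged(self):
        img = self._nucleus_with_blobs(gap_px=1)
        nuclei = nq.segment_nuclei(img, "dna", min_area_px=100)
        nucleoli = nq.segment_nucleoli(img, "marker", nuclei,
                                       merge_distance_px=2)
        assert nucleoli.ids.size == 1

    def test_distant_fragments_kept_separate(self):
        img = self._nucleus_with_blobs(gap_px=5)
        nuclei = nq.segment_nuclei(img, "dna", min_area_px=100)
        nucleoli = nq.segment_nucleoli(img, "marker", nuclei,
                                       merge_distance_px=2)
        assert nucleoli.ids.size == 2

    def test_signal_outside_nuclei_discarded(self):
        dna = np.zeros((80, 80))
        marker = np.full((80, 80), 1.0)
        dna[10:40, 10:40] = 100.0
        marker[60:70, 60:70] = 200.0          # bright blob outside the nucleus
        img = _two_channel(dna, marker)
        nuclei = nq.segment_nuclei(img, "dna", min_area_px=100)
        assert nq.segment_nucleoli(img, "marker", nuclei).ids.size == 0

    def test_nucleolus_free_nucleus_has_zero_children(self):
        spec = nq.NucleolarSceneSpec(n_nuclei=4, nucleoli_per_nucleus={0: 1.0},
                                     seed=5)
        scene = nq.gen_nucleolar_scene(spec)
        nuclei = nq.segment_nuclei(scene.image, "dna", min_area_px=200)
        nucleoli = nq.segment_nucleoli(scene.image, "marker", nuclei)
        assert nucleoli.ids.size == 0
        measures = nq.measure_nuclei(scene.image, "marker", nuclei, nucleoli)
        assert len(measures) == 4                      # nuclei retained
        assert all(m.nucleolus_count == 0 for m in measures)

    def test_shape_mismatch_raises(self, nucleolar_scene):
        bad = LabelMask(np.zeros((10, 10), dtype=np.int32))
        with pytest.raises(MaskMismatch):
            nq.segment_nucleoli(nucleolar_scene.image, "marker", bad)


class TestMeasureNuclei:
    @staticmethod
    def _manual_setup(nucleolar_v, plasm_v):
        """500-px square nucleus with a 50-px nucleolar block of known value."""
        marker = np.full((30, 30), 0.0)
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nucleoli = np.zeros((30, 30), dtype=np.int32)
        nuclei[2:27, 2:22] = 1                # 25 x 20 = 500 px
        marker[2:27, 2:22] = plasm_v
        nucleoli[5:10, 5:15] = 1              # 5 x 10 = 50 px
        marker[5:10, 5:15] = nucleolar_v
        img = MultiChannelImage(np.stack([marker, marker], axis=-1),
                                ["dna", "marker"])
        return img, LabelMask(nuclei), LabelMask(nucleoli, parent_map={1: 1})

    def test_uniform_marker_presence_ratio_one(self):
        img, nuclei, nucleoli = self._manual_setup(5.0, 5.0)
        m = nq.measure_nuclei(img, "marker", nuclei, nucleoli)[0]
        assert m.presence_ratio == pytest.approx(1.0)

    def test_doubled_nucleolar_intensity_gives_ratio_two(self):
        img, nuclei, nucleoli = self._manual_setup(10.0, 5.0)
        m = nq.measure_nuclei(img, "marker", nuclei, nucleoli)[0]
        assert m.presence_ratio == pytest.approx(2.0)
        assert m.marker_nucleolar_integrated == pytest.approx(500.0)

    def test_size_fold_is_area_ratio(self):
        img, nuclei, nucleoli = self._manual_setup(10.0, 5.0)
        m = nq.measure_nuclei(img, "marker", nuclei, nucleoli)[0]
        assert m.nuclear_area_px == 500
        assert m.nucleolar_area_px == 50
        assert m.size_fold == pytest.approx(0.1)

    def test_partition_is_exact(self, nucleolar_scene):
        """Nucleolar + nucleoplasm pixels == nuclear pixels, per nucleus."""
        sc = nucleolar_scene
        measures = nq.measure_nuclei(sc.image, "marker", sc.nuclei, sc.nucleoli)
        for m in measures:
            nuc = sc.nuclei.labels == m.nucleus_id
            kids = [c for c, p in sc.nucleoli.parent_map.items()
                    if p == m.nucleus_id]
            nucl = np.isin(sc.nucleoli.labels, kids)
            assert not (nucl & ~nuc).any()
            assert m.nucleolar_area_px == nucl.sum()
            assert m.nuclear_area_px == nuc.sum()

    def test_intensity_scale_equivariance(self, nucleolar_scene):
        sc = nucleolar_scene
        base = nq.measure_nuclei(sc.image, "marker", sc.nuclei, sc.nucleoli)
        scaled_img = MultiChannelImage(
            sc.image.pixels * np.array([1.0, 3.0]), sc.image.channel_names)
        scaled = nq.measure_nuclei(scaled_img, "marker", sc.nuclei, sc.nucleoli)
        for a, b in zip(base, scaled):
            assert b.size_fold == pytest.approx(a.size_fold)
            if not math.isnan(a.presence_ratio):
                assert b.presence_ratio == pytest.approx(a.presence_ratio)
            assert b.marker_nucleolar_integrated == pytest.approx(
                3.0 * a.marker_nucleolar_integrated)

    def test_presence_undefined_without_nucleoli(self):
        img, nuclei, _ = self._manual_setup(5.0, 5.0)
        empty = LabelMask(np.zeros((30, 30), dtype=np.int32), parent_map={})
        m = nq.measure_nuclei(img, "marker", nuclei, empty)[0]
        assert math.isnan(m.presence_ratio)
        assert m.nucleolus_count == 0


class TestNascentRna:
    def test_zero_furd_gives_zero_integrated(self, nucleolar_scene):
        sc = nucleolar_scene
        pixels = sc.image.pixels.copy()
        pixels[:, :, 1] = 0.0
        img = MultiChannelImage(pixels, ["dna", "furd"])
        df = nq.measure_nascent_rna(img, "furd", sc.nuclei, sc.nucleoli)
        assert (df.furd_nucleolar_integrated == 0).all()

    def test_furd_equal_to_marker_matches_marker_stats(self, nucleolar_scene):
        sc = nucleolar_scene
        marker_measures = nq.measure_nuclei(sc.image, "marker",
                                            sc.nuclei, sc.nucleoli)
        df = nq.measure_nascent_rna(sc.image, "marker", sc.nuclei, sc.nucleoli)
        for m, (_, row) in zip(marker_measures, df.iterrows()):
            assert row.furd_nucleolar_integrated == m.marker_nucleolar_integrated

    def test_doubling_intensity_doubles_integrated(self, nucleolar_scene):
        sc = nucleolar_scene
        df1 = nq.measure_nascent_rna(sc.image, "marker", sc.nuclei, sc.nucleoli)
        doubled = MultiChannelImage(sc.image.pixels * 2.0,
                                    sc.image.channel_names)
        df2 = nq.measure_nascent_rna(doubled, "marker", sc.nuclei, sc.nucleoli)
        np.testing.assert_allclose(df2.furd_nucleolar_integrated,
                                   2 * df1.furd_nucleolar_integrated)
        assert list(df2.furd_nucleolar_median.rank()) == \
            list(df1.furd_nucleolar_median.rank())


class TestQcOverlay:
    def test_empty_masks_leave_composite_unmodified(self, nucleolar_scene):
        img = nucleolar_scene.image
        empty = LabelMask(np.zeros(img.shape, dtype=np.int32))
        rgb = nq.qc_overlay(img, empty, empty)
        assert rgb.shape == img.shape + (3,)
        assert np.array_equal(rgb[:, :, 0], rgb[:, :, 1])
        assert np.array_equal(rgb[:, :, 1], rgb[:, :, 2])

    def test_every_nucleus_outlined(self, nucleolar_scene):
        sc = nucleolar_scene
        rgb = nq.qc_overlay(sc.image, sc.nuclei, sc.nucleoli)
        assert rgb.shape == sc.image.shape + (3,)
        cyan = (rgb[:, :, 0] == 0) & (rgb[:, :, 1] == 1) & (rgb[:, :, 2] == 1)
        import skimage.segmentation as skseg
        outlined = np.unique(sc.nuclei.labels[cyan | (rgb[:, :, 0] == 1)])
        boundary_labels = np.unique(
            sc.nuclei.labels[skseg.find_boundaries(sc.nuclei.labels,
                                                   mode="inner")])
        assert set(boundary_labels) <= set(outlined) | {0}


def test_recovery_on_well_separated_scene(nucleolar_scene):
    """Counts, size fold and presence ratio track truth on a default scene."""
    sc = nucleolar_scene
    nuclei = nq.segment_nuclei(sc.image, "dna", min_area_px=200)
    nucleoli = nq.segment_nucleoli(sc.image, "marker", nuclei)
    df = measures_to_frame(nq.measure_nuclei(sc.image, "marker",
                                             nuclei, nucleoli))
    mapping = match_to_truth(nuclei.labels, sc)
    truth = sc.truth.set_index("nucleus_id")
    hits = 0
    for label, tid in mapping.items():
        row = df[df.nucleus_id == label].iloc[0]
        t = truth.loc[tid]
        hits += int(row.nucleolus_count == t.nucleolus_count)
        if t.nucleolar_area_px > 0 and row.nucleolus_count == t.nucleolus_count:
            sf_true = t.nucleolar_area_px / t.nuclear_area_px
            assert abs(row.size_fold - sf_true) / sf_true < 0.10
            assert abs(row.presence_ratio - t.enrichment) / t.enrichment < 0.10
    assert hits / len(mapping) >= 0.9
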