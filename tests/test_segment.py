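import numpy as np
import pytest
from skimage import draw
from skimage.filters import threshold_isodata as skimage_isodata

from synquant import (
    QuantParams,
    detect_puncta,
    segment_ais,
    segment_neuropil,
    segment_somata,
    threshold_isodata,
)
from synquant.io import GeometryError

from conftest import PX, image_from


def disk_image(radius_px, value=200.0, shape=(128, 128), center=None):
    px = np.zeros(shape)
    center = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = draw.disk(center, radius_px, shape=shape)
    px[rr, cc] = value
    return px


class TestIsodata:
    def test_two_level_midpoint(self):
        """Iterating T ← (mean below + mean above)/2 on a balanced
        two-level image converges to the midpoint."""
        img = np.array([10.0] * 50 + [20.0] * 50).reshape(10, 10)
        assert threshold_isodata(img) == pytest.approx(15.0, abs=1e-9)

    def test_binary_extremes_midpoint(self):
        img = np.array([0.0] * 32 + [255.0] * 32).reshape(8, 8)
        assert threshold_isodata(img) == pytest.approx(127.5, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_isodata(np.full((8, 8), 9.0))

    def test_fixed_point_property(self):
        rng = np.random.default_rng(0)
        px = np.concatenate(
            [rng.normal(40, 5, 500), rng.normal(180, 10, 500)]
        ).reshape(25, 40).clip(0, 255)
        t = threshold_isodata(px)
        below, above = px[px <= t], px[px > t]
        assert t == pytest.approx(0.5 * (below.mean() + above.mean()), abs=1e-6)

    def test_agrees_with_histogram_based_estimator(self):
        """Independent cross-check against the bin-quantized variant."""
        rng = np.random.default_rng(1)
        px = np.concatenate(
            [rng.normal(50, 10, 2000), rng.normal(200, 12, 2000)]
        ).clip(0, 255).astype(np.uint8).reshape(50, 80)
        assert abs(threshold_isodata(px) - skimage_isodata(px)) <= 1.0


class TestSegmentSomata:
    def test_blank_image_empty(self):
        assert segment_somata(image_from(np.zeros((64, 64))), 100, 1.0) == []

    def test_disk_geometry(self):
        img = image_from(disk_image(20))
        (soma,) = segment_somata(img, 100, min_soma_area_um2=1.0)
        assert soma.area_um2 == pytest.approx(np.pi * 2.0**2, rel=0.03)
        assert soma.perimeter_um == pytest.approx(2 * np.pi * 2.0, rel=0.05)

    def test_two_disks_two_labels(self):
        px = disk_image(10, center=(30, 30)) + disk_image(10, center=(90, 90))
        somas = segment_somata(image_from(px), 100, 1.0)
        assert [s.label for s in somas] == [1, 2]
        assert not (somas[0].region & somas[1].region).any()

    def test_min_area_gate(self):
        px = disk_image(20, center=(40, 40)) + disk_image(3, center=(100, 100))
        somas = segment_somata(image_from(px), 100, min_soma_area_um2=1.0)
        assert len(somas) == 1  # 3-px-radius blob (~0.28 μm²) gated out


class TestSegmentNeuropil:
    def test_no_somata_full_foreground(self):
        px = disk_image(10)
        out = segment_neuropil(image_from(px), 100, [])
        np.testing.assert_array_equal(out, px >= 100)

    def test_soma_covering_foreground_empty(self):
        px = disk_image(10)
        (soma,) = segment_somata(image_from(px), 100, 1.0)
        assert not segment_neuropil(image_from(px), 100, [soma]).any()

    def test_annulus_pixel_oracle(self):
        px = np.zeros((64, 64))
        px[10:50, 10:50] = 150.0  # 40×40 square
        inner = image_from(disk_image(8, shape=(64, 64), center=(30, 30)))
        (soma,) = segment_somata(inner, 100, 1.0)
        out = segment_neuropil(image_from(px), 100, [soma])
        expected = np.count_nonzero(px >= 100) - np.count_nonzero(soma.region)
        assert np.count_nonzero(out) == expected

    def test_geometry_mismatch(self):
        (soma,) = segment_somata(image_from(disk_image(10)), 100, 1.0)
        with pytest.raises(GeometryError):
            segment_neuropil(image_from(np.zeros((32, 32))), 10, [soma])


class TestSegmentAis:
    def test_straight_bar_length(self):
        px = np.zeros((128, 128))
        px[60:63, 10:110] = 200.0  # 100 px long, 3 px wide
        (ais,) = segment_ais(image_from(px), 100)
        assert ais.length_um == pytest.approx(10.0, rel=0.05)

    def test_blank_empty(self):
        assert segment_ais(image_from(np.zeros((64, 64))), 100) == []

    def test_l_shape_longest_geodesic(self):
        px = np.zeros((128, 128))
        px[20:70, 20:23] = 200.0  # vertical arm, 50 px = 5 μm
        px[67:70, 20:70] = 200.0  # horizontal arm, 50 px = 5 μm
        (ais,) = segment_ais(image_from(px), 100)
        assert ais.length_um == pytest.approx(10.0, rel=0.10)

    def test_min_length_filter(self):
        px = np.zeros((128, 128))
        px[60:63, 10:110] = 200.0
        px[20:23, 10:30] = 200.0  # 2 μm stub
        out = segment_ais(image_from(px), 100, min_length_um=5.0)
        assert len(out) == 1


class TestDetectPuncta:
    @staticmethod
    def _punctum_image(n_pixels):
        px = np.zeros((64, 64))
        px.ravel()[2080 : 2080 + n_pixels] = 200.0  # one row-contiguous blob
        return image_from(px)

    def test_five_pixels_excluded_for_gad65(self, qparams):
        """0.05 μm² misses the 0.06 μm² minimum for GAD65-class boutons."""
        out = detect_puncta(self._punctum_image(5), 100, qparams, "GAD65")
        assert len(out) == 0

    def test_six_pixels_retained_for_gad65(self, qparams):
        """Exactly 0.06 μm² is kept: the size minimum is inclusive."""
        out = detect_puncta(self._punctum_image(6), 100, qparams, "GAD65")
        assert len(out) == 1
        assert out.table.area_um2.iloc[0] == pytest.approx(0.06, abs=1e-12)

    def test_five_pixels_retained_for_vglut1(self, qparams):
        out = detect_puncta(self._punctum_image(5), 100, qparams, "VGlut1")
        assert len(out) == 1

    def test_unknown_marker_class(self, qparams):
        with pytest.raises(KeyError, match="marker class"):
            detect_puncta(self._punctum_image(6), 100, qparams, "NeuN")

    def test_dumbbell_split_by_watershed(self, qparams):
        """Two touching Gaussian-spot blobs have two distance-transform
        maxima, hence watershed yields two puncta."""
        px = np.zeros((64, 64))
        rr, cc = draw.disk((32, 26), 5, shape=(64, 64))
        px[rr, cc] = 200.0
        rr, cc = draw.disk((32, 36), 5, shape=(64, 64))
        px[rr, cc] = 200.0
        out = detect_puncta(image_from(px), 100, qparams, "GAD65")
        assert len(out) == 2

    def test_area_equals_pixel_count_oracle(self, qparams, small_scene):
        _, channels, _ = small_scene
        spec = small_scene[0]
        out = detect_puncta(
            channels["presyn_marker"], spec.suggested_puncta_threshold,
            qparams, "GAD65",
        )
        for row in out.table.itertuples(index=False):
            n_px = np.count_nonzero(out.labels == row.label)
            assert row.area_um2 == pytest.approx(n_px * PX**2, abs=1e-12)

    def test_threshold_monotonicity(self, noisy_scene):
        spec, channels, _ = noisy_scene
        img = channels["presyn_marker"]
        areas = [
            np.count_nonzero(img.pixels >= t) for t in (40, 60, 80, 100)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_min_area_monotonicity(self, noisy_scene):
        spec, channels, _ = noisy_scene
        counts = []
        for min_area in (0.02, 0.05, 0.10, 0.2):
            p = QuantParams(min_punctum_area_um2={"X": min_area})
            counts.append(
                len(detect_puncta(channels["presyn_marker"],
                                  spec.suggested_puncta_threshold, p, "X"))
            )
        assert counts == sorted(counts, reverse=True)

    def test_perfect_recovery_on_clean_scene(self, qparams, small_scene):
        """Non-touching planted puncta above the minimum: recall and
        precision both 1.0 at the generating threshold."""
        spec, channels, truth = small_scene
        out = detect_puncta(
            channels["presyn_marker"], spec.suggested_puncta_threshold,
            qparams, "GAD65",
        )
        assert len(out) == len(truth.boutons)
        # every detection sits on exactly one planted punctum
        hit = {
            truth.bouton_labels[out.labels == lab].max()
            for lab in out.table["label"]
        }
        assert len(hit) == len(truth.boutons) and 0 not in hit
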