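import numpy as np
import pandas as pd
import pytest

from synquant import (
    QuantParams,
    SampleKey,
    assign_pairs_to_process,
    call_contacts,
    call_contained_clusters,
    linear_density,
    overlap_area,
    pair_synapses,
)
from synquant.io import GeometryError
from synquant.segment import PunctaSet, SomaMask

from conftest import PX


def puncta_from_labels(labels, pixel_size_um=PX):
    labels = np.asarray(labels, dtype=np.int32)
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        ys, xs = np.nonzero(labels == lab)
        rows.append(
            {
                "label": int(lab),
                "area_um2": len(ys) * pixel_size_um**2,
                "centroid_row": ys.mean(),
                "centroid_col": xs.mean(),
                "circularity": 1.0,
            }
        )
    return PunctaSet(labels=labels, table=pd.DataFrame(rows), pixel_size_um=pixel_size_um)


def soma_from_mask(mask, label=1, pixel_size_um=PX):
    mask = np.asarray(mask, dtype=bool)
    return SomaMask(
        label=label,
        region=mask,
        area_um2=mask.sum() * pixel_size_um**2,
        perimeter_um=1.0,
        centroid=(0.0, 0.0),
        pixel_size_um=pixel_size_um,
    )


def rect_labels(shape, boxes):
    """Labeled grid from (label, y0, y1, x0, x1) half-open boxes."""
    out = np.zeros(shape, dtype=np.int32)
    for lab, y0, y1, x0, x1 in boxes:
        out[y0:y1, x0:x1] = lab
    return out


class TestOverlapArea:
    def test_disjoint_is_zero(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:4], b[8:] = True, True
        assert overlap_area(a, b, PX) == 0.0

    def test_identical_ten_pixels(self):
        m = np.zeros((16, 16), bool)
        m.ravel()[:10] = True
        assert overlap_area(m, m, PX) == pytest.approx(0.10, abs=1e-12)

    def test_four_pixel_intersection(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[0:4, 0:4] = True
        b[2:6, 2:6] = True  # 2×2 intersection
        assert overlap_area(a, b, PX) == pytest.approx(0.04, abs=1e-12)

    def test_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((24, 24)) < 0.3
            b = rng.random((24, 24)) < 0.3
            brute = sum(
                1 for i in range(24) for j in range(24) if a[i, j] and b[i, j]
            ) * PX**2
            assert overlap_area(a, b, PX) == pytest.approx(brute, abs=1e-12)
            assert overlap_area(b, a, PX) == overlap_area(a, b, PX)

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryError):
            overlap_area(np.zeros((4, 4), bool), np.zeros((5, 5), bool), PX)


class TestCallContacts:
    def test_exact_threshold_overlap_is_contact(self):
        """Exactly 0.04 μm² of overlap qualifies (inclusive criterion)."""
        labels = rect_labels((32, 32), [(1, 10, 14, 8, 12)])  # 16 px punctum
        soma = soma_from_mask(rect_labels((32, 32), [(1, 10, 14, 11, 32)]) > 0)
        # punctum columns 8..11, soma columns 11..: 4 rows × 1 col = 4 px
        contacts = call_contacts(puncta_from_labels(labels), soma, 0.04)
        assert len(contacts) == 1
        assert contacts[0].overlap_area_um2 == pytest.approx(0.04, abs=1e-12)

    def test_one_pixel_below_threshold_is_no_contact(self):
        labels = rect_labels((32, 32), [(1, 10, 13, 8, 12)])  # 3 rows now
        soma = soma_from_mask(rect_labels((32, 32), [(1, 10, 14, 11, 32)]) > 0)
        # 3 rows × 1 col = 3 px = 0.03 μm² < 0.04
        assert call_contacts(puncta_from_labels(labels), soma, 0.04) == []

    def test_punctum_inside_soma_overlap_equals_area(self):
        labels = rect_labels((32, 32), [(1, 10, 14, 10, 14)])
        soma = soma_from_mask(np.ones((32, 32), bool))
        (c,) = call_contacts(puncta_from_labels(labels), soma, 0.04)
        assert c.overlap_area_um2 == pytest.approx(0.16, abs=1e-12)

    def test_assignment_prefers_larger_overlap_then_lower_id(self):
        labels = rect_labels((32, 32), [(1, 10, 14, 10, 18)])  # 4×8 punctum
        left = soma_from_mask(rect_labels((32, 32), [(1, 0, 32, 0, 13)]) > 0, label=1)
        right = soma_from_mask(rect_labels((32, 32), [(1, 0, 32, 13, 32)]) > 0, label=2)
        (c,) = call_contacts(puncta_from_labels(labels), [left, right], 0.04)
        assert c.structure_id == 2  # 4×5 px on the right vs 4×3 on the left
        # tie case: symmetric split → lower structure id wins
        labels = rect_labels((32, 32), [(1, 10, 14, 9, 17)])  # 4×4 each side
        (c,) = call_contacts(puncta_from_labels(labels), [left, right], 0.04)
        assert c.structure_id == 1

    def test_monotone_in_min_overlap(self, small_scene):
        from synquant import detect_puncta

        spec, channels, truth = small_scene
        puncta = detect_puncta(
            channels["presyn_marker"], spec.suggested_puncta_threshold,
            QuantParams(), "GAD65",
        )
        counts = [
            len(call_contacts(puncta, truth.somas, m))
            for m in (0.01, 0.04, 0.08, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)


class TestContainedClusters:
    def test_straddling_cluster_contained(self):
        labels = rect_labels((32, 32), [(1, 10, 15, 9, 12)])
        soma = soma_from_mask(rect_labels((32, 32), [(1, 0, 32, 10, 32)]) > 0)
        # 5 rows × 2 cols inside = 0.10 ≥ 0.04
        (c,) = call_contained_clusters(puncta_from_labels(labels), soma)
        assert c.overlap_area_um2 == pytest.approx(0.10, abs=1e-12)

    def test_outside_cluster_not_contained(self):
        labels = rect_labels((32, 32), [(1, 0, 4, 0, 4)])
        soma = soma_from_mask(rect_labels((32, 32), [(1, 16, 32, 16, 32)]) > 0)
        assert call_contained_clusters(puncta_from_labels(labels), soma) == []

    def test_cluster_equal_to_soma(self):
        mask = rect_labels((32, 32), [(1, 8, 16, 8, 16)])
        soma = soma_from_mask(mask > 0)
        (c,) = call_contained_clusters(puncta_from_labels(mask), soma)
        assert c.overlap_area_um2 == pytest.approx(soma.area_um2, abs=1e-12)


class TestPairSynapses:
    def test_no_overlap_no_pairs(self):
        pre = puncta_from_labels(rect_labels((32, 32), [(1, 0, 4, 0, 4)]))
        post = puncta_from_labels(rect_labels((32, 32), [(1, 20, 24, 20, 24)]))
        assert pair_synapses(pre, post) == []

    def test_exact_003_overlap_pairs(self):
        """Exactly 0.03 μm² (3 px at 0.1 μm/px) forms a synapse pair."""
        pre = puncta_from_labels(rect_labels((32, 32), [(1, 10, 13, 8, 12)]))
        post = puncta_from_labels(rect_labels((32, 32), [(1, 10, 13, 11, 15)]))
        (p,) = pair_synapses(pre, post, 0.03)
        assert p.pair_overlap_um2 == pytest.approx(0.03, abs=1e-12)

    def test_one_pixel_less_is_no_pair(self):
        pre = puncta_from_labels(rect_labels((32, 32), [(1, 10, 12, 8, 12)]))
        post = puncta_from_labels(rect_labels((32, 32), [(1, 10, 12, 11, 15)]))
        assert pair_synapses(pre, post, 0.03) == []  # 2 px = 0.02

    def test_greedy_prefers_larger_overlap(self):
        """One pre over two posts (0.05 vs 0.04): matched to the larger."""
        pre = puncta_from_labels(rect_labels((32, 32), [(1, 10, 19, 10, 11)]))
        post = puncta_from_labels(
            rect_labels((32, 32), [(1, 10, 15, 10, 14), (2, 15, 19, 10, 14)])
        )
        (p,) = pair_synapses(pre, post, 0.03)
        assert p.post_label == 1
        assert p.pair_overlap_um2 == pytest.approx(0.05, abs=1e-12)

    def test_one_to_one_matching_on_random_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pre_lab = rng.integers(0, 4, (24, 24)).astype(np.int32)
            post_lab = rng.integers(0, 4, (24, 24)).astype(np.int32)
            pairs = pair_synapses(
                puncta_from_labels(pre_lab), puncta_from_labels(post_lab), 0.03
            )
            assert len({p.pre_label for p in pairs}) == len(pairs)
            assert len({p.post_label for p in pairs}) == len(pairs)
            assert all(p.pair_overlap_um2 >= 0.03 for p in pairs)


class TestProcessAssignment:
    @staticmethod
    def _setup(pre_boxes):
        pre = puncta_from_labels(rect_labels((32, 32), pre_boxes))
        post = puncta_from_labels(rect_labels((32, 32), pre_boxes))  # same spot
        pairs = pair_synapses(pre, post, 0.03)
        return pre, post, pairs

    def test_empty_process_mask_drops_all(self):
        pre, post, pairs = self._setup([(1, 10, 14, 10, 14)])
        assert (
            assign_pairs_to_process(pairs, pre, np.zeros((32, 32), bool)) == []
        )

    def test_pre_inside_process_retained(self):
        pre, post, pairs = self._setup([(1, 10, 14, 10, 14)])
        kept = assign_pairs_to_process(pairs, pre, np.ones((32, 32), bool))
        assert len(kept) == 1
        assert kept[0].process_overlap_um2 == pytest.approx(0.16, abs=1e-12)

    def test_two_pixel_overlap_dropped(self):
        pre, post, pairs = self._setup([(1, 10, 14, 10, 14)])
        proc = rect_labels((32, 32), [(1, 10, 12, 10, 11)]) > 0  # 2 px
        assert assign_pairs_to_process(pairs, pre, proc, 0.025) == []

    def test_exact_0025_retained_at_fine_calibration(self):
        """At 0.05 μm/px, 10 shared pixels are exactly 0.025 μm² and
        qualify; 9 pixels (0.0225 μm²) do not."""
        lab = rect_labels((32, 32), [(1, 10, 15, 10, 15)])
        pre = puncta_from_labels(lab, pixel_size_um=0.05)
        post = puncta_from_labels(lab, pixel_size_um=0.05)
        pairs = pair_synapses(pre, post, 0.03)
        proc10 = rect_labels((32, 32), [(1, 10, 12, 10, 15)]) > 0  # 10 px
        assert len(assign_pairs_to_process(pairs, pre, proc10, 0.025)) == 1
        proc9 = proc10.copy()
        proc9[10, 10] = False
        assert assign_pairs_to_process(pairs, pre, proc9, 0.025) == []

    def test_union_and_either_modes(self):
        pre, post, pairs = self._setup([(1, 10, 14, 10, 14)])
        proc = rect_labels((32, 32), [(1, 10, 12, 10, 11)]) > 0  # 2 px on each
        assert assign_pairs_to_process(pairs, pre, proc, 0.025, "pre") == []
        kept = assign_pairs_to_process(pairs, pre, proc, 0.025, "union", post)
        assert len(kept) == 1  # 0.02 + 0.02 ≥ 0.025
        assert (
            assign_pairs_to_process(pairs, pre, proc, 0.025, "either", post) == []
        )

    def test_unknown_mode(self):
        pre, post, pairs = self._setup([(1, 10, 14, 10, 14)])
        with pytest.raises(ValueError, match="mode"):
            assign_pairs_to_process(pairs, pre, np.ones((32, 32), bool), mode="post")


class TestLinearDensity:
    def test_zero_contacts(self):
        soma = soma_from_mask(np.ones((8, 8), bool))
        rec = linear_density([], soma)
        assert rec.density == 0.0

    def test_five_on_25um_perimeter(self):
        soma = SomaMask(1, np.ones((8, 8), bool), 1.0, 25.0, (0, 0), PX)
        rec = linear_density(5, soma, SampleKey("c", "a", "g"))
        assert rec.density == pytest.approx(0.2)
        assert rec.per_10um == pytest.approx(2.0)
        assert rec.structure_type == "soma"

    def test_planted_scene_density(self, small_scene):
        from synquant import detect_puncta

        spec, channels, truth = small_scene
        puncta = detect_puncta(
            channels["presyn_marker"], spec.suggested_puncta_threshold,
            QuantParams(), "GAD65",
        )
        soma = truth.somas[0]
        contacts = call_contacts(puncta, soma, 0.04)
        rec = linear_density(contacts, soma)
        expected = truth.bouton_count("soma", soma.label)
        assert rec.count == expected
        assert rec.density == pytest.approx(expected / soma.perimeter_um)

    def test_zero_normalizer_rejected(self):
        soma = SomaMask(1, np.ones((4, 4), bool), 1.0, 0.0, (0, 0), PX)
        with pytest.raises(ValueError):
            linear_density(1, soma)
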