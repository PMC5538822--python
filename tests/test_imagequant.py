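"""Spot detection, pairing, pericentric segmentation and condition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetquant import imagequant as iq


def _image(dna=None, measure=None, marker=None, shape=(32, 32)):
    planes = []
    roles = {}
    for role, plane in (("dna", dna), ("measure", measure), ("marker", marker)):
        roles[role] = len(planes)
        planes.append(np.zeros(shape) if plane is None else np.asarray(plane, float))
    return iq.MultiChannelImage(np.stack(planes), roles=roles)


def _gaussian_spot(shape, center, sigma=1.5, amp=100.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# max projection
# ---------------------------------------------------------------------------

class TestMaxProject:
    def test_single_plane_is_identity(self, rng):
        plane = rng.uniform(0, 10, size=(2, 8, 8))
        img = iq.max_project(plane[None], roles={"dna": 0, "marker": 1})
        np.testing.assert_array_equal(img.data, plane)
        assert img.provenance == "projected"

    def test_pixelwise_maximum(self):
        a = np.full((1, 2, 2), 1.0)
        b = np.full((1, 2, 2), 5.0)
        img = iq.max_project(np.stack([a, b]), roles={"dna": 0})
        assert img.data.max() == img.data.min() == 5.0

    def test_matches_bruteforce_loop(self, rng):
        stack = rng.uniform(0, 100, size=(3, 2, 4, 4))
        img = iq.max_project(stack, roles={"dna": 0, "marker": 1})
        for c in range(2):
            for r in range(4):
                for col in range(4):
                    expected = max(stack[p, c, r, col] for p in range(3))
                    assert img.data[c, r, col] == expected

    def test_mismatched_plane_shapes_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            iq.max_project([np.zeros((1, 4, 4)), np.zeros((1, 5, 4))], roles={"dna": 0})


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------

def _flood_fill_components(mask, connectivity):
    """Independent BFS flood-fill oracle; returns sorted component areas."""
    mask = np.asarray(mask, bool)
    visited = np.zeros_like(mask)
    if connectivity == 1:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    areas = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or visited[r, c]:
                continue
            queue = [(r, c)]
            visited[r, c] = True
            area = 0
            while queue:
                cr, cc = queue.pop()
                area += 1
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                            and mask[nr, nc] and not visited[nr, nc]):
                        visited[nr, nc] = True
                        queue.append((nr, nc))
            areas.append(area)
    return sorted(areas)


class TestDetectSpots:
    def test_two_rendered_spots_found_at_centroids(self):
        centers = [(10.0, 10.0), (22.0, 25.0)]
        marker = sum(_gaussian_spot((32, 32), c) for c in centers)
        img = _image(marker=marker)
        spots = iq.detect_spots(img, "marker", min_size=5)
        assert len(spots) == 2
        found = sorted(s.centroid for s in spots)
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) < 0.5 and abs(fc - tc) < 0.5

    def test_component_below_min_size_excluded(self):
        marker = np.zeros((16, 16))
        marker[3, 3:6] = 100.0      # 3-pixel component
        marker[10:13, 10:13] = 100.0  # 9-pixel component keeps Otsu sane
        img = _image(marker=marker, shape=(16, 16))
        spots = iq.detect_spots(img, "marker", min_size=4)
        assert len(spots) == 1
        assert spots[0].area == 9

    def test_blank_channel_gives_empty_set(self):
        img = _image(shape=(16, 16))
        assert iq.detect_spots(img, "marker", min_size=1) == []

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2]))
    @settings(max_examples=30, deadline=None)
    def test_components_match_flood_fill_oracle(self, seed, connectivity):
        """Component count and areas agree with an independent BFS flood fill."""
        grid_rng = np.random.default_rng(seed)
        mask = grid_rng.random((32, 32)) < 0.35
        marker = np.where(mask, 10.0, 0.0)
        img = _image(marker=marker)
        spots = iq.detect_spots(img, "marker", min_size=1, threshold=0.5,
                                connectivity=connectivity)
        if not mask.any():
            assert spots == []
            return
        oracle = _flood_fill_components(mask, connectivity)
        assert sorted(s.area for s in spots) == oracle

    def test_scale_equivariance_with_quantile_threshold(self, rng):
        marker = _gaussian_spot((32, 32), (15, 15)) + rng.uniform(0, 1, (32, 32))
        img1 = _image(marker=marker)
        img2 = _image(marker=marker * 7.3)
        s1 = iq.detect_spots(img1, "marker", min_size=1, threshold=0.98)
        s2 = iq.detect_spots(img2, "marker", min_size=1, threshold=0.98)
        assert [s.pixels for s in s1] == [s.pixels for s in s2]

    def test_sorted_by_integrated_intensity(self):
        marker = _gaussian_spot((32, 32), (8, 8), amp=50.0)
        marker += _gaussian_spot((32, 32), (24, 24), amp=200.0)
        spots = iq.detect_spots(_image(marker=marker), "marker", min_size=1)
        assert spots[0].integrated_intensity >= spots[-1].integrated_intensity
        assert abs(spots[0].centroid[0] - 24) < 1


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _spot_at(r, c):
    return iq.Spot(centroid=(float(r), float(c)), area=1,
                   pixels=((int(round(r)), int(round(c))),),
                   integrated_intensity=1.0)


def _greedy_pairing_oracle(centroids, max_dist):
    """Exhaustive pairwise enumeration, greedily matched by ascending distance."""
    dists = []
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            d = np.hypot(centroids[i][0] - centroids[j][0],
                         centroids[i][1] - centroids[j][1])
            if d <= max_dist:
                dists.append((d, i, j))
    used, pairs = set(), []
    for d, i, j in sorted(dists):
        if i not in used and j not in used:
            used |= {i, j}
            pairs.append(frozenset((i, j)))
    return set(pairs)


class TestPairCentromeres:
    def test_two_spots_within_max_dist_pair(self):
        pairs, unpaired = iq.pair_centromeres([_spot_at(5, 5), _spot_at(5, 15)],
                                              max_dist=17)
        assert len(pairs) == 1 and unpaired == []
        assert pairs[0].separation == pytest.approx(10.0)

    def test_two_spots_beyond_max_dist_stay_unpaired(self):
        pairs, unpaired = iq.pair_centromeres([_spot_at(5, 5), _spot_at(5, 25)],
                                              max_dist=17)
        assert pairs == [] and len(unpaired) == 2

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    @settings(max_examples=50, deadline=None)
    def test_matches_enumeration_oracle(self, seed, n):
        pts_rng = np.random.default_rng(seed)
        pts = [tuple(p) for p in pts_rng.uniform(0, 40, size=(n, 2))]
        spots = [_spot_at(r, c) for r, c in pts]
        pairs, unpaired = iq.pair_centromeres(spots, max_dist=17)
        got = {frozenset((spots.index(p.first), spots.index(p.second))) for p in pairs}
        assert got == _greedy_pairing_oracle(pts, 17)
        assert len(pairs) * 2 + len(unpaired) == n

    def test_matching_property_no_spot_in_two_pairs(self, rng):
        spots = [_spot_at(r, c) for r, c in rng.uniform(0, 30, size=(7, 2))]
        pairs, _ = iq.pair_centromeres(spots, max_dist=17)
        seen = [id(s) for p in pairs for s in (p.first, p.second)]
        assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# pericentric segmentation
# ---------------------------------------------------------------------------

class TestSegmentPericentric:
    def test_region_area_equals_lattice_point_count(self):
        """Anchor in a uniform DNA disc: area = lattice points within radius."""
        shape = (64, 64)
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        dna = np.where(np.hypot(rr - 32, cc - 32) <= 20, 100.0, 0.0)
        img = _image(dna=dna, shape=shape)
        anchor = _spot_at(32, 32)
        regions = iq.segment_pericentric(img, pairs=[], unpaired=[anchor],
                                         radius=10, dna_threshold=0.5)
        expected = sum(
            1
            for r in range(64)
            for c in range(64)
            if (r - 32) ** 2 + (c - 32) ** 2 <= 100
        )
        assert regions[0].area == expected

    def test_dna_below_threshold_gives_empty_regions(self):
        img = _image(shape=(16, 16))
        regions = iq.segment_pericentric(img, pairs=[], unpaired=[_spot_at(8, 8)],
                                         radius=5)
        assert regions[0].area == 0

    def test_region_respects_dna_mask_and_radius(self, rng):
        dna = (rng.random((32, 32)) < 0.4) * 100.0
        img = _image(dna=dna)
        anchor = _spot_at(16, 16)
        regions = iq.segment_pericentric(img, pairs=[], unpaired=[anchor],
                                         radius=10, dna_threshold=0.5)
        for (r, c) in regions[0].pixels:
            assert dna[r, c] > 0
            assert np.hypot(r - 16, c - 16) <= 10

    def test_overlap_assigned_to_nearest_anchor(self):
        dna = np.full((16, 32), 100.0)
        dna[0, :] = 0.0  # keep the quantile threshold below the DNA plateau
        img = _image(dna=dna, shape=(16, 32))
        a, b = _spot_at(8, 10), _spot_at(8, 20)
        regions = iq.segment_pericentric(img, pairs=[], unpaired=[a, b],
                                         radius=10, dna_threshold=0.05)
        assert regions[0].area > 0 and regions[1].area > 0
        for (r, c) in regions[0].pixels:
            assert np.hypot(r - 8, c - 10) <= np.hypot(r - 8, c - 20)
        total = regions[0].area + regions[1].area
        # no pixel double-counted
        assert len({p for reg in regions for p in reg.pixels}) == total

    def test_mask_invariant_under_anchor_order(self):
        dna = np.full((16, 32), 100.0)
        dna[0, :] = 0.0
        img = _image(dna=dna, shape=(16, 32))
        a, b = _spot_at(8, 10), _spot_at(8, 21)
        r1 = iq.segment_pericentric(img, [], [a, b], radius=8, dna_threshold=0.05)
        r2 = iq.segment_pericentric(img, [], [b, a], radius=8, dna_threshold=0.05)
        assert all(r.area > 0 for r in r1)
        assert {frozenset(r.pixels) for r in r1} == {frozenset(r.pixels) for r in r2}


# ---------------------------------------------------------------------------
# quantification and condition summaries
# ---------------------------------------------------------------------------

class TestQuantifyRegions:
    def test_uniform_channel_gives_value_times_area(self):
        measure = np.full((16, 16), 3.0)
        rr, cc = np.mgrid[0:16, 0:16].astype(float)
        dna = np.where(np.hypot(rr - 8, cc - 8) <= 6, 100.0, 0.0)
        img = _image(dna=dna, measure=measure, shape=(16, 16))
        regions = iq.segment_pericentric(img, [], [_spot_at(8, 8)], radius=4,
                                         dna_threshold=0.5)
        quant = iq.quantify_regions(img, regions)
        assert quant.region_integrated[0] == pytest.approx(3.0 * regions[0].area)
        assert quant.region_mean[0] == pytest.approx(3.0)

    def test_linearity_in_measure_channel(self, rng):
        dna = np.full((16, 16), 100.0)
        dna[0, :] = 0.0
        measure = rng.uniform(0, 10, (16, 16))
        img1 = _image(dna=dna, measure=measure, shape=(16, 16))
        img2 = _image(dna=dna, measure=2 * measure, shape=(16, 16))
        regions = iq.segment_pericentric(img1, [], [_spot_at(8, 8)], radius=5,
                                         dna_threshold=0.05)
        q1 = iq.quantify_regions(img1, regions)
        q2 = iq.quantify_regions(img2, regions)
        assert q1.image_integrated > 0
        assert q2.image_integrated == pytest.approx(2 * q1.image_integrated)

    def test_empty_region_set(self):
        img = _image(shape=(8, 8))
        quant = iq.quantify_regions(img, [])
        assert quant.image_integrated == 0.0 and quant.n_regions == 0

    def test_image_total_is_sum_of_regions(self, rng):
        dna = (rng.random((32, 32)) < 0.5) * 100.0
        measure = rng.uniform(0, 5, (32, 32))
        img = _image(dna=dna, measure=measure)
        regions = iq.segment_pericentric(img, [], [_spot_at(10, 10), _spot_at(22, 22)],
                                         radius=8, dna_threshold=0.5)
        quant = iq.quantify_regions(img, regions)
        assert quant.image_integrated == pytest.approx(sum(quant.region_integrated))


def _quants(values):
    rows = []
    for cond, by_exp in values.items():
        for exp, vals in enumerate(by_exp):
            for v in vals:
                rows.append({"condition": cond, "experiment": exp, "value": v})
    return pd.DataFrame(rows)


class TestSummarizeCondition:
    def test_reference_maps_to_one_background_to_zero(self):
        df = _quants({"bg": [[1.0, 1.0]], "ref": [[5.0, 5.0]], "same": [[5.0, 5.0]]})
        out = iq.summarize_condition(df, "bg", "ref")
        assert out["ref"].value == pytest.approx(1.0)
        assert out["same"].value == pytest.approx(1.0)
        assert out["bg"].value == pytest.approx(0.0)

    def test_three_experiments_hand_arithmetic(self):
        df = _quants({
            "bg": [[1.0], [2.0], [1.0]],
            "ref": [[5.0], [6.0], [9.0]],
            "cond": [[3.0], [4.0], [5.0]],
        })
        out = iq.summarize_condition(df, "bg", "ref")
        expected = np.array([(3 - 1) / (5 - 1), (4 - 2) / (6 - 2), (5 - 1) / (9 - 1)])
        assert out["cond"].per_experiment == pytest.approx(tuple(expected))
        assert out["cond"].value == pytest.approx(expected.mean())
        assert out["cond"].sem == pytest.approx(expected.std(ddof=1) / np.sqrt(3))

    def test_reference_not_above_background_errors(self):
        df = _quants({"bg": [[5.0]], "ref": [[5.0]], "c": [[1.0]]})
        with pytest.raises(ValueError, match="reference mean"):
            iq.summarize_condition(df, "bg", "ref")

    def test_invariant_under_common_affine_rescaling(self, rng):
        df = _quants({"bg": [[1.0, 1.2]], "ref": [[7.0, 8.0]], "c": [[3.0, 3.5]]})
        out1 = iq.summarize_condition(df, "bg", "ref")
        df2 = df.copy()
        df2["value"] = df2["value"] * 3.7 + 11.0
        out2 = iq.summarize_condition(df2, "bg", "ref")
        assert out1["c"].value == pytest.approx(out2["c"].value)


class TestQuantifySpreadModes:
    def test_centromere_mode_quantifies_spot_pixels_only(self):
        marker = _gaussian_spot((64, 64), (20, 20)) + _gaussian_spot((64, 64), (40, 40))
        measure = np.full((64, 64), 2.0)
        img = _image(measure=measure, marker=marker, shape=(64, 64))
        quant = iq.quantify_spread(img, mode="centromere", min_size=5, max_size=60)
        assert quant.n_regions == 2
        # region value = uniform measure value times spot area
        for val, area in zip(quant.region_integrated, quant.region_areas):
            assert val == pytest.approx(2.0 * area)

    def test_unknown_mode_errors(self, tiny_spread_spec):
        from hetquant import synthdata as sd
        images, _, _ = sd.make_spread_images(tiny_spread_spec, 1)
        with pytest.raises(ValueError, match="mode"):
            iq.quantify_spread(images[0], mode="nucleus")


class TestImageIO:
    def test_tiff_roundtrip(self, tmp_path, rng):
        img = _image(marker=rng.uniform(0, 10, (16, 16)), shape=(16, 16))
        path = tmp_path / "img.tiff"
        iq.write_image(img, path)
        back = iq.read_image(path)
        np.testing.assert_allclose(back.data, img.data, rtol=1e-6)
        assert back.roles == dict(img.roles)
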