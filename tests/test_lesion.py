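"""Otsu thresholding, connected components (vs union-find oracle), lesion
mask extraction, and the total-NWU readout."""
import numpy as np
import pytest

from nwuct.config import RunConfig
from nwuct.errors import DegenerateHistogramError, EmptyMaskError
from nwuct.lesion import (extract_lesion_mask, largest_connected_component,
                          lesion_nwu, otsu_threshold)
from nwuct.nwu import NWUMap


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def otsu_oracle(values, nbins=256):
    """Exhaustive search over all interior bin edges maximizing the
    between-class variance, written with plain loops.  Ties (flat variance
    across an empty gap) resolve to the plateau midpoint."""
    v = np.sort(np.asarray(values, dtype=float))
    hist, edges = np.histogram(v, bins=nbins)
    centers = [(edges[i] + edges[i + 1]) / 2.0 for i in range(nbins)]
    total = hist.sum()
    sigmas = {}
    for k in range(1, nbins):           # threshold at edges[k]
        n0 = sum(hist[:k])
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = sum(hist[i] * centers[i] for i in range(k)) / n0
        mu1 = sum(hist[i] * centers[i] for i in range(k, nbins)) / n1
        sigmas[k] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    best = max(sigmas.values())
    plateau = [k for k, s in sigmas.items() if s >= best - 1e-9 * abs(best)]
    return edges[plateau[len(plateau) // 2]]


def union_find_components(mask, connectivity):
    """Brute-force connected components via union-find over voxel pairs."""
    idx = {tuple(p): n for n, p in enumerate(np.argwhere(mask))}
    parent = list(range(len(idx)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    if connectivity == 6:
        offs = [o for o in offs if sum(map(abs, o)) == 1]
    for (x, y, z), n in idx.items():
        for dx, dy, dz in offs:
            m = idx.get((x + dx, y + dy, z + dz))
            if m is not None:
                union(n, m)
    groups = {}
    for p, n in idx.items():
        groups.setdefault(find(n), []).append(p)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_bimodal_threshold_separates_modes(self, rng):
        vals = np.concatenate([rng.normal(2.0, 0.1, 100), rng.normal(20.0, 0.1, 100)])
        thr = otsu_threshold(vals)
        assert 3.0 < thr < 19.0
        assert thr == pytest.approx(otsu_oracle(vals), abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full(50, 7.0))

    def test_invariant_to_duplication(self, rng):
        vals = np.concatenate([rng.normal(3, 1, 80), rng.normal(15, 1, 40)])
        assert otsu_threshold(vals) == otsu_threshold(np.tile(vals, 3))

    def test_matches_skimage_within_one_bin(self, rng):
        # overlapping modes so the variance maximum is unique (skimage keeps
        # the first histogram bin of a tie plateau, this module its midpoint)
        from skimage.filters import threshold_otsu

        vals = np.concatenate([rng.normal(4, 2.0, 400), rng.normal(14, 2.5, 200)])
        binw = (vals.max() - vals.min()) / 256
        # skimage reports the winning bin's centre, this module the bin edge
        assert abs(otsu_threshold(vals) - threshold_otsu(vals, nbins=256)) <= 1.5 * binw


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

class TestLargestCC:
    def test_picks_larger_cuboid(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[1:4, 1:4, 1:4] = True      # 27 voxels
        m[8:10, 8:10, 8:10] = True   # 8 voxels
        out, n = largest_connected_component(m, 26)
        assert n == 2
        assert out.sum() == 27 and out[2, 2, 2] and not out[8, 8, 8]

    def test_equal_sizes_tie_break_smallest_index(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[6:9, 6:9, 6:9] = True
        m[0:3, 0:3, 0:3] = True      # same 27 voxels, smaller linear index
        out, _ = largest_connected_component(m, 26)
        assert out[1, 1, 1] and not out[7, 7, 7]

    def test_diagonal_connectivity_difference(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True   # touch only diagonally
        _, n26 = largest_connected_component(m, 26)
        _, n6 = largest_connected_component(m, 6)
        assert n26 == 1 and n6 == 2

    def test_empty_input_gives_empty_output(self):
        out, n = largest_connected_component(np.zeros((5, 5, 5), dtype=bool), 26)
        assert n == 0 and not out.any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_union_find_oracle(self, connectivity, rng):
        for _ in range(10):
            m = rng.random((12, 12, 12)) < 0.25
            out, n = largest_connected_component(m, connectivity)
            comps = union_find_components(m, connectivity)
            assert n == len(comps)
            if comps:
                assert out.sum() == max(len(c) for c in comps)


# ---------------------------------------------------------------------------
# Lesion mask extraction
# ---------------------------------------------------------------------------

def _map_from(values, valid):
    return NWUMap(values=np.where(valid, values, np.nan), valid=valid)


class TestExtractLesionMask:
    def test_zero_map_yields_empty_mask(self):
        valid = np.ones((20, 20, 20), dtype=bool)
        mask, info = extract_lesion_mask(_map_from(np.zeros(valid.shape), valid),
                                         RunConfig())
        assert not mask.any()

    def test_keeps_only_largest_blob(self):
        values = np.zeros((40, 24, 24))
        valid = np.ones(values.shape, dtype=bool)
        values[2:12, 2:12, 2:12] = 15.0       # 1000 voxels
        values[20:27, 4:11, 4:11] = 15.0      # 343 voxels
        cfg = RunConfig(erosion_radius=1, dilation_radius=1)
        mask, info = extract_lesion_mask(_map_from(values, valid), cfg)
        assert mask[5, 5, 5] and not mask[23, 7, 7]
        assert info["component_count"] == 2

    def test_output_single_component_or_empty(self, rng):
        values = np.where(rng.random((24, 24, 24)) < 0.15, 12.0, 0.0)
        valid = np.ones(values.shape, dtype=bool)
        mask, _ = extract_lesion_mask(_map_from(values, valid),
                                      RunConfig(erosion_radius=1, dilation_radius=1))
        if mask.any():
            _, n = largest_connected_component(mask, 26)
            assert n == 1

    def test_raising_cutoff_never_grows_mask(self):
        values = np.zeros((30, 20, 20))
        values[4:16, 4:16, 4:16] = 10.0
        values[6:14, 6:14, 6:14] = 18.0
        valid = np.ones(values.shape, dtype=bool)
        sizes = []
        for cutoff in (2.0, 6.0, 12.0, 19.0):
            cfg = RunConfig(lower_cutoff=cutoff, erosion_radius=1, dilation_radius=1)
            mask, _ = extract_lesion_mask(_map_from(values, valid), cfg,
                                          threshold=cutoff)
            sizes.append(int(mask.sum()))
        assert sizes == sorted(sizes, reverse=True)

    def test_flood_fill_closes_interior_cavity(self):
        values = np.zeros((24, 24, 24))
        values[4:18, 4:18, 4:18] = 15.0
        values[10:12, 10:12, 10:12] = 0.0     # cavity inside the blob
        valid = np.ones(values.shape, dtype=bool)
        cfg = RunConfig(erosion_radius=1, dilation_radius=1)
        mask, _ = extract_lesion_mask(_map_from(values, valid), cfg)
        assert mask[10, 10, 10]


class TestLesionNWU:
    def test_exact_uptake_on_phantom_mask(self, lesion_case):
        # ground-truth mask on the phantom's own grid: mirrored contralateral
        # sampling must recover the implanted uptake
        got = lesion_nwu(lesion_case.ct.values, lesion_case.gt_mask.bool_values)
        assert got == pytest.approx(lesion_case.gt_nwu, abs=0.5)

    def test_exact_uptake_noise_free(self):
        from tests_helpers_phantom import noise_free_lesion_case

        case = noise_free_lesion_case(uptake=10.0)
        got = lesion_nwu(case.ct.values, case.gt_mask.bool_values)
        assert got == pytest.approx(10.0, abs=0.1)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            lesion_nwu(np.full((10, 10, 10), 35.0), np.zeros((10, 10, 10)))
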