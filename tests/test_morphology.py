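"""Morphology primitives against brute-force oracles.

Connected components are compared with a recursive flood fill, hole
filling with a flood fill from the border, and the automatic threshold
with an exhaustive 256-candidate between-class-variance search.
"""

from collections import deque

import numpy as np
import pytest

from nsmuscle import morphology as mo


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def flood_fill_partition(mask, connectivity=8):
    """Labels foreground by BFS flood fill; returns the label image."""
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                 (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    lab = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and lab[i, j] == 0:
                nxt += 1
                q = deque([(i, j)])
                lab[i, j] = nxt
                while q:
                    r, c = q.popleft()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and lab[rr, cc] == 0):
                            lab[rr, cc] = nxt
                            q.append((rr, cc))
    return lab, nxt


def border_flood_background(mask):
    """Background pixels 4-connected to the border (the non-holes)."""
    h, w = mask.shape
    bg = ~mask
    seen = np.zeros_like(bg)
    q = deque([(i, j) for i in range(h) for j in range(w)
               if bg[i, j] and (i in (0, h - 1) or j in (0, w - 1))])
    for i, j in q:
        seen[i, j] = True
    while q:
        r, c = q.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and bg[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                q.append((rr, cc))
    return seen


def exhaustive_otsu(plane, nbins=256):
    """Maximize between-class variance over nbins candidate thresholds."""
    lo, hi = plane.min(), plane.max()
    edges = np.linspace(lo, hi, nbins + 1)[1:-1]
    best_t, best_v = edges[0], -1.0
    for t in edges:
        low = plane[plane < t]
        high = plane[plane >= t]
        if low.size == 0 or high.size == 0:
            continue
        w0 = low.size / plane.size
        v = w0 * (1 - w0) * (low.mean() - high.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def same_partition(a, b):
    """Two label images induce the same partition of the foreground."""
    fg = (a > 0)
    if not np.array_equal(fg, b > 0):
        return False
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len(pairs) == len({p[0] for p in pairs})
            == len({p[1] for p in pairs}))


# ---------------------------------------------------------------------------
# binarize / invert
# ---------------------------------------------------------------------------

def test_binarize_fixed_threshold():
    m = mo.binarize(np.array([[0.2, 0.8]]),
                    mo.ThresholdStrategy("fixed", value=0.5))
    np.testing.assert_array_equal(m.mask, [[False, True]])
    assert m.provenance["threshold_used"] == 0.5


def test_binarize_all_zero_plane_is_all_false():
    with pytest.warns(UserWarning, match="constant"):
        m = mo.binarize(np.zeros((4, 4)))
    assert not m.mask.any()


def test_binarize_empty_plane_rejected():
    with pytest.raises(ValueError):
        mo.binarize(np.empty((0, 0)))


def test_otsu_separates_bimodal_plane_like_exhaustive_search(rng):
    plane = np.clip(np.concatenate([rng.normal(0.25, 0.04, 600),
                                    rng.normal(0.75, 0.04, 400)]),
                    0, 1).reshape(25, 40)
    t_impl = mo.otsu_threshold(plane)
    t_oracle = exhaustive_otsu(plane)
    # same bin up to the oracle's grid resolution; partitions agree for
    # every pixel outside the disputed bin
    binw = (plane.max() - plane.min()) / 256
    assert abs(t_impl - t_oracle) <= binw + 1e-12
    settled = np.abs(plane - t_oracle) > binw
    np.testing.assert_array_equal((plane >= t_impl)[settled],
                                  (plane >= t_oracle)[settled])


def test_invert_involution_and_examples():
    m = mo.BinaryMask(np.array([[True, False]]))
    inv = mo.invert(m)
    np.testing.assert_array_equal(inv.mask, [[False, True]])
    np.testing.assert_array_equal(mo.invert(inv).mask, m.mask)
    assert not mo.invert(mo.BinaryMask(np.ones((2, 2), bool))).mask.any()


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def test_diagonal_pixels_are_one_component():
    mask = np.zeros((3, 3), bool)
    mask[0, 0] = mask[1, 1] = True
    lm = mo.label_components(mask)
    assert lm.n_components == 1


def test_empty_mask_has_zero_components():
    assert mo.label_components(np.zeros((5, 5), bool)).n_components == 0


def test_labeling_matches_flood_fill_on_random_masks(rng):
    for _ in range(40):
        mask = rng.random((20, 20)) < 0.45
        lm = mo.label_components(mask)
        oracle, n = flood_fill_partition(mask)
        assert lm.n_components == n
        assert same_partition(lm.labels, oracle)


# ---------------------------------------------------------------------------
# small-component filter
# ---------------------------------------------------------------------------

def _labelmap_with_areas(areas):
    """One-row-per-component label map with the given pixel counts."""
    rows = []
    for i, a in enumerate(areas, start=1):
        row = np.zeros(max(areas) + 1, dtype=np.int32)
        row[:a] = i
        rows.append(row)
        rows.append(np.zeros_like(row))    # separator keeps components apart
    return mo.LabelMap(np.array(rows), len(areas))


def test_remove_small_exact_rule():
    lm = _labelmap_with_areas([100, 100, 10])   # mean 70, cutoff 14
    out = mo.remove_small(lm, 0.2)
    assert out.n_components == 2
    assert sorted(out.areas()[1:]) == [100, 100]


def test_remove_small_keeps_equal_areas_and_singletons():
    assert mo.remove_small(_labelmap_with_areas([50, 50, 50]),
                           0.99).n_components == 3
    assert mo.remove_small(_labelmap_with_areas([7]), 0.5).n_components == 1
    empty = mo.LabelMap(np.zeros((4, 4), np.int32), 0)
    assert mo.remove_small(empty, 0.2).n_components == 0


def test_remove_small_never_deletes_at_or_above_cutoff(rng):
    for _ in range(30):
        mask = rng.random((24, 24)) < 0.4
        lm = mo.label_components(mask)
        if lm.n_components == 0:
            continue
        areas = lm.areas()[1:]
        cutoff = 0.2 * areas.mean()
        out = mo.remove_small(lm, 0.2)
        kept = np.sort(out.areas()[1:])
        np.testing.assert_array_equal(kept, np.sort(areas[areas >= cutoff]))


# ---------------------------------------------------------------------------
# hole filling
# ---------------------------------------------------------------------------

def test_ring_becomes_solid_block():
    mask = np.zeros((7, 7), bool)
    mask[1:6, 1:6] = True
    mask[2:5, 2:5] = False
    mask[3, 3] = False
    lm = mo.label_components(mask)
    out = mo.fill_holes(lm)
    assert (out.labels[1:6, 1:6] == 1).all()
    assert out.labels[0].sum() == 0


def test_fill_holes_no_enclosed_background_is_identity(rng):
    mask = np.zeros((6, 6), bool)
    mask[2:4, 2:4] = True
    lm = mo.label_components(mask)
    np.testing.assert_array_equal(mo.fill_holes(lm).labels, lm.labels)


def test_fill_holes_matches_border_flood_oracle_on_nested_rings(rng):
    h = w = 21
    mask = np.zeros((h, w), bool)
    mask[2:19, 2:19] = True
    mask[4:17, 4:17] = False     # annular cavity
    mask[7:14, 7:14] = True      # inner ring
    mask[9:12, 9:12] = False     # inner cavity
    lm = mo.label_components(mask)
    out = mo.fill_holes(lm)
    reachable = border_flood_background(mask)
    np.testing.assert_array_equal(out.labels > 0, mask | ~reachable)
    # inner cavity takes the inner ring's label
    inner_label = lm.labels[7, 7]
    assert (out.labels[9:12, 9:12] == inner_label).all()


def test_fill_holes_never_shrinks_foreground(rng):
    for _ in range(30):
        mask = rng.random((20, 20)) < 0.5
        lm = mo.label_components(mask)
        out = mo.fill_holes(lm)
        assert (out.labels[mask] == lm.labels[mask]).all()
        assert ((out.labels > 0) | ~mask).all()
        reachable = border_flood_background(mask)
        np.testing.assert_array_equal(out.labels > 0, mask | ~reachable)


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

def test_extract_edges_empty_and_monotone():
    empty = mo.LabelMap(np.zeros((10, 10), np.int32), 0)
    assert not mo.extract_edges(empty, 2).mask.any()

    lab = np.zeros((40, 40), np.int32)
    lab[10:30, 10:30] = 1
    lm = mo.LabelMap(lab, 1)
    e0 = mo.extract_edges(lm, 0).mask
    e2 = mo.extract_edges(lm, 2).mask
    assert e0.any()
    assert (e2 | e0).sum() == e2.sum()          # superset
    assert e2.sum() > e0.sum()


def test_extract_edges_square_contour_encloses_interior():
    lab = np.zeros((40, 40), np.int32)
    lab[10:30, 10:30] = 1
    edges = mo.extract_edges(mo.LabelMap(lab, 1), 1).mask
    # the centre cannot be flood-reached from the border without crossing
    # the edge contour
    reach = border_flood_background(edges)
    assert not reach[20, 20]
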