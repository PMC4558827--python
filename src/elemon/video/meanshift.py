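"""Joint spatial-range mean-shift filtering and image over-segmentation.

Each pixel carries a joint feature (row, col, colour) and is iterated toward
the mode of the local density estimated with a flat kernel: neighbours count
if they lie within ``hs`` pixels of the current spatial position and within
``hr`` (Euclidean colour distance) of the current colour.  After convergence,
pixels are grouped into connected regions whose converged colours agree to
within ``hr``, and regions smaller than ``min_region`` are absorbed by their
most similar spatial neighbour, so the result is always an exact partition of
the frame.

The filtering loop is compiled with numba; the first call in a process pays a
one-off compilation cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mean_shift_filter", "label_modes", "merge_small_regions", "mean_shift_segment"]


@njit(cache=False, fastmath=True)
def _filter_kernel(img, hs, hr2, max_iter, tol2):  # pragma: no cover - compiled
    h, w, _ = img.shape
    out_pos = np.empty((h, w, 2), dtype=np.float32)
    out_col = np.empty((h, w, 3), dtype=np.float32)
    n_iter = np.zeros((h, w), dtype=np.int32)
    for i in range(h):
        for j in range(w):
            cy = float(i)
            cx = float(j)
            c0 = img[i, j, 0]
            c1 = img[i, j, 1]
            c2 = img[i, j, 2]
            it = 0
            while it < max_iter:
                y0 = int(cy - hs)
                if y0 < 0:
                    y0 = 0
                y1 = int(cy + hs) + 1
                if y1 > h:
                    y1 = h
                x0 = int(cx - hs)
                if x0 < 0:
                    x0 = 0
                x1 = int(cx + hs) + 1
                if x1 > w:
                    x1 = w
                sy = 0.0
                sx = 0.0
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                cnt = 0
                for y in range(y0, y1):
                    dy = y - cy
                    for x in range(x0, x1):
                        dx = x - cx
                        if dy * dy + dx * dx > hs * hs:
                            continue
                        d0 = img[y, x, 0] - c0
                        d1 = img[y, x, 1] - c1
                        d2 = img[y, x, 2] - c2
                        if d0 * d0 + d1 * d1 + d2 * d2 <= hr2:
                            sy += y
                            sx += x
                            s0 += img[y, x, 0]
                            s1 += img[y, x, 1]
                            s2 += img[y, x, 2]
                            cnt += 1
                if cnt == 0:
                    break
                ny = sy / cnt
                nx = sx / cnt
                n0 = s0 / cnt
                n1 = s1 / cnt
                n2 = s2 / cnt
                shift = (
                    (ny - cy) ** 2
                    + (nx - cx) ** 2
                    + (n0 - c0) ** 2
                    + (n1 - c1) ** 2
                    + (n2 - c2) ** 2
                )
                cy, cx, c0, c1, c2 = ny, nx, n0, n1, n2
                it += 1
                if shift <= tol2:
                    break
            out_pos[i, j, 0] = cy
            out_pos[i, j, 1] = cx
            out_col[i, j, 0] = c0
            out_col[i, j, 1] = c1
            out_col[i, j, 2] = c2
            n_iter[i, j] = it
    return out_pos, out_col, n_iter


def mean_shift_filter(
    image: np.ndarray,
    hs: float,
    hr: float,
    max_iter: int = 50,
    tol: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run per-pixel joint-domain mean-shift iterations.

    Parameters
    ----------
    image : (H, W, 3) float array
        Colour image in the working colour space (e.g. CIELAB).
    hs : float
        Spatial bandwidth in pixels.
    hr : float
        Range (colour) bandwidth in the units of ``image``.
    max_iter : int
        Iteration cap per pixel.
    tol : float
        Convergence tolerance on the joint-space shift magnitude.

    Returns
    -------
    positions : (H, W, 2) converged (row, col) positions
    colors : (H, W, 3) converged colours
    n_iter : (H, W) iterations used per pixel
    """
    if hs <= 0 or hr <= 0:
        raise ValueError("bandwidths hs and hr must be positive")
    img = np.ascontiguousarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    return _filter_kernel(img, float(hs), float(hr) ** 2, int(max_iter), float(tol) ** 2)


def label_modes(colors: np.ndarray, hr: float) -> np.ndarray:
    """Group pixels into 4-connected regions of agreeing converged colours.

    Two neighbouring pixels join the same region when their mode colours are
    within ``hr`` of each other (flat-kernel grouping).  Returns an int label
    image with labels 0..n_regions-1; every pixel is labelled.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    h, w, _ = colors.shape
    c = colors.astype(np.float64)
    right = ((c[:, 1:] - c[:, :-1]) ** 2).sum(-1) <= hr * hr
    down = ((c[1:, :] - c[:-1, :]) ** 2).sum(-1) <= hr * hr
    idx = np.arange(h * w).reshape(h, w)
    rows = np.concatenate([idx[:, :-1][right].ravel(), idx[:-1, :][down].ravel()])
    cols = np.concatenate([idx[:, 1:][right].ravel(), idx[1:, :][down].ravel()])
    adj = coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(h * w, h * w)
    )
    _, labels = connected_components(adj, directed=False)
    return labels.reshape(h, w)


def merge_small_regions(labels: np.ndarray, colors: np.ndarray, min_region: int) -> np.ndarray:
    """Absorb regions below ``min_region`` pixels into their most similar neighbour.

    Similarity is Euclidean distance between region mean colours; merging
    repeats until every region reaches the size floor (or a single region
    remains), preserving the partition property.
    """
    h, w = labels.shape
    flat = labels.ravel()
    _, flat = np.unique(flat, return_inverse=True)
    flat_cols = colors.reshape(-1, 3).astype(np.float64)
    while True:
        n = int(flat.max()) + 1
        if n == 1:
            break
        counts = np.bincount(flat, minlength=n)
        small = np.flatnonzero(counts < min_region)
        if small.size == 0:
            break
        sums = np.column_stack(
            [np.bincount(flat, weights=flat_cols[:, k], minlength=n) for k in range(3)]
        )
        means = sums / counts[:, None]
        lab2 = flat.reshape(h, w)
        a = np.concatenate([lab2[:, :-1].ravel(), lab2[:-1, :].ravel()])
        b = np.concatenate([lab2[:, 1:].ravel(), lab2[1:, :].ravel()])
        diff = a != b
        pairs = np.unique(
            np.sort(np.column_stack([a[diff], b[diff]]), axis=1), axis=0
        )
        pairs = np.vstack([pairs, pairs[:, ::-1]])
        small_set = np.zeros(n, dtype=bool)
        small_set[small] = True
        cand = pairs[small_set[pairs[:, 0]]]
        if cand.size == 0:
            break
        d = np.linalg.norm(means[cand[:, 0]] - means[cand[:, 1]], axis=1)
        order = np.lexsort((d, cand[:, 0]))
        cand, d = cand[order], d[order]
        first = np.ones(len(cand), dtype=bool)
        first[1:] = cand[1:, 0] != cand[:-1, 0]
        best = cand[first]  # per small region: nearest-colour neighbour
        mapping = np.arange(n)
        mapping[best[:, 0]] = best[:, 1]
        # resolve merge chains (small -> small -> big)
        for _ in range(n):
            nxt = mapping[mapping]
            if np.array_equal(nxt, mapping):
                break
            # break 2-cycles deterministically toward the smaller label
            cyc = nxt == np.arange(n)
            mapping = np.where(cyc, np.minimum(mapping, np.arange(n)), mapping)
            nxt = mapping[mapping]
            if np.array_equal(nxt, mapping):
                break
            mapping = nxt
        new_flat = mapping[flat]
        if np.array_equal(new_flat, flat):
            break
        _, flat = np.unique(new_flat, return_inverse=True)
    _, dense = np.unique(flat, return_inverse=True)
    return dense.reshape(h, w)


def mean_shift_segment(
    image: np.ndarray,
    hs: float,
    hr: float,
    min_region: int,
    max_iter: int = 50,
    tol: float = 0.1,
) -> np.ndarray:
    """Full segmentation: filter, group modes, merge undersized regions.

    Returns a dense int label image (0..n-1) that partitions the frame.
    """
    _, colors, _ = mean_shift_filter(image, hs, hr, max_iter=max_iter, tol=tol)
    labels = label_modes(colors, hr)
    if min_region > 1:
        labels = merge_small_regions(labels, colors, min_region)
    return labels
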