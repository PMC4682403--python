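"""Independent brute-force reference implementations.

Deliberately naive: per-pixel python loops, explicit padding, BFS flood
fills.  These never share code with the package; they exist so the
vectorised implementations can be checked against something whose
correctness is obvious by inspection.
"""

from collections import deque

import numpy as np


def pad_window(img: np.ndarray, r: int, c: int, kr: int, kc: int,
               mode: str) -> np.ndarray:
    """The (kr x kc) window anchored at (r, c): rows r-kr//2 .. r+kr-kr//2-1."""
    vals = np.empty((kr, kc), dtype=float)
    H, W = img.shape
    for i in range(kr):
        for j in range(kc):
            rr = r - kr // 2 + i
            cc = c - kc // 2 + j
            if 0 <= rr < H and 0 <= cc < W:
                vals[i, j] = img[rr, cc]
            elif mode == "replicate":
                vals[i, j] = img[min(max(rr, 0), H - 1), min(max(cc, 0), W - 1)]
            else:  # zero
                vals[i, j] = 0.0
    return vals


def median_filter_bf(img: np.ndarray, kr: int, kc: int,
                     mode: str = "replicate") -> np.ndarray:
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            w = np.sort(pad_window(img, r, c, kr, kc, mode).ravel())
            out[r, c] = w[w.size // 2]  # upper median for even counts
    return out


def range_filter_bf(img: np.ndarray, kr: int, kc: int,
                    mode: str = "replicate") -> np.ndarray:
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            w = pad_window(img, r, c, kr, kc, mode)
            out[r, c] = w.max() - w.min()
    return out


def otsu_sweep_bf(img: np.ndarray, nbins: int = 256):
    """(bin centers, between-class variance at every cut) by brute force."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = edges[:-1] + np.diff(edges) / 2.0
    total = counts.sum()
    variances = np.full(nbins, -1.0)
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        variances[k] = w0 * w1 * (m0 - m1) ** 2
    return centers, variances


def otsu_threshold_bf(img: np.ndarray, nbins: int = 256) -> float:
    centers, variances = otsu_sweep_bf(img, nbins)
    return centers[int(np.argmax(variances))]


def _neighbors(r: int, c: int, H: int, W: int, connectivity: int):
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                 (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dr, dc in steps:
        rr, cc = r + dr, c + dc
        if 0 <= rr < H and 0 <= cc < W:
            yield rr, cc


def flood(mask: np.ndarray, seeds, connectivity: int) -> np.ndarray:
    """Boolean reachability from seed pixels across true pixels."""
    H, W = mask.shape
    reached = np.zeros_like(mask, dtype=bool)
    q = deque()
    for r, c in seeds:
        if mask[r, c] and not reached[r, c]:
            reached[r, c] = True
            q.append((r, c))
    while q:
        r, c = q.popleft()
        for rr, cc in _neighbors(r, c, H, W, connectivity):
            if mask[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                q.append((rr, cc))
    return reached


def _border_seeds(H: int, W: int):
    seeds = [(0, c) for c in range(W)] + [(H - 1, c) for c in range(W)]
    seeds += [(r, 0) for r in range(H)] + [(r, W - 1) for r in range(H)]
    return seeds


def clear_border_bf(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    reached = flood(mask, _border_seeds(*mask.shape), connectivity)
    return mask & ~reached


def fill_holes_bf(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Complement flood fill from the border; unreached background = hole."""
    comp_conn = 4 if connectivity == 8 else 8
    outside = flood(~mask, _border_seeds(*mask.shape), comp_conn)
    return mask | (~mask & ~outside)


def label_bf(mask: np.ndarray, connectivity: int = 8):
    """(labels, sizes) by repeated BFS."""
    labels = np.zeros(mask.shape, dtype=int)
    sizes = [0]
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                comp = flood(mask, [(r, c)], connectivity)
                labels[comp] = nxt
                sizes.append(int(comp.sum()))
    return labels, sizes


def remove_small_bf(mask: np.ndarray, min_area: int,
                    connectivity: int = 8) -> np.ndarray:
    labels, sizes = label_bf(mask, connectivity)
    out = np.zeros_like(mask)
    for lab in range(1, len(sizes)):
        if sizes[lab] >= min_area:
            out |= labels == lab
    return out


def bbox_bf(mask: np.ndarray):
    """(min_row, min_col, max_row, max_col) by full coordinate scan."""
    rmin, cmin = mask.shape
    rmax = cmax = -1
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                rmin, rmax = min(rmin, r), max(rmax, r)
                cmin, cmax = min(cmin, c), max(cmax, c)
    return rmin, cmin, rmax, cmax


def lower_roi_bf(mask: np.ndarray, ratio: float) -> float:
    """Row-census partition of the tight crop."""
    import math

    rmin, cmin, rmax, cmax = bbox_bf(mask)
    crop = mask[rmin:rmax + 1, cmin:cmax + 1]
    h = crop.shape[0]
    band = math.ceil(ratio * h)
    q = int(crop[h - band:, :].sum())
    return 100.0 * q / int(crop.sum())


def random_blob(rng: np.random.Generator, h: int, w: int,
                fill: float = 0.5) -> np.ndarray:
    """A random connected-ish blob: union of a few random discs."""
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), bool)
    cr, cc = rng.uniform(h * 0.3, h * 0.7), rng.uniform(w * 0.3, w * 0.7)
    for _ in range(rng.integers(3, 7)):
        rad = rng.uniform(min(h, w) * 0.08, min(h, w) * 0.25)
        dr = cr + rng.normal(0, h * 0.12)
        dc = cc + rng.normal(0, w * 0.12)
        mask |= (rows - dr) ** 2 + (cols - dc) ** 2 <= rad**2
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    return mask
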