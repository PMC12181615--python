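"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package itself.
"""

from collections import deque

import numpy as np


def otsu_brute_force(values, n_bins=256):
    """Exhaustive between-class-variance maximizer over histogram bins.

    Plain Python loops over every candidate split; returns the same
    bin-edge convention as the implementation (upper edge of the last
    lower-class bin), ties broken toward the lowest threshold.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    counts, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = [vmin + (i + 0.5) * (vmax - vmin) / n_bins
               for i in range(n_bins)]
    best_k, best_var = None, -np.inf
    for k in range(n_bins - 1):
        w0 = s0 = 0.0
        for i in range(k + 1):
            w0 += float(counts[i])
            s0 += float(counts[i]) * centers[i]
        w1 = s1 = 0.0
        for i in range(k + 1, n_bins):
            w1 += float(counts[i])
            s1 += float(counts[i]) * centers[i]
        if w0 == 0 or w1 == 0:
            continue
        var = w0 * w1 * (s0 / w0 - s1 / w1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return vmin + (best_k + 1) * (vmax - vmin) / n_bins


def label_flood_fill(mask, connectivity=8):
    """BFS connected-component labeling; returns (labels, sizes list)."""
    mask = np.asarray(mask, bool)
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    labels = np.zeros(mask.shape, int)
    sizes = []
    nxt = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or labels[r, c]:
                continue
            nxt += 1
            queue = deque([(r, c)])
            labels[r, c] = nxt
            size = 0
            while queue:
                rr, cc = queue.popleft()
                size += 1
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < rows and 0 <= nc < cols
                            and mask[nr, nc] and not labels[nr, nc]):
                        labels[nr, nc] = nxt
                        queue.append((nr, nc))
            sizes.append(size)
    return labels, sizes


def fill_holes_flood(mask):
    """Hole filling via background flood fill from the border (4-conn)."""
    mask = np.asarray(mask, bool)
    rows, cols = mask.shape
    reached = np.zeros_like(mask)
    queue = deque()
    for r in range(rows):
        for c in (0, cols - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(cols):
        for r in (0, rows - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if (0 <= nr < rows and 0 <= nc < cols
                    and not mask[nr, nc] and not reached[nr, nc]):
                reached[nr, nc] = True
                queue.append((nr, nc))
    return mask | ~reached


def gaussian_direct(plane, sigma):
    """Dense separable Gaussian convolution with reflect boundary.

    Same kernel radius convention as scipy.ndimage (truncate=4), built and
    applied with explicit loops over a materialized kernel.
    """
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    # np.pad "symmetric" repeats the edge sample, matching ndimage "reflect"
    padded = np.pad(np.asarray(plane, float), radius, mode="symmetric")
    tmp = np.zeros_like(padded)
    for i, k in enumerate(kernel):
        tmp += k * np.roll(padded, radius - i, axis=0)
    out = np.zeros_like(padded)
    for i, k in enumerate(kernel):
        out += k * np.roll(tmp, radius - i, axis=1)
    return out[radius:-radius, radius:-radius]


def per_object_recall(bleed_labels, detected_mask, objects,
                      min_cover=0.3):
    """Fraction of ground-truth objects covered by a detection mask.

    An object counts as detected when at least ``min_cover`` of its pixels
    are foreground in the mask. Returns dict with small/large breakdown.
    """
    got = {"small": [0, 0], "large": [0, 0]}
    diam = objects.set_index("id")["diameter_um"]
    for oid in np.unique(bleed_labels[bleed_labels > 0]):
        gt = bleed_labels == oid
        cover = (gt & detected_mask).sum() / gt.sum()
        cls = "small" if diam.loc[oid] < 50.0 else "large"
        got[cls][1] += 1
        got[cls][0] += int(cover >= min_cover)
    return got
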