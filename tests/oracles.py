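"""Independent brute-force oracles for connected components, the Euclidean
distance transform and Otsu's threshold.

These deliberately avoid the library routines they are used to check:
labeling is an explicit flood fill, the distance transform is an exhaustive
nearest-background search, and the Otsu oracle enumerates all 256 candidate
thresholds.  They are only meant for tiny inputs.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def flood_fill_components(mask: np.ndarray, full_connectivity: bool = True):
    """Label connected components by explicit flood fill.

    ``full_connectivity=True`` means 8-connectivity in 2-D / 26 in 3-D;
    ``False`` means 4 / 6.  Returns ``(labels, sizes)`` with sizes indexed by
    label-1.
    """
    mask = np.asarray(mask, dtype=bool)
    offsets = [d for d in product((-1, 0, 1), repeat=mask.ndim) if any(d)]
    if not full_connectivity:
        offsets = [d for d in offsets if sum(abs(x) for x in d) == 1]
    labels = np.zeros(mask.shape, dtype=np.int32)
    sizes: list[int] = []
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current = len(sizes) + 1
        labels[start] = current
        stack = [start]
        count = 0
        while stack:
            p = stack.pop()
            count += 1
            for off in offsets:
                q = tuple(a + b for a, b in zip(p, off))
                if (
                    all(0 <= qi < s for qi, s in zip(q, mask.shape))
                    and mask[q]
                    and not labels[q]
                ):
                    labels[q] = current
                    stack.append(q)
        sizes.append(count)
    return labels, sizes


def remove_small_by_flood_fill(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Strict small-component removal using the flood-fill labeling."""
    labels, sizes = flood_fill_components(mask, full_connectivity=True)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for lab, size in enumerate(sizes, start=1):
        if size >= min_size:
            out |= labels == lab
    return out


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Exact distance to the nearest background voxel by exhaustive search.

    Returns distances in voxel units; zero outside the mask.  Memory is kept
    bounded by chunking over foreground voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=float)
    fg = np.argwhere(mask)
    if fg.shape[0] == 0:
        return out
    bg = np.argwhere(~mask)
    if bg.shape[0] == 0:
        raise ValueError("no background")
    for i in range(0, fg.shape[0], 256):
        chunk = fg[i : i + 256].astype(float)
        d2 = ((chunk[:, None, :] - bg[None, :, :].astype(float)) ** 2).sum(axis=-1)
        out[tuple(fg[i : i + 256].T)] = np.sqrt(d2.min(axis=1))
    return out


def within_class_variance(image: np.ndarray, threshold: float) -> float:
    """Weighted intra-class variance of the split gray <= t vs gray > t."""
    values = np.asarray(image, dtype=float).ravel()
    low = values[values <= threshold]
    high = values[values > threshold]
    if low.size == 0 or high.size == 0:
        return float("inf")
    w0 = low.size / values.size
    w1 = high.size / values.size
    return w0 * low.var() + w1 * high.var()


def brute_force_otsu(image: np.ndarray) -> tuple[int, float]:
    """Exhaustive search over all 8-bit thresholds minimizing the weighted
    intra-class variance.  Returns (threshold, variance)."""
    best_t, best_v = 0, float("inf")
    for t in range(256):
        v = within_class_variance(image, t)
        if v < best_v - 1e-12:
            best_t, best_v = t, v
    return best_t, best_v
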