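"""Independent brute-force oracles used by the test suite.

Deliberately naive (python loops, elementwise iteration) and written
only from the mathematical definitions, so they share no code path with
the implementations they check.
"""

import numpy as np


def brute_disk(radius):
    side = 2 * radius + 1
    out = np.zeros((side, side), dtype=bool)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                out[dy + radius, dx + radius] = True
    return out


def brute_erode(img, footprint):
    """Flat grayscale erosion; out-of-bounds neighbours are ignored."""
    h, w = img.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(fh):
                for dx in range(fw):
                    if not footprint[dy, dx]:
                        continue
                    yy, xx = y + dy - cy, x + dx - cx
                    if 0 <= yy < h and 0 <= xx < w:
                        vals.append(img[yy, xx])
            out[y, x] = min(vals)
    return out


def brute_dilate(img, footprint):
    h, w = img.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(fh):
                for dx in range(fw):
                    if not footprint[dy, dx]:
                        continue
                    yy, xx = y + dy - cy, x + dx - cx
                    if 0 <= yy < h and 0 <= xx < w:
                        vals.append(img[yy, xx])
            out[y, x] = max(vals)
    return out


def brute_open_by_reconstruction(img, radius, final_dilation=True):
    """Erode, then repeat min(dilate(marker), original) to convergence,
    then one final clipped dilation."""
    img = np.asarray(img, dtype=float)
    disk = brute_disk(radius)
    conn8 = np.ones((3, 3), dtype=bool)
    marker = brute_erode(img, disk)
    while True:
        nxt = np.minimum(brute_dilate(marker, conn8), img)
        if np.array_equal(nxt, marker):
            break
        marker = nxt
    if final_dilation:
        marker = np.minimum(brute_dilate(marker, disk), img)
    return marker


def brute_joint_otsu(green, red, max_val=255):
    """Exhaustive search over every candidate threshold, maximizing
    between-class variance of the pooled pixels; lowest tie wins."""
    pooled = np.concatenate([np.asarray(green).ravel(), np.asarray(red).ravel()]).astype(float)
    best_t, best_var = None, -1.0
    for t in range(max_val):
        lo = pooled[pooled <= t]
        hi = pooled[pooled > t]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


def brute_confusion(pred, truth):
    tp = fp = tn = fn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_rolling_ball_background(img, radius):
    """Ball-opening background via scipy grayscale morphology with the
    ball height profile as a non-flat structuring element."""
    from scipy import ndimage as ndi

    span = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    s2 = dy * dy + dx * dx
    fp = s2 <= radius * radius
    h = np.where(fp, np.sqrt(np.clip(radius * radius - s2, 0, None)), 0.0)
    er = ndi.grey_erosion(np.asarray(img, dtype=float), footprint=fp,
                          structure=h, mode="constant", cval=np.inf)
    return ndi.grey_dilation(er, footprint=fp, structure=h,
                             mode="constant", cval=-np.inf)
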