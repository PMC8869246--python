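"""Independent brute-force oracles the fast implementations are checked against.

These deliberately use naive triple-loop window scans and exhaustive searches;
they share no code path with the package.
"""

import numpy as np


def window_scan(img, se, reduce_fn):
    """Naive window scan with replicate-border semantics.

    The window at (i, j) holds the values at (i + di - ar, j + dj - ac) for
    every active SE element, with out-of-range indices clamped to the edge.
    """
    h, w = img.shape
    sh, sw = se.shape
    ar, ac = sh // 2, sw // 2
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(sh):
                for dj in range(sw):
                    if se[di, dj]:
                        ii = min(max(i + di - ar, 0), h - 1)
                        jj = min(max(j + dj - ac, 0), w - 1)
                        vals.append(img[ii, jj])
            out[i, j] = reduce_fn(vals)
    return out


def dilate_oracle(img, se):
    return window_scan(img, se, max)


def erode_oracle(img, se):
    return window_scan(img, se, min)


def otsu_brute_force(img):
    """Exhaustive 256-candidate search of the weighted within-class variance.

    Returns (best_t, objective array).  Ties resolve to the smallest t by
    scanning in ascending order and replacing only on a strict improvement.
    """
    vals = np.asarray(img, dtype=np.float64).ravel()
    n = vals.size
    objective = np.empty(256)
    for t in range(256):
        bg = vals[vals <= t]
        fg = vals[vals > t]
        obj = 0.0
        if bg.size:
            obj += (bg.size / n) * bg.var()
        if fg.size:
            obj += (fg.size / n) * fg.var()
        objective[t] = obj
    best_t = 0
    for t in range(1, 256):
        if objective[t] < objective[best_t] - 1e-12:
            best_t = t
    return best_t, objective


ORACLE_SES = [
    np.ones((1, 1), bool),
    np.ones((3, 3), bool),
    np.ones((1, 3), bool),
    np.ones((3, 1), bool),
    np.ones((5, 5), bool),
    np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], bool),  # asymmetric diagonal
    np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),  # cross
]
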