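"""Joint spatial/color mean-shift filtering (pyramid-free, single scale).

Each pixel's (x, y, c1, c2, c3) vector is iteratively replaced by the mean
over neighbors that lie within ``spatial_radius`` in space and within
``color_radius`` in color (Euclidean over the three channels), until the
combined shift drops below 1 or a fixed iteration cap is reached.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _mean_shift_kernel(img, sp, sr, max_iter):  # pragma: no cover - jit
    h, w, _ = img.shape
    out = np.empty_like(img)
    sr2 = sr * sr
    for py in range(h):
        for px in range(w):
            x = float(px)
            y = float(py)
            c0 = img[py, px, 0]
            c1 = img[py, px, 1]
            c2 = img[py, px, 2]
            for _ in range(max_iter):
                y0 = max(0, int(y) - sp)
                y1 = min(h - 1, int(y) + sp)
                x0 = max(0, int(x) - sp)
                x1 = min(w - 1, int(x) + sp)
                sx = 0.0
                sy = 0.0
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                n = 0
                for ny in range(y0, y1 + 1):
                    for nx in range(x0, x1 + 1):
                        d0 = img[ny, nx, 0] - c0
                        d1 = img[ny, nx, 1] - c1
                        d2 = img[ny, nx, 2] - c2
                        if d0 * d0 + d1 * d1 + d2 * d2 <= sr2:
                            sx += nx
                            sy += ny
                            s0 += img[ny, nx, 0]
                            s1 += img[ny, nx, 1]
                            s2 += img[ny, nx, 2]
                            n += 1
                if n == 0:
                    break
                nx_m = sx / n
                ny_m = sy / n
                n0 = s0 / n
                n1 = s1 / n
                n2 = s2 / n
                shift = (
                    abs(nx_m - x)
                    + abs(ny_m - y)
                    + abs(n0 - c0)
                    + abs(n1 - c1)
                    + abs(n2 - c2)
                )
                x, y, c0, c1, c2 = nx_m, ny_m, n0, n1, n2
                if shift < 1.0:
                    break
            out[py, px, 0] = c0
            out[py, px, 1] = c1
            out[py, px, 2] = c2
    return out


def mean_shift_filter(
    image: np.ndarray,
    spatial_radius: int = 20,
    color_radius: float = 15.0,
    max_iter: int = 10,
) -> np.ndarray:
    """Mean-shift filter a (H, W, 3) float image; returns filtered channels."""
    img = np.ascontiguousarray(image, dtype=np.float32)
    out = _mean_shift_kernel(
        img, int(spatial_radius), np.float32(color_radius), int(max_iter)
    )
    return out.astype(np.float64)
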