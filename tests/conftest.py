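import numpy as np
import pytest

from fluoroquant import GreenChannelImage, ToothMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_rect_masks():
    """Two 40-high, 20-wide rectangular incisor masks, 4 px apart."""
    def build(h=80, w=100, top=10, height=40, gap=4, left_w=20, right_w=20,
              right_top=None):
        canvas_l = np.zeros((h, w), dtype=bool)
        canvas_r = np.zeros((h, w), dtype=bool)
        c0 = (w - (left_w + right_w + gap)) // 2
        canvas_l[top:top + height, c0:c0 + left_w] = True
        rt = top if right_top is None else right_top
        canvas_r[rt:rt + height, c0 + left_w + gap:c0 + left_w + gap + right_w] = True
        return [ToothMask("UR1", canvas_l), ToothMask("UL1", canvas_r)]
    return build


def brute_force_mean_blur(g, mask, size, mask_aware=True):
    """Double-loop window average; the independent blur oracle."""
    lo, hi = (size - 1) // 2, size // 2
    h, w = g.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            rs, re = max(0, r - lo), min(h, r + hi + 1)
            cs, ce = max(0, c - lo), min(w, c + hi + 1)
            win = g[rs:re, cs:ce]
            if mask_aware:
                out[r, c] = win[mask[rs:re, cs:ce]].mean()
            else:
                out[r, c] = win.mean()
    return out


def lp_upper_envelope(xs, ys, zs, qx, qy):
    """Independent upper-envelope oracle: max z with (qx, qy, z) in the hull.

    Solved as a linear program over convex combination weights.
    """
    from scipy.optimize import linprog

    a_eq = np.vstack([xs, ys, np.ones_like(xs, dtype=float)])
    res = linprog(
        -np.asarray(zs, dtype=float),
        A_eq=a_eq,
        b_eq=[qx, qy, 1.0],
        bounds=(0, None),
        method="highs",
    )
    assert res.status == 0
    return -res.fun
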