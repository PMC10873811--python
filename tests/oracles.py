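"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive — quadratic DP tables, exhaustive
alignment enumeration, explicit sliding windows, flood fill — and shares no
code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook full-matrix edit-distance DP."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[n][m]


def best_affine_alignment_enum(a, b, score_fn, gap_open, gap_extend):
    """Exhaustive max over every global alignment of ``a`` and ``b``.

    Explores the full alignment tree (each step pairs characters or gaps
    one of them), scoring incrementally: the first gap symbol of a run in a
    given sequence costs ``gap_open``, subsequent ones ``gap_extend``.
    Exponential — for oracle use on short strings only.
    """
    best = [-float("inf")]

    def walk(i: int, j: int, acc: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, acc + score_fn(a[i], b[j]), "M")
        if i < len(a):  # a[i] vs gap (gap run in b)
            cost = gap_extend if last == "X" else gap_open
            walk(i + 1, j, acc + cost, "X")
        if j < len(b):  # gap vs b[j] (gap run in a)
            cost = gap_extend if last == "Y" else gap_open
            walk(i, j + 1, acc + cost, "Y")

    walk(0, 0, 0.0, "")
    return best[0]


def sauvola_naive(img: np.ndarray, window: int, k: float, r: float) -> np.ndarray:
    """Per-pixel Sauvola threshold from explicit mirror-padded windows."""
    pad = window // 2
    padded = np.pad(img.astype(float), pad, mode="reflect")
    h, w = img.shape
    t = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            win = padded[y:y + window, x:x + window]
            m = win.mean()
            s = win.std()
            t[y, x] = m * (1 + k * (s / r - 1))
    return t


def connected_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Flood-fill component extraction (4- or 8-connectivity)."""
    assert connectivity in (4, 8)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            comp = set()
            while stack:
                cy, cx = stack.pop()
                comp.add((cy, cx))
                for dy, dx in offsets:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


def despeckle_fill_oracle(fg: np.ndarray, min_speck: int, min_hole: int) -> np.ndarray:
    """Reference despeckle/fill built on flood-fill components."""
    fg = fg.astype(bool).copy()
    for comp in connected_components(fg, 8):
        if len(comp) < min_speck:
            for y, x in comp:
                fg[y, x] = False
    h, w = fg.shape
    for comp in connected_components(~fg, 4):
        touches_border = any(
            y in (0, h - 1) or x in (0, w - 1) for y, x in comp
        )
        if not touches_border and len(comp) < min_hole:
            for y, x in comp:
                fg[y, x] = True
    return fg


def monte_carlo_iou(box_a, box_b, n: int, rng: np.random.Generator) -> float:
    """Point-sampling IoU estimate over the joint bounding box."""
    x0 = min(box_a.x_min, box_b.x_min)
    y0 = min(box_a.y_min, box_b.y_min)
    x1 = max(box_a.x_max, box_b.x_max)
    y1 = max(box_a.y_max, box_b.y_max)
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    in_a = (box_a.x_min <= xs) & (xs < box_a.x_max) & (box_a.y_min <= ys) & (ys < box_a.y_max)
    in_b = (box_b.x_min <= xs) & (xs < box_b.x_max) & (box_b.y_min <= ys) & (ys < box_b.y_max)
    union = (in_a | in_b).sum()
    if union == 0:
        return 0.0
    return (in_a & in_b).sum() / union
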