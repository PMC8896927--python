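"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, all-pairs scans,
three-point parabola minimizers) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def double_loop_energy(P, phi, eps, bias, t1, t2, kernel_weights, radius):
    """O(N^2) data energy: explicit sum over (n, m) pairs within the support."""
    h, w = P.shape
    H = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / eps))
    m1, m2 = 1 - H, H
    total = 0.0
    for nr in range(h):
        for nc in range(w):
            e = bias[nr, nc]
            for mr in range(max(0, nr - radius), min(h, nr + radius + 1)):
                for mc in range(max(0, nc - radius), min(w, nc + radius + 1)):
                    k = kernel_weights[nr - mr + radius, nc - mc + radius]
                    p = P[mr, mc]
                    total += k * (
                        (p - e * t1) ** 2 * m1[mr, mc] + (p - e * t2) ** 2 * m2[mr, mc]
                    )
    return total


def parabola_vertex(f):
    """Exact minimizer of a quadratic scalar function from three evaluations."""
    f0, f1, f2 = f(0.0), f(1.0), f(2.0)
    a = (f2 - 2 * f1 + f0) / 2.0
    b = f1 - f0 - a
    return -b / (2.0 * a)


def minimize_center(P, phi, eps, bias, other_t, which, kernel_weights, radius):
    """Numerically minimize the double-loop energy over one cluster center."""
    if which == 1:
        f = lambda t: double_loop_energy(P, phi, eps, bias, t, other_t, kernel_weights, radius)
    else:
        f = lambda t: double_loop_energy(P, phi, eps, bias, other_t, t, kernel_weights, radius)
    return parabola_vertex(f)


def minimize_bias_pixel(P, phi, eps, t1, t2, n, kernel_weights, radius):
    """Minimize the energy terms involving e(n) for one pixel n, by parabola."""
    h, w = P.shape
    H = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / eps))
    m1, m2 = 1 - H, H
    nr, nc = n

    def partial(e):
        total = 0.0
        for mr in range(max(0, nr - radius), min(h, nr + radius + 1)):
            for mc in range(max(0, nc - radius), min(w, nc + radius + 1)):
                k = kernel_weights[nr - mr + radius, nc - mc + radius]
                p = P[mr, mc]
                total += k * (
                    (p - e * t1) ** 2 * m1[mr, mc] + (p - e * t2) ** 2 * m2[mr, mc]
                )
        return total

    return parabola_vertex(partial)


def brute_force_edt(mask):
    """All-pairs exact Euclidean distance of 1-pixels to the nearest 0-pixel."""
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    zeros = np.argwhere(~mask)
    out = np.zeros((h, w), dtype=float)
    if zeros.size == 0:
        return np.full((h, w), float(max(h, w)))
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                d2 = (zeros[:, 0] - r) ** 2 + (zeros[:, 1] - c) ** 2
                out[r, c] = np.sqrt(d2.min())
    return out


def brute_force_watershed(relief, markers, connectivity=4, mask=None):
    """Meyer flooding with a linear-scan priority queue; FIFO tie-break.

    Mirrors the documented ordering contract — (relief value, insertion
    sequence) — but with none of the implementation's data structures.
    """
    relief = np.asarray(relief, dtype=float)
    h, w = relief.shape
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    allowed = np.ones((h, w), bool) if mask is None else np.asarray(mask) != 0
    labels = np.where(allowed, np.asarray(markers, dtype=int), 0)
    status = np.zeros((h, w), dtype=int)  # 0 unvisited, 1 queued, 2 resolved
    status[labels != 0] = 2
    status[~allowed] = 2
    queue = []  # list of (value, insertion_id, r, c)
    counter = 0

    def push_neighbors(r, c):
        nonlocal counter
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and status[nr, nc] == 0:
                queue.append((relief[nr, nc], counter, nr, nc))
                counter += 1
                status[nr, nc] = 1

    for r, c in np.argwhere(labels != 0):
        push_neighbors(r, c)
    while queue:
        best = min(range(len(queue)), key=lambda i: (queue[i][0], queue[i][1]))
        _, _, r, c = queue.pop(best)
        if status[r, c] == 2:
            continue
        neighbor_labels = set()
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and allowed[nr, nc]:
                if labels[nr, nc] > 0 and status[nr, nc] == 2:
                    neighbor_labels.add(int(labels[nr, nc]))
        labels[r, c] = neighbor_labels.pop() if len(neighbor_labels) == 1 else 0
        status[r, c] = 2
        if labels[r, c] != 0:
            push_neighbors(r, c)
    return labels


def all_pairs_mad(K, L):
    """Direct evaluation of the symmetric mean contour distance."""
    K = np.asarray(K, float)
    L = np.asarray(L, float)
    d = np.sqrt(((K[:, None, :] - L[None, :, :]) ** 2).sum(-1))
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def all_pairs_hausdorff(K, L):
    """Direct symmetric Hausdorff distance."""
    K = np.asarray(K, float)
    L = np.asarray(L, float)
    d = np.sqrt(((K[:, None, :] - L[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def boundary_by_scan(mask):
    """Foreground pixels with a 4-adjacent background pixel or on the border."""
    mask = np.asarray(mask) != 0
    h, w = mask.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            on_border = r in (0, h - 1) or c in (0, w - 1)
            has_bg = any(
                not mask[r + dr, c + dc]
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]
                if 0 <= r + dr < h and 0 <= c + dc < w
            )
            if on_border or has_bg:
                pts.append((r, c))
    return np.array(pts, dtype=float)


def chi2_closed_form(a, b, c, d):
    """Pearson chi-square for a 2x2 table via N(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def welch_formula(m1, s1, n1, m2, s2, n2):
    """Welch's t and Satterthwaite df evaluated directly."""
    va, vb = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    return t, df


def mann_whitney_u(a, b):
    """U as the brute-force count of pairwise wins plus half-ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
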