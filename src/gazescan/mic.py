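"""Maximal information coefficient (MIC) for detecting velocity-severity
dependence.

MIC scores the strongest grid-revealed association between two numeric
variables: over all nx-by-ny grids with ``nx * ny <= B(n) = n**alpha``,
it maximises the mutual information of the induced 2-D histogram,
normalised by ``log2(min(nx, ny))`` so a noiseless functional
relationship of any shape scores 1 and independent variables score near
0.  The search follows the ApproxMaxMI strategy: one axis is
mass-equipartitioned into rows, the other optimised exactly by dynamic
programming over "clumps" (maximal runs of x-consecutive points falling
in the same row), merged into at most ``c * L`` superclumps to bound the
DP.  Both orientations are searched and the elementwise maximum taken,
making the score exactly symmetric in (x, y); because only ranks enter
the grids, the score is invariant under strictly increasing transforms
of either variable.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

DEFAULT_ALPHA = 0.6
DEFAULT_CLUMPS = 15
MIN_POINTS = 30


def _tie_groups(sorted_vals: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of equal-value runs in a sorted vector."""
    n = len(sorted_vals)
    groups: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        groups.append((i, j))
        i = j
    return groups


def _equipartition_rows(y_sorted: np.ndarray, k: int) -> np.ndarray:
    """Assign row indices to y-sorted points, ~n/k per row, ties unsplit."""
    n = len(y_sorted)
    rows = np.zeros(n, dtype=int)
    row, placed = 0, 0
    target = n / k
    for i, j in _tie_groups(y_sorted):
        size = j - i
        if (
            placed
            and row < k - 1
            and abs(placed + size - target) > abs(placed - target)
        ):
            row += 1
            placed = 0
            target = (n - i) / (k - row)
        rows[i:j] = row
        placed += size
    return rows


def _clumps(
    x_groups: list[tuple[int, int]], rows_by_x: np.ndarray
) -> list[int]:
    """End offsets of clumps: maximal x-runs of points sharing one row.

    Points with tied x values can never be separated by a grid line, so a
    tie group spanning several rows always forms a clump of its own.
    """
    ends: list[int] = []
    cur_row: int | None = None
    for i, j in x_groups:
        rs = rows_by_x[i:j]
        if np.all(rs == rs[0]):
            r = int(rs[0])
            if cur_row is not None and r == cur_row:
                ends[-1] = j  # extend the current pure clump
            else:
                ends.append(j)
                cur_row = r
        else:
            ends.append(j)
            cur_row = None
    return ends


def _superclumps(ends: list[int], m_max: int) -> list[int]:
    """Merge clump ends into at most ``m_max`` mass-balanced superclumps."""
    if len(ends) <= m_max:
        return ends
    n = ends[-1]
    out: list[int] = []
    prev = 0
    for idx, e in enumerate(ends):
        slots_left = m_max - len(out)
        clumps_left = len(ends) - idx  # including this one
        if clumps_left <= slots_left or e - prev >= (n - prev) / slots_left:
            out.append(e)
            prev = e
            if len(out) == m_max:
                break
    if out[-1] != n:
        out[-1] = n
    return out


def _plogp(h: np.ndarray, n: int) -> np.ndarray:
    """Elementwise (h/n) * log2(h/n) with 0 log 0 = 0."""
    p = h / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log2(p)
    return np.where(h > 0, t, 0.0)


def _optimize_axis(row_hist_cum: np.ndarray, l_max: int) -> np.ndarray:
    """Best H(P) - H(P,Q) over x-partitions into exactly l bins, l <= l_max.

    ``row_hist_cum`` has shape (m+1, k): cumulative per-row counts at
    superclump boundaries (row 0 all zeros).  Returns ``best`` indexed by
    l (entries 0..1 are -inf).  Bin boundaries may only sit on superclump
    edges; every bin is non-empty.
    """
    m = row_hist_cum.shape[0] - 1
    n = int(row_hist_cum[-1].sum())
    counts = row_hist_cum.sum(axis=1)

    def w_vec(t: int) -> np.ndarray:
        """w[s] for s < t: score of a bin spanning superclumps (s, t]."""
        n_st = counts[t] - counts[:t]
        h = row_hist_cum[t][None, :] - row_hist_cum[:t]
        pa = n_st / n
        with np.errstate(divide="ignore", invalid="ignore"):
            a = -pa * np.log2(pa)
        a = np.where(n_st > 0, a, 0.0)
        return a + _plogp(h, n).sum(axis=1)

    ws = [np.empty(0)] + [w_vec(t) for t in range(1, m + 1)]
    best = np.full((l_max + 1, m + 1), -np.inf)
    for t in range(1, m + 1):
        best[1, t] = ws[t][0]
    for l in range(2, l_max + 1):
        for t in range(l, m + 1):
            cand = best[l - 1, l - 1 : t] + ws[t][l - 1 : t]
            best[l, t] = cand.max()
    return best[:, m]


def mic_score(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    clumps: int = DEFAULT_CLUMPS,
) -> float:
    """MIC of two equal-length numeric vectors, in [0, 1].

    ``alpha`` sets the grid budget B(n) = floor(n**alpha) and ``clumps``
    the superclump factor c; the defaults (0.6, 15) follow the
    statistic's original definition.  Requires at least 30 points.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    n = len(x)
    if n < MIN_POINTS:
        raise DataError(f"MIC needs at least {MIN_POINTS} points, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("MIC inputs must be finite")
    b = max(int(np.floor(n**alpha)), 4)

    best = 0.0
    for xx, yy in ((x, y), (y, x)):
        order_y = np.argsort(yy, kind="mergesort")
        y_sorted = yy[order_y]
        order_x = np.argsort(xx, kind="mergesort")
        x_groups = _tie_groups(xx[order_x])
        rows_of_point = np.empty(n, dtype=int)
        for k in range(2, b // 2 + 1):
            l_max = b // k
            if l_max < 2:
                break
            rows_sorted = _equipartition_rows(y_sorted, k)
            k_eff = int(rows_sorted.max()) + 1
            if k_eff < 2:
                continue  # y effectively constant
            rows_of_point[order_y] = rows_sorted
            rows_by_x = rows_of_point[order_x]
            row_counts = np.bincount(rows_sorted, minlength=k_eff)
            h_q = -_plogp(row_counts, n).sum()
            ends = _superclumps(
                _clumps(x_groups, rows_by_x), max(int(clumps * l_max), l_max + 1)
            )
            m = len(ends)
            cum = np.zeros((m + 1, k_eff))
            prev = 0
            for si, e in enumerate(ends):
                cum[si + 1] = cum[si] + np.bincount(
                    rows_by_x[prev:e], minlength=k_eff
                )
                prev = e
            vals = _optimize_axis(cum, min(l_max, m))
            for l in range(2, len(vals)):
                if not np.isfinite(vals[l]):
                    continue
                denom = np.log2(min(k_eff, l))
                if denom > 0:
                    best = max(best, (vals[l] + h_q) / denom)
    return float(min(max(best, 0.0), 1.0))
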