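"""Independent brute-force reference implementations used as oracles.

Everything here is written as plainly as possible — nested loops,
dictionaries, no vectorisation — deliberately independent of the
package's implementations.
"""

import numpy as np


def brute_local_maxima(S):
    out = []
    for r in range(1, S.shape[0] - 1):
        for c in range(1, S.shape[1] - 1):
            vals = [
                S[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            ]
            if all(S[r, c] > v for v in vals):
                out.append((r, c))
    return out


def brute_significant(S, pos, I, A):
    r, c = pos
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if not S[r + dr, c + dc] > I:
                return False
    extra = 0
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            if max(abs(dr), abs(dc)) == 2:
                rr, cc = r + dr, c + dc
                if 0 <= rr < S.shape[0] and 0 <= cc < S.shape[1] and S[rr, cc] > I:
                    extra += 1
    return extra >= A


def brute_watershed(S, min_level):
    """Descending-flood reference: dict-based, cell at a time."""
    cells = sorted(
        ((r, c) for r in range(S.shape[0]) for c in range(S.shape[1])),
        key=lambda rc: (-S[rc], rc),
    )
    labels = {}
    founders = []
    for r, c in cells:
        if S[r, c] < min_level:
            break
        neighbors = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in labels
        ]
        if neighbors:
            best = min(neighbors, key=lambda rc: (-S[rc], labels[rc]))
            labels[(r, c)] = labels[best]
        else:
            labels[(r, c)] = len(founders)
            founders.append((r, c))
    return founders, labels


def brute_two_means(x, max_iter=100, tol=1e-6):
    """Lloyd's algorithm in one dimension, centers at min/max, run to a
    fixed point; returns the boundary (midpoint of the two centers)."""
    c_lo, c_hi = float(np.min(x)), float(np.max(x))
    for _ in range(max_iter):
        lo_pts = [v for v in x if abs(v - c_lo) <= abs(v - c_hi)]
        hi_pts = [v for v in x if abs(v - c_hi) < abs(v - c_lo)]
        new_lo = float(np.mean(lo_pts)) if lo_pts else c_lo
        new_hi = float(np.mean(hi_pts)) if hi_pts else c_hi
        if abs(new_lo - c_lo) < tol and abs(new_hi - c_hi) < tol:
            break
        c_lo, c_hi = new_lo, new_hi
    return (c_lo + c_hi) / 2.0


def flood_fill_components(mask):
    """BFS flood fill with 8-connectivity."""
    seen = set()
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = []
            queue = [(r, c)]
            seen.add((r, c))
            while queue:
                rr, cc = queue.pop()
                comp.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and (nr, nc) not in seen
                        ):
                            seen.add((nr, nc))
                            queue.append((nr, nc))
            comps.append(sorted(comp))
    return comps


def brute_centroid(region, S):
    best = None
    for cell in region:
        dists = [
            np.hypot(cell[0] - other[0], cell[1] - other[1])
            for other in region
            if other != cell
        ]
        mean_dist = sum(dists) / max(len(region) - 1, 1)
        key = (mean_dist, -S[cell], cell)
        if best is None or key < best[0]:
            best = (key, cell)
    return best[1]


def _pair_mergeable(p, q, t_tol=0.003, r_base=3.0, r_frac=0.1):
    return abs(p.t - q.t) < t_tol and abs(p.r - q.r) < r_base + p.r * r_frac


def brute_merge_sweep(peaks):
    """Reference greedy merge: sort descending intensity (ties (r, t)),
    drop a peak iff it merges into an already-retained one.  Returns
    (retained, representative map dropped-peak -> retained peak)."""
    ordered = sorted(peaks, key=lambda p: (-p.s, p.r, p.t))
    retained = []
    rep = {}
    for p in ordered:
        home = None
        for keeper in retained:
            if _pair_mergeable(keeper, p):
                home = keeper
                break
        if home is None:
            retained.append(p)
        else:
            rep[p] = home
    return retained, rep


def brute_overlap_count(v_peaks, w_peaks):
    n = 0
    for p in v_peaks:
        for q in w_peaks:
            if p.i == q.i and _pair_mergeable(p, q):
                n += 1
                break
    return n
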