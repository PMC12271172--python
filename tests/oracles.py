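"""Independent brute-force reference implementations used by the tests.

Everything here is O(n^2) / enumerative and deliberately shares no code with
the library: distance matrices instead of KD-trees, BFS flood fill instead
of ndimage, ray casting instead of shapely, exhaustive rank enumeration
instead of scipy.
"""

from itertools import combinations

import numpy as np


def brute_dbscan(points, eps, min_points):
    """Deterministic DBSCAN by full distance matrix.

    Core point: >= min_points neighbours within eps including itself;
    clusters: density-connected core components; border points join the
    cluster of their nearest core point; labels canonicalized by lowest
    member index.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    within = d <= eps
    core = within.sum(1) >= min_points

    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cluster
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(within[j] & core):
                    if labels[k] == -1:
                        labels[k] = cluster
                        stack.append(k)
            cluster += 1
    for i in range(n):
        if not core[i]:
            cands = np.flatnonzero(core & within[i])
            labels[i] = labels[cands[np.argmin(d[i, cands])]] if len(cands) else -1
    # canonicalize ids by first occurrence
    mapping = {}
    out = labels.copy()
    for i in range(n):
        if labels[i] >= 0:
            mapping.setdefault(labels[i], len(mapping))
            out[i] = mapping[labels[i]]
    return out


def brute_local_density(points, radius):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return (d <= radius).sum(1) / (np.pi * radius ** 2)


def ray_cast_inside(ring, point):
    """Strict interior test by horizontal ray casting (ring: closed or open
    list of (x, y) vertices)."""
    x, y = point
    ring = [tuple(v) for v in ring]
    if ring[0] == ring[-1]:
        ring = ring[:-1]
    inside = False
    m = len(ring)
    for i in range(m):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % m]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > x:
                inside = not inside
    return inside


def flood_count_components(mask):
    """8-connected component count by BFS flood fill."""
    mask = np.asarray(mask) != 0
    seen = np.zeros_like(mask)
    count = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < rows and 0 <= cc < cols
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def brute_link(frames, xy, photons, precision, radius, max_gap=0):
    """Chain-following re-blink linker over all frame-compatible pairs.

    Returns (frame, x, y, photons, precision) arrays of the merged table,
    unordered.  Photon-weighted merge, photons summed, earliest frame kept.
    """
    n = len(frames)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            df = abs(int(frames[i]) - int(frames[j]))
            if 1 <= df <= max_gap + 1:
                if np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]) <= radius:
                    parent[find(j)] = find(i)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        w = np.asarray([photons[i] for i in members], dtype=float)
        w = np.where(w > 0, w, 1.0)
        mx = np.average([xy[i, 0] for i in members], weights=w)
        my = np.average([xy[i, 1] for i in members], weights=w)
        mp = np.average([precision[i] for i in members], weights=w)
        out.append((min(frames[i] for i in members), mx, my,
                    sum(photons[i] for i in members), mp))
    return np.array(sorted(out))


def mann_whitney_exact_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    a, b = list(a), list(b)
    na = len(a)
    merged = sorted(a + b)
    assert len(set(merged)) == len(merged), "exact enumeration assumes no ties"

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = min(u_stat(a, b), u_stat(b, a))
    count = 0
    total = 0
    for idx in combinations(range(len(merged)), na):
        ga = [merged[i] for i in idx]
        gb = [merged[i] for i in range(len(merged)) if i not in idx]
        u = min(u_stat(ga, gb), u_stat(gb, ga))
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def partition_signature(labels):
    """Order-free signature of a clustering: frozenset of member frozensets."""
    groups = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            groups.setdefault(lab, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())
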