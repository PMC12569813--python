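"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (plain
loops, `math` module, exact interval arithmetic) and shares no code with
the package: these are the second route of every dual-route check.
"""

from __future__ import annotations

import math


def brute_force_adjacency(points, radius):
    """Exact Voronoi adjacency inside a disk by half-plane intersection.

    Pair (i, j) is adjacent iff some segment of their perpendicular
    bisector lies closer to i and j than to every other point and inside
    the disk.  The bisector is parameterised and every other point's
    half-plane constraint is intersected as an interval in the parameter;
    adjacency holds iff a positive-length interval survives.
    """
    n = len(points)
    pairs = set()
    big = 1e9
    for i in range(n):
        xi, yi = points[i]
        for j in range(i + 1, n):
            xj, yj = points[j]
            mx, my = (xi + xj) / 2.0, (yi + yj) / 2.0
            dx, dy = -(yj - yi), (xj - xi)
            norm = math.hypot(dx, dy)
            if norm == 0:
                continue
            dx, dy = dx / norm, dy / norm
            lo, hi = -big, big
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                xk, yk = points[k]
                # |p(t)-pi|^2 - |p(t)-pk|^2 = a + b t <= 0
                a = ((mx - xi) ** 2 + (my - yi) ** 2
                     - (mx - xk) ** 2 - (my - yk) ** 2)
                b = 2.0 * (dx * (xk - xi) + dy * (yk - yi))
                if abs(b) < 1e-14:
                    if a > 1e-12:
                        ok = False
                        break
                    continue
                t = -a / b
                if b > 0:
                    hi = min(hi, t)
                else:
                    lo = max(lo, t)
                if hi - lo <= 1e-9:
                    ok = False
                    break
            if not ok:
                continue
            # disk constraint: |m + t d|^2 <= R^2 (|d| = 1)
            c2 = 1.0
            c1 = 2.0 * (mx * dx + my * dy)
            c0 = mx * mx + my * my - radius * radius
            disc = c1 * c1 - 4.0 * c2 * c0
            if disc <= 0:
                continue
            r = math.sqrt(disc)
            lo = max(lo, (-c1 - r) / 2.0)
            hi = min(hi, (-c1 + r) / 2.0)
            if hi - lo > 1e-9:
                pairs.add((i, j))
    return pairs


def monte_carlo_lens(r1, r2, cx, cy, n_points, rng):
    """Monte-Carlo estimate of the intersection area of two disks.

    Disk 1 centred at the origin with radius r1; disk 2 at (cx, cy) with
    radius r2.  Samples uniformly in the bounding box of disk 1.
    """
    xs = rng.uniform(-r1, r1, n_points)
    ys = rng.uniform(-r1, r1, n_points)
    in1 = xs ** 2 + ys ** 2 <= r1 ** 2
    in2 = (xs - cx) ** 2 + (ys - cy) ** 2 <= r2 ** 2
    return 4.0 * r1 * r1 * float((in1 & in2).mean())


def shoelace(points):
    s = 0.0
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def convex_hull_area(points):
    """Area of the convex hull (Andrew's monotone chain + shoelace)."""
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return ((a[0] - o[0]) * (b[1] - o[1])
                - (a[1] - o[1]) * (b[0] - o[0]))

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return shoelace(lower[:-1] + upper[:-1])


# ---------------------------------------------------------------------------
# Clean-room index derivation for small stands
# ---------------------------------------------------------------------------

def derive_indexes(trees, radius, buffer_width=2.0, w_reference=0.496,
                   no_overlap_value=1.0, w_neighbours=4):
    """Per-tree W, U, Mc, S, CI and the objective L, from first principles.

    ``trees`` is a list of dicts with keys id, species, x, y, dbh, height,
    crown_width, crown_length, rel_elev.  Returns (per_tree, means, stds, L).
    Mirrors the published definitions: Voronoi units (adjacency within the
    plot disk) for U/Mc/S/CI, the classical 4-nearest-neighbour gap
    construction for W, layers from thirds of the terrain-adjusted
    dominant height, population standard deviations with a zero guard,
    and the multiplicative-divisive mean for L.
    """
    pts = [(t["x"], t["y"]) for t in trees]
    n = len(trees)
    adj_pairs = brute_force_adjacency(pts, radius)
    adj = {i: set() for i in range(n)}
    for i, j in adj_pairs:
        adj[i].add(j)
        adj[j].add(i)

    area_ha = math.pi * radius ** 2 / 1e4
    k_dom = int(math.floor(100 * area_ha))
    heights = sorted(range(n), key=lambda i: -trees[i]["height"])[:k_dom]
    h_d = sum(trees[i]["height"] + trees[i]["rel_elev"]
              for i in heights) / len(heights)

    def layer(height):
        if h_d / 3.0 <= height <= 2.0 * h_d / 3.0:
            return 0
        return -1 if height < h_d / 3.0 else 1

    def lens(r1, r2, d):
        if d >= r1 + r2:
            return no_overlap_value
        if d <= abs(r1 - r2):
            return math.pi * min(r1, r2) ** 2
        a1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        a2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        kern = ((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2)
                * (d + r1 + r2))
        return r1 * r1 * a1 + r2 * r2 * a2 - 0.5 * math.sqrt(kern)

    core = [i for i in range(n)
            if math.hypot(*pts[i]) <= radius - buffer_width + 1e-9]
    per_tree = {}
    for i in core:
        t = trees[i]
        neigh = sorted(adj[i])
        nn = len(neigh)
        # U
        u = sum(1 for j in neigh if trees[j]["dbh"] > t["dbh"]) / nn
        # Mc
        m = sum(1 for j in neigh
                if trees[j]["species"] != t["species"]) / nn
        counts = {}
        for j in neigh:
            sp = trees[j]["species"]
            counts[sp] = counts.get(sp, 0) + 1
        simpson = 1.0 - sum(v * v for v in counts.values()) / (nn + 1) ** 2
        mc = min(1.0, 0.5 * m * (simpson + len(counts) / nn))
        # S
        fl_i = layer(t["height"])
        same = sum(1 for j in neigh
                   if layer(trees[j]["height"]) == fl_i) / nn
        z = len({layer(trees[j]["height"]) for j in neigh} | {fl_i})
        s_val = z / 3.0 * same
        # CI
        li = t["height"] * t["crown_width"] * t["crown_length"]
        zi = math.pi * (t["crown_width"] / 2.0) ** 2
        ci = 0.0
        for j in neigh:
            tj = trees[j]
            d = math.hypot(tj["x"] - t["x"], tj["y"] - t["y"])
            ao = lens(t["crown_width"] / 2.0, tj["crown_width"] / 2.0, d)
            lj = tj["height"] * tj["crown_width"] * tj["crown_length"]
            ci += ao * lj / li
        ci /= zi
        # W over the 4 nearest stems
        others = sorted((j for j in range(n) if j != i),
                        key=lambda j: (trees[j]["x"] - t["x"]) ** 2
                        + (trees[j]["y"] - t["y"]) ** 2)[:w_neighbours]
        az = sorted((math.degrees(math.atan2(trees[j]["x"] - t["x"],
                                             trees[j]["y"] - t["y"]))
                     % 360.0) for j in others)
        gaps = [az[k + 1] - az[k] for k in range(len(az) - 1)]
        gaps.append(az[0] + 360.0 - az[-1])
        alphas = [min(g, 360.0 - g) for g in gaps]
        w = sum(1 for a in alphas
                if a < 360.0 / (len(others) + 1)) / len(alphas)
        per_tree[t["id"]] = {"W": w, "U": u, "Mc": mc, "S": s_val, "CI": ci}

    def mean(key):
        return sum(v[key] for v in per_tree.values()) / len(per_tree)

    def pstd(values):
        mu = sum(values) / len(values)
        var = sum((v - mu) ** 2 for v in values) / len(values)
        sd = math.sqrt(var)
        return sd if sd > 1e-12 else 1.0

    means = {k: mean(k) for k in ("W", "U", "Mc", "S", "CI")}
    stds = {
        "W_abs": pstd([abs(v["W"] - w_reference)
                       for v in per_tree.values()]),
        "U": pstd([v["U"] for v in per_tree.values()]),
        "Mc": pstd([v["Mc"] for v in per_tree.values()]),
        "S": pstd([v["S"] for v in per_tree.values()]),
        "CI": pstd([v["CI"] for v in per_tree.values()]),
    }
    total = 0.0
    for v in per_tree.values():
        num = (1 + v["Mc"] / stds["Mc"]) * (1 + v["S"] / stds["S"])
        den = ((1 + v["U"] / stds["U"]) * (1 + v["CI"] / stds["CI"])
               * (1 + abs(v["W"] - w_reference) / stds["W_abs"]))
        total += num / den
    l_value = total / len(per_tree)
    return per_tree, means, stds, l_value
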