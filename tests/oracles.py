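"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — O(n²) loops, direct formula
transcriptions — and shares no code with the package, so agreement between
the two routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- geometry

def closest_point_on_triangle(p, a, b, c):
    """Exact closest point on triangle abc to p (Voronoi-region case analysis)."""
    p, a, b, c = (np.asarray(v, dtype=float) for v in (p, a, b, c))
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def exhaustive_surface_distance(vertices, faces, query):
    """Global min point-to-triangle distance by checking every face."""
    best = np.inf
    best_point = None
    for f in faces:
        cp = closest_point_on_triangle(query, *vertices[f])
        d = np.linalg.norm(np.asarray(query, dtype=float) - cp)
        if d < best:
            best, best_point = d, cp
    return best, best_point


# -------------------------------------------------------------- statistics

def auc_concordance(truth, score):
    """AUC as the Mann-Whitney probability over all pos x neg pairs, ties 1/2."""
    pos = [s for t, s in zip(truth, score) if t]
    neg = [s for t, s in zip(truth, score) if not t]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def cohen_kappa_loops(a, b, categories):
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = 0.0
    for c in categories:
        pe += (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n)
    return (po - pe) / (1 - pe)


def weighted_kappa_loops(a, b, categories, scheme):
    k = len(categories)
    idx = {c: i for i, c in enumerate(categories)}
    n = len(a)
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[idx[x], idx[y]] += 1
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1) if scheme == "linear" else ((i - j) / (k - 1)) ** 2
            e_ij = obs[i].sum() * obs[:, j].sum() / n
            num += w * obs[i, j]
            den += w * e_ij
    return 1.0 - num / den


def spearman_on_ranks(x, y):
    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, xi in enumerate(v):
            less = np.sum(v < xi)
            equal = np.sum(v == xi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def kendall_tau_b_loops(x, y):
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    # pair counts: ties in both are excluded from every term
    nx = n0 - ties_y - concordant - discordant  # pairs tied in x (incl. both)
    ny = n0 - ties_x - concordant - discordant
    return (concordant - discordant) / np.sqrt((n0 - nx) * (n0 - ny))


def icc3k_pingouin(panel, software):
    import pandas as pd
    import pingouin as pg

    n = len(panel)
    df = pd.DataFrame(
        {
            "subject": list(range(n)) * 2,
            "rater": ["panel"] * n + ["software"] * n,
            "score": list(panel) + list(software),
        }
    )
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    # two-way mixed, consistency, average measures; pingouin labels it ICC(C,k)
    row = res[res["Type"].isin(["ICC3k", "ICC(C,k)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return float(row["ICC"]), tuple(float(v) for v in row[ci_col])


def tail_overlap_sets(ids, panel, software, fraction, tail):
    import math

    m = math.ceil(fraction * len(ids))

    def pick(values):
        key = [(v, str(i)) for v, i in zip(values, ids)]
        if tail == "top":
            key = [(-v, str(i)) for v, i in zip(values, ids)]
        order = sorted(range(len(ids)), key=lambda k: key[k])
        return {ids[k] for k in order[:m]}

    sp, ss = pick(panel), pick(software)
    return 100.0 * len(sp & ss) / len(sp)
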