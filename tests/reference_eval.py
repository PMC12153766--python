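"""Independent naive reference implementations used as test oracles.

Everything here is written from the metric definitions in a deliberately
direct style — pure-Python loops, shapely for rectangle overlap, exhaustive
permutation enumeration for assignments where feasible — and shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

from shapely.geometry import box as shapely_box

BIG = 1e9


# ---------------------------------------------------------------------------
# geometry via shapely

def ref_iou(a, b) -> float:
    """IoU from shapely polygon areas; boxes are (left, top, w, h) tuples."""
    pa = shapely_box(a[0], a[1], a[0] + a[2], a[1] + a[3])
    pb = shapely_box(b[0], b[1], b[0] + b[2], b[1] + b[3])
    inter = pa.intersection(pb).area
    return inter / (pa.area + pb.area - inter)


def ref_center_distance(a, b) -> float:
    ax, ay = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx, by = b[0] + b[2] / 2, b[1] + b[3] / 2
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2)


def pixel_iou(a, b) -> float:
    """IoU by enumerating unit pixels; integer-coordinate boxes only."""
    cells_a = {(x, y) for x in range(int(a[0]), int(a[0] + a[2]))
               for y in range(int(a[1]), int(a[1] + a[3]))}
    cells_b = {(x, y) for x in range(int(b[0]), int(b[0] + b[2]))
               for y in range(int(b[1]), int(b[1] + b[3]))}
    return len(cells_a & cells_b) / len(cells_a | cells_b)


# ---------------------------------------------------------------------------
# assignment by brute force

def brute_force_assignment(cost, gate=float("inf")):
    """Exhaustive gated minimum-cost assignment.

    Ineligible pairs (cost > gate) are penalized by BIG, so the optimum
    first maximizes the number of eligible matches, then minimizes their
    summed cost; returns the eligible pairs of the best full padding
    permutation.
    """
    n_rows = len(cost)
    n_cols = len(cost[0]) if n_rows else 0
    n = max(n_rows, n_cols)
    padded = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i < n_rows and j < n_cols and cost[i][j] <= gate:
                padded[i][j] = cost[i][j]
            elif i < n_rows and j < n_cols:
                padded[i][j] = BIG
            else:
                padded[i][j] = 0.0  # dummy row/column
    best, best_pairs = float("inf"), []
    for perm in itertools.permutations(range(n)):
        total = sum(padded[i][perm[i]] for i in range(n))
        if total < best - 1e-12:
            best = total
            best_pairs = [(i, perm[i]) for i in range(n)
                          if i < n_rows and perm[i] < n_cols
                          and cost[i][perm[i]] <= gate]
    return best_pairs


def _best_frame_matching(gt_boxes, hyp_boxes, threshold):
    """Max-cardinality, then max-total-IoU matching at an IoU threshold.

    Exhaustive over permutations; inputs are {id: box} dicts.
    """
    gids, hids = sorted(gt_boxes), sorted(hyp_boxes)
    if not gids or not hids:
        return []
    short, long_, flipped = (gids, hids, False) if len(gids) <= len(hids) \
        else (hids, gids, True)
    best_pairs, best_key = [], (-1, -1.0)
    for combo in itertools.permutations(long_, len(short)):
        pairs = []
        total = 0.0
        for s, l in zip(short, combo):
            g, h = (s, l) if not flipped else (l, s)
            v = ref_iou(gt_boxes[g], hyp_boxes[h])
            if v >= threshold:
                pairs.append((g, h))
                total += v
        key = (len(pairs), total)
        if key > best_key:
            best_key, best_pairs = key, pairs
    return best_pairs


# ---------------------------------------------------------------------------
# CLEAR protocol

def ref_clear(gt, hyp, threshold=0.5):
    """Naive CLEAR evaluation.

    ``gt`` and ``hyp``: {frame: {id: (left, top, w, h)}}.  Returns a dict
    with FP, FN, IDSW, GT, matches (count) and motp_iou (mean matched IoU).
    """
    frames = sorted(set(gt) | set(hyp))
    prev = {}
    last = {}
    fp = fn = idsw = n_match = 0
    gt_total = 0
    iou_sum = 0.0
    per_gt_present = {}
    per_gt_matched = {}
    for t in frames:
        g = gt.get(t, {})
        h = hyp.get(t, {})
        gt_total += len(g)
        for gid in g:
            per_gt_present[gid] = per_gt_present.get(gid, 0) + 1
        pairs = []
        used_g, used_h = set(), set()
        for gid, hid in prev.items():
            if gid in g and hid in h and ref_iou(g[gid], h[hid]) >= threshold:
                pairs.append((gid, hid))
                used_g.add(gid)
                used_h.add(hid)
        rem_g = {k: v for k, v in g.items() if k not in used_g}
        rem_h = {k: v for k, v in h.items() if k not in used_h}
        pairs += _best_frame_matching(rem_g, rem_h, threshold)
        prev = {}
        for gid, hid in pairs:
            if gid in last and last[gid] != hid:
                idsw += 1
            last[gid] = hid
            prev[gid] = hid
            iou_sum += ref_iou(g[gid], h[hid])
            n_match += 1
            per_gt_matched[gid] = per_gt_matched.get(gid, 0) + 1
        fn += len(g) - len(pairs)
        fp += len(h) - len(pairs)
    mt = sum(1 for gid, p in per_gt_present.items()
             if per_gt_matched.get(gid, 0) / p >= 0.8)
    ml = sum(1 for gid, p in per_gt_present.items()
             if per_gt_matched.get(gid, 0) / p <= 0.2)
    return {
        "FP": fp, "FN": fn, "IDSW": idsw, "GT": gt_total,
        "MOTA": 1.0 - (fn + fp + idsw) / gt_total if gt_total else float("nan"),
        "MOTP": iou_sum / n_match if n_match else float("nan"),
        "MT": mt, "ML": ml, "matches": n_match,
    }


# ---------------------------------------------------------------------------
# identity metrics

def ref_idf1(gt, hyp, threshold=0.5):
    """IDF1 from the best global identity bijection.

    Exhaustive over bijections when feasible (<= 8 identities on the
    smaller side), otherwise falls back to the Hungarian algorithm on the
    co-occurrence counts.
    """
    gids = sorted({i for fb in gt.values() for i in fb})
    hids = sorted({i for fb in hyp.values() for i in fb})
    gt_total = sum(len(fb) for fb in gt.values())
    hyp_total = sum(len(fb) for fb in hyp.values())
    counts = {(g, h): 0 for g in gids for h in hids}
    for t in set(gt) & set(hyp):
        for g, gb in gt[t].items():
            for h, hb in hyp[t].items():
                if ref_iou(gb, hb) >= threshold:
                    counts[(g, h)] += 1
    short, long_, flip = (gids, hids, False) if len(gids) <= len(hids) \
        else (hids, gids, True)
    if len(short) <= 8:
        idtp = 0
        for combo in itertools.permutations(long_, len(short)):
            total = sum(counts[(s, l) if not flip else (l, s)]
                        for s, l in zip(short, combo))
            idtp = max(idtp, total)
    else:  # pragma: no cover - large fixtures only
        import numpy as np
        from scipy.optimize import linear_sum_assignment
        mat = np.array([[counts[(g, h)] for h in hids] for g in gids])
        r, c = linear_sum_assignment(-mat)
        idtp = int(mat[r, c].sum())
    denom = 2 * idtp + (hyp_total - idtp) + (gt_total - idtp)
    return 2 * idtp / denom if denom else float("nan"), idtp


# ---------------------------------------------------------------------------
# HOTA

def ref_hota(gt, hyp, use_sqrt=True):
    """Naive HOTA: the standard two-pass protocol written with plain loops."""
    gids = sorted({i for fb in gt.values() for i in fb})
    hids = sorted({i for fb in hyp.values() for i in fb})
    frames = sorted(set(gt) | set(hyp))
    n_gt = sum(len(fb) for fb in gt.values())
    n_hyp = sum(len(fb) for fb in hyp.values())

    gt_count = {g: sum(1 for t in frames if g in gt.get(t, {})) for g in gids}
    hyp_count = {h: sum(1 for t in frames if h in hyp.get(t, {})) for h in hids}
    potential = {(g, h): 0.0 for g in gids for h in hids}
    sims = {}
    for t in frames:
        gfb, hfb = gt.get(t, {}), hyp.get(t, {})
        sim = {(g, h): ref_iou(gfb[g], hfb[h]) for g in gfb for h in hfb}
        sims[t] = sim
        for g in gfb:
            for h in hfb:
                denom = (sum(sim[(g2, h)] for g2 in gfb)
                         + sum(sim[(g, h2)] for h2 in hfb) - sim[(g, h)])
                if denom > 1e-12:
                    potential[(g, h)] += sim[(g, h)] / denom
    align = {}
    for g in gids:
        for h in hids:
            denom = gt_count[g] + hyp_count[h] - potential[(g, h)]
            align[(g, h)] = potential[(g, h)] / denom if denom else 0.0

    alphas = [0.05 * k for k in range(1, 20)]
    eps = 1e-12
    tp = {a: 0 for a in alphas}
    match_count = {a: {} for a in alphas}
    for t in frames:
        gfb, hfb = gt.get(t, {}), hyp.get(t, {})
        if not gfb or not hfb:
            continue
        sim = sims[t]
        # exhaustive max of alignment-weighted similarity
        gs, hs = sorted(gfb), sorted(hfb)
        short, long_, flip = (gs, hs, False) if len(gs) <= len(hs) else (hs, gs, True)
        best_pairs, best = [], -1.0
        for combo in itertools.permutations(long_, len(short)):
            pairs = [((s, l) if not flip else (l, s)) for s, l in zip(short, combo)]
            total = sum(align[p] * sim[p] for p in pairs)
            if total > best + 1e-15:
                best, best_pairs = total, pairs
        for a in alphas:
            for p in best_pairs:
                if sim[p] >= a - eps:
                    tp[a] += 1
                    match_count[a][p] = match_count[a].get(p, 0) + 1

    scores = []
    for a in alphas:
        fn = n_gt - tp[a]
        fp = n_hyp - tp[a]
        det = tp[a] / (tp[a] + fn + fp) if tp[a] + fn + fp else 0.0
        if tp[a] > 0:
            ass = sum(c * (c / (gt_count[g] + hyp_count[h] - c))
                      for (g, h), c in match_count[a].items()) / tp[a]
        else:
            ass = 0.0
        prod = det * ass
        scores.append(math.sqrt(prod) if use_sqrt else prod)
    return sum(scores) / len(scores)
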