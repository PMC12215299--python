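"""Naive reference implementations used as independent oracles.

Everything here is deliberately written the slow, obvious way —
flood fills, double/triple loops, literal formula transcriptions —
and shares no code with the package under test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

NEIGHBORS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
NEIGHBORS_8 = NEIGHBORS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS connected-component labeling; labels 1..n in scan order."""
    neigh = NEIGHBORS_8 if connectivity == 8 else NEIGHBORS_4
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int64)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def naive_area_open(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    labels = flood_fill_label(mask, connectivity)
    out = mask.copy()
    for lab in range(1, labels.max() + 1):
        member = labels == lab
        if member.sum() < min_area:
            out[member] = False
    return out


def naive_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Mark every background pixel not reachable from the border (4-connected)."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    queue: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in NEIGHBORS_4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~reach


def brute_otsu(hist: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over all 256 cuts."""
    best_t, best_var = 0, -1.0
    total = hist.sum()
    for t in range(256):
        lo = hist[:t]
        hi = hist[t:]
        w0, w1 = lo.sum(), hi.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (lo * np.arange(t)).sum() / w0
        mu1 = (hi * np.arange(t, 256)).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


# ---------------------------------------------------------------------------
# cluster validity indices, per-definition loops


def _dist(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def naive_silhouette(points, labels):
    points = [tuple(p) for p in np.asarray(points, float)]
    labels = list(labels)
    uniq = sorted(set(labels))
    s_values = []
    for i, (p, li) in enumerate(zip(points, labels)):
        own = [q for j, q in enumerate(points) if labels[j] == li and j != i]
        if not own:
            s_values.append(0.0)
            continue
        a = sum(_dist(p, q) for q in own) / len(own)
        b = min(
            sum(_dist(p, q) for j, q in enumerate(points) if labels[j] == c)
            / sum(1 for lj in labels if lj == c)
            for c in uniq
            if c != li
        )
        s_values.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return s_values, sum(s_values) / len(s_values)


def _centroid(members):
    d = len(members[0])
    return tuple(sum(p[j] for p in members) / len(members) for j in range(d))


def naive_davies_bouldin(points, labels):
    points = [tuple(p) for p in np.asarray(points, float)]
    uniq = sorted(set(labels))
    members = {c: [p for p, l in zip(points, labels) if l == c] for c in uniq}
    cents = {c: _centroid(members[c]) for c in uniq}
    radii = {c: sum(_dist(p, cents[c]) for p in members[c]) / len(members[c]) for c in uniq}
    total = 0.0
    for i in uniq:
        total += max(
            (radii[i] + radii[j]) / _dist(cents[i], cents[j]) for j in uniq if j != i
        )
    return total / len(uniq)


def naive_dunn_standard(points, labels):
    points = [tuple(p) for p in np.asarray(points, float)]
    uniq = sorted(set(labels))
    members = {c: [p for p, l in zip(points, labels) if l == c] for c in uniq}
    diam = 0.0
    for c in uniq:
        for p in members[c]:
            for q in members[c]:
                diam = max(diam, _dist(p, q))
    inter = math.inf
    for a in uniq:
        for b in uniq:
            if a < b:
                for p in members[a]:
                    for q in members[b]:
                        inter = min(inter, _dist(p, q))
    return math.inf if diam == 0 else inter / diam


def naive_dunn_paper(points, labels):
    # literal evaluation of the summation form over centroid distances
    return naive_davies_bouldin(points, labels)


# ---------------------------------------------------------------------------
# agglomerative clustering via Lance-Williams recurrences


def naive_linkage_heights(points, method: str) -> list[float]:
    """Merge heights of a bottom-up clustering, smallest-pair-first."""
    points = np.asarray(points, float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = _dist(points[i], points[j])
    heights = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for k in clusters:
            dak = d[(min(a, k), max(a, k))]
            dbk = d[(min(b, k), max(b, k))]
            nk = len(clusters[k])
            if method == "single":
                val = min(dak, dbk)
            elif method == "complete":
                val = max(dak, dbk)
            elif method == "average":
                val = (na * dak + nb * dbk) / (na + nb)
            elif method == "ward":
                val = math.sqrt(
                    ((nk + na) * dak**2 + (nk + nb) * dbk**2 - nk * h**2) / (nk + na + nb)
                )
            else:
                raise ValueError(method)
            new_d[(min(next_id, k), max(next_id, k))] = val
        d = {
            (i, j): v
            for (i, j), v in d.items()
            if i not in (a, b) and j not in (a, b)
        }
        d.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return heights


# ---------------------------------------------------------------------------
# evaluation metrics from definitions


def naive_classification(y_true, y_pred, averaging="macro"):
    y_true, y_pred = list(y_true), list(y_pred)
    classes = sorted(set(y_true))
    n = len(y_true)

    def counts(c):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        return tp, fp, fn

    def zdiv(a, b):
        return a / b if b else 0.0

    if averaging == "micro":
        tp = sum(counts(c)[0] for c in classes)
        fp = sum(counts(c)[1] for c in classes)
        fn = sum(counts(c)[2] for c in classes)
        prec, rec = zdiv(tp, tp + fp), zdiv(tp, tp + fn)
        f1 = zdiv(2 * prec * rec, prec + rec)
        jac = zdiv(tp, tp + fp + fn)
    else:
        per = []
        for c in classes:
            tp, fp, fn = counts(c)
            prec_c, rec_c = zdiv(tp, tp + fp), zdiv(tp, tp + fn)
            per.append(
                (
                    prec_c,
                    rec_c,
                    zdiv(2 * prec_c * rec_c, prec_c + rec_c),
                    zdiv(tp, tp + fp + fn),
                    sum(1 for t in y_true if t == c),
                )
            )
        if averaging == "macro":
            w = [1.0] * len(per)
        else:
            w = [p[4] for p in per]
        wsum = sum(w)
        prec = sum(p[0] * wi for p, wi in zip(per, w)) / wsum
        rec = sum(p[1] * wi for p, wi in zip(per, w)) / wsum
        f1 = sum(p[2] * wi for p, wi in zip(per, w)) / wsum
        jac = sum(p[3] * wi for p, wi in zip(per, w)) / wsum

    hamming = sum(1 for t, p in zip(y_true, y_pred) if t != p) / n
    # MCC from the confusion matrix
    c_total = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    t_k = {c: sum(1 for t in y_true if t == c) for c in classes}
    p_k = {c: sum(1 for p in y_pred if p == c) for c in classes}
    num = c_total * n - sum(t_k[c] * p_k[c] for c in classes)
    den = math.sqrt(n**2 - sum(v**2 for v in p_k.values())) * math.sqrt(
        n**2 - sum(v**2 for v in t_k.values())
    )
    mcc = zdiv(num, den)
    return {
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "hamming_loss": hamming,
        "jaccard_score": jac,
        "mcc": mcc,
    }


def naive_regression(y_true, y_pred):
    y_true, y_pred = list(map(float, y_true)), list(map(float, y_pred))
    n = len(y_true)
    mae = sum(abs(p - t) for t, p in zip(y_true, y_pred)) / n
    mse = sum((p - t) ** 2 for t, p in zip(y_true, y_pred)) / n
    mean_t = sum(y_true) / n
    sst = sum((t - mean_t) ** 2 for t in y_true)
    r2 = 1 - sum((p - t) ** 2 for t, p in zip(y_true, y_pred)) / sst
    rmsle = math.sqrt(
        sum((math.log(1 + p) - math.log(1 + t)) ** 2 for t, p in zip(y_true, y_pred)) / n
    )
    smape = (
        100.0
        / n
        * sum(
            0.0 if abs(p) + abs(t) == 0 else 2 * abs(p - t) / (abs(p) + abs(t))
            for t, p in zip(y_true, y_pred)
        )
    )
    return {
        "mae": mae,
        "mse": mse,
        "rmse": math.sqrt(mse),
        "r2": r2,
        "rmsle": rmsle,
        "smape": smape,
    }
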