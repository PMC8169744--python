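"""Brute-force re-implementations used as independent oracles in tests.

Deliberately naive: per-pixel loops, BFS flood fill, if-chains.  Nothing
here imports the library's scoring internals beyond its public data
containers, so agreement between the two routes is meaningful.
"""

from collections import deque

import numpy as np

VESSELS = ("LCA", "LAD", "LCX", "RCA")


def naive_weight(max_hu):
    if max_hu > 130 and max_hu < 200:
        return 1
    if 200 <= max_hu < 300:
        return 2
    if 300 <= max_hu < 400:
        return 3
    if max_hu >= 400:
        return 4
    return 0


def naive_score_volume(calc_prob, vessel_prob, hu, pixel_area_mm2,
                       min_area=0.0):
    """Flood-fill per-slice scoring; returns (per_vessel dict, lesions).

    lesions are (slice, frozenset of pixels, area, max_hu, vessel).
    """
    n_slices, h, w = calc_prob.shape
    per_vessel = {v: 0.0 for v in VESSELS}
    lesions = []
    for si in range(n_slices):
        mask = calc_prob[si] > 0.5
        seen = np.zeros((h, w), dtype=bool)
        for r in range(h):
            for q in range(w):
                if not mask[r, q] or seen[r, q]:
                    continue
                comp = []
                todo = deque([(r, q)])
                seen[r, q] = True
                while todo:
                    y, x = todo.popleft()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w
                                    and mask[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                todo.append((yy, xx))
                area = sum(1 for (y, x) in comp if hu[si, y, x] > 130) \
                    * pixel_area_mm2
                if area < min_area:
                    continue
                max_hu = max(hu[si, y, x] for (y, x) in comp)
                votes = [0, 0, 0, 0]
                mass = [0.0, 0.0, 0.0, 0.0]
                for (y, x) in comp:
                    probs = [vessel_prob[si, k, y, x] for k in range(4)]
                    best = max(range(4), key=lambda k: probs[k])
                    votes[best] += 1
                    for k in range(4):
                        mass[k] += probs[k]
                label = max(range(4), key=lambda k: (votes[k], mass[k], -k))
                vessel = VESSELS[label]
                per_vessel[vessel] += area * naive_weight(max_hu)
                lesions.append((si, frozenset(comp), area, max_hu, vessel))
    return per_vessel, lesions


def naive_kappa(reference, predicted):
    """Textbook Cohen's Kappa from raw agreement and marginals."""
    n = len(reference)
    cats = sorted(set(reference) | set(predicted), key=str)
    po = sum(1 for r, p in zip(reference, predicted) if r == p) / n
    pe = 0.0
    for cat in cats:
        pr = sum(1 for r in reference if r == cat) / n
        pp = sum(1 for p in predicted if p == cat) / n
        pe += pr * pp
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def naive_ks_statistic(a, b):
    """Empirical-CDF sweep over the pooled sample."""
    a, b = np.sort(a), np.sort(b)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.sum(a <= t) / len(a)
        fb = np.sum(b <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best
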