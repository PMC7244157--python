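"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most direct method
available (exhaustive scans, per-pixel loops, iterative relaxation) and
share no code with the implementation paths they check.
"""

import numpy as np

_NEIGHBORS = ((-1, -1, 2.0), (-1, 0, 1.0), (-1, 1, 2.0),
              (0, -1, 1.0), (0, 1, 1.0),
              (1, -1, 2.0), (1, 0, 1.0), (1, 1, 2.0))


def otsu_bruteforce(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over a 256-bin
    histogram on [0, 1]; threshold at the upper edge of the best bin."""
    idx = np.clip((np.asarray(image, float).ravel() * nbins).astype(int),
                  0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins).astype(float)
    centers = (np.arange(nbins) + 0.5) / nbins
    best_k, best_v = None, -np.inf
    total = counts.sum()
    for k in range(nbins - 1):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_k, best_v = k, v
    assert best_k is not None
    return (best_k + 1) / nbins


def propagation_bruteforce(seeds: np.ndarray, image: np.ndarray,
                           mask: np.ndarray, lam: float) -> np.ndarray:
    """Multi-source shortest-path labelling by per-label iterative
    relaxation (Bellman-Ford style), then argmin over labels with ties
    going to the lower label."""
    seeds = np.asarray(seeds)
    image = np.asarray(image, float)
    mask_eff = np.asarray(mask, bool) | (seeds > 0)
    H, W = image.shape
    labels = sorted(set(np.unique(seeds).tolist()) - {0})
    dists = []
    for lab in labels:
        dist = np.full((H, W), np.inf)
        dist[seeds == lab] = 0.0
        changed = True
        while changed:
            changed = False
            for dr, dc, d2 in _NEIGHBORS:
                # relax p -> q for every in-mask pixel pair
                pr0, pr1 = max(0, -dr), min(H, H - dr)
                pc0, pc1 = max(0, -dc), min(W, W - dc)
                p = (slice(pr0, pr1), slice(pc0, pc1))
                q = (slice(pr0 + dr, pr1 + dr), slice(pc0 + dc, pc1 + dc))
                step = np.sqrt((image[p] - image[q]) ** 2 + lam * d2)
                cand = np.where(mask_eff[p], dist[p], np.inf) + step
                cand = np.where(mask_eff[q], cand, np.inf)
                better = cand < dist[q]
                if better.any():
                    dist[q][better] = cand[better]
                    changed = True
        dists.append(dist)
    out = np.zeros((H, W), dtype=np.int32)
    if not labels:
        return out
    stack = np.stack(dists)
    best = stack.min(axis=0)
    reachable = np.isfinite(best)
    # ties -> lower label: first argmin over the label-sorted stack
    winner = np.argmin(stack, axis=0)
    out[reachable] = np.asarray(labels, dtype=np.int32)[winner[reachable]]
    return out


def paired_t_closed_form(auto, manual):
    """t = mean(d) / (sd(d)/sqrt(n)) on paired differences, df = n-1."""
    from scipy.stats import t as tdist
    d = np.asarray(auto, float) - np.asarray(manual, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * tdist.sf(abs(t), n - 1)
    return t, p
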