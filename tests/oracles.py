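"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (loops, enumeration,
grid refinement) and deliberately shares no code with the package,
except the quartile *rule* (type 7 / linear interpolation), which both
sides must agree on for the comparisons to be meaningful.
"""

from __future__ import annotations

import numpy as np


def quartile_type7(sorted_vals, p: float) -> float:
    """Linear interpolation between order statistics (manual type-7)."""
    v = sorted(float(x) for x in sorted_vals)
    n = len(v)
    h = (n - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_outlier_fraction(samples, factor: float = 1.5) -> float:
    q1 = quartile_type7(samples, 0.25)
    q3 = quartile_type7(samples, 0.75)
    iqr = q3 - q1
    n_out = sum(1 for x in samples if x < q1 - factor * iqr or x > q3 + factor * iqr)
    return n_out / len(samples)


def brute_quartile_skewness(samples) -> float:
    q1 = quartile_type7(samples, 0.25)
    q2 = quartile_type7(samples, 0.50)
    q3 = quartile_type7(samples, 0.75)
    if q3 == q1:
        return 0.5
    return (q2 - q1) / (q3 - q1)


def brute_histogram(samples, lo=0.0, hi=0.5, bins=4):
    step = (hi - lo) / bins
    counts = [0] * bins
    for x in samples:
        for k in range(bins):
            if lo + k * step <= x < lo + (k + 1) * step:
                counts[k] += 1
                break
    return [c / len(samples) for c in counts]


def brute_coordination(press, release) -> float:
    pairs = []
    for i in range(len(press) - 1):
        overlap = release[i] - press[i + 1]
        pairs.append(max(overlap, 0.0))
    return sum(pairs) / len(pairs) if pairs else 0.0


def brute_window_assignment(press_times, width: float):
    """Map press time -> window index by explicit interval scan."""
    out = []
    for t in press_times:
        i = 0
        while not (i * width <= t < (i + 1) * width):
            i += 1
        out.append(i)
    return out


def brute_auc(scores, labels, positive="PD") -> float:
    """Exhaustive pair counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def svr_primal_objective(w, b, X, y, C: float, epsilon: float) -> float:
    """½‖w‖² + C·Σ max(0, |w·x + b − y| − ε)."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    resid = np.abs(X @ w + b - y) - epsilon
    return 0.5 * float(w @ w) + C * float(np.sum(np.clip(resid, 0.0, None)))


def svr_grid_oracle(X, y, C: float, epsilon: float,
                    span: float = 2.0, rounds: int = 12, grid: int = 41):
    """Minimize the 1-feature primal by iterative dense grid refinement.

    Returns (w, b) to well below 1e-5 accuracy for bounded toy problems.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    w0, b0 = 0.0, float(np.mean(y))
    half_w, half_b = span, span
    for _ in range(rounds):
        ws = np.linspace(w0 - half_w, w0 + half_w, grid)
        bs = np.linspace(b0 - half_b, b0 + half_b, grid)
        vals = np.array(
            [[svr_primal_objective([w], b, X, y, C, epsilon) for b in bs] for w in ws]
        )
        iw, ib = np.unravel_index(np.argmin(vals), vals.shape)
        w0, b0 = float(ws[iw]), float(bs[ib])
        half_w *= 2.2 / (grid - 1)  # keep neighbours of the best cell
        half_b *= 2.2 / (grid - 1)
    return w0, b0


def svr_optimal_b_interval(w, X, y, C: float, epsilon: float):
    """Exact argmin interval of the primal in b at fixed w.

    The objective is convex piecewise linear in b with kinks at
    z_i ± ε (z_i = y_i − w·x_i); the argmin set is the interval of
    kink points achieving the minimal value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    z = y - X @ w
    kinks = np.unique(np.concatenate([z - epsilon, z + epsilon]))
    vals = np.array([svr_primal_objective(w, b, X, y, C, epsilon) for b in kinks])
    best = vals.min()
    opt = kinks[vals <= best + 1e-12]
    return float(opt.min()), float(opt.max())


def bootstrap_auc_diff_variance(scores_a, scores_b, labels, n_boot=2000, seed=0):
    """Subject-bootstrap variance of AUC_a − AUC_b (stratified by class)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos_idx = np.flatnonzero(labels == "PD")
    neg_idx = np.flatnonzero(labels != "PD")
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        q = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([p, q])
        lab = labels[idx]
        diffs[i] = brute_auc(scores_a[idx], lab) - brute_auc(scores_b[idx], lab)
    return float(np.var(diffs, ddof=1))


def bootstrap_auc_variance(scores, labels, n_boot=2000, seed=0):
    """Subject-bootstrap variance of a single AUC (stratified by class)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos_idx = np.flatnonzero(labels == "PD")
    neg_idx = np.flatnonzero(labels != "PD")
    vals = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        q = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([p, q])
        vals[i] = brute_auc(scores[idx], labels[idx])
    return float(np.var(vals, ddof=1))
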