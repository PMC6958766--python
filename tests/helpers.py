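"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the folding
oracle enumerates structures recursively without memoization, the metric
oracles evaluate the defining formulas directly, and the gradient oracle
is central-difference numerical differentiation.
"""

import math

import numpy as np

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pair count by exhaustive interval recursion."""

    def rec(i, j):
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1) if seq else 0


def metrics_bruteforce(tp, tn, fp, fn):
    """Direct evaluation of the five confusion-matrix formulas."""
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    denom = math.sqrt((tp + fn) * (tn + fp) * (tn + fn) * (tp + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    return sens, spec, f1, mcc, acc


def concordance_auc(labels, scores) -> float:
    """Pairwise concordance statistic (ties count half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def numerical_gradients(net, loss_fn, x, y, eps: float = 1e-6):
    """Central-difference gradients of the loss w.r.t. every parameter."""
    grads = []
    for p in net.parameters():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            old = p[ix]
            p[ix] = old + eps
            lp = loss_fn.forward(net.forward(x), y)
            p[ix] = old - eps
            lm = loss_fn.forward(net.forward(x), y)
            p[ix] = old
            g[ix] = (lp - lm) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("AUGC"), size=n))
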