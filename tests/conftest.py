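"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything from first principles (python
loops, full enumeration) so they share no code path with the package."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from gwofs.synthetic import make_worked_fixture

# ---------------------------------------------------------------------------
# naive O(L^2) KNN oracle


def naive_knn_predict(X_train, y_train, X_test, k):
    """Per-sample loops; neighbours sorted by (distance, class, index),
    votes resolved to the lowest class among the most-voted."""
    preds = []
    for x in X_test:
        cand = []
        for idx, (xt, yt) in enumerate(zip(X_train, y_train)):
            dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, xt)))
            cand.append((dist, int(yt), idx))
        cand.sort()
        votes = {}
        for dist, label, _ in cand[: min(k, len(cand))]:
            votes[label] = votes.get(label, 0) + 1
        top = max(votes.values())
        preds.append(min(lbl for lbl, v in votes.items() if v == top))
    return np.array(preds)


def naive_cv_error(features, labels, bits, fold_plan, k):
    """Mean fold error using the naive KNN; same folds as the package."""
    errs = []
    all_preds = []
    for tr, te in fold_plan:
        Xtr = features[np.ix_(tr, np.flatnonzero(bits))]
        Xte = features[np.ix_(te, np.flatnonzero(bits))]
        pred = naive_knn_predict(Xtr, labels[tr], Xte, k)
        errs.append(float(np.mean(pred != labels[te])))
        all_preds.append((te, pred))
    return float(np.mean(errs)), errs, all_preds


# ---------------------------------------------------------------------------
# brute-force fitness-distance-balance oracle


def brute_fdb(positions, fitness, best_pos):
    """Recompute FDB scores independently: explicit loops and min-max."""
    n = len(positions)
    dp = [math.sqrt(sum((p - b) ** 2 for p, b in zip(positions[i], best_pos)))
          for i in range(n)]
    fmin, fmax = min(fitness), max(fitness)
    dmin, dmax = min(dp), max(dp)
    norm_f = [0.0 if fmax == fmin else (fmax - f) / (fmax - fmin) for f in fitness]
    norm_dp = [0.0 if dmax == dmin else (d - dmin) / (dmax - dmin) for d in dp]
    return np.array(dp), np.array(norm_f), np.array(norm_dp), np.array(
        [a + b for a, b in zip(norm_f, norm_dp)]
    )


# ---------------------------------------------------------------------------
# exact rank-sum enumeration oracle


def enumerated_ranksum_p(a, b):
    """Two-sided exact p by enumerating every rank assignment (no ties)."""
    a, b = list(a), list(b)
    na, n = len(a), len(a) + len(b)
    pooled = sorted(a + b)
    ranks_a = [pooled.index(v) + 1 for v in a]
    u_obs = sum(ranks_a) - na * (na + 1) / 2
    us = [sum(c) - na * (na + 1) / 2
          for c in itertools.combinations(range(1, n + 1), na)]
    lo = sum(1 for u in us if u <= u_obs) / len(us)
    hi = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def worked_fixture():
    return make_worked_fixture()
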