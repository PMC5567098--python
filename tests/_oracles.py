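"""Brute-force reference implementations used only as test oracles.

Each oracle recomputes a quantity by direct enumeration of its definition
(every pair, every subset, every candidate cut), independently of the
package's vectorised code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def poisson_dev_sum(events, times):
    """Unnormalised within-node deviance, straight from the definition."""
    c = np.asarray(events, float)
    t = np.asarray(times, float)
    lam = c.sum() / t.sum()
    total = 0.0
    for ci, ti in zip(c, t):
        term = ci * math.log(ci / (lam * ti)) if ci > 0 and lam > 0 else 0.0
        total += term - (ci - lam * ti)
    return total


def enumerate_splits(columns, kinds, min_bucket):
    """Yield (feature, mask, descriptor) for every admissible binary split."""
    n = len(columns[0])
    for j, (col, kind) in enumerate(zip(columns, kinds)):
        if kind == "categorical":
            levels = sorted(set(col), key=str)
            if len(levels) < 2:
                continue
            for r in range(1, len(levels)):
                for subset in itertools.combinations(levels, r):
                    mask = np.isin(np.asarray(col, object), subset)
                    if min_bucket <= mask.sum() <= n - min_bucket:
                        yield j, mask, frozenset(subset)
        else:
            x = np.asarray(col, float)
            vals = np.unique(x)
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2
                mask = x <= thr
                if min_bucket <= mask.sum() <= n - min_bucket:
                    yield j, mask, thr


def best_poisson_split(columns, kinds, events, times, min_bucket):
    """Exhaustive argmax of the deviance improvement; None if no positive
    improvement exists. Returns (gain, set of argmax descriptors)."""
    c = np.asarray(events, float)
    t = np.asarray(times, float)
    d_parent = poisson_dev_sum(c, t)
    best_gain, best_set = 0.0, set()
    for j, mask, desc in enumerate_splits(columns, kinds, min_bucket):
        gain = d_parent - poisson_dev_sum(c[mask], t[mask]) - poisson_dev_sum(c[~mask], t[~mask])
        if gain > best_gain + 1e-12:
            best_gain, best_set = gain, {(j, desc)}
        elif best_set and abs(gain - best_gain) <= 1e-9 * max(1.0, best_gain):
            best_set.add((j, desc))
    return (best_gain, best_set) if best_set else (0.0, set())


def gini_impurity(labels, weights):
    y = np.asarray(labels, float)
    w = np.asarray(weights, float)
    W = w.sum()
    if W <= 0:
        return 0.0
    p = (w * y).sum() / W
    return 2.0 * p * (1 - p) * W


def best_gini_split(columns, kinds, labels, weights, min_bucket):
    y = np.asarray(labels, float)
    w = np.asarray(weights, float)
    parent = gini_impurity(y, w)
    best_gain, best_set = 0.0, set()
    for j, mask, desc in enumerate_splits(columns, kinds, min_bucket):
        gain = parent - gini_impurity(y[mask], w[mask]) - gini_impurity(y[~mask], w[~mask])
        if gain > best_gain + 1e-12:
            best_gain, best_set = gain, {(j, desc)}
        elif best_set and abs(gain - best_gain) <= 1e-9 * max(1.0, best_gain):
            best_set.add((j, desc))
    return (best_gain, best_set) if best_set else (0.0, set())


def concordance_pairs(times, events, risks):
    """Harrell's C by explicit double loop over ordered pairs."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    r = np.asarray(risks, float)
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j or not (t[i] < t[j] and e[i] == 1):
                continue
            den += 1
            if r[i] > r[j]:
                num += 1
            elif r[i] == r[j]:
                num += 0.5
    return num / den if den else None


def auc_pairs(labels, scores, weights):
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    w = np.asarray(weights, float)
    num = den = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] == 1 and y[j] == 0:
                pw = w[i] * w[j]
                den += pw
                if s[i] > s[j]:
                    num += pw
                elif s[i] == s[j]:
                    num += 0.5 * pw
    return num / den if den else None


def cox_loglik_1d(beta, x, times, events):
    """Breslow partial log-likelihood for a single covariate."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll
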