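"""Independent brute-force oracles, coded directly from first principles.

These deliberately use plain Python loops and none of the package's code
paths, so that agreement with the vectorized implementations is a real
cross-check.
"""

from __future__ import annotations

import math
from statistics import median


# ---------------------------------------------------------------------------
# nearest shrunken centroids


def nsc_fit_oracle(x, labels, delta, priors=None, convention="+"):
    """x: list of feature rows; labels: per-sample class labels."""
    p = len(x)
    n = len(labels)
    classes = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    K = len(classes)
    idx = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}
    n_k = {c: len(idx[c]) for c in classes}

    centroids = [[sum(x[j][i] for i in idx[c]) / n_k[c] for c in classes] for j in range(p)]
    overall = [sum(row) / n for row in x]
    s = []
    for j in range(p):
        ss = 0.0
        for ci, c in enumerate(classes):
            for i in idx[c]:
                ss += (x[j][i] - centroids[j][ci]) ** 2
        s.append(math.sqrt(ss / (n - K)))
    s0 = median(s)
    m_k = {}
    for c in classes:
        if convention == "+":
            m_k[c] = math.sqrt(1.0 / n_k[c] + 1.0 / n)
        else:
            m_k[c] = math.sqrt(max(1.0 / n_k[c] - 1.0 / n, 0.0))
    d = [[(centroids[j][ci] - overall[j]) / (m_k[c] * (s[j] + s0))
          for ci, c in enumerate(classes)] for j in range(p)]
    d_shr = [[math.copysign(max(abs(v) - delta, 0.0), v) for v in row] for row in d]
    shrunk = [[overall[j] + m_k[c] * (s[j] + s0) * d_shr[j][ci]
               for ci, c in enumerate(classes)] for j in range(p)]
    if priors is None:
        priors = [n_k[c] / n for c in classes]
    return {
        "classes": classes, "centroids": centroids, "overall": overall,
        "s": s, "s0": s0, "m_k": [m_k[c] for c in classes],
        "d": d, "d_shrunk": d_shr, "shrunken": shrunk, "priors": priors,
    }


def nsc_score_oracle(fit, xstar):
    """Discriminants and posteriors for one sample (list of feature values)."""
    K = len(fit["classes"])
    p = len(xstar)
    disc = []
    for ci in range(K):
        acc = 0.0
        for j in range(p):
            acc += (xstar[j] - fit["shrunken"][j][ci]) ** 2 / (fit["s"][j] + fit["s0"]) ** 2
        disc.append(acc - 2.0 * math.log(fit["priors"][ci]))
    lo = min(disc)
    w = [math.exp(-(dd - lo) / 2.0) for dd in disc]
    tot = sum(w)
    post = [v / tot for v in w]
    pred = fit["classes"][post.index(max(post))]
    return disc, post, pred


# ---------------------------------------------------------------------------
# BH step-up


def bh_oracle(p):
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


# ---------------------------------------------------------------------------
# pooled-variance two-sample t-test (textbook formulas + scipy CDF)


def pooled_ttest_oracle(a, b):
    from scipy.stats import t as tdist

    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((v - m1) ** 2 for v in a) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in b) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0 if m1 == m2 else 1e-300
    tstat = (m1 - m2) / se
    return 2.0 * float(tdist.sf(abs(tstat), n1 + n2 - 2))


# ---------------------------------------------------------------------------
# AUC by pair counting


def auc_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# one-way fixed-effects ANOVA


def anova_oracle(groups):
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        raise ZeroDivisionError("no within-group variance")
    f = (ssb / dfb) / (ssw / dfw)
    from scipy.stats import f as fdist

    return f, float(fdist.sf(f, dfb, dfw))


# ---------------------------------------------------------------------------
# Cohen's kappa from an agreement table


def kappa_oracle(table):
    """table[i][j]: counts of (rater A = i, rater B = j)."""
    n = sum(sum(row) for row in table)
    k = len(table)
    p_o = sum(table[i][i] for i in range(k)) / n
    p_e = sum(
        (sum(table[i]) / n) * (sum(table[r][i] for r in range(k)) / n) for i in range(k)
    )
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# ComBat empirical-Bayes adjustment (direct transliteration, loops)


def combat_oracle(x, batch, tol=1e-4, max_iter=500):
    """x: list of feature rows, batch: per-sample labels."""
    p = len(x)
    n = len(batch)
    levels = []
    for b in batch:
        if b not in levels:
            levels.append(b)
    idx = {b: [i for i, bb in enumerate(batch) if bb == b] for b in levels}
    n_b = {b: len(idx[b]) for b in levels}

    batch_mean = {b: [sum(x[j][i] for i in idx[b]) / n_b[b] for j in range(p)] for b in levels}
    alpha = [sum(n_b[b] / n * batch_mean[b][j] for b in levels) for j in range(p)]
    sigma = []
    for j in range(p):
        ss = 0.0
        for b in levels:
            for i in idx[b]:
                ss += (x[j][i] - batch_mean[b][j]) ** 2
        sigma.append(math.sqrt(ss / n))
    z = [[(x[j][i] - alpha[j]) / sigma[j] for i in range(n)] for j in range(p)]

    out = [row[:] for row in z]
    for b in levels:
        g_hat = [sum(z[j][i] for i in idx[b]) / n_b[b] for j in range(p)]
        d_hat = [
            sum((z[j][i] - g_hat[j]) ** 2 for i in idx[b]) / (n_b[b] - 1) for j in range(p)
        ]
        g_bar = sum(g_hat) / p
        t2 = sum((g - g_bar) ** 2 for g in g_hat) / (p - 1)
        dm = sum(d_hat) / p
        dv = sum((d - dm) ** 2 for d in d_hat) / (p - 1)
        a = (2 * dv + dm**2) / dv
        bb = (dm * dv + dm**3) / dv
        g_old, d_old = g_hat[:], d_hat[:]
        for _ in range(max_iter):
            g_new = [
                (n_b[b] * t2 * g_hat[j] + d_old[j] * g_bar) / (n_b[b] * t2 + d_old[j])
                for j in range(p)
            ]
            d_new = []
            for j in range(p):
                ss = sum((z[j][i] - g_new[j]) ** 2 for i in idx[b])
                d_new.append((0.5 * ss + bb) / (n_b[b] / 2 + a - 1))
            change = max(
                max(abs(gn - go) for gn, go in zip(g_new, g_old)),
                max(abs(dn - do) for dn, do in zip(d_new, d_old)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        for j in range(p):
            for i in idx[b]:
                out[j][i] = (z[j][i] - g_old[j]) / math.sqrt(d_old[j])
    return [
        [out[j][i] * sigma[j] + alpha[j] for i in range(n)] for j in range(p)
    ]
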