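"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal textbook loops, deliberately sharing
no code with the package implementations it checks.
"""

import math

import numpy as np
from scipy import optimize, stats


def bh_brute(pvals):
    """Step-up BH by definition: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for rank_pos, i in enumerate(order):
        candidates = []
        for later_pos in range(rank_pos, n):
            j = order[later_pos]
            candidates.append(p[j] * n / (later_pos + 1))
        q[i] = min(min(candidates), 1.0)
    return q


def welch_t_brute(a, b):
    """Welch t statistic and two-sided p, straight from the formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def km_brute(times, events):
    """Product-limit estimate evaluated after each distinct event time."""
    records = sorted(zip(times, events))
    out_t, out_s = [], []
    s = 1.0
    distinct = sorted({t for t, e in records if e})
    for t in distinct:
        at_risk = sum(1 for tt, _ in records if tt >= t)
        d = sum(1 for tt, e in records if tt == t and e)
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


def logrank_2group_brute(times, events, group):
    """Two-group log-rank via explicit per-event-time 2x2 tables."""
    data = list(zip(times, events, group))
    event_times = sorted({t for t, e, _ in data if e})
    O = E = V = 0.0
    for t in event_times:
        n = sum(1 for tt, _, _ in data if tt >= t)
        n1 = sum(1 for tt, _, g in data if tt >= t and g)
        d = sum(1 for tt, e, _ in data if tt == t and e)
        d1 = sum(1 for tt, e, g in data if tt == t and e and g)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    p = stats.chi2.sf(chi2, 1) if chi2 > 0 else 1.0
    return O - E, V, chi2, p


def cox_loglik_brute(beta, times, events, x):
    """Log partial likelihood for a single covariate, no ties assumed."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_mle_brute(times, events, x):
    """Maximize the literal partial likelihood over a scalar coefficient."""
    res = optimize.minimize_scalar(
        lambda b: -cox_loglik_brute(b, times, events, x),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-8})
    return res.x


def gsva_brute(X, gene_names, gene_sets, tau=1.0):
    """GSVA scores by literal loops over the published equations."""
    p, n = len(X), len(X[0])
    # kernel CDF statistic, Gaussian kernel, bandwidth s_i / 4
    Z = [[0.0] * n for _ in range(p)]
    for i in range(p):
        mean = sum(X[i]) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in X[i]) / (n - 1))
        h = sd / 4.0
        for j in range(n):
            if h == 0:
                Z[i][j] = 0.5
            else:
                Z[i][j] = sum(stats.norm.cdf((X[i][j] - X[i][k]) / h)
                              for k in range(n)) / n
    scores = {}
    for name, members in gene_sets.items():
        member_idx = {gi for gi, g in enumerate(gene_names) if g in members}
        m = len(member_idx)
        scores[name] = []
        for j in range(n):
            col = [Z[i][j] for i in range(p)]
            # ranks (average ties), highest statistic -> rank p
            ranks = stats.rankdata(col)
            weights = [abs(p / 2.0 - r) ** tau for r in ranks]
            order = sorted(range(p), key=lambda i: -col[i])
            denom = sum(weights[i] for i in member_idx)
            inc = dec = 0.0
            best_pos, best_neg = 0.0, 0.0
            for i in order:
                if i in member_idx:
                    inc += weights[i] / denom
                else:
                    dec += 1.0 / (p - m)
                nu = inc - dec
                best_pos = max(best_pos, nu)
                best_neg = min(best_neg, nu)
            scores[name].append(best_pos + best_neg)
    return scores


def maxsel_cutoff_brute(scores, times, events, minprop=0.1):
    """Exhaustive maximally-selected log-rank scan over every admissible
    cutpoint (high = score > cut; both groups >= minprop * n)."""
    n = len(scores)
    best = None
    for c in sorted(set(scores)):
        high = [s > c for s in scores]
        nh = sum(high)
        if nh < minprop * n or (n - nh) < minprop * n:
            continue
        _, V, chi2, _ = logrank_2group_brute(times, events, high)
        z = math.sqrt(chi2)
        if best is None or z > best[1] + 1e-12:
            best = (c, z)
    return best
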