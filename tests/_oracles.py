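"""Independent brute-force oracles used by the test suite.

Each function here recomputes a statistic from first principles by a
different route than the package implementation (enumeration, direct
summation, grid search), so agreement is evidence of correctness rather
than a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln


def by_stepup(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up written directly from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m * c_m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up (no harmonic factor)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """HWE exact p by full enumeration with log-gamma probabilities.

    P(het = h | n, allele counts) = 2^h n! nA! na! / (nAA! nAa! naa! (2n)!)
    summed over all achievable tables; two-sided by probability ordering.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a

    def logprob(h: int) -> float:
        haa = (n_a - h) // 2
        hAA = (n_A - h) // 2
        return (
            h * math.log(2.0)
            + gammaln(n + 1)
            + gammaln(n_A + 1)
            + gammaln(n_a + 1)
            - gammaln(hAA + 1)
            - gammaln(h + 1)
            - gammaln(haa + 1)
            - gammaln(2 * n + 1)
        )

    rare = min(n_a, n_A)
    hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = {h: logprob(h) for h in hets}
    norm = max(logs.values())
    probs = {h: math.exp(v - norm) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_Aa]
    return min(
        1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-10)) / total
    )


def mutual_information_direct(table) -> float:
    """I(rows; cols) in bits by direct summation over the joint table."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    p = t / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * math.log2(p[i, j] / (pr[i, 0] * pc[0, j]))
    return mi


def km_product_limit(times, events):
    """Kaplan-Meier by the textbook product over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_observed_expected(times_a, events_a, times_b, events_b):
    """Mantel-Cox chi-square from the observed-minus-expected form."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single binary covariate."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        dead = (t == u) & (e == 1)
        d = int(dead.sum())
        s = float(x[dead].sum())
        denom = np.sum(np.exp(beta * x[at_risk]))
        ll += beta * s - d * math.log(denom)
    return ll


def cox_grid_search(times, events, x, lo=-3.0, hi=3.0, tol=1e-6):
    """Maximize the Breslow partial likelihood by golden-section search."""
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc = cox_breslow_loglik(c, times, events, x)
    fd = cox_breslow_loglik(d, times, events, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = cox_breslow_loglik(c, times, events, x)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = cox_breslow_loglik(d, times, events, x)
    return math.exp((a + b) / 2)
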