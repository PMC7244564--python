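"""Independent brute-force oracles: literal transcriptions of the definitions.

Deliberately unvectorized and written without reference to the package
internals, so they can arbitrate the fast implementations.
"""

import itertools
import math

from bcpred.sequence_io import ALPHABET


def oracle_ac(seq):
    return [seq.count(aa) / len(seq) for aa in ALPHABET]


def oracle_dc(seq):
    dipeps = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return [dipeps.count(a + b) / len(dipeps)
            for a in ALPHABET for b in ALPHABET]


def oracle_tc(seq):
    tripeps = [seq[i : i + 3] for i in range(len(seq) - 2)]
    counts = {}
    for t in tripeps:
        counts[t] = counts.get(t, 0) + 1
    return [counts.get(a + b + c, 0) / len(tripeps)
            for a in ALPHABET for b in ALPHABET for c in ALPHABET]


def _standardize(scale_dict):
    vals = [scale_dict[aa] for aa in ALPHABET]
    mean = sum(vals) / 20
    var = sum((v - mean) ** 2 for v in vals) / 19  # sample variance, n-1
    sd = math.sqrt(var)
    return {aa: (scale_dict[aa] - mean) / sd for aa in ALPHABET}


def oracle_apaac(seq, h1, h2, lam, w):
    """Literal tau sums: h1/h2 are {aa: value} dicts of the raw scales."""
    n = len(seq)
    H1 = _standardize(h1)
    H2 = _standardize(h2)
    taus = []
    for j in range(1, lam + 1):
        t1 = sum(H1[seq[i]] * H1[seq[i + j]] for i in range(n - j)) / (n - j)
        t2 = sum(H2[seq[i]] * H2[seq[i + j]] for i in range(n - j)) / (n - j)
        taus.extend([t1, t2])
    denom = 1.0 + w * sum(taus)
    f = oracle_ac(seq)
    return [fu / denom for fu in f] + [w * t / denom for t in taus]


def oracle_mb(seq, scales, nlag):
    """scales: ordered {name: {aa: value}}; returns scale-major, lag-minor."""
    n = len(seq)
    out = []
    for sc in scales.values():
        P = _standardize(sc)
        for d in range(1, nlag + 1):
            out.append(sum(P[seq[i]] * P[seq[i + d]] for i in range(n - d)) / (n - d))
    return out


def oracle_auroc(pos_scores, neg_scores):
    """Pairwise concordance: P(positive ranked above negative), ties = 0.5."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def oracle_chi2(column, labels):
    """Feature-sum contingency chi2 for one non-negative column."""
    n = len(labels)
    total = sum(column)
    score = 0.0
    for cls in (0, 1):
        observed = sum(x for x, y in zip(column, labels) if y == cls)
        expected = total * sum(1 for y in labels if y == cls) / n
        score += (observed - expected) ** 2 / expected
    return score


def oracle_mannwhitney(x, y):
    """U for group x and exact two-sided p by enumerating all group splits.

    U is computed by pairwise comparison (wins + half-ties); the null
    distribution enumerates every choice of |x| positions from the pooled
    values, so ties are handled without any rank machinery.
    """

    def u_stat(a, b):
        u = 0.0
        for p in a:
            for q in b:
                if p > q:
                    u += 1.0
                elif p == q:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    pooled = list(x) + list(y)
    n1 = len(x)
    center = n1 * len(y) / 2
    dev = abs(u_obs - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total
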