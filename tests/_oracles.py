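"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately restate each procedure in the most direct way possible
(closed-form enumeration, plain loops) and stay independent of the package
implementations they check.
"""

import itertools
from math import lgamma

import numpy as np


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct evaluation of the conditional pmf at every
    admissible heterozygote count."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    if n == 0 or na == 0 or na == 2 * n:
        return 1.0

    def logpmf(h):
        haa = (na - h) // 2
        hbb = n - h - haa
        return (lgamma(n + 1) - lgamma(haa + 1) - lgamma(h + 1)
                - lgamma(hbb + 1) + h * np.log(2.0)
                + lgamma(na + 1) + lgamma(2 * n - na + 1) - lgamma(2 * n + 1))

    hs = list(range(na % 2, min(na, 2 * n - na) + 1, 2))
    probs = np.exp([logpmf(h) for h in hs])
    obs = probs[hs.index(n_ab)]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def greedy_clump_oracle(pvals, chrom, pos, dosage, r2=0.1, window=200_000):
    """Plain restatement of greedy clumping, one pair at a time."""
    m = len(pvals)
    alive = [True] * m
    kept = []
    while any(alive):
        cands = [j for j in range(m) if alive[j]]
        j = min(cands, key=lambda k: (pvals[k], chrom[k], pos[k]))
        kept.append(j)
        alive[j] = False
        for k in range(m):
            if alive[k] and chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= window:
                r = np.corrcoef(dosage[:, j], dosage[:, k])[0, 1]
                if r * r > r2:
                    alive[k] = False
    return kept


def bh_oracle(p):
    """q_i as the minimum of p_(j) * m / j over every j whose sorted p is
    at least p_i, computed pair by pair."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    out = np.empty(m)
    for i in range(m):
        js = [j for j in range(m) if p[order[j]] >= p[order[i]] - 1e-15]
        out[order[i]] = min(min(p[order[j]] * m / (j + 1) for j in js), 1.0)
    return out


def rxc_oracle(t):
    """Freeman-Halton p by enumerating every inner-cell assignment."""
    t = np.asarray(t)
    rs, cs = t.sum(1), t.sum(0)
    if (rs == 0).any() or (cs == 0).any():
        return 1.0
    n = t.sum()
    const = (sum(lgamma(v + 1) for v in rs) + sum(lgamma(v + 1) for v in cs)
             - lgamma(n + 1))

    def logp(cells):
        return const - sum(lgamma(v + 1) for v in cells)

    obs = logp(t.ravel())
    R, C = len(rs), len(cs)
    ranges = [range(min(rs[i], cs[j]) + 1)
              for i in range(R - 1) for j in range(C - 1)]
    total = 0.0
    for inner in itertools.product(*ranges):
        tab = np.zeros((R, C), dtype=int)
        tab[:R - 1, :C - 1] = np.reshape(inner, (R - 1, C - 1))
        tab[:R - 1, C - 1] = rs[:R - 1] - tab[:R - 1, :C - 1].sum(1)
        tab[R - 1, :] = cs - tab[:R - 1, :].sum(0)
        if (tab < 0).any():
            continue
        lp = logp(tab.ravel())
        if lp <= obs + 1e-12:
            total += np.exp(lp)
    return float(min(total, 1.0))
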