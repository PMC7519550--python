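"""Independent brute-force oracles for the stability estimators.

Everything here is written as naive explicit loops over the defining
formulas, deliberately sharing no code with the package implementation.
Matrices are plain dicts ``gene -> list of Cq values`` over a common sample
ordering.
"""

import math
from itertools import combinations


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def _mad(xs):
    m = _mean(xs)
    return _mean([abs(x - m) for x in xs])


def _pearson(xs, ys):
    mx, my = _mean(xs), _mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs)) * math.sqrt(
        sum((y - my) ** 2 for y in ys)
    )
    return num / den


def cv_percent(matrix):
    """CV% of 2**-Cq per gene."""
    out = {}
    for gene, cqs in matrix.items():
        linear = [2.0 ** (-c) for c in cqs]
        out[gene] = 100.0 * _sd(linear) / _mean(linear)
    return out


def genorm_m_full(matrix):
    """M value of every gene against all others, via explicit Q ratios."""
    out = {}
    for gene, cqs in matrix.items():
        q_g = [2.0 ** (min(cqs) - c) for c in cqs]
        sds = []
        for other, ocqs in matrix.items():
            if other == gene:
                continue
            q_h = [2.0 ** (min(ocqs) - c) for c in ocqs]
            ratios = [math.log2(a / b) for a, b in zip(q_g, q_h)]
            sds.append(_sd(ratios))
        out[gene] = _mean(sds)
    return out


def genorm_exclusion(matrix):
    """Iterative exclusion: (exclusion order, M at removal, final pair)."""
    remaining = dict(matrix)
    order, removal_m = [], {}
    while len(remaining) > 2:
        m = genorm_m_full(remaining)
        worst_val = max(m.values())
        worst = max(g for g, v in m.items() if v == worst_val)
        order.append(worst)
        removal_m[worst] = worst_val
        del remaining[worst]
    pair = sorted(remaining)
    ratios = [a - b for a, b in zip(matrix[pair[0]], matrix[pair[1]])]
    for g in pair:
        removal_m[g] = _sd(ratios)
    return order, removal_m, pair


def v_series(matrix, stability_order):
    """V_n/n+1 from explicit normalization factors (geometric means of Q)."""
    n_samples = len(next(iter(matrix.values())))
    qs = {
        g: [2.0 ** (min(cqs) - c) for c in cqs] for g, cqs in matrix.items()
    }
    out = {}
    for n in range(2, len(stability_order)):
        diffs = []
        for s in range(n_samples):
            nf_n = math.prod(qs[g][s] for g in stability_order[:n]) ** (1.0 / n)
            nf_n1 = math.prod(qs[g][s] for g in stability_order[: n + 1]) ** (
                1.0 / (n + 1)
            )
            diffs.append(math.log2(nf_n / nf_n1))
        out[n] = _sd(diffs)
    return out


def delta_ct_scores(matrix):
    """Mean SD of pairwise delta-Ct per gene."""
    genes = list(matrix)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            sds.append(_sd([a - b for a, b in zip(matrix[g], matrix[h])]))
        out[g] = _mean(sds)
    return out


def bestkeeper(matrix, dispersion="mad"):
    """Descriptives, gene-pair correlations, index and gene-index correlations."""
    genes = list(matrix)
    n = len(next(iter(matrix.values())))
    desc = {}
    for g, cqs in matrix.items():
        disp = _mad(cqs) if dispersion == "mad" else _sd(cqs)
        geo = math.exp(_mean([math.log(c) for c in cqs]))
        desc[g] = {
            "geo_mean_cp": geo,
            "mean_cp": _mean(cqs),
            "min_cp": min(cqs),
            "max_cp": max(cqs),
            "sd_cp": disp,
            "x_fold": 2.0**disp,
        }
    index = [
        math.exp(_mean([math.log(matrix[g][s]) for g in genes])) for s in range(n)
    ]
    pair_r = {
        (a, b): _pearson(matrix[a], matrix[b]) for a, b in combinations(genes, 2)
    }
    index_r = {g: _pearson(matrix[g], index) for g in genes}
    return desc, pair_r, index, index_r


def normfinder_single_group(matrix):
    """Bias-corrected per-gene variances of the additive two-way model."""
    genes = list(matrix)
    k = len(genes)
    n = len(next(iter(matrix.values())))
    grand = _mean([c for cqs in matrix.values() for c in cqs])
    row_means = {g: _mean(matrix[g]) for g in genes}
    col_means = [_mean([matrix[g][s] for g in genes]) for s in range(n)]
    u = {}
    for g in genes:
        resid = [
            matrix[g][s] - row_means[g] - col_means[s] + grand for s in range(n)
        ]
        u[g] = sum(r * r for r in resid) / (n - 1)
    total = sum(u.values())
    out = {}
    for g in genes:
        sigma2 = (k / (k - 2)) * (u[g] - total / (k * (k - 1)))
        out[g] = max(sigma2, 0.0)
    return out
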