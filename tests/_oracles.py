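"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity with the most literal possible
formulation (explicit loops over branches, taxa or pairs), sharing no code
path with the package implementations it checks.
"""

import numpy as np


def naive_gunifrac(tree, rel_abund, alpha):
    """Generalized UniFrac by explicit per-branch, per-pair loops.

    ``rel_abund`` is a dict sample -> {tip: proportion}.
    """
    branches = []  # (length, set of tip names below)
    for node in tree.tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        branches.append((node.length or 0.0, tips))

    samples = list(rel_abund)
    out = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            num = den = 0.0
            for length, tips in branches:
                p = sum(rel_abund[a].get(t, 0.0) for t in tips)
                q = sum(rel_abund[b].get(t, 0.0) for t in tips)
                if p + q > 0:
                    w = length * (p + q) ** alpha
                    num += w * abs(p - q) / (p + q)
                    den += w
            out[(a, b)] = 0.0 if den == 0 else num / den
    return out


def naive_bmntd(patristic, freqs):
    """Weighted beta-MNTD by explicit double loops.

    ``patristic`` is a dict-of-dict tip -> tip -> distance; ``freqs`` a
    dict sample -> {tip: relative abundance > 0}.
    """
    samples = list(freqs)
    out = {}
    for x, a in enumerate(samples):
        for b in samples[x + 1:]:
            total = 0.0
            for i, fi in freqs[a].items():
                total += 0.5 * fi * min(patristic[i][j] for j in freqs[b])
            for j, fj in freqs[b].items():
                total += 0.5 * fj * min(patristic[j][i] for i in freqs[a])
            out[(a, b)] = total
    return out


def classical_anova_f(values, groups):
    """Textbook one-way ANOVA F from group means."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    grand = values.mean()
    ss_b = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
               for g in labels)
    ss_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
               for g in labels)
    k, n = len(labels), len(values)
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def naive_dbmem(positions):
    """Independent dbMEM pipeline: truncation, centering, eigh.

    Returns (eigenvalues > 0 descending, eigenvectors as columns).
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    D = np.abs(x[:, None] - x[None, :])
    thr = np.max(np.diff(np.sort(x)))
    T = np.where(D > thr, 4.0 * thr, D)
    np.fill_diagonal(T, 0.0)
    ones = np.ones((n, n)) / n
    A = -0.5 * T ** 2
    G = A - ones @ A - A @ ones + ones @ A @ ones
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > vals.max() * 1e-12
    return vals[keep], vecs[:, keep]


def tukey_q_pvalue(means, sds, ns, i, j):
    """Tukey HSD p for one pair from the studentized range distribution."""
    from scipy.stats import studentized_range
    k = len(means)
    dfw = sum(ns) - k
    msw = sum((n - 1) * s ** 2 for s, n in zip(sds, ns)) / dfw
    q = abs(means[i] - means[j]) / np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
    return studentized_range.sf(q, k, dfw)
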