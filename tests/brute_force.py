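"""Literal, scalar-by-scalar reference implementation of the MDS/SQI rules.

Kept deliberately naive (explicit loops, no vectorized shortcuts) so it can
serve as an independent oracle for the packaged implementation: Pearson
correlations are accumulated element-wise, Norm values evaluate the defining
formula one indicator at a time, and the selection rules are applied in
their stated order on plain Python lists.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def pearson_scalar(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(sum((b - my) ** 2 for b in y))
    return num / den


def correlation_matrix(data) -> list[list[float]]:
    p = len(data[0])
    cols = [[row[j] for row in data] for j in range(p)]
    return [
        [1.0 if i == j else pearson_scalar(cols[i], cols[j]) for j in range(p)]
        for i in range(p)
    ]


def brute_sqi(data, directions=None, alpha=0.01):
    """Full literal pipeline on a list-of-rows table.

    Returns a dict with eigenvalues, loadings, norms, groups, survivors,
    final set (as column indices), weights and per-sample SQI.
    """
    n = len(data)
    p = len(data[0])
    directions = directions or ["ascending"] * p

    corr = np.array(correlation_matrix(data))
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = [max(float(eigval[j]), 0.0) for j in order]
    vecs = [[float(eigvec[i, j]) for j in order] for i in range(p)]

    # loadings u_ij = v_ij * sqrt(e_j), sign fixed so max-|u| per component > 0
    load = [[vecs[i][j] * math.sqrt(eigval[j]) for j in range(p)] for i in range(p)]
    for j in range(p):
        i_star = 0
        for i in range(p):
            if abs(load[i][j]) > abs(load[i_star][j]):
                i_star = i
        if load[i_star][j] < 0:
            for i in range(p):
                load[i][j] = -load[i][j]

    # rule 1: retain components with eigenvalue >= 1 (fallback: PC1)
    k = sum(1 for e in eigval if e >= 1.0) or 1

    # rule 2: group each indicator on one retained component
    group_of = []
    for i in range(p):
        hits = [j for j in range(k) if abs(load[i][j]) >= 0.5]
        if not hits:
            hits = list(range(k))
        best = hits[0]
        for j in hits:
            if abs(load[i][j]) > abs(load[i][best]):
                best = j
        group_of.append(best)

    # rule 3: Norm values over the retained components
    norms = [
        math.sqrt(sum(load[i][j] ** 2 * eigval[j] for j in range(k))) for i in range(p)
    ]

    survivors = []
    final = []
    for g in sorted(set(group_of)):
        members = [i for i in range(p) if group_of[i] == g]
        gmax = max(norms[i] for i in members)
        kept = [i for i in members if norms[i] >= 0.9 * gmax]  # rule 4
        survivors.extend(kept)
        ranked = sorted(kept, key=lambda i: (-norms[i], i))
        chosen = []
        for i in ranked:  # rule 5
            ok = True
            for c in chosen:
                r = corr[i][c]
                t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else math.inf
                pval = 0.0 if math.isinf(t) else 2.0 * float(sps.t.sf(t, n - 2))
                if pval < alpha:
                    ok = False
                    break
            if ok:
                chosen.append(i)
        final.extend(chosen)
    survivors = sorted(survivors)
    final = sorted(final)  # rule 6: union, original column order

    # weights: communality over retained components, normalized on final set
    comm = [sum(load[i][j] ** 2 for j in range(k)) for i in range(p)]
    wsum = sum(comm[i] for i in final)
    weights = {i: comm[i] / wsum for i in final}

    sqi = []
    for s in range(n):
        total = 0.0
        for i in final:
            col = [data[r][i] for r in range(n)]
            xmin, xmax = min(col), max(col)
            f = (data[s][i] - xmin) / (xmax - xmin)
            if directions[i] == "descending":
                f = 1.0 - f
            total += weights[i] * f
        sqi.append(total)

    return {
        "eigenvalues": eigval,
        "loadings": load,
        "retained_k": k,
        "groups": group_of,
        "norms": norms,
        "survivors": survivors,
        "final": final,
        "weights": weights,
        "sqi": sqi,
    }
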