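"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the DBSCAN oracle
computes density-reachability by boolean matrix closure over the full
distance matrix, and the chi-square oracles evaluate the textbook formulas
term by term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dbscan_oracle(df: pd.DataFrame, eps: float, min_pts: int) -> dict[str, int]:
    """Exhaustive density-reachability closure on <=50-point instances.

    Same contract as ``hfemap.cluster.dbscan``: clusters are connected
    components of core points (numbered by smallest member id over the
    id-sorted points), border points join the cluster of their smallest-id
    core neighbour, everything else is noise (-1).
    """
    df = df.sort_values("id").reset_index(drop=True)
    xy = df[["pc1", "pc2"]].to_numpy()
    n = len(df)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    within = d <= eps
    core = within.sum(axis=1) >= min_pts  # self counted

    # transitive closure of the core-core within-eps relation
    adj = within & core[:, None] & core[None, :]
    reach = adj.copy()
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt

    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            members = np.where(reach[i] & core)[0]
            labels[members] = cluster
            labels[i] = cluster
            cluster += 1
    for i in range(n):
        if not core[i]:
            core_nb = [j for j in range(n) if within[i, j] and core[j]]
            labels[i] = labels[core_nb[0]] if core_nb else -1
    return dict(zip(df["id"], (int(l) for l in labels)))


def hwe_chi2_oracle(hom_ref: int, het: int, hom_alt: int) -> float:
    """Sum of (O-E)^2/E with HWE expectations, written out longhand."""
    n = hom_ref + het + hom_alt
    q = (2 * hom_alt + het) / (2 * n)
    p = 1 - q
    e = [p * p * n, 2 * p * q * n, q * q * n]
    o = [hom_ref, het, hom_alt]
    return sum((oi - ei) ** 2 / ei for oi, ei in zip(o, e))


def chi2_2x2_oracle(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of a 2x2 table from expected-count first principles."""
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def pearson_oracle(x, y) -> float:
    """Covariance over the product of standard deviations, written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    return cov / (np.sqrt(((x - mx) ** 2).mean()) * np.sqrt(((y - my) ** 2).mean()))
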