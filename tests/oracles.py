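"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force
enumeration, dense quadrature, gene-dropping simulation, and direct
sums-of-squares arithmetic.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def exclusion_p1_enumeration(freqs: np.ndarray) -> float:
    """First-parent exclusion probability by exhaustive enumeration.

    Enumerates (mother, father) genotype pairs under Hardy-Weinberg,
    offspring by Mendelian segregation, and a random unrelated candidate
    male under HWE; the candidate is excluded iff he carries no allele of
    the offspring.
    """
    p = np.asarray(freqs, dtype=float)
    k = p.size
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def gprob(g):
        i, j = g
        return p[i] ** 2 if i == j else 2 * p[i] * p[j]

    total = 0.0
    for mg in genos:
        for fg in genos:
            w_par = gprob(mg) * gprob(fg)
            for ma in mg:
                for fa in fg:
                    off = {ma, fa}
                    w_off = w_par * 0.25
                    excl = 0.0
                    for cg in genos:
                        if not (set(cg) & off):
                            excl += gprob(cg)
                    total += w_off * excl
    return total


def gene_drop_relationship(
    pedigree: pd.DataFrame, n_rep: int, seed: int
) -> tuple[np.ndarray, dict[str, int]]:
    """Estimate the additive relationship matrix as 2x the gene-dropping
    kinship: founders get unique allele labels, alleles descend by
    Mendelian sampling, and kinship(i, j) is the probability that a
    random allele from i equals a random allele from j.
    """
    rng = np.random.default_rng(seed)
    ids = list(pedigree["id"])
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    alleles = np.empty((n, 2, n_rep), dtype=np.int32)
    next_label = 0
    for row, rec in enumerate(pedigree.itertuples(index=False)):
        for slot, parent in enumerate((rec.dam, rec.sire)):
            if parent and parent in index:
                pi = index[parent]
                pick = rng.integers(2, size=n_rep)
                alleles[row, slot] = alleles[pi, pick, np.arange(n_rep)]
            else:
                alleles[row, slot] = next_label
                next_label += 1
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            s = 0.0
            for a in range(2):
                for b in range(2):
                    s += (alleles[i, a] == alleles[j, b]).mean()
            A[i, j] = A[j, i] = s / 2.0
    return A, index


def random_multigeneration_pedigree(
    n_founders: int, n_generations: int, per_gen: int, seed: int
) -> pd.DataFrame:
    """Random pedigree with the given depth; parents drawn from all
    earlier individuals (sexes ignored: any two distinct earlier ids)."""
    rng = np.random.default_rng(seed)
    rows = [{"id": f"g0_{i}", "dam": "", "sire": ""} for i in range(n_founders)]
    pool = [r["id"] for r in rows]
    for g in range(1, n_generations):
        new = []
        for i in range(per_gen):
            dam, sire = rng.choice(len(pool), size=2, replace=False)
            new.append({"id": f"g{g}_{i}", "dam": pool[dam], "sire": pool[sire]})
        rows.extend(new)
        pool.extend(r["id"] for r in new)
    return pd.DataFrame(rows)


def max_chroma_line_search(direction: np.ndarray, vertices: np.ndarray,
                           tol: float = 1e-9) -> float:
    """r_max by bisection on "is the point still inside the tetrahedron"."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    def inside(pt):
        # point is inside iff it is on the inner side of all four faces
        for opposite in range(4):
            pts = vertices[[i for i in range(4) if i != opposite]]
            nvec = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            off = nvec @ pts[0]
            if off < 0:
                nvec, off = -nvec, -off
            if nvec @ pt > off + 1e-12:
                return False
        return True

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if inside(mid * d):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def icc_from_sums_of_squares(values: np.ndarray, groups: np.ndarray) -> float:
    """ICC via explicit ANOVA sums of squares and variance components."""
    df = pd.DataFrame({"v": values, "g": groups})
    N = len(df)
    G = df["g"].nunique()
    grand = df["v"].mean()
    counts = df.groupby("g").size()
    means = df.groupby("g")["v"].mean()
    ss_a = float((counts * (means - grand) ** 2).sum())
    ss_w = float(((df["v"] - df["g"].map(means)) ** 2).sum())
    ms_a = ss_a / (G - 1)
    ms_w = ss_w / (N - G)
    k0 = (N - (counts**2).sum() / N) / (G - 1)
    var_among = (ms_a - ms_w) / k0
    return var_among / (var_among + ms_w)
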