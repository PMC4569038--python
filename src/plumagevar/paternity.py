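"""Microsatellite paternity analysis by allele-mismatch exclusion.

An offspring is called extra-pair when its genotype mismatches the
social father at two or more loci. A locus mismatches when none of the
offspring's candidate paternal alleles (offspring alleles not
attributable to the mother, both retained when maternity of an allele is
ambiguous) is carried by the candidate male. One mismatching locus is
tolerated, absorbing mutation and genotyping error.

Exclusion probabilities use the standard first-parent (no known parent)
polynomial in the allele-frequency power sums: with ``a_k = sum_i p_i^k``,

    P1 = 1 - 4 a2 + 4 a3 - 3 a4 + 2 a2^2

per locus, and combined over independent loci as 1 - prod(1 - P1).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "count_mismatches",
    "classify_offspring",
    "assign_extra_pair_sire",
    "exclusion_probabilities",
    "epy_summary",
    "PaternityClassifier",
    "genotype_table_to_dict",
]

# genotype: mapping locus -> (allele1, allele2); missing loci simply absent
Genotype = Mapping[str, tuple[int, int]]


def genotype_table_to_dict(genotypes: pd.DataFrame) -> dict[str, dict[str, tuple[int, int]]]:
    """Convert a long genotype table (individual, locus, allele1, allele2)
    into a nested dict keyed by individual then locus."""
    required = {"individual", "locus", "allele1", "allele2"}
    if not required.issubset(genotypes.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for ind, loc, a1, a2 in genotypes[["individual", "locus", "allele1", "allele2"]].itertuples(index=False):
        out.setdefault(str(ind), {})[str(loc)] = (int(a1), int(a2))
    return out


def _paternal_candidates(off: tuple[int, int], mother: tuple[int, int] | None) -> tuple[int, ...]:
    """Offspring alleles that could have come from the father."""
    if mother is None:
        return tuple(set(off))
    o1, o2 = off
    in_mom = (o1 in mother, o2 in mother)
    if in_mom == (True, False):
        return (o2,)
    if in_mom == (False, True):
        return (o1,)
    # both attributable (ambiguous) or neither (maternal mismatch /
    # mutation): test both alleles, the conservative choice.
    return tuple(set(off))


def count_mismatches(
    offspring: Genotype,
    candidate: Genotype,
    mother: Genotype | None = None,
) -> tuple[int, int]:
    """Count loci at which the candidate male cannot have sired the offspring.

    Returns ``(n_mismatch, n_compared)`` where ``n_compared`` is the number
    of loci typed in both offspring and candidate (others are skipped).
    """
    n_mismatch = 0
    n_compared = 0
    for locus, off in offspring.items():
        cand = candidate.get(locus)
        if cand is None:
            continue
        n_compared += 1
        mom = mother.get(locus) if mother is not None else None
        paternal = _paternal_candidates(tuple(off), tuple(mom) if mom else None)
        if not any(a in cand for a in paternal):
            n_mismatch += 1
    if n_compared == 0:
        raise ValueError("no locus typed in both offspring and candidate")
    return n_mismatch, n_compared


def classify_offspring(
    offspring: Genotype,
    social_father: Genotype,
    mother: Genotype | None = None,
    threshold: int = 2,
    min_typed_loci: int = 4,
) -> dict:
    """Within-pair / extra-pair call against the social father.

    ``extra_pair`` iff the mismatch count is >= ``threshold`` (default 2:
    a single mismatching locus is tolerated).
    """
    n_mismatch, n_compared = count_mismatches(offspring, social_father, mother)
    if n_compared < min_typed_loci:
        raise ValueError(
            f"only {n_compared} loci typed in both; {min_typed_loci} required"
        )
    status = "extra_pair" if n_mismatch >= threshold else "within_pair"
    return {"status": status, "mismatch_count": n_mismatch, "n_loci_compared": n_compared}


def assign_extra_pair_sire(
    offspring: Genotype,
    mother: Genotype | None,
    candidate_males: Mapping[str, Genotype],
) -> str | None:
    """Assign the extra-pair sire when exactly one candidate is compatible.

    A candidate is compatible when it mismatches the offspring at zero
    typed loci. Zero or multiple compatible candidates -> None (unknown);
    ambiguity is deliberately not resolved by likelihood.
    """
    compatible = []
    for male_id, geno in candidate_males.items():
        try:
            n_mismatch, _ = count_mismatches(offspring, geno, mother)
        except ValueError:
            continue
        if n_mismatch == 0:
            compatible.append(male_id)
    return compatible[0] if len(compatible) == 1 else None


def exclusion_probabilities(freqs: Mapping[str, Mapping[int, float]]) -> pd.DataFrame:
    """Per-locus and combined first-parent exclusion probabilities.

    ``freqs`` maps locus -> {allele: frequency}. Returns a DataFrame with
    one row per locus plus a final "combined" row.
    """
    rows = []
    prod_non_excl = 1.0
    for locus, fmap in freqs.items():
        p = np.asarray(list(fmap.values()), dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies at locus {locus} must be nonnegative and sum to 1")
        a2, a3, a4 = (p**2).sum(), (p**3).sum(), (p**4).sum()
        p1 = 1.0 - 4.0 * a2 + 4.0 * a3 - 3.0 * a4 + 2.0 * a2**2
        rows.append({"locus": locus, "P1": p1})
        prod_non_excl *= 1.0 - p1
    if not rows:
        raise ValueError("no loci given")
    rows.append({"locus": "combined", "P1": 1.0 - prod_non_excl})
    return pd.DataFrame(rows)


def epy_summary(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Annual and overall extra-pair young rates plus per-nest EPY proportions.

    ``calls`` needs columns offspring, status, nest, year. Returns
    ``(summary, per_nest)`` where summary has one row per year plus an
    "all" row with columns pct_epy and pct_nests_with_epy, and per_nest
    is the EPY proportion per nest (for histogramming).
    """
    required = {"offspring", "status", "nest", "year"}
    if calls.empty:
        raise ValueError("no paternity calls given")
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    df = calls.copy()
    df["is_ep"] = (df["status"] == "extra_pair").astype(float)

    def _block(sub: pd.DataFrame) -> dict:
        nest_prop = sub.groupby("nest")["is_ep"].mean()
        return {
            "n_offspring": len(sub),
            "n_epy": int(sub["is_ep"].sum()),
            "pct_epy": 100.0 * sub["is_ep"].mean(),
            "pct_nests_with_epy": 100.0 * (nest_prop > 0).mean(),
        }

    rows = []
    for year, sub in df.groupby("year"):
        rows.append({"year": year, **_block(sub)})
    rows.append({"year": "all", **_block(df)})
    per_nest = df.groupby("nest")["is_ep"].mean().rename("epy_proportion")
    return pd.DataFrame(rows), per_nest


class PaternityClassifier(BaseEstimator):
    """Estimator wrapper: fit on a genotype table, predict paternity calls.

    Parameters
    ----------
    threshold : int
        Mismatching loci required to call extra-pair (default 2).
    min_typed_loci : int
        Minimum loci typed in both offspring and social father (default 4).
    assign_sires : bool
        If True, attempt to identify the extra-pair sire among same-site
        males by zero-mismatch compatibility.
    """

    def __init__(self, threshold: int = 2, min_typed_loci: int = 4,
                 assign_sires: bool = True):
        self.threshold = threshold
        self.min_typed_loci = min_typed_loci
        self.assign_sires = assign_sires

    def fit(self, genotypes: pd.DataFrame, y=None):
        """Store the genotype lookup. ``genotypes`` is the long table
        (individual, locus, allele1, allele2)."""
        self.genotypes_ = genotype_table_to_dict(genotypes)
        return self

    def predict(self, social: pd.DataFrame) -> pd.DataFrame:
        """Call every offspring in ``social`` (columns: individual, nest,
        social_mother, social_father, year; optional site) and return the
        calls table (offspring, status, mismatch_count, assigned_sire,
        nest, year)."""
        if not hasattr(self, "genotypes_"):
            raise ValueError("fit must be called before predict")
        has_site = "site" in social.columns
        # candidate pools per site (all social fathers at the site)
        site_males: dict = {}
        if has_site:
            for site, sub in social.groupby("site"):
                site_males[site] = sorted(set(sub["social_father"]))
        all_males = sorted(set(social["social_father"]))
        rows = []
        for rec in social.itertuples(index=False):
            off = self.genotypes_.get(str(rec.individual))
            dad = self.genotypes_.get(str(rec.social_father))
            mom = self.genotypes_.get(str(rec.social_mother))
            if off is None or dad is None:
                raise ValueError(f"missing genotype for {rec.individual} or its social father")
            call = classify_offspring(off, dad, mom, self.threshold, self.min_typed_loci)
            assigned = None
            if call["status"] == "extra_pair" and self.assign_sires:
                pool = site_males.get(rec.site, all_males) if has_site else all_males
                cands = {
                    m: self.genotypes_[str(m)]
                    for m in pool
                    if m != rec.social_father and str(m) in self.genotypes_
                }
                assigned = assign_extra_pair_sire(off, mom, cands)
            rows.append(
                {
                    "offspring": rec.individual,
                    "status": call["status"],
                    "mismatch_count": call["mismatch_count"],
                    "assigned_sire": assigned,
                    "nest": rec.nest,
                    "year": rec.year,
                }
            )
        return pd.DataFrame(rows)
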