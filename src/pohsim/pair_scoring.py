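"""POH and ASp pair scores, and enumeration of eligible breeding pairs.

For a biallelic locus and a parental genotype pair, POH is the probability
that a Mendelian offspring is heterozygous: 1 for opposite homozygotes
(AA x BB), 0 for identical homozygotes, 0.5 whenever at least one parent is
heterozygous.  ASp is 0.25 times the number of alleles the two genotypes
share (a similarity, minimised by the comparator strategy); ASp_(0-1) is ASp
rescaled to [0, 1].  Multi-locus pair scores are plain arithmetic means over
loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import Population

__all__ = [
    "MatingPair",
    "poh_locus",
    "asp_locus",
    "asp_scaled",
    "pair_score",
    "poh_matrix",
    "asp_matrix",
    "enumerate_eligible_pairs",
    "mating_plan",
    "write_mating_plan",
]


@dataclass(frozen=True)
class MatingPair:
    """One male x female mating with an optional score."""

    male_index: int
    female_index: int
    score: float = float("nan")


def _check_genotype(g: int) -> int:
    if g not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    return g


def poh_locus(g1: int, g2: int) -> float:
    """Probability that an offspring of genotypes *g1* x *g2* is heterozygous.

    Symmetric in its arguments.  Equals 0.5*|g1 - g2| except for the
    heterozygote x heterozygote mating, which also yields 0.5.
    """
    g1, g2 = _check_genotype(g1), _check_genotype(g2)
    if g1 == 1 or g2 == 1:
        return 0.5
    return 0.5 * abs(g1 - g2)


def asp_locus(g1: int, g2: int) -> float:
    """Allele-sharing proportion: 0.25 x (number of shared alleles).

    Two genotypes share 2 alleles when identical (AA/AA, BB/BB, AB/AB),
    1 allele for a heterozygote x homozygote mating, and 0 for opposite
    homozygotes.
    """
    g1, g2 = _check_genotype(g1), _check_genotype(g2)
    return 0.25 * (2 - abs(g1 - g2))


def asp_scaled(g1: int, g2: int) -> float:
    """ASp rescaled to the [0, 1] range (divided by its maximum, 0.5)."""
    return asp_locus(g1, g2) / 0.5


def pair_score(parent1: np.ndarray, parent2: np.ndarray, metric: str = "POH") -> float:
    """Mean per-locus score of a parental pair under ``metric`` ("POH" or "ASp")."""
    a = np.atleast_1d(np.asarray(parent1))
    b = np.atleast_1d(np.asarray(parent2))
    if a.shape != b.shape:
        raise ValueError(f"parent genotype vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("parent genotype vectors must have at least one locus")
    if metric == "POH":
        fn = poh_locus
    elif metric == "ASp":
        fn = asp_locus
    else:
        raise ValueError(f"metric must be 'POH' or 'ASp', got {metric!r}")
    return float(np.mean([fn(int(x), int(y)) for x, y in zip(a.ravel(), b.ravel())]))


def poh_matrix(g_males: np.ndarray, g_females: np.ndarray) -> np.ndarray:
    """Mean POH for every male x female pair, vectorised.

    Parameters are (n_males, n_loci) and (n_females, n_loci) dosage matrices;
    the result is (n_males, n_females).
    """
    gm = g_males[:, None, :].astype(np.int8)
    gf = g_females[None, :, :].astype(np.int8)
    diff = np.abs(gm - gf)
    score = 0.5 * diff.astype(np.float64)
    score[(gm == 1) | (gf == 1)] = 0.5
    return score.mean(axis=2)


def asp_matrix(g_males: np.ndarray, g_females: np.ndarray) -> np.ndarray:
    """Mean ASp for every male x female pair, vectorised; shape (n_males, n_females)."""
    diff = np.abs(g_males[:, None, :].astype(np.int8) - g_females[None, :, :].astype(np.int8))
    return (0.25 * (2 - diff).astype(np.float64)).mean(axis=2)


def enumerate_eligible_pairs(pop: Population) -> list[MatingPair]:
    """All male x female pairs excluding littermates (equal litter_id).

    Returns an empty list when no eligible pair exists; candidates carry no
    score.
    """
    males, females = pop.males, pop.females
    if males.size == 0 or females.size == 0:
        raise ValueError("population must contain at least one male and one female")
    pairs = []
    for m in males:
        for f in females:
            if pop.litter_id[m] != pop.litter_id[f]:
                pairs.append(MatingPair(int(m), int(f)))
    return pairs


def mating_plan(pop: Population, sort_by: str = "POH") -> pd.DataFrame:
    """Rank all eligible pairs by POH (descending) or ASp (ascending).

    Returns a DataFrame with columns male_id, female_id, POH, ASp — the
    applied, single-generation use of the method: recommend matings for a
    genotyped cohort.
    """
    if sort_by not in ("POH", "ASp"):
        raise ValueError(f"sort_by must be 'POH' or 'ASp', got {sort_by!r}")
    pairs = enumerate_eligible_pairs(pop)
    g = pop.genotypes
    rows = [
        {
            "male_id": pop.ids[p.male_index],
            "female_id": pop.ids[p.female_index],
            "POH": pair_score(g[p.male_index], g[p.female_index], "POH"),
            "ASp": pair_score(g[p.male_index], g[p.female_index], "ASp"),
        }
        for p in pairs
    ]
    plan = pd.DataFrame(rows, columns=["male_id", "female_id", "POH", "ASp"])
    if len(plan):
        ascending = sort_by == "ASp"
        plan = plan.sort_values(sort_by, ascending=ascending, kind="stable").reset_index(drop=True)
    return plan


def write_mating_plan(plan: pd.DataFrame, path) -> None:
    """Write a mating plan as TSV with 4-decimal scores."""
    plan.to_csv(path, sep="\t", index=False, float_format="%.4f")
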