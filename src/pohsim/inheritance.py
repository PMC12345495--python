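"""Mendelian gamete formation and litter production.

Loci are unlinked by default: a homozygous parent always transmits its
allele, a heterozygous parent transmits either allele with probability 0.5,
independently per locus.  The linked mode carries phased parental haplotypes
with a per-passenger-locus recombination fraction relative to the focal
locus (locus 0), for studying the fate of loci that sit near a selected
marker but do not enter the selection score.  No mutation, no selfing, no
overlapping generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_model import FEMALE, MALE, Population
from .pair_scoring import MatingPair

__all__ = [
    "HaplotypePair",
    "gamete_unlinked",
    "gamete_linked",
    "make_litter",
    "litter_sexes",
    "breed_pairs",
]


@dataclass
class HaplotypePair:
    """Phased parental haplotypes for linked-locus gamete formation.

    hapA/hapB hold one allele (0 or 1, the B-allele indicator) per locus;
    locus 0 is the focal (selected) locus.  ``r[i]`` is the recombination
    probability between the focal locus and passenger locus i+1, each in
    [0, 0.5]; r = 0 is complete linkage, r = 0.5 free recombination.
    """

    hapA: np.ndarray
    hapB: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.hapA = np.asarray(self.hapA, dtype=np.int8)
        self.hapB = np.asarray(self.hapB, dtype=np.int8)
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.hapA.shape != self.hapB.shape:
            raise ValueError("hapA and hapB must have the same length")
        if self.r.shape[0] != self.hapA.shape[0] - 1:
            raise ValueError(
                f"r must have length n_loci - 1 = {self.hapA.shape[0] - 1}, got {self.r.shape[0]}"
            )
        if ((self.r < 0) | (self.r > 0.5)).any():
            raise ValueError("recombination probabilities must lie in [0, 0.5]")


def gamete_unlinked(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete (allele-B indicator per locus) from unlinked genotypes."""
    g = np.asarray(parent, dtype=np.int8).ravel()
    allele = (g == 2).astype(np.int8)
    het = g == 1
    if het.any():
        allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def gamete_linked(parent: HaplotypePair, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete from phased haplotypes with focal-anchored recombination.

    The focal allele comes from hapA or hapB with probability 0.5; passenger
    locus i co-segregates with the focal locus with probability 1 - r[i] and
    recombines onto the other haplotype with probability r[i], independently
    across passengers (no interference).
    """
    n = parent.hapA.shape[0]
    from_b = np.empty(n, dtype=bool)
    from_b[0] = rng.random() < 0.5
    if n > 1:
        recomb = rng.random(n - 1) < parent.r
        from_b[1:] = from_b[0] ^ recomb
    return np.where(from_b, parent.hapB, parent.hapA).astype(np.int8)


def litter_sexes(li: int, litter_index: int = 0) -> list[str]:
    """Deterministic half-male/half-female litter composition.

    For odd litter sizes the extra individual alternates sex across litters
    (by ``litter_index``), keeping the sex ratio balanced at the generation
    level so every breeding-pair setting can be seated.
    """
    if li < 1:
        raise ValueError(f"litter size must be >= 1, got {li}")
    half, extra = divmod(li, 2)
    n_males = half + (extra if litter_index % 2 == 0 else 0)
    return [MALE] * n_males + [FEMALE] * (li - n_males)


def make_litter(
    pair: MatingPair,
    pop: Population,
    li: int,
    rng: np.random.Generator,
    litter_id: int | str = 0,
    litter_index: int = 0,
) -> Population:
    """Produce one litter of *li* offspring from *pair*.

    Each offspring genotype is the per-locus sum of one sire gamete and one
    dam gamete; all offspring share the fresh ``litter_id`` and get sexes
    from :func:`litter_sexes`.
    """
    sire = pop.genotypes[pair.male_index]
    dam = pop.genotypes[pair.female_index]
    kids = np.stack([
        gamete_unlinked(sire, rng) + gamete_unlinked(dam, rng) for _ in range(li)
    ])
    return Population(
        genotypes=kids,
        sex=np.array(litter_sexes(li, litter_index), dtype=object),
        litter_id=np.full(li, litter_id),
        generation_index=pop.generation_index + 1,
    )


def breed_pairs(
    g_sires: np.ndarray,
    g_dams: np.ndarray,
    li: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised litters for many pairs at once.

    ``g_sires``/``g_dams`` are (n_pairs, n_loci) genotype matrices of the
    seated pairs; returns (n_pairs * li, n_loci) offspring dosages, litter by
    litter, each offspring an independent Mendelian draw.
    """
    n_pairs, n_loci = g_sires.shape
    rep_s = np.repeat(g_sires, li, axis=0)
    rep_d = np.repeat(g_dams, li, axis=0)
    shape = (n_pairs * li, n_loci)

    def gametes(g: np.ndarray) -> np.ndarray:
        allele = (g == 2).astype(np.int8)
        het = g == 1
        allele[het] = (rng.random(shape)[het] < 0.5).astype(np.int8)
        return allele

    return gametes(rep_s) + gametes(rep_d)
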