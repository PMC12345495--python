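"""Per-generation heterozygosity statistics and trajectory smoothing.

Two distinct "expected heterozygosity" notions appear in this problem and
are kept as separately named outputs:

* :func:`h_exp` — gene diversity, mean over loci of 2*p_k*q_k computed from
  the generation's allele frequencies; bounded by 0.5 for biallelic loci.
* :func:`mean_pair_poh` — the mean POH of a seated breeding-pair set, i.e.
  the expected observed heterozygosity of the NEXT generation given those
  breeders; it can reach 1.0 (three AA x BB pairs).

Conflating the two makes walkthroughs of single-locus runs inconsistent, so
both are reported side by side in trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import Population, allele_freqs
from .mate_selection import SelectionOutcome

__all__ = [
    "GenerationStats",
    "h_obs",
    "h_exp",
    "mean_pair_poh",
    "ewma_smooth",
    "write_trajectory",
]


@dataclass(frozen=True)
class GenerationStats:
    """Summary of one generation.

    ``mean_pair_poh`` is the mean POH of the breeders that PRODUCED this
    generation (NaN for the base population, which has no recorded parents).
    """

    generation_index: int
    h_obs: float
    h_exp: float
    mean_pair_poh: float = float("nan")


def h_obs(pop: Population) -> float:
    """Observed heterozygosity: fraction of heterozygous genotype calls.

    Defined per locus as (number of heterozygotes) / N, averaged over loci
    and then over individuals; the double averaging reduces exactly to the
    overall fraction of 1-dosage entries in the genotype matrix.
    """
    g = pop.genotypes
    if g.size == 0:
        raise ValueError("population is empty")
    return float((g == 1).mean())


def h_exp(pop: Population) -> float:
    """Expected heterozygosity (gene diversity): mean over loci of 2*p*q.

    p and q are this generation's allele frequencies; the per-individual
    averaging step in the population-level definition is an identity, since
    2*p_k*q_k does not depend on the individual.
    """
    g = pop.genotypes
    if g.size == 0:
        raise ValueError("population is empty")
    p, q = allele_freqs(g)
    return float(np.mean(2.0 * p * q))


def mean_pair_poh(outcome: SelectionOutcome) -> float:
    """Mean POH score of a seated pair set = expected next-generation h_obs."""
    if len(outcome.pairs) == 0:
        raise ValueError("selection outcome contains no pairs")
    return float(np.mean([p.score for p in outcome.pairs]))


def ewma_smooth(series, span: int = 10) -> np.ndarray:
    """Exponentially weighted moving average for display smoothing.

    Element n is the ratio of the (1-alpha)^j-weighted sum of the first n+1
    values to the sum of the weights, with alpha = 2 / (span + 1).  A
    constant series is returned unchanged; span = 1 (alpha = 1) has no
    memory.
    """
    if span < 1:
        raise ValueError(f"span must be >= 1, got {span}")
    s = pd.Series(np.asarray(series, dtype=np.float64))
    if s.empty:
        return np.array([], dtype=np.float64)
    return s.ewm(span=span, adjust=True).mean().to_numpy()


def write_trajectory(df: pd.DataFrame, path) -> None:
    """Write a trajectory table as TSV (columns generation, h_obs, h_exp,
    mean_pair_poh, replicate) at full precision."""
    df.to_csv(path, sep="\t", index=False)
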