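"""Base (founder) populations: synthesis and genotype-table I/O.

The synthetic generator emulates a small genotyped founder cohort scored at
unlinked, highly informative SNPs: 29 males and 41 females at 51 loci by
default, per-locus allele frequencies drawn uniform on (0.4, 0.5] (every
marker close to maximally informative) and genotypes sampled under
Hardy-Weinberg proportions.  Under that spec the expected gene diversity is
E[2p(1-p)] for p ~ U(0.4, 0.5), i.e. about 0.4933.

Frequencies are drawn above the MAF bound but realised sample MAF may fall
below it; synthetic loci are not re-filtered, keeping the locus count fixed.
The MAF filter applies to real-data ingestion.

The genotype-table dialect is delimited text with a header row: columns
``id``, ``sex`` (M/F), optional ``litter``, then one column per locus with
allele-B dosages 0/1/2.  Missing values are rejected (complete calls only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import FEMALE, MALE, Population

__all__ = ["SyntheticBaseSpec", "synthesize_base", "load_population", "write_population"]


@dataclass(frozen=True)
class SyntheticBaseSpec:
    """Shape of a synthetic founder cohort.

    maf_low/maf_high bound the per-locus allele frequency draw, uniform on
    (maf_low, maf_high]; defaults emulate a 70-dog cohort at 51 unlinked
    SNPs with MAF > 0.4.
    """

    n_males: int = 29
    n_females: int = 41
    n_loci: int = 51
    maf_low: float = 0.4
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males + self.n_females < 1:
            raise ValueError("synthetic base must contain at least one individual")
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("sex counts must be non-negative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 <= self.maf_low < self.maf_high <= 0.5):
            raise ValueError(
                f"need 0 <= maf_low < maf_high <= 0.5, got ({self.maf_low}, {self.maf_high})"
            )


def synthesize_base(spec: SyntheticBaseSpec, rng: np.random.Generator | None = None) -> Population:
    """Draw a founder population per *spec*.

    Per locus, the minor-allele frequency is uniform on (maf_low, maf_high];
    genotypes are independent Hardy-Weinberg draws (p^2, 2pq, q^2).  Founders
    get unique litter ids so none are treated as littermates.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_males + spec.n_females
    # uniform on (low, high]: flip the half-open side of random()'s [0, 1)
    maf = spec.maf_high - rng.random(spec.n_loci) * (spec.maf_high - spec.maf_low)
    u = rng.random((n, spec.n_loci))
    # dosage of allele B with freq q = maf: P(0)=p^2, P(1)=2pq, P(2)=q^2
    p = 1.0 - maf
    genotypes = (u >= p * p).astype(np.int8) + (u >= p * p + 2 * p * maf).astype(np.int8)
    sex = np.array([MALE] * spec.n_males + [FEMALE] * spec.n_females, dtype=object)
    litter = np.array([f"founder{i}" for i in range(n)], dtype=object)
    return Population(genotypes=genotypes, sex=sex, litter_id=litter, generation_index=0)


def load_population(path) -> Population:
    """Read a genotype table (see module docstring for the dialect).

    Raises ``ValueError`` on missing genotypes, dosages outside {0, 1, 2},
    or unknown sex labels.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if len(df.columns) < 3 or cols[0] != "id" or cols[1] != "sex":
        raise ValueError(
            "genotype table must start with columns 'id', 'sex'[, 'litter'], then loci"
        )
    has_litter = len(cols) > 2 and cols[2] == "litter"
    first_locus = 3 if has_litter else 2
    if len(df.columns) <= first_locus:
        raise ValueError("genotype table contains no locus columns")
    geno = df.iloc[:, first_locus:]
    if geno.isna().any().any():
        raise ValueError("genotype table contains missing calls (complete calls required)")
    if has_litter:
        litter = df.iloc[:, 2].astype(str).to_numpy(dtype=object)
    else:
        litter = np.array([f"founder{i}" for i in range(len(df))], dtype=object)
    return Population(
        genotypes=geno.to_numpy(),
        sex=df.iloc[:, 1].astype(str).str.upper().to_numpy(dtype=object),
        litter_id=litter,
        generation_index=0,
        ids=df.iloc[:, 0].to_numpy(dtype=object),
    )


def write_population(pop: Population, path) -> None:
    """Write a population in the genotype-table dialect (TSV); round-trips
    through :func:`load_population`."""
    df = pd.DataFrame(pop.genotypes, columns=[f"locus{k}" for k in range(pop.n_loci)])
    df.insert(0, "litter", pop.litter_id)
    df.insert(0, "sex", pop.sex)
    df.insert(0, "id", pop.ids)
    df.to_csv(path, sep="\t", index=False)
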