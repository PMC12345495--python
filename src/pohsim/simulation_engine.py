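"""The generational loop: breed, measure, repeat; replicate and aggregate.

Each cycle seats BP disjoint breeding pairs under the active selection mode,
replaces the population with their BP x Li offspring (generations never
overlap), and records the new generation's observed heterozygosity, gene
diversity and the mean POH of the breeders that produced it.  Trajectories
include generation 0 (the base population, measured before any selection)
and are fully determined by the base population and the condition's seed.

Fixation of every locus is not an error: all pair scores then tie and the
seeded tie-break keeps seating pairs, so heterozygosity simply stays at
zero.  A structural inability to seat BP disjoint pairs truncates the
trajectory and flags it.

A linked mode co-simulates passenger loci on phased haplotypes around the
single selected (focal) locus, with per-passenger recombination fractions,
to follow the fate of loci that never enter the selection score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .base_population import SyntheticBaseSpec, synthesize_base
from .diversity_metrics import GenerationStats, h_exp, h_obs
from .genotype_model import Population, SimulationCondition
from .inheritance import breed_pairs, litter_sexes
from .mate_selection import InfeasibleSelectionError, select_pairs

__all__ = [
    "TrajectoryResult",
    "parse_condition",
    "run_generation",
    "run_simulation",
    "run_replicates",
    "run_linked_simulation",
]

TRAJECTORY_COLUMNS = ["generation", "h_obs", "h_exp", "mean_pair_poh"]


def parse_condition(tag: str, mode: str = "POH", seed: int = 0) -> SimulationCondition:
    """Parse a ``M<int>-BP<int>-Li<int>-Ge<int>`` tag into a condition."""
    return SimulationCondition.from_tag(tag, mode=mode, seed=seed)


@dataclass
class TrajectoryResult:
    """Replicated trajectories plus their per-generation arithmetic mean.

    ``replicates`` is a long DataFrame (columns generation, h_obs, h_exp,
    mean_pair_poh, replicate); ``aggregate`` averages the replicate values at
    each generation.  Smoothing, if any, is applied downstream for display,
    never before aggregation.
    """

    condition: SimulationCondition
    replicates: pd.DataFrame
    aggregate: pd.DataFrame
    n_replicates: int
    truncated_replicates: tuple[int, ...] = ()


def _pair_poh(g_sires: np.ndarray, g_dams: np.ndarray) -> np.ndarray:
    """Per-pair mean POH for aligned sire/dam genotype matrices."""
    s = 0.5 * np.abs(g_sires - g_dams).astype(np.float64)
    s[(g_sires == 1) & (g_dams == 1)] = 0.5
    return s.mean(axis=1)


def run_generation(
    pop: Population,
    cond: SimulationCondition,
    rng: np.random.Generator,
) -> tuple[Population, GenerationStats]:
    """One breeding cycle: select BP pairs, breed BP x Li offspring.

    Returns the new generation and its stats; ``mean_pair_poh`` in the stats
    is the mean POH of the seated breeders regardless of the selection
    metric (it is the expected h_obs of the generation being returned).
    Selection infeasibility propagates.
    """
    outcome = select_pairs(pop, cond.bp, cond.mode, rng)
    sire_idx = np.array([p.male_index for p in outcome.pairs])
    dam_idx = np.array([p.female_index for p in outcome.pairs])
    g_s = pop.genotypes[sire_idx]
    g_d = pop.genotypes[dam_idx]
    kids = breed_pairs(g_s, g_d, cond.li, rng)

    sexes = np.concatenate(
        [np.array(litter_sexes(cond.li, j), dtype=object) for j in range(cond.bp)]
    )
    litters = np.repeat(np.arange(cond.bp) + (pop.generation_index + 1) * 100000, cond.li)
    nxt = Population(
        genotypes=kids,
        sex=sexes,
        litter_id=litters,
        generation_index=pop.generation_index + 1,
    )
    stats = GenerationStats(
        generation_index=nxt.generation_index,
        h_obs=h_obs(nxt),
        h_exp=h_exp(nxt),
        mean_pair_poh=float(_pair_poh(g_s, g_d).mean()),
    )
    return nxt, stats


def run_simulation(
    base: Population,
    cond: SimulationCondition,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Run one replicate for Ge generations from *base*.

    Returns (trajectory, truncated): the trajectory has Ge + 1 rows starting
    at generation 0 (base-population stats, no recorded breeders) unless an
    infeasible selection truncates it, in which case ``truncated`` is True.
    """
    if rng is None:
        rng = np.random.default_rng(cond.seed)
    rows = [
        (0, h_obs(base), h_exp(base), np.nan),
    ]
    pop = base
    truncated = False
    for _ in range(cond.ge):
        try:
            pop, stats = run_generation(pop, cond, rng)
        except InfeasibleSelectionError:
            truncated = True
            break
        rows.append((stats.generation_index, stats.h_obs, stats.h_exp, stats.mean_pair_poh))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS), truncated


def run_replicates(
    base_spec: Population | SyntheticBaseSpec,
    cond: SimulationCondition,
    n_runs: int,
) -> TrajectoryResult:
    """Replicate a condition ``n_runs`` times and average per generation.

    Replicate r runs from seed ``cond.seed + r``.  If *base_spec* is a
    :class:`SyntheticBaseSpec`, each replicate draws a fresh founder cohort
    from its own stream (averaging over cohorts removes founder sampling
    noise); a fixed :class:`Population` is reused across replicates, with
    only the breeding randomness varying.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    frames = []
    truncated = []
    for r in range(n_runs):
        rng = np.random.default_rng(cond.seed + r)
        if isinstance(base_spec, SyntheticBaseSpec):
            base = synthesize_base(replace(base_spec, seed=cond.seed + r), rng=rng)
        else:
            base = base_spec
        traj, trunc = run_simulation(base, replace(cond, seed=cond.seed + r), rng=rng)
        traj = traj.assign(replicate=r)
        frames.append(traj)
        if trunc:
            truncated.append(r)
    long = pd.concat(frames, ignore_index=True)
    agg = (
        long.groupby("generation", as_index=False)[["h_obs", "h_exp", "mean_pair_poh"]]
        .mean()
        .sort_values("generation")
        .reset_index(drop=True)
    )
    return TrajectoryResult(
        condition=cond,
        replicates=long,
        aggregate=agg,
        n_replicates=n_runs,
        truncated_replicates=tuple(truncated),
    )


def run_linked_simulation(
    r: np.ndarray,
    cond: SimulationCondition,
    base_spec: SyntheticBaseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Follow passenger loci linked to a single selected focal locus.

    The focal locus (index 0) is the only locus scored for selection
    (cond.m must be 1); ``r[i]`` is the recombination fraction between the
    focal locus and passenger i+1.  Founders are drawn per *base_spec*
    (focal + passengers all with the base MAF spectrum) and phased by random
    assignment of heterozygote alleles to the two haplotypes.  Gametes pick
    a starting haplotype at the focal locus with probability 0.5; each
    passenger co-segregates with it with probability 1 - r[i].

    Returns a DataFrame with one row per generation (0..Ge) and one
    ``h_obs_locus<k>`` column per locus: per-locus observed heterozygosity.
    """
    r = np.asarray(r, dtype=np.float64)
    if ((r < 0) | (r > 0.5)).any():
        raise ValueError("recombination probabilities must lie in [0, 0.5]")
    if cond.m != 1:
        raise ValueError("linked mode scores the focal locus only; condition must have M = 1")
    n_loci = 1 + r.size
    if base_spec is None:
        base_spec = SyntheticBaseSpec(n_loci=n_loci, seed=cond.seed)
    if base_spec.n_loci != n_loci:
        raise ValueError(f"base_spec.n_loci must be {n_loci} (focal + passengers)")
    if rng is None:
        rng = np.random.default_rng(cond.seed)

    base = synthesize_base(base_spec, rng=rng)
    g = base.genotypes
    # phase founders: homozygotes are forced; heterozygote alleles assigned at random
    hap_a = (g == 2).astype(np.int8)
    hap_b = hap_a.copy()
    het = g == 1
    coin = rng.random(g.shape) < 0.5
    hap_a[het] = coin[het]
    hap_b[het] = ~coin[het]

    sex = base.sex
    litter = base.litter_id
    gen_index = 0

    def het_row() -> np.ndarray:
        return (hap_a != hap_b).mean(axis=0)

    records = [het_row()]
    for gen in range(1, cond.ge + 1):
        focal = (hap_a[:, :1] + hap_b[:, :1]).astype(np.int8)
        pop = Population(genotypes=focal, sex=sex, litter_id=litter,
                         generation_index=gen_index)
        outcome = select_pairs(pop, cond.bp, cond.mode, rng)
        sire = np.array([p.male_index for p in outcome.pairs])
        dam = np.array([p.female_index for p in outcome.pairs])

        n_kids = cond.bp * cond.li
        rep_s = np.repeat(sire, cond.li)
        rep_d = np.repeat(dam, cond.li)

        def gametes(idx: np.ndarray) -> np.ndarray:
            a, b = hap_a[idx], hap_b[idx]
            from_b = np.empty((n_kids, n_loci), dtype=bool)
            from_b[:, 0] = rng.random(n_kids) < 0.5
            if n_loci > 1:
                recomb = rng.random((n_kids, n_loci - 1)) < r
                from_b[:, 1:] = from_b[:, :1] ^ recomb
            return np.where(from_b, b, a).astype(np.int8)

        hap_a, hap_b = gametes(rep_s), gametes(rep_d)
        sex = np.concatenate(
            [np.array(litter_sexes(cond.li, j), dtype=object) for j in range(cond.bp)]
        )
        litter = np.repeat(np.arange(cond.bp) + gen * 100000, cond.li)
        gen_index = gen
        records.append(het_row())

    out = pd.DataFrame(records, columns=[f"h_obs_locus{k}" for k in range(n_loci)])
    out.insert(0, "generation", np.arange(cond.ge + 1))
    return out
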