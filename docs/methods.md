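# Methods

## Model

`pohsim` simulates discrete, non-overlapping generations of a closed diploid
population genotyped at biallelic SNPs, with mate allocation as the only
intervention. The model deliberately excludes everything else: no mutation,
no selfing, no overlapping generations, no phenotypic selection, no
genome-wide linkage map. Genotypes are allele-B dosages in {0, 1, 2}.

**Pair scores.** For parents with dosages (g₁, g₂) at one locus, the
probability of a heterozygous offspring under Mendelian segregation is
POH = 0.5·|g₁ − g₂| except for the double heterozygote, where it is 0.5.
This equals the fraction of the four equiprobable gamete combinations that
yield a heterozygote (the identity the test suite asserts by exhaustive
enumeration). The allele-sharing comparator is ASp = 0.25·(2 − |g₁ − g₂|);
its rescaled form ASp₀₋₁ = 2·ASp satisfies POH = 1 − ASp₀₋₁ for every
mating type except AB × AB. Multi-locus scores are unweighted means over
the scored loci — no LD correction, consistent with the unlinked-marker
assumption.

**Selection.** Each generation, all male × female pairs that are not
littermates (same parental pair, same generation) are enumerated and seated
greedily: shuffle candidates with the replicate's seeded generator, stable-
sort by score (descending for POH, ascending for ASp, no sort for random
mode), and accept in order while both members are unused, until BP pairs
are seated. The shuffle makes tie-breaking uniformly random — essential
because per-locus scores take at most three values, so ties are pervasive
and a deterministic index order would bias lineages. Greedy ranked seating,
not maximum-weight matching, is the implemented policy: it is the plainest
reading of "take the best pairs", and the brute-force matching oracle is
used only in tests at toy sizes. When every locus is fixed, all scores tie
and the tie-break alone seats pairs; heterozygosity then stays at zero
(fixation is a state, not an error). Only a structural inability to seat BP
disjoint pairs (e.g. BP = 1, where the single litter is all littermates)
raises an error / truncates a trajectory, flagged as such. Random mode
keeps both the littermate and monogamy constraints by default
(`exclude_littermates` lifts the former), so mode comparisons isolate the
scoring criterion.

**Inheritance.** Offspring dosage per locus is the sum of two parental
gametes; homozygotes transmit their allele, heterozygotes transmit either
with probability 0.5, independently across loci. Litters have fixed
half/half sex composition (2M/2F at Li = 4; odd sizes alternate the extra
sex across litters) — the sex ratio must be balanced for every BP setting
to remain seatable, and fixed composition removes a nuisance source of
variance. In linked mode each individual carries two phased haplotypes;
a gamete picks a starting haplotype at the focal locus fairly, and each
passenger locus i co-segregates with the focal locus with probability
1 − rᵢ (pairwise recombination to the focal locus, independent across
passengers, no interference, no map function). Founder heterozygotes are
phased by random assignment. Only the focal locus is ever scored.

**Diversity statistics.** H_OBS is the fraction of heterozygous calls in
the genotype matrix (the per-locus/per-individual double average reduces to
exactly this). H_EXP is the mean over loci of 2p_k q_k with p_k estimated
from the current generation — bounded by 0.5 for biallelic loci. A third
series, `mean_pair_poh`, is the mean POH of the seated breeders: the
expected H_OBS of the *next* generation, which can reach 1.0. The latter
two are deliberately distinct named outputs; conflating them makes
single-marker walkthroughs inconsistent (a breeder set of three AA × BB
pairs has expectation 1.0, unreachable by 2pq). `mean_pair_poh` is always
reported in POH units, whatever the selection metric, so trajectories are
comparable across modes.

## Synthetic founder cohort

`SyntheticBaseSpec` defaults emulate a real founding scenario: 29 males and
41 females genotyped at 51 unlinked, highly informative SNPs. Per locus a
minor-allele frequency is drawn uniform on (0.4, 0.5] and genotypes are
independent Hardy–Weinberg draws. Closed form: E[2p(1−p)] for
p ~ U(0.4, 0.5) is 0.49333; the sample-frequency estimate of H_EXP carries
the finite-sample factor (1 − 1/2N) ≈ 0.9929 at N = 70, giving a grand
mean of ≈ 0.4899, while H_OBS averages 0.4933 exactly. Drawn frequencies
respect the MAF bound but realised sample MAF may fall below it; synthetic
loci are not re-filtered (locus count stays fixed; the strict `maf_filter`
applies to ingested real tables). What the generator does **not** emulate:
LD and haplotype structure, family/line structure among founders, and any
real MAF spectrum beyond the uniform band — so passing tests demonstrate
the selection dynamics under idealised founders, not performance on a
specific breed.

## Replication and aggregation

A condition is the tuple (M, BP, Li, Ge) — written `M51-BP10-Li4-Ge50` —
plus mode and seed. Replicate r runs from seed `seed + r`; with a synthetic
base spec each replicate draws its own founder cohort from that stream,
integrating out founder sampling noise (a fixed `Population` can be passed
to hold the cohort constant instead). Trajectories include generation 0,
measured before any selection. Aggregates are plain per-generation
arithmetic means across replicates. EWMA smoothing
(α = 2/(span + 1), history-weighted ratio form; default span 10, a free
display parameter) is applied only to display columns, never before
aggregation. Trajectories are stored at full precision; display rounding is
2–3 decimals.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use the study-scale designs
directly — 50 replicates of 1000 generations at 51 markers for the
long-horizon endpoints (≈ 20 s per design on one CPU thanks to vectorised
scoring and breeding), 20 runs of up to 2000 generations for the
passenger-locus properties, 10 seeded runs for the single-marker
oscillation mechanism, and ≥ 10⁴ offspring per mating type for the χ²
segregation checks (threshold p > 0.01). The example scripts are scaled to
a few seconds (e.g. 10 replicates × 300 generations) and say so.

Tie-breaks, seeds and determinism: every stochastic routine takes a
`numpy.random.Generator`; a condition's trajectory is a pure function of
(base population, seed). Degenerate inputs: monomorphic loci are legal
everywhere (POH/ASp just score 0/0.5); empty populations, dosages outside
{0,1,2}, missing calls, unknown sex labels and malformed condition tags are
rejected with named errors.

## Known limitations

- Greedy seating reports infeasibility with the count its maximal matching
  achieved, which can understate the true maximum matching in contrived
  litter structures.
- The linked mode anchors recombination to the focal locus only; it is not
  a chromosome model and cannot express interference or multi-locus maps.
- Single-generation mating plans (`mating_plan`) rank all eligible pairs
  but do not optimise parental contributions across litters.
- With five or fewer breeding pairs the long-run endpoints carry visible
  founder- and drift-variance; replicate counts below ~50 give noticeably
  noisy aggregates there.
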