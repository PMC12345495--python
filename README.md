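# pohsim

Mate allocation and forward-in-time breeding simulation by **probability of
offspring heterozygosity (POH)** — a conservation-breeding strategy for
small, endangered populations managed with SNP genotypes.

## The problem and the method

Small managed populations (rare dog breeds, zoo populations, livestock gene
banks) lose heterozygosity to drift and inbreeding. Classic genetic
management minimises parental relatedness; POH selection instead scores
each candidate mating by the *offspring* it would produce. For a biallelic
locus with genotypes coded as allele-B dosage (0 = AA, 1 = AB, 2 = BB), the
probability that a Mendelian offspring is heterozygous is

| parents      | POH | ASp | ASp₀₋₁ |
|--------------|-----|------|--------|
| AA × AA, BB × BB | 0   | 0.50 | 1.0 |
| AA × BB      | 1   | 0    | 0   |
| het × hom    | 0.5 | 0.25 | 0.5 |
| AB × AB      | 0.5 | 0.50 | 1.0 |

and a pair's score over L unlinked markers is the mean of its per-locus
POH values. ASp (0.25 × number of shared alleles) is the allele-sharing
comparator, minimised instead of maximised. Each generation the BP
highest-POH male × female pairs are seated greedily — every individual used
at most once, littermates never mated — and each pair leaves a litter of Li
offspring that replaces the parental generation entirely. Diversity is
tracked as observed heterozygosity H_OBS (fraction of heterozygous calls)
and gene diversity H_EXP = mean over loci of 2p_k q_k.

The library also provides a linked mode that co-simulates *passenger* loci
on phased haplotypes around the selected marker, with per-locus
recombination fractions, to show what happens to loci the score never sees.

## Worked example

```python
from pohsim import SyntheticBaseSpec, parse_condition, run_replicates

spec = SyntheticBaseSpec()          # 29 males + 41 females, 51 SNPs, MAF in (0.4, 0.5]
cond = parse_condition("M51-BP10-Li4-Ge300", mode="POH", seed=1)
agg = run_replicates(spec, cond, 10).aggregate
print(agg[["generation", "h_obs", "h_exp"]].tail(1))
```

Running `python examples/long_term_maintenance.py` (the same computation
for POH, ASp and random selection) prints:

```
mode    final H_OBS  final H_EXP  min H_OBS
POH         0.5358       0.4631     0.5295
ASp         0.3987       0.3417     0.3889
random      0.0021       0.0017     0.0010
```

The founder cohort has gene diversity ≈ 0.493. Under POH selection with ten
breeding pairs, observed heterozygosity never drops below ≈ 0.53 — above
the founder level — for as long as the simulation runs, whereas
allele-sharing selection decays steadily and random mating collapses to
fixation. The other scripts in `examples/` demonstrate single-generation
mating plans (`mating_plan.py`), the intrinsic zigzag of single-marker POH
selection (`single_marker_oscillation.py`) and the loss of unscored
passenger loci (`passenger_loci.py`).

A shell interface wraps the same calls:

```
pohsim simulate --cond M51-BP10-Li4-Ge1000 --mode POH --runs 50 --seed 1 --out run/
pohsim plan cohort.tsv --sort-by POH --out plan.tsv
pohsim compare --cond M51-BP5-Li4-Ge1000 --modes POH,ASp --runs 50 --out cmp/
```

Every output directory carries a `manifest.json` from which the run can be
reproduced bit-for-bit.

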