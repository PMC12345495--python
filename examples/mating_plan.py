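"""Rank every eligible mating of a small genotyped cohort.

Builds a six-animal cohort at three SNPs, scores all male x female pairs by
POH (probability the offspring is heterozygous, averaged over loci) and by
ASp (proportion of shared alleles), and prints the ranked plan.  The top
rows are the matings a diversity-focused breeding program would fund first:
POH 1.0 means every offspring is guaranteed heterozygous at every scored
locus, POH 0.5 rows involve at least one heterozygous parent.
"""

import numpy as np

from pohsim import Population, mating_plan

pop = Population(
    genotypes=np.array(
        [
            [0, 0, 2],  # sire Alpha
            [2, 2, 0],  # sire Bravo
            [1, 1, 1],  # sire Charlie
            [2, 2, 0],  # dam Delta
            [0, 0, 2],  # dam Echo
            [1, 0, 2],  # dam Foxtrot
        ]
    ),
    sex=np.array(list("MMMFFF"), dtype=object),
    litter_id=np.arange(6),  # unrelated founders
    ids=np.array(["Alpha", "Bravo", "Charlie", "Delta", "Echo", "Foxtrot"], dtype=object),
)

plan = mating_plan(pop, sort_by="POH")
print(plan.to_string(index=False, float_format="%.4f"))
print()
print("Top pair:", plan.iloc[0]["male_id"], "x", plan.iloc[0]["female_id"],
      "- opposite homozygotes at all three loci, so POH = 1 and ASp = 0.")
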