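"""Seating of disjoint breeding pairs by POH, ASp or at random.

Selection is greedy ranked seating: candidates are shuffled (seeded, so
equal-score pairs are taken in random order rather than in a lineage-biasing
index order), stably sorted by score — descending for POH, ascending for
ASp, no sort for random — and accepted in order while both members are still
unused, until the requested number of pairs is seated.  Each individual
appears in at most one pair per generation (monogamy), and littermates are
never paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_model import Population
from .pair_scoring import MatingPair, asp_matrix, poh_matrix

__all__ = ["SelectionOutcome", "InfeasibleSelectionError", "select_pairs"]


class InfeasibleSelectionError(ValueError):
    """Raised when fewer disjoint eligible pairs exist than were requested."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"cannot seat {requested} disjoint breeding pairs; only {achievable} achievable"
        )


@dataclass(frozen=True)
class SelectionOutcome:
    """The seated breeding pairs and their mean score under the active metric."""

    pairs: tuple[MatingPair, ...]
    mean_pair_score: float


def select_pairs(
    pop: Population,
    bp: int,
    mode: str = "POH",
    rng: np.random.Generator | None = None,
    exclude_littermates: bool = True,
) -> SelectionOutcome:
    """Seat *bp* disjoint breeding pairs from *pop* under ``mode``.

    Parameters
    ----------
    pop
        Current generation; must contain males and females.
    bp
        Number of pairs to seat.
    mode
        ``"POH"`` (maximise), ``"ASp"`` (minimise) or ``"random"``.
    rng
        Seeded generator driving the tie-break shuffle (and random mode).
    exclude_littermates
        Littermate exclusion also applies in random mode by default, so the
        comparison across modes isolates the scoring criterion; set False to
        lift it there.

    Notes
    -----
    In random mode every disjoint seating that respects the constraints has
    nonzero probability.  The reported score is always the pairs' mean score
    under the metric in use (POH for random mode's bookkeeping, see
    :func:`pohsim.simulation_engine.run_generation`).

    Raises
    ------
    InfeasibleSelectionError
        If the greedy scan cannot seat *bp* pairs; carries the achievable
        count.
    """
    if bp < 1:
        raise ValueError(f"bp must be >= 1, got {bp}")
    if mode not in ("POH", "ASp", "random"):
        raise ValueError(f"mode must be POH, ASp or random, got {mode!r}")
    if rng is None:
        rng = np.random.default_rng()

    males, females = pop.males, pop.females
    if males.size == 0 or females.size == 0:
        raise ValueError("population must contain at least one male and one female")

    g = pop.genotypes
    score = poh_matrix(g[males], g[females])
    if mode == "ASp":
        score = asp_matrix(g[males], g[females])

    eligible = np.ones((males.size, females.size), dtype=bool)
    if exclude_littermates:
        eligible = pop.litter_id[males][:, None] != pop.litter_id[females][None, :]

    cand_m, cand_f = np.nonzero(eligible)
    n_cand = cand_m.size
    if n_cand == 0:
        raise InfeasibleSelectionError(bp, 0)

    order = rng.permutation(n_cand)
    if mode == "POH":
        order = order[np.argsort(-score[cand_m[order], cand_f[order]], kind="stable")]
    elif mode == "ASp":
        order = order[np.argsort(score[cand_m[order], cand_f[order]], kind="stable")]

    used_m = np.zeros(males.size, dtype=bool)
    used_f = np.zeros(females.size, dtype=bool)
    chosen: list[MatingPair] = []
    for k in order:
        i, j = cand_m[k], cand_f[k]
        if used_m[i] or used_f[j]:
            continue
        used_m[i] = used_f[j] = True
        chosen.append(MatingPair(int(males[i]), int(females[j]), float(score[i, j])))
        if len(chosen) == bp:
            break
    if len(chosen) < bp:
        raise InfeasibleSelectionError(bp, len(chosen))

    mean_score = float(np.mean([p.score for p in chosen]))
    return SelectionOutcome(pairs=tuple(chosen), mean_pair_score=mean_score)
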