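"""Core genotype containers and allele-frequency utilities.

Genotypes are stored as allele-B dosages: 0 (AA), 1 (AB), 2 (BB) per
individual and biallelic locus.  A :class:`Population` bundles a genotype
matrix with per-individual sex labels and litter identifiers (the parental
pair that produced each individual), which drive the littermate-exclusion
rule during pair selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "validate_genotypes",
    "Population",
    "SimulationCondition",
    "allele_freq",
    "allele_freqs",
    "maf_filter",
]

MALE = "M"
FEMALE = "F"

_CONDITION_RE = re.compile(r"^M(?P<M>\d+)-BP(?P<BP>\d+)-Li(?P<Li>\d+)-Ge(?P<Ge>\d+)$")


def validate_genotypes(values: np.ndarray) -> np.ndarray:
    """Validate and coerce a genotype matrix to int8 dosages in {0, 1, 2}.

    Accepts any array-like of shape (n_individuals, n_loci); 1-D input is
    treated as a single individual.
    """
    arr = np.asarray(values)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(
            f"genotype matrix must be 2-D with at least one individual and one "
            f"locus, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"genotype matrix must be numeric, got dtype {arr.dtype}")
    if np.isnan(arr.astype(float)).any():
        raise ValueError("genotype matrix contains missing values (complete calls required)")
    out = arr.astype(np.int8)
    if (out.astype(float) != arr.astype(float)).any():
        raise ValueError("genotype dosages must be integers")
    if ((out < 0) | (out > 2)).any():
        bad = np.unique(arr[(out < 0) | (out > 2)])
        raise ValueError(f"genotype dosages must be in {{0, 1, 2}}, found {bad.tolist()}")
    return out


@dataclass
class Population:
    """A non-overlapping generation of diploid individuals.

    Parameters
    ----------
    genotypes
        (n_individuals, n_loci) allele-B dosage matrix, entries in {0, 1, 2}.
    sex
        Per-individual label, ``"M"`` or ``"F"``.
    litter_id
        Per-individual identifier of the parental pair that produced it.
        Individuals sharing a litter_id are littermates and may not be mated.
        Founders receive unique ids so no two founders are treated as
        littermates.
    generation_index
        0 for the base population, incremented each breeding cycle.
    ids
        Optional per-individual names (defaults to ``ind0 .. indN-1``).
    """

    genotypes: np.ndarray
    sex: np.ndarray
    litter_id: np.ndarray
    generation_index: int = 0
    ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = validate_genotypes(self.genotypes)
        self.sex = np.asarray(self.sex, dtype=object)
        self.litter_id = np.asarray(self.litter_id)
        n = self.genotypes.shape[0]
        if self.sex.shape[0] != n:
            raise ValueError(f"sex has length {self.sex.shape[0]}, expected {n}")
        if self.litter_id.shape[0] != n:
            raise ValueError(f"litter_id has length {self.litter_id.shape[0]}, expected {n}")
        bad = set(np.unique(self.sex)) - {MALE, FEMALE}
        if bad:
            raise ValueError(f"unknown sex labels {sorted(map(str, bad))}; use 'M'/'F'")
        if self.generation_index < 0:
            raise ValueError("generation_index must be non-negative")
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if self.ids.shape[0] != n:
                raise ValueError(f"ids has length {self.ids.shape[0]}, expected {n}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def males(self) -> np.ndarray:
        """Indices of male individuals."""
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        """Indices of female individuals."""
        return np.flatnonzero(self.sex == FEMALE)


@dataclass(frozen=True)
class SimulationCondition:
    """A parameter condition, conventionally written ``M<m>-BP<bp>-Li<li>-Ge<ge>``.

    M is the number of scored markers, BP the number of breeding pairs
    seated per generation, Li the litter size and Ge the number of simulated
    generations.  ``mode`` picks the selection criterion: ``"POH"`` maximises
    expected offspring heterozygosity, ``"ASp"`` minimises allele sharing,
    ``"random"`` applies no criterion.
    """

    m: int
    bp: int
    li: int
    ge: int
    mode: str = "POH"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m", "bp", "li", "ge"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name.upper()} must be >= 1, got {getattr(self, name)}")
        if self.mode not in ("POH", "ASp", "random"):
            raise ValueError(f"mode must be POH, ASp or random, got {self.mode!r}")

    @property
    def tag(self) -> str:
        return f"M{self.m}-BP{self.bp}-Li{self.li}-Ge{self.ge}"

    @classmethod
    def from_tag(cls, tag: str, mode: str = "POH", seed: int = 0) -> "SimulationCondition":
        """Parse a condition tag such as ``"M51-BP10-Li4-Ge50"``."""
        match = _CONDITION_RE.match(tag.strip())
        if match is None:
            # name the first field that fails to aid CLI error messages
            for name, pat in (("M", r"^M\d+"), ("BP", r"^M\d+-BP\d+"),
                              ("Li", r"^M\d+-BP\d+-Li\d+"),
                              ("Ge", r"^M\d+-BP\d+-Li\d+-Ge\d+$")):
                if not re.match(pat, tag.strip()):
                    raise ValueError(f"malformed condition tag {tag!r}: cannot parse field {name}")
            raise ValueError(f"malformed condition tag {tag!r}")
        return cls(m=int(match["M"]), bp=int(match["BP"]), li=int(match["Li"]),
                   ge=int(match["Ge"]), mode=mode, seed=seed)


def allele_freqs(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus allele frequencies (p, q) for all loci.

    p is the frequency of allele A (dosage-0 allele), q = 1 - p the frequency
    of allele B, estimated by allele counting over all individuals.
    """
    g = validate_genotypes(genotypes)
    q = g.sum(axis=0, dtype=np.float64) / (2.0 * g.shape[0])
    return 1.0 - q, q


def allele_freq(genotypes: np.ndarray, locus: int) -> tuple[float, float]:
    """Allele frequencies (p, q) at one locus; p + q = 1."""
    p, q = allele_freqs(genotypes)
    return float(p[locus]), float(q[locus])


def maf_filter(genotypes: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of loci whose minor-allele frequency strictly exceeds *threshold*.

    The comparison is strict: a locus with MAF exactly equal to the threshold
    is dropped.  With threshold 0 this keeps exactly the polymorphic loci.
    """
    if not 0.0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    p, q = allele_freqs(genotypes)
    maf = np.minimum(p, q)
    return np.flatnonzero(maf > threshold)
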