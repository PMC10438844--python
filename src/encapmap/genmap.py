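"""Genetic maps, backcross cohorts and the Haldane map function.

A backcross between an F1 heterozygote and the susceptible parent produces
progeny that are either heterozygous (``HET``, one resistant allele) or
homozygous for the susceptible allele (``HOM_S``) at every autosomal locus.
Genotypes along a chromosome form a two-state Markov chain whose transition
probability between adjacent loci is the recombination fraction given by the
Haldane map function (no crossover interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# integer genotype codes used in every genotype matrix
HET = 1
HOM_S = 0
MISSING = -1

GENOTYPE_LABELS = {HET: "HET", HOM_S: "HOM_S", MISSING: "NA"}
GENOTYPE_CODES = {"HET": HET, "HOM_S": HOM_S, "NA": MISSING, "": MISSING}


def haldane_recomb(d):
    """Recombination fraction for a map distance ``d`` in centimorgans.

    Uses the Haldane map function ``r = (1 - exp(-2 d / 100)) / 2``, which
    assumes no crossover interference and is exactly consistent with
    generating genotypes as a Markov chain along the chromosome.

    Parameters
    ----------
    d : float or array-like
        Map distance in cM; must be non-negative.

    Returns
    -------
    float or ndarray
        Recombination fraction in ``[0, 0.5)``.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    if np.isscalar(d) or arr.ndim == 0:
        return float(r)
    return r


@dataclass(frozen=True)
class GeneticMap:
    """Ordered molecular markers with cM positions on one chromosome.

    Parameters
    ----------
    chromosome : str
        Chromosome label, e.g. ``"2"`` or ``"2L"``.
    markers : sequence of (str, float)
        ``(name, position_cM)`` pairs; positions must be strictly
        increasing and names unique. At least two markers are required.
    """

    chromosome: str
    markers: tuple = ()

    def __post_init__(self):
        markers = tuple((str(n), float(p)) for n, p in self.markers)
        object.__setattr__(self, "markers", markers)
        if len(markers) < 2:
            raise ValueError("a genetic map needs at least two markers")
        pos = np.array([p for _, p in markers])
        if np.any(pos < 0):
            raise ValueError("marker positions must be non-negative cM")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        names = [n for n, _ in markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @property
    def names(self) -> list:
        return [n for n, _ in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.markers], dtype=float)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def span(self) -> tuple:
        pos = self.positions
        return float(pos[0]), float(pos[-1])

    def contains(self, position: float) -> bool:
        lo, hi = self.span
        return lo <= position <= hi

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def evenly_spaced_map(
    n_markers: int = 12,
    start: float = 3.0,
    end: float = 27.0,
    chromosome: str = "2",
    prefix: str = "m",
) -> GeneticMap:
    """Evenly spaced marker map; the default emulates a 12-marker panel
    spanning 3-27 cM used for fine-mapping within a QTL interval."""
    pos = np.linspace(start, end, n_markers)
    return GeneticMap(chromosome, tuple((f"{prefix}{i + 1}", p) for i, p in enumerate(pos)))


@dataclass
class BackcrossCohort:
    """Genotyped and phenotyped individuals from a backcross.

    Attributes
    ----------
    map : GeneticMap
    genotypes : ndarray, shape (n_individuals, n_markers)
        Integer codes: ``HET=1``, ``HOM_S=0``, ``MISSING=-1``.
    phenotype : ndarray of bool
        True when the individual melanized the parasitoid (resistant).
    survived : ndarray of bool
        True when the individual survived infection to adulthood.
    causal_position : float or None
        True causal locus in cM, known only for simulated cohorts.
    """

    map: GeneticMap
    genotypes: np.ndarray
    phenotype: np.ndarray
    survived: np.ndarray
    causal_position: float | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        self.survived = np.asarray(self.survived, dtype=bool)
        n, m = self.genotypes.shape
        if m != self.map.n_markers:
            raise ValueError("genotype matrix does not match map")
        if self.phenotype.shape != (n,) or self.survived.shape != (n,):
            raise ValueError("phenotype/survived must have one entry per individual")
        bad = ~np.isin(self.genotypes, (HET, HOM_S, MISSING))
        if np.any(bad):
            raise ValueError("genotype codes must be HET/HOM_S/MISSING")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def survivors(self) -> "BackcrossCohort":
        """Subset to individuals that survived infection."""
        keep = self.survived
        return BackcrossCohort(
            self.map,
            self.genotypes[keep],
            self.phenotype[keep],
            self.survived[keep],
            self.causal_position,
        )
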