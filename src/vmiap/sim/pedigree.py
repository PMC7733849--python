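"""Forward breeding simulator: founders, meiosis, crosses, pedigrees.

Chromosome ancestry is tracked as *paintings*: run-length encoded segments
tagged with the founder strain of origin.  Meiosis draws a Poisson number
of crossovers per chromosome (no interference) with breakpoints uniform on
physical length under a linear genetic-to-physical map, which is the
simplest recombination model sufficient for interval-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeSpec, Strain

__all__ = [
    "Painting",
    "Individual",
    "Pedigree",
    "simulate_founder",
    "meiosis",
    "cross",
    "genotype_individual",
    "cast_fraction",
    "breed_reciprocal_f1",
    "breed_backcross",
]


@dataclass(frozen=True)
class Painting:
    """Ancestry of one haplotype of one chromosome.

    Segment ``i`` covers the half-open bp interval ``[ends[i-1], ends[i])``
    (with ``ends[-1]`` equal to the chromosome length) and originates from
    strain ``strains[i]``.
    """

    ends: np.ndarray  # int64, strictly increasing, last == chrom length
    strains: np.ndarray  # int8 strain codes, same length as ends

    def __post_init__(self) -> None:
        if len(self.ends) != len(self.strains) or len(self.ends) == 0:
            raise ValueError("ends and strains must be equal-length and non-empty")
        if np.any(np.diff(self.ends) <= 0):
            raise ValueError("segment ends must be strictly increasing")

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    def ancestry_at(self, pos) -> np.ndarray:
        """Strain code(s) at bp position(s) in [0, length)."""
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= self.length):
            raise ValueError("position outside chromosome")
        idx = np.searchsorted(self.ends, pos, side="right")
        return self.strains[idx]

    def simplify(self) -> "Painting":
        """Merge adjacent segments with identical strain of origin."""
        keep = np.ones(len(self.ends), dtype=bool)
        keep[:-1] = self.strains[:-1] != self.strains[1:]
        return Painting(self.ends[keep], self.strains[keep])

    def strain_length(self, strain_code: int) -> int:
        widths = np.diff(np.concatenate(([0], self.ends)))
        return int(widths[self.strains == strain_code].sum())

    @classmethod
    def uniform(cls, length: int, strain_code: int) -> "Painting":
        return cls(np.array([length], dtype=np.int64), np.array([strain_code], dtype=np.int8))


@dataclass
class Individual:
    """One simulated mouse with painted diploid chromosomes."""

    id: str
    sex: str  # 'F' or 'M'
    generation: str  # F0 / F1 / N1 / N2 / N3 / ...
    dam_id: Optional[str]
    sire_id: Optional[str]
    dam_strain: Optional[str]  # strain label of the mother
    haplotypes: Dict[str, Tuple[Painting, Painting]]
    modifier_alleles: int = 0

    def ancestry_pair(self, chrom: str, pos: int) -> Tuple[int, int]:
        h0, h1 = self.haplotypes[chrom]
        return int(h0.ancestry_at(pos)), int(h1.ancestry_at(pos))


class Pedigree:
    """Ordered collection of individuals with parent links."""

    def __init__(self) -> None:
        self._members: Dict[str, Individual] = {}

    def add(self, ind: Individual) -> Individual:
        if ind.id in self._members:
            raise ValueError(f"duplicate individual id {ind.id!r}")
        self._members[ind.id] = ind
        return ind

    def extend(self, inds: Iterable[Individual]) -> None:
        for ind in inds:
            self.add(ind)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._members[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def by_generation(self, generation: str) -> List[Individual]:
        return [i for i in self if i.generation == generation]

    def offspring_of(self, parent_id: str) -> List[Individual]:
        return [i for i in self if parent_id in (i.dam_id, i.sire_id)]


def _count_modifier_alleles(haplotypes: Dict[str, Tuple[Painting, Painting]], genome: GenomeSpec) -> int:
    chrom, pos = genome.modifier_locus
    carrier = Strain.code(genome.modifier_strain)
    h0, h1 = haplotypes[chrom]
    return int(h0.ancestry_at(pos) == carrier) + int(h1.ancestry_at(pos) == carrier)


def simulate_founder(strain: str, genome: GenomeSpec, ind_id: str = None, sex: str = "F") -> Individual:
    """Inbred founder: both haplotypes painted entirely with one strain."""
    code = Strain.code(strain)  # raises on unknown label
    haps = {
        c.name: (Painting.uniform(c.length_bp, code), Painting.uniform(c.length_bp, code))
        for c in genome.chromosomes
    }
    return Individual(
        id=ind_id or f"{strain}_F0",
        sex=sex,
        generation="F0",
        dam_id=None,
        sire_id=None,
        dam_strain=strain,
        haplotypes=haps,
        modifier_alleles=_count_modifier_alleles(haps, genome),
    )


def _recombine(h0: Painting, h1: Painting, breakpoints: np.ndarray, start_hap: int) -> Painting:
    """Gamete painting alternating between parental haplotypes at breakpoints."""
    length = h0.length
    cuts = np.concatenate(([0], np.sort(breakpoints), [length]))
    parents = (h0, h1)
    ends: List[int] = []
    strains: List[int] = []
    hap = start_hap
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if lo == hi:
            hap ^= 1
            continue
        p = parents[hap]
        i0 = int(np.searchsorted(p.ends, lo, side="right"))
        i1 = int(np.searchsorted(p.ends, hi - 1, side="right"))
        for j in range(i0, i1 + 1):
            ends.append(int(min(p.ends[j], hi)))
            strains.append(int(p.strains[j]))
        hap ^= 1
    return Painting(np.asarray(ends, dtype=np.int64), np.asarray(strains, dtype=np.int8)).simplify()


def meiosis(parent: Individual, genome: GenomeSpec, rng: np.random.Generator) -> Dict[str, Painting]:
    """One gamete: per chromosome, Poisson(genetic length) crossovers,
    breakpoints uniform on physical length, no interference."""
    gamete: Dict[str, Painting] = {}
    for c in genome.chromosomes:
        h0, h1 = parent.haplotypes[c.name]
        n_xo = rng.poisson(c.genetic_length_morgans)
        bps = rng.integers(1, c.length_bp, size=n_xo) if n_xo else np.empty(0, dtype=np.int64)
        start = int(rng.integers(0, 2))
        gamete[c.name] = _recombine(h0, h1, np.asarray(bps, dtype=np.int64), start)
    return gamete


_GEN_AFTER_B6_BACKCROSS = {"F1": "N1", "N1": "N2", "N2": "N3", "N3": "N4"}


def _derive_generation(dam: Individual, sire: Individual) -> str:
    if dam.generation == "F0" and sire.generation == "F0":
        return "F1"
    for a, b in ((dam, sire), (sire, dam)):
        if a.generation == "F0" and b.generation in _GEN_AFTER_B6_BACKCROSS:
            return _GEN_AFTER_B6_BACKCROSS[b.generation]
    return "X"


def cross(
    dam: Individual,
    sire: Individual,
    n_offspring: int,
    genome: GenomeSpec,
    rng: np.random.Generator,
    id_prefix: str = "ind",
) -> List[Individual]:
    """Mate two individuals; each offspring from independent gametes."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    generation = _derive_generation(dam, sire)
    dam_strain = _founder_strain(dam)
    out: List[Individual] = []
    for k in range(n_offspring):
        egg = meiosis(dam, genome, rng)
        sperm = meiosis(sire, genome, rng)
        haps = {chrom: (egg[chrom], sperm[chrom]) for chrom in egg}
        out.append(
            Individual(
                id=f"{id_prefix}_{k}",
                sex="F" if rng.integers(0, 2) == 0 else "M",
                generation=generation,
                dam_id=dam.id,
                sire_id=sire.id,
                dam_strain=dam_strain,
                haplotypes=haps,
                modifier_alleles=_count_modifier_alleles(haps, genome),
            )
        )
    return out


def _founder_strain(ind: Individual) -> str:
    """Strain label recorded for maternal-effect phenotyping.

    For founders this is their own strain; for hybrids/backcrosses the
    label is the strain of the genome-wide majority ancestry, which for
    the designs modelled here (B6 dams throughout the backcross) equals
    the dam's strain of origin.
    """
    lengths: Dict[int, int] = {}
    for h0, h1 in ind.haplotypes.values():
        for p in (h0, h1):
            widths = np.diff(np.concatenate(([0], p.ends)))
            for s, w in zip(p.strains, widths):
                lengths[int(s)] = lengths.get(int(s), 0) + int(w)
    return Strain.name(max(lengths, key=lengths.get))


def genotype_individual(ind: Individual, genome: GenomeSpec) -> Dict[str, np.ndarray]:
    """Marker calls per chromosome: number of modifier-strain alleles (0/1/2).

    Deterministically recoverable from the two paintings; serves as the
    oracle for genotype-matrix construction.
    """
    carrier = Strain.code(genome.modifier_strain)
    calls: Dict[str, np.ndarray] = {}
    for chrom, pos in genome.marker_positions.items():
        h0, h1 = ind.haplotypes[chrom]
        calls[chrom] = (
            (h0.ancestry_at(pos) == carrier).astype(np.int8)
            + (h1.ancestry_at(pos) == carrier).astype(np.int8)
        )
    return calls


def cast_fraction(ind: Individual, genome: GenomeSpec) -> float:
    """Fraction of the diploid genome painted with CAST ancestry."""
    cast = sum(
        h.strain_length(Strain.CAST) for pair in ind.haplotypes.values() for h in pair
    )
    return cast / (2 * genome.total_length_bp())


# ---------------------------------------------------------------------------
# Breeding designs
# ---------------------------------------------------------------------------

def breed_reciprocal_f1(
    genome: GenomeSpec,
    rng: np.random.Generator,
    n_b6: int = 60,
    n_bc: int = 40,
    n_cb: int = 40,
) -> Tuple[Pedigree, Dict[str, List[str]]]:
    """Reciprocal hybrid design: B6 controls, BC (B6 dam x CAST sire) and
    CB (CAST dam x B6 sire) F1 cohorts.  Returns the pedigree and the
    group assignment (B6 / BC / CB -> individual ids)."""
    ped = Pedigree()
    b6_f = ped.add(simulate_founder("B6", genome, "B6_dam", "F"))
    b6_m = ped.add(simulate_founder("B6", genome, "B6_sire", "M"))
    cast_f = ped.add(simulate_founder("CAST", genome, "CAST_dam", "F"))
    cast_m = ped.add(simulate_founder("CAST", genome, "CAST_sire", "M"))
    groups: Dict[str, List[str]] = {"B6": [], "BC": [], "CB": []}
    b6_pop = cross(b6_f, b6_m, n_b6, genome, rng, id_prefix="B6")
    bc = cross(b6_f, cast_m, n_bc, genome, rng, id_prefix="BC")
    cb = cross(cast_f, b6_m, n_cb, genome, rng, id_prefix="CB")
    for pop, name in ((b6_pop, "B6"), (bc, "BC"), (cb, "CB")):
        ped.extend(pop)
        groups[name] = [i.id for i in pop]
    return ped, groups


def breed_backcross(
    genome: GenomeSpec,
    rng: np.random.Generator,
    n_n1: int = 30,
    n_n1_selected: int = 3,
    n_n2_per_family: int = 8,
    n_n3: int = 47,
) -> Pedigree:
    """Serial B6 backcross design used for modifier mapping.

    F1 males (B6 dam x CAST sire) are backcrossed to B6 females to give
    N1; carrier (high) and non-carrier (low) N1 males each found N2
    families; carrier N2 males are backcrossed again to produce ``n_n3``
    N3 individuals.
    """
    ped = Pedigree()
    b6_f = ped.add(simulate_founder("B6", genome, "B6_dam", "F"))
    cast_m = ped.add(simulate_founder("CAST", genome, "CAST_sire", "M"))
    f1 = cross(b6_f, cast_m, 4, genome, rng, id_prefix="F1")
    ped.extend(f1)
    f1_sire = f1[0]  # every F1 is a carrier
    f1_sire.sex = "M"
    n1 = cross(b6_f, f1_sire, n_n1, genome, rng, id_prefix="N1")
    ped.extend(n1)
    carriers = [i for i in n1 if i.modifier_alleles >= 1][:n_n1_selected]
    noncarriers = [i for i in n1 if i.modifier_alleles == 0][:n_n1_selected]
    n2: List[Individual] = []
    for sel in carriers + noncarriers:
        sel.sex = "M"
        fam = cross(b6_f, sel, n_n2_per_family, genome, rng, id_prefix=f"N2_{sel.id}")
        ped.extend(fam)
        n2.extend(fam)
    n2_carriers = [i for i in n2 if i.modifier_alleles >= 1]
    if not n2_carriers:
        raise RuntimeError("no carrier N2 males available for the N3 cross")
    n3: List[Individual] = []
    k = 0
    while len(n3) < n_n3:
        sire = n2_carriers[k % len(n2_carriers)]
        sire.sex = "M"
        fam = cross(b6_f, sire, min(10, n_n3 - len(n3)), genome, rng, id_prefix=f"N3_{sire.id}_{k}")
        ped.extend(fam)
        n3.extend(fam)
        k += 1
    return ped
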