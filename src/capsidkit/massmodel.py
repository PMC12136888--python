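"""Theoretical particle masses and cargo enumeration for AAV capsids.

An AAV capsid is a 60-mer of the three capsid proteins VP1, VP2 and VP3
(commonly near 5:5:50); its total mass is the stoichiometric sum of monomer
masses plus the mass of the encapsidated single-stranded DNA.  Given a
measured overpackaged-particle mass, the cargo mass above the empty capsid
can be decomposed into integer combinations of candidate DNA species
(full-length genome, fragments, oversized genome) by bounded exhaustive
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .constants import SSDNA_DA_PER_BASE

__all__ = [
    "ParticleComposition",
    "CargoSolution",
    "particle_mass",
    "cargo_mass",
    "bases_from_mass",
    "enumerate_cargo_compositions",
]

#: Default single-stranded DNA packaging capacity, nucleotides (wild-type
#: genome ~4.7 kb plus packaging margin).
DEFAULT_CAPACITY_BASES = 5200

#: Default cap on the number of cargo molecules per particle considered in
#: enumeration; packaging of many independent short fragments grades into a
#: continuum of partial particles that mass alone cannot resolve.
DEFAULT_MAX_MOLECULES = 5


@dataclass
class ParticleComposition:
    """VP stoichiometry plus genome content of one particle."""

    vp_counts: tuple          # (n_VP1, n_VP2, n_VP3)
    vp_monomer_masses: tuple  # Da each
    genome_bases: int = 0
    per_base_mass: float = SSDNA_DA_PER_BASE
    allow_vp_loss: bool = False

    def __post_init__(self):
        if len(self.vp_counts) != 3 or len(self.vp_monomer_masses) != 3:
            raise ValueError("need three VP counts and three monomer masses")
        if any(c < 0 for c in self.vp_counts):
            raise ValueError("VP counts must be non-negative")
        if sum(self.vp_counts) != 60 and not self.allow_vp_loss:
            raise ValueError(
                "capsid is a 60-mer; counts must sum to 60 "
                "(set allow_vp_loss=True for VP-loss scenarios)")
        if any(m <= 0 for m in self.vp_monomer_masses) and any(
                m != 0 for m in self.vp_monomer_masses):
            if any(m < 0 for m in self.vp_monomer_masses):
                raise ValueError("monomer masses must be non-negative")


@dataclass
class CargoSolution:
    """One integer cargo composition consistent with a target mass."""

    counts: dict              # label -> copies
    total_mass: float         # Da
    residual: float           # Da, total - target
    total_bases: int = 0

    @property
    def n_molecules(self) -> int:
        return sum(self.counts.values())


def particle_mass(comp: ParticleComposition) -> float:
    """Total particle mass in Da: Σ count·monomer + bases·per-base mass."""
    capsid = sum(n * m for n, m in zip(comp.vp_counts, comp.vp_monomer_masses))
    return capsid + comp.genome_bases * comp.per_base_mass


def cargo_mass(total_particle_mass: float, empty_particle_mass: float) -> float:
    """Cargo mass as measured-particle minus empty-capsid mass (Da)."""
    if total_particle_mass < empty_particle_mass:
        raise ValueError("total particle mass is below the empty-capsid mass")
    return total_particle_mass - empty_particle_mass


def bases_from_mass(mass: float, per_base_mass: float = SSDNA_DA_PER_BASE) -> int:
    """Nucleotide count equivalent to an ssDNA mass, rounded to integer."""
    if per_base_mass <= 0:
        raise ValueError("per-base mass must be positive")
    return int(round(mass / per_base_mass))


def enumerate_cargo_compositions(target_cargo: float, candidates,
                                 tolerance: float,
                                 max_total_bases: int = DEFAULT_CAPACITY_BASES,
                                 per_base_mass: float = SSDNA_DA_PER_BASE,
                                 max_molecules: int = DEFAULT_MAX_MOLECULES
                                 ) -> list[CargoSolution]:
    """Enumerate integer cargo compositions matching a target mass.

    ``candidates`` is a list of ``(label, mass_da)``.  Every non-negative
    integer count vector whose total mass lies within ``tolerance`` of
    ``target_cargo``, whose nucleotide total respects ``max_total_bases``
    and whose molecule count does not exceed ``max_molecules`` is returned,
    sorted by absolute residual then by fewest molecules.

    A zero target with zero tolerance yields only the empty composition;
    no feasible composition yields an empty list.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    labels = [str(c[0]) for c in candidates]
    masses = [float(c[1]) for c in candidates]
    if any(m <= 0 for m in masses):
        raise ValueError("candidate masses must be positive")

    # per-species bound from the mass window, then intersect with the caps
    hi = target_cargo + tolerance
    bounds = [min(int(hi // m), max_molecules) for m in masses]

    solutions = []
    for counts in product(*(range(b + 1) for b in bounds)):
        if sum(counts) > max_molecules:
            continue
        total = sum(n * m for n, m in zip(counts, masses))
        resid = total - target_cargo
        if abs(resid) > tolerance:
            continue
        bases = sum(n * bases_from_mass(m, per_base_mass)
                    for n, m in zip(counts, masses))
        if max_total_bases is not None and bases > max_total_bases:
            continue
        solutions.append(CargoSolution(
            counts={l: n for l, n in zip(labels, counts) if n > 0},
            total_mass=total, residual=resid, total_bases=bases))
    solutions.sort(key=lambda s: (abs(s.residual), s.n_molecules))
    return solutions
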