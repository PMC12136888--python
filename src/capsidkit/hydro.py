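"""Hydrodynamic interpretation of sedimentation-velocity peaks.

The Svedberg relation, s = M(1 − v̄ρ)/(N_A·f), links a species'
sedimentation coefficient s to its molar mass M (g/mol), partial specific
volume v̄ (mL/g), solvent density ρ (g/mL) and translational frictional
coefficient f (g/s).  The frictional ratio f/f0 — f relative to the
anhydrous equivalent sphere of the same mass and v̄ — reports particle
shape: ≈1.2 for compact globular particles, larger for elongated ones.

Peak composition is read from the A260/A230 area ratio: nucleic-acid-rich
species absorb strongly at 260 nm, protein-only capsids at 230 nm.  All
internal arithmetic is CGS; s is taken and returned in svedbergs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (N_AVOGADRO, PBS_DENSITY, PBS_VISCOSITY, SVEDBERG,
                        VBAR_PROTEIN, VBAR_SSDNA)

__all__ = [
    "HydroConditions",
    "SedimentationPeak",
    "sedimentation_coefficient",
    "frictional_coefficient",
    "frictional_ratio",
    "expected_s_after_mass_change",
    "composite_vbar",
    "classify_peak",
    "aggregate_loss",
    "read_peak_table",
    "DEFAULT_REFERENCE_RATIOS",
]

#: Reference A260/A230 ratios for peak classification: purified empty
#: particles measure ≈0.10, full particles ≈0.47.
DEFAULT_REFERENCE_RATIOS = {"EP": 0.10, "FP": 0.47}


@dataclass
class HydroConditions:
    """Solvent conditions. Defaults: PBS at 20 °C."""

    density: float = PBS_DENSITY       # g/mL
    viscosity: float = PBS_VISCOSITY   # poise
    temperature_c: float = 20.0

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class SedimentationPeak:
    s: float          # svedbergs
    area_230: float
    area_260: float
    label: str | None = None

    @property
    def ratio(self) -> float:
        if self.area_230 <= 0:
            raise ValueError("A260/A230 undefined: zero area at 230 nm")
        return self.area_260 / self.area_230


def _buoyancy(vbar: float, density: float) -> float:
    b = 1.0 - vbar * density
    if b <= 0:
        raise ValueError(
            f"non-sedimenting species: buoyancy factor 1 − v̄ρ = {b:.3g} ≤ 0")
    return b


def sedimentation_coefficient(mass: float, vbar: float,
                              cond: HydroConditions = HydroConditions(),
                              f: float = None) -> float:
    """s = M(1 − v̄ρ)/(N_A·f), in svedbergs.  ``f`` in g/s."""
    if f is None or f <= 0:
        raise ValueError("frictional coefficient f must be positive")
    b = _buoyancy(vbar, cond.density)
    s_seconds = mass * b / (N_AVOGADRO * f)
    return s_seconds / SVEDBERG


def frictional_coefficient(mass: float, vbar: float, s: float,
                           cond: HydroConditions = HydroConditions()) -> float:
    """Invert the Svedberg relation for f (g/s) given s in svedbergs."""
    if s <= 0:
        raise ValueError("s must be positive")
    b = _buoyancy(vbar, cond.density)
    return mass * b / (N_AVOGADRO * s * SVEDBERG)


def stokes_f0(mass: float, vbar: float,
              cond: HydroConditions = HydroConditions()) -> float:
    """Frictional coefficient of the anhydrous equivalent sphere,
    f0 = 6πη·R0 with R0 = (3Mv̄ / 4πN_A)^(1/3)."""
    r0 = (3.0 * mass * vbar / (4.0 * np.pi * N_AVOGADRO)) ** (1.0 / 3.0)
    return 6.0 * np.pi * cond.viscosity * r0


def frictional_ratio(mass: float, s: float, vbar: float,
                     cond: HydroConditions = HydroConditions(),
                     warn_unphysical: bool = True) -> float:
    """Frictional ratio f/f0 from mass, s and v̄.

    Values below 1 are hydrodynamically impossible (no particle is more
    compact than its anhydrous sphere) and raise unless ``warn_unphysical``
    is disabled for exploratory use.
    """
    f = frictional_coefficient(mass, vbar, s, cond)
    ratio = f / stokes_f0(mass, vbar, cond)
    if ratio < 1.0 and warn_unphysical:
        raise ValueError(
            f"f/f0 = {ratio:.3f} < 1 is unphysical; check M, s or v̄")
    return ratio


def expected_s_after_mass_change(s_ref: float, mass_ref: float,
                                 mass_new: float) -> float:
    """Predicted s after a mass change at unchanged f and v̄:
    s_new = s_ref · M_new / M_ref."""
    if mass_ref <= 0 or mass_new <= 0:
        raise ValueError("masses must be positive")
    return s_ref * mass_new / mass_ref


def composite_vbar(components) -> float:
    """Mass-weighted mean partial specific volume of a multi-component
    particle, e.g. protein capsid + ssDNA cargo.

    ``components``: iterable of ``(mass_da, vbar_ml_per_g)``.
    """
    components = list(components)
    if not components:
        raise ValueError("need at least one component")
    masses = np.array([c[0] for c in components], dtype=float)
    vbars = np.array([c[1] for c in components], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("component masses must be positive")
    return float(np.sum(masses * vbars) / np.sum(masses))


def capsid_genome_vbar(protein_mass: float, dna_mass: float,
                       vbar_protein: float = VBAR_PROTEIN,
                       vbar_dna: float = VBAR_SSDNA) -> float:
    """Convenience composite v̄ for a protein capsid holding ssDNA."""
    return composite_vbar([(protein_mass, vbar_protein), (dna_mass, vbar_dna)])


def classify_peak(peak: SedimentationPeak,
                  references: dict = None) -> str:
    """Assign a species label by nearest reference A260/A230 ratio.

    Ties break toward the lower reference ratio (the more protein-like,
    hence more conservative, assignment).
    """
    if references is None:
        references = DEFAULT_REFERENCE_RATIOS
    if not references:
        raise ValueError("references must be nonempty")
    ratio = peak.ratio  # raises if area_230 == 0
    # sort by (distance, reference ratio): equidistant → lower reference
    best = min(references.items(), key=lambda kv: (abs(ratio - kv[1]), kv[1]))
    return best[0]


def aggregate_loss(signal_before: float, signal_after: float) -> float:
    """Fraction of signal lost to large aggregates removed by a clearing
    spin: (before − after)/before."""
    if signal_before <= 0:
        raise ValueError("signal_before must be positive")
    return (signal_before - signal_after) / signal_before


def read_peak_table(path_or_buf) -> list[SedimentationPeak]:
    """Read a peak table from delimited text (columns s_S, area_230, area_260)."""
    df = pd.read_csv(path_or_buf, comment="#")
    return [SedimentationPeak(s=row.s_S, area_230=row.area_230,
                              area_260=row.area_260)
            for row in df.itertuples()]
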