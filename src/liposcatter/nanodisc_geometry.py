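"""Derived nanodisc geometry: from fitted disc shape to molecular counts.

Given the fitted shape of an elliptical protein-belted lipid disc
(minor semi-axis, ellipticity, belt width), this module derives the
quantities a structural biologist reads off a nanodisc model: the disc
circumference at the belt mid-line, the number of amino-acid residues
in contact with the bilayer rim (at 1.5 Å helical rise per residue),
the maximum circumference a given protein can wrap, the area per lipid
implied by the chain volume and core thickness, the lipid count per
leaflet, and the number of belt proteins per disc under the double-belt
picture (one belt per leaflet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GeometryReport",
    "eq1_circumference",
    "residues_in_contact",
    "max_belt_circumference",
    "area_per_lipid",
    "lipids_per_leaflet",
    "proteins_per_disc",
    "geometry_report",
]

RISE_PER_RESIDUE = 1.5  # Å per amino acid along an amphipathic helix
APOE_RESIDUES = 299  # mature ApoE chain length


def _round_half_away(x: float) -> int:
    """Round half away from zero (counts never round to even)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def eq1_circumference(r_minor: float, ellipticity: float,
                      d_belt: float) -> float:
    """Disc circumference from the elliptical belt mid-line.

    2π·sqrt(((r_minor + d_belt)² + (r_major + d_belt)²)/2), the
    perimeter of the ellipse approximated through the quadratic mean of
    its belt-offset semi-axes; exact for a circle.
    """
    if r_minor < 0 or d_belt < 0:
        raise ValueError("r_minor and d_belt must be >= 0")
    if ellipticity < 1.0:
        raise ValueError("ellipticity must be >= 1")
    a = r_minor + d_belt
    b = ellipticity * r_minor + d_belt
    return 2.0 * math.pi * math.sqrt((a**2 + b**2) / 2.0)


def residues_in_contact(circumference: float,
                        rise_per_residue: float = RISE_PER_RESIDUE) -> int:
    """Amino acids needed to wrap the circumference once."""
    if circumference <= 0 or rise_per_residue <= 0:
        raise ValueError("inputs must be positive")
    return _round_half_away(circumference / rise_per_residue)


def max_belt_circumference(n_residues: int = APOE_RESIDUES,
                           rise_per_residue: float = RISE_PER_RESIDUE) -> float:
    """Longest rim one fully extended protein belt can cover."""
    if n_residues <= 0 or rise_per_residue <= 0:
        raise ValueError("inputs must be positive")
    return n_residues * rise_per_residue


def area_per_lipid(chain_volume: float, core_thickness: float) -> float:
    """In-plane area per lipid: APL = 2·V_chain / L (per-leaflet prism)."""
    if chain_volume <= 0 or core_thickness <= 0:
        raise ValueError("inputs must be positive")
    return 2.0 * chain_volume / core_thickness


def lipids_per_leaflet(r_minor: float, ellipticity: float,
                       apl: float) -> int:
    """Lipid count in one leaflet: ellipse area / area per lipid."""
    if r_minor <= 0 or apl <= 0:
        raise ValueError("inputs must be positive")
    if ellipticity < 1.0:
        raise ValueError("ellipticity must be >= 1")
    return _round_half_away(math.pi * r_minor * (ellipticity * r_minor) / apl)


def proteins_per_disc(circumference: float, n_residues: int = APOE_RESIDUES,
                      rise_per_residue: float = RISE_PER_RESIDUE,
                      n_belts: int = 2) -> int:
    """Whole proteins needed for ``n_belts`` rim windings.

    Double-belt picture by default (one belt per leaflet).  Uses a
    ceiling: a partially filled belt still requires a whole protein.
    """
    if circumference <= 0 or n_residues <= 0 or n_belts <= 0:
        raise ValueError("inputs must be positive")
    capacity = max_belt_circumference(n_residues, rise_per_residue)
    return math.ceil(n_belts * circumference / capacity)


@dataclass
class GeometryReport:
    """Full derivation chain for one fitted disc."""

    circumference: float
    short_axis_diameter: float
    long_axis_diameter: float
    n_residues_in_contact: int
    max_circumference: float
    area_per_lipid: float
    lipids_per_leaflet: int
    proteins_per_disc: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("short_long_axis_diameter", f"{self.short_axis_diameter:.1f}-"
             f"{self.long_axis_diameter:.1f}", "Å"),
            ("disc_circumference", f"{self.circumference:.0f}", "Å"),
            ("n_amino_acids", str(self.n_residues_in_contact), ""),
            ("max_belt_circumference", f"{self.max_circumference:.0f}", "Å"),
            ("area_per_lipid", f"{self.area_per_lipid:.1f}", "Å²"),
            ("n_lipids_per_leaflet", str(self.lipids_per_leaflet), ""),
            ("n_proteins_per_disc", str(self.proteins_per_disc), ""),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value", "units"])


def geometry_report(r_minor: float, ellipticity: float, d_belt: float,
                    core_thickness: float, chain_volume: float,
                    n_residues: int = APOE_RESIDUES,
                    rise_per_residue: float = RISE_PER_RESIDUE,
                    n_belts: int = 2) -> GeometryReport:
    """Run the whole derivation chain on one fitted disc geometry."""
    circ = eq1_circumference(r_minor, ellipticity, d_belt)
    apl = area_per_lipid(chain_volume, core_thickness)
    return GeometryReport(
        circumference=circ,
        short_axis_diameter=2.0 * (r_minor + d_belt),
        long_axis_diameter=2.0 * (ellipticity * r_minor + d_belt),
        n_residues_in_contact=residues_in_contact(circ, rise_per_residue),
        max_circumference=max_belt_circumference(n_residues, rise_per_residue),
        area_per_lipid=apl,
        lipids_per_leaflet=lipids_per_leaflet(r_minor, ellipticity, apl),
        proteins_per_disc=proteins_per_disc(circ, n_residues,
                                            rise_per_residue, n_belts),
    )
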