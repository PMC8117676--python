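"""Scattering-length densities, molecular volumes and solvent mixing.

All SLDs are in units of 1e-6 Å⁻², volumes in Å³, lengths in Å.  A
material's SLD in a mixed H₂O/D₂O buffer interpolates linearly between
its value in pure H₂O and pure D₂O; for materials without labile
(exchangeable) hydrogens the two endpoints coincide.  Buffer salts are
neglected: the solvent SLD of an x·100 % D₂O buffer is the linear mix of
the pure-water endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

SLD_H2O = -0.56
SLD_D2O = 6.36


@dataclass(frozen=True)
class Material:
    """A scattering component with solvent-dependent contrast.

    Parameters
    ----------
    name:
        Identifier used in configuration files.
    sld_in_h2o, sld_in_d2o:
        Real SLD endpoints in pure H₂O and pure D₂O buffer (1e-6 Å⁻²).
        Unequal endpoints encode labile-hydrogen exchange.
    molecular_volume:
        Volume per molecule (or per relevant fragment), Å³.  ``None``
        when not needed.
    """

    name: str
    sld_in_h2o: float
    sld_in_d2o: float
    molecular_volume: float | None = None

    @property
    def labile_exchange_fraction(self) -> float:
        """Normalised SLD swing relative to the solvent swing."""
        return (self.sld_in_d2o - self.sld_in_h2o) / (SLD_D2O - SLD_H2O)

    def sld(self, d2o_fraction: float) -> float:
        """SLD at the given D₂O volume fraction of the buffer."""
        if not 0.0 <= d2o_fraction <= 1.0:
            raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
        return self.sld_in_h2o + d2o_fraction * (self.sld_in_d2o - self.sld_in_h2o)


def solvent_sld(d2o_fraction: float) -> float:
    """SLD of an H₂O/D₂O buffer at the given D₂O volume fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    return SLD_H2O + d2o_fraction * (SLD_D2O - SLD_H2O)


def match_point(target_sld: float) -> float:
    """D₂O fraction at which the buffer SLD equals ``target_sld``.

    The contrast-match point of a component: at this solvent composition
    the component scatters like the buffer and becomes invisible.
    Raises ``ValueError`` when the target lies outside the water window.
    """
    if not SLD_H2O <= target_sld <= SLD_D2O:
        raise ValueError(
            f"target SLD {target_sld} outside the attainable range "
            f"[{SLD_H2O}, {SLD_D2O}]"
        )
    return (target_sld - SLD_H2O) / (SLD_D2O - SLD_H2O)


def _default_materials() -> dict[str, Material]:
    mats = [
        Material("h2o", SLD_H2O, SLD_H2O),
        Material("d2o", SLD_D2O, SLD_D2O),
        Material("silicon", 2.07, 2.07),
        Material("silica", 3.47, 3.47),
        # Acyl-chain (tail) region materials; chain volume per DMPC 782 Å³
        Material("dDMPC_tails", 6.93, 6.93, 782.0),
        Material("hDMPC_tails", -0.39, -0.39, 782.0),
        # d67-POPC, 95 % tail deuteration
        Material("dPOPC_tails", 6.40, 6.40, 925.0),
        # Phosphatidylcholine headgroup: no labile H
        Material("PC_head", 1.84, 1.84, 319.0),
        Material("h_cholesterol", 0.21, 0.21, 630.0),
        # matchout-deuterated cholesterol: zero contrast in 100 % D₂O
        Material("d_cholesterol", SLD_D2O, SLD_D2O, 630.0),
        # Unlabelled protein with 90 % labile-H exchange folded into the
        # D₂O endpoint; solves to a ~42 % D₂O match point
        Material("protein", 1.86, 3.11),
    ]
    return {m.name: m for m in mats}


@dataclass
class MaterialsTable:
    """Configurable lookup of the scattering materials used by the models."""

    materials: dict[str, Material] = field(default_factory=_default_materials)

    def __getitem__(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; known: {sorted(self.materials)}"
            ) from None

    def add(self, material: Material) -> None:
        self.materials[material.name] = material

    @classmethod
    def from_yaml(cls, path) -> "MaterialsTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = cls(materials={})
        for name, fields in raw.items():
            table.add(
                Material(
                    name=name,
                    sld_in_h2o=float(fields["sld_in_h2o"]),
                    sld_in_d2o=float(fields["sld_in_d2o"]),
                    molecular_volume=(
                        float(fields["molecular_volume"])
                        if fields.get("molecular_volume") is not None
                        else None
                    ),
                )
            )
        return table

    def to_yaml(self, path) -> None:
        raw = {
            m.name: {
                "sld_in_h2o": m.sld_in_h2o,
                "sld_in_d2o": m.sld_in_d2o,
                "molecular_volume": m.molecular_volume,
            }
            for m in self.materials.values()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


DEFAULT_MATERIALS = MaterialsTable()
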