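"""Specular neutron reflectivity of slab models and supported-bilayer stacks.

The reflectivity of a stack of homogeneous layers is computed with the
Abelès optical transfer-matrix formalism, with Gaussian interfacial
roughness applied as Nevot–Croce damping of the interfacial Fresnel
coefficients.  Supported-lipid-bilayer (SLB) stacks follow a symmetric
heads–tails–heads parameterisation on a Si/SiO₂ substrate, optionally
with a thin solvent gap under the membrane and a protein/particle layer
on top.  Solvent penetration of a layer is expressed as a solvent
volume fraction which mixes the layer SLD with the backing (solvent)
SLD by volume.

Units: lengths Å, momentum transfer Å⁻¹, SLD 1e-6 Å⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "Slab",
    "LayerStack",
    "SLBFitModel",
    "ReflectivityCurve",
    "SubstrateParams",
    "build_slb_stack",
    "reflectivity_abeles",
    "critical_edge",
    "smear_gaussian",
    "smear_pointwise",
]

_SLD_SCALE = 1e-6  # table SLDs are in 1e-6 Å⁻²


@dataclass
class Slab:
    """One homogeneous layer.

    ``solvent_fraction`` is the volume fraction of the slab occupied by
    the bulk solvent; the effective SLD used in the optical calculation
    is ``(1 - f)·sld + f·sld_solvent``.  ``roughness_to_previous`` is
    the Gaussian width σ of the interface between this slab and the one
    before it (towards the fronting).
    """

    thickness: float
    sld: float
    isld: float = 0.0
    roughness_to_previous: float = 0.0
    solvent_fraction: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"negative thickness {self.thickness}")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError(f"solvent_fraction {self.solvent_fraction} not in [0, 1]")
        if self.roughness_to_previous < 0:
            raise ValueError(f"negative roughness {self.roughness_to_previous}")


@dataclass
class LayerStack:
    """Semi-infinite fronting | ordered slabs | semi-infinite solvent backing."""

    fronting_sld: float
    slabs: list[Slab]
    backing_sld: float
    backing_roughness: float = 0.0

    def effective_profile(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-medium (SLD, iSLD, thickness, roughness) arrays, solvent-mixed.

        Zero-thickness slabs are dropped so no degenerate interface
        enters the matrix evaluation.  Roughness entries are indexed by
        interface: element ``i`` is the roughness between medium ``i``
        and medium ``i+1``.
        """
        slds = [self.fronting_sld]
        islds = [0.0]
        thick = [0.0]
        rough = []
        for slab in self.slabs:
            if slab.thickness <= 0.0:
                continue
            f = slab.solvent_fraction
            slds.append((1.0 - f) * slab.sld + f * self.backing_sld)
            islds.append((1.0 - f) * slab.isld)
            thick.append(slab.thickness)
            rough.append(slab.roughness_to_previous)
        slds.append(self.backing_sld)
        islds.append(0.0)
        thick.append(0.0)
        rough.append(self.backing_roughness)
        return (
            np.asarray(slds, dtype=float),
            np.asarray(islds, dtype=float),
            np.asarray(thick, dtype=float),
            np.asarray(rough, dtype=float),
        )


@dataclass
class SubstrateParams:
    """Si/SiO₂ substrate description shared by all contrasts of a sample."""

    oxide_thickness: float = 12.0
    oxide_solvation: float = 0.08
    oxide_roughness: float = 3.0
    silicon_sld: float = 2.07
    oxide_sld: float = 3.47


@dataclass
class SLBFitModel:
    """Symmetric heads–tails–heads supported-bilayer parameterisation.

    Both headgroup layers share thickness, coverage and SLD, and a
    single roughness applies to every membrane interface.  Coverage is
    the lipid volume fraction of a layer (1 − solvent fraction).  An
    optional pure-solvent gap sits between the oxide and the membrane,
    and an optional protein/particle layer sits on top of it; either is
    omitted from the stack when its thickness is zero.
    """

    head_thickness: float = 9.0
    tail_thickness: float = 27.2
    head_coverage: float = 0.62
    tail_coverage: float = 0.96
    head_sld_material: float = 1.84
    tail_sld_material: float = 6.93
    roughness_common: float = 3.0
    gap_thickness: float = 0.0
    top_layer_thickness: float = 0.0
    top_layer_material_sld: float = 2.0
    top_layer_coverage: float = 0.0

    def validate(self) -> None:
        for attr in ("head_thickness", "tail_thickness", "gap_thickness",
                     "top_layer_thickness"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0, got {getattr(self, attr)}")
        for attr in ("head_coverage", "tail_coverage", "top_layer_coverage"):
            value = getattr(self, attr)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {value}")
        if self.roughness_common < 0:
            raise ValueError("roughness_common must be >= 0")

    def with_params(self, **updates) -> "SLBFitModel":
        return replace(self, **updates)


@dataclass
class ReflectivityCurve:
    """Reduced 1-D reflectivity: q, R, 1σ uncertainty and resolution fwhm."""

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray
    dq: np.ndarray = None  # fwhm

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.dR = np.asarray(self.dR, dtype=float)
        if self.dq is None:
            self.dq = np.zeros_like(self.q)
        self.dq = np.asarray(self.dq, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")


def build_slb_stack(
    model: SLBFitModel,
    substrate: SubstrateParams,
    solvent_sld: float,
) -> LayerStack:
    """Assemble Si | SiO₂ | [gap] | heads | tails | heads | [top] | solvent.

    Layer SLDs are stored dry; solvent mixing per coverage happens at
    evaluation time through each slab's ``solvent_fraction``.
    """
    model.validate()
    r = model.roughness_common
    slabs = [
        Slab(substrate.oxide_thickness, substrate.oxide_sld,
             roughness_to_previous=substrate.oxide_roughness,
             solvent_fraction=substrate.oxide_solvation, name="oxide"),
    ]
    if model.gap_thickness > 0:
        slabs.append(Slab(model.gap_thickness, solvent_sld,
                          roughness_to_previous=r, solvent_fraction=1.0,
                          name="gap"))
    slabs += [
        Slab(model.head_thickness, model.head_sld_material,
             roughness_to_previous=r,
             solvent_fraction=1.0 - model.head_coverage, name="inner_heads"),
        Slab(model.tail_thickness, model.tail_sld_material,
             roughness_to_previous=r,
             solvent_fraction=1.0 - model.tail_coverage, name="tails"),
        Slab(model.head_thickness, model.head_sld_material,
             roughness_to_previous=r,
             solvent_fraction=1.0 - model.head_coverage, name="outer_heads"),
    ]
    if model.top_layer_thickness > 0:
        slabs.append(Slab(model.top_layer_thickness, model.top_layer_material_sld,
                          roughness_to_previous=r,
                          solvent_fraction=1.0 - model.top_layer_coverage,
                          name="top_layer"))
    return LayerStack(
        fronting_sld=substrate.silicon_sld,
        slabs=slabs,
        backing_sld=solvent_sld,
        backing_roughness=r,
    )


def reflectivity_abeles(stack: LayerStack, q: np.ndarray) -> np.ndarray:
    """Specular reflectivity R(q) by the Abelès transfer-matrix recursion.

    Nevot–Croce roughness: each interfacial Fresnel coefficient r_n is
    damped by exp(−2 k_n k_{n+1} σ_n²).  Valid for q > 0; returns values
    clipped to the physical band [0, 1] only through the formalism
    itself (no explicit clipping).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    slds, islds, thick, rough = stack.effective_profile()
    nmedia = len(slds)
    # wavevector normal component in each medium, relative to fronting
    k0sq = (q / 2.0) ** 2
    rho = (slds - slds[0]) * _SLD_SCALE + 1j * islds * _SLD_SCALE
    # k_n = sqrt(k0² − 4π(ρ_n − ρ_0))
    k = np.sqrt(k0sq[:, None] - 4.0 * np.pi * rho[None, :] + 0j)

    # Abelès 2x2 characteristic matrices accumulated across interfaces
    M00 = np.ones_like(q, dtype=complex)
    M01 = np.zeros_like(q, dtype=complex)
    M10 = np.zeros_like(q, dtype=complex)
    M11 = np.ones_like(q, dtype=complex)
    for n in range(nmedia - 1):
        kn, kn1 = k[:, n], k[:, n + 1]
        rn = (kn - kn1) / (kn + kn1)
        rn = rn * np.exp(-2.0 * kn * kn1 * rough[n] ** 2)
        if n == 0:
            beta = np.zeros_like(q, dtype=complex)
        else:
            beta = 1j * kn * thick[n]
        e_p, e_m = np.exp(beta), np.exp(-beta)
        A00, A01 = e_p, rn * e_p
        A10, A11 = rn * e_m, e_m
        M00, M01, M10, M11 = (
            M00 * A00 + M01 * A10,
            M00 * A01 + M01 * A11,
            M10 * A00 + M11 * A10,
            M10 * A01 + M11 * A11,
        )
    r_amp = M10 / M00
    return np.abs(r_amp) ** 2


def critical_edge(fronting_sld: float, backing_sld: float) -> float:
    """Total-reflection edge q_c = 4·sqrt(π·Δρ); 0 when Δρ ≤ 0."""
    delta = (backing_sld - fronting_sld) * _SLD_SCALE
    if delta <= 0:
        return 0.0
    return 4.0 * np.sqrt(np.pi * delta)


_SMEAR_ORDER = 17
_SMEAR_WIDTH = 3.5  # integration half-width in units of σ
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _gauss_nodes(order: int = _SMEAR_ORDER):
    x, w = leggauss(order)
    t = _SMEAR_WIDTH * x  # node offsets in units of σ
    gw = w * np.exp(-0.5 * t**2)
    gw /= gw.sum()  # renormalise the truncated Gaussian
    return t, gw


def smear_pointwise(
    q: np.ndarray,
    model_fn,
    dq_fwhm: np.ndarray,
    order: int = _SMEAR_ORDER,
) -> np.ndarray:
    """Convolve ``model_fn`` with a Gaussian of per-point fwhm ``dq_fwhm``.

    Fixed-order Gauss–Legendre quadrature over ±3.5σ with Gaussian
    weights, renormalised so a constant function is preserved exactly.
    ``model_fn`` maps a flat q array to model values.
    """
    q = np.asarray(q, dtype=float)
    dq_fwhm = np.broadcast_to(np.asarray(dq_fwhm, dtype=float), q.shape)
    if np.all(dq_fwhm == 0):
        return model_fn(q)
    t, gw = _gauss_nodes(order)
    sigma = dq_fwhm / _FWHM
    q_nodes = q[:, None] + sigma[:, None] * t[None, :]
    q_nodes = np.clip(q_nodes, 1e-6, None)  # reflectivity undefined at q <= 0
    values = model_fn(q_nodes.ravel()).reshape(q_nodes.shape)
    return values @ gw


def smear_gaussian(
    q: np.ndarray,
    model_fn,
    dq_over_q: float,
    order: int = _SMEAR_ORDER,
) -> np.ndarray:
    """Constant-relative-resolution smearing: fwhm dq = (dq/q)·q."""
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    q = np.asarray(q, dtype=float)
    if dq_over_q == 0:
        return model_fn(q)
    return smear_pointwise(q, model_fn, dq_over_q * q, order=order)
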