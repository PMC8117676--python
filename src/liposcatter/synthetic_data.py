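"""Synthetic NR and SANS data with known ground truth.

Emulates the reduced form of the instrument data the pipeline is built
for: time-of-flight reflectometry curves over 0.01–0.3 Å⁻¹ at constant
Δq/q = 7 % in three solvent contrasts, and pinhole SANS curves over
0.002–0.3 Å⁻¹ with a 9 % wavelength spread, both with Gaussian
counting noise of stated relative size.  Every generator is
deterministic given its seed, with independent noise realisations per
contrast, so recovery tests can compare fitted parameters against the
exact truth that produced the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contrast_refinement import ContrastDataset
from .nanodisc_sans import NanodiscModel, SansCurve, SansDataset, disc_intensity
from .slab_reflectivity import (
    ReflectivityCurve,
    SLBFitModel,
    SubstrateParams,
    build_slb_stack,
    reflectivity_abeles,
    smear_pointwise,
)

__all__ = [
    "NR_CONTRASTS",
    "SANS_CONTRASTS",
    "GeneratorRecipe",
    "simulate_reflectivity",
    "simulate_sans",
    "simulate_kinetics",
]

# measurement conditions the generators emulate
NR_Q_RANGE = (0.01, 0.3)
NR_N_POINTS = 120
NR_DQ_OVER_Q = 0.07
NR_REL_NOISE = 0.03
NR_NOISE_FLOOR = 1e-8

SANS_Q_RANGE = (0.002, 0.3)
SANS_N_POINTS = 150
SANS_WAVELENGTH_FWHM = 0.09
SANS_REL_NOISE = 0.02

NR_CONTRASTS = {"h-TBS": 0.0, "cmSi": 0.38, "d-TBS": 1.0}
SANS_CONTRASTS = {"h-TBS": 0.0, "42-dTBS": 0.42, "d-TBS": 1.0}
# flat incoherent background per SANS contrast, cm⁻¹ (H-rich buffers scatter more)
SANS_BACKGROUNDS = {"h-TBS": 0.05, "42-dTBS": 0.03, "d-TBS": 0.005}


@dataclass
class GeneratorRecipe:
    """Ground truth plus instrument conditions for one synthetic dataset."""

    truth: SLBFitModel | NanodiscModel
    contrasts: dict[str, float] = None
    seed: int = 0
    rel_noise: float | None = None
    noise_floor: float = NR_NOISE_FLOOR
    q_range: tuple[float, float] = None
    n_points: int | None = None
    substrate: SubstrateParams = field(default_factory=SubstrateParams)
    smearing: bool = True

    def __post_init__(self) -> None:
        is_nr = isinstance(self.truth, SLBFitModel)
        if self.contrasts is None:
            self.contrasts = dict(NR_CONTRASTS if is_nr else SANS_CONTRASTS)
        if self.rel_noise is None:
            self.rel_noise = NR_REL_NOISE if is_nr else SANS_REL_NOISE
        if self.q_range is None:
            self.q_range = NR_Q_RANGE if is_nr else SANS_Q_RANGE
        if self.n_points is None:
            self.n_points = NR_N_POINTS if is_nr else SANS_N_POINTS
        if self.rel_noise < 0:
            raise ValueError("rel_noise must be >= 0")


def _q_grid(q_range, n_points) -> np.ndarray:
    return np.geomspace(q_range[0], q_range[1], n_points)


def _contrast_rngs(seed: int, labels) -> dict:
    children = np.random.default_rng(seed).spawn(len(labels))
    return dict(zip(labels, children))


def simulate_reflectivity(recipe: GeneratorRecipe) -> list[ContrastDataset]:
    """Generate multi-contrast reflectivity data from an SLB truth model.

    Per contrast: exact slab-model curve, resolution-smeared at
    Δq/q = 7 %, then perturbed by Gaussian noise with
    dR = max(rel_noise·R, floor).  The dq column carries the fwhm.
    """
    if not isinstance(recipe.truth, SLBFitModel):
        raise TypeError("recipe.truth must be an SLBFitModel")
    from .materials import solvent_sld

    q = _q_grid(recipe.q_range, recipe.n_points)
    dq = NR_DQ_OVER_Q * q if recipe.smearing else np.zeros_like(q)
    rngs = _contrast_rngs(recipe.seed, recipe.contrasts)
    datasets = []
    for label, x in recipe.contrasts.items():
        stack = build_slb_stack(recipe.truth, recipe.substrate, solvent_sld(x))
        r_exact = smear_pointwise(q, lambda qq: reflectivity_abeles(stack, qq), dq)
        dr = np.maximum(recipe.rel_noise * r_exact, recipe.noise_floor)
        noise = rngs[label].normal(0.0, 1.0, q.shape) if recipe.rel_noise > 0 \
            else np.zeros_like(q)
        curve = ReflectivityCurve(q=q, R=r_exact + noise * dr, dR=dr, dq=dq)
        datasets.append(ContrastDataset(label, x, curve))
    return datasets


def simulate_sans(recipe: GeneratorRecipe, order: int = 40) -> list[SansDataset]:
    """Generate multi-contrast SANS data from a nanodisc truth model.

    Adds the per-contrast flat incoherent background before applying
    noise, dI = max(rel_noise·I, 1e-4 cm⁻¹).  Wavelength smearing at
    9 % fwhm when ``recipe.smearing`` is set.
    """
    if not isinstance(recipe.truth, NanodiscModel):
        raise TypeError("recipe.truth must be a NanodiscModel")
    q = _q_grid(recipe.q_range, recipe.n_points)
    fwhm = SANS_WAVELENGTH_FWHM if recipe.smearing else 0.0
    rngs = _contrast_rngs(recipe.seed, recipe.contrasts)
    datasets = []
    for label, x in recipe.contrasts.items():
        background = SANS_BACKGROUNDS.get(label, 0.01)
        i_exact = disc_intensity(q, recipe.truth, x, background=background,
                                 order=order, wavelength_fwhm=fwhm)
        di = np.maximum(recipe.rel_noise * np.abs(i_exact), 1e-4)
        noise = rngs[label].normal(0.0, 1.0, q.shape) if recipe.rel_noise > 0 \
            else np.zeros_like(q)
        curve = SansCurve(q=q, I=i_exact + noise * di, dI=di,
                          dq=fwhm * q if fwhm else None)
        datasets.append(SansDataset(label, x, curve, background=background))
    return datasets


def simulate_kinetics(
    trajectory,
    slice_times,
    recipe: GeneratorRecipe,
    d_lipid_tail_sld: float = 6.93,
    h_lipid_tail_sld: float = -0.39,
) -> list[tuple[float, ContrastDataset]]:
    """Timestamped single-contrast (h-TBS) curves during lipid exchange.

    ``trajectory(t)`` gives the hydrogenous (exchanged) volume fraction
    of the tail region at time t; each slice's tail SLD is set to the
    corresponding d/h mixture.  Other structural parameters stay at the
    recipe truth.  Returns (time, dataset) pairs.
    """
    if not isinstance(recipe.truth, SLBFitModel):
        raise TypeError("recipe.truth must be an SLBFitModel")
    slice_times = list(slice_times)
    if any(t1 <= t0 for t0, t1 in zip(slice_times, slice_times[1:])):
        raise ValueError("slice times must be strictly increasing")
    results = []
    for i, t in enumerate(slice_times):
        x_h = float(trajectory(t))
        if not 0.0 <= x_h <= 1.0:
            raise ValueError(f"trajectory value {x_h} at t={t} not in [0, 1]")
        tail_sld = d_lipid_tail_sld + x_h * (h_lipid_tail_sld - d_lipid_tail_sld)
        slice_recipe = GeneratorRecipe(
            truth=recipe.truth.with_params(tail_sld_material=tail_sld),
            contrasts={"h-TBS": 0.0},
            seed=recipe.seed + 10007 * i,
            rel_noise=recipe.rel_noise,
            noise_floor=recipe.noise_floor,
            q_range=recipe.q_range,
            n_points=recipe.n_points,
            substrate=recipe.substrate,
            smearing=recipe.smearing,
        )
        (dataset,) = simulate_reflectivity(slice_recipe)
        results.append((t, dataset))
    return results
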