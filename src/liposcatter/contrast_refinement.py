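"""Simultaneous fitting of one bilayer model to several isotopic contrasts.

Contrast variation measures the same structure in buffers of different
H₂O/D₂O composition; fitting all curves against a single structural
model (with per-dataset scale and background nuisances) breaks the
degeneracies a single contrast cannot resolve.  The global optimiser is
differential evolution (a population-based genetic scheme) followed by
a derivative-free local polish; parameter uncertainties come from
Monte-Carlo resampling of the data within their error bars; nested
models are compared with an F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .materials import solvent_sld
from .slab_reflectivity import (
    ReflectivityCurve,
    SLBFitModel,
    SubstrateParams,
    build_slb_stack,
    reflectivity_abeles,
    smear_pointwise,
)

__all__ = [
    "ContrastDataset",
    "FitResult",
    "joint_chi_square",
    "fit_global",
    "mc_uncertainty",
    "f_test_model_comparison",
    "layer_mma",
    "mma_mismatch",
]

# model parameters that may be freed by name
_MODEL_PARAMS = (
    "head_thickness", "tail_thickness", "head_coverage", "tail_coverage",
    "head_sld_material", "tail_sld_material", "roughness_common",
    "gap_thickness", "top_layer_thickness", "top_layer_material_sld",
    "top_layer_coverage",
)


@dataclass
class ContrastDataset:
    """One reduced reflectivity curve bound to a solvent composition."""

    label: str
    d2o_fraction: float
    curve: ReflectivityCurve
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction must be in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def solvent_sld(self) -> float:
        return solvent_sld(self.d2o_fraction)


@dataclass
class FitResult:
    """Best-fit parameters of a co-refinement and their bookkeeping."""

    parameters: dict[str, float]
    chi_square: float
    degrees_of_freedom: int
    model: SLBFitModel
    datasets: list[ContrastDataset]
    rng_seed: int | None = None
    converged: bool = True
    uncertainties: dict[str, float] = field(default_factory=dict)
    resample_table: np.ndarray | None = None

    @property
    def reduced_chi_square(self) -> float:
        return self.chi_square / self.degrees_of_freedom


def _model_curve(
    model: SLBFitModel,
    dataset: ContrastDataset,
    substrate: SubstrateParams,
) -> np.ndarray:
    stack = build_slb_stack(model, substrate, dataset.solvent_sld)
    curve = dataset.curve

    def evaluate(qflat):
        return reflectivity_abeles(stack, qflat)

    smeared = smear_pointwise(curve.q, evaluate, curve.dq)
    return smeared * dataset.scale + dataset.background


def joint_chi_square(
    model: SLBFitModel,
    datasets: list[ContrastDataset],
    substrate: SubstrateParams | None = None,
) -> float:
    """χ² of one structural model against all contrasts simultaneously.

    χ² = Σ_d Σ_i ((scale·R_model + bkg − R_obs) / dR)², with the model
    curve resolution-smeared per point.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    substrate = substrate or SubstrateParams()
    model.validate()
    total = 0.0
    for ds in datasets:
        if np.any(ds.curve.dR <= 0):
            raise ValueError(f"dataset {ds.label!r} has non-positive dR; "
                             "weights undefined")
        resid = (_model_curve(model, ds, substrate) - ds.curve.R) / ds.curve.dR
        total += float(np.sum(resid**2))
    return total


def layer_mma(thickness_per_leaflet: float, coverage: float,
              molecular_volume: float) -> float:
    """Mean molecular area of one leaflet-region: MMA = V / (t·coverage).

    ``thickness_per_leaflet`` is the thickness occupied by one molecule
    along the normal — the headgroup-layer thickness for heads, half the
    tail-layer thickness for tails.
    """
    if thickness_per_leaflet <= 0:
        raise ValueError("thickness must be > 0")
    if coverage <= 0:
        raise ValueError("coverage must be > 0 (MMA undefined for empty layer)")
    return molecular_volume / (thickness_per_leaflet * coverage)


def mma_mismatch(model: SLBFitModel, head_volume: float,
                 tail_volume: float) -> float:
    """Relative head/tail MMA discrepancy |MMA_h − MMA_t| / MMA_t."""
    mma_head = layer_mma(model.head_thickness, model.head_coverage, head_volume)
    mma_tail = layer_mma(model.tail_thickness / 2.0, model.tail_coverage,
                         tail_volume)
    return abs(mma_head - mma_tail) / mma_tail


def _split_free_set(free_parameter_set, datasets):
    model_names, nuisance = [], []
    labels = {ds.label for ds in datasets}
    for name in free_parameter_set:
        if name in _MODEL_PARAMS:
            model_names.append(name)
        elif ":" in name:
            kind, label = name.split(":", 1)
            if kind not in ("scale", "background") or label not in labels:
                raise ValueError(f"unknown free parameter {name!r}")
            nuisance.append((kind, label))
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    return model_names, nuisance


def _apply_theta(theta, model_template, datasets, model_names, nuisance):
    updates = dict(zip(model_names, theta[: len(model_names)]))
    model = model_template.with_params(**updates)
    ds_out = []
    k = len(model_names)
    overrides = {pair: theta[k + i] for i, pair in enumerate(nuisance)}
    for ds in datasets:
        scale = overrides.get(("scale", ds.label), ds.scale)
        background = overrides.get(("background", ds.label), ds.background)
        ds_out.append(ContrastDataset(ds.label, ds.d2o_fraction, ds.curve,
                                      scale=scale, background=background))
    return model, ds_out


def fit_global(
    datasets: list[ContrastDataset],
    model_template: SLBFitModel,
    free_parameter_set: list[str],
    bounds: dict[str, tuple[float, float]],
    seed: int,
    substrate: SubstrateParams | None = None,
    mma_volumes: tuple[float, float] | None = None,
    mma_tolerance: float = 0.05,
    mma_weight: float = 1e3,
    maxiter: int = 200,
    popsize: int = 15,
    tol: float = 1e-8,
) -> FitResult:
    """Global co-refinement: seeded differential evolution + local polish.

    ``free_parameter_set`` names model attributes and per-dataset
    nuisances (``"scale:<label>"``, ``"background:<label>"``); every
    free parameter needs finite ``bounds``.  With ``mma_volumes =
    (head_volume, tail_volume)`` a soft penalty is added when the head
    and tail mean molecular areas disagree by more than
    ``mma_tolerance``.  Deterministic given ``seed``.  An empty free set
    returns the template and its χ² unchanged.
    """
    substrate = substrate or SubstrateParams()
    n_points = sum(len(ds.curve.q) for ds in datasets)

    def penalty(model: SLBFitModel) -> float:
        if mma_volumes is None:
            return 0.0
        excess = mma_mismatch(model, *mma_volumes) - mma_tolerance
        return mma_weight * excess**2 if excess > 0 else 0.0

    if not free_parameter_set:
        chi2 = joint_chi_square(model_template, datasets, substrate)
        return FitResult(parameters={}, chi_square=chi2,
                         degrees_of_freedom=n_points, model=model_template,
                         datasets=list(datasets), rng_seed=seed)

    model_names, nuisance = _split_free_set(free_parameter_set, datasets)
    names = model_names + [f"{k}:{lbl}" for k, lbl in nuisance]
    try:
        bnds = [tuple(map(float, bounds[name])) for name in names]
    except KeyError as err:
        raise ValueError(f"missing bounds for free parameter {err}") from None
    if not all(np.isfinite(b) for pair in bnds for b in pair):
        raise ValueError("all bounds must be finite")

    def objective(theta):
        model, ds = _apply_theta(theta, model_template, datasets,
                                 model_names, nuisance)
        try:
            return joint_chi_square(model, ds, substrate) + penalty(model)
        except ValueError:
            return 1e30

    de = optimize.differential_evolution(
        objective, bnds, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=tol, polish=False, init="latinhypercube", updating="deferred",
    )
    # derivative-free polish within the same bounds
    polish = optimize.minimize(
        objective, de.x, method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1500},
    )
    theta = polish.x if polish.fun <= de.fun else de.x
    theta = np.clip(theta, [b[0] for b in bnds], [b[1] for b in bnds])
    chi2 = objective(theta)
    model, ds = _apply_theta(theta, model_template, datasets,
                             model_names, nuisance)
    dof = n_points - len(names)
    if dof <= 0:
        raise ValueError("model has as many parameters as data points")
    return FitResult(
        parameters=dict(zip(names, map(float, theta))),
        chi_square=float(chi2),
        degrees_of_freedom=dof,
        model=model,
        datasets=ds,
        rng_seed=seed,
        converged=bool(de.success or polish.success),
    )


def mc_uncertainty(
    fit: FitResult,
    datasets: list[ContrastDataset],
    n_resamples: int,
    seed: int,
    substrate: SubstrateParams | None = None,
    mma_volumes: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Monte-Carlo parameter uncertainties by data resampling.

    Each resample perturbs every reflectivity point by Gaussian(0, dR)
    and re-polishes the fit starting from the best-fit parameters; the
    reported σ is the standard deviation of each parameter over the
    resamples.  Results are stored on ``fit`` and returned.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if not fit.parameters:
        fit.uncertainties = {}
        return {}
    if all(np.all(ds.curve.dR == 0) for ds in datasets):
        # nothing to resample: every refit reproduces the best fit exactly
        fit.uncertainties = {name: 0.0 for name in fit.parameters}
        fit.resample_table = np.tile(
            [list(fit.parameters.values())], (n_resamples, 1))
        return fit.uncertainties
    substrate = substrate or SubstrateParams()
    rng = np.random.default_rng(seed)
    names = list(fit.parameters)
    model_names = [n for n in names if n in _MODEL_PARAMS]
    nuisance = [tuple(n.split(":", 1)) for n in names if ":" in n]
    theta0 = np.array([fit.parameters[n] for n in names])

    rows = []
    for _ in range(n_resamples):
        perturbed = []
        for ds in datasets:
            curve = ds.curve
            noisy = ReflectivityCurve(
                q=curve.q,
                R=curve.R + rng.normal(0.0, 1.0, curve.R.shape) * curve.dR,
                dR=curve.dR,
                dq=curve.dq,
            )
            perturbed.append(ContrastDataset(ds.label, ds.d2o_fraction, noisy,
                                             ds.scale, ds.background))

        def objective(theta):
            model, ds_t = _apply_theta(theta, fit.model, perturbed,
                                       model_names, nuisance)
            try:
                chi2 = joint_chi_square(model, ds_t, substrate)
            except ValueError:
                return 1e30
            if mma_volumes is not None:
                excess = mma_mismatch(model, *mma_volumes) - 0.05
                if excess > 0:
                    chi2 += 1e3 * excess**2
            return chi2

        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-7,
                                         "maxiter": 800})
        rows.append(res.x)

    table = np.array(rows)
    sigma = {name: float(np.std(table[:, i], ddof=1))
             for i, name in enumerate(names)}
    fit.uncertainties = sigma
    fit.resample_table = table
    return sigma


def f_test_model_comparison(fit_restricted: FitResult,
                            fit_full: FitResult) -> float:
    """Upper-tail F-test p-value for nested model comparison.

    F = ((χ²_r − χ²_f)/(dof_r − dof_f)) / (χ²_f/dof_f), assuming
    normally distributed residuals.  A fit that does not improve
    (χ²_r ≤ χ²_f) yields p = 1.
    """
    chi_r, chi_f = fit_restricted.chi_square, fit_full.chi_square
    dof_r, dof_f = fit_restricted.degrees_of_freedom, fit_full.degrees_of_freedom
    if dof_r <= dof_f:
        raise ValueError("restricted model must have more degrees of freedom "
                         "than the full model (models must be nested)")
    if chi_f <= 0:
        raise ValueError("full-model chi-square must be positive")
    f_stat = max((chi_r - chi_f) / (dof_r - dof_f), 0.0) / (chi_f / dof_f)
    return float(stats.f.sf(f_stat, dof_r - dof_f, dof_f))


def significance_stars(p_value: float) -> str:
    """Report convention: * for p < 0.1, ** for p < 0.05."""
    if p_value < 0.05:
        return "**"
    if p_value < 0.1:
        return "*"
    return ""
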