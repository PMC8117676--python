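"""Decomposition of fitted bilayer parameters into compositional quantities.

Contrast variation on a tail-deuterated membrane lets three effects be
separated after incubation with protein or lipoprotein particles:

* **lipid removal** — net loss of membrane material, read from the
  increase in solvent fraction of the bilayer;
* **lipid exchange** — replacement of deuterated membrane lipids by
  hydrogenous particle lipids, read from the drop of the dry (solvent-
  corrected) SLD of the tail region;
* **protein insertion** — for lipid-free protein incubations, the same
  SLD drop read against the protein SLD instead.

SLDs mix by volume, so all fractions reported here are volume
fractions; a mole-fraction helper using molecular volumes is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CompositionReport",
    "lipid_removal_percent",
    "exchange_percent",
    "protein_core_fraction",
    "colocalisation_percent",
    "kinetics_series",
    "fit_exponential_approach",
    "cholesterol_specificity",
    "volume_to_mole_fraction",
]

_ENDPOINT_TOLERANCE = 0.02  # fractional over/under-shoot allowed outside [ρ_h, ρ_d]


@dataclass
class CompositionReport:
    """Headline quantities of one before/after incubation comparison."""

    lipid_removal_percent: float = float("nan")
    lipid_exchange_percent: float = float("nan")
    protein_core_volume_fraction: float = float("nan")
    protein_top_volume_fraction: float = float("nan")
    colocalisation_percent: float = float("nan")
    sigma: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        sigma = self.sigma or {}
        rows = [
            ("lipid_removal", self.lipid_removal_percent, "%"),
            ("lipid_exchange", self.lipid_exchange_percent, "%"),
            ("protein_core_volume_fraction",
             self.protein_core_volume_fraction, "1"),
            ("protein_top_volume_fraction",
             self.protein_top_volume_fraction, "1"),
            ("colocalisation", self.colocalisation_percent, "%"),
        ]
        return pd.DataFrame(
            [(q, v, sigma.get(q, float("nan")), u) for q, v, u in rows],
            columns=["quantity", "value", "sigma", "units"],
        )


def lipid_removal_percent(coverage_before: float, coverage_after: float) -> float:
    """Net lipid removal: 100·(coverage_before − coverage_after).

    Signed — a negative value means net deposition of material.
    """
    for c in (coverage_before, coverage_after):
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"coverage {c} not in [0, 1]")
    return 100.0 * (coverage_before - coverage_after)


def _check_in_interval(observed: float, lo: float, hi: float) -> float:
    span = hi - lo
    slack = _ENDPOINT_TOLERANCE * span
    if observed < lo - slack or observed > hi + slack:
        raise ValueError(
            f"fitted dry SLD {observed:.3f} lies outside the two-component "
            f"interval [{lo:.3f}, {hi:.3f}] beyond tolerance — the "
            "two-component decomposition does not describe these data"
        )
    return float(np.clip(observed, lo, hi))


def exchange_percent(fitted_dry_tail_sld: float, d_lipid_tail_sld: float,
                     h_lipid_tail_sld: float) -> float:
    """Volume percentage of deuterated tails replaced by hydrogenous ones.

    100·(ρ_d − ρ_obs)/(ρ_d − ρ_h); ``fitted_dry_tail_sld`` must already
    be solvent-corrected (the fitted material SLD, not the wet slab SLD).
    """
    if d_lipid_tail_sld == h_lipid_tail_sld:
        raise ValueError("d- and h-lipid SLDs must differ")
    lo, hi = sorted((h_lipid_tail_sld, d_lipid_tail_sld))
    obs = _check_in_interval(fitted_dry_tail_sld, lo, hi)
    return 100.0 * (d_lipid_tail_sld - obs) / (d_lipid_tail_sld - h_lipid_tail_sld)


def protein_core_fraction(fitted_dry_tail_sld: float, d_lipid_tail_sld: float,
                          protein_sld_in_contrast: float) -> float:
    """Protein volume fraction of the hydrophobic core.

    For a lipid-free protein incubation the dry core is a d-lipid +
    protein mixture: φ_prot = (ρ_d − ρ_obs)/(ρ_d − ρ_prot).
    """
    if protein_sld_in_contrast == d_lipid_tail_sld:
        raise ValueError("protein and d-lipid SLDs must differ")
    lo, hi = sorted((protein_sld_in_contrast, d_lipid_tail_sld))
    obs = _check_in_interval(fitted_dry_tail_sld, lo, hi)
    return (d_lipid_tail_sld - obs) / (d_lipid_tail_sld - protein_sld_in_contrast)


def colocalisation_percent(phi_core: float, core_thickness: float,
                           phi_top: float, top_thickness: float) -> float:
    """Share of bound protein residing inside the membrane core.

    Equal-area slabs: 100·φ_core·t_core / (φ_core·t_core + φ_top·t_top).
    """
    for phi in (phi_core, phi_top):
        if not 0.0 <= phi <= 1.0:
            raise ValueError(f"volume fraction {phi} not in [0, 1]")
    if core_thickness <= 0 or top_thickness <= 0:
        raise ValueError("thicknesses must be positive")
    core_amount = phi_core * core_thickness
    top_amount = phi_top * top_thickness
    if core_amount + top_amount == 0:
        raise ValueError("no protein in either region; co-localisation undefined")
    return 100.0 * core_amount / (core_amount + top_amount)


def kinetics_series(time_slices: list[dict], d_lipid_tail_sld: float,
                    h_lipid_tail_sld: float) -> pd.DataFrame:
    """Time-resolved lipid-replacement metrics from single-contrast fits.

    Each slice is a mapping with keys ``time`` (h), ``tail_solvent_fraction``
    and ``dry_tail_sld`` — the output of fitting one h-TBS curve with
    structure frozen at the pre-incubation values.  Per slice, relative
    to the first (t = 0) slice, the returned table reports:

    * ``delta_solvent`` — change in tail solvent fraction (lipid removal);
    * ``exchanged_fraction`` — hydrogenous fraction of the remaining
      lipid from the dry-tail SLD;
    * ``replaced_lipid_fraction`` — combined metric
      1 − [φ_lip(t)·x_d(t)] / [φ_lip(0)·x_d(0)], the fraction of the
      original deuterated lipid no longer present, whether removed or
      exchanged.
    """
    if not time_slices:
        raise ValueError("need at least one time slice")
    times = [s["time"] for s in time_slices]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("timestamps must be strictly increasing")

    def deuterated_fraction(slice_):
        x_h = exchange_percent(slice_["dry_tail_sld"], d_lipid_tail_sld,
                               h_lipid_tail_sld) / 100.0
        return 1.0 - x_h

    phi0 = 1.0 - time_slices[0]["tail_solvent_fraction"]
    xd0 = deuterated_fraction(time_slices[0])
    if phi0 * xd0 <= 0:
        raise ValueError("t=0 slice has no deuterated lipid")

    rows = []
    for s in time_slices:
        phi = 1.0 - s["tail_solvent_fraction"]
        xd = deuterated_fraction(s)
        rows.append({
            "time": s["time"],
            "delta_solvent": s["tail_solvent_fraction"]
            - time_slices[0]["tail_solvent_fraction"],
            "exchanged_fraction": 1.0 - xd,
            "replaced_lipid_fraction": 1.0 - (phi * xd) / (phi0 * xd0),
        })
    return pd.DataFrame(rows)


def fit_exponential_approach(times: np.ndarray, values: np.ndarray,
                             ) -> tuple[float, float]:
    """Fit A·(1 − exp(−t/τ)) and return (plateau A, time constant τ)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)

    def model(t, plateau, tau):
        return plateau * (1.0 - np.exp(-t / tau))

    p0 = (max(values.max(), 1e-3), max(times.max() / 3.0, 1e-3))
    popt, _ = optimize.curve_fit(model, times, values, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def cholesterol_specificity(exchange_h_chol: tuple[float, float],
                            exchange_d_chol: tuple[float, float],
                            n_sigma: float = 2.0) -> dict:
    """Compare lipid exchange against h- vs d-cholesterol membranes.

    Preferential cholesterol uptake would show as a net exchange
    difference between otherwise matched membranes.  Returns the signed
    difference, its propagated σ, and a significance verdict at
    ``n_sigma``.
    """
    (a, sa), (b, sb) = exchange_h_chol, exchange_d_chol
    diff = a - b
    sigma = math.hypot(sa, sb)
    significant = abs(diff) > n_sigma * sigma
    return {
        "difference_percent": diff,
        "sigma": sigma,
        "significant": significant,
        "verdict": ("preferential cholesterol exchange detected" if significant
                    else "no preferential cholesterol exchange"),
    }


def volume_to_mole_fraction(volume_fraction: float, volume_a: float,
                            volume_b: float) -> float:
    """Convert a volume fraction of component A to a mole fraction.

    x_A = (φ_A/V_A) / (φ_A/V_A + (1−φ_A)/V_B).
    """
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError("volume fraction must be in [0, 1]")
    na = volume_fraction / volume_a
    nb = (1.0 - volume_fraction) / volume_b
    return na / (na + nb)
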