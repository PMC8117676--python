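"""Independent reference implementations used only to check the package.

These deliberately re-derive each quantity by a different route than
the implementation: Parratt's recursion instead of the Abelès matrix,
the closed-form Fresnel formula, dense trapezoidal convolution instead
of Gaussian quadrature, the circular core-shell bicelle amplitude, and
a brute-force voxel Fourier sum for the disc intensity.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def parratt_reflectivity(slds, islds, thicknesses, roughnesses, q):
    """Specular reflectivity by Parratt's bottom-up recursion.

    ``slds``/``islds`` in 1e-6 Å⁻² per medium (fronting first),
    ``thicknesses`` per medium (semi-infinite media 0), ``roughnesses``
    per interface (len = nmedia - 1), Nevot-Croce damping.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slds = np.asarray(slds, dtype=float)
    n = len(slds)
    k0sq = (q / 2.0) ** 2
    rho = (slds - slds[0]) * 1e-6 + 1j * np.asarray(islds, dtype=float) * 1e-6
    k = np.sqrt(k0sq[:, None] - 4.0 * np.pi * rho[None, :] + 0j)

    # start from the bottom interface and fold upwards
    r_total = np.zeros_like(q, dtype=complex)
    for j in range(n - 2, -1, -1):
        kj, kj1 = k[:, j], k[:, j + 1]
        r_j = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 *
                                               roughnesses[j] ** 2)
        if j == n - 2:
            r_total = r_j
        else:
            phase = np.exp(2j * kj1 * thicknesses[j + 1])
            r_total = (r_j + r_total * phase) / (1.0 + r_j * r_total * phase)
    return np.abs(r_total) ** 2


def fresnel_reflectivity(sld_front, sld_back, q):
    """Closed-form Fresnel reflectivity of a single sharp interface."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k0 = q / 2.0
    k1 = np.sqrt(k0**2 - 4.0 * np.pi * (sld_back - sld_front) * 1e-6 + 0j)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


def dense_gaussian_convolution(q, model_fn, dq_over_q, n_sigma=5.0, n=801):
    """Brute-force trapezoidal Gaussian convolution, one point at a time."""
    out = np.empty_like(q, dtype=float)
    fwhm_to_sigma = 2.0 * np.sqrt(2.0 * np.log(2.0))
    for i, qi in enumerate(q):
        sigma = dq_over_q * qi / fwhm_to_sigma
        grid = np.linspace(qi - n_sigma * sigma, qi + n_sigma * sigma, n)
        grid = np.clip(grid, 1e-6, None)
        weights = np.exp(-0.5 * ((grid - qi) / sigma) ** 2)
        values = model_fn(grid)
        out[i] = np.trapezoid(values * weights, grid) / np.trapezoid(weights, grid)
    return out


def circular_bicelle_amplitude(q, alpha, radius, belt, half_core, half_total,
                               rho_core, rho_face, rho_rim, rho_solvent):
    """Core-shell bicelle amplitude for the circular (ε = 1) case."""

    def cyl(r, h, contrast):
        volume = np.pi * r**2 * 2.0 * h
        arg_z = q * h * np.cos(alpha)
        u = q * r * np.sin(alpha)
        sinc = np.where(arg_z == 0, 1.0, np.sin(arg_z) / np.where(arg_z == 0, 1.0, arg_z))
        jinc = np.where(u == 0, 1.0, 2.0 * special.j1(u) / np.where(u == 0, 1.0, u))
        return contrast * volume * sinc * jinc

    return (cyl(radius + belt, half_total, rho_rim - rho_solvent)
            + cyl(radius, half_total, rho_face - rho_rim)
            + cyl(radius, half_core, rho_core - rho_face))


def voxel_disc_intensity(q_values, model, d2o_fraction, voxel=2.0,
                         n_alpha=24):
    """Brute-force voxelised Fourier sum for the disc intensity (ε = 1 only).

    Builds the excess-SLD map on a cartesian grid and sums
    Δρ·exp(i q·r) voxel by voxel for each orientation; the orientation
    average uses the same sin α weight on a uniform α grid.  Slow —
    keep q_values short.
    """
    from liposcatter.materials import solvent_sld as _solvent
    from liposcatter.nanodisc_sans import _INTENSITY_SCALE

    assert model.ellipticity == 1.0, "voxel oracle assumes a circular disc"
    rho_core, rho_face, rho_rim = model.region_slds(d2o_fraction)
    rho_s = _solvent(d2o_fraction)
    a, d = model.r_minor, model.belt_thickness
    half_core = model.core_length / 2.0
    half_total = half_core + model.face_thickness

    rmax = a + d
    xs = np.arange(-rmax + voxel / 2.0, rmax, voxel)
    zs = np.arange(-half_total + voxel / 2.0, half_total, voxel)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    R2 = X**2 + Y**2
    contrast_map = np.zeros((len(xs), len(xs), len(zs)))
    for iz, z in enumerate(zs):
        inside_rim = R2 <= rmax**2
        inside_core_fp = R2 <= a**2
        layer = np.where(inside_rim, rho_rim - rho_s, 0.0)
        if abs(z) <= half_core:
            layer = np.where(inside_core_fp, rho_core - rho_s, layer)
        else:
            layer = np.where(inside_core_fp, rho_face - rho_s, layer)
        contrast_map[:, :, iz] = layer

    alphas = np.linspace(1e-3, np.pi / 2.0 - 1e-3, n_alpha)
    weights = np.sin(alphas)
    dV = voxel**3
    out = np.empty(len(q_values))
    for iq, q in enumerate(q_values):
        acc = 0.0
        for alpha, w in zip(alphas, weights):
            qx, qz = q * np.sin(alpha), q * np.cos(alpha)
            phase = np.exp(1j * (qx * X[:, :, None] + qz * zs[None, None, :]))
            F = np.sum(contrast_map * phase) * dV
            acc += w * np.abs(F) ** 2
        out[iq] = _INTENSITY_SCALE * acc / weights.sum() / model.outer_volume
    return out
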