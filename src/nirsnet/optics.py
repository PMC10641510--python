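"""Optical constants: hemoglobin extinction spectra and pathlength factors.

The extinction table holds molar extinction coefficients for oxy- and
deoxy-hemoglobin at the two instrument wavelengths, expressed in
cm^-1 per µM (i.e. compiled literature values in cm^-1·M^-1 scaled by
1e-6), so that concentrations are carried in micromolar and
source-detector distances in cm throughout. Values are from the standard
compiled in-vitro absorption spectra used across fNIRS toolboxes; both the
table and the DPF model are config-overridable in the pipeline.
"""
from __future__ import annotations

import numpy as np

# wavelength nm -> (eps_HbO, eps_HbR) in cm^-1 / µM
EXTINCTION_CM_UM: dict[float, tuple[float, float]] = {
    760.0: (5.860e-4, 1.5485e-3),
    850.0: (1.0580e-3, 6.9132e-4),
}

# alias kept for callers that care about the unit convention in the name
EXTINCTION_UMOL_MM = EXTINCTION_CM_UM


def extinction_pair(wavelength: float) -> tuple[float, float]:
    """(eps_HbO, eps_HbR) at ``wavelength`` nm, nearest tabulated entry."""
    if wavelength in EXTINCTION_CM_UM:
        return EXTINCTION_CM_UM[wavelength]
    nearest = min(EXTINCTION_CM_UM, key=lambda lam: abs(lam - wavelength))
    if abs(nearest - wavelength) > 25:
        raise ValueError(f"no extinction entry near {wavelength} nm")
    return EXTINCTION_CM_UM[nearest]


def dpf_general(wavelength: float, age_years: float) -> float:
    """General age- and wavelength-dependent differential pathlength factor.

    DPF(lambda, A) = a + b*A^c + d*lambda^3 + e*lambda^2 + f*lambda with the
    published general-equation coefficients; valid roughly for 690-830 nm
    and extrapolated mildly beyond (850 nm gives ~4.7 for a child, in the
    accepted range).
    """
    lam = float(wavelength)
    a_ = 223.3
    b_ = 0.05624
    c_ = 0.8493
    d_ = -5.723e-7
    e_ = 0.001245
    f_ = -0.9025
    return a_ + b_ * age_years**c_ + d_ * lam**3 + e_ * lam**2 + f_ * lam


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 matrix [[eps_HbO(l1), eps_HbR(l1)], [eps_HbO(l2), eps_HbR(l2)]]."""
    rows = [extinction_pair(lam) for lam in wavelengths]
    mat = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(mat)) < 1e-12:
        raise ValueError("extinction matrix is singular for these wavelengths")
    return mat
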