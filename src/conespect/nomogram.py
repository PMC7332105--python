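"""Visual-pigment absorbance nomograms as order-8 polynomials.

Opsin absorbance spectra plotted against the normalized reciprocal
wavelength x = λmax/λ collapse onto a near-universal shape.  Two
polynomial templates are shipped (as package data): one for red, green
and blue cones and a slightly narrower one for UV cones.  Each polynomial
P(x) gives log10 relative quantal sensitivity, normalized so that
P(1) ≈ 0 at the absorbance peak.

The saturation model consumes the spectral weight A(λmax, λ) = 10^(−P(x)):
A equals 1 at the peak and grows off-peak, so the effective semi-saturation
irradiance k·A is referred to λmax and increases as the stimulus moves away
from the pigment's peak.

Polynomials of this order cannot be trusted outside the reciprocal-wavelength
range they were fit on.  P is therefore clamped to its value at the edge of a
per-family validity window.  On the long-wavelength side (small x) both
polynomials fall smoothly and steeply to at least x = 0.5, so the window
extends there; on the short-wavelength side the r/g/b template levels off in
a β-band-like plateau and stays usable to x = 1.25, while the UV template
turns upward (unphysically predicting off-peak hypersensitivity) above
x ≈ 1.15 and is clamped there.
"""
from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CONE_FAMILY",
    "VALIDITY_WINDOWS",
    "coefficients",
    "log_rel_sensitivity",
    "nomogram_A",
    "NomogramClampWarning",
]

#: Which polynomial family each cone class uses.
CONE_FAMILY: dict[str, str] = {"r": "rgb", "g": "rgb", "b": "rgb", "u": "uv"}

#: Reciprocal-wavelength validity window (x_lo, x_hi) per family; P is clamped
#: to its boundary value outside.
VALIDITY_WINDOWS: dict[str, tuple[float, float]] = {
    "rgb": (0.5, 1.25),
    "uv": (0.5, 1.15),
}


class NomogramClampWarning(UserWarning):
    """Emitted when x falls outside the polynomial's validity window."""


def _load_coefficients() -> dict[str, np.ndarray]:
    with resources.files("conespect.data").joinpath("nomogram_coefficients.csv").open() as fh:
        tab = pd.read_csv(fh)
    out: dict[str, np.ndarray] = {}
    for family, grp in tab.groupby("family"):
        out[str(family)] = grp.sort_values("k")["coefficient"].to_numpy(float)
    return out


_COEFFS = _load_coefficients()


def coefficients(family: str) -> np.ndarray:
    """Polynomial coefficients C0..C8 for ``family`` ('rgb' or 'uv')."""
    try:
        return _COEFFS[family].copy()
    except KeyError:
        raise KeyError(f"unknown nomogram family {family!r}; expected 'rgb' or 'uv'")


def log_rel_sensitivity(
    family: str,
    x,
    window: tuple[float, float] | None = None,
    warn_on_clamp: bool = True,
):
    """Evaluate P(x) = Σ Ck·x^k, log10 relative quantal sensitivity.

    ``x`` outside the validity window is clamped to the window edge (the
    polynomial is not extrapolated); a :class:`NomogramClampWarning` is
    emitted unless ``warn_on_clamp`` is False.
    """
    c = _COEFFS[family] if family in _COEFFS else coefficients(family)
    lo, hi = window if window is not None else VALIDITY_WINDOWS[family]
    x = np.asarray(x, dtype=float)
    if warn_on_clamp and (np.any(x < lo) or np.any(x > hi)):
        warnings.warn(
            f"reciprocal wavelength outside [{lo}, {hi}] for family {family!r}; "
            "clamping to the window edge",
            NomogramClampWarning,
            stacklevel=2,
        )
    xc = np.clip(x, lo, hi)
    p = np.polyval(c[::-1], xc)
    return p if p.ndim else float(p)


def nomogram_A(
    cone_class: str,
    lambda_max: float,
    wavelength_nm,
    window: tuple[float, float] | None = None,
    reciprocal: bool = True,
):
    """Spectral weight A(λmax, λ) = 10^(−P(λmax/λ)) for one cone class.

    A ≈ 1 at λ = λmax and increases off-peak; the model's effective
    semi-saturation irradiance at wavelength λ is k·A(λmax, λ).

    ``reciprocal=False`` switches the polynomial argument to λ/λmax for
    sensitivity analyses; the near-symmetry of P about x = 1 makes the two
    conventions numerically similar close to the peak.
    """
    if cone_class not in CONE_FAMILY:
        raise KeyError(f"unknown cone class {cone_class!r}; expected one of r,g,b,u")
    family = CONE_FAMILY[cone_class]
    lam = np.asarray(wavelength_nm, dtype=float)
    x = lambda_max / lam if reciprocal else lam / lambda_max
    p = log_rel_sensitivity(family, x, window=window, warn_on_clamp=False)
    a = 10.0 ** (-np.asarray(p))
    return a if a.ndim else float(a)
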