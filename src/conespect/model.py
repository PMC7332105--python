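"""Four-cone saturation model of the cone-PIII ERG amplitude.

The trough-to-peak PIII amplitude evoked by a flash of quantal irradiance I
at wavelength λ is modelled as the sum of four hyperbolic (Naka-Rushton
type, exponent 1) saturation terms, one per cone class x ∈ {r, g, b, u}:

    V(I, λ) = Σ_x  Vx · I / (I + kx · A(λx_max, λ))

where Vx is the cone's saturation amplitude on the dataset-peak-normalized
scale (its *fractional contribution* to the maximal PIII response), kx the
semi-saturation irradiance at the cone's peak wavelength, λx_max the
wavelength of peak sensitivity, and A the pigment nomogram weight
(:mod:`conespect.nomogram`).  Amplitudes are dimensionless throughout this
layer; microvolts exist only upstream in the trace pipeline.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nomogram import nomogram_A

__all__ = [
    "CONE_CLASSES",
    "ConeParams",
    "ModelParams",
    "piii_amplitude",
    "irradiance_response_curve",
    "spectral_scan",
    "fractional_contributions",
]

CONE_CLASSES = ("r", "g", "b", "u")


@dataclass(frozen=True)
class ConeParams:
    """Saturation parameters of one cone class.

    ``fixed_k`` marks a semi-saturation that was substituted with a standard
    value rather than fitted; ``fixed_lambda`` marks a spectral peak that the
    data could not resolve ("no fit"); ``dropped`` marks a cone removed from
    the model entirely (Vmax = 0, peak and k unreported).
    """

    cone_class: str
    vmax: float
    log_k: float
    lambda_max: float
    fixed_k: bool = False
    fixed_lambda: bool = False
    dropped: bool = False

    def __post_init__(self) -> None:
        if self.cone_class not in CONE_CLASSES:
            raise ValueError(f"unknown cone class {self.cone_class!r}")
        if self.vmax < 0:
            raise ValueError("Vmax must be non-negative")
        if self.dropped and self.vmax != 0:
            raise ValueError("a dropped cone must have Vmax = 0")

    @property
    def k(self) -> float:
        """Linear semi-saturation irradiance, quanta·μm⁻²·s⁻¹."""
        return 10.0 ** self.log_k


@dataclass(frozen=True)
class ModelParams:
    """The complete parameter set: exactly one entry per cone class r,g,b,u."""

    cones: tuple[ConeParams, ConeParams, ConeParams, ConeParams]

    def __post_init__(self) -> None:
        classes = tuple(c.cone_class for c in self.cones)
        if classes != CONE_CLASSES:
            raise ValueError(f"cones must be ordered {CONE_CLASSES}, got {classes}")

    def __getitem__(self, cone_class: str) -> ConeParams:
        return self.cones[CONE_CLASSES.index(cone_class)]

    def with_cone(self, cone: ConeParams) -> "ModelParams":
        cones = tuple(cone if c.cone_class == cone.cone_class else c for c in self.cones)
        return ModelParams(cones=cones)  # type: ignore[arg-type]

    @classmethod
    def from_arrays(cls, vmax, log_k, lambda_max, **flags) -> "ModelParams":
        cones = tuple(
            ConeParams(c, float(v), float(k), float(l))
            for c, v, k, l in zip(CONE_CLASSES, vmax, log_k, lambda_max)
        )
        return cls(cones=cones)  # type: ignore[arg-type]

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            c.cone_class: {
                "Vmax": c.vmax,
                "log_k": c.log_k,
                "lambda_max": c.lambda_max,
                "fixed_k": c.fixed_k,
                "fixed_lambda": c.fixed_lambda,
                "dropped": c.dropped,
            }
            for c in self.cones
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        cones = tuple(
            ConeParams(
                cone_class=c,
                vmax=float(d[c]["Vmax"]),
                log_k=float(d[c]["log_k"]),
                lambda_max=float(d[c]["lambda_max"]),
                fixed_k=bool(d[c].get("fixed_k", False)),
                fixed_lambda=bool(d[c].get("fixed_lambda", False)),
                dropped=bool(d[c].get("dropped", False)),
            )
            for c in CONE_CLASSES
        )
        return cls(cones=cones)  # type: ignore[arg-type]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def piii_amplitude(irradiance, wavelength_nm, params: ModelParams):
    """Evaluate the four-cone saturation model.

    ``irradiance`` (linear quanta·μm⁻²·s⁻¹) and ``wavelength_nm`` broadcast
    against each other; returns the summed normalized amplitude.
    """
    I = np.asarray(irradiance, dtype=float)
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be non-negative")
    out = np.zeros(np.broadcast(I, lam).shape, dtype=float)
    for cone in params.cones:
        if cone.dropped or cone.vmax == 0:
            continue
        a = nomogram_A(cone.cone_class, cone.lambda_max, lam)
        out = out + cone.vmax * I / (I + cone.k * a)
    return out if out.ndim else float(out)


def irradiance_response_curve(
    params: ModelParams, wavelength_nm: float, log_i_grid
) -> pd.DataFrame:
    """Model amplitude along an irradiance series at one wavelength."""
    logs = np.asarray(log_i_grid, dtype=float)
    if np.any(np.diff(logs) < 0):
        raise ValueError("log irradiance grid must be sorted ascending")
    v = piii_amplitude(10.0 ** logs, wavelength_nm, params)
    return pd.DataFrame({"log_irradiance": logs, "amplitude": v})


def spectral_scan(
    params: ModelParams,
    log_quanta: float = 4.6,
    wavelengths=None,
) -> pd.DataFrame:
    """Constant-quantal spectral scan.

    Evaluates the model across wavelength at a fixed quantal irradiance
    (default 4.6 log(quanta·μm⁻²·s⁻¹), below semi-saturation for all but UV
    cones in larvae).  Returns both raw and peak-normalized amplitudes.
    """
    lam = (
        np.arange(330.0, 651.0, 1.0) if wavelengths is None else np.asarray(wavelengths, float)
    )
    v = piii_amplitude(10.0 ** log_quanta, lam, params)
    peak = float(np.max(v)) if np.max(v) > 0 else 1.0
    return pd.DataFrame(
        {"wavelength_nm": lam, "amplitude": v, "amplitude_normalized": v / peak}
    )


def fractional_contributions(params: ModelParams) -> dict[str, float]:
    """Fitted Vmax per cone class, read as fractions of the maximal PIII.

    Valid when the fit was performed on dataset-peak-normalized data; the
    values are *not* renormalized to sum to one (cones saturate at different
    wavelengths, so the sum may exceed 1).
    """
    return {c.cone_class: c.vmax for c in params.cones}
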