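"""Genotype-level pooling and bounded least-squares fitting of the cone model.

Datasets from many eyes are normalized to their own peak response and
concatenated into a genotype-level dataset of (wavelength, irradiance,
amplitude) points, which is fit jointly to the four-cone saturation model.
The fit mimics the original procedure: bounded least squares (trust-region
reflective, the bounded analogue of Levenberg-Marquardt) capped at 100
iterations, with two fallbacks —

* a semi-saturation (log k) that fails to converge or lands on its bound is
  replaced by a standard fixed value and the fit repeated with the remaining
  parameters free;
* a cone whose fitted saturation amplitude falls below a drop threshold is
  removed from the model and reported "no fit".

A spectral peak is reported only when the data actually resolve it: cones
whose λmax standard error exceeds a ceiling (default 12 nm) or whose λmax
lands on its search-window boundary keep their amplitude but are flagged
"no fit" for the peak.  Standard errors come from the Jacobian-based
covariance at the solution.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .model import CONE_CLASSES, ConeParams, ModelParams, piii_amplitude
from .preprocess import AmplitudeDataset

__all__ = [
    "GenotypeDataset",
    "FitConfig",
    "FitResult",
    "FitFailure",
    "Substitution",
    "normalize_and_pool",
    "default_seeds",
    "fit_spectral_model",
    "parameter_contrast",
    "genotype_anova",
    "ContrastResult",
    "AnovaResult",
]

#: λmax seeds per age class: wild-type larval and adult peak estimates.
LAMBDA_SEEDS = {
    "larva": {"r": 553.7, "g": 461.8, "b": 403.2, "u": 357.5},
    "adult": {"r": 566.8, "g": 465.6, "b": 447.9, "u": 364.4},
}


@dataclass
class GenotypeDataset:
    """Pooled, per-eye-normalized amplitude points for one genotype."""

    frame: pd.DataFrame  # columns: wavelength_nm, irradiance, amplitude
    label: str = ""
    n_source_datasets: int = 1

    def __post_init__(self) -> None:
        need = {"wavelength_nm", "irradiance", "amplitude"}
        if not need <= set(self.frame.columns):
            raise ValueError(f"genotype table needs columns {sorted(need)}")

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = self.frame
        return (
            f["wavelength_nm"].to_numpy(float),
            f["irradiance"].to_numpy(float),
            f["amplitude"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "label", self.label)
        out["n_source_datasets"] = self.n_source_datasets
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeDataset":
        tab = pd.read_csv(path)
        label = str(tab["label"].iloc[0]) if "label" in tab else ""
        n_src = int(tab["n_source_datasets"].iloc[0]) if "n_source_datasets" in tab else 1
        return cls(
            frame=tab[["wavelength_nm", "irradiance", "amplitude"]].copy(),
            label=label,
            n_source_datasets=n_src,
        )


def normalize_and_pool(
    datasets: list[AmplitudeDataset], label: str = ""
) -> GenotypeDataset:
    """Scale each dataset to its own maximum and concatenate.

    Excluded (unstable) datasets are rejected; each source contributes its
    amplitudes divided by its own peak, so the pooled amplitudes are
    dimensionless fractions with max 1 per source.
    """
    if not datasets:
        raise ValueError("no datasets to pool")
    chunks = []
    for ds in datasets:
        if ds.excluded:
            raise ValueError(
                f"dataset {ds.dataset_id!r} is flagged excluded "
                f"(stability ratio {ds.stability_ratio:.3g}); remove it before pooling"
            )
        peak = ds.max_amplitude()
        if peak <= 0:
            raise ValueError(f"dataset {ds.dataset_id!r} has zero peak amplitude")
        f = ds.frame
        chunks.append(
            pd.DataFrame(
                {
                    "wavelength_nm": f["wavelength_nm"].to_numpy(float),
                    "irradiance": 10.0 ** f["log_irradiance"].to_numpy(float),
                    "amplitude": f["amplitude"].to_numpy(float) / peak,
                }
            )
        )
    frame = pd.concat(chunks, ignore_index=True)
    return GenotypeDataset(frame=frame, label=label, n_source_datasets=len(datasets))


@dataclass(frozen=True)
class FitConfig:
    """Bounds, seeds, iteration cap and fallback rules for the model fit.

    ``fixed_k_defaults`` are the standard semi-saturation values substituted
    on non-convergence or a boundary hit.  ``lambda_windows`` keep the four
    peaks in disjoint, cone-class-appropriate ranges so labels cannot swap.
    ``lambda_se_max`` is the peak-reportability ceiling: a λmax whose
    standard error exceeds it is "no fit".
    """

    log_k_bounds: tuple[float, float] = (1.0, 6.0)
    vmax_bounds: tuple[float, float] = (0.0, 1.5)
    lambda_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "r": (500.0, 620.0),
            "g": (420.0, 540.0),
            "b": (370.0, 470.0),
            "u": (330.0, 400.0),
        }
    )
    max_iterations: int = 100
    fixed_k_defaults: dict[str, float] = field(
        default_factory=lambda: {"r": 4.5, "g": 4.0, "b": 3.5, "u": 3.0}
    )
    drop_threshold: float = 0.02
    lambda_se_max: float = 12.0
    vmax_seed: float = 0.25
    boundary_tol: float = 1e-3


@dataclass(frozen=True)
class Substitution:
    parameter: str
    reason: str  # "non_convergence" | "boundary_hit"
    value: float


class FitFailure(RuntimeError):
    """No convergent model after all fallbacks; carries a diagnostic report."""

    def __init__(self, report: str):
        super().__init__(report)
        self.report = report


def default_seeds(config: FitConfig | None = None, age_class: str = "larva") -> ModelParams:
    """Starting values: Vmax 0.25 per cone, log k at the fixed defaults,
    λmax at the wild-type peaks for the age class."""
    cfg = config or FitConfig()
    lam = LAMBDA_SEEDS.get(age_class, LAMBDA_SEEDS["larva"])
    cones = tuple(
        ConeParams(c, cfg.vmax_seed, cfg.fixed_k_defaults[c], lam[c])
        for c in CONE_CLASSES
    )
    return ModelParams(cones=cones)  # type: ignore[arg-type]


# -- internal parameter bookkeeping -------------------------------------------


@dataclass
class _Structure:
    """Which parameters are free in the current fit round."""

    active: list[str]  # cone classes still in the model
    fixed_k: dict[str, float]  # cone -> substituted log k

    def free_names(self) -> list[str]:
        names = []
        for c in self.active:
            names.append(f"vmax_{c}")
            if c not in self.fixed_k:
                names.append(f"log_k_{c}")
            names.append(f"lambda_max_{c}")
        return names


def _pack_seeds(struct: _Structure, seeds: ModelParams) -> np.ndarray:
    vals = []
    for c in struct.active:
        cone = seeds[c]
        vals.append(cone.vmax)
        if c not in struct.fixed_k:
            vals.append(cone.log_k)
        vals.append(cone.lambda_max)
    return np.asarray(vals, float)


def _bounds(struct: _Structure, cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for c in struct.active:
        lo.append(cfg.vmax_bounds[0])
        hi.append(cfg.vmax_bounds[1])
        if c not in struct.fixed_k:
            lo.append(cfg.log_k_bounds[0])
            hi.append(cfg.log_k_bounds[1])
        lo.append(cfg.lambda_windows[c][0])
        hi.append(cfg.lambda_windows[c][1])
    return np.asarray(lo), np.asarray(hi)


def _unpack(theta: np.ndarray, struct: _Structure, seeds: ModelParams) -> ModelParams:
    params = seeds
    i = 0
    for c in struct.active:
        vmax = theta[i]
        i += 1
        if c in struct.fixed_k:
            log_k = struct.fixed_k[c]
            fixed = True
        else:
            log_k = theta[i]
            i += 1
            fixed = False
        lam = theta[i]
        i += 1
        params = params.with_cone(
            ConeParams(c, float(max(vmax, 0.0)), float(log_k), float(lam), fixed_k=fixed)
        )
    for c in CONE_CLASSES:
        if c not in struct.active:
            params = params.with_cone(
                ConeParams(c, 0.0, seeds[c].log_k, seeds[c].lambda_max, dropped=True)
            )
    return params


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one genotype-level fit."""

    params: ModelParams
    se: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    substitutions: list[Substitution]
    no_fit: dict[str, str]  # cone -> reason the peak is unreportable
    label: str = ""
    cov: np.ndarray | None = None
    free_names: list[str] = field(default_factory=list)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def dof(self) -> int:
        return self.n_points - self.n_free

    def estimate(self, parameter: str) -> tuple[float, float]:
        """(value, se) of a free parameter, e.g. 'lambda_max_r'."""
        if parameter not in self.free_names:
            raise ValueError(f"{parameter!r} is not a free parameter of this fit")
        field_name, cone = parameter.rsplit("_", 1)
        value = getattr(self.params[cone], field_name)
        return float(value), self.se[parameter]

    def peak_estimates(self) -> dict[str, tuple[float, float] | None]:
        """λmax ± SE per cone; None where the peak is 'no fit'."""
        out: dict[str, tuple[float, float] | None] = {}
        for c in CONE_CLASSES:
            if c in self.no_fit:
                out[c] = None
            else:
                out[c] = (self.params[c].lambda_max, self.se[f"lambda_max_{c}"])
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in CONE_CLASSES:
            cone = self.params[c]
            rows.append(
                {
                    "cone": c,
                    "Vmax": cone.vmax,
                    "se_Vmax": self.se.get(f"vmax_{c}", float("nan")),
                    "log_k": cone.log_k if not cone.dropped else float("nan"),
                    "se_log_k": self.se.get(f"log_k_{c}", float("nan")),
                    "lambda_max": cone.lambda_max if c not in self.no_fit else float("nan"),
                    "se_lambda_max": self.se.get(f"lambda_max_{c}", float("nan"))
                    if c not in self.no_fit
                    else float("nan"),
                    "peak": "no fit" if c in self.no_fit else "fit",
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "params": self.params.to_dict(),
            "se": self.se,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "substitutions": [vars(s) for s in self.substitutions],
            "no_fit": self.no_fit,
            "free_parameters": self.free_names,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _run_lsq(data_arrays, struct: _Structure, seeds: ModelParams, cfg: FitConfig):
    lam, irr, v = data_arrays
    x0 = _pack_seeds(struct, seeds)
    lo, hi = _bounds(struct, cfg)
    x0 = np.clip(x0, lo, hi)

    def residual(theta: np.ndarray) -> np.ndarray:
        p = _unpack(theta, struct, seeds)
        return piii_amplitude(irr, lam, p) - v

    max_nfev = cfg.max_iterations * (x0.size + 1)
    return least_squares(
        residual, x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev
    )


def fit_spectral_model(
    data: GenotypeDataset,
    config: FitConfig | None = None,
    seeds: ModelParams | None = None,
    age_class: str = "larva",
    force_free: tuple[str, ...] = (),
) -> FitResult:
    """Fit the four-cone model with the fixed-value and no-fit fallback rules.

    ``force_free`` names parameters (e.g. ``("vmax_r",)``) that must stay
    free — their cone is never dropped and their log k never substituted —
    used by the genotype comparisons.
    """
    cfg = config or FitConfig()
    seeds = seeds or default_seeds(cfg, age_class)
    arrays = data.arrays()
    forced_cones = {name.rsplit("_", 1)[1] for name in force_free}
    forced_k = {name.rsplit("_", 1)[1] for name in force_free if name.startswith("log_k")}

    struct = _Structure(active=list(CONE_CLASSES), fixed_k={})
    if data.n_points < len(struct.free_names()):
        raise ValueError(
            f"{data.n_points} points cannot constrain {len(struct.free_names())} parameters"
        )
    substitutions: list[Substitution] = []
    history: list[str] = []
    result = None
    current_seeds = seeds

    for _round in range(10):
        result = _run_lsq(arrays, struct, current_seeds, cfg)
        params = _unpack(result.x, struct, current_seeds)
        history.append(
            f"round {_round}: free={struct.free_names()} status={result.status} "
            f"rss={2 * result.cost:.5g}"
        )
        if result.status == 0:
            # non-convergence within the iteration cap: substitute the fixed
            # k of the least-constrained (smallest-amplitude) cone still free
            candidates = [
                c
                for c in struct.active
                if c not in struct.fixed_k and c not in forced_k
            ]
            if not candidates:
                raise FitFailure(
                    "fit did not converge and no semi-saturation left to fix:\n"
                    + "\n".join(history)
                )
            worst = min(candidates, key=lambda c: params[c].vmax)
            struct.fixed_k[worst] = cfg.fixed_k_defaults[worst]
            substitutions.append(
                Substitution(f"log_k_{worst}", "non_convergence", cfg.fixed_k_defaults[worst])
            )
            current_seeds = params
            continue

        # boundary check on free log k
        lo_k, hi_k = cfg.log_k_bounds
        hit = [
            c
            for c in struct.active
            if c not in struct.fixed_k
            and c not in forced_k
            and (
                abs(params[c].log_k - lo_k) < cfg.boundary_tol
                or abs(params[c].log_k - hi_k) < cfg.boundary_tol
            )
        ]
        if hit:
            for c in hit:
                struct.fixed_k[c] = cfg.fixed_k_defaults[c]
                substitutions.append(
                    Substitution(f"log_k_{c}", "boundary_hit", cfg.fixed_k_defaults[c])
                )
            current_seeds = params
            continue

        # drop cones indistinguishable from zero amplitude
        drop = [
            c
            for c in struct.active
            if params[c].vmax < cfg.drop_threshold and c not in forced_cones
        ]
        if drop:
            struct.active = [c for c in struct.active if c not in drop]
            for c in drop:
                struct.fixed_k.pop(c, None)
            current_seeds = params
            continue
        break
    else:
        raise FitFailure("fallback cascade did not stabilize:\n" + "\n".join(history))

    assert result is not None
    params = _unpack(result.x, struct, current_seeds)
    free_names = struct.free_names()
    rss = float(2.0 * result.cost)
    n, p = data.n_points, len(free_names)
    J = result.jac
    if n > p:
        cov = float(rss / (n - p)) * np.linalg.pinv(J.T @ J)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        cov = np.full((p, p), np.nan)
        se_vec = np.full(p, np.nan)
    se = {name: float(s) for name, s in zip(free_names, se_vec)}

    # peak reportability
    no_fit: dict[str, str] = {}
    for c in CONE_CLASSES:
        if c not in struct.active:
            no_fit[c] = "amplitude_below_threshold"
            continue
        lam_lo, lam_hi = cfg.lambda_windows[c]
        lam_hat = params[c].lambda_max
        se_lam = se[f"lambda_max_{c}"]
        if not np.isfinite(se_lam) or se_lam > cfg.lambda_se_max:
            no_fit[c] = "peak_unresolved"
        elif (
            abs(lam_hat - lam_lo) < cfg.boundary_tol
            or abs(lam_hat - lam_hi) < cfg.boundary_tol
        ):
            no_fit[c] = "window_boundary"
    for c in no_fit:
        if c in struct.active:
            params = params.with_cone(replace(params[c], fixed_lambda=True))

    return FitResult(
        params=params,
        se=se,
        rss=rss,
        n_points=n,
        converged=True,
        substitutions=substitutions,
        no_fit=no_fit,
        label=data.label,
        cov=cov,
        free_names=free_names,
    )


# -- genotype comparisons ------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    statistic: float
    df: int
    p: float


def parameter_contrast(fit_a: FitResult, fit_b: FitResult, parameter: str) -> ContrastResult:
    """Wald comparison of one fitted parameter between two genotype fits.

    t = (θA − θB)/√(seA² + seB²) with point-level degrees of freedom
    nA + nB − pA − pB, two-tailed p.
    """
    va, sa = fit_a.estimate(parameter)
    vb, sb = fit_b.estimate(parameter)
    if sa == 0 and sb == 0:
        raise ValueError(f"both fits report zero uncertainty for {parameter!r}")
    t = (va - vb) / float(np.hypot(sa, sb))
    df = fit_a.n_points + fit_b.n_points - fit_a.n_free - fit_b.n_free
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ContrastResult(statistic=float(t), df=int(df), p=min(p, 1.0))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    pairwise: tuple  # (label_a, label_b, q, p) per pair


def genotype_anova(
    datasets: list[GenotypeDataset],
    parameter: str,
    config: FitConfig | None = None,
    age_class: str = "larva",
) -> AnovaResult:
    """Extra-sum-of-squares F test for one parameter across ≥2 genotypes.

    The full model fits the parameter separately in each group (all other
    parameters are group-specific in both models); the reduced model shares
    it.  df1 = G − 1 and df2 = N_total − p_full use point-level accounting.
    Pairwise contrasts use a studentized-range (Tukey-style) adjustment on
    the Wald statistics of the separate fits.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two genotype datasets")
    cfg = config or FitConfig()
    fits = [
        fit_spectral_model(
            d, cfg, age_class=age_class, force_free=(parameter,)
        )
        for d in datasets
    ]
    rss_full = sum(f.rss for f in fits)
    p_full = sum(f.n_free for f in fits)
    n_total = sum(f.n_points for f in fits)
    df1 = len(datasets) - 1
    df2 = n_total - p_full

    rss_reduced = _shared_parameter_rss(datasets, fits, parameter, cfg)
    F = max(0.0, (rss_reduced - rss_full) / df1) / (rss_full / df2)
    p = float(stats.f.sf(F, df1, df2))

    pairs = []
    k = len(datasets)
    for i in range(k):
        for j in range(i + 1, k):
            vi, si = fits[i].estimate(parameter)
            vj, sj = fits[j].estimate(parameter)
            q = abs(vi - vj) / np.sqrt((si**2 + sj**2) / 2.0)
            p_ij = float(stats.studentized_range.sf(q, k, df2))
            pairs.append((fits[i].label, fits[j].label, float(q), min(p_ij, 1.0)))
    return AnovaResult(F=float(F), df1=df1, df2=int(df2), p=p, pairwise=tuple(pairs))


def _shared_parameter_rss(
    datasets: list[GenotypeDataset],
    fits: list[FitResult],
    parameter: str,
    cfg: FitConfig,
) -> float:
    """RSS of the joint fit in which ``parameter`` is shared across groups.

    Each group keeps the free-parameter structure of its separate fit; the
    joint optimization starts from the separate solutions.
    """
    field_name, cone = parameter.rsplit("_", 1)
    structs = []
    for f in fits:
        active = [c for c in CONE_CLASSES if not f.params[c].dropped]
        fixed_k = {
            c: f.params[c].log_k for c in active if f.params[c].fixed_k
        }
        structs.append(_Structure(active=active, fixed_k=fixed_k))

    # global vector: [shared, group0 free (minus shared slot), group1 ...]
    group_names = [s.free_names() for s in structs]
    for names in group_names:
        if parameter not in names:
            raise ValueError(f"{parameter!r} not free in every group")
    offsets = []
    sizes = []
    pos = 1
    for names in group_names:
        offsets.append(pos)
        sizes.append(len(names) - 1)
        pos += len(names) - 1

    shared0 = float(np.mean([f.estimate(parameter)[0] for f in fits]))
    x0 = [shared0]
    lo = [-np.inf]
    hi = [np.inf]
    if field_name == "vmax":
        lo[0], hi[0] = cfg.vmax_bounds
    elif field_name == "log_k":
        lo[0], hi[0] = cfg.log_k_bounds
    else:
        lo[0], hi[0] = cfg.lambda_windows[cone]

    per_group_idx = []
    for g, (names, struct, f) in enumerate(zip(group_names, structs, fits)):
        seed_vec = _pack_seeds(struct, f.params)
        lo_g, hi_g = _bounds(struct, cfg)
        keep = [i for i, nm in enumerate(names) if nm != parameter]
        shared_slot = names.index(parameter)
        per_group_idx.append((keep, shared_slot))
        x0.extend(seed_vec[keep])
        lo.extend(lo_g[keep])
        hi.extend(hi_g[keep])

    x0 = np.asarray(x0, float)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    x0 = np.clip(x0, lo, hi)
    arrays = [d.arrays() for d in datasets]

    def residual(theta: np.ndarray) -> np.ndarray:
        res = []
        for g, ((keep, shared_slot), struct, f) in enumerate(
            zip(per_group_idx, structs, fits)
        ):
            vec = np.empty(len(keep) + 1)
            vec[keep] = theta[offsets[g] : offsets[g] + sizes[g]]
            vec[shared_slot] = theta[0]
            p = _unpack(vec, struct, f.params)
            lam, irr, v = arrays[g]
            res.append(piii_amplitude(irr, lam, p) - v)
        return np.concatenate(res)

    out = least_squares(
        residual, x0, bounds=(lo, hi), method="trf",
        max_nfev=cfg.max_iterations * (x0.size + 1),
    )
    return float(2.0 * out.cost)
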