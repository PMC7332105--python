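"""Synthetic spectral datasets, sweeps and behavioral counts.

Genotype presets collect the published parameter estimates for each
*trβ2* strain (wild type, heterozygote and frameshift/in-frame mutants,
larval and adult); values the source tables do not print fall back to
documented defaults and every field carries a provenance tag.  The
generators draw amplitude datasets (the four-cone model plus Gaussian
amplitude noise, floored at zero), full 2000-Hz sweep sets with a
PIII-like waveform, pooled genotype-level datasets for parameter-recovery
studies, and binomial optomotor plate counts.  All generators are pure
functions of their arguments and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ContingencyTable2x2
from .fitting import GenotypeDataset
from .model import CONE_CLASSES, ConeParams, ModelParams, piii_amplitude
from .preprocess import AmplitudeDataset, PreprocessConfig, SweepSet, stability_index
from .protocol import SpectralProtocol, default_protocol

__all__ = [
    "GenotypePreset",
    "NoiseModel",
    "preset",
    "PRESET_NAMES",
    "simulate_amplitude_dataset",
    "simulate_genotype_dataset",
    "simulate_sweepset",
    "simulate_omr_counts",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise and waveform-shape settings for the generators.

    ``amplitude_sigma`` is additive Gaussian noise on normalized amplitudes
    (0.05 makes synthetic genotype-level fit SEs comparable to the published
    ones); ``trace_sigma_uv`` is per-sample sweep noise; ``rebound_fraction``
    sizes the post-offset depolarizing rebound relative to the plateau
    (cosmetic — only the trough-to-peak total matters); ``gain_uv`` converts
    normalized amplitude to μV at the vitreal electrode.
    """

    amplitude_sigma: float = 0.05
    trace_sigma_uv: float = 2.0
    rebound_fraction: float = 0.3
    gain_uv: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_sigma < 0 or self.trace_sigma_uv < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class GenotypePreset:
    """Model parameters of one genotype with per-field provenance tags."""

    name: str
    params: ModelParams
    age_class: str
    provenance: dict = field(default_factory=dict)

    def provenance_of(self, cone: str, field_name: str) -> str:
        return self.provenance.get(f"{field_name}_{cone}", "default")


def _mk(name, age, spec):
    """Build a preset from {cone: (vmax, log_k, lambda_max, tags)}."""
    cones = []
    prov = {}
    for c in CONE_CLASSES:
        vmax, log_k, lam, tags = spec[c]
        cones.append(ConeParams(c, vmax, log_k, lam))
        for fld, tag in zip(("vmax", "log_k", "lambda_max"), tags):
            prov[f"{fld}_{c}"] = tag
    return GenotypePreset(
        name=name,
        params=ModelParams(cones=tuple(cones)),  # type: ignore[arg-type]
        age_class=age,
        provenance=prov,
    )


_T = "table"  # printed in a source table or results paragraph
_D = "default"  # not printed; package default (documented)

_PRESETS = {
    # larval strains -----------------------------------------------------------
    "wt_larva": _mk(
        "wt_larva",
        "larva",
        {
            "r": (0.551, 4.5, 553.7, (_T, _D, _T)),
            "g": (0.25, 4.57, 461.8, (_D, _T, _T)),
            "b": (0.196, 3.5, 403.2, (_T, _D, _T)),
            "u": (0.289, 3.0, 357.5, (_T, _D, _T)),
        },
    ),
    "het_6bp1_larva": _mk(
        "het_6bp1_larva",
        "larva",
        {
            "r": (0.456, 4.5, 556.7, (_T, _D, _T)),
            "g": (0.25, 4.57, 466.4, (_D, _D, _T)),
            "b": (0.218, 3.5, 396.4, (_T, _D, _T)),
            "u": (0.447, 3.0, 350.3, (_T, _D, _T)),
        },
    ),
    "mut_6bp1_larva": _mk(
        "mut_6bp1_larva",
        "larva",
        {
            # red peak is "no fit" in the source; the wild-type peak stands in
            "r": (0.030, 4.5, 553.7, (_T, _D, _D)),
            "g": (0.20, 4.93, 461.8, (_D, _T, _D)),
            "b": (0.329, 3.5, 399.7, (_T, _D, _T)),
            "u": (0.435, 3.0, 354.6, (_T, _D, _T)),
        },
    ),
    "mut_3bp_larva": _mk(
        "mut_3bp_larva",
        "larva",
        {
            "r": (0.501, 4.5, 552.9, (_T, _D, _T)),
            "g": (0.25, 4.57, 460.6, (_D, _D, _T)),
            "b": (0.196, 3.5, 396.8, (_D, _D, _T)),
            "u": (0.289, 3.0, 350.1, (_D, _D, _T)),
        },
    ),
    # adult strains ------------------------------------------------------------
    "wt_adult": _mk(
        "wt_adult",
        "adult",
        {
            "r": (0.551, 4.79, 566.8, (_D, _T, _T)),
            "g": (0.25, 3.17, 465.6, (_D, _T, _T)),
            "b": (0.196, 3.5, 447.9, (_D, _D, _T)),
            "u": (0.289, 3.0, 364.4, (_D, _D, _T)),
        },
    ),
    "het_6bp1_adult": _mk(
        "het_6bp1_adult",
        "adult",
        {
            "r": (0.551, 5.21, 568.3, (_D, _T, _T)),
            "g": (0.25, 3.73, 469.6, (_D, _T, _T)),
            "b": (0.196, 3.5, 441.4, (_D, _D, _T)),
            "u": (0.289, 3.0, 351.8, (_D, _D, _T)),
        },
    ),
    "mut_6bp1_adult": _mk(
        "mut_6bp1_adult",
        "adult",
        {
            "r": (0.030, 4.5, 566.8, (_D, _D, _D)),
            "g": (0.35, 5.64, 502.2, (_D, _T, _T)),
            "b": (0.25, 3.5, 438.4, (_D, _D, _T)),
            "u": (0.40, 3.0, 359.6, (_D, _D, _T)),
        },
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> GenotypePreset:
    """Look up a genotype preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )


# -- generators ----------------------------------------------------------------


def _rng(noise: NoiseModel, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(noise.seed if seed is None else seed)


def simulate_amplitude_dataset(
    gp: GenotypePreset,
    protocol: SpectralProtocol | None = None,
    noise: NoiseModel | None = None,
    dataset_id: str = "",
    seed: int | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> AmplitudeDataset:
    """Draw one eye's 70-row amplitude dataset on the normalized scale.

    Each protocol combination gets model amplitude + N(0, amplitude_sigma),
    floored at zero; the two 650-nm blocks are drawn independently and feed
    the stability index, after which their steps are block-averaged exactly
    as the preprocessing pipeline does.
    """
    proto = protocol or default_protocol()
    nm = noise or NoiseModel()
    cfg = preprocess_config or PreprocessConfig()
    rng = _rng(nm, seed)
    frame = proto.combos()
    clean = piii_amplitude(
        10.0 ** frame["log_irradiance"].to_numpy(float),
        frame["wavelength_nm"].to_numpy(float),
        gp.params,
    )
    noisy = np.clip(clean + rng.normal(0.0, nm.amplitude_sigma, clean.size), 0.0, None)
    frame = frame.assign(amplitude=noisy)
    ratio, excluded = stability_index(
        frame, band=cfg.stability_band, min_index_fraction=cfg.stability_min_fraction
    )
    dup = frame[frame["wavelength_nm"] == 650]
    means = dup.groupby("step_index")["amplitude"].mean()
    sel = frame["wavelength_nm"] == 650
    frame.loc[sel, "amplitude"] = frame.loc[sel, "step_index"].map(means).to_numpy()
    return AmplitudeDataset(
        frame=frame,
        dataset_id=dataset_id or f"{gp.name}-sim",
        stability_ratio=ratio,
        excluded=excluded,
        genotype_label=gp.name,
        age_class=gp.age_class,
    )


def simulate_genotype_dataset(
    gp: GenotypePreset,
    n_datasets: int,
    protocol: SpectralProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    label: str = "",
) -> GenotypeDataset:
    """Draw a pooled genotype-level dataset directly on the normalized scale.

    Concatenates ``n_datasets`` independent 70-point draws at unit gain —
    the generator knows the true amplitude scale, so no division by a noisy
    empirical maximum is applied.  This is the input for parameter-recovery
    studies of the fit itself; gain-bearing (μV) data go through
    :func:`conespect.fitting.normalize_and_pool` instead, whose empirical
    normalization slightly shrinks amplitude estimates (see the methods
    note).
    """
    proto = protocol or default_protocol()
    nm = noise or NoiseModel()
    rng = _rng(nm, seed)
    combos = proto.combos()
    lam = combos["wavelength_nm"].to_numpy(float)
    irr = 10.0 ** combos["log_irradiance"].to_numpy(float)
    clean = piii_amplitude(irr, lam, gp.params)
    chunks = []
    for _ in range(n_datasets):
        noisy = np.clip(clean + rng.normal(0.0, nm.amplitude_sigma, clean.size), 0.0, None)
        chunks.append(
            pd.DataFrame({"wavelength_nm": lam, "irradiance": irr, "amplitude": noisy})
        )
    return GenotypeDataset(
        frame=pd.concat(chunks, ignore_index=True),
        label=label or gp.name,
        n_source_datasets=n_datasets,
    )


def _piii_waveform(
    time_s: np.ndarray,
    onset_s: float,
    offset_s: float,
    amplitude: float,
    rebound_fraction: float,
) -> np.ndarray:
    """PIII-like template: hyperpolarizing plateau, then a rebound peak.

    Rise time constant 20 ms; after offset the plateau decays (τ 20 ms)
    while a rebound transient R·(s/τ₂)·e^(1−s/τ₂) peaks at τ₂ = 120 ms with
    value R = rebound_fraction·amplitude, so the trough-to-peak total is
    (1 + rebound_fraction)·amplitude to within a fraction of a percent.
    """
    w = np.zeros_like(time_s)
    tau_on = 0.02
    tau_reb = 0.12
    during = (time_s >= onset_s) & (time_s < offset_s)
    w[during] = -amplitude * (1.0 - np.exp(-(time_s[during] - onset_s) / tau_on))
    after = time_s >= offset_s
    s = time_s[after] - offset_s
    plateau = -amplitude * (1.0 - np.exp(-(offset_s - onset_s) / tau_on))
    rebound = rebound_fraction * amplitude * (s / tau_reb) * np.exp(1.0 - s / tau_reb)
    w[after] = plateau * np.exp(-s / tau_on) + rebound
    return w


def simulate_sweepset(
    gp: GenotypePreset,
    protocol: SpectralProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    subject_id: str = "",
    pre_s: float = 0.1,
    post_s: float = 0.8,
    sample_rate_hz: float = 2000.0,
) -> SweepSet:
    """Draw raw 2000-Hz replicate sweeps for every flash of the protocol.

    Per stimulus the model amplitude (times ``gain_uv``) shapes a PIII-like
    template; each of the 4 replicates gets independent Gaussian trace
    noise.  Sweep time is relative to stimulus onset (onset at 0 s).
    """
    proto = protocol or default_protocol()
    nm = noise or NoiseModel()
    rng = _rng(nm, seed)
    duration_s = proto.duration_ms / 1000.0
    n = int(round((pre_s + duration_s + post_s) * sample_rate_hz))
    time_s = np.arange(n) / sample_rate_hz - pre_s
    traces: dict[int, np.ndarray] = {}
    for stim in proto.stimuli:
        v_norm = piii_amplitude(stim.irradiance, stim.wavelength_nm, gp.params)
        template = _piii_waveform(time_s, 0.0, duration_s, nm.gain_uv * v_norm, nm.rebound_fraction)
        reps = template[None, :] + rng.normal(0.0, nm.trace_sigma_uv, (1, n))
        traces[stim.stimulus_index] = reps
    return SweepSet(
        sample_rate_hz=sample_rate_hz,
        time_s=time_s,
        traces=traces,
        subject_id=subject_id or f"{gp.name}-sweeps",
        age_class=gp.age_class,
        genotype_label=gp.name,
    )


def simulate_omr_counts(
    p_region3_before: float,
    p_region3_after: float,
    n: int,
    seed: int = 0,
) -> ContingencyTable2x2:
    """Binomial draw of optomotor plate counts before/after stimulation."""
    if not (0 <= p_region3_before <= 1 and 0 <= p_region3_after <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    before_3 = int(rng.binomial(n, p_region3_before))
    after_3 = int(rng.binomial(n, p_region3_after))
    return ContingencyTable2x2(
        before_regions_1_2=n - before_3,
        before_region_3=before_3,
        after_regions_1_2=n - after_3,
        after_region_3=after_3,
    )
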