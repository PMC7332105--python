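"""From raw ERG sweeps to a 70-row amplitude dataset.

A recording session yields 280 sweeps (10 wavelength blocks × 7 irradiance
steps × 4 replicate flashes) digitized at 2000 Hz.  The pipeline replicates
the original analysis order: replicates are averaged, the averaged trace is
noise-filtered with a 33-point (16.5 ms) running mean, and the PIII
trough-to-peak amplitude is measured — the vitreal-negative plateau during
the flash against the depolarizing rebound after stimulus offset.  The two
650-nm blocks index response stability over the recording; datasets whose
second-block maximum drifts outside a configurable band of the first are
flagged for exclusion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import SpectralProtocol

__all__ = [
    "PreprocessConfig",
    "SweepSet",
    "AmplitudeDataset",
    "average_replicates",
    "smooth_running_mean",
    "trough_to_peak",
    "stability_index",
    "build_amplitude_dataset",
]

#: Columns of the amplitude-dataset table (schema v1).
AMPLITUDE_COLUMNS = [
    "block_index",
    "wavelength_nm",
    "step_index",
    "log_irradiance",
    "amplitude",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing choices.

    The trough is searched from stimulus onset to 50 ms past offset and the
    rebound peak from offset to 500 ms past offset — windows chosen to
    bracket the PIII waveform (plateau during the 300-ms flash, rebound
    decaying within a few hundred ms).  The stability band accepts up to
    ±30 % drift between the two 650-nm blocks.
    """

    smoothing_window: int = 33
    trough_pad_s: float = 0.05
    peak_window_s: float = 0.5
    stability_band: tuple[float, float] = (0.7, 1.3)
    stability_min_fraction: float = 0.15
    expected_replicates: int = 4


@dataclass
class SweepSet:
    """Raw sweeps of one eye, keyed by protocol stimulus index.

    ``traces[stimulus_index]`` is a (n_replicates, n_samples) array of
    vitreal voltage in μV on the shared ``time_s`` axis; time 0 is stimulus
    onset.
    """

    sample_rate_hz: float
    time_s: np.ndarray
    traces: dict[int, np.ndarray]
    subject_id: str = ""
    age_class: str = "larva"
    genotype_label: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for idx, tr in self.traces.items():
            if tr.ndim != 2 or tr.shape[1] != n:
                raise ValueError(
                    f"stimulus {idx}: traces must be (replicates, {n}) arrays"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, voltage_uV, stimulus_index, sweep_id."""
        chunks = []
        for idx in sorted(self.traces):
            arr = self.traces[idx]
            for rep in range(arr.shape[0]):
                chunks.append(
                    pd.DataFrame(
                        {
                            "time_s": self.time_s,
                            "voltage_uV": arr[rep],
                            "stimulus_index": idx,
                            "sweep_id": f"s{idx:03d}r{rep}",
                        }
                    )
                )
        return pd.concat(chunks, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sample_rate_hz: float = 2000.0,
        **meta,
    ) -> "SweepSet":
        traces: dict[int, np.ndarray] = {}
        time_s: np.ndarray | None = None
        for idx, grp in frame.groupby("stimulus_index"):
            reps = []
            for _, rep_grp in grp.groupby("sweep_id"):
                rep_grp = rep_grp.sort_values("time_s")
                reps.append(rep_grp["voltage_uV"].to_numpy(float))
                if time_s is None:
                    time_s = rep_grp["time_s"].to_numpy(float)
            traces[int(idx)] = np.vstack(reps)
        assert time_s is not None, "empty sweep table"
        return cls(sample_rate_hz=sample_rate_hz, time_s=time_s, traces=traces, **meta)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "SweepSet":
        return cls.from_frame(pd.read_csv(path), **meta)


@dataclass
class AmplitudeDataset:
    """One eye's 70 trough-to-peak amplitudes plus stability metadata.

    ``frame`` has one row per (block, wavelength, step) combination; the two
    650-nm blocks appear separately but carry block-averaged amplitudes (see
    :func:`build_amplitude_dataset`).  ``stability_ratio`` is the 650-nm
    second-to-first block maximum ratio; ``excluded`` marks datasets whose
    ratio left the configured band.
    """

    frame: pd.DataFrame
    dataset_id: str = ""
    stability_ratio: float = float("nan")
    excluded: bool = False
    genotype_label: str = "unknown"
    age_class: str = "larva"
    missing_combos: tuple = ()

    def __post_init__(self) -> None:
        missing_cols = set(AMPLITUDE_COLUMNS) - set(self.frame.columns)
        if missing_cols:
            raise ValueError(f"amplitude table missing columns {sorted(missing_cols)}")
        if (self.frame["amplitude"] < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def complete(self) -> bool:
        return not self.missing_combos

    def max_amplitude(self) -> float:
        return float(self.frame["amplitude"].max())

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "dataset_id", self.dataset_id)
        out["stability_ratio"] = self.stability_ratio
        out["excluded"] = self.excluded
        out["genotype_label"] = self.genotype_label
        out["age_class"] = self.age_class
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AmplitudeDataset":
        tab = pd.read_csv(path)
        meta = {}
        if "dataset_id" in tab:
            meta["dataset_id"] = str(tab["dataset_id"].iloc[0])
        if "stability_ratio" in tab:
            meta["stability_ratio"] = float(tab["stability_ratio"].iloc[0])
        if "excluded" in tab:
            meta["excluded"] = bool(tab["excluded"].iloc[0])
        if "genotype_label" in tab:
            meta["genotype_label"] = str(tab["genotype_label"].iloc[0])
        if "age_class" in tab:
            meta["age_class"] = str(tab["age_class"].iloc[0])
        return cls(frame=tab[AMPLITUDE_COLUMNS].copy(), **meta)


# -- operations ---------------------------------------------------------------


def average_replicates(traces: np.ndarray, expected: int = 4) -> np.ndarray:
    """Pointwise mean across replicate sweeps.

    Warns (and averages what is present) when the replicate count differs
    from ``expected``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.shape[0] != expected:
        warnings.warn(
            f"expected {expected} replicates, got {traces.shape[0]}; averaging those present",
            stacklevel=2,
        )
    return traces.mean(axis=0)


def smooth_running_mean(trace: np.ndarray, window: int = 33) -> np.ndarray:
    """Centered running mean; edges shrink symmetrically to keep the length.

    At sample i the window half-width is min(h, i, n−1−i) with h = (window−1)/2,
    so output length equals input length and a constant trace is unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n <= window:
        raise ValueError(f"trace length {n} must exceed window {window}")
    h = window // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    half = np.minimum(h, np.minimum(i, n - 1 - i))
    lo = i - half
    hi = i + half + 1
    return (cs[hi] - cs[lo]) / (hi - lo)


def trough_to_peak(
    time_s: np.ndarray,
    voltage: np.ndarray,
    stim_onset_s: float,
    stim_offset_s: float,
    config: PreprocessConfig | None = None,
) -> float:
    """PIII trough-to-peak amplitude of one averaged, smoothed trace.

    amplitude = max(V in [offset, offset+peak_window]) −
                min(V in [onset, offset+trough_pad]), floored at zero.
    """
    cfg = config or PreprocessConfig()
    if stim_onset_s >= stim_offset_s:
        raise ValueError("stimulus onset must precede offset")
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(voltage, dtype=float)
    t_end = stim_offset_s + cfg.peak_window_s
    if t[0] > stim_onset_s + 1e-12 or t[-1] < t_end - 1e-12:
        raise ValueError(
            f"trace [{t[0]:.3f}, {t[-1]:.3f}] s does not cover the measurement "
            f"windows [{stim_onset_s:.3f}, {t_end:.3f}] s"
        )
    trough_mask = (t >= stim_onset_s) & (t <= stim_offset_s + cfg.trough_pad_s)
    peak_mask = (t >= stim_offset_s) & (t <= t_end)
    amplitude = float(v[peak_mask].max() - v[trough_mask].min())
    return max(amplitude, 0.0)


def stability_index(
    block_amplitudes: pd.DataFrame,
    stability_wavelength: int = 650,
    band: tuple[float, float] = (0.7, 1.3),
    min_index_fraction: float = 0.15,
) -> tuple[float, bool]:
    """Response-stability ratio from the repeated 650-nm blocks.

    ``block_amplitudes`` needs columns block_index, wavelength_nm, amplitude.
    Returns (ratio, excluded): ratio = max(second 650 block)/max(first);
    excluded is True when the ratio leaves ``band`` or the first-block
    maximum is zero (ratio undefined → NaN).

    The index only carries information when the indexing response is
    measurable: for eyes that barely respond at 650 nm (red-cone-less
    mutants) the ratio is noise over noise, so the screen is not applied
    when the first-block maximum falls below ``min_index_fraction`` of the
    dataset's overall peak (unless that peak is itself zero).
    """
    blocks = sorted(
        block_amplitudes.loc[
            block_amplitudes["wavelength_nm"] == stability_wavelength, "block_index"
        ].unique()
    )
    if len(blocks) < 2:
        raise ValueError(
            f"need two {stability_wavelength}-nm blocks for a stability index"
        )
    first, second = blocks[0], blocks[-1]
    sel = block_amplitudes["wavelength_nm"] == stability_wavelength
    max1 = float(
        block_amplitudes.loc[sel & (block_amplitudes["block_index"] == first), "amplitude"].max()
    )
    max2 = float(
        block_amplitudes.loc[sel & (block_amplitudes["block_index"] == second), "amplitude"].max()
    )
    overall_max = float(block_amplitudes["amplitude"].max())
    if max1 == 0:
        return float("nan"), True
    ratio = max2 / max1
    if overall_max > 0 and max1 < min_index_fraction * overall_max:
        return ratio, False  # indexing response too small to screen on
    return ratio, not (band[0] <= ratio <= band[1])


def build_amplitude_dataset(
    sweepset: SweepSet,
    protocol: SpectralProtocol,
    config: PreprocessConfig | None = None,
    dataset_id: str = "",
) -> AmplitudeDataset:
    """Run the full pipeline: average → smooth → trough-to-peak → stability.

    Emits one row per protocol combination (70 for the standard protocol).
    The duplicated 650-nm combinations are averaged across the two blocks
    *after* the stability index is computed, and both rows carry the
    averaged value.  Missing combinations are listed in ``missing_combos``.
    """
    cfg = config or PreprocessConfig()
    onset = 0.0
    offset = protocol.duration_ms / 1000.0

    # map (block, step) -> contiguous stimulus indices
    stim_by_combo: dict[tuple[int, int], list[int]] = {}
    for s in protocol.stimuli:
        stim_by_combo.setdefault((s.block_index, s.step_index), []).append(s.stimulus_index)

    rows = []
    missing = []
    for b, wl in enumerate(protocol.blocks):
        for step in range(1, protocol.n_steps + 1):
            idxs = stim_by_combo[(b, step)]
            present = [sweepset.traces[i] for i in idxs if i in sweepset.traces]
            if not present:
                missing.append((b, wl, step))
                continue
            stacked = np.vstack(present)
            mean = average_replicates(stacked, expected=cfg.expected_replicates)
            smoothed = smooth_running_mean(mean, cfg.smoothing_window)
            amp = trough_to_peak(sweepset.time_s, smoothed, onset, offset, cfg)
            rows.append(
                {
                    "block_index": b,
                    "wavelength_nm": wl,
                    "step_index": step,
                    "log_irradiance": protocol.log_irradiance(wl, step),
                    "amplitude": amp,
                }
            )
    frame = pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS)

    ratio, excluded = stability_index(
        frame, band=cfg.stability_band, min_index_fraction=cfg.stability_min_fraction
    )

    # average duplicated 650-nm combos across the two blocks
    dup = frame[frame["wavelength_nm"] == 650]
    if not dup.empty:
        means = dup.groupby("step_index")["amplitude"].mean()
        sel = frame["wavelength_nm"] == 650
        frame.loc[sel, "amplitude"] = frame.loc[sel, "step_index"].map(means).to_numpy()

    return AmplitudeDataset(
        frame=frame,
        dataset_id=dataset_id or sweepset.subject_id,
        stability_ratio=ratio,
        excluded=excluded,
        genotype_label=sweepset.genotype_label,
        age_class=sweepset.age_class,
        missing_combos=tuple(missing),
    )
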