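"""Spectral stimulus protocol for cone-PIII ERG recordings.

The protocol is a fixed 17-minute schedule of 280 monochromatic flashes:
ten wavelength blocks (650 nm delivered twice, as a response-stability
index), seven irradiance steps per block in 0.5 log-unit increments, and
four replicate flashes per step.  Irradiances are represented internally
as absolute log10 quantal irradiances, log(quanta·μm⁻²·s⁻¹), which is the
quantity the saturation model consumes; attenuation (neutral-density) units
are a display offset only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ProtocolError",
    "StimulusSpec",
    "SpectralProtocol",
    "default_protocol",
    "WAVELENGTH_BLOCKS",
    "MAX_LOG_IRRADIANCE",
]

#: Block delivery order; 650 nm repeats so that response stability over the
#: recording can be indexed by comparing the two blocks.
WAVELENGTH_BLOCKS: tuple[int, ...] = (650, 570, 490, 410, 330, 650, 610, 530, 450, 370)

#: Maximal (step 7) log10 quantal irradiance available at each wavelength.
MAX_LOG_IRRADIANCE: dict[int, float] = {
    650: 7.2,
    610: 6.3,
    570: 6.4,
    530: 6.3,
    490: 6.4,
    450: 6.1,
    410: 5.7,
    370: 5.7,
    330: 5.2,
}

N_STEPS = 7
STEP_LOG_UNITS = 0.5
N_REPLICATES = 4
FLASH_DURATION_MS = 300.0


class ProtocolError(ValueError):
    """Raised for unknown wavelengths or out-of-range irradiance steps."""


@dataclass(frozen=True)
class StimulusSpec:
    """One flash of the schedule.

    ``step_index`` runs 1 (dimmest) to 7 (brightest);
    ``log_irradiance`` = max_log(wavelength) − 0.5·(7 − step_index).
    """

    wavelength_nm: int
    step_index: int
    log_irradiance: float
    block_index: int
    stimulus_index: int
    onset_s: float
    duration_ms: float = FLASH_DURATION_MS
    replicate_count: int = N_REPLICATES

    @property
    def irradiance(self) -> float:
        """Linear quantal irradiance, quanta·μm⁻²·s⁻¹."""
        return 10.0 ** self.log_irradiance


@dataclass(frozen=True)
class SpectralProtocol:
    """The full flash schedule plus the per-wavelength irradiance calibration."""

    blocks: tuple[int, ...] = WAVELENGTH_BLOCKS
    max_log_irradiance: dict[int, float] = field(
        default_factory=lambda: dict(MAX_LOG_IRRADIANCE)
    )
    n_steps: int = N_STEPS
    step_log_units: float = STEP_LOG_UNITS
    replicate_count: int = N_REPLICATES
    duration_ms: float = FLASH_DURATION_MS

    def __post_init__(self) -> None:
        for wl in self.blocks:
            if wl not in self.max_log_irradiance:
                raise ProtocolError(f"block wavelength {wl} nm has no calibrated maximum")

    # -- irradiance arithmetic -------------------------------------------------

    def log_irradiance(self, wavelength_nm: int, step_index: int) -> float:
        if wavelength_nm not in self.max_log_irradiance:
            raise ProtocolError(f"unknown wavelength {wavelength_nm} nm")
        if not 1 <= step_index <= self.n_steps:
            raise ProtocolError(
                f"step_index {step_index} outside 1..{self.n_steps}"
            )
        return self.max_log_irradiance[wavelength_nm] - self.step_log_units * (
            self.n_steps - step_index
        )

    def irradiance_of(self, wavelength_nm: int, step_index: int) -> float:
        """Linear quantal irradiance for one (wavelength, step) combination."""
        return 10.0 ** self.log_irradiance(wavelength_nm, step_index)

    # -- schedule --------------------------------------------------------------

    @property
    def combo_count(self) -> int:
        return len(self.blocks) * self.n_steps

    @property
    def stimuli(self) -> tuple[StimulusSpec, ...]:
        """All flashes in delivery order (blocks × steps × replicates)."""
        out: list[StimulusSpec] = []
        onset = 0.0
        idx = 0
        for b, wl in enumerate(self.blocks):
            for step in range(1, self.n_steps + 1):
                # brighter flashes are separated by longer dark intervals
                interval = 2.5 + 0.5 * (step - 1)
                for _ in range(self.replicate_count):
                    out.append(
                        StimulusSpec(
                            wavelength_nm=wl,
                            step_index=step,
                            log_irradiance=self.log_irradiance(wl, step),
                            block_index=b,
                            stimulus_index=idx,
                            onset_s=onset,
                            duration_ms=self.duration_ms,
                            replicate_count=self.replicate_count,
                        )
                    )
                    idx += 1
                    onset += self.duration_ms / 1000.0 + interval
        return tuple(out)

    def combos(self) -> pd.DataFrame:
        """One row per (block, wavelength, step) combination (70 rows)."""
        rows = [
            {
                "block_index": b,
                "wavelength_nm": wl,
                "step_index": step,
                "log_irradiance": self.log_irradiance(wl, step),
            }
            for b, wl in enumerate(self.blocks)
            for step in range(1, self.n_steps + 1)
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Flash-level schedule (280 rows) for CSV export."""
        return pd.DataFrame(
            {
                "stimulus_index": s.stimulus_index,
                "block_index": s.block_index,
                "wavelength_nm": s.wavelength_nm,
                "step_index": s.step_index,
                "log_irradiance": s.log_irradiance,
                "onset_s": s.onset_s,
            }
            for s in self.stimuli
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    # -- config round-trip -----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "blocks": list(self.blocks),
            "max_log_irradiance": {int(k): float(v) for k, v in self.max_log_irradiance.items()},
            "n_steps": self.n_steps,
            "step_log_units": self.step_log_units,
            "replicate_count": self.replicate_count,
            "duration_ms": self.duration_ms,
        }

    def save_config(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))

    @classmethod
    def from_config(cls, cfg: dict) -> "SpectralProtocol":
        return cls(
            blocks=tuple(cfg["blocks"]),
            max_log_irradiance={int(k): float(v) for k, v in cfg["max_log_irradiance"].items()},
            n_steps=int(cfg.get("n_steps", N_STEPS)),
            step_log_units=float(cfg.get("step_log_units", STEP_LOG_UNITS)),
            replicate_count=int(cfg.get("replicate_count", N_REPLICATES)),
            duration_ms=float(cfg.get("duration_ms", FLASH_DURATION_MS)),
        )

    @classmethod
    def load_config(cls, path: str | Path) -> "SpectralProtocol":
        return cls.from_config(yaml.safe_load(Path(path).read_text()))


def default_protocol() -> SpectralProtocol:
    """The standard 280-flash schedule with the calibrated irradiance maxima."""
    return SpectralProtocol()
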