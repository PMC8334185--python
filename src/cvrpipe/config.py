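"""Pipeline configuration and the parcellation container.

The configuration gathers every constant of the acquisition and analysis
protocol in one place: the EPI repetition time, how many equilibration
volumes to discard, the polynomial detrend order, the voxelwise probability
threshold and family-wise alpha for cluster correction, the number of
Monte-Carlo iterations, and the delay search window.  Defaults reflect the
protocol this package models: TR = 1.25 s, 12 discarded volumes, 5th-order
detrend, voxel p < 0.005 corrected to alpha < 0.05 with 2000 Monte-Carlo
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Parameters
    ----------
    sampling_rate_physio : float
        Sampling rate of the gas/flow recordings in Hz.  The recording
        hardware rate is not a protocol constant; 100 Hz is a configurable
        assumption.
    tr : float
        BOLD repetition time in seconds.
    n_discard_volumes : int
        Initial volumes dropped before equilibrium magnetization.
    detrend_order : int
        Order of the Legendre polynomial drift model.
    voxel_p : float
        Voxelwise two-sided probability threshold.
    alpha : float
        Family-wise significance level for cluster-extent correction.
    n_mc_iterations : int
        Monte-Carlo iterations for the cluster-extent simulation.
    lag_search_window : float
        Half-width in seconds of the admissible BOLD response delay range.
        Must stay below half the paradigm period to avoid phase wrapping.
    band : tuple of float
        Pass band (Hz) retaining the paradigm fundamental and first
        harmonic for the analytic-signal analysis.
    r_at : str
        ``"peak"`` signs the analytic coupling magnitude with the zero-lag
        correlation sign; ``"zero"`` reports the plain zero-lag correlation.
    connectivity : int
        Cluster connectivity: 6 (faces), 18 (+edges) or 26 (+corners).
    rng_seed : int
        Seed for every stochastic step (Monte-Carlo null, simulation).
    """

    sampling_rate_physio: float = 100.0
    tr: float = 1.25
    n_discard_volumes: int = 12
    detrend_order: int = 5
    voxel_p: float = 0.005
    alpha: float = 0.05
    n_mc_iterations: int = 2000
    lag_search_window: float = 20.0
    band: tuple[float, float] = (0.004, 0.02)
    delay_band: tuple[float, float] = (0.0, 0.12)
    r_at: str = "peak"
    connectivity: int = 6
    max_technical_lag: float = 5.0
    min_breath_duration: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ConfigError("tr must be positive")
        if not (0.0 < self.voxel_p < self.alpha < 1.0):
            raise ConfigError(
                f"need 0 < voxel_p < alpha < 1, got voxel_p={self.voxel_p}, "
                f"alpha={self.alpha}"
            )
        if self.n_discard_volumes < 0:
            raise ConfigError("n_discard_volumes must be >= 0")
        if self.detrend_order < 0:
            raise ConfigError("detrend_order must be >= 0")
        if self.sampling_rate_physio <= 0:
            raise ConfigError("sampling_rate_physio must be positive")
        if not (0.0 < self.band[0] < self.band[1]):
            raise ConfigError("band must satisfy 0 < low < high")
        if not (0.0 <= self.delay_band[0] < self.delay_band[1]):
            raise ConfigError("delay_band must satisfy 0 <= low < high")
        if self.r_at not in ("peak", "zero"):
            raise ConfigError("r_at must be 'peak' or 'zero'")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw = dict(raw)
        for key in ("band", "delay_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["band"] = list(data["band"])
        data["delay_band"] = list(data["delay_band"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class ParcellationVolume:
    """Integer-labelled brain parcellation.

    ``labels`` is a 3-D integer volume; label 0 is reserved for background.
    ``lookup`` maps every nonzero label to a region name.  ``voxel_dims``
    are the voxel edge lengths in mm.
    """

    labels: np.ndarray
    lookup: dict[int, str]
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ConfigError("parcellation labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigError("parcellation labels must be integers")
        if any(d <= 0 for d in self.voxel_dims):
            raise ConfigError("voxel_dims must be strictly positive")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ConfigError(
                f"labels missing from lookup table: {sorted(missing)[:10]}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    @property
    def region_labels(self) -> list[int]:
        """Sorted nonzero labels actually present in the volume."""
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)
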