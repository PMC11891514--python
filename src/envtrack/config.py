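"""Run configuration for envelope-tracking analyses.

All defaults reproduce the standard analysis settings: delta--gamma bands
plus a broad band, acquisition at 8192 Hz, an intermediate processing rate
of 512 Hz, an analysis rate of 128 Hz, a -200..500 ms lag window with a
0..400 ms integration window, 1000 surrogate permutations and a 1..25 min
cropping grid.  An empty YAML file therefore yields the canonical analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 49.0),
    "broad": (0.5, 49.0),
}

#: The five narrow bands used as classifier features (broad excluded).
FEATURE_BANDS = ("delta", "theta", "alpha", "beta", "gamma")

# 22-channel fronto-central + parieto-occipital selection (10-20 labels of
# the BioSemi-64 cap).  The exact montage subset is a documented,
# overridable default: frontal/central midline and surround plus a
# parieto-occipital arc.
DEFAULT_CHANNEL_SELECTION: tuple[str, ...] = (
    # fronto-central
    "Fz", "F1", "F2", "F3", "F4", "FCz", "FC1", "FC2", "FC3", "FC4",
    "Cz", "C1", "C2",
    # parieto-occipital
    "Pz", "P1", "P2", "P3", "P4", "POz", "PO3", "PO4", "Oz",
)


def _nyquist(rate: float) -> float:
    return rate / 2.0


@dataclass
class AnalysisConfig:
    """Settings shared by every stage of the analysis."""

    band_definitions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_BANDS.items()}
    )
    acquisition_rate: float = 8192.0
    intermediate_rate: float = 512.0
    analysis_rate: float = 128.0
    lag_window_ms: tuple[float, float] = (-200.0, 500.0)
    integration_window_ms: tuple[float, float] = (0.0, 400.0)
    n_null_permutations: int = 1000
    n_cluster_permutations: int = 1000
    cluster_alpha: float = 0.05
    channel_selection: tuple[str, ...] = DEFAULT_CHANNEL_SELECTION
    crop_grid_minutes: tuple[float, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25)
    global_seed: int = 0
    # Estimator options (documented defaults; see docs/methods.md)
    null_statistic: str = "mean_mi"  # or "peak_mi"
    copula_per_lag: bool = True
    restandardize_after_downsample: bool = False
    cluster_stat: str = "welch"  # or "ranksum"
    mc_correction: str = "holm"  # or "bonferroni", "fdr_bh"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.intermediate_rate % self.analysis_rate != 0:
            raise ValueError(
                "analysis rate must divide the intermediate rate; got "
                f"{self.analysis_rate} / {self.intermediate_rate}"
            )
        nyq = _nyquist(self.analysis_rate)
        for name, (lo, hi) in self.band_definitions.items():
            if not (0.0 < lo < hi <= nyq):
                raise ValueError(
                    f"band {name!r}=({lo}, {hi}) violates 0 < low < high <= "
                    f"Nyquist({self.analysis_rate} Hz) = {nyq} Hz"
                )
        lo, hi = self.lag_window_ms
        if not lo < hi:
            raise ValueError(f"lag window {self.lag_window_ms} must be increasing")
        ilo, ihi = self.integration_window_ms
        if not (lo <= ilo < ihi <= hi):
            raise ValueError(
                f"integration window {self.integration_window_ms} must lie "
                f"inside the lag window {self.lag_window_ms}"
            )
        for nm, n in [("n_null_permutations", self.n_null_permutations),
                      ("n_cluster_permutations", self.n_cluster_permutations)]:
            if int(n) < 1:
                raise ValueError(f"{nm} must be >= 1")
        if not 0.0 < self.cluster_alpha < 1.0:
            raise ValueError("cluster_alpha must be a probability in (0, 1)")
        if list(self.crop_grid_minutes) != sorted(set(self.crop_grid_minutes)):
            raise ValueError("crop grid must be strictly increasing")
        if self.null_statistic not in ("mean_mi", "peak_mi"):
            raise ValueError("null_statistic must be 'mean_mi' or 'peak_mi'")

    # -- lag grid -----------------------------------------------------------
    def lag_samples(self) -> np.ndarray:
        """Sample shifts covering the lag window at the analysis rate.

        The window edges are rounded outward so that the grid covers the
        full stated window: [-200, 500] ms at 128 Hz gives shifts -26..64.
        """
        lo = int(np.floor(self.lag_window_ms[0] * self.analysis_rate / 1000.0))
        hi = int(np.ceil(self.lag_window_ms[1] * self.analysis_rate / 1000.0))
        return np.arange(lo, hi + 1)

    def lags_ms(self) -> np.ndarray:
        return self.lag_samples() * 1000.0 / self.analysis_rate

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_definitions"] = {k: list(v) for k, v in self.band_definitions.items()}
        return d

    def config_hash(self) -> str:
        """Stable content hash (key order independent)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "band_definitions" in kwargs:
            kwargs["band_definitions"] = {
                k: tuple(float(x) for x in v)
                for k, v in kwargs["band_definitions"].items()
            }
        for key in ("lag_window_ms", "integration_window_ms", "crop_grid_minutes",
                    "channel_selection"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def derive_seed(global_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Deterministically derive a child seed for a named stage/subject.

    String keys are hashed to integers so that seeding is independent of
    dict ordering or subject insertion order.
    """
    spawn = []
    for k in keys:
        if isinstance(k, str):
            spawn.append(int.from_bytes(hashlib.sha256(k.encode()).digest()[:4], "little"))
        else:
            spawn.append(int(k))
    return np.random.SeedSequence(int(global_seed), spawn_key=tuple(spawn))


def rng_for(global_seed: int, *keys: int | str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, *keys))
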