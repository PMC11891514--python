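"""EEG conditioning from the band-filtering step onward.

Input EEG is assumed artefact-cleaned and at the intermediate rate
(512 Hz).  Conditioning mirrors the envelope path exactly: common-average
reference, the same least-squares band filters, per-channel z-scoring and
anti-alias downsampling to the analysis rate (128 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import match_channels
from .envelope import apply_band_filter, design_band_filter, downsample, zscore
from .io import EEGRecording


@dataclass
class EEGBand:
    """Band-filtered, referenced, z-scored EEG at the analysis rate."""

    data: np.ndarray  # channels x samples
    rate: float
    band: str
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must equal the number of channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def crop(self, seconds: float) -> "EEGBand":
        n = int(round(seconds * self.rate))
        if n > self.n_samples:
            raise ValueError("crop longer than the recording")
        return EEGBand(self.data[:, :n], self.rate, self.band, list(self.channel_names))


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def condition_eeg(
    rec: EEGRecording,
    band: str | tuple[float, float],
    rate_out: float = 128.0,
    band_name: str | None = None,
    reference: bool = True,
    restandardize: bool = False,
) -> EEGBand:
    """Reference -> band filter -> z-score -> downsample, per channel."""
    data = rec.data
    if reference:
        data = common_average_reference(data)
    spec = design_band_filter(band, rec.rate, band_name=band_name)
    y = apply_band_filter(data, spec)
    y = zscore(y, axis=-1)
    y = downsample(y, rec.rate, rate_out)
    if restandardize:
        y = zscore(y, axis=-1)
    return EEGBand(y, rate_out, spec.band, list(rec.channel_names))


def select_channels(eeg_band: EEGBand, selection: list[str]) -> EEGBand:
    """Subset and reorder channels to the requested selection (matched
    case-insensitively, BioSemi A/B aliases accepted)."""
    idx = match_channels(eeg_band.channel_names, list(selection))
    return EEGBand(
        eeg_band.data[idx],
        eeg_band.rate,
        eeg_band.band,
        [eeg_band.channel_names[i] for i in idx],
    )
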