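"""Synthetic envelopes, subjects and two-group cohorts.

Generative model (the minimal model under which every downstream stage has
known expected behaviour): the EEG is the band-filtered stimulus envelope
convolved with a two-peaked response kernel (peaks near 50 and 170 ms),
projected onto channels through a smooth fronto-central topography, plus
1/f Gaussian noise.  The "aphasia" group attenuates the second kernel peak
multiplicatively in the delta, theta and gamma bands (the bands with
reported group differences); alpha and beta kernels are identical across
groups.  Subjects additionally carry a log-normal tracking-strength gain so
that between-subject reliability analyses have true variance to resolve.

Per-band signal-to-noise ratios are quoted at the topography peak for a
unit-gain subject, and default to values decreasing with frequency,
emulating the lower SNR of high-frequency EEG under 1/f noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .channels import frontocentral_gain, spread_subset
from .config import FEATURE_BANDS, DEFAULT_BANDS, derive_seed
from .envelope import apply_band_filter, design_band_filter
from .io import EEGRecording, SubjectRecord

DEFAULT_SNR_DB: dict[str, float] = {
    "delta": 2.0, "theta": 1.0, "alpha": -2.0, "beta": -4.0, "gamma": -5.0,
}
#: Default second-peak attenuation for the aphasia group (1 = no effect).
DEFAULT_EFFECT: dict[str, float] = {
    "delta": 0.5, "theta": 0.5, "alpha": 1.0, "beta": 1.0, "gamma": 0.5,
}


@dataclass
class ResponseKernel:
    """Two-peaked envelope-response kernel (ERP-like latencies, ms)."""

    peak1_latency: float = 50.0
    peak2_latency: float = 170.0
    peak1_width: float = 15.0
    peak2_width: float = 30.0
    peak1_amplitude: float = 0.5
    peak2_amplitude: float = 1.0
    support_ms: float = 400.0

    def __post_init__(self) -> None:
        if not 0 <= self.peak1_latency < self.peak2_latency:
            raise ValueError("peak latencies must satisfy 0 <= peak1 < peak2")
        if self.support_ms > 500.0:
            raise ValueError("kernel support must stay within [0, 500] ms")

    def sample(self, rate: float, peak2_scale: float = 1.0) -> np.ndarray:
        """Kernel amplitudes on a causal [0, support] ms grid; the second
        peak is scaled by ``peak2_scale`` (group attenuation)."""
        if not 0.0 <= peak2_scale <= 1.0:
            raise ValueError("peak2_scale must be in [0, 1]")
        t = np.arange(0.0, self.support_ms, 1000.0 / rate)
        k1 = self.peak1_amplitude * np.exp(-0.5 * ((t - self.peak1_latency) / self.peak1_width) ** 2)
        k2 = self.peak2_amplitude * np.exp(-0.5 * ((t - self.peak2_latency) / self.peak2_width) ** 2)
        return k1 + peak2_scale * k2


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_control: int = 22
    n_aphasia: int = 26
    duration_min: float = 25.0
    n_channels: int = 64
    rate: float = 512.0
    snr_db: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SNR_DB))
    effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    kernel: ResponseKernel = field(default_factory=ResponseKernel)
    subject_gain_sd: float = 0.3  # log-sd of the per-subject tracking gain
    bands: tuple[str, ...] = FEATURE_BANDS  # bands carrying envelope response
    age_mean: float = 72.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (40.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_aphasia) < 1:
            raise ValueError("counts must be >= 1")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        for band, e in self.effect.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"effect[{band!r}]={e} outside [0, 1]")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return spread_subset(self.n_channels)


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def gen_envelope(duration_s: float, rate: float = 512.0,
                 seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Story-like stimulus envelope: nonnegative, with a syllable-rate
    (3--5 Hz) modulation bump, built by rectifying filtered noise."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    white = rng.standard_normal(n)
    syllabic = sps.sosfilt(sps.butter(4, [2.5, 5.5], "bandpass", fs=rate, output="sos"), white)
    slow = sps.sosfilt(sps.butter(4, 1.5, "lowpass", fs=rate, output="sos"), white)
    fast = sps.sosfilt(sps.butter(2, [6.0, 30.0], "bandpass", fs=rate, output="sos"), white)
    x = syllabic / syllabic.std() + 0.7 * slow / slow.std() + 0.25 * fast / fast.std()
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

_F_FLOOR = 0.1  # Hz; keeps the 1/f spectrum integrable


def one_over_f_noise(n_channels: int, n_samples: int, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectral density ~ 1/f."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    spec *= 1.0 / np.sqrt(np.maximum(freqs, _F_FLOOR))
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _inband_noise_fraction(band: tuple[float, float], rate: float) -> float:
    """Fraction of 1/f noise power falling inside a band (analytic)."""
    lo = max(band[0], _F_FLOOR)
    hi = min(band[1], rate / 2.0)
    total = np.log((rate / 2.0) / _F_FLOOR) + 1.0  # flat below the floor
    return float(np.log(hi / lo) / total)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def _band_components(envelope: np.ndarray, kernel: ResponseKernel, rate: float,
                     bands: dict[str, tuple[float, float]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per band: (first-peak component, second-peak component) of the
    envelope response, i.e. band-filtered envelope convolved with each
    kernel peak separately so group attenuation can scale the second."""
    out = {}
    k1 = kernel.sample(rate, peak2_scale=0.0)
    k2 = kernel.sample(rate) - k1
    for name, edges in bands.items():
        spec = design_band_filter(edges, rate, band_name=name)
        benv = apply_band_filter(envelope - envelope.mean(), spec)
        c1 = sps.oaconvolve(benv, k1, mode="full")[: benv.size]
        c2 = sps.oaconvolve(benv, k2, mode="full")[: benv.size]
        out[name] = (c1, c2)
    return out


def gen_subject_eeg(
    envelope: np.ndarray,
    kernel: ResponseKernel,
    spec: CohortSpec,
    group: str,
    seed: int | np.random.SeedSequence,
    components: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    gain: float = 1.0,
) -> EEGRecording:
    """One subject's EEG: per-band envelope responses projected through the
    fronto-central topography plus 1/f noise at the per-band SNR."""
    rate = spec.rate
    n = envelope.size
    kernel_len = kernel.sample(rate).size
    if kernel_len > n:
        raise ValueError("kernel longer than the envelope")
    if components is None:
        bands = {b: DEFAULT_BANDS[b] for b in spec.bands}
        components = _band_components(envelope, kernel, rate, bands)
    names = list(spec.channel_names)
    topo = frontocentral_gain(names)
    rng = np.random.default_rng(seed)
    noise = one_over_f_noise(len(names), n, rate, rng)
    signal_sum = np.zeros(n)
    for band, (c1, c2) in components.items():
        s = spec.effect.get(band, 1.0) if group == "aphasia" else 1.0
        if np.isinf(spec.snr_db.get(band, 0.0)):  # noise-free band
            scale = 1.0
        else:
            # calibrate against the unattenuated (control) in-band power
            p_noise = _inband_noise_fraction(DEFAULT_BANDS[band], rate)
            p_sig = np.var(c1 + c2)
            scale = np.sqrt(p_noise * 10.0 ** (spec.snr_db.get(band, 0.0) / 10.0) / p_sig)
        signal_sum += scale * (c1 + s * c2)
    noise_free = all(np.isinf(v) for v in spec.snr_db.values())
    data = gain * topo[:, None] * signal_sum[None, :]
    if not noise_free:
        data = data + noise
    return EEGRecording(data, names, rate)


@dataclass
class Cohort:
    """Generated cohort: shared stimulus plus per-subject recordings."""

    spec: CohortSpec
    envelope: np.ndarray
    subjects: list[SubjectRecord]

    @property
    def rate(self) -> float:
        return self.spec.rate

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full two-group cohort (deterministic given ``spec.seed``).

    All subjects hear the same story envelope; per-subject seeds are
    derived from the cohort seed by counter.
    """
    env = gen_envelope(spec.duration_min * 60.0, spec.rate, derive_seed(spec.seed, "stimulus"))
    bands = {b: DEFAULT_BANDS[b] for b in spec.bands}
    components = _band_components(env, spec.kernel, spec.rate, bands)
    meta_rng = np.random.default_rng(derive_seed(spec.seed, "metadata"))
    subjects: list[SubjectRecord] = []
    groups = ["control"] * spec.n_control + ["aphasia"] * spec.n_aphasia
    for i, group in enumerate(groups):
        age = _truncated_normal(meta_rng, spec.age_mean, spec.age_sd, spec.age_range)
        gain = float(np.exp(meta_rng.normal(0.0, spec.subject_gain_sd)))
        rec = gen_subject_eeg(env, spec.kernel, spec, group,
                              derive_seed(spec.seed, "subject", i),
                              components=components, gain=gain)
        subjects.append(SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            group=group,
            age=age,
            eeg=rec,
            seed=i,
            extras={"gain": gain},
        ))
    return Cohort(spec=spec, envelope=env, subjects=subjects)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    while True:
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
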