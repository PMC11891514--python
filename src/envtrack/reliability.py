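"""Recording-length and reliability analyses.

* Cropping: TMIFs recomputed on the leading 1, 3, 5, ... minutes of the
  conditioned recordings (cropping happens at the analysis rate, after
  filtering, so short crops are not contaminated by filter transients).
* Within-subject stability: ICC between each cropped TMIF and the
  full-recording TMIF over lag bins, averaged across subjects.
* Between-subject stability: ICC across subjects between cropped-duration
  mean MI (0--400 ms) and full-duration mean MI.
* Knee point: Kneedle on the normalized concave-increasing curve
  (sensitivity 1, no smoothing or interpolation).
* Split-half reliability: one-way random-effects, single-rater ICC(1,1)
  between the mean MI of the first and second half of the recording, per
  band and group, with F-based confidence intervals, Holm-corrected
  p-values, and Fisher-z group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .envelope import BandEnvelope
from .mi import TMIF, compute_tmif, mean_mi
from .preprocess import EEGBand


# ---------------------------------------------------------------------------
# one-way random-effects ICC
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    p_value: float
    n_targets: int
    n_raters: int


def icc_oneway(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(1,1): one-way random effects, single rater.

    ``data`` is targets x raters (e.g. subjects x two recording halves, or
    lag bins x two TMIFs).  CI and p come from the one-way ANOVA F ratio.
    """
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 targets and 2 raters")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((Y - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise ValueError("constant data: ICC undefined")
    if msw == 0:  # identical raters
        return ICCResult(1.0, (1.0, 1.0), 0.0, n, k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    F = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    p = float(stats.f.sf(F, df1, df2))
    fl = F / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = F * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return ICCResult(float(icc), (float(ci[0]), float(ci[1])), p, n, k)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided z test comparing two correlation-type coefficients via the
    Fisher transform with variance 1/(n-3) per group."""
    if min(n1, n2) < 4:
        raise ValueError("need at least 4 observations per group")
    clip = 1.0 - 1e-12
    z1, z2 = np.arctanh(np.clip(r1, -clip, clip)), np.arctanh(np.clip(r2, -clip, clip))
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def bonferroni_correction(p_values: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p_values, dtype=float) * p_values.size, 1.0)


# ---------------------------------------------------------------------------
# knee point (Kneedle)
# ---------------------------------------------------------------------------

@dataclass
class KneeResult:
    knee: float
    found: bool
    index: int


def knee_point(x: np.ndarray, y: np.ndarray, sensitivity: float = 1.0) -> KneeResult:
    """Kneedle knee detection for concave, increasing curves.

    Both axes are min-max normalized; the difference curve ``y_n - x_n`` is
    scanned for local maxima, and a knee is declared at the first local
    maximum whose difference value is not re-crossed before the next local
    maximum (threshold = local max - sensitivity * mean x-spacing).  If no
    knee exists (e.g. a straight line) the last grid point is returned with
    ``found=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    xn = (x - x[0]) / (x[-1] - x[0])
    span = np.ptp(y)
    if span == 0:
        return KneeResult(float(x[-1]), False, x.size - 1)
    yn = (y - y.min()) / span
    yd = yn - xn
    n = yd.size
    lmx = [i for i in range(1, n - 1) if yd[i] > yd[i - 1] and yd[i] >= yd[i + 1]]
    if not lmx:
        return KneeResult(float(x[-1]), False, n - 1)
    t_step = sensitivity * np.mean(np.diff(xn))
    lmx_set = set(lmx)
    for start in lmx:
        threshold = yd[start] - t_step
        for j in range(start + 1, n):
            if j in lmx_set:
                break
            if yd[j] < threshold:
                return KneeResult(float(x[start]), True, start)
        else:
            # curve ends while still above threshold: accept the last
            # candidate only if it is the global maximum of the difference
            if yd[start] >= yd.max() - 1e-12:
                return KneeResult(float(x[start]), True, start)
    return KneeResult(float(x[lmx[0]]), True, lmx[0])


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_and_tmif(
    eeg_band: EEGBand,
    env: BandEnvelope,
    minutes_grid: list[float],
    variant: str = "multivariate",
    lag_window_ms: tuple[float, float] = (-200.0, 500.0),
) -> dict[float, TMIF]:
    """TMIF on the leading crop of each duration (identical settings)."""
    full_s = eeg_band.n_samples / eeg_band.rate
    out = {}
    for minutes in minutes_grid:
        seconds = minutes * 60.0
        if seconds > full_s + 1e-9:
            raise ValueError(f"crop of {minutes} min exceeds the {full_s / 60:.2f} min recording")
        out[minutes] = compute_tmif(
            eeg_band.crop(min(seconds, full_s)), env.crop(min(seconds, full_s)),
            lag_window_ms, variant,
        )
    return out


# ---------------------------------------------------------------------------
# stability curves
# ---------------------------------------------------------------------------

@dataclass
class StabilityCurve:
    minutes: np.ndarray
    values: np.ndarray
    curve_kind: str  # "svm_performance" | "within_subject" | "between_subject"
    band: str = ""
    knee_minutes: float = float("nan")
    knee_found: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("minutes grid must be strictly increasing")

    def detect_knee(self) -> "StabilityCurve":
        if self.minutes.size == 1:
            self.knee_minutes, self.knee_found = float(self.minutes[0]), True
            return self
        if self.minutes.size == 2:  # no curvature to speak of
            self.knee_minutes, self.knee_found = float(self.minutes[-1]), False
            return self
        res = knee_point(self.minutes, self.values)
        self.knee_minutes, self.knee_found = res.knee, res.found
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "minutes": self.minutes, "value": self.values,
            "curve_kind": self.curve_kind, "band": self.band,
        })


def _pair_icc(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(1,1) between two paired vectors; NaN when degenerate."""
    try:
        return icc_oneway(np.column_stack([a, b])).icc
    except ValueError:
        warnings.warn("constant pair: ICC recorded as missing", stacklevel=2)
        return float("nan")


def within_subject_stability(
    cropped: dict[str, dict[float, list[TMIF]]],
    full: dict[str, list[TMIF]],
) -> dict[str, StabilityCurve]:
    """Mean-over-subjects ICC between cropped and full TMIFs per band.

    ``cropped[band][minutes]`` is a list of per-subject TMIFs; ``full[band]``
    the matching full-recording TMIFs.  Returns one curve per band plus an
    ``"average"`` curve (across bands) carrying the knee point.
    """
    curves: dict[str, StabilityCurve] = {}
    for band, per_minute in cropped.items():
        minutes = sorted(per_minute)
        values = []
        for m in minutes:
            iccs = [
                _pair_icc(t.channel_average(), f.channel_average())
                for t, f in zip(per_minute[m], full[band])
            ]
            values.append(np.nanmean(iccs))
        curves[band] = StabilityCurve(minutes, values, "within_subject", band)
    bands = list(curves)
    avg = np.mean([curves[b].values for b in bands], axis=0)
    curves["average"] = StabilityCurve(
        curves[bands[0]].minutes, avg, "within_subject", "average"
    ).detect_knee()
    return curves


def between_subject_stability(
    mean_mi_by_duration: dict[str, dict[float, np.ndarray]],
    mean_mi_full: dict[str, np.ndarray],
) -> dict[str, StabilityCurve]:
    """ICC across subjects between cropped and full mean MI per band."""
    curves: dict[str, StabilityCurve] = {}
    for band, per_minute in mean_mi_by_duration.items():
        full_vals = np.asarray(mean_mi_full[band], dtype=float)
        if full_vals.size < 3:
            raise ValueError("need at least 3 subjects")
        minutes = sorted(per_minute)
        values = [_pair_icc(np.asarray(per_minute[m], dtype=float), full_vals)
                  for m in minutes]
        curves[band] = StabilityCurve(minutes, values, "between_subject", band)
    bands = list(curves)
    avg = np.mean([curves[b].values for b in bands], axis=0)
    curves["average"] = StabilityCurve(
        curves[bands[0]].minutes, avg, "between_subject", "average"
    ).detect_knee()
    return curves


def performance_vs_time(
    features_by_duration: dict[float, "FeatureMatrix"],
    labels: list[str],
    seed: int = 0,
    **cv_kwargs,
) -> StabilityCurve:
    """Nested-CV classifier performance per recording duration."""
    from .classify import nested_cv_svm

    minutes = sorted(features_by_duration)
    acc, f1, auc = [], [], []
    for m in minutes:
        rep = nested_cv_svm(features_by_duration[m], labels, seed=seed, **cv_kwargs)
        acc.append(rep.accuracy)
        f1.append(rep.f1)
        auc.append(rep.auc)
    curve = StabilityCurve(minutes, acc, "svm_performance",
                           extras={"f1": np.asarray(f1), "auc": np.asarray(auc)})
    return curve.detect_knee()


# ---------------------------------------------------------------------------
# split-half reliability
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfReport:
    table: pd.DataFrame  # per band x group: icc, ci_low, ci_high, p, p_corrected
    fisher: pd.DataFrame  # per band: z, p, p_corrected

    def to_frame(self) -> pd.DataFrame:
        return self.table


def split_half_mean_mi(
    eeg_band: EEGBand,
    env: BandEnvelope,
    window_ms: tuple[float, float] = (0.0, 400.0),
    lag_window_ms: tuple[float, float] = (-200.0, 500.0),
) -> tuple[float, float]:
    """Mean MI (integration window) of each half of the recording."""
    half_s = eeg_band.n_samples / eeg_band.rate / 2.0
    n_half = int(eeg_band.n_samples // 2)
    first = compute_tmif(eeg_band.crop(half_s), env.crop(half_s), lag_window_ms)
    eeg2 = EEGBand(eeg_band.data[:, n_half:2 * n_half], eeg_band.rate,
                   eeg_band.band, list(eeg_band.channel_names))
    env2 = BandEnvelope(env.samples[n_half:2 * n_half], env.rate, env.band, env.passband)
    second = compute_tmif(eeg2, env2, lag_window_ms)
    return mean_mi(first, window_ms), mean_mi(second, window_ms)


def split_half_icc(
    halves: dict[str, dict[str, np.ndarray]],
    correction: str = "holm",
) -> SplitHalfReport:
    """ICC(1,1) between first- and second-half mean MI.

    ``halves[band][group]`` is an (n_subjects, 2) array.  All ICC p-values
    are corrected jointly; Fisher-z group comparisons are corrected as
    their own family.
    """
    correct = {"holm": holm_correction, "bonferroni": bonferroni_correction}.get(correction)
    if correct is None:
        raise ValueError(f"unknown correction {correction!r}")
    rows, fisher_rows = [], []
    for band, by_group in halves.items():
        res = {}
        for group, mat in by_group.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape[0] < 3:
                raise ValueError(f"group {group!r} has fewer than 3 subjects")
            res[group] = icc_oneway(mat)
            rows.append({
                "band": band, "group": group, "icc": res[group].icc,
                "ci_low": res[group].ci[0], "ci_high": res[group].ci[1],
                "p": res[group].p_value, "n": res[group].n_targets,
            })
        if len(res) == 2:
            (g1, r1), (g2, r2) = res.items()
            z, p = fisher_z_compare(r1.icc, r1.n_targets, r2.icc, r2.n_targets)
            fisher_rows.append({"band": band, "groups": f"{g1}-{g2}", "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_corrected"] = correct(table["p"].to_numpy())
    fisher = pd.DataFrame(fisher_rows)
    if not fisher.empty:
        fisher["p_corrected"] = correct(fisher["p"].to_numpy())
    return SplitHalfReport(table, fisher)
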