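"""Cluster-based permutation tests for group differences in TMIFs.

Temporal variant: one statistic per lag (multivariate TMIFs).
Spatio-temporal variant: one statistic per channel x lag (single-channel
TMIFs), with clusters joined over lag contiguity and channel adjacency
(Delaunay neighbours on the 2-D montage).

The sample-level statistic is a Welch t (a rank-sum z is available via
config); bins exceeding the two-sided t critical value at the cluster
alpha are joined into clusters whose mass is the summed statistic.
Group labels are permuted (group sizes preserved) and the maximum absolute
cluster mass per permutation forms the reference distribution; p-values
use the (1 + exceedances) / (1 + n_permutations) rule, so the attainable
floor is 1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib

import numpy as np
from scipy import ndimage, stats

from .channels import delaunay_adjacency
from .mi import TMIF


@dataclass
class Cluster:
    mass: float
    p_value: float
    lag_start_ms: float
    lag_end_ms: float
    bins: np.ndarray  # boolean mask over the stat map
    channels: list[str] | None = None

    def to_json_dict(self) -> dict:
        return {
            "mass": self.mass,
            "p_value": self.p_value,
            "lag_start_ms": self.lag_start_ms,
            "lag_end_ms": self.lag_end_ms,
            "channels": self.channels,
        }


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_map: np.ndarray
    lags_ms: np.ndarray
    threshold: float
    n_permutations: int
    threshold_alpha: float = 0.05
    variant: str = "temporal"
    channel_names: list[str] | None = None
    band: str = ""

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_json_dict(self) -> dict:
        return {
            "variant": self.variant,
            "band": self.band,
            "threshold": self.threshold,
            "threshold_alpha": self.threshold_alpha,
            "n_permutations": self.n_permutations,
            "clusters": [c.to_json_dict() for c in self.clusters],
        }

    def mask_frame(self):
        """Cluster-membership mask as a table: one row per (channel,) lag
        bin, one boolean column per cluster."""
        import pandas as pd

        if self.variant == "temporal":
            df = pd.DataFrame({"lag_ms": self.lags_ms})
            for i, c in enumerate(self.clusters):
                df[f"cluster_{i}"] = c.bins
            return df
        names = self.channel_names or []
        rows = {"channel": np.repeat(names, self.lags_ms.size),
                "lag_ms": np.tile(self.lags_ms, len(names))}
        df = pd.DataFrame(rows)
        for i, c in enumerate(self.clusters):
            df[f"cluster_{i}"] = c.bins.ravel()
        return df


def _stack(tmifs: list[TMIF]) -> tuple[np.ndarray, np.ndarray]:
    lags = tmifs[0].lags_ms
    for t in tmifs[1:]:
        if t.lags_ms.shape != lags.shape or not np.allclose(t.lags_ms, lags):
            raise ValueError("TMIFs must share the lag grid")
    return np.stack([t.mi for t in tmifs]), lags


def samplewise_stat(group_a: np.ndarray, group_b: np.ndarray,
                    kind: str = "welch") -> np.ndarray:
    """Per-bin two-sample statistic, sign = A - B.

    ``group_a``/``group_b`` are (n_subjects, ...bins...).
    """
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if kind == "welch":
        t, _ = stats.ttest_ind(group_a, group_b, axis=0, equal_var=False)
        return np.nan_to_num(np.asarray(t), nan=0.0)
    if kind == "ranksum":
        na = group_a.shape[0]
        both = np.concatenate([group_a, group_b], axis=0)
        ranks = stats.rankdata(both, axis=0)
        ra = ranks[:na].sum(axis=0)
        nb = group_b.shape[0]
        mu = na * (na + nb + 1) / 2.0
        sd = np.sqrt(na * nb * (na + nb + 1) / 12.0)
        return (ra - mu) / sd
    raise ValueError(f"unknown statistic kind {kind!r}")


def _t_threshold(n_a: int, n_b: int, alpha: float, kind: str) -> float:
    if kind == "ranksum":
        return float(stats.norm.ppf(1.0 - alpha / 2.0))
    return float(stats.t.ppf(1.0 - alpha / 2.0, df=n_a + n_b - 2))


def form_clusters(stat_map: np.ndarray, threshold: float,
                  adjacency: np.ndarray | None = None) -> list[tuple[np.ndarray, float]]:
    """Supra-threshold bins joined by lag contiguity (and channel adjacency
    for 2-D maps); positive and negative excursions are tracked separately.

    Returns ``(mask, mass)`` pairs sorted by decreasing |mass|.
    """
    out: list[tuple[np.ndarray, float]] = []
    for sign in (+1, -1):
        supra = sign * stat_map > threshold
        if stat_map.ndim == 1:
            labels, n_lab = ndimage.label(supra)
            for lab in range(1, n_lab + 1):
                mask = labels == lab
                out.append((mask, float(stat_map[mask].sum())))
        else:
            if adjacency is None:
                raise ValueError("spatio-temporal clustering needs a channel adjacency")
            masks = _label_spatiotemporal(supra, adjacency)
            out.extend((m, float(stat_map[m].sum())) for m in masks)
    return sorted(out, key=lambda pair: -abs(pair[1]))


def _label_spatiotemporal(supra: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components over (channel, lag) bins: neighbours share a
    channel and adjacent lags, or the same lag and adjacent channels."""
    n_ch, n_lag = supra.shape
    idx_map = -np.ones(supra.shape, dtype=int)
    coords = np.argwhere(supra)
    for k, (c, l) in enumerate(coords):
        idx_map[c, l] = k
    parent = list(range(len(coords)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for k, (c, l) in enumerate(coords):
        if l + 1 < n_lag and idx_map[c, l + 1] >= 0:
            union(k, idx_map[c, l + 1])
        for c2 in np.nonzero(adjacency[c])[0]:
            if idx_map[c2, l] >= 0:
                union(k, idx_map[c2, l])
    groups: dict[int, list[int]] = {}
    for k in range(len(coords)):
        groups.setdefault(find(k), []).append(k)
    masks = []
    for members in groups.values():
        mask = np.zeros(supra.shape, dtype=bool)
        for k in members:
            mask[tuple(coords[k])] = True
        masks.append(mask)
    return masks


def cluster_permutation_test(
    tmifs_a: list[TMIF],
    tmifs_b: list[TMIF],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    stat_kind: str = "welch",
) -> ClusterResult:
    """Group comparison (A - B) with max-cluster-mass permutation control.

    Temporal for multivariate TMIFs, spatio-temporal for single-channel
    TMIFs (adjacency from the montage of the shared channel list).
    """
    data_a, lags = _stack(tmifs_a)
    data_b, _ = _stack(tmifs_b)
    variant = "spatiotemporal" if data_a.ndim == 3 else "temporal"
    channel_names = tmifs_a[0].channel_names if variant == "spatiotemporal" else None
    adjacency = delaunay_adjacency(channel_names) if channel_names else None
    n_a, n_b = data_a.shape[0], data_b.shape[0]
    threshold = _t_threshold(n_a, n_b, alpha, stat_kind)

    observed = samplewise_stat(data_a, data_b, stat_kind)
    obs_clusters = form_clusters(observed, threshold, adjacency)

    # canonicalize subject order so the permutation null (hence every
    # p-value) is invariant to how subjects were listed within groups
    def _canon(data: np.ndarray) -> np.ndarray:
        keys = [hashlib.sha256(np.ascontiguousarray(row).tobytes()).hexdigest()
                for row in data]
        return data[np.argsort(keys, kind="stable")]

    pooled = np.concatenate([_canon(data_a), _canon(data_b)], axis=0)
    rng = np.random.default_rng(seed)
    max_mass = np.zeros(int(n_permutations))
    for p in range(int(n_permutations)):
        perm = rng.permutation(n_a + n_b)
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        cl = form_clusters(samplewise_stat(pa, pb, stat_kind), threshold, adjacency)
        max_mass[p] = abs(cl[0][1]) if cl else 0.0

    clusters = []
    for mask, mass in obs_clusters:
        p_val = float((1 + np.sum(max_mass >= abs(mass))) / (1 + n_permutations))
        lag_mask = mask if mask.ndim == 1 else mask.any(axis=0)
        lag_idx = np.nonzero(lag_mask)[0]
        chans = None
        if mask.ndim == 2 and channel_names is not None:
            chans = [channel_names[c] for c in np.nonzero(mask.any(axis=1))[0]]
        clusters.append(Cluster(
            mass=mass,
            p_value=p_val,
            lag_start_ms=float(lags[lag_idx[0]]),
            lag_end_ms=float(lags[lag_idx[-1]]),
            bins=mask,
            channels=chans,
        ))
    return ClusterResult(
        clusters=clusters,
        stat_map=observed,
        lags_ms=lags,
        threshold=threshold,
        n_permutations=int(n_permutations),
        threshold_alpha=alpha,
        variant=variant,
        channel_names=channel_names,
        band=tmifs_a[0].band,
    )
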