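"""BioSemi-64 montage helpers: naming, 2-D positions, adjacency, topography.

Channel names follow the 10-20 equivalents of the BioSemi 64-channel cap;
the native ``A1..B32`` labels are accepted as aliases (index-wise mapping
onto the standard cap layout).  Matching is case-insensitive everywhere.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=1)
def biosemi64_names() -> tuple[str, ...]:
    import mne

    return tuple(mne.channels.make_standard_montage("biosemi64").ch_names)


@lru_cache(maxsize=1)
def _positions_3d() -> dict[str, np.ndarray]:
    import mne

    pos = mne.channels.make_standard_montage("biosemi64").get_positions()["ch_pos"]
    return {name: np.asarray(p, dtype=float) for name, p in pos.items()}


@lru_cache(maxsize=1)
def _alias_map() -> dict[str, str]:
    names = biosemi64_names()
    alias = {n.lower(): n for n in names}
    for i in range(32):
        alias[f"a{i + 1}"] = names[i]
        alias[f"b{i + 1}"] = names[32 + i]
    return alias


def canonical_name(name: str) -> str:
    """Resolve a channel label (10-20 or A/B alias, any case) to its
    canonical 10-20 form; unknown labels are returned stripped but intact so
    that recordings with non-cap channel names still work."""
    return _alias_map().get(name.strip().lower(), name.strip())


def match_channels(available: list[str], requested: list[str]) -> list[int]:
    """Indices of ``requested`` channels inside ``available`` (order of the
    request is preserved).  Raises ``KeyError`` naming the first missing
    channel."""
    lookup = {canonical_name(n).lower(): i for i, n in enumerate(available)}
    out = []
    for name in requested:
        key = canonical_name(name).lower()
        if key not in lookup:
            raise KeyError(f"channel {name!r} not present in recording")
        out.append(lookup[key])
    return out


def positions_2d(names: list[str]) -> np.ndarray:
    """Azimuthal-equidistant 2-D projection of electrode positions."""
    pos3 = _positions_3d()
    pts = []
    for name in names:
        cn = canonical_name(name)
        if cn not in pos3:
            raise KeyError(f"no montage position for channel {name!r}")
        x, y, z = pos3[cn]
        r = np.linalg.norm([x, y, z])
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))
        phi = np.arctan2(y, x)
        pts.append([theta * np.cos(phi), theta * np.sin(phi)])
    return np.asarray(pts)


def delaunay_adjacency(names: list[str]) -> np.ndarray:
    """Boolean channel-adjacency matrix from Delaunay triangulation of the
    2-D projected montage positions."""
    from scipy.spatial import Delaunay

    pts = positions_2d(names)
    n = len(names)
    adj = np.zeros((n, n), dtype=bool)
    if n < 3:
        adj[:] = ~np.eye(n, dtype=bool)
        return adj
    tri = Delaunay(pts)
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    adj[i, j] = True
    return adj


def frontocentral_gain(names: list[str], floor: float = 0.25) -> np.ndarray:
    """Raised-cosine topography gain centred between Cz and FCz.

    Used by the synthetic generator to project the envelope response onto
    channels; the floor keeps every channel carrying some signal.
    """
    pts = positions_2d(list(names))
    centre = positions_2d(["Cz", "FCz"]).mean(axis=0)
    dist = np.linalg.norm(pts - centre, axis=1)
    reach = 1.8  # radians of projected arc over which the gain decays
    gain = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * np.clip(dist / reach, 0, 1)))
    return gain


def spread_subset(n: int) -> tuple[str, ...]:
    """A deterministic n-channel subset spread across the cap (used by the
    synthetic generator when fewer than 64 channels are requested)."""
    names = biosemi64_names()
    if not 1 <= n <= 64:
        raise ValueError("n must be in 1..64")
    idx = np.unique(np.round(np.linspace(0, 63, n)).astype(int))
    k = 0
    while len(idx) < n:  # fill gaps caused by rounding collisions
        if k not in idx:
            idx = np.sort(np.append(idx, k))
        k += 1
    return tuple(names[i] for i in idx)
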