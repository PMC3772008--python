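"""DGGE densitometric profiles: band calling, Shannon diversity, lane distance.

A DGGE lane is summarized as a 1-D densitometric trace (normalized migration
position vs staining intensity).  Bands are called as local maxima after
light smoothing and rolling-minimum baseline subtraction; bands whose
relative peak height is at most 1% of the summed candidate peak heights are
discarded (the standard densitometry detection rule), and each retained band
i carries a "significant probability"

    P_i = n_i / N,

its peak height n_i over the lane's summed retained peak heights N.  The
lane's Shannon diversity is H = -sum_i P_i ln P_i.

Two lanes A and B are compared over the union of their bands: with
P = n_A + n_B - c union bands (c = bands common to both lanes, matched
greedily by migration position), the lane distance is

    D = sum_i |A_i - B_i| / P,

where A_i, B_i are the significant probabilities of band i in each lane and
a band absent from a lane contributes probability zero.  A presence/absence
alternative (Dice) is available behind the same strategy interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "LaneProfile",
    "Band",
    "BandSet",
    "BandMatch",
    "LaneDistanceMatrix",
    "detect_bands",
    "shannon_index",
    "match_bands",
    "lane_distance",
    "distance_matrix",
    "LANE_DISTANCE_STRATEGIES",
    "read_lane_csv",
    "read_lanes_wide_csv",
]


@dataclass(frozen=True)
class LaneProfile:
    """1-D densitometric trace of one gel lane."""

    lane_id: str
    positions: np.ndarray  # strictly increasing, normalized to [0, 1]
    intensities: np.ndarray  # non-negative, same length

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if pos.shape != inten.shape:
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class Band:
    """A called band: migration position, peak height n_i, probability P_i."""

    position: float
    peak_height: float
    significant_probability: float

    def __post_init__(self) -> None:
        if self.peak_height <= 0:
            raise ValueError("peak height must be > 0")
        if not 0.0 <= self.significant_probability <= 1.0:
            raise ValueError("significant probability must be in [0, 1]")


@dataclass(frozen=True)
class BandSet:
    """Bands of one lane, sorted by position, with probabilities summing to 1."""

    lane_id: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(sorted(self.bands, key=lambda b: b.position)))
        if self.bands:
            total = sum(b.significant_probability for b in self.bands)
            # equality holds after renormalization; < 1 when the mass of
            # bands discarded by the 1% rule is deliberately not redistributed
            if total > 1.0 + 1e-9 or total <= 0:
                raise ValueError(f"band probabilities sum to {total}, expected <= 1")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def total_peak_height(self) -> float:
        """N, the sum of retained band peak heights."""
        return sum(b.peak_height for b in self.bands)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.bands])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lane_id": self.lane_id,
                "position": [b.position for b in self.bands],
                "peak_height": [b.peak_height for b in self.bands],
                "significant_probability": [b.significant_probability for b in self.bands],
            }
        )


def detect_bands(
    profile: LaneProfile,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.02,
    baseline_window: int = 51,
    min_relative_height: float = 0.01,
    renormalize_after_filter: bool = True,
) -> BandSet:
    """Call bands from a densitometric profile.

    The trace is smoothed by a moving average and a morphological-opening
    (top-hat) baseline — a rolling minimum followed by a rolling maximum over
    ``baseline_window`` samples — is subtracted, which removes monotone
    background trends exactly and preserves the relative heights of bands
    narrower than the window.  Local maxima with prominence at least
    ``min_prominence_fraction`` of the maximum corrected intensity become
    candidate bands.  Candidates whose peak height is <= ``min_relative_height``
    of the summed candidate heights are discarded (1% rule); probabilities
    are then renormalized over the retained bands (set
    ``renormalize_after_filter=False`` to keep pre-filter probabilities).
    """
    y = uniform_filter1d(profile.intensities, size=max(int(smoothing_window), 1), mode="nearest")
    w = max(int(baseline_window), 1)
    baseline = maximum_filter1d(minimum_filter1d(y, size=w, mode="nearest"), size=w, mode="nearest")
    y = y - baseline
    top = float(y.max())
    if top <= 0:
        warnings.warn(f"lane {profile.lane_id}: flat profile, no bands called", stacklevel=2)
        return BandSet(lane_id=profile.lane_id, bands=())

    idx, _ = find_peaks(y, prominence=min_prominence_fraction * top)
    if idx.size == 0:
        warnings.warn(f"lane {profile.lane_id}: no local maxima, no bands called", stacklevel=2)
        return BandSet(lane_id=profile.lane_id, bands=())

    heights = y[idx]
    total = heights.sum()
    keep = heights / total > min_relative_height
    idx, heights = idx[keep], heights[keep]
    norm = heights.sum() if renormalize_after_filter else total
    bands = tuple(
        Band(
            position=float(profile.positions[i]),
            peak_height=float(h),
            significant_probability=float(h / norm),
        )
        for i, h in zip(idx, heights)
    )
    return BandSet(lane_id=profile.lane_id, bands=bands)


def shannon_index(bands: BandSet, base: float = math.e) -> float:
    """Shannon diversity H = -sum_i P_i log(P_i) of a lane's band pattern.

    Natural log by default; pass ``base`` to report in another log base.
    """
    if bands.n_bands == 0:
        raise ValueError(f"lane {bands.lane_id}: Shannon index undefined for empty band set")
    p = np.array([b.significant_probability for b in bands.bands])
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


@dataclass(frozen=True)
class BandMatch:
    """Greedy position matching of two lanes' bands."""

    pairs: tuple[tuple[int, int], ...]  # (index in A, index in B)
    n_a: int
    n_b: int

    @property
    def c(self) -> int:
        """Number of bands common to both lanes."""
        return len(self.pairs)

    @property
    def p(self) -> int:
        """P = n_A + n_B - c, the number of union bands."""
        return self.n_a + self.n_b - self.c


def match_bands(a: BandSet, b: BandSet, position_tolerance: float = 0.01) -> BandMatch:
    """Match bands across two lanes by closest migration position.

    Candidate pairs within ``position_tolerance`` are accepted greedily in
    order of increasing position gap; each band is used at most once.
    """
    if position_tolerance < 0:
        raise ValueError("position tolerance must be >= 0")
    candidates = sorted(
        ((abs(ba.position - bb.position), i, j)
         for i, ba in enumerate(a.bands)
         for j, bb in enumerate(b.bands)
         if abs(ba.position - bb.position) <= position_tolerance),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return BandMatch(pairs=tuple(sorted(pairs)), n_a=a.n_bands, n_b=b.n_bands)


def _probability_l1(a: BandSet, b: BandSet, match: BandMatch) -> float:
    """D = sum |A_i - B_i| / P over the union bands (absent band -> 0)."""
    total = 0.0
    matched_a = {i for i, _ in match.pairs}
    matched_b = {j for _, j in match.pairs}
    for i, j in match.pairs:
        total += abs(a.bands[i].significant_probability - b.bands[j].significant_probability)
    total += sum(x.significant_probability for k, x in enumerate(a.bands) if k not in matched_a)
    total += sum(x.significant_probability for k, x in enumerate(b.bands) if k not in matched_b)
    return total / match.p


def _dice(a: BandSet, b: BandSet, match: BandMatch) -> float:
    """Presence/absence distance 1 - 2c / (n_A + n_B)."""
    return 1.0 - 2.0 * match.c / (match.n_a + match.n_b)


LANE_DISTANCE_STRATEGIES: dict[str, Callable[[BandSet, BandSet, BandMatch], float]] = {
    "probability_l1": _probability_l1,
    "dice": _dice,
}


def lane_distance(
    a: BandSet,
    b: BandSet,
    position_tolerance: float = 0.01,
    strategy: str = "probability_l1",
) -> float:
    """Distance between two lanes' band patterns (0 = identical)."""
    if a.n_bands == 0 and b.n_bands == 0:
        warnings.warn("both lanes empty; distance defined as 0", stacklevel=2)
        return 0.0
    match = match_bands(a, b, position_tolerance)
    return LANE_DISTANCE_STRATEGIES[strategy](a, b, match)


@dataclass(frozen=True)
class LaneDistanceMatrix:
    """Symmetric pairwise lane distances with zero diagonal."""

    lane_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.lane_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} lanes")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lane_ids", tuple(self.lane_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lane_ids, columns=self.lane_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LaneDistanceMatrix":
        return cls(lane_ids=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float))


def distance_matrix(
    lanes: Sequence[BandSet],
    position_tolerance: float = 0.01,
    strategy: str = "probability_l1",
) -> LaneDistanceMatrix:
    """Pairwise :func:`lane_distance` over a set of lanes."""
    if len(lanes) < 2:
        raise ValueError("need at least 2 lanes")
    ids = [lane.lane_id for lane in lanes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lane ids")
    n = len(lanes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = lane_distance(lanes[i], lanes[j], position_tolerance, strategy)
    return LaneDistanceMatrix(lane_ids=tuple(ids), values=d)


def read_lane_csv(path, lane_id: str | None = None) -> LaneProfile:
    """Read one lane from a two-column CSV (position, intensity)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("lane CSV needs position and intensity columns")
    return LaneProfile(
        lane_id=lane_id or str(path),
        positions=df.iloc[:, 0].to_numpy(dtype=float),
        intensities=df.iloc[:, 1].to_numpy(dtype=float),
    )


def read_lanes_wide_csv(path) -> list[LaneProfile]:
    """Read a wide CSV: first column positions, one column per lane."""
    df = pd.read_csv(path)
    pos = df.iloc[:, 0].to_numpy(dtype=float)
    return [
        LaneProfile(lane_id=str(col), positions=pos, intensities=df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]
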