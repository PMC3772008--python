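"""Synthetic inputs for every pipeline stage.

All generators are pure functions of (specification, seed), so any analysis
can be rebuilt from scratch without external data:

* random Yule trees and K2P-evolved alignments (for digestion, phylotyping,
  NJ and bootstrap),
* densitometric gel lanes as Gaussian band mixtures over a constant
  baseline with additive Gaussian noise (for band calling, Shannon
  diversity, lane distances and ordination), including a stratified-soil
  preset with per-horizon band richness 20/12/8 mirroring the surface-to-
  substratum richness decline seen in soil-community fingerprints,
* per-isolate activity records whose tabulation reproduces a requested
  horizon x category count table exactly.

Sequence evolution uses the closed-form K2P site transition probabilities
per branch (branch lengths in expected substitutions/site): with rates
normalized so alpha + 2*beta = 1 and kappa = alpha/beta,

    P(transition, t)       = 1/4 + 1/4 e^(-4 beta t) - 1/2 e^(-2 (alpha+beta) t)
    P(each transversion,t) = 1/4 - 1/4 e^(-4 beta t)

so the expected number of substitutions along a branch of length t is t and
the K2P distance estimator is consistent for t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .dgge import LaneProfile
from .oxidation import ActivityRecord, categorize
from .phylo import Alignment

__all__ = [
    "LaneSpec",
    "simulate_tree",
    "simulate_alignment",
    "simulate_lane",
    "simulate_horizon_lanes",
    "simulate_activity_table",
    "DEFAULT_HORIZON_RICHNESS",
    "ACTIVITY_INTERVALS",
]

#: Bands per horizon lane in the stratified-soil preset (A > B > C richness).
DEFAULT_HORIZON_RICHNESS = {"A": 20, "B": 12, "C": 8}

#: Sampling interval (µM MnO2) per activity category; the "high" upper bound
#: is the top of the survey's reported overall activity range.
ACTIVITY_INTERVALS = {
    "high": (50.0, 240.0),
    "medium": (10.0, 50.0),
    "low": (1.0, 10.0),
    "none": (0.0, 1.0),
}


def simulate_tree(
    n_taxa: int, seed: int, mean_branch_length: float = 0.1
) -> dendropy.Tree:
    """Yule (pure-birth) topology with i.i.d. exponential branch lengths.

    Leaves are labeled ``T01 .. Tnn`` (zero-padded) in a fixed traversal
    order; deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    leaves = [root]
    while len(leaves) < n_taxa:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        children = [dendropy.Node(), dendropy.Node()]
        for child in children:
            parent.add_child(child)
        leaves.extend(children)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    width = max(2, len(str(n_taxa)))
    counter = 0
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = float(rng.exponential(mean_branch_length))
        if node.is_leaf():
            counter += 1
            node.taxon = tns.new_taxon(label=f"T{counter:0{width}d}")
    tree.is_rooted = False
    return tree


def _k2p_step_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-transversion prob) across a branch of length t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return float(p_ts), float(p_tv)


def simulate_alignment(
    tree: dendropy.Tree, length: int, kappa: float = 2.0, seed: int = 0
) -> Alignment:
    """Evolve a gapless alignment along ``tree`` under the K2P model.

    The root sequence is uniform over {A, C, G, T}; each branch applies the
    closed-form K2P site transition probabilities for its length (negative
    or missing branch lengths are treated as 0).  Deterministic given
    ``seed``.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rng = np.random.default_rng(seed)
    # Internal coding A=0, G=1, C=2, T=3; transition partner is code ^ 1.
    letters = np.array(list("AGCT"))

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length, dtype=np.int64)
    ids: list[str] = []
    rows: list[str] = []
    for node in tree.preorder_node_iter():
        if node is not root:
            t = node.edge.length or 0.0
            parent_seq = seqs[id(node.parent_node)]
            p_ts, p_tv = _k2p_step_probs(max(t, 0.0), kappa)
            u = rng.random(length)
            child = parent_seq.copy()
            p_same = 1.0 - p_ts - 2.0 * p_tv
            ts_mask = (u >= p_same) & (u < p_same + p_ts)
            tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
            tv2_mask = u >= p_same + p_ts + p_tv
            child[ts_mask] ^= 1
            child[tv1_mask] ^= 2
            child[tv2_mask] ^= 3
            seqs[id(node)] = child
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append("".join(letters[seqs[id(node)]]))
    return Alignment(ids=tuple(ids), rows=tuple(rows))


@dataclass(frozen=True)
class LaneSpec:
    """Generative description of one densitometric gel lane."""

    lane_id: str
    positions: tuple[float, ...]  # band centers in (0, 1)
    intensities: tuple[float, ...]  # band peak heights > 0
    sigma: float = 0.01  # Gaussian band width, normalized units
    baseline: float = 0.05  # constant background level
    noise_sd: float = 0.0  # additive Gaussian noise
    n_samples: int = 1000

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities differ in length")
        if any(not 0.0 < p < 1.0 for p in self.positions):
            raise ValueError("band positions must be in (0, 1)")
        if any(h <= 0 for h in self.intensities):
            raise ValueError("band intensities must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def simulate_lane(spec: LaneSpec, seed: int = 0) -> LaneProfile:
    """Render a lane spec to a sampled trace: baseline + Gaussian bands + noise,
    clipped at zero.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, spec.n_samples)
    y = np.full_like(x, float(spec.baseline))
    for pos, height in zip(spec.positions, spec.intensities):
        y += height * np.exp(-((x - pos) ** 2) / (2.0 * spec.sigma**2))
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=x.shape)
    return LaneProfile(lane_id=spec.lane_id, positions=x, intensities=np.clip(y, 0.0, None))


def simulate_horizon_lanes(
    richness: Mapping[str, int] | None = None,
    seed: int = 0,
    pool_size: int = 24,
    sigma: float = 0.006,
    baseline: float = 0.05,
    noise_sd: float = 0.01,
    n_samples: int = 2000,
) -> dict[str, tuple[LaneProfile, LaneSpec]]:
    """Stratified-soil community lanes drawn from a shared band pool.

    A pool of ``pool_size`` well-separated band positions (jittered around a
    regular grid on (0.06, 0.94)) represents the taxa detectable across the
    profile; each horizon's lane includes a random subset of ``richness[h]``
    pool bands with random relative intensities (uniform on [0.6, 1.6]).
    The default richness 20/12/8 encodes the decreasing surface-to-depth
    diversity of the stratified communities.
    """
    richness = dict(DEFAULT_HORIZON_RICHNESS if richness is None else richness)
    if max(richness.values()) > pool_size:
        raise ValueError("richness cannot exceed the band pool size")
    rng = np.random.default_rng(seed)
    pool = np.linspace(0.06, 0.94, pool_size) + rng.uniform(-0.005, 0.005, pool_size)
    out: dict[str, tuple[LaneProfile, LaneSpec]] = {}
    for lane_id, k in richness.items():
        chosen = np.sort(rng.choice(pool_size, size=k, replace=False))
        spec = LaneSpec(
            lane_id=lane_id,
            positions=tuple(float(p) for p in pool[chosen]),
            intensities=tuple(float(h) for h in rng.uniform(0.6, 1.6, size=k)),
            sigma=sigma,
            baseline=baseline,
            noise_sd=noise_sd,
            n_samples=n_samples,
        )
        out[lane_id] = (simulate_lane(spec, seed=int(rng.integers(2**31))), spec)
    return out


def simulate_activity_table(
    per_horizon_counts: Mapping[str, Mapping[str, int]], seed: int = 0
) -> list[ActivityRecord]:
    """Emit isolate records reproducing a horizon x category count table.

    Each record's MnO2-equivalent concentration is drawn uniformly within
    its category's interval (see :data:`ACTIVITY_INTERVALS`), so
    re-categorizing any emitted record recovers its category and tabulating
    the output recovers ``per_horizon_counts`` exactly.
    """
    if not per_horizon_counts or all(
        not any(cats.values()) for cats in per_horizon_counts.values()
    ):
        raise ValueError("empty activity specification")
    rng = np.random.default_rng(seed)
    records: list[ActivityRecord] = []
    for horizon in sorted(per_horizon_counts):
        counter = 0
        for category, count in per_horizon_counts[horizon].items():
            if category not in ACTIVITY_INTERVALS:
                raise ValueError(f"unknown category {category!r}")
            if count < 0:
                raise ValueError("counts must be >= 0")
            lo, hi = ACTIVITY_INTERVALS[category]
            for _ in range(int(count)):
                counter += 1
                value = float(rng.uniform(lo, hi))
                assert categorize(value) == category
                records.append(
                    ActivityRecord(
                        isolate_id=f"{horizon}{counter:03d}",
                        horizon=horizon,
                        mno2_uM=value,
                    )
                )
    return records
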