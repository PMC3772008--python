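"""16S phylotyping and distance-based phylogenetics.

Pairwise distances on a pre-aligned set of sequences use pairwise deletion:
a site enters a comparison only when both sequences carry a plain base
(A/C/G/T); gaps and ambiguity codes are skipped per pair.  Two distances are
provided: the uncorrected p-distance, and the Kimura two-parameter (K2P)
correction

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition and transversion fractions over comparable
sites.  When a log argument is non-positive (saturation) the entry is
flagged undefined (NaN).

Phylotypes are complete-linkage clusters cut so that every within-cluster
pair differs by less than the threshold (default 3%, uncorrected
p-distance) — the standard OTU-style grouping guarantee.

Trees are built with the Saitou-Nei neighbor-joining algorithm; node
confidence comes from column-resampling bootstrap, scoring each internal
branch of the full-data tree by the percentage of replicate trees containing
the same leaf bipartition.  Trees are dendropy objects; Newick I/O is a thin
wrapper preserving branch lengths (6 decimals) and integer supports as
internal node labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Alignment",
    "DistMatrix",
    "PhylotypeAssignment",
    "p_distance",
    "k2p_distance",
    "dist_matrix",
    "cluster_phylotypes",
    "neighbor_joining",
    "bootstrap_support",
    "branch_supports",
    "bipartitions",
    "write_newick",
    "read_newick",
]

# Base encoding: A=0, G=1, C=2, T=3 (transition partner = code ^ 1), other=4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences over {A, C, G, T, -, N}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must all have the same length")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """(n_sequences, length) uint8 matrix in the internal base coding."""
        return _CODE[np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)].reshape(
            self.n_sequences, self.length
        )

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(ids=tuple(r.id for r in records), rows=tuple(str(r.seq) for r in records))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n{row}\n")


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for two encoded rows."""
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    transitions = int(np.sum(diff & ((a >> 1) == (b >> 1))))
    return int(np.sum(comparable)), transitions, int(np.sum(diff)) - transitions


def _encode_row(s: str | np.ndarray) -> np.ndarray:
    if isinstance(s, np.ndarray):
        return s
    return _CODE[np.frombuffer(s.upper().encode(), dtype=np.uint8)]


def p_distance(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Uncorrected proportion of differing sites under pairwise deletion."""
    ea, eb = _encode_row(a), _encode_row(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must be aligned to equal length")
    m, ts, tv = _pair_counts(ea, eb)
    if m == 0:
        raise ValueError("no comparable sites between the two sequences")
    return (ts + tv) / m


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Kimura two-parameter distance (NaN when the correction saturates)."""
    ea, eb = _encode_row(a), _encode_row(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must be aligned to equal length")
    m, ts, tv = _pair_counts(ea, eb)
    if m == 0:
        raise ValueError("no comparable sites between the two sequences")
    p, q = ts / m, tv / m
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@dataclass(frozen=True)
class DistMatrix:
    """Symmetric pairwise distance matrix; NaN marks undefined entries."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


_METRICS = {"p": p_distance, "k2p": k2p_distance}


def dist_matrix(aln: Alignment, metric: str = "k2p") -> DistMatrix:
    """All-pairs distance matrix of an alignment (``metric``: "p" or "k2p")."""
    fn = _METRICS[metric]
    enc = aln.encoded()
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(enc[i], enc[j])
    return DistMatrix(ids=aln.ids, values=d)


@dataclass(frozen=True)
class PhylotypeAssignment:
    """Mapping of sequence ids to phylotype indices at a divergence threshold."""

    assignments: dict[str, int]
    threshold: float

    @property
    def n_phylotypes(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, idx in self.assignments.items():
            out.setdefault(idx, []).append(name)
        return out


def cluster_phylotypes(
    aln: Alignment,
    threshold: float = 0.03,
    metric: str = "p",
    linkage: str = "complete",
) -> PhylotypeAssignment:
    """Group sequences into phylotypes at ``< threshold`` divergence.

    Complete linkage (default) guarantees every within-phylotype pair is
    strictly below the threshold; single/average linkage are available but
    only bound the linked, not all, pairs.
    """
    if aln.n_sequences == 1:
        return PhylotypeAssignment(assignments={aln.ids[0]: 0}, threshold=threshold)
    dm = dist_matrix(aln, metric=metric)
    for a, b in dm.undefined_pairs:
        raise ValueError(f"distance undefined between {a!r} and {b!r}")
    condensed = squareform(dm.values, checks=False)
    z = scipy_linkage(condensed, method=linkage)
    # fcluster cuts at height <= t; the grouping guarantee is strict (< threshold).
    labels = fcluster(z, t=np.nextafter(threshold, 0.0), criterion="distance")
    relabel: dict[int, int] = {}
    assignments = {}
    for name, lab in zip(aln.ids, labels):
        assignments[name] = relabel.setdefault(int(lab), len(relabel))
    return PhylotypeAssignment(assignments=assignments, threshold=threshold)


def neighbor_joining(d: DistMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a distance matrix.

    Iteratively joins the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j
    (ties broken by lowest index pair), with the standard branch-length
    formulas; the final three lineages are resolved in closed form around an
    unrooted central node.  Negative branch lengths are retained unless
    ``clamp_negative`` is set.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.undefined_pairs:
        a, b = d.undefined_pairs[0]
        raise ValueError(f"distance undefined between {a!r} and {b!r}")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in d.ids:
        node = dendropy.Node(taxon=tns.new_taxon(label=name))
        nodes.append(node)
    dist = d.values.astype(float).copy()

    def _blen(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # row-major: lowest (i, j)
        if i > j:
            i, j = j, i
        vi = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dist[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _blen(vi)
        nodes[j].edge.length = _blen(vj)
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_row[keep]])
        dist = np.hstack([dist, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    center = dendropy.Node()
    lengths = ((d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2)
    for node, v in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = _blen(v)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of an unrooted tree.

    Each internal branch splits the leaves in two; the split is canonicalized
    as the side not containing the alphabetically smallest leaf label, and
    only splits with at least two leaves on both sides are reported.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    distance: str = "k2p",
    replicates: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on branches.

    Alignment columns are resampled with replacement ``replicates`` times
    (deterministic given ``seed``); each internal branch of the full-data
    tree is labeled with the percentage of successful replicates whose NJ
    tree contains the same bipartition.  Replicates whose resampled distance
    matrix has undefined entries are skipped; the counts are stored on the
    returned tree as ``bootstrap_replicates_used`` / ``bootstrap_skipped``.
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    tree = neighbor_joining(dist_matrix(aln, metric=distance))
    target = bipartitions(tree)
    enc = aln.encoded()
    rng = np.random.default_rng(seed)
    fn = _METRICS[distance]
    n = aln.n_sequences

    counts = {bip: 0 for bip in target}
    used = 0
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, aln.length)
        sub = enc[:, cols]
        d = np.zeros((n, n))
        bad = False
        for i in range(n):
            if bad:
                break
            for j in range(i + 1, n):
                try:
                    v = fn(sub[i], sub[j])
                except ValueError:
                    bad = True
                    break
                if np.isnan(v):
                    bad = True
                    break
                d[i, j] = d[j, i] = v
        if bad:
            skipped += 1
            continue
        used += 1
        rep = neighbor_joining(DistMatrix(ids=aln.ids, values=d))
        for bip in bipartitions(rep):
            if bip in counts:
                counts[bip] += 1

    if used == 0:
        raise ValueError("all bootstrap replicates had undefined distances")

    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        if side in counts:
            node.label = str(round(100.0 * counts[side] / used))
    tree.bootstrap_replicates_used = used
    tree.bootstrap_skipped = skipped
    return tree


def branch_supports(tree: dendropy.Tree) -> dict[frozenset[str], int]:
    """Extract {bipartition: support} from internal node labels."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(labels)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels - side)
        out[side] = int(node.label)
    return out


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick (branch lengths to 6 decimals, supports as
    internal node labels)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal node labels are kept as labels."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree
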