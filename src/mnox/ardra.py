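"""In-silico ARDRA: restriction digestion and two-stage pattern grouping.

Amplified ribosomal DNA restriction analysis (ARDRA) types isolates by the
restriction-fragment patterns of their 16S amplicons.  The survey protocol
digests with HaeIII (GG^CC) first, groups isolates by pattern, then
re-digests and regroups the members of each group with Sau3AI (^GATC); one
representative per final group is sequenced.

Digestion here is exact and in-silico: the amplicon is treated as a linear
single-stranded representation of the double-stranded product, every
occurrence of the recognition site (including overlapping ones) is cut at
the enzyme's offset, and zero-length fragments are dropped.  ``N`` never
matches a site position.  A "gel mode" preset (5% length tolerance, 50 bp
detection floor) emulates agarose resolution when grouping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "RestrictionEnzyme",
    "FragmentPattern",
    "ArdraGrouping",
    "HAEIII",
    "SAU3AI",
    "GEL_MODE",
    "digest",
    "pattern_equal",
    "group_by_ardra",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition site and cut offset within it."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site
        if not site or any(ch not in "ACGT" for ch in site):
            raise ValueError(f"recognition site must be non-empty over ACGT, got {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"cut offset {self.cut_offset} outside site of length {len(site)}")


HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
SAU3AI = RestrictionEnzyme("Sau3AI", "GATC", 0)

#: (tolerance_fraction, min_detectable_bp) emulating agarose-gel resolution.
GEL_MODE = (0.05, 50)


@dataclass(frozen=True)
class FragmentPattern:
    """Fragment-length fingerprint of one digestion (lengths sorted descending)."""

    enzyme_name: str
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        object.__setattr__(
            self, "fragment_lengths", tuple(sorted(self.fragment_lengths, reverse=True))
        )

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


def digest(sequence: str, enzyme: RestrictionEnzyme) -> FragmentPattern:
    """Cut ``sequence`` at every occurrence of the enzyme's recognition site.

    The scan is left-to-right and counts overlapping occurrences.  Fragments
    are the intervals between successive cut positions; zero-length pieces
    (cuts at the very ends, or coincident cuts) are dropped.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")

    site = enzyme.recognition_site
    cuts = [0]
    start = seq.find(site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = seq.find(site, start + 1)  # overlapping occurrences all count
    cuts.append(len(seq))
    cuts.sort()
    lengths = tuple(b - a for a, b in zip(cuts, cuts[1:]) if b > a)
    return FragmentPattern(enzyme_name=enzyme.name, fragment_lengths=lengths)


def pattern_equal(
    p: FragmentPattern,
    q: FragmentPattern,
    tolerance_fraction: float = 0.0,
    min_detectable_bp: int = 0,
) -> bool:
    """Decide whether two fragment patterns are indistinguishable.

    After discarding fragments below ``min_detectable_bp`` from both, the
    patterns must have equal band counts and the i-th largest lengths must
    differ by at most ``tolerance_fraction`` of the larger of the two.
    Tolerance 0 is exact multiset equality.
    """
    if p.enzyme_name != q.enzyme_name:
        raise ValueError(f"cannot compare {p.enzyme_name} and {q.enzyme_name} patterns")
    if tolerance_fraction < 0:
        raise ValueError("tolerance_fraction must be >= 0")
    a = [x for x in p.fragment_lengths if x >= min_detectable_bp]
    b = [x for x in q.fragment_lengths if x >= min_detectable_bp]
    if len(a) != len(b):
        return False
    return all(abs(x - y) <= tolerance_fraction * max(x, y) for x, y in zip(a, b))


@dataclass(frozen=True)
class ArdraGrouping:
    """Final partition of isolates with one representative per group."""

    assignments: dict[str, int]
    representatives: dict[int, str]

    @property
    def n_groups(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isolate_id": iso,
                "group_id": grp,
                "representative": iso == self.representatives[grp],
            }
            for iso, grp in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows)


def _partition(
    ids: list[str],
    patterns: Mapping[str, FragmentPattern],
    tolerance_fraction: float,
    min_detectable_bp: int,
) -> list[list[str]]:
    """Partition ids by pattern equivalence.

    With tolerance 0 this is a hash partition on the exact length multiset.
    With tolerance > 0 the relation is not transitive, so the partition is
    its single-linkage (connected-component) closure, which is well defined
    and order independent.
    """
    ids = sorted(ids)
    if tolerance_fraction == 0 and min_detectable_bp == 0:
        buckets: dict[tuple[int, ...], list[str]] = {}
        for iso in ids:
            buckets.setdefault(patterns[iso].fragment_lengths, []).append(iso)
        return [buckets[key] for key in sorted(buckets)]

    parent = {iso: iso for iso in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pattern_equal(patterns[a], patterns[b], tolerance_fraction, min_detectable_bp):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for iso in ids:
        groups.setdefault(find(iso), []).append(iso)
    return [groups[root] for root in sorted(groups)]


def group_by_ardra(
    sequences: Mapping[str, str],
    tolerance_fraction: float = 0.0,
    min_detectable_bp: int = 0,
    enzymes: tuple[RestrictionEnzyme, RestrictionEnzyme] = (HAEIII, SAU3AI),
) -> ArdraGrouping:
    """Two-stage ARDRA grouping of isolate amplicons.

    Stage 1 partitions isolates by first-enzyme (HaeIII) pattern equivalence;
    stage 2 re-partitions each stage-1 group by second-enzyme (Sau3AI)
    equivalence.  Representatives are the lexicographically smallest isolate
    id in each final group (the deterministic stand-in for the survey's
    unstated pick of which isolate to sequence).
    """
    if not sequences:
        raise ValueError("no sequences to group")
    first, second = enzymes
    pat1 = {iso: digest(seq, first) for iso, seq in sequences.items()}
    pat2 = {iso: digest(seq, second) for iso, seq in sequences.items()}

    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    group_id = 0
    for stage1 in _partition(list(sequences), pat1, tolerance_fraction, min_detectable_bp):
        for stage2 in _partition(stage1, pat2, tolerance_fraction, min_detectable_bp):
            for iso in stage2:
                assignments[iso] = group_id
            representatives[group_id] = min(stage2)
            group_id += 1
    return ArdraGrouping(assignments=assignments, representatives=representatives)
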