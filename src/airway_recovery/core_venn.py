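"""Prevalence-thresholded core-microbiome sets and Venn partitions."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass(frozen=True)
class CoreSet:
    stratum: str
    threshold: float
    members: frozenset[str]


@dataclass
class VennPartition:
    """Counts of every non-empty membership-pattern region of 2-4 sets."""

    labels: tuple[str, ...]
    regions: dict[tuple[str, ...], int]
    members: dict[tuple[str, ...], frozenset[str]]


def core_taxa(prevalence, threshold: float = 0.8, stratum: str = "") -> CoreSet:
    """Taxa whose subject-level prevalence meets the threshold (inclusive).

    The emulated design uses 0.8 for core genera and 0.5 for network core
    ASVs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    prev = pd.Series(prevalence)
    if ((prev < 0) | (prev > 1)).any():
        raise ValueError("prevalence values must lie in [0, 1]")
    members = frozenset(prev.index[prev >= threshold])
    return CoreSet(stratum=stratum, threshold=threshold, members=members)


def venn_partition(sets: dict[str, set]) -> VennPartition:
    """Partition the union of 2-4 labelled sets into membership regions.

    Every element of the union lands in exactly one region, keyed by the
    sorted-by-label-order tuple of sets containing it.
    """
    labels = tuple(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn_partition requires between 2 and 4 sets")
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")
    regions: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], set] = {}
    union = set().union(*sets.values())
    for el in union:
        key = tuple(l for l in labels if el in sets[l])
        regions[key] = regions.get(key, 0) + 1
        members.setdefault(key, set()).add(el)
    # deterministic region ordering: by size of pattern then label order
    order = sorted(regions, key=lambda k: (len(k), tuple(labels.index(l) for l in k)))
    return VennPartition(
        labels=labels,
        regions={k: regions[k] for k in order},
        members={k: frozenset(members[k]) for k in order},
    )


def core_overlap_table(cores_by_site: dict[str, dict[str, set]]) -> pd.DataFrame:
    """Long-format overlap table: one row per (site, region pattern).

    ``cores_by_site`` maps site -> {group -> core member set}.
    """
    rows = []
    for site, by_group in cores_by_site.items():
        if len(by_group) < 2:
            raise ValueError(f"site {site!r}: need at least 2 core sets")
        part = venn_partition({g: set(s) for g, s in by_group.items()})
        for pattern, count in part.regions.items():
            rows.append({
                "site": site,
                "region": "&".join(pattern),
                "count": count,
                "members": ";".join(sorted(map(str, part.members[pattern]))),
            })
    return pd.DataFrame(rows, columns=["site", "region", "count", "members"])


def all_region_patterns(labels: tuple[str, ...]):
    """All non-empty label subsets in the deterministic region order."""
    pats = []
    for r in range(1, len(labels) + 1):
        pats.extend(combinations(labels, r))
    return pats
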