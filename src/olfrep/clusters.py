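"""Tandem gene-cluster analysis.

A gene cluster is a contiguous run of receptor genes on one scaffold whose
largest intergenic gap does not exceed one third of the cluster's genomic
span. The rule is self-referential (the allowed gap grows with the span),
so clusters are built by smallest-gap-first agglomeration of adjacent
clusters until no admissible merge remains; this is deterministic and
insensitive to coordinate translation.

Also here: pairwise sequence identity (PSI) matrices in genomic order,
greedy identity-threshold grouping of receptor proteins, and cluster
homology mapping through shared flanking synteny anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import percent_identity
from .annotate import GeneModel


@dataclass(frozen=True)
class GeneCluster:
    id: str
    scaffold: str
    members: tuple[str, ...]  # gene ids in genomic order
    start: int
    end: int
    family_counts: dict[str, int] = field(default_factory=dict, compare=False)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HomologyLink:
    cluster_a: str
    clusters_b: tuple[str, ...]
    anchors: tuple[str, ...]
    split: bool


class GeneOverlapError(ValueError):
    pass


def _max_gap(intervals: list[tuple[int, int]]) -> int:
    return max(
        (intervals[i + 1][0] - intervals[i][1] for i in range(len(intervals) - 1)),
        default=0,
    )


def validate_cluster(intervals: list[tuple[int, int]]) -> bool:
    """True iff the largest intergenic gap is at most a third of the span."""
    if len(intervals) <= 1:
        return True
    span = intervals[-1][1] - intervals[0][0]
    return _max_gap(intervals) <= span / 3


def call_clusters(models: list[GeneModel], prefix: str = "cl") -> list[GeneCluster]:
    """Partition one scaffold's genes into clusters under the gap rule.

    Starting from singletons, the adjacent cluster pair with the smallest
    inter-cluster gap whose merged cluster still satisfies
    max-gap <= span/3 is merged; ties go to the leftmost pair; merging
    stops at a fixed point.
    """
    if not models:
        return []
    scaffolds = {m.scaffold for m in models}
    if len(scaffolds) != 1:
        raise ValueError("call_clusters expects genes from one scaffold")
    ordered = sorted(models, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise GeneOverlapError(f"genes {a.id} and {b.id} overlap")

    blocks: list[list[GeneModel]] = [[m] for m in ordered]
    while True:
        best = None  # (gap, index)
        for i in range(len(blocks) - 1):
            left, right = blocks[i], blocks[i + 1]
            gap = right[0].start - left[-1].end
            merged = left + right
            if validate_cluster([(m.start, m.end) for m in merged]):
                if best is None or gap < best[0]:
                    best = (gap, i)
        if best is None:
            break
        i = best[1]
        blocks[i: i + 2] = [blocks[i] + blocks[i + 1]]

    clusters = []
    for k, block in enumerate(blocks):
        fam: dict[str, int] = {}
        for m in block:
            fam[m.family] = fam.get(m.family, 0) + 1
        clusters.append(
            GeneCluster(
                id=f"{prefix}{k + 1}",
                scaffold=block[0].scaffold,
                members=tuple(m.id for m in block),
                start=block[0].start,
                end=block[-1].end,
                family_counts=fam,
            )
        )
    return clusters


def call_clusters_genome(models: list[GeneModel]) -> list[GeneCluster]:
    """Cluster every scaffold; ids are numbered genome-wide."""
    out: list[GeneCluster] = []
    counter = 0
    for scaffold in sorted({m.scaffold for m in models}):
        sub = [m for m in models if m.scaffold == scaffold]
        for cluster in call_clusters(sub, prefix=""):
            counter += 1
            out.append(
                GeneCluster(
                    id=f"cl{counter}",
                    scaffold=cluster.scaffold,
                    members=cluster.members,
                    start=cluster.start,
                    end=cluster.end,
                    family_counts=cluster.family_counts,
                )
            )
    return out


def filter_for_display(
    clusters: list[GeneCluster], min_genes: int = 5
) -> list[GeneCluster]:
    """Drop clusters below the display threshold (default: fewer than 5)."""
    return [c for c in clusters if c.size >= min_genes]


def psi_matrix(proteins: dict[str, str] | list[tuple[str, str]]) -> pd.DataFrame:
    """Pairwise percent-identity matrix in the given (genomic) order.

    Global BLOSUM62 alignment with affine gaps 11/1; identity is identical
    columns over alignment columns, terminal gap columns excluded.
    """
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    if not items:
        raise ValueError("psi_matrix needs at least one protein")
    if any(not seq for _, seq in items):
        raise ValueError("empty protein sequence")
    ids = [gid for gid, _ in items]
    n = len(items)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = percent_identity(items[i][1], items[j][1])
    return pd.DataFrame(mat, index=ids, columns=ids)


def identity_groups(
    proteins: dict[str, str] | list[tuple[str, str]], threshold: float
) -> list[dict]:
    """Greedy longest-first grouping at an identity threshold.

    Sequences are visited in order of decreasing length; each joins the
    first existing group whose representative it matches at or above the
    threshold, otherwise it founds a new group.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    ordered = sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))
    groups: list[dict] = []
    for gid, seq in ordered:
        for group in groups:
            if percent_identity(seq, group["representative_seq"]) >= threshold:
                group["members"].append(gid)
                break
        else:
            groups.append(
                {"representative": gid, "representative_seq": seq, "members": [gid]}
            )
    return groups


def cluster_homology(
    clusters_a: list[GeneCluster],
    clusters_b: list[GeneCluster],
    anchors: dict[str, set[str]],
) -> list[HomologyLink]:
    """Match clusters across species via shared flanking anchor groups.

    ``anchors`` maps cluster id -> set of flanking-gene ortholog-group ids.
    A cluster matching two or more partners is flagged as a rearrangement
    split. Clusters without anchors yield no links (reported silently).
    """
    links = []
    for ca in clusters_a:
        ga = anchors.get(ca.id, set())
        matched = []
        shared: set[str] = set()
        for cb in clusters_b:
            common = ga & anchors.get(cb.id, set())
            if common:
                matched.append(cb.id)
                shared |= common
        if matched:
            links.append(
                HomologyLink(
                    cluster_a=ca.id,
                    clusters_b=tuple(sorted(matched)),
                    anchors=tuple(sorted(shared)),
                    split=len(matched) >= 2,
                )
            )
    return links
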