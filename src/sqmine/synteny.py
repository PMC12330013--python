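"""Colinear syntenic block matching with bounded insertion tolerance.

Within a co-location cluster, a *block* is a set of genes whose family
labels, read in genomic order, equal a contiguous sub-run of a reference
arrangement — either in the arrangement's order (forward) or in its exact
reverse (reverse orientation). Genes lying between matched genes but not
part of the match count as insertions, whether they are unassigned or
assigned to an off-pattern family; the total per block is bounded by
``max_insertions`` (default 2). A block must match at least
``min(min_block, |pattern|)`` genes (default min_block 4, relaxed to the
pattern length so short marker arrangements stay callable).

``find_blocks`` is the production search (pruned depth-first chain
extension); ``brute_force_blocks`` is an exhaustive subsequence enumerator
used as a test oracle on small clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

from .catalog import MiningParams
from .colocation import GeneCluster

__all__ = ["SyntenyMatch", "find_blocks", "brute_force_blocks"]

_ORACLE_MAX_GENES = 15


@dataclass(frozen=True)
class SyntenyMatch:
    """One colinear block matched against one reference arrangement."""

    pathway_id: str
    arrangement_index: int
    genome_id: str
    cluster_id: str
    matched_genes: tuple[tuple[str, str], ...]  # (gene_id, family_id), genomic order
    n_insertions: int
    orientation: str  # "forward" | "reverse"
    sum_bitscore: float = field(compare=False, default=0.0)
    start_index: int = field(compare=False, default=0)  # slot index within cluster

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for _, f in self.matched_genes)

    def __len__(self) -> int:
        return len(self.matched_genes)


@dataclass(frozen=True)
class _Slot:
    family: str | None
    gene_id: str | None
    bitscore: float


def _slots(cluster: GeneCluster) -> list[_Slot]:
    """Cluster genes in genomic order: members plus unassigned interveners."""
    out: list[_Slot] = []
    for i, (feat, asg) in enumerate(cluster.members):
        if i > 0:
            out.extend([_Slot(None, None, 0.0)] * cluster.intervening_counts[i - 1])
        out.append(_Slot(asg.family_id, feat.gene_id, asg.bitscore))
    return out


def _min_len(params: MiningParams, pattern: Sequence[str]) -> int:
    return min(params.min_block, len(pattern))


def _build_match(
    cluster: GeneCluster,
    slots: list[_Slot],
    indices: Sequence[int],
    orientation: str,
    pathway_id: str,
    arrangement_index: int,
) -> SyntenyMatch:
    span = indices[-1] - indices[0] + 1
    return SyntenyMatch(
        pathway_id=pathway_id,
        arrangement_index=arrangement_index,
        genome_id=cluster.genome_id,
        cluster_id=cluster.cluster_id,
        matched_genes=tuple((slots[i].gene_id, slots[i].family) for i in indices),
        n_insertions=span - len(indices),
        orientation=orientation,
        sum_bitscore=sum(slots[i].bitscore for i in indices),
        start_index=indices[0],
    )


def _sort_key(m: SyntenyMatch):
    return (
        -len(m),
        -m.sum_bitscore,
        m.start_index,
        m.orientation != "forward",
        m.matched_genes,
    )


def find_blocks(
    cluster: GeneCluster,
    pattern: Sequence[str],
    params: MiningParams | None = None,
    pathway_id: str = "",
    arrangement_index: int = 0,
) -> list[SyntenyMatch]:
    """All maximal colinear blocks of ``cluster`` matching ``pattern``.

    A block is maximal when its matched gene set is not a strict subset of
    another valid block's. Blocks are reported longest-first; ties break to
    higher summed bitscore, then leftmost start, forward before reverse.
    Returns an empty list when nothing matches.
    """
    params = params or MiningParams()
    if not pattern:
        raise ValueError("pattern must be non-empty")
    slots = _slots(cluster)
    need = _min_len(params, pattern)

    raw: list[tuple[tuple[int, ...], str]] = []
    directions = [("forward", tuple(pattern))]
    if len(pattern) > 1:
        directions.append(("reverse", tuple(reversed(pattern))))

    for orientation, pat in directions:
        n, m = len(slots), len(pat)

        def feasible_next(first: int, last: int, matched: int, s1: int) -> bool:
            if params.per_pair_insertions:
                return s1 - last - 1 <= params.max_insertions
            return (s1 - first + 1) - (matched + 1) <= params.max_insertions

        def extend(path: list[int], p: int) -> None:
            last = path[-1]
            extended = False
            if p + 1 < m:
                for s1 in range(last + 1, n):
                    if not feasible_next(path[0], last, len(path), s1):
                        if not params.per_pair_insertions:
                            break  # insertions only grow with s1
                        continue
                    if slots[s1].family == pat[p + 1]:
                        extended = True
                        path.append(s1)
                        extend(path, p + 1)
                        path.pop()
            if not extended:
                raw.append((tuple(path), orientation))

        for p0 in range(m):
            for s0 in range(n):
                if slots[s0].family == pat[p0]:
                    extend([s0], p0)

    # validity, dedupe (forward preferred), maximality
    valid = [(idx, ori) for idx, ori in raw if len(idx) >= need]
    dedup: dict[frozenset[int], tuple[tuple[int, ...], str]] = {}
    for idx, ori in sorted(valid, key=lambda c: (c[1] != "forward", c[0])):
        dedup.setdefault(frozenset(idx), (idx, ori))
    kept = list(dedup.items())
    maximal = [
        (idx, ori)
        for key, (idx, ori) in kept
        if not any(key < other for other, _ in dedup.items() if other != key)
    ]
    matches = [
        _build_match(cluster, slots, idx, ori, pathway_id, arrangement_index)
        for idx, ori in maximal
    ]
    return sorted(matches, key=_sort_key)


def _subruns(pat: tuple[str, ...], length: int) -> Iterator[tuple[str, ...]]:
    for a in range(len(pat) - length + 1):
        yield pat[a : a + length]


def brute_force_blocks(
    cluster: GeneCluster,
    pattern: Sequence[str],
    params: MiningParams | None = None,
    pathway_id: str = "",
    arrangement_index: int = 0,
) -> list[SyntenyMatch]:
    """Exhaustive oracle: identical output to ``find_blocks`` by
    enumeration of every subsequence of the cluster's gene slots.

    Refuses clusters longer than 15 genes (2^15 subsets).
    """
    params = params or MiningParams()
    if not pattern:
        raise ValueError("pattern must be non-empty")
    slots = _slots(cluster)
    if len(slots) > _ORACLE_MAX_GENES:
        raise ValueError(
            f"oracle limited to clusters of <= {_ORACLE_MAX_GENES} genes, "
            f"got {len(slots)}"
        )
    pat_f = tuple(pattern)
    pat_r = tuple(reversed(pattern))
    need = _min_len(params, pattern)
    assigned = [i for i, s in enumerate(slots) if s.family is not None]

    candidates: list[tuple[tuple[int, ...], str]] = []
    for size in range(need, min(len(assigned), len(pat_f)) + 1):
        for idx in combinations(assigned, size):
            if params.per_pair_insertions:
                if any(b - a - 1 > params.max_insertions for a, b in zip(idx, idx[1:])):
                    continue
            else:
                if (idx[-1] - idx[0] + 1) - size > params.max_insertions:
                    continue
            fams = tuple(slots[i].family for i in idx)
            if fams in set(_subruns(pat_f, size)):
                candidates.append((idx, "forward"))
            elif len(pat_f) > 1 and fams in set(_subruns(pat_r, size)):
                candidates.append((idx, "reverse"))

    # maximality: drop candidates strictly contained in another candidate
    sets = [set(idx) for idx, _ in candidates]
    maximal = [
        (idx, ori)
        for k, (idx, ori) in enumerate(candidates)
        if not any(sets[k] < s for j, s in enumerate(sets) if j != k)
    ]
    matches = [
        _build_match(cluster, slots, idx, ori, pathway_id, arrangement_index)
        for idx, ori in maximal
    ]
    return sorted(matches, key=_sort_key)
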