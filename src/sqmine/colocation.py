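"""Co-location: group family-assigned genes into clusters by proximity.

Two consecutive assigned genes on the same contig belong to one cluster when
their intergenic distance (start of the later gene minus end of the earlier
gene minus 1; overlapping genes count as 0) is at most ``max_gap_nt``
(inclusive, default 3500 nt). Clusters are maximal runs under this chaining
relation, so they partition the assigned genes; singletons are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import MiningParams
from .genome_io import FamilyAssignment, GeneFeature

__all__ = ["GeneCluster", "build_clusters", "intergenic_distance", "clusters_to_bed", "clusters_to_tsv"]


def intergenic_distance(earlier: GeneFeature, later: GeneFeature) -> int:
    """Nucleotides strictly between two genes; overlaps clamp to 0."""
    return max(0, later.start - earlier.end - 1)


@dataclass(frozen=True)
class GeneCluster:
    """A maximal run of proximal family-assigned genes on one contig."""

    cluster_id: str
    genome_id: str
    contig_id: str
    members: tuple[tuple[GeneFeature, FamilyAssignment], ...]
    intervening_counts: tuple[int, ...]  # unassigned genes between members

    def __post_init__(self) -> None:
        if len(self.intervening_counts) != max(0, len(self.members) - 1):
            raise ValueError(
                f"cluster {self.cluster_id}: need |members|-1 intervening counts"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(f.start for f, _ in self.members),
            max(f.end for f, _ in self.members),
        )

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(a.family_id for _, a in self.members)

    def __len__(self) -> int:
        return len(self.members)


def build_clusters(
    features: Sequence[GeneFeature],
    assignments: Mapping[str, FamilyAssignment] | Iterable[FamilyAssignment],
    params: MiningParams | None = None,
) -> list[GeneCluster]:
    """Chain assigned genes into maximal proximity clusters.

    ``assignments`` maps gene_id to its family assignment (or is an iterable
    of assignments). An assignment referencing a gene absent from
    ``features`` raises ``KeyError``; filter such assignments upstream if a
    lenient join is wanted.

    With ``params.require_co_orientation`` a strand flip also splits
    clusters (off by default).
    """
    params = params or MiningParams()
    if not isinstance(assignments, Mapping):
        assignments = {a.gene_id: a for a in assignments}

    by_gene = {f.gene_id: f for f in features}
    unknown = sorted(set(assignments) - set(by_gene))
    if unknown:
        raise KeyError(
            f"assignments reference genes absent from features: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )

    # contig order is independent of input ordering
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in sorted(features, key=lambda f: (f.contig_id, f.rank)):
        by_contig.setdefault(f.contig_id, []).append(f)

    clusters: list[GeneCluster] = []
    for contig_id in sorted(by_contig):
        genes = by_contig[contig_id]
        assigned = [g for g in genes if g.gene_id in assignments]
        if not assigned:
            continue
        runs: list[list[GeneFeature]] = [[assigned[0]]]
        for prev, cur in zip(assigned, assigned[1:]):
            split = intergenic_distance(prev, cur) > params.max_gap_nt
            if params.require_co_orientation and prev.strand != cur.strand:
                split = True
            if split:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        for run in runs:
            genome_id = run[0].genome_id
            cid = f"{genome_id}|{contig_id}|{run[0].start}"
            members = tuple((g, assignments[g.gene_id]) for g in run)
            intervening = tuple(
                cur.rank - prev.rank - 1 for prev, cur in zip(run, run[1:])
            )
            clusters.append(
                GeneCluster(cid, genome_id, contig_id, members, intervening)
            )
    return clusters


def clusters_to_tsv(clusters: Iterable[GeneCluster], path: str | Path | None = None) -> pd.DataFrame:
    rows = []
    for c in clusters:
        start, end = c.span
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "start": start,
                "end": end,
                "n_members": len(c),
                "families": ",".join(c.families),
                "genes": ",".join(f.gene_id for f, _ in c.members),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "genome_id", "contig_id", "start", "end",
            "n_members", "families", "genes",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def clusters_to_bed(clusters: Iterable[GeneCluster], path: str | Path | None = None) -> str:
    """BED6 export; 1-based inclusive spans become 0-based half-open."""
    lines = []
    for c in clusters:
        start, end = c.span
        lines.append(f"{c.contig_id}\t{start - 1}\t{end}\t{c.cluster_id}\t{len(c)}\t.")
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
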