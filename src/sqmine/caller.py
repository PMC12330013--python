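"""Pathway calling and per-bin prevalence tabulation.

A pathway is called *complete* in a genome when a single colinear block
covers all core families of one of its reference arrangements (a cluster-
level criterion: genes split across contigs or distant clusters never
complete a pathway). Per-genome calls are then tabulated per species-level
genome bin into counts and percentages, with collection totals over MAGs
and over bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Catalog, MiningParams
from .colocation import GeneCluster, build_clusters
from .genome_io import DomainHit, FamilyAssignment, GeneFeature, assign_families
from .synteny import SyntenyMatch, find_blocks

__all__ = [
    "GenomeCall",
    "mine_genome",
    "call_pathways",
    "summarize_bins",
    "summary_to_tsv",
    "calls_to_tsv",
    "round_pct",
    "TOTAL_MAGS_ROW",
    "TOTAL_BINS_ROW",
]

TOTAL_MAGS_ROW = "TOTAL_MAGS"
TOTAL_BINS_ROW = "TOTAL_BINS"

EXTENDED_FLAG = "extended_sulfoglycolytic"
SQDG_CLEAVAGE_FLAG = "sqdg_cleavage"
_SULFOQUINOVOSIDASES = ("YihQ", "SqgA")


@dataclass
class GenomeCall:
    """Per-genome result: complete pathways, evidence blocks, QC flags."""

    genome_id: str
    pathways: frozenset[str] = frozenset()
    evidence: dict[str, SyntenyMatch] = field(default_factory=dict)
    flags: frozenset[str] = frozenset()
    qc: tuple[str, ...] = ()
    bin_id: str | None = None

    def __post_init__(self) -> None:
        missing = self.pathways - set(self.evidence)
        if missing:
            raise ValueError(f"called pathways without evidence: {sorted(missing)}")


def _best_match(matches: Sequence[SyntenyMatch]) -> SyntenyMatch:
    return min(matches, key=lambda m: (-len(m), -m.sum_bitscore, m.cluster_id))


def call_pathways(
    genome_id: str,
    clusters: Sequence[GeneCluster],
    catalog: Catalog,
    params: MiningParams | None = None,
    assignments: Mapping[str, FamilyAssignment] | None = None,
) -> GenomeCall:
    """Call complete pathways for one genome from its clusters.

    ``assignments`` (all family assignments of the genome) is only needed
    for QC fragmentation notes, the sulfoquinovosidase annotation flag and
    the genome-level sensitivity mode.
    """
    params = params or MiningParams()
    called: set[str] = set()
    evidence: dict[str, SyntenyMatch] = {}
    qc: list[str] = []

    for pw in catalog.pathways.values():
        qualifying: list[SyntenyMatch] = []
        for ai, arrangement in enumerate(pw.arrangements):
            for cluster in clusters:
                for m in find_blocks(cluster, arrangement, params, pw.pathway_id, ai):
                    if pw.core_families <= set(m.families):
                        qualifying.append(m)
        if qualifying:
            called.add(pw.pathway_id)
            evidence[pw.pathway_id] = _best_match(qualifying)
        elif assignments is not None:
            assigned_fams = {a.family_id for a in assignments.values()}
            if pw.core_families <= assigned_fams:
                if params.genome_level_completeness:
                    # sensitivity mode: cores anywhere in the genome suffice
                    called.add(pw.pathway_id)
                    placeholder = SyntenyMatch(
                        pathway_id=pw.pathway_id,
                        arrangement_index=-1,
                        genome_id=genome_id,
                        cluster_id="<genome-level>",
                        matched_genes=tuple(
                            (a.gene_id, a.family_id)
                            for a in sorted(
                                assignments.values(), key=lambda a: a.gene_id
                            )
                            if a.family_id in pw.core_families
                        ),
                        n_insertions=0,
                        orientation="forward",
                    )
                    evidence[pw.pathway_id] = placeholder
                else:
                    qc.append(f"fragmented:{pw.pathway_id}")

    flags: set[str] = set()
    if any(p.startswith("sulfo-") for p in called) and any(
        p.startswith("DHPS-") for p in called
    ):
        flags.add(EXTENDED_FLAG)
    if assignments is not None and any(
        a.family_id in _SULFOQUINOVOSIDASES for a in assignments.values()
    ):
        flags.add(SQDG_CLEAVAGE_FLAG)

    return GenomeCall(
        genome_id=genome_id,
        pathways=frozenset(called),
        evidence=evidence,
        flags=frozenset(flags),
        qc=tuple(qc),
    )


def mine_genome(
    features: Sequence[GeneFeature],
    hits: Iterable[DomainHit],
    catalog: Catalog,
    params: MiningParams | None = None,
    genome_id: str | None = None,
) -> GenomeCall:
    """Full per-genome pipeline: filter hits, cluster, match, call.

    Hits to genes absent from the feature table are dropped with a warning
    (mixed annotation sources are common); a genome with no features or no
    qualifying hits yields an empty call, never an error.
    """
    params = params or MiningParams()
    if genome_id is None:
        genome_id = features[0].genome_id if features else "genome"
    assignments, _ = assign_families(hits, catalog)
    known_genes = {f.gene_id for f in features}
    orphans = set(assignments) - known_genes
    if orphans:
        warnings.warn(
            f"{genome_id}: dropped {len(orphans)} assignment(s) to genes "
            "absent from the feature table",
            stacklevel=2,
        )
        assignments = {g: a for g, a in assignments.items() if g in known_genes}
    clusters = build_clusters(features, assignments, params)
    return call_pathways(genome_id, clusters, catalog, params, assignments)


# ---------------------------------------------------------------------------
# Per-bin tabulation
# ---------------------------------------------------------------------------


def round_pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (exact rational arithmetic)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_bins(
    calls: Iterable[GenomeCall],
    bin_map: Mapping[str, str],
    catalog: Catalog | None = None,
) -> pd.DataFrame:
    """Tabulate pathway prevalence per species-level bin.

    One row per bin (ordered by total genome count descending, then bin id)
    plus two collection-total rows: ``TOTAL_MAGS`` (counts/percentages over
    all genomes) and ``TOTAL_BINS`` (number of bins with >= 1 positive
    genome, percentages over all bins). Besides per-pathway columns, the
    category tallies ``sq_any`` (any sulfoglycolytic pathway), ``dhps_any``
    and ``both`` count each genome once per category however many pathways
    it carries.
    """
    calls = list(calls)
    missing = sorted({c.genome_id for c in calls} - set(bin_map))
    if missing:
        raise KeyError(f"genomes absent from bin map: {missing[:10]}")

    if catalog is not None:
        pathway_ids = list(catalog.pathways)
    else:
        pathway_ids = sorted({p for c in calls for p in c.pathways})
    categories = ["sq_any", "dhps_any", "both"]

    def cats(call: GenomeCall) -> set[str]:
        sq = any(p.startswith("sulfo-") for p in call.pathways)
        dhps = any(p.startswith("DHPS-") for p in call.pathways)
        out = set()
        if sq:
            out.add("sq_any")
        if dhps:
            out.add("dhps_any")
        if sq and dhps:
            out.add("both")
        return out

    per_bin: dict[str, dict[str, int]] = {}
    bin_sizes: dict[str, int] = {}
    for call in calls:
        b = bin_map[call.genome_id]
        bin_sizes[b] = bin_sizes.get(b, 0) + 1
        counts = per_bin.setdefault(b, {k: 0 for k in pathway_ids + categories})
        for p in call.pathways:
            if p in counts:
                counts[p] += 1
        for c in cats(call):
            counts[c] += 1

    n_mags = len(calls)
    n_bins = len(bin_sizes)
    order = sorted(bin_sizes, key=lambda b: (-bin_sizes[b], b))

    cols = pathway_ids + categories
    rows = []
    for b in order:
        row: dict[str, object] = {"bin_id": b, "n_genomes": bin_sizes[b]}
        for k in cols:
            row[f"{k}_n"] = per_bin[b][k]
            row[f"{k}_pct"] = round_pct(per_bin[b][k], bin_sizes[b])
        rows.append(row)

    total_mags: dict[str, object] = {"bin_id": TOTAL_MAGS_ROW, "n_genomes": n_mags}
    total_bins: dict[str, object] = {"bin_id": TOTAL_BINS_ROW, "n_genomes": n_bins}
    for k in cols:
        mag_count = sum(per_bin[b][k] for b in order)
        bin_count = sum(1 for b in order if per_bin[b][k] > 0)
        total_mags[f"{k}_n"] = mag_count
        total_mags[f"{k}_pct"] = round_pct(mag_count, n_mags)
        total_bins[f"{k}_n"] = bin_count
        total_bins[f"{k}_pct"] = round_pct(bin_count, n_bins)
    rows.extend([total_mags, total_bins])

    columns = ["bin_id", "n_genomes"]
    for k in cols:
        columns.extend([f"{k}_n", f"{k}_pct"])
    return pd.DataFrame(rows, columns=columns)


def summary_to_tsv(summary: pd.DataFrame, path: str | Path | None = None) -> str:
    """Serialize a bin summary deterministically (percentages as '%.1f')."""
    df = summary.copy()
    for col in df.columns:
        if col.endswith("_pct"):
            df[col] = df[col].map(lambda v: f"{v:.1f}")
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def calls_to_tsv(
    calls: Iterable[GenomeCall], path: str | Path | None = None
) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda c: c.genome_id):
        rows.append(
            {
                "genome_id": c.genome_id,
                "bin_id": c.bin_id or "",
                "pathways": ",".join(sorted(c.pathways)),
                "flags": ",".join(sorted(c.flags)),
                "qc": ",".join(c.qc),
            }
        )
    df = pd.DataFrame(rows, columns=["genome_id", "bin_id", "pathways", "flags", "qc"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
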