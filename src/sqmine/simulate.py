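"""Synthetic genome cohorts with planted SQ/DHPS gene clusters.

The generator emulates the structure the miner assumes in a MAG collection:
contigs of ordered genes with realistic lengths and intergenic gaps,
planted pathway arrangements that satisfy (or deliberately violate, one
criterion at a time) the mining thresholds, inserted non-pathway genes,
fragmentation across contigs, and background decoy hits whose bitscores
straddle the homolog cutoff. Every genome carries a truth record of its
intended calls, so mined summaries can be compared against ground truth.

Fixed seeds give byte-identical outputs. The generator emits coordinates
and scores, not sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .caller import GenomeCall, mine_genome, summarize_bins
from .catalog import Catalog, MiningParams, default_catalog, singleton_callable_families
from .colocation import intergenic_distance
from .genome_io import DomainHit, GeneFeature

__all__ = [
    "CohortSpec",
    "SyntheticGenome",
    "Cohort",
    "TruthCall",
    "generate_genome",
    "generate_cohort",
    "mine_cohort",
    "VIOLATIONS",
]

VIOLATIONS = (None, "gap", "insertions", "fragment")

_PLANT_BUFFER_NT = 6000  # keeps planted clusters distinct from neighbours
_SIM_SOURCE = "sqmine-sim"


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults model a small MAG collection: ~60 genes per genome over 3
    contigs, lognormal gene lengths with ~900 nt median, near-operonic
    intergenic gaps (normal, mean 120 nt, sd 80 nt, truncated at 0), and a
    background of decoy HMM hits (mostly sub-cutoff, rare isolated
    supra-cutoff singletons).
    """

    n_genomes: int = 200
    n_bins: int = 20
    prevalence: dict[str, float] = field(default_factory=dict)
    violation: str | None = None  # applied to every plant
    gene_len_median: float = 900.0
    gene_len_sigma: float = 0.45
    gap_mean: float = 120.0
    gap_sd: float = 80.0
    gap_max: float = 3000.0
    n_background_genes: int = 60
    n_contigs: int = 3
    max_planted_insertions: int = 2
    decoy_rate: float = 8.0
    supra_decoy_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{pid!r}] must lie in [0,1], got {p}")
        if self.violation not in VIOLATIONS:
            raise ValueError(f"unknown violation {self.violation!r}")
        if self.n_contigs < 1 or self.n_genomes < 1 or self.n_bins < 1:
            raise ValueError("n_genomes, n_bins and n_contigs must be >= 1")


@dataclass(frozen=True)
class TruthCall:
    """Ground-truth analogue of a GenomeCall (pathways intended callable)."""

    genome_id: str
    pathways: frozenset[str]


@dataclass
class SyntheticGenome:
    genome_id: str
    bin_id: str
    features: list[GeneFeature]
    hits: list[DomainHit]
    truth: dict[str, bool]  # pathway_id -> intended call

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for f in self.features:
            lines.append(
                f"{f.contig_id}\t{_SIM_SOURCE}\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.gene_id}"
            )
        return "\n".join(lines) + "\n"

    def hits_tsv_text(self) -> str:
        lines = ["#gene_id\tfamily_id\tbitscore"]
        for h in self.hits:
            lines.append(f"{h.gene_id}\t{h.family_id}\t{h.bitscore:.1f}")
        return "\n".join(lines) + "\n"


@dataclass
class Cohort:
    spec: CohortSpec
    genomes: list[SyntheticGenome]
    bin_map: dict[str, str]
    truth_summary: pd.DataFrame

    def truth_calls(self) -> list[TruthCall]:
        return [
            TruthCall(g.genome_id, frozenset(p for p, v in g.truth.items() if v))
            for g in self.genomes
        ]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        (out / "hits").mkdir(parents=True, exist_ok=True)
        for g in self.genomes:
            (out / "genomes" / f"{g.genome_id}.gff3").write_text(g.gff3_text())
            (out / "hits" / f"{g.genome_id}.tsv").write_text(g.hits_tsv_text())
        bins = pd.DataFrame(
            sorted(self.bin_map.items()), columns=["genome_id", "bin_id"]
        )
        bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        rows = [
            {
                "genome_id": g.genome_id,
                "bin_id": g.bin_id,
                "pathways": ",".join(sorted(p for p, v in g.truth.items() if v)),
            }
            for g in self.genomes
        ]
        pd.DataFrame(rows, columns=["genome_id", "bin_id", "pathways"]).to_csv(
            out / "truth_calls.tsv", sep="\t", index=False
        )
        from .caller import summary_to_tsv

        summary_to_tsv(self.truth_summary, out / "truth_summary.tsv")
        return out


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


@dataclass
class _Item:
    """One gene slot before coordinates are laid down."""

    length: int
    gap_before: int
    family: str | None = None  # family with a planted supra-cutoff hit
    bitscore: float = 0.0


def _gene_length(rng: np.random.Generator, spec: CohortSpec) -> int:
    ln = rng.lognormal(mean=np.log(spec.gene_len_median), sigma=spec.gene_len_sigma)
    return max(90, int(round(ln / 3.0)) * 3)  # whole codons, >= 30 aa


def _gap(rng: np.random.Generator, spec: CohortSpec) -> int:
    g = rng.normal(spec.gap_mean, spec.gap_sd)
    return int(round(min(max(g, 0.0), spec.gap_max)))


def _core_split_point(arrangement: Sequence[str], core: frozenset[str]) -> int:
    """Index after which to split so both sides miss >= 1 core family."""
    core_pos = [i for i, fam in enumerate(arrangement) if fam in core]
    if len(core_pos) < 2:
        raise ValueError(
            "violation plants need >= 2 core genes in the arrangement; "
            f"got {list(arrangement)} with core {sorted(core)}"
        )
    return core_pos[0]  # split between first and second core gene


def _inserted_decoy(rng: np.random.Generator, spec: CohortSpec) -> _Item:
    # Inserted genes sit between pattern genes, so their length plus the
    # flanking gaps counts toward the intergenic distance of the pattern
    # pair. Capping keeps even a 3-gene insertion run within 3500 nt, so
    # insertion plants violate only the insertion-tolerance criterion.
    return _Item(
        length=min(_gene_length(rng, spec), 1000),
        gap_before=min(_gap(rng, spec), 80),
    )


def _plant_items(
    rng: np.random.Generator,
    spec: CohortSpec,
    arrangement: Sequence[str],
    core: frozenset[str],
    violation: str | None,
) -> tuple[list[_Item], list[_Item]]:
    """Items for one plant; second list is non-empty only for fragmentation."""
    items = [
        _Item(
            length=_gene_length(rng, spec),
            gap_before=_gap(rng, spec),
            family=fam,
            bitscore=float(rng.uniform(120.0, 250.0)),
        )
        for fam in arrangement
    ]

    if violation is None:
        n_ins = int(rng.integers(0, spec.max_planted_insertions + 1))
        if len(items) > 1:
            for _ in range(n_ins):
                pos = int(rng.integers(1, len(items)))  # internal positions only
                items.insert(pos, _inserted_decoy(rng, spec))
                items[pos + 1].gap_before = min(items[pos + 1].gap_before, 80)
        return items, []

    split = _core_split_point(arrangement, core)
    if violation == "gap":
        items[split + 1].gap_before = 3501 + int(rng.integers(0, 2000))
        return items, []
    if violation == "insertions":
        for _ in range(3):
            items.insert(split + 1, _inserted_decoy(rng, spec))
            items[split + 2].gap_before = min(items[split + 2].gap_before, 80)
        return items, []
    if violation == "fragment":
        return items[: split + 1], items[split + 1 :]
    raise ValueError(f"unknown violation {violation!r}")


def generate_genome(
    spec: CohortSpec,
    genome_id: str,
    bin_id: str,
    planted: Sequence[tuple[str, str | None]],
    seed: int,
    catalog: Catalog | None = None,
    params: MiningParams | None = None,
) -> SyntheticGenome:
    """Generate one genome with the given plants.

    ``planted`` pairs a pathway id with a violation (``None`` for a clean,
    callable plant; ``"gap"``, ``"insertions"`` or ``"fragment"`` to break
    exactly the co-location, insertion-tolerance or single-contig criterion).
    Violations require an arrangement with >= 2 core genes — a single-gene
    marker call cannot be suppressed by any of them — otherwise ``ValueError``.
    """
    catalog = catalog or default_catalog()
    params = params or MiningParams()
    rng = np.random.default_rng(seed)

    unsafe = singleton_callable_families(catalog, params)

    # contigs as segment lists; a segment is a background singleton or a
    # whole plant part (atomic, so later plants can never nest inside it)
    n_bg = rng.multinomial(spec.n_background_genes, [1.0 / spec.n_contigs] * spec.n_contigs)
    contigs: list[list[list[_Item]]] = [
        [[_Item(_gene_length(rng, spec), _gap(rng, spec))] for _ in range(int(k))]
        for k in n_bg
    ]

    truth: dict[str, bool] = {pid: False for pid in catalog.pathways}
    for pathway_id, violation in planted:
        if pathway_id not in catalog.pathways:
            raise ValueError(f"unknown pathway {pathway_id!r}")
        pw = catalog.pathways[pathway_id]
        # plant the longest (most complete) reference arrangement
        arrangement = max(pw.arrangements, key=len)
        part_a, part_b = _plant_items(
            rng, spec, arrangement, pw.core_families, violation
        )
        targets = [int(rng.integers(0, spec.n_contigs))]
        parts = [part_a]
        if part_b:
            if spec.n_contigs < 2:
                raise ValueError("fragmentation requires >= 2 contigs")
            targets.append((targets[0] + 1) % spec.n_contigs)
            parts.append(part_b)
        for contig_idx, part in zip(targets, parts):
            segments = contigs[contig_idx]
            pos = int(rng.integers(0, len(segments) + 1))
            part[0].gap_before = _PLANT_BUFFER_NT
            if pos < len(segments):
                segments[pos][0].gap_before = _PLANT_BUFFER_NT
            contigs[contig_idx] = segments[:pos] + [part] + segments[pos:]
        truth[pathway_id] = violation is None

    # lay down coordinates and build features
    features: list[GeneFeature] = []
    hits: list[DomainHit] = []
    gene_no = 0
    for ci, segments in enumerate(contigs):
        contig_id = f"{genome_id}_c{ci}"
        contig = [item for seg in segments for item in seg]
        pos = 0
        for rank, item in enumerate(contig):
            start = pos + item.gap_before + 1
            end = start + item.length - 1
            pos = end
            gid = f"{genome_id}_g{gene_no:05d}"
            gene_no += 1
            strand = "+" if item.family is not None else ("+", "-")[int(rng.integers(0, 2))]
            features.append(
                GeneFeature(genome_id, contig_id, rank, start, end, strand, gid)
            )
            if item.family is not None:
                hits.append(DomainHit(gid, item.family, round(item.bitscore, 1)))

    # decoy hits on background genes
    planted_ids = {h.gene_id for h in hits}
    background = [f for f in features if f.gene_id not in planted_ids]
    qualifying = [f for f in features if f.gene_id in planted_ids]
    fam_ids = sorted(catalog.families)
    safe_fams = [f for f in fam_ids if f not in unsafe]
    n_decoys = int(rng.poisson(spec.decoy_rate))
    by_gene = {f.gene_id: f for f in features}
    for _ in range(n_decoys):
        if not background:
            break
        gene = background[int(rng.integers(0, len(background)))]
        if rng.random() < spec.supra_decoy_frac:
            # supra-cutoff singleton: must stay isolated from every other
            # qualifying hit so it can never co-locate into a pattern
            if _isolated(gene, qualifying, params.max_gap_nt) and safe_fams:
                fam = safe_fams[int(rng.integers(0, len(safe_fams)))]
                score = float(rng.uniform(105.0, 180.0))
                hits.append(DomainHit(gene.gene_id, fam, round(score, 1)))
                qualifying.append(gene)
            # else: drop this decoy draw rather than risk a false cluster
        else:
            fam = fam_ids[int(rng.integers(0, len(fam_ids)))]
            score = float(rng.uniform(40.0, 99.5))
            hits.append(DomainHit(gene.gene_id, fam, round(score, 1)))

    hits.sort(key=lambda h: (h.gene_id, h.family_id))
    return SyntheticGenome(genome_id, bin_id, features, hits, truth)


def _isolated(
    gene: GeneFeature, qualifying: Iterable[GeneFeature], max_gap_nt: int
) -> bool:
    for other in qualifying:
        if other.contig_id != gene.contig_id:
            continue
        earlier, later = sorted([gene, other], key=lambda f: f.start)
        if intergenic_distance(earlier, later) <= max_gap_nt:
            return False
    return True


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    spec: CohortSpec,
    catalog: Catalog | None = None,
    params: MiningParams | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a deterministic cohort; optionally write it to ``out_dir``.

    The truth summary has the same schema (and serialization) as the mined
    bin summary, so perfect recovery can be checked byte-for-byte.
    """
    catalog = catalog or default_catalog()
    params = params or MiningParams()
    rng = np.random.default_rng(spec.seed)

    genomes: list[SyntheticGenome] = []
    bin_map: dict[str, str] = {}
    width = max(4, len(str(spec.n_genomes)))
    for i in range(spec.n_genomes):
        genome_id = f"sim{i:0{width}d}"
        bin_id = f"bin{int(rng.integers(0, spec.n_bins)):03d}"
        planted = [
            (pid, spec.violation)
            for pid in catalog.pathways
            if rng.random() < spec.prevalence.get(pid, 0.0)
        ]
        child_seed = int(rng.integers(0, 2**31 - 1))
        genomes.append(
            generate_genome(spec, genome_id, bin_id, planted, child_seed, catalog, params)
        )
        bin_map[genome_id] = bin_id

    truth_calls = [
        TruthCall(g.genome_id, frozenset(p for p, v in g.truth.items() if v))
        for g in genomes
    ]
    truth_summary = summarize_bins(truth_calls, bin_map, catalog)
    cohort = Cohort(spec, genomes, bin_map, truth_summary)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def mine_cohort(
    cohort: Cohort,
    catalog: Catalog | None = None,
    params: MiningParams | None = None,
) -> tuple[list[GenomeCall], pd.DataFrame]:
    """Run the full mining pipeline over a cohort's genomes."""
    catalog = catalog or default_catalog()
    params = params or MiningParams()
    calls = [
        mine_genome(g.features, g.hits, catalog, params, genome_id=g.genome_id)
        for g in cohort.genomes
    ]
    summary = summarize_bins(calls, cohort.bin_map, catalog)
    return calls, summary
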