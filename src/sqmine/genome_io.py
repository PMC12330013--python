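"""Readers for gene coordinates and profile-HMM hit tables.

Genomes enter the pipeline as gene coordinate sets (GFF3 or a simple TSV)
plus HMM hit tables (HMMER per-domain tabular output or a simplified
3-column TSV). ``assign_families`` then reduces hits to at most one
enzyme-family assignment per gene using each family's inclusive bitscore
cutoff. All coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SearchIO

from .catalog import Catalog

__all__ = [
    "GeneFeature",
    "DomainHit",
    "FamilyAssignment",
    "GenomeIOError",
    "read_features",
    "read_hits",
    "assign_families",
]


class GenomeIOError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One gene: 1-based inclusive coordinates plus contig order index."""

    genome_id: str
    contig_id: str
    rank: int  # 0-based index in contig gene order sorted by start
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GenomeIOError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """A profile-HMM match of one gene to one enzyme family."""

    gene_id: str
    family_id: str
    bitscore: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise GenomeIOError(
                f"hit {self.gene_id!r}/{self.family_id!r}: non-finite bitscore"
            )


@dataclass(frozen=True)
class FamilyAssignment:
    """The single best qualifying family for a gene (bitscore >= cutoff)."""

    gene_id: str
    family_id: str
    bitscore: float


def _open_text(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def _strip_gz(path: Path) -> str:
    name = path.name
    return name[:-3] if name.endswith(".gz") else name


def _rank_features(
    raw: list[tuple[str, int, int, str, str]], genome_id: str
) -> list[GeneFeature]:
    seen: dict[str, None] = {}
    for contig, start, end, strand, gid in raw:
        if gid in seen:
            raise GenomeIOError(f"duplicate gene_id {gid!r} in genome {genome_id!r}")
        seen[gid] = None
    out: list[GeneFeature] = []
    raw.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    rank = 0
    prev_contig: str | None = None
    for contig, start, end, strand, gid in raw:
        if contig != prev_contig:
            rank = 0
            prev_contig = contig
        out.append(GeneFeature(genome_id, contig, rank, start, end, strand, gid))
        rank += 1
    return out


def read_features(
    path: str | Path,
    fmt: str | None = None,
    genome_id: str | None = None,
    feature_types: Sequence[str] = ("CDS", "gene"),
) -> list[GeneFeature]:
    """Read one genome's gene features from GFF3 or TSV.

    Parameters
    ----------
    path:
        GFF3 file (``.gff``/``.gff3``, optionally ``.gz``) or a TSV with
        columns ``contig_id, gene_id, start, end, strand``.
    fmt:
        ``"GFF3"`` or ``"TSV"``; inferred from the extension when omitted.
    genome_id:
        Defaults to the file stem.
    feature_types:
        GFF3 record types to keep; when both CDS and gene records describe
        the same locus only CDS records are used.

    Returns features sorted by (contig, start) with 0-based per-contig ranks.
    A file with zero gene records yields an empty list, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"feature file not found: {path}")
    if genome_id is None:
        genome_id = Path(_strip_gz(path)).stem
    if fmt is None:
        suffix = Path(_strip_gz(path)).suffix.lower()
        fmt = "GFF3" if suffix in (".gff", ".gff3") else "TSV"
    fmt = fmt.upper()

    raw: list[tuple[str, int, int, str, str]] = []
    if fmt == "GFF3":
        with _open_text(path) as fh:
            if not any(line.strip() and not line.startswith("#") for line in fh):
                return []  # zero gene records is a valid (empty) genome
        try:
            db = gffutils.create_db(
                str(path), ":memory:", merge_strategy="error", keep_order=True
            )
        except Exception as exc:  # gffutils raises assorted parse errors
            raise GenomeIOError(f"cannot parse GFF3 {path}: {exc}") from exc
        types = [t for t in feature_types if t in set(db.featuretypes())]
        if "CDS" in types:
            types = ["CDS"]
        for ftype in types:
            for feat in db.features_of_type(ftype):
                gid = feat.attributes.get("ID", [feat.id])[0]
                strand = feat.strand if feat.strand in ("+", "-") else "+"
                if feat.end < feat.start:
                    raise GenomeIOError(
                        f"{path}: gene {gid!r} has end < start "
                        f"({feat.end} < {feat.start})"
                    )
                raw.append((feat.seqid, feat.start, feat.end, strand, gid))
    elif fmt == "TSV":
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
        required = {"contig_id", "gene_id", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise GenomeIOError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                start, end = int(row.start), int(row.end)
            except ValueError as exc:
                raise GenomeIOError(f"{path}: line {i}: non-integer coordinate") from exc
            if end < start:
                raise GenomeIOError(
                    f"{path}: line {i}: gene {row.gene_id!r} has end < start"
                )
            raw.append((row.contig_id, start, end, row.strand, row.gene_id))
    else:
        raise GenomeIOError(f"unknown feature format {fmt!r}")
    return _rank_features(raw, genome_id)


def _read_hits_domtbl(path: Path) -> list[DomainHit]:
    # HMMER hmmsearch --domtblout: query = profile HMM (family),
    # hit = protein (gene); full-sequence bitscore and E-value.
    hits: list[DomainHit] = []
    with _open_text(path) as fh:
        for qresult in SearchIO.parse(fh, "hmmsearch3-domtab"):
            for hit in qresult.hits:
                hits.append(
                    DomainHit(
                        gene_id=hit.id,
                        family_id=qresult.id,
                        bitscore=float(hit.bitscore),
                        evalue=float(hit.evalue),
                    )
                )
    return hits


def _read_hits_tsv(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "gene_id":  # optional header
                continue
            if len(parts) < 3:
                raise GenomeIOError(f"{path}: row {lineno}: expected >= 3 columns")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise GenomeIOError(
                    f"{path}: row {lineno}: non-numeric bitscore {parts[2]!r}"
                ) from exc
            evalue = None
            if len(parts) > 3:
                try:
                    evalue = float(parts[3])
                except ValueError as exc:
                    raise GenomeIOError(
                        f"{path}: row {lineno}: non-numeric evalue {parts[3]!r}"
                    ) from exc
            hits.append(DomainHit(parts[0], parts[1], score, evalue))
    return hits


def read_hits(path: str | Path, fmt: str | None = None) -> list[DomainHit]:
    """Read HMM hits from HMMER per-domain tabular output or a simple TSV.

    The simplified dialect has columns ``gene_id, family_id, bitscore``
    (optional fourth column ``evalue``); comment lines start with ``#``.
    Format is sniffed from the first data row when ``fmt`` is omitted:
    rows with >= 23 whitespace-separated columns are treated as HMMER
    ``--domtblout``. Multiple hits per gene are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"hits file not found: {path}")
    if fmt is None:
        fmt = "tsv"
        with _open_text(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    if len(line.split()) >= 23:
                        fmt = "domtbl"
                    break
    fmt = fmt.lower()
    if fmt in ("domtbl", "domtblout", "hmmer"):
        return _read_hits_domtbl(path)
    if fmt == "tsv":
        return _read_hits_tsv(path)
    raise GenomeIOError(f"unknown hits format {fmt!r}")


def assign_families(
    hits: Iterable[DomainHit],
    catalog: Catalog,
    best_hit_only: bool = True,
) -> tuple[dict[str, FamilyAssignment], dict[str, int]]:
    """Filter hits by family cutoffs and keep the best family per gene.

    A hit qualifies when ``bitscore >= cutoff`` of its family (inclusive).
    Per gene, the highest-scoring qualifying hit wins; bitscore ties break
    to the lexicographically smallest family_id for determinism. Hits to
    families absent from the catalog are dropped and counted in the returned
    warning summary under ``"unknown_family"``.

    With ``best_hit_only=False`` the returned mapping holds one assignment
    per (gene, family) pair keyed ``"gene::family"`` — a sensitivity mode;
    the standard pipeline uses best-hit semantics.
    """
    warnings_count = {"unknown_family": 0, "below_cutoff": 0}
    qualifying: dict[str, FamilyAssignment] = {}
    multi: dict[str, FamilyAssignment] = {}
    for hit in hits:
        fam = catalog.families.get(hit.family_id)
        if fam is None:
            warnings_count["unknown_family"] += 1
            continue
        if hit.bitscore < fam.bitscore_cutoff:
            warnings_count["below_cutoff"] += 1
            continue
        cand = FamilyAssignment(hit.gene_id, hit.family_id, hit.bitscore)
        if best_hit_only:
            prev = qualifying.get(hit.gene_id)
            if (
                prev is None
                or cand.bitscore > prev.bitscore
                or (cand.bitscore == prev.bitscore and cand.family_id < prev.family_id)
            ):
                qualifying[hit.gene_id] = cand
        else:
            key = f"{hit.gene_id}::{hit.family_id}"
            prev = multi.get(key)
            if prev is None or cand.bitscore > prev.bitscore:
                multi[key] = cand
    if warnings_count["unknown_family"]:
        warnings.warn(
            f"dropped {warnings_count['unknown_family']} hit(s) to families "
            "absent from the catalog",
            stacklevel=2,
        )
    return (qualifying if best_hit_only else multi), warnings_count
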