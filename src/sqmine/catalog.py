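"""Enzyme-family and pathway catalog for SQ/SQDG and DHPS degradation.

The miner searches genomes for colinear arrangements of profile-HMM-defined
enzyme families. This module holds those definitions: which families exist,
their homolog-detection bitscore cutoffs, and the reference gene arrangements
that define each pathway. Built-in defaults cover the four sulfoglycolytic
pathways (sulfo-EMP, sulfo-ED, sulfo-SFT, sulfo-TK) and four anaerobic DHPS
degradation marker systems (hpsGH, hpfGH, hpsN, dhpA). Users can override or
extend any entry through a YAML catalog document (see ``docs/catalog-schema.md``).
"""

from __future__ import annotations

import copy
import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "EnzymeFamily",
    "PathwayDefinition",
    "MiningParams",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "default_catalog",
    "SQ_PATHWAYS",
    "DHPS_PATHWAYS",
]

DEFAULT_BITSCORE_CUTOFF = 100.0

#: Sulfoglycolytic (SQ-degrading) pathway identifiers.
SQ_PATHWAYS = ("sulfo-EMP", "sulfo-ED", "sulfo-SFT", "sulfo-TK")
#: Anaerobic DHPS degradation marker systems.
DHPS_PATHWAYS = ("DHPS-hpsGH", "DHPS-hpfGH", "DHPS-hpsN", "DHPS-dhpA")


class CatalogError(ValueError):
    """Raised for malformed or internally inconsistent catalog documents."""


@dataclass(frozen=True)
class EnzymeFamily:
    """One named enzyme family backed by a profile HMM.

    Parameters
    ----------
    family_id:
        Short community name (e.g. ``SftT``, ``YihQ``, ``HpsG``).
    description:
        Free-text enzymatic role.
    bitscore_cutoff:
        Inclusive homolog-detection cutoff in bits (default 100).
    """

    family_id: str
    description: str = ""
    bitscore_cutoff: float = DEFAULT_BITSCORE_CUTOFF

    def __post_init__(self) -> None:
        if not self.family_id:
            raise CatalogError("family_id must be non-empty")
        if not self.bitscore_cutoff > 0:
            raise CatalogError(
                f"family {self.family_id!r}: bitscore_cutoff must be > 0, "
                f"got {self.bitscore_cutoff}"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway defined by reference gene arrangements and a core-family set.

    ``arrangements`` are ordered family-id lists, one per reference genome
    (or per distinct observed gene order). A pathway is called *complete* in
    a genome when a single colinear block covers all ``core_families``;
    ``accessory_families`` (transporters, sulfoquinovosidases, regulators,
    activating enzymes) may appear in arrangements but are not required.
    """

    pathway_id: str
    arrangements: tuple[tuple[str, ...], ...]
    core_families: frozenset[str]
    accessory_families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.arrangements:
            raise CatalogError(f"pathway {self.pathway_id!r}: no arrangements")
        arranged: set[str] = set()
        for arr in self.arrangements:
            if not arr:
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: empty arrangement"
                )
            arranged.update(arr)
        if not self.core_families:
            raise CatalogError(f"pathway {self.pathway_id!r}: empty core set")
        if not self.core_families <= arranged:
            missing = sorted(self.core_families - arranged)
            raise CatalogError(
                f"pathway {self.pathway_id!r}: core families {missing} do not "
                "appear in any arrangement"
            )
        for arr in self.arrangements:
            if not self.core_families & set(arr):
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: arrangement {list(arr)} "
                    "contains no core family"
                )

    @property
    def families(self) -> frozenset[str]:
        """All family ids referenced by any arrangement."""
        return frozenset(f for arr in self.arrangements for f in arr)

    def is_sq(self) -> bool:
        return self.pathway_id.startswith("sulfo-")

    def is_dhps(self) -> bool:
        return self.pathway_id.startswith("DHPS-")


@dataclass(frozen=True)
class MiningParams:
    """Tunable thresholds of the mining pipeline.

    Defaults reproduce the homolog-screen/co-location/synteny criteria used
    throughout this package: inclusive bitscore cutoff of 100 bits, maximum
    intergenic distance of 3500 nt, a total tolerance of 2 gene insertions
    per block, a minimum block length of 4 co-located genes (relaxed to the
    pattern length for shorter marker arrangements), and an adjusted-p
    threshold of 0.01 for amplicon responder calling.
    """

    bitscore_cutoff: float = DEFAULT_BITSCORE_CUTOFF
    max_gap_nt: int = 3500
    max_insertions: int = 2
    min_block: int = 4
    alpha: float = 0.01
    #: require co-oriented members within a cluster (off by default; operonic
    #: reference arrangements are co-directional but divergent layouts exist)
    require_co_orientation: bool = False
    #: count insertions per adjacent matched pair instead of per block total
    per_pair_insertions: bool = False
    #: call a pathway complete when core families occur anywhere in the
    #: genome (sensitivity mode) instead of within one matched block
    genome_level_completeness: bool = False

    def __post_init__(self) -> None:
        for name in ("bitscore_cutoff", "max_gap_nt", "min_block"):
            if not getattr(self, name) > 0:
                raise CatalogError(f"MiningParams.{name} must be > 0")
        if self.max_insertions < 0:
            raise CatalogError("MiningParams.max_insertions must be >= 0")
        if not 0 < self.alpha < 1:
            raise CatalogError("MiningParams.alpha must lie in (0, 1)")


@dataclass
class Catalog:
    """A validated set of enzyme families and pathway definitions."""

    families: dict[str, EnzymeFamily] = field(default_factory=dict)
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)

    def validate(self) -> "Catalog":
        for pid, pw in self.pathways.items():
            if pid != pw.pathway_id:
                raise CatalogError(f"pathway key {pid!r} != id {pw.pathway_id!r}")
            unknown = sorted(
                (pw.families | pw.core_families | pw.accessory_families)
                - set(self.families)
            )
            if unknown:
                raise CatalogError(
                    f"pathway {pid!r} references unknown families: {unknown}"
                )
        return self

    def cutoff(self, family_id: str) -> float:
        return self.families[family_id].bitscore_cutoff

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "families": {
                f.family_id: {
                    "description": f.description,
                    "bitscore_cutoff": f.bitscore_cutoff,
                }
                for f in self.families.values()
            },
            "pathways": {
                p.pathway_id: {
                    "arrangements": [list(a) for a in p.arrangements],
                    "core": sorted(p.core_families),
                    "accessory": sorted(p.accessory_families),
                }
                for p in self.pathways.values()
            },
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return self.families == other.families and self.pathways == other.pathways


def _family_from_entry(fid: str, entry: Mapping | None) -> EnzymeFamily:
    entry = entry or {}
    if not isinstance(entry, Mapping):
        raise CatalogError(f"family {fid!r}: entry must be a mapping, got {entry!r}")
    extra = set(entry) - {"description", "bitscore_cutoff"}
    if extra:
        raise CatalogError(f"family {fid!r}: unknown keys {sorted(extra)}")
    try:
        cutoff = float(entry.get("bitscore_cutoff", DEFAULT_BITSCORE_CUTOFF))
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"family {fid!r}: bad bitscore_cutoff") from exc
    return EnzymeFamily(fid, str(entry.get("description", "")), cutoff)


def _pathway_from_entry(pid: str, entry: Mapping) -> PathwayDefinition:
    if not isinstance(entry, Mapping):
        raise CatalogError(f"pathway {pid!r}: entry must be a mapping")
    extra = set(entry) - {"arrangements", "core", "accessory"}
    if extra:
        raise CatalogError(f"pathway {pid!r}: unknown keys {sorted(extra)}")
    arrangements = entry.get("arrangements")
    if not isinstance(arrangements, list) or not all(
        isinstance(a, list) and all(isinstance(f, str) for f in a)
        for a in arrangements
    ):
        raise CatalogError(
            f"pathway {pid!r}: 'arrangements' must be a list of family-id lists"
        )
    return PathwayDefinition(
        pathway_id=pid,
        arrangements=tuple(tuple(a) for a in arrangements),
        core_families=frozenset(entry.get("core", [])),
        accessory_families=frozenset(entry.get("accessory", [])),
    )


# ---------------------------------------------------------------------------
# Built-in defaults
#
# Arrangements follow the reference gene clusters of the field's model
# organisms: the E. coli K-12 / S. flexneri yih operon for sulfo-EMP, the
# E. clostridioformis YL32 sft cluster (locus order sftA..sftI..yihQ..sftR..
# sftT, unnamed genes between named ones are absorbed by the insertion
# tolerance) for sulfo-SFT, the B. wadsworthia hps cluster for DHPS-hpsGH and
# the YL32 hpfD..hpfH..hpfG cluster for DHPS-hpfGH. HpsN and DhpA act as
# single-gene markers with accessory suyAB / slaB. sulfo-ED and sulfo-TK
# reference orders are not conserved across the literature; the shipped
# orders are editable placeholders with package-local family ids.
# ---------------------------------------------------------------------------

_DEFAULT_FAMILIES: dict[str, str] = {
    # sulfo-EMP (yih operon)
    "YihO": "SQ/sulfoquinovoside transporter",
    "YihP": "SQ/sulfoquinovoside transporter",
    "YihQ": "sulfoquinovosidase (GH31)",
    "YihR": "SQ mutarotase",
    "YihS": "SQ isomerase",
    "YihT": "6-deoxy-6-sulfofructose-1-phosphate aldolase",
    "YihU": "3-sulfolactaldehyde reductase",
    "YihV": "6-deoxy-6-sulfofructose kinase",
    "YihW": "transcriptional regulator CsqR",
    # sulfo-SFT
    "SftA": "SQ transporter",
    "SftI": "SQ isomerase",
    "SftR": "3-sulfolactaldehyde reductase",
    "SftT": "6-deoxy-6-sulfofructose transaldolase",
    # sulfoquinovosidases / SQDG cleavage
    "SqgA": "NAD+-dependent sulfoquinovosidase (GH188)",
    # sulfo-ED (package-local ids; override via catalog config)
    "SqdD": "SQ dehydrogenase",
    "SqdL": "6-deoxy-6-sulfogluconolactone lactonase",
    "SqdH": "6-deoxy-6-sulfogluconate dehydratase",
    "SqdA": "2-keto-3,6-dideoxy-6-sulfogluconate aldolase",
    "SqdR": "3-sulfolactaldehyde dehydrogenase",
    # sulfo-TK (package-local ids; override via catalog config)
    "SqtI": "SQ isomerase (transketolase pathway)",
    "SqtA": "sulfofructose transketolase, subunit A",
    "SqtB": "sulfofructose transketolase, subunit B",
    "SqtD": "sulfoacetaldehyde reductase (isethionate-forming)",
    # DHPS degradation
    "HpsG": "DHPS-sulfolyase (glycyl radical enzyme)",
    "HpsH": "DHPS-sulfolyase activating enzyme",
    "HpsP": "DHPS-2-dehydrogenase (NAD+)",
    "HpsO": "DHPS-2-dehydrogenase (NADPH)",
    "HpfG": "DHPS dehydratase (glycyl radical enzyme)",
    "HpfH": "DHPS dehydratase activating enzyme",
    "HpfD": "sulfopropionaldehyde reductase",
    "HpsN": "DHPS-3-dehydrogenase",
    "SuyA": "(R)-sulfolactate sulfolyase, alpha subunit",
    "SuyB": "(R)-sulfolactate sulfolyase, beta subunit",
    "DhpA": "DHPS dehydrogenase",
    "SlaB": "3-sulfolactaldehyde dehydrogenase",
    # downstream sulfite/sulfonate catabolism markers (catalog entries only,
    # never called as standalone pathways)
    "ComC": "(R)-sulfolactate dehydrogenase",
    "ComDE": "3-sulfopyruvate decarboxylase",
    "Xsc": "sulfoacetaldehyde acetyltransferase",
}

_DEFAULT_PATHWAYS: dict[str, dict] = {
    "sulfo-EMP": {
        "arrangements": [
            ["YihO", "YihP", "YihQ", "YihR", "YihS", "YihT", "YihU", "YihV", "YihW"],
        ],
        "core": ["YihS", "YihT", "YihU", "YihV"],
        "accessory": ["YihO", "YihP", "YihQ", "YihR", "YihW"],
    },
    "sulfo-ED": {
        "arrangements": [
            ["SqdD", "SqdL", "SqdH", "SqdA", "SqdR"],
        ],
        "core": ["SqdD", "SqdH", "SqdA"],
        "accessory": ["SqdL", "SqdR"],
    },
    "sulfo-SFT": {
        "arrangements": [
            ["SftA", "SftI", "YihQ", "SftR", "SftT"],
            ["SftI", "SftR", "SftT"],
        ],
        "core": ["SftI", "SftR", "SftT"],
        "accessory": ["SftA", "YihQ", "SqgA"],
    },
    "sulfo-TK": {
        "arrangements": [
            ["SqtI", "SqtA", "SqtB", "SqtD"],
        ],
        "core": ["SqtI", "SqtA", "SqtB"],
        "accessory": ["SqtD"],
    },
    "DHPS-hpsGH": {
        "arrangements": [
            ["HpsO", "HpsP", "HpsG", "HpsH"],
            ["HpsG", "HpsH"],
        ],
        "core": ["HpsG", "HpsH"],
        "accessory": ["HpsO", "HpsP"],
    },
    "DHPS-hpfGH": {
        "arrangements": [
            ["HpfD", "HpfH", "HpfG"],
            ["HpfG", "HpfH"],
        ],
        "core": ["HpfG", "HpfH"],
        "accessory": ["HpfD"],
    },
    "DHPS-hpsN": {
        "arrangements": [
            ["HpsN", "SuyA", "SuyB"],
            ["HpsN"],
        ],
        "core": ["HpsN"],
        "accessory": ["SuyA", "SuyB"],
    },
    "DHPS-dhpA": {
        "arrangements": [
            ["DhpA", "SlaB"],
            ["DhpA"],
        ],
        "core": ["DhpA"],
        "accessory": ["SlaB"],
    },
}


def default_catalog() -> Catalog:
    """Return the built-in SQ/DHPS catalog (a fresh copy each call)."""
    fams = {
        fid: EnzymeFamily(fid, desc) for fid, desc in _DEFAULT_FAMILIES.items()
    }
    pws = {
        pid: _pathway_from_entry(pid, entry)
        for pid, entry in _DEFAULT_PATHWAYS.items()
    }
    return Catalog(fams, pws).validate()


def load_catalog(
    config_path: str | Path | None = None, merge_defaults: bool = True
) -> Catalog:
    """Load the catalog, optionally merging a YAML config over the defaults.

    Entries in the config replace same-keyed defaults; unmentioned defaults
    are kept (so overriding one family's ``bitscore_cutoff`` leaves all
    others at 100). Pass ``merge_defaults=False`` for a config-only catalog.
    """
    if config_path is None:
        return default_catalog()
    path = Path(config_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise CatalogError(f"cannot parse catalog {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise CatalogError(f"catalog {path}: top level must be a mapping")
    extra = set(doc) - {"families", "pathways"}
    if extra:
        raise CatalogError(f"catalog {path}: unknown top-level keys {sorted(extra)}")

    base = default_catalog() if merge_defaults else Catalog()
    fam_doc = doc.get("families") or {}
    pw_doc = doc.get("pathways") or {}
    if not isinstance(fam_doc, Mapping) or not isinstance(pw_doc, Mapping):
        raise CatalogError(f"catalog {path}: 'families'/'pathways' must be mappings")

    merged_fams = dict(base.families)
    for fid, entry in fam_doc.items():
        if merge_defaults and fid in merged_fams and isinstance(entry, Mapping):
            # partial override: unset keys inherit the default entry
            prev = merged_fams[fid]
            full = {
                "description": entry.get("description", prev.description),
                "bitscore_cutoff": entry.get("bitscore_cutoff", prev.bitscore_cutoff),
            }
            bad = set(entry) - {"description", "bitscore_cutoff"}
            if bad:
                raise CatalogError(f"family {fid!r}: unknown keys {sorted(bad)}")
            merged_fams[fid] = _family_from_entry(fid, full)
        else:
            merged_fams[fid] = _family_from_entry(fid, entry)

    merged_pws = dict(base.pathways)
    for pid, entry in pw_doc.items():
        merged_pws[pid] = _pathway_from_entry(pid, entry)

    return Catalog(merged_fams, merged_pws).validate()


def singleton_callable_families(catalog: Catalog, params: MiningParams) -> frozenset[str]:
    """Families whose lone above-cutoff hit already completes some pathway.

    A family ``f`` is singleton-callable when a pathway has an arrangement
    ``A`` with ``f in A``, ``min(min_block, |A|) <= 1`` and core ⊆ {f}.
    Used by the synthetic generator to keep decoy hits from creating true
    pathway calls.
    """
    out = set()
    for pw in catalog.pathways.values():
        for arr in pw.arrangements:
            if min(params.min_block, len(arr)) <= 1:
                for f in arr:
                    if pw.core_families <= {f}:
                        out.add(f)
    return frozenset(out)
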