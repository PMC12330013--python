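# Methods

## The mining model

`sqmine` treats pathway presence as a *conserved gene cluster* question,
not a per-gene annotation question. A genome encodes a pathway when
homologs of the pathway's enzymes occur together, in a conserved order,
within one genomic neighborhood. The pipeline factors this into four
independent criteria, each with one tunable threshold
(`sqmine.catalog.MiningParams`):

| Parameter | Default | Unit | Meaning |
|---|---|---|---|
| `bitscore_cutoff` | 100 | bits | inclusive per-family homolog cutoff on profile-HMM hits |
| `max_gap_nt` | 3500 | nt | maximum intergenic distance chaining two assigned genes into one cluster |
| `max_insertions` | 2 | genes | non-pattern genes tolerated inside one colinear block (total per block) |
| `min_block` | 4 | genes | minimum matched genes per block, relaxed to `min(min_block, |pattern|)` |
| `alpha` | 0.01 | — | strict adjusted-p threshold for amplicon responder calling |

Defaults are the thresholds commonly used for this kind of
HMM-plus-synteny screen of gut-bacterial SQ/DHPS pathways; they are
deliberately conservative — the goal is few, high-confidence calls across
tens of thousands of MAGs rather than sensitive single-gene annotation.

### Homolog filtering

Hits are read from HMMER `--domtblout` tables (via Bio.SearchIO; query =
HMM/family, target = gene, full-sequence bitscore) or a simplified
3-column TSV. The cutoff is **inclusive** (a hit at exactly 100.0 bits
qualifies), following the usual HMMER reporting convention. Per gene only
the highest-scoring qualifying family is kept; ties break to the
lexicographically smallest family id so results are order-invariant. An
all-hits mode exists for sensitivity analysis.

### Co-location

Distance between genes is the **intergenic separation**
(`later.start − earlier.end − 1`), the most literal reading of a
"distance between genes" criterion; overlapping genes count as distance
0, and the 3500 nt bound is inclusive (boundary-tested at 3500/3501).
Chaining is transitive (maximal runs), the standard gene-neighborhood
semantics: a cluster may span arbitrarily many genes as long as each
consecutive assigned pair is close. Strand is recorded but ignored by
default — reference operons are co-directional, but requiring
co-orientation would silently drop divergently transcribed arrangements;
a `require_co_orientation` flag enables the strict variant. Clusters are
never stitched across contigs; fragmented core sets are reported as QC
notes (`fragmented:<pathway>`) instead.

### Colinear block matching

A block matches when the cluster's family-label sequence contains, as a
subsequence of a contiguous window, a **contiguous sub-run** of a
reference arrangement — forward or exactly reversed. All genes inside the
window that are not part of the match count as insertions, whether they
are unassigned or assigned to an off-pattern family (the conservative
choice; the criterion is about physical interruption of the cluster, not
about annotation status). The insertion budget is a **total per block**,
matching k-insertion semantics of colinear-syntenic-block finders; a
per-adjacent-pair mode is available as a flag. Matching only a sub-run is
intentional: completeness is decided downstream from core-family
coverage, so accessory genes absent from a genome do not block a call.

`min_block` is relaxed to the pattern length so that two-gene DHPS marker
systems (hpsGH, hpfGH) remain callable under a 4-gene default; without
the relaxation no 2–3-gene marker arrangement could ever match.

The production search (`find_blocks`) does pruned depth-first chain
extension over (gene, pattern-position) pairs and keeps maximal chains; a
mechanism-independent oracle (`brute_force_blocks`) enumerates all 2^n
subsequences on clusters of ≤ 15 genes. Both report maximal blocks
(no match whose gene set is strictly contained in another valid match),
sorted longest-first, ties broken by summed bitscore, then leftmost
start, forward before reverse — a total, deterministic order.

### Pathway calling and tabulation

A pathway is complete iff **one single block** covers all core families
of one arrangement — the cluster-level reading of "complete gene
cluster". A permissive genome-level mode (cores anywhere in the genome)
exists for sensitivity analysis only. Sulfoquinovosidases (YihQ/SqgA) are
an annotation flag (`sqdg_cleavage`), not a pathway; genomes calling both
an SQ and a DHPS pathway get the `extended_sulfoglycolytic` flag.
ComC/ComDE/Xsc are catalog families available to user-defined
arrangements but are not standalone pathways.

Percentages are rounded **half-up** to one decimal with exact rational
arithmetic (76/26,640 → 0.3, 48/26,640 → 0.2, 16/1,094 → 1.5,
8/1,094 → 0.7); bins are ordered by genome count, descending. Summary
tables carry per-pathway counts plus `sq_any`/`dhps_any`/`both` category
tallies, so a genome with several pathways is counted once per pathway
*and* once per category — both conventions one might want from a
prevalence figure are emitted side by side.

## Catalog defaults

Arrangements follow the reference organisms of the field: the
*E. coli* K-12 / *S. flexneri* yihOPQRSTUVW operon (sulfo-EMP, core
YihS/YihT/YihU/YihV), the *E. clostridioformis* sft cluster
(sulfo-SFT, core SftI/SftR/SftT, accessory SftA transporter and YihQ
sulfoquinovosidase), the *B. wadsworthia*-type hpsOPGH cluster
(DHPS-hpsGH) and the hpfD–hpfH–hpfG cluster (DHPS-hpfGH, accessory
HpfD). HpsN and DhpA act as single-gene markers with accessory SuyAB /
SlaB: their single-core design means a lone above-cutoff marker hit
suffices, which is the only consistent way to count hpsN-only and
dhpA-only genomes while keeping suyAB/slaB optional. Genes drawn without
predicted function in reference cluster figures are *not* catalog
members; they are absorbed by the insertion tolerance. sulfo-ED and
sulfo-TK gene orders are not conserved enough in the literature to pin
down; the shipped orders use package-local family ids and exist chiefly
so the catalog is complete — users with curated HMM sets should override
them (`docs/catalog-schema.md`).

## Synthetic cohorts

The generator emulates a MAG collection at desk scale: per genome,
~60 background genes over 3 contigs, lognormal gene lengths (median
900 nt, σ = 0.45 — typical bacterial CDS statistics), intergenic gaps
normal(120, 80) truncated to [0, 3000] nt. Planted arrangements draw
bitscores in [120, 250] and up to 2 inserted decoy genes; inserted genes
are capped at 1000 nt with ≤ 80 nt flanking gaps so that an insertion run
never also violates the 3500-nt distance criterion (each violation mode
must break exactly one criterion). The three violation modes split the
arrangement **between two consecutive core genes**, so no remaining block
can cover all cores: `gap` dilates one intergenic distance past 3500 nt,
`insertions` interleaves 3 decoy genes, `fragment` moves the tail to
another contig. Violations are refused for single-core pathways
(hpsN, dhpA) — no gap/insertion/fragmentation can suppress a single-gene
marker call, so such plants cannot be constructed as negatives.

Decoy hits straddle the cutoff: most draw bitscores in [40, 99.5]
(exercising the filter), a small fraction (5%) are supra-cutoff
singletons restricted to families that cannot complete a pathway alone
and to genes > 3500 nt from any other qualifying gene (exercising
co-location). This guarantees the two headline invariants the tests
check: mined summary == planted truth in the violation-free regime, and
zero calls in violation-only cohorts.

What the generator does **not** model: real sequence (no emissions, no
HMM scoring noise correlated with family similarity), paralog families
with cross-hits, assembly chimerism, or truncated genes at contig edges.
Passing the recovery tests therefore shows the *decision logic* is exact
under its stated criteria — it does not validate HMM sensitivity or
annotation quality on real MAGs.

## Downstream study calculations

*Responder calling*: "enriched" is operationalized as
log2 fold change > 0 **and** adjusted p strictly < α — the only reading
consistent with calling an increase significant; the boundary p = α is
not significant. The dual-control rule intersects enrichment against a
0 h baseline and against a minimal-dose control at the same time point;
the control-exclusion rule subtracts ASVs that also bloom in the
unamended control over time. Both are monotone in α and row-order
invariant.

*Absolute abundance* is the literal product
relative abundance × total 16S copies (qPCR), vectorized; totals are
conserved by construction.

*Breath rate*: rate = ((APE₉₀ₛ − APE₃₀ₛ)/100 × m_CO₂)/Δt with
Δt = 1 min. The CO₂ mass in the sealed 1-l breath container is an
explicit parameter of the setup (it depends on the animal's CO₂ output
during the draw window and is not derivable from the container volume
alone), so reported rates scale linearly with it; negative APE
differences are returned as-is with a warning rather than clipped.

## Problem sizes and determinism

All randomized components take explicit integer seeds
(`numpy.random.default_rng`); fixed seeds give byte-identical cohort
files. The shipped verification sizes — 1,000 random clusters for oracle
equivalence, a 200-genome recovery cohort, three 60-genome negative
cohorts — run in seconds and were chosen as comfortably large for the
properties they check (the oracle bound of 15 genes per cluster is the
2^n enumeration limit, far above any co-location cluster the default
catalog can produce).

## Known limitations

- Cross-contig stitching is deliberately absent; heavily fragmented
  assemblies under-call pathways (visible in QC notes).
- Completeness is binary; there is no partial-cluster score.
- The catalog ships with reasonable default arrangements, but arrangement
  accuracy ultimately depends on the user's HMM set and references;
  sulfo-ED/sulfo-TK defaults in particular are placeholders.
- Best-hit-per-gene assignment can drop a genuine second function of a
  bifunctional gene; the all-hits flag trades that for more insertions
  counted inside blocks.
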