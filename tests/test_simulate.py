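import pytest

from sqmine.caller import mine_genome, summary_to_tsv
from sqmine.catalog import MiningParams
from sqmine.colocation import build_clusters, intergenic_distance
from sqmine.genome_io import assign_families
from sqmine.simulate import (
    Cohort,
    CohortSpec,
    generate_cohort,
    generate_genome,
    mine_cohort,
)

PREV = {"sulfo-SFT": 0.15, "sulfo-EMP": 0.1, "DHPS-hpfGH": 0.1, "DHPS-hpsN": 0.08}


class TestGenerateGenome:
    def test_clean_plant_is_recovered(self, catalog, params):
        g = generate_genome(CohortSpec(), "g0", "b0",
                            [("sulfo-SFT", None)], seed=3)
        call = mine_genome(g.features, g.hits, catalog, params, genome_id="g0")
        assert "sulfo-SFT" in call.pathways
        assert g.truth["sulfo-SFT"] is True

    @pytest.mark.parametrize("violation", ["gap", "insertions", "fragment"])
    @pytest.mark.parametrize("pathway", ["sulfo-SFT", "sulfo-EMP", "DHPS-hpfGH"])
    def test_each_violation_suppresses_the_call(self, catalog, params,
                                                violation, pathway):
        g = generate_genome(CohortSpec(), "g0", "b0",
                            [(pathway, violation)], seed=5)
        call = mine_genome(g.features, g.hits, catalog, params, genome_id="g0")
        assert pathway not in call.pathways
        assert g.truth[pathway] is False

    def test_gap_violation_breaks_only_colocation(self, catalog, params):
        """The planted genes still carry qualifying hits and land in two
        clusters on one contig — only the distance criterion is broken."""
        g = generate_genome(CohortSpec(n_background_genes=0), "g0", "b0",
                            [("sulfo-SFT", "gap")], seed=5)
        assignments, _ = assign_families(g.hits, catalog)
        assert len(assignments) == 5  # all planted genes pass the cutoff
        clusters = build_clusters(g.features, assignments, params)
        contigs = {c.contig_id for c in clusters}
        assert len(clusters) == 2 and len(contigs) == 1

    def test_fragment_violation_splits_contigs(self, catalog, params):
        g = generate_genome(CohortSpec(n_background_genes=0), "g0", "b0",
                            [("sulfo-SFT", "fragment")], seed=5)
        assignments, _ = assign_families(g.hits, catalog)
        clusters = build_clusters(g.features, assignments, params)
        assert len({c.contig_id for c in clusters}) == 2

    def test_violation_on_single_core_marker_refused(self):
        with pytest.raises(ValueError, match="core"):
            generate_genome(CohortSpec(), "g0", "b0",
                            [("DHPS-hpsN", "gap")], seed=1)

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError, match="unknown pathway"):
            generate_genome(CohortSpec(), "g0", "b0",
                            [("no-such-pathway", None)], seed=1)

    def test_supra_cutoff_decoys_are_isolated(self, catalog, params):
        spec = CohortSpec(decoy_rate=30.0, supra_decoy_frac=0.5)
        g = generate_genome(spec, "g0", "b0", [("sulfo-SFT", None)], seed=11)
        assignments, _ = assign_families(g.hits, catalog)
        feats = {f.gene_id: f for f in g.features}
        planted = {h.gene_id for h in g.hits if h.bitscore >= 120.0}
        decoy_assigned = [feats[gid] for gid in assignments if gid not in planted]
        for d in decoy_assigned:
            for gid in assignments:
                if gid == d.gene_id:
                    continue
                o = feats[gid]
                if o.contig_id != d.contig_id:
                    continue
                a, b = sorted([d, o], key=lambda f: f.start)
                assert intergenic_distance(a, b) > params.max_gap_nt


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = CohortSpec(n_genomes=6, n_bins=2, prevalence=PREV, seed=99)
        a = generate_cohort(spec, out_dir=tmp_path / "a")
        b = generate_cohort(spec, out_dir=tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b")
                         for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes()

    def test_zero_prevalence_all_zero(self, catalog, params):
        spec = CohortSpec(n_genomes=10, n_bins=2, seed=4)
        cohort = generate_cohort(spec, catalog, params)
        calls, mined = mine_cohort(cohort, catalog, params)
        assert all(not c.pathways for c in calls)
        assert summary_to_tsv(mined) == summary_to_tsv(cohort.truth_summary)

    def test_perfect_recovery_small_cohort(self, catalog, params):
        spec = CohortSpec(n_genomes=40, n_bins=6, prevalence=PREV, seed=12)
        cohort = generate_cohort(spec, catalog, params)
        assert any(any(g.truth.values()) for g in cohort.genomes)
        _, mined = mine_cohort(cohort, catalog, params)
        assert summary_to_tsv(mined) == summary_to_tsv(cohort.truth_summary)

    @pytest.mark.parametrize("violation", ["gap", "insertions", "fragment"])
    def test_violation_cohorts_yield_zero_calls(self, catalog, params, violation):
        spec = CohortSpec(
            n_genomes=12, n_bins=3,
            prevalence={"sulfo-SFT": 0.6, "DHPS-hpfGH": 0.5},
            violation=violation, seed=31,
        )
        cohort = generate_cohort(spec, catalog, params)
        calls, _ = mine_cohort(cohort, catalog, params)
        assert sum(len(c.pathways) for c in calls) == 0

    def test_cohort_files_roundtrip_through_readers(self, tmp_path, catalog, params):
        from sqmine.genome_io import read_features, read_hits

        spec = CohortSpec(n_genomes=3, n_bins=2,
                          prevalence={"sulfo-SFT": 1.0}, seed=8)
        cohort = generate_cohort(spec, catalog, params, out_dir=tmp_path)
        for g in cohort.genomes:
            feats = read_features(tmp_path / "genomes" / f"{g.genome_id}.gff3",
                                  genome_id=g.genome_id)
            hits = read_hits(tmp_path / "hits" / f"{g.genome_id}.tsv")
            assert [(f.gene_id, f.start, f.end) for f in feats] == \
                [(f.gene_id, f.start, f.end) for f in g.features]
            call = mine_genome(feats, hits, catalog, params,
                               genome_id=g.genome_id)
            assert "sulfo-SFT" in call.pathways

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortSpec(prevalence={"sulfo-SFT": 1.5})
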