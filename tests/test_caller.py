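import pandas as pd
import pytest

from sqmine.caller import (
    EXTENDED_FLAG,
    SQDG_CLEAVAGE_FLAG,
    TOTAL_BINS_ROW,
    TOTAL_MAGS_ROW,
    GenomeCall,
    call_pathways,
    mine_genome,
    round_pct,
    summarize_bins,
    summary_to_tsv,
)
from sqmine.catalog import MiningParams
from sqmine.genome_io import DomainHit
from sqmine.synteny import SyntenyMatch

from conftest import make_cluster, make_features


def sft_cluster(contig="c", cluster_id="cl"):
    return make_cluster(
        ["SftA", "SftI", "YihQ", "SftR", "SftT"],
        contig_id=contig, cluster_id=cluster_id,
    )


class TestCallPathways:
    def test_complete_sft_cluster_called(self, catalog, params):
        call = call_pathways("g", [sft_cluster()], catalog, params)
        assert call.pathways == {"sulfo-SFT"}
        ev = call.evidence["sulfo-SFT"]
        assert {"SftI", "SftR", "SftT"} <= set(ev.families)

    def test_cores_split_across_contigs_not_called(self, catalog, params):
        c1 = make_cluster(["SftA", "SftI"], contig_id="c1", cluster_id="cl1")
        c2 = make_cluster(["SftR", "SftT"], contig_id="c2", cluster_id="cl2")
        asg = {
            f.gene_id: a for cl in (c1, c2) for f, a in cl.members
        }
        call = call_pathways("g", [c1, c2], catalog, params, asg)
        assert "sulfo-SFT" not in call.pathways
        assert "fragmented:sulfo-SFT" in call.qc

    def test_genome_level_mode_rescues_fragmented_cores(self, catalog):
        c1 = make_cluster(["SftA", "SftI"], contig_id="c1", cluster_id="cl1")
        c2 = make_cluster(["SftR", "SftT"], contig_id="c2", cluster_id="cl2")
        asg = {f.gene_id: a for cl in (c1, c2) for f, a in cl.members}
        lax = MiningParams(genome_level_completeness=True)
        call = call_pathways("g", [c1, c2], catalog, lax, asg)
        assert "sulfo-SFT" in call.pathways

    def test_multiple_dhps_pathways_called_once_each(self, catalog, params):
        c1 = make_cluster(["HpsG", "HpsH"], contig_id="c1", cluster_id="cl1")
        c2 = make_cluster(["DhpA", "SlaB"], contig_id="c2", cluster_id="cl2")
        call = call_pathways("g", [c1, c2], catalog, params)
        assert call.pathways == {"DHPS-hpsGH", "DHPS-dhpA"}

    def test_extended_flag_on_sq_plus_dhps(self, catalog, params):
        c1 = sft_cluster(contig="c1", cluster_id="cl1")
        c2 = make_cluster(["HpfD", "HpfH", "HpfG"], contig_id="c2",
                          cluster_id="cl2")
        call = call_pathways("g", [c1, c2], catalog, params)
        assert {"sulfo-SFT", "DHPS-hpfGH"} <= call.pathways
        assert EXTENDED_FLAG in call.flags

    def test_sulfoquinovosidase_is_annotation_not_pathway(self, catalog, params):
        cl = make_cluster(["YihQ"])
        asg = {f.gene_id: a for f, a in cl.members}
        call = call_pathways("g", [cl], catalog, params, asg)
        assert call.pathways == frozenset()
        assert SQDG_CLEAVAGE_FLAG in call.flags

    def test_single_gene_marker_hpsn_called(self, catalog, params):
        cl = make_cluster(["HpsN"])
        call = call_pathways("g", [cl], catalog, params)
        assert call.pathways == {"DHPS-hpsN"}

    def test_called_pathway_requires_evidence(self):
        with pytest.raises(ValueError):
            GenomeCall("g", pathways=frozenset({"sulfo-SFT"}))


class TestMineGenome:
    def test_empty_genome_is_empty_call(self, catalog, params):
        call = mine_genome([], [], catalog, params, genome_id="g")
        assert call.pathways == frozenset()

    def test_orphan_hits_dropped_with_warning(self, catalog, params):
        feats = make_features(["a"])
        hits = [DomainHit("ghost", "SftT", 500.0)]
        with pytest.warns(UserWarning, match="absent from the feature table"):
            call = mine_genome(feats, hits, catalog, params)
        assert call.pathways == frozenset()

    def test_relabeling_and_contig_reversal_invariance(self, catalog, params):
        from sqmine.genome_io import GeneFeature

        labels = ["SftA", "SftI", "YihQ", "SftR", "SftT"]
        feats = make_features(labels)
        hits = [
            DomainHit(f.gene_id, fam, 150.0) for f, fam in zip(feats, labels)
        ]
        call = mine_genome(feats, hits, catalog, params)

        # reverse the contig: flip coordinates and strands, relabel genes
        length = max(f.end for f in feats) + 100
        flipped = sorted(
            (length - f.end + 1, length - f.start + 1, fam)
            for f, fam in zip(feats, labels)
        )
        rev_feats, rev_hits = [], []
        for rank, (start, end, fam) in enumerate(flipped):
            gid = f"flip{rank}"
            rev_feats.append(GeneFeature("g", "c", rank, start, end, "-", gid))
            rev_hits.append(DomainHit(gid, fam, 150.0))
        call_rev = mine_genome(rev_feats, rev_hits, catalog, params)
        assert call_rev.pathways == call.pathways


class TestSummarizeBins:
    def _calls(self, positive, total, pathway, prefix="g"):
        calls = []
        for i in range(total):
            if i < positive:
                ev = SyntenyMatch(pathway, 0, f"{prefix}{i}", "cl",
                                  (("x", "F"),), 0, "forward")
                calls.append(GenomeCall(f"{prefix}{i}",
                                        frozenset({pathway}), {pathway: ev}))
            else:
                calls.append(GenomeCall(f"{prefix}{i}"))
        return calls

    def test_printed_percentages_for_bins(self):
        # 16 positive bins of 1094 -> 1.5%; genomes spread one per bin
        calls = self._calls(16, 1094, "sulfo-SFT")
        bin_map = {f"g{i}": f"b{i}" for i in range(1094)}
        df = summarize_bins(calls, bin_map)
        bins_row = df[df.bin_id == TOTAL_BINS_ROW].iloc[0]
        assert bins_row["sq_any_n"] == 16
        assert bins_row["sq_any_pct"] == 1.5

    def test_printed_percentages_for_mags(self):
        calls = self._calls(76, 26640, "sulfo-SFT")
        bin_map = {f"g{i}": "b0" for i in range(26640)}
        df = summarize_bins(calls, bin_map)
        mags = df[df.bin_id == TOTAL_MAGS_ROW].iloc[0]
        assert mags["sq_any_n"] == 76
        assert mags["sq_any_pct"] == 0.3

    def test_zero_positive_genomes_all_zero(self, catalog):
        calls = self._calls(0, 10, "sulfo-SFT")
        bin_map = {f"g{i}": f"b{i % 2}" for i in range(10)}
        df = summarize_bins(calls, bin_map, catalog)
        assert (df.filter(like="_pct") == 0.0).all().all()

    def test_per_bin_counts_sum_to_collection_count(self, catalog):
        calls = self._calls(7, 30, "DHPS-dhpA")
        bin_map = {f"g{i}": f"b{i % 3}" for i in range(30)}
        df = summarize_bins(calls, bin_map, catalog)
        per_bin = df[~df.bin_id.isin([TOTAL_MAGS_ROW, TOTAL_BINS_ROW])]
        total = df[df.bin_id == TOTAL_MAGS_ROW].iloc[0]
        assert per_bin["DHPS-dhpA_n"].sum() == total["DHPS-dhpA_n"] == 7

    def test_bins_ordered_by_genome_count_desc(self, catalog):
        calls = self._calls(0, 9, "sulfo-SFT")
        bin_map = {f"g{i}": ("big" if i < 6 else "small") for i in range(9)}
        df = summarize_bins(calls, bin_map, catalog)
        assert list(df.bin_id[:2]) == ["big", "small"]

    def test_missing_genome_in_bin_map_errors(self):
        calls = self._calls(0, 2, "sulfo-SFT")
        with pytest.raises(KeyError, match="g1"):
            summarize_bins(calls, {"g0": "b0"})

    def test_genome_with_both_dhps_pathways_counted_once_in_category(self):
        ev = lambda p: SyntenyMatch(p, 0, "g0", "cl", (("x", "F"),), 0, "forward")
        calls = [GenomeCall("g0",
                            frozenset({"DHPS-hpsGH", "DHPS-dhpA"}),
                            {"DHPS-hpsGH": ev("DHPS-hpsGH"),
                             "DHPS-dhpA": ev("DHPS-dhpA")})]
        df = summarize_bins(calls, {"g0": "b0"})
        row = df[df.bin_id == TOTAL_MAGS_ROW].iloc[0]
        assert row["DHPS-hpsGH_n"] == 1 and row["DHPS-dhpA_n"] == 1
        assert row["dhps_any_n"] == 1

    def test_serialization_fixed_decimals(self):
        calls = self._calls(1, 3, "sulfo-SFT")
        df = summarize_bins(calls, {f"g{i}": "b0" for i in range(3)})
        text = summary_to_tsv(df)
        assert "33.3" in text and text.endswith("\n")


@pytest.mark.parametrize(
    "count,total,expected",
    [(76, 26640, 0.3), (48, 26640, 0.2), (16, 1094, 1.5), (8, 1094, 0.7),
     (1, 400, 0.3), (1, 800, 0.1), (0, 5, 0.0)],
)
def test_round_pct_half_up(count, total, expected):
    assert round_pct(count, total) == expected
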