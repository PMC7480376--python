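import numpy as np
import pytest

from cazloci.loci import (
    assign_ranks,
    call_puls,
    detect_cellulosomes,
    detect_sus_pairs,
    summarize_pul,
)
from cazloci.model import Gene
from cazloci.summarize import FunctionMap

from oracles import brute_force_pul_scan, brute_force_sus_pairs
from test_architecture import arch_from_string
from cazloci.architecture import classify_protein


def make_gene(rank, labels=("OTHER",), contig="c1", genome="g1", strand="+"):
    start = 1 + rank * 1000
    return Gene(
        genome_id=genome, contig_id=contig, protein_id=f"{genome}_{contig}_{rank:03d}",
        start=start, end=start + 899, strand=strand, rank=rank,
        functional_labels=frozenset(labels),
    )


def contig_of(n, special):
    """n OTHER genes with `special` = {rank: labels} overrides."""
    return [
        make_gene(r, labels=special.get(r, ("OTHER",))) for r in range(n)
    ]


class TestDetectSusPairs:
    def test_adjacent_pair_found_either_order(self):
        genes = contig_of(10, {4: ("SUSC",), 5: ("SUSD",)})
        (pair,) = detect_sus_pairs(genes)
        assert (pair.susc.rank, pair.susd.rank) == (4, 5)
        genes = contig_of(10, {4: ("SUSD",), 5: ("SUSC",)})
        (pair,) = detect_sus_pairs(genes)
        assert (pair.susc.rank, pair.susd.rank) == (5, 4)

    def test_distant_susd_not_paired(self):
        genes = contig_of(10, {2: ("SUSC",), 5: ("SUSD",)})
        assert detect_sus_pairs(genes) == []

    def test_strict_order_rejects_reversed_pair(self):
        genes = contig_of(10, {4: ("SUSD",), 5: ("SUSC",)})
        assert detect_sus_pairs(genes, require_susc_first=True) == []

    def test_run_of_four_greedy_matches_maximum_matching(self):
        genes = contig_of(
            12, {3: ("SUSC",), 4: ("SUSD",), 5: ("SUSC",), 6: ("SUSD",)}
        )
        pairs = detect_sus_pairs(genes)
        got = frozenset(
            (("g1", "c1"), p.susc.rank, p.susd.rank) for p in pairs
        )
        matchings, best_size = brute_force_sus_pairs(genes)
        assert len(pairs) == best_size == 2
        assert got in matchings

    def test_each_gene_in_at_most_one_pair(self):
        genes = contig_of(8, {2: ("SUSC",), 3: ("SUSD",), 4: ("SUSC",)})
        pairs = detect_sus_pairs(genes)
        used = [g.protein_id for p in pairs for g in (p.susc, p.susd)]
        assert len(used) == len(set(used))


class TestCallPuls:
    def test_cargo_within_window_included(self):
        genes = contig_of(
            30,
            {
                10: ("SUSC",), 11: ("SUSD",),
                14: ("CAZYME:GH:GH16",), 7: ("CAZYME:CE:CE3",),
            },
        )
        pairs = detect_sus_pairs(genes)
        (call,) = call_puls(genes, pairs, window=5)
        fams = {f for g in call.member_genes for _, f in g.cazyme_families()}
        assert fams == {"GH16", "CE3"}
        assert not call.no_cazyme

    def test_cazyme_beyond_window_excluded_and_flagged(self):
        genes = contig_of(30, {10: ("SUSC",), 11: ("SUSD",), 17: ("CAZYME:GH:GH5",)})
        pairs = detect_sus_pairs(genes)
        (call,) = call_puls(genes, pairs, window=5)
        assert call.no_cazyme
        assert all(g.rank != 17 for g in call.member_genes)

    def test_window_clipped_at_contig_ends(self):
        genes = contig_of(6, {0: ("SUSC",), 1: ("SUSD",)})
        pairs = detect_sus_pairs(genes)
        (call,) = call_puls(genes, pairs, window=5)
        assert call.rank_span == (0, 5)

    def test_overlapping_windows_merge_into_one_call(self):
        genes = contig_of(
            25, {5: ("SUSC",), 6: ("SUSD",), 10: ("SUSC",), 11: ("SUSD",)}
        )
        pairs = detect_sus_pairs(genes)
        calls = call_puls(genes, pairs, window=5)
        assert len(calls) == 1
        assert len(calls[0].anchor_pairs) == 2

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            call_puls([], [], window=-1)

    def test_row_order_invariance(self):
        special = {8: ("SUSC",), 9: ("SUSD",), 12: ("CAZYME:GH:GH13",)}
        genes = contig_of(20, special)
        rng = np.random.default_rng(2)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        reranked = assign_ranks(
            [
                Gene(
                    genome_id=g.genome_id, contig_id=g.contig_id,
                    protein_id=g.protein_id, start=g.start, end=g.end,
                    strand=g.strand, rank=0, functional_labels=g.functional_labels,
                )
                for g in shuffled
            ]
        )
        a = call_puls(genes, detect_sus_pairs(genes), 5)
        b = call_puls(reranked, detect_sus_pairs(reranked), 5)
        assert [(c.rank_span, len(c.anchor_pairs)) for c in a] == [
            (c.rank_span, len(c.anchor_pairs)) for c in b
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_contig_matches_brute_force_interval_merge(self, seed):
        rng = np.random.default_rng(seed)
        special = {}
        # 4 susCD pairs at random positions on a 50-gene contig
        positions = rng.choice(np.arange(0, 48, 2), size=4, replace=False)
        for pos in positions:
            special[int(pos)] = ("SUSC",)
            special[int(pos) + 1] = ("SUSD",)
        for _ in range(6):
            r = int(rng.integers(0, 50))
            if r not in special:
                special[r] = (f"CAZYME:GH:GH{int(rng.integers(1, 100))}",)
        genes = contig_of(50, special)
        pairs = detect_sus_pairs(genes)
        calls = call_puls(genes, pairs, window=5)
        got = {
            (
                (c.genome_id, c.contig_id),
                frozenset((p.min_rank, p.max_rank) for p in c.anchor_pairs),
                frozenset(g.rank for g in c.member_genes),
            )
            for c in calls
        }
        assert got == brute_force_pul_scan(genes, pairs, window=5)

    def test_window_growth_never_drops_cargo(self):
        genes = contig_of(
            40, {15: ("SUSC",), 16: ("SUSD",), 11: ("CAZYME:GH:GH3",),
                 21: ("CAZYME:CE:CE1",), 24: ("CAZYME:PL:PL1",)}
        )
        pairs = detect_sus_pairs(genes)
        prev = set()
        for w in range(4, 12):
            (call,) = call_puls(genes, pairs, window=w)
            members = {g.rank for g in call.member_genes}
            assert prev <= members
            prev = members


class TestSummarizePul:
    def test_oligosaccharide_rich_locus_composition(self):
        fams = ["GH2", "GH29", "GH31", "GH42", "GH97", "GH5", "GH43"]
        special = {10: ("SUSC",), 11: ("SUSD",)}
        for i, f in enumerate(fams):
            special[12 + i] = (f"CAZYME:GH:{f}",)
        genes = contig_of(25, special)
        pairs = detect_sus_pairs(genes)
        (call,) = call_puls(genes, pairs, window=7)
        rec = summarize_pul(call, function_map=FunctionMap())
        assert rec["n_distinct_cazy_families"] == 7
        assert sorted(rec["substrate_categories"]["oligosaccharide-degrading"]) == [
            "GH2", "GH29", "GH31", "GH42", "GH97"
        ]
        assert rec["substrate_categories"]["cellulase"] == ["GH5"]

    def test_empty_cargo_composition(self):
        genes = contig_of(12, {5: ("SUSC",), 6: ("SUSD",)})
        pairs = detect_sus_pairs(genes)
        (call,) = call_puls(genes, pairs, window=3)
        rec = summarize_pul(call)
        assert rec["no_cazyme"]
        assert rec["n_distinct_cazy_families"] == 0

    def test_fixture_pul_compositions_match_manifest(self, pipeline_results, manifest):
        calls = pipeline_results["pul_calls"]
        by_anchor = {
            (c.genome_id, c.contig_id, p.min_rank, p.max_rank): c
            for c in calls
            for p in c.anchor_pairs
        }
        for entry in manifest.planted_puls:
            key = (
                entry["genome"], entry["contig"],
                min(entry["susc_rank"], entry["susd_rank"]),
                max(entry["susc_rank"], entry["susd_rank"]),
            )
            call = by_anchor[key]
            anchor_ids = {p.susc.protein_id for p in call.anchor_pairs} | {
                p.susd.protein_id for p in call.anchor_pairs
            }
            got_fams = sorted(
                f
                for g in call.member_genes
                if g.protein_id not in anchor_ids
                for _, f in g.cazyme_families()
            )
            assert got_fams == sorted(c["family"] for c in entry["cargo"])
            assert call.cargo["regulator"], entry
            assert call.cargo["peptidase"], entry


class TestDetectCellulosomes:
    def _classify(self, arch_strings):
        archs = {f"p{i}": arch_from_string(f"p{i}", s) for i, s in enumerate(arch_strings)}
        return {pid: classify_protein(a) for pid, a in archs.items()}

    def test_cohesin_with_plain_dockerin_enzyme_not_capable(self):
        cls = self._classify(["cohesin_I-cohesin_I", "GH5-dockerin_I"])
        rep = detect_cellulosomes("gX", cls)
        assert rep.scaffoldins == ["p0"]
        assert rep.dockerin_catalytic == ["p1"]
        assert rep.dockerin_multimodular == []
        assert not rep.is_cellulosome_capable

    def test_cohesin_with_multimodular_dockerin_capable(self):
        cls = self._classify(["cohesin_I-SLH", "GH9-CBM3-dockerin_I"])
        rep = detect_cellulosomes("gY", cls)
        assert rep.is_cellulosome_capable
        assert rep.dockerin_multimodular == ["p1"]

    def test_dockerin_without_cohesin_not_capable(self):
        cls = self._classify(["GH9-CBM3-dockerin_I", "GH5_4-CBM22-CE3-dockerin_I"])
        rep = detect_cellulosomes("gZ", cls)
        assert rep.scaffoldins == []
        assert not rep.is_cellulosome_capable

    def test_empty_genome_empty_report(self):
        rep = detect_cellulosomes("gE", self._classify(["GH5", ""]))
        assert rep.scaffoldins == rep.dockerin_catalytic == []
        assert not rep.is_cellulosome_capable
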