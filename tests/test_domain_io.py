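import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cazloci.domain_io import (
    DomtbloutParseError,
    build_architecture,
    filter_hits,
    parse_domtblout,
    resolve_overlaps,
    write_domtblout,
)
from cazloci.model import DomainHit, ModelClass

from oracles import filter_predicate, greedy_overlap_sim


def make_hit(
    protein_id="p1",
    model_name="GH5",
    i_evalue=1e-9,
    model_length=100,
    hmm_span=(1, 80),
    ali_span=(10, 90),
    score=100.0,
    protein_length=500,
):
    return DomainHit(
        protein_id=protein_id,
        protein_length=protein_length,
        model_name=model_name,
        model_length=model_length,
        hmm_from=hmm_span[0],
        hmm_to=hmm_span[1],
        ali_from=ali_span[0],
        ali_to=ali_span[1],
        i_evalue=i_evalue,
        score=score,
    )


def random_hits(rng, n, protein_id="p1", model_length=100, protein_length=1000):
    """Hits with uniform log10 E-value in [-12, 0] and uniform HMM coverage in [0, 1]."""
    hits = []
    for _ in range(n):
        cov = rng.uniform()
        span = max(1, round(cov * model_length))
        hmm_from = int(rng.integers(1, model_length - span + 2))
        ali_from = int(rng.integers(1, protein_length - span + 1))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                protein_length=protein_length,
                model_name=f"GH{int(rng.integers(1, 150))}",
                model_length=model_length,
                hmm_from=hmm_from,
                hmm_to=hmm_from + span - 1,
                ali_from=ali_from,
                ali_to=ali_from + span - 1,
                i_evalue=10.0 ** rng.uniform(-12, 0),
                score=float(np.round(rng.uniform(10, 300), 1)),
            )
        )
    return hits


class TestParse:
    def test_empty_file_yields_no_hits(self, tmp_path):
        p = tmp_path / "empty.domtbl"
        p.write_text("# only a header comment\n")
        assert parse_domtblout(p) == []

    def test_dockerin_model_classified_as_dockerin(self, tmp_path):
        p = tmp_path / "one.domtbl"
        write_domtblout([make_hit(model_name="dockerin")], p)
        (hit,) = parse_domtblout(p)
        assert hit.model_class is ModelClass.DOCKERIN

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.domtbl"
        p.write_text("# header\nGH5 - 100\n")
        with pytest.raises(DomtbloutParseError, match=":2:"):
            parse_domtblout(p)

    def test_roundtrip_preserves_hits(self, tmp_path):
        rng = np.random.default_rng(11)
        hits = random_hits(rng, 50)
        # round evalues to the emitted precision so equality is exact
        hits = [
            DomainHit(
                protein_id=h.protein_id, protein_length=h.protein_length,
                model_name=h.model_name, model_length=h.model_length,
                hmm_from=h.hmm_from, hmm_to=h.hmm_to,
                ali_from=h.ali_from, ali_to=h.ali_to,
                i_evalue=float(f"{h.i_evalue:.3g}"), score=h.score,
            )
            for h in hits
        ]
        p = tmp_path / "hits.domtbl"
        write_domtblout(hits, p)
        assert parse_domtblout(p) == hits

    def test_fixture_hit_count_matches_manifest(self, fixture_dir, manifest):
        hits = parse_domtblout(fixture_dir / "hits.domtbl")
        assert len(hits) == manifest.n_hits_emitted


class TestFilter:
    def test_good_hit_retained(self):
        h = make_hit(i_evalue=1e-8, model_length=100, hmm_span=(1, 60))
        assert filter_hits([h]) == [h]

    def test_weak_evalue_removed(self):
        h = make_hit(i_evalue=1e-4)
        assert filter_hits([h]) == []

    def test_boundary_evalue_exactly_kept(self):
        # the cutoff is read as "remove E > 1e-6": equality survives
        h = make_hit(i_evalue=1e-6)
        assert filter_hits([h]) == [h]

    def test_low_coverage_removed(self):
        h = make_hit(i_evalue=1e-20, model_length=200, hmm_span=(1, 50))
        assert filter_hits([h]) == []

    def test_matches_independent_predicate_on_random_hits(self):
        rng = np.random.default_rng(42)
        hits = random_hits(rng, 1000)
        expected = [h for h in hits if filter_predicate(h)]
        assert filter_hits(hits) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        hits = random_hits(rng, 200)
        once = filter_hits(hits)
        assert filter_hits(once) == once

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        e1=st.floats(min_value=-12, max_value=0),
        e2=st.floats(min_value=-12, max_value=0),
        c1=st.floats(min_value=0.0, max_value=1.0),
        c2=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_relaxing_thresholds_never_shrinks(self, e1, e2, c1, c2, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, 50)
        loose_e, tight_e = 10.0 ** max(e1, e2), 10.0 ** min(e1, e2)
        loose_c, tight_c = min(c1, c2), max(c1, c2)
        tight = set(filter_hits(hits, tight_e, tight_c))
        loose = set(filter_hits(hits, loose_e, loose_c))
        assert tight <= loose


class TestResolveOverlaps:
    def test_disjoint_hits_both_kept(self):
        a = make_hit(model_name="GH5", ali_span=(10, 100))
        b = make_hit(model_name="CBM22", ali_span=(150, 250))
        assert resolve_overlaps([a, b]) == [a, b]

    def test_identical_interval_keeps_lower_evalue(self):
        a = make_hit(model_name="GH5", i_evalue=1e-9, ali_span=(10, 100))
        b = make_hit(model_name="GH8", i_evalue=1e-7, ali_span=(10, 100))
        assert resolve_overlaps([a, b]) == [a]
        assert resolve_overlaps([b, a]) == [a]

    def test_mixed_proteins_rejected(self):
        a = make_hit(protein_id="p1")
        b = make_hit(protein_id="p2")
        with pytest.raises(ValueError):
            resolve_overlaps([a, b])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_greedy_simulation(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):  # 200 random per-protein hit sets across seeds
            hits = random_hits(rng, int(rng.integers(1, 21)))
            assert resolve_overlaps(hits) == greedy_overlap_sim(hits)

    def test_survivors_pairwise_satisfy_overlap_bound(self):
        rng = np.random.default_rng(99)
        hits = random_hits(rng, 20)
        kept = resolve_overlaps(hits)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                ov = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
                assert ov <= 0.5 * min(a.ali_length, b.ali_length)


class TestArchitecture:
    def test_cellulosomal_multidomain_architecture_string(self):
        hits = [
            make_hit(model_name="GH5_4", ali_span=(10, 210), protein_length=700),
            make_hit(model_name="CBM22", ali_span=(230, 380), protein_length=700),
            make_hit(model_name="CE3", ali_span=(400, 520), protein_length=700),
            make_hit(model_name="dockerin", ali_span=(540, 600), protein_length=700),
        ]
        arch = build_architecture(hits)
        assert arch.architecture_string == "GH5_4-CBM22-CE3-dockerin"

    def test_single_domain(self):
        arch = build_architecture([make_hit(model_name="CBM50")])
        assert arch.architecture_string == "CBM50"

    def test_empty_architecture(self):
        arch = build_architecture([], protein_id="p9")
        assert arch.architecture_string == ""
        assert len(arch) == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=2**16), perm=st.randoms())
    def test_input_order_invariance(self, seed, perm):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, 6)
        shuffled = list(hits)
        perm.shuffle(shuffled)
        assert (
            build_architecture(shuffled).architecture_string
            == build_architecture(hits).architecture_string
        )
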