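import numpy as np
import pytest
from hypothesis import given, strategies as st

from symbiopart.source_classifier import (
    BLATTODEA_TAXID, FLAGELLATE, TERMITE, UNCLEAR,
    ClassifierParams, HitRecord, HitTableError, SourceCall,
    best_hit, classify_transcript, conflict_free, parse_hits,
    tabulate_sources, _hit_rank_key,
)
from symbiopart.syndata import generate_taxonomy


def mk_hit(qseqid="q1", sseqid="s1", pident=95.0, length=500, qstart=1,
           qend=None, evalue=1e-50, bitscore=900.0, staxid=1000103):
    qend = qend if qend is not None else qstart + length - 1
    return HitRecord(qseqid, sseqid, pident, length, 5, 1, qstart, qend,
                     1, length, evalue, bitscore, staxid)


@pytest.fixture(scope="module")
def tax():
    return generate_taxonomy()


class TestParsing:
    def test_evalue_cutoff_is_inclusive(self, tmp_path):
        path = tmp_path / "hits.tsv"
        row = "q1\ts1\t95.0\t500\t5\t1\t1\t500\t1\t500\t{}\t900\t1000103\n"
        path.write_text(row.format("1e-3") + row.format("1e-5"))
        hits = parse_hits(path, evalue_cutoff=1e-5)
        assert len(hits["q1"]) == 1 and hits["q1"][0].evalue == 1e-5

    def test_empty_file_gives_empty_map(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert parse_hits(path) == {}

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t95.0\t500\t5\t1\t1\t500\t1\t500\t1e-50\t900\t1\n"
            "q2\ts1\t95.0\t500\t5\t1\t1\t500\t1\t500\t1e-50\t900\n")
        with pytest.raises(HitTableError, match=":2"):
            parse_hits(path)

    def test_non_numeric_field_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\tNA\t500\t5\t1\t1\t500\t1\t500\t1e-50\t900\t1\n")
        with pytest.raises(HitTableError, match=":1"):
            parse_hits(path)


class TestBestHit:
    def test_single_hit(self):
        h = mk_hit()
        assert best_hit([h]) is h

    def test_higher_bitscore_wins(self):
        lo = mk_hit(sseqid="a", bitscore=180)
        hi = mk_hit(sseqid="b", bitscore=200)
        assert best_hit([lo, hi]) is hi

    def test_matches_bruteforce_composite_key(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            hits = [mk_hit(sseqid=f"s{rng.integers(5)}",
                           pident=float(rng.choice([90.0, 95.0])),
                           evalue=float(rng.choice([1e-50, 1e-40])),
                           bitscore=float(rng.choice([100.0, 200.0])))
                    for _ in range(int(rng.integers(1, 8)))]
            brute = sorted(hits, key=_hit_rank_key)[0]
            assert best_hit(hits) == brute

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            best_hit([])


class TestConflictFree:
    def test_only_focal_hits_vacuously_true(self, tax):
        hits = [mk_hit(), mk_hit(sseqid="s2", bitscore=500)]
        assert conflict_free(hits, hits[0], BLATTODEA_TAXID, tax, 30)

    def test_offclade_overhang_beyond_tolerance(self, tax):
        best = mk_hit(qstart=1, qend=500)
        fungal = mk_hit(sseqid="f", qstart=450, qend=700, staxid=1000302,
                        bitscore=100)
        # 200 bases outside [1, 500] > 30 -> conflict
        assert not conflict_free([best, fungal], best, BLATTODEA_TAXID,
                                 tax, 30)

    def test_offclade_hit_inside_best_region(self, tax):
        best = mk_hit(qstart=1, qend=500)
        fungal = mk_hit(sseqid="f", qstart=100, qend=400, staxid=1000302,
                        bitscore=100)
        assert conflict_free([best, fungal], best, BLATTODEA_TAXID, tax, 30)

    def test_multi_hsp_best_subject_union(self, tax):
        # two HSPs of the best subject cover [1,300]+[400,700]; an
        # off-clade hit inside the union is not a conflict
        h1 = mk_hit(qstart=1, qend=300, bitscore=900)
        h2 = mk_hit(qstart=400, qend=700, bitscore=800)
        fungal = mk_hit(sseqid="f", qstart=420, qend=680, staxid=1000302,
                        bitscore=100)
        assert conflict_free([h1, h2, fungal], h1, BLATTODEA_TAXID, tax, 30)


def flagellate_hits(pidents, staxids):
    return [mk_hit(sseqid=f"m{i}", pident=p, staxid=s,
                   bitscore=1000 - 10 * i)
            for i, (p, s) in enumerate(zip(pidents, staxids))]


class TestClassification:
    def test_host_best_hit_is_termite(self, tax):
        call = classify_transcript("t", [mk_hit()], tax)
        assert call.source == TERMITE and call.order is None

    def test_no_hits_is_unclear(self, tax):
        assert classify_transcript("t", [], tax).source == UNCLEAR

    def test_genus_consensus_devescovina(self, tax):
        # five Devescovina-species hits, identities 95..91 -> genus call
        hits = flagellate_hits([95, 94, 93, 92, 91], [1000203] * 5)
        call = classify_transcript("t", hits, tax)
        assert call.source == FLAGELLATE
        assert tax.name(call.order) == "Cristamonadida"
        assert tax.name(call.genus) == "Devescovina"

    def test_mixed_orders_block_consensus(self, tax):
        # orders {Crist x4, Oxym x1}: no order, hence no genus
        hits = flagellate_hits([95, 94, 93, 92, 81],
                               [1000203] * 4 + [1000213])
        call = classify_transcript("t", hits, tax)
        assert call.source == FLAGELLATE
        assert call.order is None and call.genus is None

    def test_identity_at_90_blocks_genus_but_not_order(self, tax):
        # strict > 90: one hit at exactly 90 keeps the order, drops genus
        hits = flagellate_hits([95, 94, 93, 92, 90.0], [1000203] * 5)
        call = classify_transcript("t", hits, tax)
        assert tax.name(call.order) == "Cristamonadida"
        assert call.genus is None

    def test_fewer_than_five_symbiont_hits_stay_unresolved(self, tax):
        hits = flagellate_hits([95, 94, 93], [1000203] * 3)
        call = classify_transcript("t", hits, tax)
        assert call.source == FLAGELLATE and call.order is None
        relaxed = classify_transcript(
            "t", hits, tax, ClassifierParams(min_consensus_hits=3))
        assert tax.name(relaxed.genus) == "Devescovina"

    def test_conflicting_offclade_hit_moves_to_unclear(self, tax):
        best = mk_hit(qstart=1, qend=500)
        fungal = mk_hit(sseqid="f", qstart=450, qend=900, staxid=1000302,
                        bitscore=200)
        call = classify_transcript("t", [best, fungal], tax)
        assert call.source == UNCLEAR

    @given(st.permutations(range(6)))
    def test_hit_order_permutation_invariance(self, perm):
        tax = generate_taxonomy()
        hits = flagellate_hits([95, 94, 93, 92, 91, 85],
                               [1000203, 1000203, 1000204, 1000203,
                                1000204, 1000213])
        call0 = classify_transcript("t", hits, tax)
        call1 = classify_transcript("t", [hits[i] for i in perm], tax)
        assert (call0.source, call0.order, call0.genus) == \
            (call1.source, call1.order, call1.genus)

    def test_adding_offclade_hit_never_rescues_unclear(self, tax):
        # monotonicity: extra non-focal hits only move calls toward UNCLEAR
        base_sets = [
            [mk_hit()],
            flagellate_hits([95, 94, 93, 92, 91], [1000203] * 5),
            [],
        ]
        extra = mk_hit(sseqid="x", qstart=600, qend=1400, staxid=1000312,
                       bitscore=50)
        rank = {TERMITE: 1, FLAGELLATE: 1, UNCLEAR: 0}
        for hits in base_sets:
            before = classify_transcript("t", hits, tax).source
            after = classify_transcript("t", hits + [extra], tax).source
            assert rank[after] <= rank[before]


class TestTabulation:
    def test_empty_calls_give_zero_table(self, tax):
        table = tabulate_sources([], {}, tax)
        assert table.loc["total", "total"] == 0

    def test_missing_gene_label_counts_as_others(self, tax):
        calls = [SourceCall("a", FLAGELLATE, order=tax.taxid_of(
            "Cristamonadida"))]
        with pytest.warns(UserWarning, match="missing"):
            table = tabulate_sources(calls, {}, tax)
        assert table.loc["others", "Cristamonadida"] == 1

    def test_totals_are_exact_sums(self, tax):
        crist = tax.taxid_of("Cristamonadida")
        oxy = tax.taxid_of("Oxymonadida")
        calls = [SourceCall(f"t{i}", FLAGELLATE, order=o)
                 for i, o in enumerate([crist, crist, oxy, None])]
        calls.append(SourceCall("host", TERMITE))   # not counted
        labels = {"t0": "actin", "t1": "actin", "t2": "18S rRNA",
                  "t3": "actin"}
        table = tabulate_sources(calls, labels, tax)
        assert table.loc["total", "total"] == 4
        assert table.loc["actin", "total"] == 3
        assert table.loc["total", "Cristamonadida"] == 2
        assert table.loc["total", "unclassified"] == 1
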