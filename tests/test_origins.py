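"""Origin classification: NG86 Ks against an enumeration oracle, clock
dating, collinearity chaining, duplication-mode precedence and the
overlap / TE / de novo rules."""

import random

import numpy as np
import pytest

from orphanforge.homology import HomologyHit
from orphanforge.origins import (classify_duplication, collinear_blocks,
                                 date_duplication, de_novo_origin,
                                 nei_gojobori_ks, overlap_origin,
                                 paralog_pairs, te_origin)
from orphanforge.seq_io import GeneModel, ReferenceDB, translate
from orphanforge.synthetic import _mutate_to_ks, _random_cds

from .oracles import chain_oracle, ng86_oracle


class TestNeiGojobori:
    def test_identical_pair_ks_zero(self):
        cds = "ATGAAACCCGGGTTTCTG"
        r = nei_gojobori_ks(cds, cds, aligned=True)
        assert r["ks"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_alignments(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = _random_cds(rng, 30)[:-3]      # drop stop codon
            b = list(a)
            for _k in range(int(rng.integers(1, 12))):
                i = int(rng.integers(len(b)))
                b[i] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            # skip pairs that mutated into stop codons: both paths drop them
            r = nei_gojobori_ks(a, b, aligned=True)
            o = ng86_oracle(a, b)
            assert r["S"] == pytest.approx(o["S"], abs=1e-9)
            assert r["Sd"] == pytest.approx(o["Sd"], abs=1e-9)
            if o["ks"] is None:
                assert r["ks"] is None
            else:
                assert r["ks"] == pytest.approx(o["ks"], abs=1e-9)

    def test_three_synonymous_third_position_changes(self):
        rng = np.random.default_rng(9)
        a = _random_cds(rng, 32)[:-3]
        b = _mutate_to_ks(rng, a, 0.08)
        r = nei_gojobori_ks(a, b, aligned=True)
        o = ng86_oracle(a, b)
        assert r["ks"] == pytest.approx(o["ks"], abs=1e-9)
        assert r["ka"] == pytest.approx(0.0, abs=1e-12)

    def test_saturation_flagged(self):
        # third positions maximally scrambled: force ps >= 0.75 via a
        # synthetic alignment of highly divergent synonymous codons
        a = "CTA" * 40
        b = "TTG" * 40     # Leu vs Leu: every difference synonymous
        r = nei_gojobori_ks(a, b, aligned=True)
        assert r["ks"] is None
        assert r["ps"] >= 0.75

    def test_unaligned_input_uses_protein_backthreading(self):
        rng = np.random.default_rng(3)
        a = _random_cds(rng, 60)
        b = _mutate_to_ks(rng, a, 0.2)
        r = nei_gojobori_ks(a, b)          # full CDSs with stop codons
        assert 0.05 < r["ks"] < 0.4

    def test_ks_recovery_of_planted_values(self):
        rng = np.random.default_rng(17)
        planted, estimated = [], []
        for _ in range(40):
            ks = float(rng.uniform(0.1, 0.8))
            a = _random_cds(rng, 200)
            b = _mutate_to_ks(rng, a, ks)
            r = nei_gojobori_ks(a, b, aligned=True)
            planted.append(ks)
            estimated.append(r["ks"])
        rel = np.abs(np.array(estimated) / np.array(planted) - 1.0)
        assert np.median(rel) < 0.15
        assert np.mean(rel) < 0.20


class TestClockDating:
    @pytest.mark.parametrize("ks,expected", [(0.20, 15.38), (0.40, 30.77)])
    def test_published_endpoints(self, ks, expected):
        assert date_duplication(ks) == pytest.approx(expected, abs=0.01)

    def test_zero_ks_zero_age(self):
        assert date_duplication(0.0) == 0.0

    def test_linearity(self):
        assert date_duplication(0.3) == pytest.approx(3 * date_duplication(0.1))

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            date_duplication(-0.1)


class TestCollinearity:
    def _ranks(self, placements):
        return {g: (c, r) for g, (c, r) in placements.items()}

    def test_planted_run_of_six_yields_one_block(self):
        ranks = {}
        anchors = []
        for k in range(6):
            ranks[f"a{k}"] = ("c1", 10 + k)
            ranks[f"b{k}"] = ("c2", 20 + k)
            anchors.append((f"a{k}", f"b{k}"))
        blocks = collinear_blocks(anchors, ranks, min_anchors=5)
        assert len(blocks) == 1 and blocks[0].size == 6

    def test_four_anchors_below_threshold(self):
        ranks = {}
        anchors = []
        for k in range(4):
            ranks[f"a{k}"] = ("c1", k)
            ranks[f"b{k}"] = ("c2", k)
            anchors.append((f"a{k}", f"b{k}"))
        assert collinear_blocks(anchors, ranks, min_anchors=5) == []

    def test_inverted_block_detected(self):
        ranks = {}
        anchors = []
        for k in range(6):
            ranks[f"a{k}"] = ("c1", k)
            ranks[f"b{k}"] = ("c2", 50 - k)
            anchors.append((f"a{k}", f"b{k}"))
        blocks = collinear_blocks(anchors, ranks, min_anchors=5)
        assert len(blocks) == 1 and blocks[0].orientation == -1

    def test_chain_size_matches_exhaustive_oracle(self):
        rng = random.Random(13)
        for _ in range(20):
            n = rng.randint(4, 12)
            pairs = [(rng.randint(0, 30), rng.randint(0, 30)) for _ in range(n)]
            pairs = list(dict.fromkeys(pairs))
            ranks = {}
            anchors = []
            for k, (ra, rb) in enumerate(pairs):
                ranks[f"a{k}"] = ("c1", ra)
                ranks[f"b{k}"] = ("c2", rb)
                anchors.append((f"a{k}", f"b{k}"))
            blocks = collinear_blocks(anchors, ranks, min_anchors=1, max_gap=8)
            got = blocks[0].size if blocks else 0
            assert got == chain_oracle(pairs, max_gap=8)


class TestDuplicationModes:
    RANKS = {"a": ("c1", 10), "b": ("c1", 11), "c": ("c1", 15),
             "d": ("c2", 3), "w1": ("c1", 20), "w2": ("c2", 40)}

    def test_tandem_adjacent(self):
        assert classify_duplication(("a", "b"), self.RANKS, []) == "tandem"

    def test_proximal_window(self):
        assert classify_duplication(("a", "c"), self.RANKS, []) == "proximal"

    def test_dispersed_across_chromosomes(self):
        assert classify_duplication(("a", "d"), self.RANKS, []) == "dispersed"

    def test_wgd_precedence_over_tandem(self):
        from orphanforge.origins import CollinearBlock
        block = CollinearBlock("c1", "c1", [("a", "b")] * 5, 1)
        assert classify_duplication(("a", "b"), self.RANKS, [block]) == "wgd"

    def test_transposed_requires_outgroup_asymmetry(self):
        assert classify_duplication(("a", "d"), self.RANKS, [],
                                    ancestral_loci={"a"}) == "transposed"
        assert classify_duplication(("a", "d"), self.RANKS, [],
                                    ancestral_loci={"a", "d"}) == "dispersed"
        assert classify_duplication(("a", "d"), self.RANKS, [],
                                    ancestral_loci=None) == "dispersed"

    def test_unannotated_gene_raises(self):
        with pytest.raises(KeyError):
            classify_duplication(("a", "zz"), self.RANKS, [])


def _og_model(cds, gene_id="og1"):
    return GeneModel(gene_id, "chr1", "+", 1, len(cds), [(1, len(cds))],
                     cds, translate(cds))


class TestOverlapRule:
    def _db(self, records):
        return ReferenceDB(name="cds", kind="nucleotide", records=records)

    def test_sixty_percent_coverage_true(self):
        rng = np.random.default_rng(2)
        cds = _random_cds(rng, 200)
        frag = cds[:int(0.6 * len(cds))]
        ok, ev = overlap_origin(_og_model(cds), self._db([("x", frag)]))
        assert ok and ev["coverage"] >= 0.5

    def test_forty_percent_coverage_false(self):
        rng = np.random.default_rng(2)
        cds = _random_cds(rng, 200)
        frag = cds[:int(0.4 * len(cds))]
        ok, ev = overlap_origin(_og_model(cds), self._db([("x", frag)]))
        assert not ok and ev["coverage"] < 0.5

    def test_union_of_two_hits_crosses_threshold(self):
        rng = np.random.default_rng(4)
        cds = _random_cds(rng, 300)
        L = len(cds)
        # two fragments in separate records: 0-30 % and 20-50 %
        records = [("p1", cds[: int(0.3 * L)]),
                   ("p2", cds[int(0.2 * L): int(0.5 * L)])]
        ok, ev = overlap_origin(_og_model(cds), self._db(records))
        assert ok
        assert ev["coverage"] == pytest.approx(0.5, abs=0.02)


class TestTeRule:
    def test_planted_te_fragment_detected(self, study, origin_calls):
        truth = study.truth
        calls = {c.gene_id: c for c in origin_calls[0]}
        for gid in truth[truth.category == "te"].gene_id:
            assert calls[gid].mechanism == "te"

    def test_random_cds_rarely_hits_te_library(self):
        rng = np.random.default_rng(6)
        lib = [(f"te{i}", _random_nt_seq(rng, 500)) for i in range(10)]
        n_hits = sum(te_origin(_random_cds(rng, 150), lib)[0]
                     for _ in range(60))
        assert n_hits <= 3

    def test_empty_library_false(self):
        assert te_origin("ATGAAATAA", []) == (False, {"n_hits": 0})
        assert te_origin("ATGAAATAA", None)[0] is False


def _random_nt_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestDeNovoRule:
    def _region_db(self, region):
        return ReferenceDB(name="genome", kind="nucleotide",
                           records=[("scaf1", region)])

    def _setup(self, rng, stop_at=0.4):
        cds = _random_cds(rng, 150)
        region = list(cds)
        k = int(stop_at * (len(cds) // 3))
        region[3 * k:3 * k + 3] = "TAA"
        return _og_model(cds), "".join(region)

    def test_planted_enabler_case_true(self):
        rng = np.random.default_rng(8)
        og, region = self._setup(rng)
        ok, ev = de_novo_origin(og, [self._region_db("A" * 90 + region + "C" * 90)])
        assert ok
        assert ev["orf_aa"] < 0.5 * og.protein_length

    def test_low_identity_fails_criterion(self):
        rng = np.random.default_rng(8)
        og, _region = self._setup(rng)
        unrelated = _random_nt_seq(rng, 600)
        ok, _ = de_novo_origin(og, [self._region_db(unrelated)])
        assert not ok

    def test_full_orf_fails_truncation_criterion(self):
        rng = np.random.default_rng(8)
        og = _og_model(_random_cds(rng, 150))
        region = og.cds_seq[:-3]        # intact frame, no premature stop
        ok, _ = de_novo_origin(og, [self._region_db(region)])
        assert not ok


class TestParalogPairs:
    def test_planted_pair_detected_and_symmetric(self, study, origin_calls):
        truth = study.truth
        calls = {c.gene_id: c for c in origin_calls[0]}
        for gid, row in truth[truth.category.isin(
                ("tandem", "proximal", "dispersed", "wgd", "transposed"))].iterrows():
            c = calls[gid]
            assert c.mechanism == "duplication"
            assert c.partner_id == row.partner

    def test_unrelated_proteome_yields_no_pairs(self):
        rng = random.Random(5)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        proteome = [(f"g{i}", "".join(rng.choice(aas) for _ in range(150)))
                    for i in range(30)]
        pairs, best = paralog_pairs(proteome)
        assert pairs == [] and best == {}


class TestEndToEndOrigins:
    def test_mechanism_table_matches_plan(self, study, origin_calls):
        _calls, counts = origin_calls
        truth = study.truth
        expected = (truth[truth.is_orphan].origin_mode
                    .fillna("unclassified").value_counts().to_dict())
        assert counts == expected

    def test_each_orphan_has_exactly_one_mechanism(self, cascade_summary, origin_calls):
        calls, counts = origin_calls
        assert len(calls) == len(cascade_summary.orphan_ids)
        assert sum(counts.values()) == len(calls)

    def test_duplication_ks_near_planted(self, study, origin_calls):
        truth = study.truth
        for c in origin_calls[0]:
            if c.ks is None:
                continue
            planted = truth.loc[c.gene_id].planted_ks
            assert c.ks == pytest.approx(planted, rel=0.25)
            assert c.age_mya == pytest.approx(c.ks / (2 * 6.5e-9) / 1e6)
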