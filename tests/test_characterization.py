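"""Gene-structure statistics, isoelectric point, rank-sum contrasts and
chromosomal density summaries."""

import itertools

import numpy as np
import pytest

from orphanforge.characterization import (chromosome_density, contrast_table,
                                          gene_stats, gene_stats_table,
                                          isoelectric_point, net_charge,
                                          wilcoxon_rank_sum)
from orphanforge.seq_io import GeneModel

from .oracles import wilcoxon_exact_oracle


def _gene(cds, exons, gene_id="g", chrom="chr1", strand="+"):
    from orphanforge.seq_io import translate
    return GeneModel(gene_id, chrom, strand, exons[0][0], exons[-1][1],
                     exons, cds, translate(cds))


class TestGeneStats:
    def test_gc_and_protein_length(self):
        st = gene_stats(_gene("ATGGGCTAA", [(1, 9)]))
        assert st.gc_content == pytest.approx(4 / 9)
        assert st.protein_length == 2

    def test_exon_count_and_mean_length(self):
        st = gene_stats(_gene("ATG" + "AAA" * 64 + "TAA", [(1, 100), (201, 300)]))
        assert st.exon_count == 2
        assert st.mean_exon_length == pytest.approx(100.0)

    def test_all_gc_cds(self):
        st = gene_stats(_gene("GGGCCCGGGCCC", [(1, 12)]))
        assert st.gc_content == 1.0

    def test_missing_cds_rejected(self):
        g = _gene("ATGTAA", [(1, 6)])
        g.cds_seq = ""
        with pytest.raises(ValueError, match="missing CDS"):
            gene_stats(g)


class TestIsoelectricPoint:
    def test_glycine_dipeptide_midpoint_of_termini(self):
        # only termini ionize: root sits midway between pK 8.6 and 3.6
        assert isoelectric_point("GG") == pytest.approx(6.10, abs=0.01)

    def test_appending_lysine_raises_pi(self):
        for pep in ("GG", "AAAA", "DDK"):
            assert isoelectric_point(pep + "K") > isoelectric_point(pep)

    def test_acidic_peptide_negative_at_neutral_ph(self):
        assert net_charge("DDDD", 7.0) < 0

    def test_charge_zero_at_reported_pi(self):
        for pep in ("GG", "KRKR", "DEDE", "MKWVTFISLLLF"):
            pi = isoelectric_point(pep)
            assert abs(net_charge(pep, pi)) < 1e-3

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            isoelectric_point("")


class TestWilcoxon:
    def test_small_sample_exact_enumeration(self):
        c = wilcoxon_rank_sum([1, 2], [3, 4])
        assert c.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p_value == 1.0

    def test_exact_path_matches_enumeration_oracle(self):
        values = [3.1, 1.2, 9.4, 4.4, 5.9, 0.3, 7.7, 8.1, 2.2, 6.6]
        for k in range(2, 9):
            for comb in itertools.combinations(range(10), k):
                x = [values[i] for i in comb]
                y = [values[i] for i in range(10) if i not in set(comb)]
                got = wilcoxon_rank_sum(x, y).p_value
                assert got == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-9)

    def test_normal_approximation_close_to_enumeration(self):
        # the asymptotic fallback (used for pooled n > 10) deviates from
        # the exact null by at most ~0.039, reached at the extreme 2-vs-8
        # split; the deviation depends only on ranks, not on the values
        from scipy.stats import mannwhitneyu
        values = [3.1, 1.2, 9.4, 4.4, 5.9, 0.3, 7.7, 8.1, 2.2, 6.6]
        worst = 0.0
        for k in range(2, 9):
            for comb in itertools.combinations(range(10), k):
                x = [values[i] for i in comb]
                y = [values[i] for i in range(10) if i not in set(comb)]
                approx = mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic",
                                      use_continuity=True).pvalue
                worst = max(worst, abs(min(approx, 1.0)
                                       - wilcoxon_exact_oracle(x, y)))
        assert worst <= 0.04

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1], [2, 3])


class TestContrasts:
    def test_planted_shorter_orphans_detected(self, study, cascade_summary):
        stats_df = gene_stats_table(study.package.genes,
                                    set(cascade_summary.orphan_ids))
        table = contrast_table(stats_df).set_index("metric")
        row = table.loc["protein_length"]
        assert row.direction == "OG<NOG"
        assert row.p_value < 1e-3


class TestChromosomeDensity:
    def _uniform_genes(self, n, length=1_000_000, rng=None):
        rng = rng or np.random.default_rng(0)
        genes = []
        for i in range(n):
            start = int(rng.integers(1, length - 100))
            genes.append(GeneModel(f"g{i}", "chr1", "+", start, start + 99,
                                   [(start, start + 99)], "ATGTAA", "M"))
        return genes

    def test_single_window_equals_global_fraction(self):
        genes = self._uniform_genes(100)
        og = {g.gene_id for g in genes[:25]}
        win, per_chrom, _ = chromosome_density(genes, og, {"chr1": 1_000_000},
                                               window_bp=10_000_000)
        assert len(win) == 1
        assert win.og_fraction[0] == pytest.approx(0.25)
        assert per_chrom.og_percent[0] == pytest.approx(25.0)

    def test_uniform_placement_ratio_near_one(self):
        rng = np.random.default_rng(7)
        genes = self._uniform_genes(2000, rng=rng)
        og = {g.gene_id for g in genes if rng.random() < 0.3}
        _, _, ratio = chromosome_density(genes, og, {"chr1": 1_000_000},
                                         window_bp=50_000)
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_terminal_enrichment_detected(self):
        genes = self._uniform_genes(1000)
        # orphans only in the outer 10 % of the chromosome
        og = {g.gene_id for g in genes
              if g.start < 100_000 or g.end > 900_000}
        _, _, ratio = chromosome_density(genes, og, {"chr1": 1_000_000},
                                         window_bp=50_000)
        assert ratio > 1.0

    def test_gene_beyond_chromosome_rejected(self):
        genes = self._uniform_genes(10)
        with pytest.raises(ValueError, match="beyond chromosome"):
            chromosome_density(genes, set(), {"chr1": 50}, window_bp=10)
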