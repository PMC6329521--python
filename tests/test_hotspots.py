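"""Recurrence catalog, TTCCG annotation, motif classes, burden coupling."""
import itertools

import numpy as np
import pytest

from uvhotspot import hotspots as hs
from uvhotspot import synth
from uvhotspot.genome import Genome, revcomp
from uvhotspot.io import MutationRecord, TssRecord

import pandas as pd


def M(chrom, pos, ref, alt, sample):
    return MutationRecord(chrom, pos, ref, alt, sample)


class TestRecurrence:
    def test_distinct_tumor_counting(self):
        muts = [M("chr1", 100, "C", "T", f"s{i}") for i in range(3)]
        assert hs.recurrence_table(muts) == {("chr1", 100): 3}

    def test_one_tumor_two_calls_counts_once(self):
        muts = [M("chr1", 100, "C", "T", "s1"), M("chr1", 100, "C", "A", "s1")]
        assert hs.recurrence_table(muts) == {("chr1", 100): 1}

    def test_equals_bruteforce_on_synthetic_cohort(self, cohort):
        sub = cohort[:3000]
        table = hs.recurrence_table(sub)
        brute = {}
        for key in {(m.chrom, m.pos) for m in sub}:
            brute[key] = len({m.sample_id for m in sub
                              if (m.chrom, m.pos) == key})
        assert table == brute


class TestTssDistance:
    def test_upstream_of_plus_gene_is_negative(self):
        tss = [TssRecord("g", "chr1", 1000, "+")]
        assert hs.tss_distance("chr1", 884, tss) == (-116, "g")

    def test_minus_strand_orientation_mirror(self):
        tss = [TssRecord("g", "chr1", 1000, "-")]
        assert hs.tss_distance("chr1", 1116, tss) == (-116, "g")

    def test_site_at_tss_is_zero_and_ties_break_lexicographically(self):
        tss = [TssRecord("gB", "chr1", 90, "+"), TssRecord("gA", "chr1", 110, "+")]
        assert hs.tss_distance("chr1", 100, tss) == (-10, "gA")
        assert hs.tss_distance("chr1", 110, tss) == (0, "gA")

    def test_empty_tss_list_is_error(self):
        with pytest.raises(ValueError):
            hs.TssIndex([])


class TestAnnotate:
    def test_plus_strand_context_flag(self):
        seq = "A" * 8 + "CCTTCCG" + "A" * 20
        g = Genome({"c": seq})
        flag, ctx = hs.annotate_ttccg(g, "c", 9, "+")      # second C of CC
        assert flag and len(ctx) == 21 and ctx[10] == "C"

    def test_minus_strand_reverse_complement_oracle(self):
        # plus strand shows CGGAA ~ the minus strand reads TTCCG
        seq = "T" * 10 + "G" + "CGGAA" + "T" * 10
        g = Genome({"c": seq})
        flag, ctx = hs.annotate_ttccg(g, "c", 10, "-")     # ref G site
        assert ctx == revcomp(g.fetch("c", 0, 21))
        assert flag

    def test_ttcct_is_not_ttccg(self):
        seq = "A" * 8 + "CCTTCCT" + "A" * 20
        g = Genome({"c": seq})
        assert not hs.annotate_ttccg(g, "c", 9, "+")[0]

    def test_flag_is_exactly_substring_predicate_at_boundary(self):
        """All 4^5 windows at the context edge: flag == substring test."""
        for w in map("".join, itertools.product("ACGT", repeat=5)):
            seq = w + "A" * 5 + "C" + "A" * 30
            g = Genome({"c": seq})
            flag, ctx = hs.annotate_ttccg(g, "c", 10, "+")
            assert ctx == seq[:21]
            assert flag == ("TTCCG" in seq[:21]) == (w == "TTCCG")

    def test_edge_context_padded_with_n(self):
        g = Genome({"c": "CCTTCCG" + "A" * 30})
        flag, ctx = hs.annotate_ttccg(g, "c", 1, "+")
        assert len(ctx) == 21 and ctx.startswith("N" * 9) and flag


class TestClassify:
    def _ctx(self, hept, mut_idx):
        """21-mer with heptamer placed so its ``mut_idx`` base is central."""
        left = "A" * (10 - mut_idx)
        right = "A" * (21 - len(left) - 7)
        return left + hept + right

    @pytest.mark.parametrize("hept,idx,expected", [
        ("CCTTCCG", 0, "CCTTCCG"), ("CCTTCCG", 1, "CCTTCCG"),
        ("TCTTCCG", 1, "TCTTCCG"), ("CTTTCCG", 0, "CTTTCCG"),
        ("ACTTCCG", 4, "TTCCG-internal"),
    ])
    def test_named_classes(self, hept, idx, expected):
        assert hs.classify_motif(self._ctx(hept, idx)) == expected

    def test_distant_motif_is_other(self):
        ctx = "TTCCG" + "A" * 5 + "C" + "A" * 10
        assert hs.classify_motif(ctx) == "other"

    def test_no_motif_is_precondition_error(self):
        with pytest.raises(ValueError):
            hs.classify_motif("A" * 21)


class TestUniqueLoci:
    def _site(self, pos, ctx, n=6, strand="+"):
        return hs.HotspotSite("chr1", pos, n, strand, ctx, True, -100, "g",
                              hs.classify_motif(ctx))

    def test_both_cc_cytosines_collapse_to_one_locus(self):
        a = self._site(100, self._ctx_for(0))
        b = self._site(101, self._ctx_for(1))
        loci = hs.unique_loci([a, b])
        assert len(loci) == 1
        assert loci[0].motif_class == "CCTTCCG" and len(loci[0].sites) == 2

    def _ctx_for(self, idx):
        left = "A" * (10 - idx)
        return left + "CCTTCCG" + "A" * (21 - len(left) - 7)

    def test_separate_motifs_stay_separate(self):
        a = self._site(100, self._ctx_for(0))
        b = self._site(1100, self._ctx_for(0))
        assert len(hs.unique_loci([a, b])) == 2

    def test_loci_match_planted_anchors(self, genome, tss_list, planted, cohort):
        """On the synthetic catalog, recovered loci coincide with planted
        TTCCG anchors and carry the planted class (brute-force grouping)."""
        cat = hs.build_catalog(cohort, genome, tss_list, min_n=5)
        hot = {}
        for p in planted:
            for h in p.hotspot_positions:
                hot[(p.chrom, h)] = p
        loci = hs.unique_loci([s for s in cat if (s.chrom, s.pos) in hot])
        planted_anchor = {
            (p.chrom, p.ttccg_anchor, p.motif_strand):
                "TTCCG-internal" if p.motif_class == "ACTTCCG" else p.motif_class
            for p in planted if p.motif_class}
        for l in loci:
            key = (l.chrom, l.anchor_pos, l.strand)
            assert key in planted_anchor
            assert l.motif_class == planted_anchor[key]


class TestFractionAndBurden:
    def _catalog(self):
        ctx_t = "A" * 8 + "CCTTCCG" + "A" * 6
        ctx_o = "A" * 21
        sites = []
        for i in range(4):
            sites.append(hs.HotspotSite("chr1", i * 50, 6, "+", ctx_t, True,
                                        -100, "g", "CCTTCCG"))
            sites.append(hs.HotspotSite("chr1", 5000 + i * 50, 6, "+", ctx_o,
                                        False, -100, "g", None))
        return sites

    def test_half_ttccg_fraction(self):
        df = hs.ttccg_fraction_by_recurrence(self._catalog(), thresholds=(5,))
        assert df.loc[0, "fraction"] == 0.5 and df.loc[0, "total"] == 8

    def test_exclusion_list_removes_known_drivers(self):
        df = hs.ttccg_fraction_by_recurrence(self._catalog(), thresholds=(5,),
                                             exclude={("chr1", 5000)})
        assert df.loc[0, "total"] == 7
        assert hs.ttccg_fraction_by_recurrence(
            self._catalog(), thresholds=(5,), exclude=set()).loc[0, "total"] == 8

    def test_promoter_window_restriction(self):
        sites = self._catalog()
        far = hs.HotspotSite("chr1", 9000, 6, "+", "A" * 21, False, 800, "g", None)
        df = hs.ttccg_fraction_by_recurrence(sites + [far], thresholds=(5,))
        assert df.loc[0, "total"] == 8

    def test_perfectly_monotone_cohort_has_rho_one(self):
        df = pd.DataFrame({"sample_id": list("abcde"),
                           "total_snvs": [10, 20, 30, 40, 50],
                           "hotspot_sites": [1, 2, 3, 4, 5]})
        rho, p = hs.burden_correlation(df)
        assert rho == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        df = pd.DataFrame({"sample_id": list("abc"), "total_snvs": [1, 2, 3],
                           "hotspot_sites": [2, 2, 2]})
        with pytest.raises(ValueError):
            hs.burden_correlation(df)

    def test_independent_axes_give_small_rho(self):
        """Monte-Carlo null: independent axes across 40 seeds stay below
        |rho| = 0.2 in at least 95% of draws (n = 200 tumors)."""
        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"sample_id": [str(i) for i in range(200)],
                               "total_snvs": rng.poisson(100, 200),
                               "hotspot_sites": rng.poisson(5, 200)})
            rho, _ = hs.burden_correlation(df)
            ok += abs(rho) < 0.2
        assert ok >= 38


class TestCatalogRecovery:
    def test_planted_hotspots_recovered_with_class(self, genome, tss_list, planted):
        """Strong enrichment: every planted hotspot whose expected
        recurrence is well above the catalog threshold appears, with the
        planted motif class."""
        spec = synth.CohortSpec(n_tumors=221, phi=1000.0, seed=12)
        muts = synth.gen_cohort(genome, planted, spec)
        cat = {(s.chrom, s.pos): s for s in
               hs.build_catalog(muts, genome, tss_list, min_n=5)}
        w, _, _, _ = synth._position_weights(genome, spec.signature)
        W = sum(a.sum() for a in w.values())
        mean_burden = spec.burden_median * np.exp(spec.burden_sigma ** 2 / 2)
        n_checked = 0
        for p in planted:
            for h in p.hotspot_positions:
                p_mut = min(1.0, (spec.phi - 1) * mean_burden * w[p.chrom][h] / W)
                if spec.n_tumors * p_mut < 12:
                    continue
                n_checked += 1
                site = cat.get((p.chrom, h))
                assert site is not None, f"missing planted hotspot {p.chrom}:{h}"
                assert site.ttccg_flag
                expected_class = ("TTCCG-internal" if p.motif_class == "ACTTCCG"
                                  else p.motif_class)
                assert site.motif_class == expected_class
        assert n_checked > 100

    def test_catalog_invariant_under_strand_mirror(self, genome, tss_list, planted):
        """Reverse-complementing the genome and mirroring all inputs yields
        an identical catalog (contexts, classes, recurrence, distances)."""
        spec = synth.CohortSpec(n_tumors=40, burden_median=100, phi=500.0, seed=13)
        muts = synth.gen_cohort(genome, planted, spec)
        cat = hs.build_catalog(muts, genome, tss_list, min_n=3)

        L = genome.length("chr1")
        g2 = Genome({"chr1": revcomp(genome["chr1"])})
        comp = dict(zip("ACGT", "TGCA"))
        muts2 = [MutationRecord(m.chrom, L - 1 - m.pos, comp[m.ref], comp[m.alt],
                                m.sample_id) for m in muts]
        tss2 = [TssRecord(t.gene_id, t.chrom, L - 1 - t.tss_pos,
                          "-" if t.strand == "+" else "+") for t in tss_list]
        cat2 = hs.build_catalog(muts2, g2, tss2, min_n=3)
        key = lambda s: (s.n, s.context_21, s.motif_class, s.tss_distance,
                         s.nearest_gene, s.ttccg_flag)
        assert sorted(map(key, cat)) == sorted(map(key, cat2))
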