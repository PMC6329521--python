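"""Meta-profiles: orientation, normalization, null models, recovery."""
import numpy as np
import pandas as pd
import pytest

from uvhotspot import cpd, profiles, synth
from uvhotspot.genome import Genome
from uvhotspot.hotspots import HotspotSite, MotifLocus
from uvhotspot.io import MutationRecord, TssRecord
from uvhotspot.profiles import Trinuc96Signature


def _site(pos, strand="+", chrom="c1"):
    return HotspotSite(chrom, pos, 5, strand, "A" * 21, False, 0, "g", None)


class TestProfileAtSites:
    def test_event_at_site_is_offset_zero(self):
        prof = profiles.profile_at_sites(
            [MutationRecord("c1", 100, "C", "T", "s")], [_site(100)], window=10)
        assert prof.counts[prof.offsets == 0] == [1] and prof.total == 1

    def test_minus_strand_site_flips_orientation(self):
        # 3 bp 5' of a minus-strand site = higher plus coordinate
        prof = profiles.profile_at_sites(
            [MutationRecord("c1", 103, "C", "T", "s")], [_site(100, "-")],
            window=10)
        assert prof.counts[prof.offsets == -3] == [1]

    def test_window_total_matches_bruteforce(self, cohort):
        muts = cohort[:2000]
        sites = [_site(m.pos, m.pyrimidine_strand, m.chrom) for m in muts[:40]]
        prof = profiles.profile_at_sites(muts, sites, window=250)
        brute = sum(1 for s in sites for m in muts
                    if m.chrom == s.chrom and abs(m.pos - s.pos) <= 250)
        assert prof.total == brute

    def test_divisor_is_site_count(self):
        prof = profiles.profile_at_sites(
            [MutationRecord("c1", 100, "C", "T", "s")],
            [_site(100), _site(500)], window=10)
        assert prof.n_anchors == 2
        assert prof.normalized()[prof.offsets == 0] == pytest.approx([0.5])


class TestMotifProfiles:
    def _loci(self):
        return [MotifLocus("c1", 100, "+", "CCTTCCG", 0, ()),
                MotifLocus("c1", 504, "-", "CCTTCCG", 0, ())]

    def test_flank_lesions_peak_bridging_minus2_minus1(self):
        # flank dimer 5' base: offset -2 on the motif strand, both strands
        # of planted loci (plus locus: pos5 = 98; minus locus anchors at
        # 508, flank covers plus 509-510, minus-strand 5' base = 510)
        evs = [cpd.CPDEvent("c1", 98, "+", "CC"), cpd.CPDEvent("c1", 510, "-", "CC")]
        prof = profiles.profile_by_motif_class(evs, self._loci(), "CCTTCCG",
                                               window=10, per_base_cpd=True)
        same = prof["motif_strand"]
        assert same.counts[same.offsets == -2] == [2]
        assert same.counts[same.offsets == -1] == [2]
        assert prof["opposite_strand"].total == 0

    def test_middle_tc_lesions_peak_inside_motif(self):
        # middle TC of TTCCG: offsets +1 (T) and +2 (C) from the motif start
        evs = [cpd.CPDEvent("c1", 101, "+", "TC"), cpd.CPDEvent("c1", 507, "-", "TC")]
        prof = profiles.profile_by_motif_class(evs, self._loci(), "CCTTCCG",
                                               window=10, per_base_cpd=True)
        same = prof["motif_strand"]
        assert same.counts[same.offsets == 1] == [2]
        assert same.counts[same.offsets == 2] == [2]

    def test_uniform_events_are_flat_across_strands(self, genome, planted,
                                                    truth_loci, tmp_path):
        spec = synth.CpdReadSpec(n_fragments=30_000,
                                 lesion_weights={d: 1.0 for d in
                                                 ("TT", "TC", "CT", "CC", "AG",
                                                  "GA", "AC", "GT")},
                                 motif_multiplier=1.0, background_rate=0.0,
                                 seed=31)
        synth.gen_cpd_reads(genome, planted, spec, tmp_path / "u.sam")
        events, _ = cpd.extract_events(tmp_path / "u.sam", genome)
        prof = profiles.profile_by_motif_class(events, truth_loci, "CCTTCCG",
                                               window=200)
        a, b = prof["motif_strand"], prof["opposite_strand"]
        tot = a.total + b.total
        assert abs(a.total - b.total) < 4 * np.sqrt(tot / 2)
        exp = a.total / len(a.counts)
        assert a.counts.max() < exp + 5 * np.sqrt(exp) + 3


class TestLibraryScale:
    def test_ratio_and_identity(self):
        p = profiles.DensityProfile(np.arange(3), np.ones(3), 1, 1)
        q = profiles.DensityProfile(np.arange(3), np.ones(3), 1, 1)
        _, s = profiles.library_scale(p, q, 200, 100)
        assert s.scale == pytest.approx(2.0)
        _, s1 = profiles.library_scale(p, q, 150, 150)
        assert s1.scale == pytest.approx(1.0)

    def test_zero_total_is_error(self):
        p = profiles.DensityProfile(np.arange(3), np.ones(3), 1, 1)
        with pytest.raises(ValueError):
            profiles.library_scale(p, p, 0, 10)


class TestTssProfile:
    def test_upstream_mutation_bins_correctly(self):
        tss = [TssRecord("g", "c1", 1000, "+")]
        prof = profiles.tss_binned_profile(
            [MutationRecord("c1", 970, "C", "T", "s")], tss, window=1000,
            bin_width=20)
        assert prof.counts[prof.offsets == -40] == [1]

    def test_minus_strand_gene_same_bin(self):
        tss = [TssRecord("g", "c1", 1000, "-")]
        prof = profiles.tss_binned_profile(
            [MutationRecord("c1", 1030, "C", "T", "s")], tss, window=1000,
            bin_width=20)
        assert prof.counts[prof.offsets == -40] == [1]

    def test_bad_bin_width_is_error(self):
        with pytest.raises(ValueError):
            profiles.tss_binned_profile([], [TssRecord("g", "c1", 0, "+")],
                                        window=1000, bin_width=30)

    def test_delta_ttccg_removes_motif_context_mutations(self):
        seq = "A" * 990 + "CCTTCCG" + "A" * 1003
        g = Genome({"c1": seq})
        tss = [TssRecord("g", "c1", 1200, "+")]
        muts = [MutationRecord("c1", 991, "C", "T", "s"),     # TTCCG context
                MutationRecord("c1", 600, "A", "C", "s")]     # plain context
        full = profiles.tss_binned_profile(muts, tss, window=1000, bin_width=20)
        delta = profiles.tss_binned_profile(muts, tss, window=1000, bin_width=20,
                                            genome=g, exclude_ttccg=True)
        assert full.total == 2 and delta.total == 1


class TestSignature:
    def test_single_mutation_single_class(self):
        g = Genome({"c1": "ATCAG"})
        sig = profiles.signature_from_cohort(
            [MutationRecord("c1", 2, "C", "T", "s")], g)
        assert sig.probs[Trinuc96Signature.key("T", "C", "T", "A")] == 1.0

    def test_known_signature_recovered(self, genome, planted):
        """phi = 1 cohort of ~1e5 draws recovers the generating signature
        within L1 distance 0.05 (multinomial oracle)."""
        spec = synth.CohortSpec(n_tumors=100, burden_median=1000,
                                burden_sigma=0.0, phi=1.0, seed=9)
        muts = synth.gen_cohort(genome, planted, spec)
        sig = profiles.signature_from_cohort(muts, genome)
        assert spec.signature.l1(sig) < 0.05

    def test_all_n_context_is_error(self):
        g = Genome({"c1": "NCNN"})
        with pytest.raises(ValueError):
            profiles.signature_from_cohort(
                [MutationRecord("c1", 1, "C", "T", "s")], g)


class TestExpectedProfiles:
    def test_zero_observed_is_zero_profile(self):
        sig = synth.uv_signature()
        prof = profiles.expected_mutation_profile(["ACGT" * 10], sig, 0, seed=1,
                                                  window=20, bin_width=10)
        assert prof.total == 0

    def test_placement_conserves_count_every_seed(self):
        sig = synth.uv_signature()
        for seed in (1, 2, 3):
            prof = profiles.expected_mutation_profile(
                ["TTCCTTCC" * 10], sig, 57, seed=seed, window=40, bin_width=20,
                replicates=11)
            assert np.allclose(prof.extra["replicate_totals"], 57)

    def test_uniform_weight_sequence_gives_uniform_bins(self):
        # every position the same context weight -> multinomial-uniform bins
        prof = profiles.expected_cpd_profile(["TT" * 500], 20_000, seed=4,
                                             window=500, bin_width=100,
                                             replicates=50)
        exp = prof.total / len(prof.counts)
        assert np.all(np.abs(prof.counts - exp) < 4 * np.sqrt(exp / 50) + 2)

    def test_no_dipyrimidine_mass_is_error(self):
        with pytest.raises(ValueError):
            profiles.expected_cpd_profile(["AC" * 20], 10, seed=1, window=20,
                                          bin_width=10)

    def test_observed_over_expected_near_one_for_uniform_library(
            self, genome, planted, tss_list, tmp_path):
        """Uniform dipyrimidine lesion weights: the observed TSS-binned CPD
        profile matches the dinucleotide-based expectation bin by bin."""
        spec = synth.CpdReadSpec(
            n_fragments=60_000,
            lesion_weights={d: 1.0 for d in ("TT", "TC", "CT", "CC")},
            motif_multiplier=1.0, background_rate=0.0, seed=33)
        synth.gen_cpd_reads(genome, planted, spec, tmp_path / "u.sam")
        events, _ = cpd.extract_events(tmp_path / "u.sam", genome)
        retained, _, _ = cpd.filter_dipyrimidine(events)
        obs = profiles.tss_binned_profile(retained, tss_list, window=1000,
                                          bin_width=20)
        seqs = [genome.fetch_padded(t.chrom, t.tss_pos - 1000, t.tss_pos + 1000,
                                    strand=t.strand) for t in tss_list]
        exp = profiles.expected_cpd_profile(seqs, int(obs.total), seed=34,
                                            window=1000, bin_width=20,
                                            replicates=30)
        ratio = obs.counts[exp.counts > 20] / exp.counts[exp.counts > 20]
        assert abs(ratio.mean() - 1) < 0.02
        se = 1 / np.sqrt(exp.counts[exp.counts > 20])
        assert np.all(np.abs(ratio - 1) < 5 * se + 0.05)


class TestRecurrenceStratification:
    def test_cpd_peak_monotone_in_motif_multiplier(self, genome, planted,
                                                   truth_loci, tmp_path):
        """Stronger lesion enrichment yields a stronger profile peak."""
        peaks = []
        for mult, seed in ((1.0, 41), (5.0, 42), (15.0, 43)):
            spec = synth.CpdReadSpec(n_fragments=40_000, motif_multiplier=mult,
                                     background_rate=0.0, seed=seed)
            synth.gen_cpd_reads(genome, planted, spec, tmp_path / f"m{seed}.sam")
            events, _ = cpd.extract_events(tmp_path / f"m{seed}.sam", genome)
            prof = profiles.profile_by_motif_class(events, truth_loci,
                                                   "CCTTCCG", window=20)
            same = prof["motif_strand"]
            peak = same.counts[same.offsets == -2][0] / max(same.total, 1)
            peaks.append(peak)
        assert peaks[0] < peaks[1] < peaks[2]
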