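"""Allele counting: pileup vs naive recount, quality gates, flank background."""

import numpy as np
import pytest

from mippseq.design import PanelDesign, TargetVariant
from mippseq.quantify import (
    AlleleCountTable,
    NotCoveredError,
    background_stats,
    flanking_error,
    pileup_counts,
    variant_aaf,
)
from mippseq.readproc import process_reads
from mippseq.simulate import ErrorModel, simulate_amplicon_reads, simulate_counts


def _aligned(panel, target, amp, n_alt, n_ref, depth, em, seed):
    reads = simulate_amplicon_reads(amp, target, n_alt, n_ref, depth, em,
                                    np.random.default_rng(seed))
    sub = PanelDesign(amplicons=[amp], target=target)
    aligned, _ = process_reads(reads, sub)
    return aligned[amp.id]


def _naive_recount(alns, amp, min_base_q=20, min_map_q=20):
    """Brute-force per-position tally straight from the alignment records."""
    ins_lo = amp.insert_start - amp.start
    ins_hi = amp.insert_end - amp.start
    L = ins_hi - ins_lo
    counts = {b: np.zeros(L, int) for b in "ACGT"}
    dels = np.zeros(L, int)
    for a in alns:
        if a.mapq < min_map_q:
            continue
        lo, hi = a.clip_bounds
        ref_pos, read_pos = a.aln_start, 0
        for op, ln in a.ops:
            if op in ("M", "X"):
                for k in range(ln):
                    rp = ref_pos + k
                    if max(lo, ins_lo) <= rp < min(hi, ins_hi):
                        if a.read.qualities[read_pos + k] >= min_base_q:
                            counts[a.read.bases[read_pos + k]][rp - ins_lo] += 1
                ref_pos += ln
                read_pos += ln
            elif op == "D":
                if ref_pos >= max(lo, ins_lo) and ref_pos + ln <= min(hi, ins_hi):
                    dels[ref_pos - ins_lo : ref_pos - ins_lo + ln] += 1
                ref_pos += ln
            else:
                read_pos += ln
    return counts, dels


class TestPileup:
    def test_equals_naive_recount(self, panel, target):
        amp = panel.amplicons[0]
        alns = _aligned(panel, target, amp, 100, 200, 300, ErrorModel(), 5)
        table = pileup_counts(alns, amp)
        counts, dels = _naive_recount(alns, amp)
        for i, b in enumerate("ACGT"):
            assert np.array_equal(table.acgt[i], counts[b])
        assert np.array_equal(table.dels, dels)

    def test_conservation_counts_sum_to_depth(self, panel, target):
        amp = panel.amplicons[1]
        alns = _aligned(panel, target, amp, 50, 50, 150, ErrorModel(), 6)
        table = pileup_counts(alns, amp)
        assert np.array_equal(table.acgt.sum(axis=0) + table.dels, table.depth)

    def test_base_quality_gate(self, panel, target, error_free):
        amp = panel.amplicons[0]
        alns = _aligned(panel, target, amp, 0, 50, 60,
                        ErrorModel(sub_rate=0, polymerase_rate=0, indel_rate=0,
                                   quality_mean=30, quality_sd=0), 7)
        # force one read's insert bases to quality 19: all excluded
        t_full = pileup_counts(alns, amp)
        alns[0].read.qualities[:] = 19
        t_gated = pileup_counts(alns, amp)
        assert t_gated.depth.sum() == t_full.depth.sum() - len(t_full)

    def test_mapq_gate_excludes_whole_read(self, panel, target, error_free):
        amp = panel.amplicons[0]
        alns = _aligned(panel, target, amp, 0, 30, 40, error_free, 8)
        for a in alns:  # flat qualities so each read contributes all positions
            a.read.qualities[:] = 30
        before = pileup_counts(alns, amp).depth.sum()
        alns[0].mapq = 19
        after = pileup_counts(alns, amp).depth.sum()
        assert after == before - len(pileup_counts(alns, amp))


class TestVariantAaf:
    def test_simple_arithmetic(self, panel, target):
        amp = panel.amplicons[0]
        table = AlleleCountTable(amp.id, amp.insert_seq, amp.insert_start)
        off = target.span[0] - amp.insert_start
        ref_idx = "ACGT".index(target.ref)
        alt_idx = "ACGT".index(target.alt)
        table.acgt[ref_idx, off] = 9995
        table.acgt[alt_idx, off] = 5
        aaf, depth = variant_aaf(table, target)
        assert aaf == pytest.approx(5e-4)
        assert depth == 10_000

    def test_zero_alt_is_zero(self, panel, target):
        amp = panel.amplicons[0]
        table = AlleleCountTable(amp.id, amp.insert_seq, amp.insert_start)
        table.acgt["ACGT".index(target.ref), target.span[0] - amp.insert_start] = 100
        assert variant_aaf(table, target)[0] == 0.0

    def test_target_outside_insert_raises(self, panel):
        amp = panel.amplicons[0]
        table = AlleleCountTable(amp.id, amp.insert_seq, amp.insert_start)
        outside = TargetVariant("locus", amp.insert_start, "A", "G")  # pos0 = start-1
        with pytest.raises(NotCoveredError):
            variant_aaf(table, outside)

    def test_heterozygote_near_half_in_all_amplicons(self, panel, target, rng):
        for amp in panel:
            t = simulate_counts(amp, target, 4000, 4000, 10_000, ErrorModel(), rng)
            aaf, depth = variant_aaf(t, target)
            assert aaf == pytest.approx(0.5, abs=0.02)

    def test_deletion_and_insertion_aaf(self, locus, panel):
        amp = panel.amplicons[0]
        pos = amp.insert_start + 40  # 0-based anchor inside the insert
        ref2 = locus[pos : pos + 3]
        deletion = TargetVariant("locus", pos + 1, ref2, ref2[0])
        insertion = TargetVariant("locus", pos + 1, ref2[0], ref2[0] + "TTA")
        t = simulate_counts(amp, deletion, 300, 700, 10_000, ErrorModel(),
                            np.random.default_rng(3))
        aaf, _ = variant_aaf(t, deletion)
        assert aaf == pytest.approx(0.3, abs=0.03)
        t = simulate_counts(amp, insertion, 300, 700, 10_000, ErrorModel(),
                            np.random.default_rng(4))
        aaf, _ = variant_aaf(t, insertion)
        assert aaf == pytest.approx(0.3, abs=0.03)


class TestFlankingError:
    def test_error_free_flanks_all_zero(self, panel, target, error_free, rng):
        amp = panel.amplicons[0]
        t = simulate_counts(amp, target, 100, 900, 5000, error_free, rng)
        obs = flanking_error(t, target)
        assert all(o.nonref_fraction == 0.0 for o in obs if not o.excluded)
        mean, sd, n = background_stats(obs)
        assert mean == 0.0 and n > 0

    def test_flank_mean_estimates_substitution_rate(self, panel, target):
        em = ErrorModel(indel_rate=0.0)
        amp = panel.amplicons[0]
        t = simulate_counts(amp, target, 0, 1000, 100_000, em,
                            np.random.default_rng(9))
        obs = flanking_error(t, target)
        mean, sd, n = background_stats(obs)
        se = np.sqrt(em.total_sub_rate / (n * 100_000))
        assert mean == pytest.approx(em.total_sub_rate, abs=4 * se)

    def test_target_position_never_in_background(self, panel, target, rng):
        amp = panel.amplicons[0]
        t = simulate_counts(amp, target, 5000, 5000, 10_000, ErrorModel(), rng)
        obs = flanking_error(t, target)
        t_off = target.span[0] - amp.insert_start
        assert all(o.offset != t_off for o in obs)
        # a 50% allele nearby must not leak into the background
        mean, _, _ = background_stats(obs)
        assert mean < 1e-3

    def test_germline_site_excluded_and_background_unchanged(self, panel, target):
        """A het SNP at a flank position is flagged excluded, so background
        matches a run without the SNP."""
        amp = panel.amplicons[0]
        g_pos0 = target.span[0] + 15  # genomic 0-based, inside flank
        g_base = amp.insert_seq[g_pos0 - amp.insert_start]
        germ = TargetVariant("locus", g_pos0 + 1, g_base,
                             "A" if g_base != "A" else "G")
        em = ErrorModel()
        t_clean = simulate_counts(amp, target, 0, 1000, 50_000, em,
                                  np.random.default_rng(11))
        t_germ = simulate_counts(amp, germ, 500, 500, 50_000, em,
                                 np.random.default_rng(11))
        obs_clean = background_stats(flanking_error(t_clean, target))
        obs_germ = background_stats(
            flanking_error(t_germ, target, germline_sites={g_pos0})
        )
        flagged = [o for o in flanking_error(t_germ, target, germline_sites={g_pos0})
                   if o.excluded and o.reason == "germline"]
        assert len(flagged) == 1
        assert obs_germ[0] == pytest.approx(obs_clean[0], abs=5e-5)

    def test_flank_truncated_at_insert_edge(self, panel, target):
        amp = panel.amplicons[0]
        t = AlleleCountTable(amp.id, amp.insert_seq, amp.insert_start)
        obs = flanking_error(t, target, flank=5000)
        assert len(obs) == len(amp.insert_seq) - 1  # everything but the target
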