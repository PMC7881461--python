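"""Read processing: demux rules, trimming, alignment oracle, clipping, UMIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mippseq.design import PanelDesign
from mippseq.readproc import (
    AlignedRead,
    ReadRecord,
    _quality_trim_point,
    align_full_dp,
    align_to_amplicon,
    clip_primers,
    demultiplex,
    trim_reads,
    umi_collapse,
)
from mippseq.dna import random_reference
from mippseq.simulate import simulate_amplicon_reads


def _read(bases: str, q: int = 30, rid: str = "r", amp=None) -> ReadRecord:
    return ReadRecord(id=rid, bases=bases, qualities=np.full(len(bases), q),
                      assigned_amplicon=amp)


def _mutate_prefix(bases: str, n: int) -> str:
    out = list(bases)
    for i in range(n):
        out[i] = "A" if out[i] != "A" else "C"
    return "".join(out)


class TestDemultiplex:
    def _probe(self, amp, n_mm=0):
        prefix = amp.barcode + "T" * amp.umi_scheme + amp.forward.seq
        body = prefix + "ACGT" * 30
        if n_mm:
            body = _mutate_prefix(body, n_mm)
        return _read(body)

    def test_exact_prefix_assigned(self, panel):
        amp = panel.amplicons[0]
        assigned, un = demultiplex([self._probe(amp)], panel)
        assert len(assigned[amp.id]) == 1 and not un

    def test_three_mismatches_assigned_four_not(self, panel):
        amp = panel.amplicons[1]
        assigned, un = demultiplex([self._probe(amp, 3)], panel)
        assert len(assigned[amp.id]) == 1
        assigned, un = demultiplex([self._probe(amp, 4)], panel)
        assert len(un) == 1

    def test_equidistant_read_unassigned(self, panel):
        a, b = panel.amplicons[0], panel.amplicons[1]
        # craft a prefix equidistant from both amplicons' expected 15-mers:
        # take a's expected prefix and move it 2 mismatches toward b in
        # positions where they differ (barcodes differ by >= 4)
        diff = [i for i in range(10) if a.barcode[i] != b.barcode[i]]
        bc = list(a.barcode)
        d_ab = len(diff) + sum(
            x != y for x, y in zip(a.forward.seq[:5], b.forward.seq[:5])
        )
        k = d_ab // 2 + (d_ab % 2)
        for i in diff[:k]:
            bc[i] = b.barcode[i]
        probe = "".join(bc) + "T" * a.umi_scheme + a.forward.seq
        d_a = sum(x != y for x, y in zip(probe[:10] + probe[10 + a.umi_scheme:][:5],
                                          a.barcode + a.forward.seq[:5]))
        d_b = sum(x != y for x, y in zip(probe[:10] + probe[10 + b.umi_scheme:][:5],
                                          b.barcode + b.forward.seq[:5]))
        reads = [_read(probe + "ACGT" * 30)]
        assigned, un = demultiplex(reads, panel)
        if d_a == d_b:  # equidistant -> tie rule
            assert len(un) == 1
        else:  # closer to one: assigned iff within 3 mismatches
            expect = a.id if d_a < d_b else b.id
            if min(d_a, d_b) <= 3:
                assert len(assigned[expect]) == 1

    def test_partition_property(self, panel, target, error_free, rng):
        reads = []
        for amp in panel:
            reads += simulate_amplicon_reads(amp, target, 20, 20, 30, error_free, rng)
        assigned, un = demultiplex(reads, panel)
        assert sum(len(v) for v in assigned.values()) + len(un) == len(reads)
        # error-free reads all assign to their true amplicon
        assert not un
        for amp in panel:
            assert all(r.id.startswith(amp.id) for r in assigned[amp.id])


class TestTrim:
    def test_head_trim_removes_barcode_and_umi(self, panel):
        amp = panel.amplicons[0]
        body = "ACGT" * 25
        read = _read(amp.barcode + "GGTTT" * 2 + body, amp=amp.id)
        trimmed, n = trim_reads([read], panel)
        assert n == 0
        assert trimmed[0].bases == body
        assert trimmed[0].umi == "GGTTTGGTTT"[: amp.umi_scheme]

    def test_low_quality_suffix_removed(self):
        quals = np.array([30] * 7 + [9, 9, 9])
        read = ReadRecord(id="r", bases="ACGTACGTAC", qualities=quals)
        trimmed, _ = trim_reads([read], None, head_trim=0, quality_cutoff=10)
        assert trimmed[0].bases == "ACGTACG"

    def test_too_short_read_discarded(self, panel):
        read = _read("ACGTACGT", amp=panel.amplicons[0].id)
        trimmed, n = trim_reads([read], panel, head_trim=10)
        assert trimmed == [] and n == 1

    @given(st.lists(st.integers(2, 41), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_quality_trim_matches_brute_force(self, quals):
        """The running-sum cut equals exhaustive maximisation of
        sum(cutoff - q) over all suffixes."""
        arr = np.array(quals)
        cutoff = 10
        best_cut, best_val = len(arr), 0
        for cut in range(len(arr) - 1, -1, -1):
            val = np.sum(cutoff - arr[cut:])
            if val > best_val:
                best_val, best_cut = val, cut
        assert _quality_trim_point(arr, cutoff) == best_cut


class TestAlign:
    def test_error_free_read_full_match_at_origin(self, panel):
        amp = panel.amplicons[0]
        read = _read(amp.amplicon_ref)
        aln = align_to_amplicon(read, amp.amplicon_ref)
        assert aln.aln_start == 0
        assert aln.ops == [("M", len(amp.amplicon_ref))]

    def test_read_from_other_amplicon_unaligned(self, panel):
        a, b = panel.amplicons[0], panel.amplicons[1]
        # use the other amplicon's primer-distal half to avoid any overlap
        read = _read(b.amplicon_ref)
        assert align_to_amplicon(read, a.amplicon_ref) is None

    def test_score_matches_unbanded_oracle(self, rng):
        ref = random_reference(240, 17)
        for trial in range(12):
            r = list(ref)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, len(r)))
                r[i] = "A" if r[i] != "A" else "G"
            if trial % 2:
                i = int(rng.integers(10, len(r) - 10))
                del r[i : i + int(rng.integers(1, 3))]
            bases = "".join(r)
            aln = align_to_amplicon(_read(bases), ref)
            assert aln is not None
            assert aln.score == align_full_dp(bases, ref)

    def test_homopolymer_deletion_left_aligned(self):
        ref = "ACGT" + "A" * 6 + random_reference(80, 2)
        read = ref[:7] + ref[9:]  # drop 2 bases from inside the A-run
        aln = align_to_amplicon(_read(read), ref)
        dels = []
        pos = aln.aln_start
        for op, ln in aln.ops:
            if op == "D":
                dels.append((pos, ln))
            if op in ("M", "X", "D"):
                pos += ln
        assert dels == [(4, 2)]  # leftmost equivalent placement


class TestClip:
    def test_full_length_read_clipped_to_insert(self, panel):
        amp = panel.amplicons[0]
        aln = align_to_amplicon(_read(amp.amplicon_ref), amp.amplicon_ref, amplicon_id=amp.id)
        aln = clip_primers(aln, amp)
        lo, hi = aln.clip_bounds
        assert lo == amp.insert_start - amp.start
        assert hi == amp.insert_end - amp.start

    def test_read_inside_primer_discarded(self, panel):
        amp = panel.amplicons[0]
        frag = amp.forward.seq
        aln = AlignedRead(
            amplicon_id=amp.id,
            read=_read(frag),
            aln_start=0,
            ops=[("M", len(frag))],
            score=len(frag),
            mapq=60,
        )
        assert clip_primers(aln, amp) is None


class TestUmiCollapse:
    def _family(self, amp, umi, variants):
        """Aligned reads over the same amplicon sharing a UMI; ``variants``
        is a list of (offset, base) substitutions per read."""
        out = []
        for k, subs in enumerate(variants):
            bases = list(amp.amplicon_ref)
            for off, b in subs:
                bases[off] = b
            read = ReadRecord(
                id=f"fam{k}", bases="".join(bases),
                qualities=np.full(len(bases), 30),
                assigned_amplicon=amp.id, umi=umi,
            )
            out.append(align_to_amplicon(read, amp.amplicon_ref, amplicon_id=amp.id))
        return out

    def test_majority_base_wins(self, panel):
        amp = panel.amplicons[0]
        alt = "A" if amp.amplicon_ref[100] != "A" else "C"
        fam = self._family(amp, "AAAAA", [[(100, alt)], [(100, alt)], []])
        cons = umi_collapse(fam)
        assert len(cons) == 1
        assert cons[0].read.bases[100] == alt

    def test_discordant_position_masked(self, panel):
        amp = panel.amplicons[0]
        alt = "A" if amp.amplicon_ref[100] != "A" else "C"
        fam = self._family(amp, "CCCCC", [[(100, alt)], []])
        cons = umi_collapse(fam)
        assert cons[0].read.bases[100] == "N"
        assert cons[0].read.qualities[100] == 0  # fails any quality gate

    def test_distinct_umis_never_merged(self, panel):
        amp = panel.amplicons[0]
        fam1 = self._family(amp, "AAAAA", [[], []])
        fam2 = self._family(amp, "GGGGG", [[], []])
        cons = umi_collapse(fam1 + fam2)
        assert len(cons) == 2  # one consensus per family, never more

    def test_min_family_size_filters_singletons(self, panel):
        amp = panel.amplicons[0]
        fam = self._family(amp, "AAAAA", [[]])
        assert umi_collapse(fam, min_family=2) == []
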