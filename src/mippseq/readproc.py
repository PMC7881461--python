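"""Read processing: demultiplex, trim, align, primer-clip, UMI-collapse.

Because every read's amplicon of origin is fixed by its barcode, reads
are aligned *globally* to their known ~225-300 bp amplicon reference
with a banded affine-gap aligner rather than mapped genome-wide; this is
both simpler and stricter than read mapping, and deterministic
left-shifting of gaps substitutes for a separate indel-realignment step.

Demultiplexing follows the barcoded-amplicon convention: the first 15
informative nucleotides (10 nt barcode + first 5 nt of the forward
primer) are matched against every amplicon's expected prefix with up to
3 mismatches; ties are left unassigned rather than resolved by order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .design import AmpliconSet, PanelDesign

MATCH = 1
MISMATCH = -4
GAP_OPEN = -6  # first gap base
GAP_EXTEND = -1
BAND = 30
MIN_SCORE_FRACTION = 0.5
MAPQ_CAP = 60

NEG = -(10**9)


@dataclass
class ReadRecord:
    id: str
    bases: str
    qualities: np.ndarray  # Phred ints, len == len(bases)
    assigned_amplicon: str | None = None
    umi: str | None = None

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")


def as_read_record(obj) -> ReadRecord:
    """Coerce any (id, bases, qualities) object into a ReadRecord."""
    if isinstance(obj, ReadRecord):
        return obj
    return ReadRecord(id=obj.id, bases=obj.bases, qualities=obj.qualities)


@dataclass
class AlignedRead:
    amplicon_id: str
    read: ReadRecord
    aln_start: int  # 0-based offset on the amplicon reference
    ops: list[tuple[str, int]]  # runs of M (match), X (mismatch), I, D
    score: int
    mapq: int
    clip_bounds: tuple[int, int] | None = None  # unclipped ref interval
    clipped: bool = False

    @property
    def aln_end(self) -> int:
        return self.aln_start + sum(
            ln for op, ln in self.ops if op in ("M", "X", "D")
        )


# ---------------------------------------------------------------------------
# demultiplexing


def _expected_prefix(amp: AmpliconSet) -> tuple[str, str]:
    """(barcode, 5 nt of forward primer) that begin every read of ``amp``.
    A UMI of ``umi_scheme`` degenerate bases sits between them."""
    return amp.barcode, amp.forward.seq[:5]


def demultiplex(
    reads, panel: PanelDesign, max_mismatch: int = 3
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to amplicons by their 15 informative leading nt.

    A read goes to the amplicon with the (unique) smallest Hamming
    distance <= ``max_mismatch`` between the read's leading barcode+primer
    nucleotides and the amplicon's expected ones; equidistant best
    matches are unassigned (order-independent tie rule).
    """
    amps = panel.amplicons
    if any(not a.barcode for a in amps):
        raise ValueError("panel must be tagged before demultiplexing")
    assigned: dict[str, list[ReadRecord]] = {a.id: [] for a in amps}
    unassigned: list[ReadRecord] = []
    for obj in reads:
        read = as_read_record(obj)
        best, best_d, tie = None, max_mismatch + 1, False
        for a in amps:
            bc, p5 = _expected_prefix(a)
            u = a.umi_scheme
            probe = read.bases[: len(bc)] + read.bases[len(bc) + u : len(bc) + u + 5]
            expect = bc + p5
            if len(probe) < len(expect):
                continue
            d = sum(x != y for x, y in zip(probe, expect))
            if d < best_d:
                best, best_d, tie = a, d, False
            elif d == best_d:
                tie = True
        if best is None or tie or best_d > max_mismatch:
            unassigned.append(read)
        else:
            read.assigned_amplicon = best.id
            assigned[best.id].append(read)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# trimming


def _quality_trim_point(quals: np.ndarray, cutoff: int) -> int:
    """3' trim position by the running-sum rule (as in cutadapt/BWA):
    remove the suffix over which the sum of (cutoff - q) is maximal."""
    best_sum, run, cut = 0, 0, len(quals)
    for i in range(len(quals) - 1, -1, -1):
        run += cutoff - int(quals[i])
        if run > best_sum:
            best_sum, cut = run, i
    return cut


def trim_reads(
    reads: list[ReadRecord],
    panel: PanelDesign | None = None,
    head_trim: int = 10,
    quality_cutoff: int = 10,
) -> tuple[list[ReadRecord], int]:
    """Remove the barcode head and low-quality 3' tail of each read.

    The first ``head_trim`` bases (the barcode) are removed; when the
    read's amplicon has an active UMI scheme the following UMI bases are
    captured into ``read.umi`` and removed as well. Reads shorter than
    the head are discarded and counted. Returns (kept_reads, n_discarded).
    """
    umi_by_amp = {a.id: a.umi_scheme for a in panel.amplicons} if panel else {}
    out: list[ReadRecord] = []
    discarded = 0
    for read in reads:
        u = umi_by_amp.get(read.assigned_amplicon, 0)
        head = head_trim + u
        if len(read.bases) <= head:
            discarded += 1
            continue
        umi = read.bases[head_trim:head] if u else None
        bases = read.bases[head:]
        quals = read.qualities[head:]
        cut = _quality_trim_point(quals, quality_cutoff)
        if cut == 0:
            discarded += 1
            continue
        out.append(
            ReadRecord(
                id=read.id,
                bases=bases[:cut],
                qualities=quals[:cut],
                assigned_amplicon=read.assigned_amplicon,
                umi=umi,
            )
        )
    return out, discarded


# ---------------------------------------------------------------------------
# banded global alignment


def align_to_amplicon(
    read: ReadRecord,
    amplicon_ref: str,
    band: int = BAND,
    amplicon_id: str = "",
) -> AlignedRead | None:
    """Banded global alignment of the full read against the amplicon.

    Affine gaps (open -6 including the first base, extend -1), match +1,
    mismatch -4; reference end gaps are free, so the read may align to
    any contiguous stretch of the amplicon. Alignments scoring below
    half the read length are rejected (returns None). Indels are then
    shifted to their leftmost equivalent position.
    """
    m, n = len(read.bases), len(amplicon_ref)
    if m == 0 or n == 0:
        return None
    r = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    q = np.frombuffer(amplicon_ref.encode(), dtype=np.uint8)

    # rows: read positions 0..m; column j at row i maps to reference
    # position i - 1 + (j - band): the band tracks the main diagonal
    width = 2 * band + 1
    cols = np.arange(width)
    M = np.full((m + 1, width), NEG, dtype=np.int64)  # match/mismatch state
    X = np.full((m + 1, width), NEG, dtype=np.int64)  # gap in read (deletion)
    Y = np.full((m + 1, width), NEG, dtype=np.int64)  # gap in ref (insertion)
    M[0, :] = 0  # free leading reference gap: any start column costs nothing

    ext_idx = cols * GAP_EXTEND
    for i in range(1, m + 1):
        ref_off = i - 1 + cols - band
        valid = (ref_off >= 0) & (ref_off < n)
        sub = np.where(r[i - 1] == q[np.clip(ref_off, 0, n - 1)], MATCH, MISMATCH)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i] = np.where(valid, prev_best + sub, NEG)
        # deletion run ending at column j starting after M[i, k] (k < j)
        # costs GAP_OPEN + (j-k-1)*GAP_EXTEND; a prefix max handles all runs
        run = np.maximum.accumulate(M[i] - ext_idx)
        X[i, 1:] = run[:-1] + ext_idx[1:] + (GAP_OPEN - GAP_EXTEND)
        X[i] = np.where(valid, X[i], NEG)
        # insertion: consume read base, reference stays -> from (i-1, j+1)
        Y[i, :-1] = np.maximum(M[i - 1, 1:] + GAP_OPEN, Y[i - 1, 1:] + GAP_EXTEND)
        Y[i] = np.where(valid, Y[i], NEG)

    # best end state over last row (free trailing reference gap)
    final = np.maximum(np.maximum(M[m], X[m]), Y[m])
    jbest = int(np.argmax(final))
    score = int(final[jbest])
    if score < MIN_SCORE_FRACTION * m:
        return None

    # traceback with on-the-fly decisions (prefer M on ties)
    state = int(np.argmax([M[m, jbest], X[m, jbest], Y[m, jbest]]))
    i, j = m, jbest
    ops_rev: list[str] = []
    while i > 0:
        ref_pos = i - 1 + (j - band)
        if state == 0:  # M: diagonal; j unchanged because columns track i
            ops_rev.append("M" if r[i - 1] == q[ref_pos] else "X")
            state = int(np.argmax([M[i - 1, j], X[i - 1, j], Y[i - 1, j]]))
            i -= 1
        elif state == 1:  # deletion: consume ref
            ops_rev.append("D")
            opened = X[i, j] == M[i, j - 1] + GAP_OPEN
            j -= 1
            state = 0 if opened else 1
        else:  # insertion: consume read
            ops_rev.append("I")
            opened = Y[i, j] == M[i - 1, j + 1] + GAP_OPEN
            i -= 1
            j += 1
            state = 0 if opened else 2
    aln_start = j - band
    if aln_start < 0:
        return None
    ops = _compress_ops(ops_rev[::-1])
    ops, aln_start = _left_align_indels(ops, aln_start, read.bases, amplicon_ref)
    mapq = int(np.clip(round(score / max(1, m) * MAPQ_CAP), 0, MAPQ_CAP))
    return AlignedRead(
        amplicon_id=amplicon_id,
        read=read,
        aln_start=aln_start,
        ops=ops,
        score=score,
        mapq=mapq,
    )


def _compress_ops(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _left_align_indels(
    ops: list[tuple[str, int]], aln_start: int, read: str, ref: str
) -> tuple[list[tuple[str, int]], int]:
    """Shift each indel to its leftmost equivalent position (deterministic
    substitute for a separate realignment step; resolves homopolymers)."""
    # expand to per-base ops for simple manipulation
    flat: list[str] = []
    for op, ln in ops:
        flat.extend([op] * ln)
    changed = True
    while changed:
        changed = False
        ref_pos = aln_start
        read_pos = 0
        for k, op in enumerate(flat):
            if op in ("M", "X"):
                ref_pos += 1
                read_pos += 1
            elif op == "D":
                # deletion of ref[ref_pos]; can shift left past an M if the
                # deleted base equals the base entering from the left
                kk, rp = k, ref_pos
                while (
                    kk > 0
                    and flat[kk - 1] == "M"
                    and ref[rp] == ref[rp - 1]
                ):
                    flat[kk - 1], flat[kk] = flat[kk], flat[kk - 1]
                    kk -= 1
                    rp -= 1
                    changed = True
                ref_pos += 1
            else:  # I
                kk, rdp = k, read_pos
                while (
                    kk > 0
                    and flat[kk - 1] == "M"
                    and read[rdp] == read[rdp - 1]
                ):
                    flat[kk - 1], flat[kk] = flat[kk], flat[kk - 1]
                    kk -= 1
                    rdp -= 1
                    changed = True
                read_pos += 1
            if changed:
                break
    # re-label M/X after shuffling
    ref_pos = aln_start
    read_pos = 0
    for k, op in enumerate(flat):
        if op in ("M", "X"):
            flat[k] = "M" if read[read_pos] == ref[ref_pos] else "X"
            ref_pos += 1
            read_pos += 1
        elif op == "D":
            ref_pos += 1
        else:
            read_pos += 1
    return _compress_ops(flat), aln_start


def align_full_dp(read: str, ref: str) -> int:
    """Unbanded affine-gap global-in-read alignment score (oracle use)."""
    m, n = len(read), len(ref)
    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    M[0, :] = 0
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            if j > 0:
                sub = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
                X[i, j] = max(M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_EXTEND)
            Y[i, j] = max(M[i - 1, j] + GAP_OPEN, Y[i - 1, j] + GAP_EXTEND)
    return int(max(M[m].max(), X[m].max(), Y[m].max()))


# ---------------------------------------------------------------------------
# primer clipping


def clip_primers(aln: AlignedRead, amplicon: AmpliconSet) -> AlignedRead | None:
    """Exclude primer-binding positions from downstream counting.

    Bases overlapping either primer are marked clipped (soft-clip
    semantics: retained in the record, ignored by the pileup); reads
    lying entirely within a primer are discarded (returns None).
    """
    ins_lo = amplicon.insert_start - amplicon.start
    ins_hi = amplicon.insert_end - amplicon.start
    if aln.aln_end <= ins_lo or aln.aln_start >= ins_hi:
        return None
    aln.clip_bounds = (max(aln.aln_start, ins_lo), min(aln.aln_end, ins_hi))
    aln.clipped = True
    return aln


# ---------------------------------------------------------------------------
# UMI consensus


def umi_collapse(
    alignments: list[AlignedRead],
    min_family: int = 1,
    majority: float = 0.6,
) -> list[AlignedRead]:
    """Collapse alignments sharing an (amplicon, UMI) into one consensus.

    Per reference position the consensus base is the one reaching the
    majority threshold among family members covering it; positions
    without a majority are masked (emitted with quality 0 so they fail
    the pileup's quality gate). Indels are retained only when present in
    a majority of the family. Families smaller than ``min_family`` are
    dropped.
    """
    families: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for aln in alignments:
        if aln is None or aln.read.umi is None:
            continue
        families[(aln.amplicon_id, aln.read.umi)].append(aln)

    out: list[AlignedRead] = []
    for (amp_id, umi), fam in sorted(families.items()):
        if len(fam) < min_family:
            continue
        if len(fam) == 1:
            out.append(fam[0])
            continue
        out.append(_consensus(amp_id, umi, fam, majority))
    return out


def _consensus(
    amp_id: str, umi: str, fam: list[AlignedRead], majority: float
) -> AlignedRead:
    start = min(a.aln_start for a in fam)
    end = max(a.aln_end for a in fam)
    span = end - start
    votes: list[defaultdict] = [defaultdict(int) for _ in range(span)]
    cover = np.zeros(span, dtype=int)
    for a in fam:
        ref_pos, read_pos = a.aln_start, 0
        for op, ln in a.ops:
            if op in ("M", "X"):
                for k in range(ln):
                    votes[ref_pos + k - start][a.read.bases[read_pos + k]] += 1
                    cover[ref_pos + k - start] += 1
                ref_pos += ln
                read_pos += ln
            elif op == "D":
                for k in range(ln):
                    votes[ref_pos + k - start]["-"] += 1
                    cover[ref_pos + k - start] += 1
                ref_pos += ln
            else:
                read_pos += ln
    bases: list[str] = []
    quals: list[int] = []
    ops: list[str] = []
    for off in range(span):
        if cover[off] == 0:
            continue
        winner, count = max(sorted(votes[off].items()), key=lambda kv: kv[1])
        if count / cover[off] >= majority:
            if winner == "-":
                ops.append("D")
                continue
            bases.append(winner)
            quals.append(40)
            ops.append("M")
        else:
            bases.append("N")
            quals.append(0)  # masked: below any quality gate
            ops.append("X")
    read = ReadRecord(
        id=f"consensus:{amp_id}:{umi}",
        bases="".join(bases),
        qualities=np.array(quals),
        assigned_amplicon=amp_id,
        umi=umi,
    )
    return AlignedRead(
        amplicon_id=amp_id,
        read=read,
        aln_start=start,
        ops=_compress_ops(ops),
        score=len(bases),
        mapq=MAPQ_CAP,
    )


# ---------------------------------------------------------------------------
# pipeline convenience


def process_reads(
    reads,
    panel: PanelDesign,
    max_mismatch: int = 3,
    head_trim: int = 10,
    quality_cutoff: int = 10,
    collapse_umi: bool = False,
) -> tuple[dict[str, list[AlignedRead]], dict]:
    """Demultiplex, trim, align and primer-clip a read set.

    Returns per-amplicon clipped alignments plus a summary dict
    (assigned/unassigned/discarded/unaligned counts).
    """
    by_amp, unassigned = demultiplex(reads, panel, max_mismatch)
    amp_by_id = {a.id: a for a in panel.amplicons}
    result: dict[str, list[AlignedRead]] = {}
    stats = {
        "assigned": sum(len(v) for v in by_amp.values()),
        "unassigned": len(unassigned),
        "discarded": 0,
        "unaligned": 0,
    }
    for amp_id, amp_reads in by_amp.items():
        amp = amp_by_id[amp_id]
        trimmed, ndisc = trim_reads(amp_reads, panel, head_trim, quality_cutoff)
        stats["discarded"] += ndisc
        alns = []
        for read in trimmed:
            aln = align_to_amplicon(read, amp.amplicon_ref, amplicon_id=amp_id)
            if aln is None:
                stats["unaligned"] += 1
                continue
            aln = clip_primers(aln, amp)
            if aln is not None:
                alns.append(aln)
        if collapse_umi:
            alns = umi_collapse(alns)
        result[amp_id] = alns
    return result, stats
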