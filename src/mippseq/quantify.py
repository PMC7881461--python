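"""Quality-filtered per-position allele counts and allele-fraction extraction.

The unit of quantification is one amplicon insert (primer-clipped region).
An AlleleCountTable tallies, for every 0-based insert offset, the
A/C/G/T observations passing the base-quality and mapping-quality
thresholds, deletion-spanning reads, and insertion events keyed to the
preceding reference position. The target variant's alternate allelic
fraction (AAF) and the background error observed at flanking positions
are both read off this table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AmpliconSet, TargetVariant
from .dna import BASES

MIN_BASE_QUALITY = 20
MIN_MAPPING_QUALITY = 20
DEFAULT_FLANK = 50  # bases per side, i.e. 100 flanking positions total
MIN_FLANK_POSITIONS = 30  # fewer -> low-confidence background

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


class NotCoveredError(ValueError):
    """Target position lies outside the amplicon insert."""


@dataclass
class AlleleCountTable:
    """Per-position allele counts over one amplicon insert.

    ``acgt`` has shape (4, L) indexed A=0,C=1,G=2,T=3; ``dels`` counts
    reads with a deletion spanning each position; ``ins`` maps an insert
    offset to a Counter of inserted sequences (keyed to the position
    *before* the insertion); ``del_events`` counts reads spanning a full
    deletion event keyed by (start_offset, length).
    """

    amplicon_id: str
    insert_ref: str
    insert_start: int = 0  # genomic 0-based coordinate of offset 0
    acgt: np.ndarray = None
    dels: np.ndarray = None
    ins: dict[int, Counter] = field(default_factory=dict)
    del_events: Counter = field(default_factory=Counter)

    def __post_init__(self):
        L = len(self.insert_ref)
        if self.acgt is None:
            self.acgt = np.zeros((4, L), dtype=np.int64)
        if self.dels is None:
            self.dels = np.zeros(L, dtype=np.int64)

    def __len__(self):
        return len(self.insert_ref)

    @property
    def depth(self) -> np.ndarray:
        """Passing depth per position (base observations + spanning deletions)."""
        return self.acgt.sum(axis=0) + self.dels

    @property
    def ref_index(self) -> np.ndarray:
        return np.array([_BASE_IDX[b] for b in self.insert_ref])

    def ref_counts(self) -> np.ndarray:
        return self.acgt[self.ref_index, np.arange(len(self))]

    def nonref_fraction(self, include_indels: bool = False) -> np.ndarray:
        """Per-position fraction of non-reference observations.

        By default this pools the three alternative *bases* only
        (substitution errors), mirroring pileup-style outputs; indels can
        be included via the flag. Positions with zero depth return NaN.
        """
        depth = self.depth.astype(float)
        nonref = (self.acgt.sum(axis=0) - self.ref_counts()).astype(float)
        if include_indels:
            nonref += self.dels
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0, nonref / depth, np.nan)

    def base_fraction(self, offset: int, base: str) -> float:
        d = float(self.depth[offset])
        if d == 0:
            return float("nan")
        return self.acgt[_BASE_IDX[base], offset] / d

    def add_base(self, offset: int, base: str, n: int = 1) -> None:
        self.acgt[_BASE_IDX[base], offset] += n

    def add_deletion(self, start: int, length: int, n: int = 1) -> None:
        self.dels[start : start + length] += n
        self.del_events[(start, length)] += n

    def add_insertion(self, offset: int, seq: str, n: int = 1) -> None:
        self.ins.setdefault(offset, Counter())[seq] += n

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "offset": np.arange(len(self)),
                "pos": self.insert_start + np.arange(len(self)) + 1,  # 1-based
                "ref": list(self.insert_ref),
                **{b: self.acgt[i] for b, i in _BASE_IDX.items()},
                "del": self.dels,
                "ins": [
                    sum(self.ins[o].values()) if o in self.ins else 0
                    for o in range(len(self))
                ],
            }
        )
        df["depth"] = self.depth
        df.insert(0, "amplicon", self.amplicon_id)
        return df


@dataclass(frozen=True)
class FlankObservation:
    """One flanking-position observation used for the background error."""

    offset: int  # insert offset
    ref_base: str
    nonref_fraction: float  # pooled over the three alternative bases
    alt_fraction: float  # the target's alternate base specifically
    depth: int
    excluded: bool = False
    reason: str | None = None  # {germline, target, no_depth}


def pileup_counts(
    alignments,
    amplicon: AmpliconSet,
    min_base_q: int = MIN_BASE_QUALITY,
    min_map_q: int = MIN_MAPPING_QUALITY,
) -> AlleleCountTable:
    """Tally quality-filtered allele counts from primer-clipped alignments.

    A base contributes iff its Phred quality >= ``min_base_q``, its read's
    mapping quality >= ``min_map_q``, and the position is inside the
    unclipped (insert) part of the alignment. Deletions count at every
    deleted position (their spanning reads define the event depth);
    insertions attach to the preceding reference position. Insertions and
    deletions inherit the read-level quality gate via the mapping-quality
    filter only, as they carry no single base quality.
    """
    ins_local = amplicon.insert_start - amplicon.start
    ins_end_local = amplicon.insert_end - amplicon.start
    table = AlleleCountTable(
        amplicon_id=amplicon.id,
        insert_ref=amplicon.insert_seq,
        insert_start=amplicon.insert_start,
    )
    for aln in alignments:
        if aln is None or aln.mapq < min_map_q:
            continue
        lo, hi = aln.clip_bounds if aln.clip_bounds is not None else (0, len(amplicon.amplicon_ref))
        lo = max(lo, ins_local)
        hi = min(hi, ins_end_local)
        if lo >= hi:
            continue
        ref_pos = aln.aln_start
        read_pos = 0
        bases, quals = aln.read.bases, aln.read.qualities
        for op, length in aln.ops:
            if op in ("M", "X"):
                for k in range(length):
                    rp = ref_pos + k
                    if lo <= rp < hi and quals[read_pos + k] >= min_base_q:
                        table.add_base(rp - ins_local, bases[read_pos + k])
                ref_pos += length
                read_pos += length
            elif op == "D":
                if lo <= ref_pos and ref_pos + length <= hi:
                    table.add_deletion(ref_pos - ins_local, length)
                ref_pos += length
            elif op == "I":
                anchor = ref_pos - 1
                if lo <= anchor < hi:
                    table.add_insertion(
                        anchor - ins_local, bases[read_pos : read_pos + length]
                    )
                read_pos += length
    return table


def variant_aaf(
    table: AlleleCountTable, target: TargetVariant
) -> tuple[float, int]:
    """Extract the target variant's AAF and the passing depth used.

    SNV: alternate-base count / depth at the position. Deletion: reads
    spanning the full deleted span / depth at the first deleted position.
    Insertion: reads carrying exactly the inserted sequence after the
    anchor position / depth at the anchor.
    """
    start, end = target.span
    lo, hi = table.insert_start, table.insert_start + len(table)
    if not (lo <= start and end <= hi):
        raise NotCoveredError(
            f"target {target.contig}:{target.pos} not inside insert of {table.amplicon_id}"
        )
    if target.kind == "SNV":
        off = start - lo
        depth = int(table.depth[off])
        if depth == 0:
            return float("nan"), 0
        return table.acgt[_BASE_IDX[target.alt], off] / depth, depth
    if target.kind == "deletion":
        d_start = start + 1 - lo  # first deleted base (VCF anchor excluded)
        d_len = len(target.ref) - len(target.alt)
        depth = int(table.depth[d_start])
        if depth == 0:
            return float("nan"), 0
        return table.del_events.get((d_start, d_len), 0) / depth, depth
    # insertion
    off = start - lo
    inserted = target.alt[len(target.ref) :]
    depth = int(table.depth[off])
    if depth == 0:
        return float("nan"), 0
    count = table.ins.get(off, Counter()).get(inserted, 0)
    return count / depth, depth


def flanking_error(
    table: AlleleCountTable,
    target: TargetVariant,
    flank: int = DEFAULT_FLANK,
    germline_sites: set[int] | None = None,
) -> list[FlankObservation]:
    """Observations at up to ``flank`` positions either side of the target.

    These positions carry no real variant, so their non-reference
    fractions estimate the per-position error of this amplicon; the
    target's AAF is later tested against their mean and spread. Positions
    carrying known germline variants are flagged excluded so real alleles
    cannot inflate the background; positions beyond the insert edge are
    simply unavailable (the flank is truncated).

    ``germline_sites`` holds genomic 0-based positions.
    """
    germline_sites = germline_sites or set()
    start, end = target.span
    lo = table.insert_start
    t_offsets = set(range(start - lo, end - lo))  # event span, never background
    if target.kind == "deletion":
        t_offsets |= set(range(start - lo, start - lo + len(target.ref)))
    alt_base = target.alt[0] if target.kind == "SNV" else None

    nonref = table.nonref_fraction()
    depth = table.depth
    out: list[FlankObservation] = []
    center = start - lo
    for off in range(max(0, center - flank), min(len(table), center + flank + 1)):
        if off in t_offsets:
            continue
        ref_b = table.insert_ref[off]
        if alt_base is not None:
            alt_frac = table.base_fraction(off, alt_base) if depth[off] else float("nan")
            if ref_b == alt_base:
                alt_frac = float("nan")  # target base is the reference here
        else:
            alt_frac = float("nan")
        excluded, reason = False, None
        if lo + off in germline_sites:
            excluded, reason = True, "germline"
        elif depth[off] == 0:
            excluded, reason = True, "no_depth"
        out.append(
            FlankObservation(
                offset=off,
                ref_base=ref_b,
                nonref_fraction=float(nonref[off]),
                alt_fraction=float(alt_frac) if alt_frac == alt_frac else float("nan"),
                depth=int(depth[off]),
                excluded=excluded,
                reason=reason,
            )
        )
    return out


def background_stats(
    observations: list[FlankObservation], mode: str = "pooled"
) -> tuple[float, float, int]:
    """Mean and SD of the background error over non-excluded observations.

    ``mode`` 'pooled' uses the non-reference fraction summed over the
    three alternative bases (default; matches pileup-style parsing);
    'alt' uses the target's alternate base only.
    """
    if mode not in ("pooled", "alt"):
        raise ValueError(f"unknown background mode {mode!r}")
    vals = np.array(
        [
            o.nonref_fraction if mode == "pooled" else o.alt_fraction
            for o in observations
            if not o.excluded
        ]
    )
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)
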