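"""File-format interfaces: FASTA/VCF in, panel sheets, BED, SAM, VCF out.

Coordinates are 1-based in VCF-facing records and 0-based half-open in
BED, matching the conventions of both formats.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import (
    AmpliconSet,
    DesignConfig,
    PanelDesign,
    PrimerCandidate,
    TargetVariant,
)


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def load_fastq(path):
    """Yield ReadRecords from a (possibly gzipped) FASTQ file."""
    import gzip

    from .readproc import ReadRecord

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                id=rec.id,
                bases=str(rec.seq),
                qualities=np.array(rec.letter_annotations["phred_quality"]),
            )


def load_variants_vcf(path) -> list[TargetVariant]:
    """Read SNVs and indels from a VCF; one TargetVariant per ALT allele."""
    out: list[TargetVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                if set(rec.ref + alt) <= set("ACGT"):
                    out.append(TargetVariant(rec.contig, rec.pos, rec.ref, alt))
    return out


# ---------------------------------------------------------------------------
# panel sheets


_PANEL_COLUMNS = [
    "amplicon_id",
    "contig",
    "fwd_seq",
    "fwd_start",
    "fwd_end",
    "fwd_tm",
    "rev_seq",
    "rev_start",
    "rev_end",
    "rev_tm",
    "barcode",
    "umi_len",
    "fwd_adapter",
    "rev_adapter",
    "fwd_oligo",
    "rev_oligo",
]


def write_panel(panel: PanelDesign, outdir) -> None:
    """Write the panel as a TSV sheet, BED intervals and amplicon FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "panel.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_PANEL_COLUMNS)
        for a in panel.amplicons:
            fwd_oligo = a.adapters[0] + a.barcode + "N" * a.umi_scheme + a.forward.seq
            rev_oligo = a.adapters[1] + a.reverse.seq
            w.writerow(
                [
                    a.id,
                    a.contig,
                    a.forward.seq,
                    a.forward.start,
                    a.forward.end,
                    f"{a.forward.tm:.2f}",
                    a.reverse.seq,
                    a.reverse.start,
                    a.reverse.end,
                    f"{a.reverse.tm:.2f}",
                    a.barcode,
                    a.umi_scheme,
                    a.adapters[0],
                    a.adapters[1],
                    fwd_oligo,
                    rev_oligo,
                ]
            )
    with open(outdir / "inserts.bed", "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.contig}\t{a.insert_start}\t{a.insert_end}\t{a.id}\n")
    with open(outdir / "primers.bed", "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.contig}\t{a.forward.start}\t{a.forward.end}\t{a.id}_F\t0\t+\n")
            fh.write(f"{a.contig}\t{a.reverse.start}\t{a.reverse.end}\t{a.id}_R\t0\t-\n")
    write_fasta({a.id: a.amplicon_ref for a in panel.amplicons}, outdir / "amplicons.fasta")
    if panel.target is not None:
        t = panel.target
        with open(outdir / "target.json", "w") as fh:
            json.dump(
                {"contig": t.contig, "pos": t.pos, "ref": t.ref, "alt": t.alt}, fh
            )


def load_panel(outdir, config: DesignConfig | None = None) -> PanelDesign:
    """Reconstruct a PanelDesign from a written panel directory."""
    outdir = Path(outdir)
    amp_refs = load_fasta(outdir / "amplicons.fasta")
    amplicons: list[AmpliconSet] = []
    with open(outdir / "panel.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            fwd = PrimerCandidate(
                seq=row["fwd_seq"],
                start=int(row["fwd_start"]),
                end=int(row["fwd_end"]),
                strand="+",
                tm=float(row["fwd_tm"]),
            )
            rev = PrimerCandidate(
                seq=row["rev_seq"],
                start=int(row["rev_start"]),
                end=int(row["rev_end"]),
                strand="-",
                tm=float(row["rev_tm"]),
            )
            amplicons.append(
                AmpliconSet(
                    id=row["amplicon_id"],
                    contig=row["contig"],
                    forward=fwd,
                    reverse=rev,
                    amplicon_ref=amp_refs[row["amplicon_id"]],
                    barcode=row["barcode"],
                    umi_scheme=int(row["umi_len"]),
                    adapters=(row["fwd_adapter"], row["rev_adapter"]),
                )
            )
    target = None
    tpath = outdir / "target.json"
    if tpath.exists():
        d = json.loads(tpath.read_text())
        target = TargetVariant(d["contig"], d["pos"], d["ref"], d["alt"])
    return PanelDesign(
        amplicons=amplicons, target=target, config=config or DesignConfig()
    )


# ---------------------------------------------------------------------------
# alignments (SAM) and counts


def write_sam(aligned: dict[str, list], panel: PanelDesign, path) -> None:
    """Write per-amplicon alignments as SAM against the amplicon references,
    with primer-clipped bases soft-clipped."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": a.id, "LN": len(a.amplicon_ref)} for a in panel.amplicons
        ],
    }
    order = {a.id: i for i, a in enumerate(panel.amplicons)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for amp_id, alns in aligned.items():
            for aln in alns:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = aln.read.id
                seg.query_sequence = aln.read.bases
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in aln.read.qualities)
                )
                seg.reference_id = order[amp_id]
                seg.mapping_quality = aln.mapq
                cigar, ref_start = _ops_to_cigar(aln, panel, amp_id)
                seg.reference_start = ref_start
                seg.cigartuples = cigar
                out.write(seg)


_OP_CODE = {"M": 0, "I": 1, "D": 2, "X": 0}  # report mismatches as M


def _ops_to_cigar(aln, panel: PanelDesign, amp_id: str):
    """Convert internal ops to CIGAR, soft-clipping primer overhang."""
    amp = next(a for a in panel.amplicons if a.id == amp_id)
    lo, hi = aln.clip_bounds if aln.clip_bounds is not None else (
        aln.aln_start,
        aln.aln_end,
    )
    cigar: list[tuple[int, int]] = []
    ref_pos, read_pos = aln.aln_start, 0
    left_clip = right_clip = 0
    ref_start = None
    for op, ln in aln.ops:
        for _ in range(ln):
            if op in ("M", "X", "I"):
                inside = (lo <= ref_pos < hi) if op != "I" else (lo <= ref_pos - 1 < hi)
                if not inside:
                    if ref_start is None:
                        left_clip += 1
                    else:
                        right_clip += 1
                else:
                    if ref_start is None:
                        ref_start = ref_pos
                    _cig_push(cigar, _OP_CODE[op])
                read_pos += 1
                if op != "I":
                    ref_pos += 1
            else:  # D
                if lo <= ref_pos < hi and ref_start is not None:
                    _cig_push(cigar, 2)
                ref_pos += 1
    if left_clip:
        cigar.insert(0, (4, left_clip))
    if right_clip:
        cigar.append((4, right_clip))
    return cigar, ref_start if ref_start is not None else aln.aln_start


def _cig_push(cigar: list, code: int) -> None:
    if cigar and cigar[-1][0] == code:
        cigar[-1] = (code, cigar[-1][1] + 1)
    else:
        cigar.append((code, 1))


def write_counts_tsv(tables: dict, path) -> None:
    import pandas as pd

    pd.concat([t.to_dataframe() for t in tables.values()]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# calls


def write_calls_vcf(calls: list, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write AafCalls as VCF with per-amplicon AAFs and background stats."""
    header = pysam.VariantHeader()
    contigs = {c.target.contig for c in calls}
    for contig in sorted(contigs):
        ln = (contig_lengths or {}).get(contig, 10**7)
        header.contigs.add(contig, length=ln)
    header.info.add("MEAN_AAF", 1, "Float", "Pooled mean alternate allele fraction")
    header.info.add("CI95", 2, "Float", "95% confidence interval of the mean AAF")
    header.info.add("AMP_AAF", ".", "Float", "Per-amplicon AAFs")
    header.info.add("AMP_IDS", ".", "String", "Amplicon identifiers")
    header.info.add("BG_MEAN", 1, "Float", "Flanking background mean error")
    header.info.add("BG_SD", 1, "Float", "Flanking background error SD")
    header.info.add("PVAL", 1, "Float", "Welch test p-value vs background")
    header.info.add("VERDICT", 1, "String", "detected/not_detected/low_confidence")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            t = c.target
            rec = out.new_record(
                contig=t.contig, start=t.pos - 1, alleles=(t.ref, t.alt)
            )
            rec.info["MEAN_AAF"] = float(c.mean_aaf)
            if not np.isnan(c.ci95[0]):
                rec.info["CI95"] = tuple(float(x) for x in c.ci95)
            rec.info["AMP_AAF"] = tuple(float(a) for a in c.aafs)
            rec.info["AMP_IDS"] = ",".join(c.amplicon_ids)
            rec.info["BG_MEAN"] = float(c.background_mean)
            rec.info["BG_SD"] = float(c.background_sd)
            if not np.isnan(c.p_value):
                rec.info["PVAL"] = float(c.p_value)
            rec.info["VERDICT"] = c.verdict
            out.write(rec)


def call_to_dict(call) -> dict:
    t = call.target
    return {
        "target": {"contig": t.contig, "pos": t.pos, "ref": t.ref, "alt": t.alt},
        "amplicons": call.amplicon_ids,
        "aafs": [None if np.isnan(a) else a for a in call.aafs],
        "depths": call.depths,
        "mean_aaf": None if np.isnan(call.mean_aaf) else call.mean_aaf,
        "ci95": [None if np.isnan(x) else x for x in call.ci95],
        "background_mean": call.background_mean,
        "background_sd": call.background_sd,
        "p_value": None if np.isnan(call.p_value) else call.p_value,
        "verdict": call.verdict,
        "flags": call.flags,
    }
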