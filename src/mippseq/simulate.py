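"""Synthetic amplicon sequencing over dilution series.

The generator reproduces the two sampling stages that govern detection of
ultra-low allele fractions:

1. *Molecule sampling.* A PCR reaction receives a fixed DNA mass; at
   3.3 pg per haploid genome, 50 ng is ~15,000 amplifiable copies of the
   locus. The number of mutant copies entering the reaction is binomial
   in the true allele fraction — at 0.01% AAF and 50 ng that is 1–2
   copies, and this, not sequencing depth, limits detection.
2. *Read sampling and error.* Each read is drawn from the molecule pool
   (all amplicons of a multiplexed reaction share one pool), then
   corrupted: substitutions at a per-base rate, indels at a rate scaled
   up inside homopolymer runs, and Phred qualities from a truncated
   normal. PCR polymerase errors are folded in as an additive per-base
   substitution rate (the fidelity estimate for the full reaction), not
   simulated per amplification cycle.

A fast count-level path (`simulate_counts`) draws the per-position
multinomial tallies directly and is statistically equivalent to
generating reads and piling them up with no alignment loss; the
read-level path (`simulate_amplicon_reads`) emits FASTQ-style records
with barcode+UMI prefixes for exercising the processing pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .design import AmpliconSet, PanelDesign, TargetVariant
from .dna import BASES, homopolymer_lengths
from .quantify import AlleleCountTable

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

GENOME_MASS_PG = 3.3  # pg of DNA per haploid genome copy


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates of the sequencing + library process.

    sub_rate: substitution probability per sequenced base (platform).
    polymerase_rate: additional substitutions introduced by PCR over the
        whole reaction, per base (high-fidelity polymerase estimate).
    indel_rate: indel probability per base outside homopolymers.
    homopolymer_factor: multiplicative indel scaling per homopolymer base
        beyond length 3 (capped at ``homopolymer_cap``).
    quality_mean/sd: emitted Phred quality distribution, clipped to [2, 41].
    """

    sub_rate: float = 7e-5
    polymerase_rate: float = 8.8e-6
    indel_rate: float = 1e-5
    homopolymer_factor: float = 2.0
    homopolymer_cap: float = 50.0
    quality_mean: float = 30.0
    quality_sd: float = 5.0

    def __post_init__(self):
        for name in ("sub_rate", "polymerase_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 2.0 <= self.quality_mean <= 41.0:
            raise ValueError("quality_mean must be in [2,41]")

    @property
    def total_sub_rate(self) -> float:
        return self.sub_rate + self.polymerase_rate

    def indel_rates(self, seq: str) -> np.ndarray:
        """Per-position indel rate with homopolymer scaling."""
        hp = homopolymer_lengths(seq)
        scale = np.minimum(
            self.homopolymer_factor ** np.maximum(0, hp - 3), self.homopolymer_cap
        )
        return self.indel_rate * scale

    def pass_probability(self, threshold: int = 20) -> float:
        """Probability an emitted base quality passes ``threshold``
        (qualities are rounded, so the cut sits at threshold - 0.5)."""
        return float(
            stats.norm.sf(threshold - 0.5, loc=self.quality_mean, scale=self.quality_sd)
        )


@dataclass(frozen=True)
class DilutionSeries:
    """Two-fold serial dilution of a heterozygous sample into wild type."""

    start_aaf: float = 0.5
    fold: float = 2.0
    n_steps: int = 12

    def aafs(self) -> np.ndarray:
        return self.start_aaf / self.fold ** np.arange(self.n_steps + 1)


@dataclass
class SimScenario:
    """One simulated sequencing experiment at a fixed true AAF."""

    panel: PanelDesign
    true_aaf: float
    input_mass_ng: float = 50.0
    genome_mass_pg: float = GENOME_MASS_PG
    depth_per_amplicon: int = 50_000
    error_model: ErrorModel = field(default_factory=ErrorModel)
    platform: str = "ion"
    seed: int = 0
    shared_input: bool = True  # one multiplexed reaction feeds all amplicons

    def __post_init__(self):
        if not 0.0 <= self.true_aaf <= 1.0:
            raise ValueError("true_aaf must be in [0,1]")
        if self.input_mass_ng < 0 or self.depth_per_amplicon < 0:
            raise ValueError("mass and depth must be non-negative")


def molecules_from_mass(mass_ng: float, genome_mass_pg: float = GENOME_MASS_PG) -> int:
    """Haploid genome copies in a DNA mass (1 ng = 1000 pg). Cells carry
    two copies, so 25 ng at 3.3 pg/copy is ~7,576 copies = ~3,788 cells."""
    if mass_ng < 0:
        raise ValueError(f"mass must be non-negative, got {mass_ng}")
    return int(round(mass_ng * 1000.0 / genome_mass_pg))


def sample_input_molecules(
    copies: int, true_aaf: float, rng: np.random.Generator | int
) -> tuple[int, int]:
    """Binomial draw of (alt_copies, ref_copies) entering a reaction."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if copies < 0:
        raise ValueError("copies must be non-negative")
    alt = int(rng.binomial(copies, true_aaf)) if copies else 0
    return alt, copies - alt


def make_dilution_series(series: DilutionSeries) -> np.ndarray:
    """True AAFs of the serial dilution, highest first."""
    return series.aafs()


def _split_multinomial(
    rng: np.random.Generator, n: np.ndarray, k: int
) -> list[np.ndarray]:
    """Split count vector ``n`` uniformly into ``k`` parts, vectorised."""
    parts = []
    remaining = n.copy()
    for i in range(k - 1):
        p = 1.0 / (k - i)
        drawn = rng.binomial(remaining, p)
        parts.append(drawn)
        remaining = remaining - drawn
    parts.append(remaining)
    return parts


def simulate_counts(
    amplicon: AmpliconSet,
    target: TargetVariant | None,
    alt_copies: int,
    ref_copies: int,
    depth: int,
    error_model: ErrorModel | None = None,
    rng: np.random.Generator | int = 0,
) -> AlleleCountTable:
    """Count-level simulation of one amplicon sequenced to ``depth``.

    Every read spans the full insert. Per position, the passing depth is
    binomially thinned by the base-quality pass rate; reads originate
    from the alt molecule class with probability alt/(alt+ref);
    substitution errors move counts uniformly onto the three other
    bases; indel errors (homopolymer-scaled) register as single-base
    deletion/insertion observations.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    table = AlleleCountTable(
        amplicon_id=amplicon.id,
        insert_ref=amplicon.insert_seq,
        insert_start=amplicon.insert_start,
    )
    if depth == 0:
        return table
    if alt_copies + ref_copies <= 0:
        raise SimulationError("no input molecules but depth > 0 requested")

    L = len(table)
    seq = table.insert_ref
    ref_idx = table.ref_index
    p_alt = alt_copies / (alt_copies + ref_copies)
    p_pass = em.pass_probability()
    r_sub = em.total_sub_rate
    r_ind = em.indel_rates(seq)

    n_pass = rng.binomial(depth, p_pass, size=L)

    # reads from the alt molecule class, drawn once per position (reads are
    # exchangeable per position at count level)
    n_alt = rng.binomial(n_pass, p_alt) if p_alt > 0 else np.zeros(L, dtype=np.int64)
    n_ref = n_pass - n_alt

    counts = np.zeros((4, L), dtype=np.int64)
    counts[ref_idx, np.arange(L)] = n_pass  # start all-reference

    # apply the target variant to alt-class reads
    if target is not None and alt_copies > 0:
        t0 = target.span[0] - amplicon.insert_start  # offset of VCF anchor base
        if target.kind == "SNV":
            counts[ref_idx[t0], t0] -= n_alt[t0]
            counts[_BASE_IDX[target.alt], t0] += n_alt[t0]
        elif target.kind == "deletion":
            d_start = t0 + 1
            d_len = len(target.ref) - len(target.alt)
            span = slice(d_start, d_start + d_len)
            n_event = n_alt[d_start]
            counts[ref_idx[span], np.arange(d_start, d_start + d_len)] -= n_event
            table.dels[span] += n_event
            table.del_events[(d_start, d_len)] += int(n_event)
        else:  # insertion
            inserted = target.alt[len(target.ref) :]
            table.add_insertion(t0, inserted, int(n_alt[t0]))

    # substitution errors: each counted base flips with rate r_sub,
    # uniformly to the three other bases
    for b in range(4):
        col = counts[b]
        err = rng.binomial(col, r_sub)
        if not err.any():
            continue
        counts[b] -= err
        others = [x for x in range(4) if x != b]
        for o, part in zip(others, _split_multinomial(rng, err, 3)):
            counts[o] += part

    # indel errors: single-base events, homopolymer-scaled
    n_ind = rng.binomial(n_pass, np.minimum(r_ind, 1.0))
    n_del = rng.binomial(n_ind, 0.5)
    n_insv = n_ind - n_del
    for off in np.nonzero(n_del)[0]:
        k = int(min(n_del[off], counts[ref_idx[off], off]))
        if k:
            counts[ref_idx[off], off] -= k
            table.dels[off] += k
            table.del_events[(int(off), 1)] += k
    for off in np.nonzero(n_insv)[0]:
        table.add_insertion(int(off), seq[off], int(n_insv[off]))

    table.acgt += counts
    return table


def simulate_scenario(
    scenario: SimScenario,
) -> tuple[dict[str, AlleleCountTable], tuple[int, int]]:
    """Count-level simulation of a whole scenario.

    Returns per-amplicon tables and the (alt, ref) molecule draw. With
    ``shared_input`` (the default) all amplicons sample reads from one
    molecule pool, as in a single multiplexed reaction; otherwise each
    amplicon gets an independent reaction drawing its own molecules from
    the same mass.
    """
    rng = np.random.default_rng(scenario.seed)
    copies = molecules_from_mass(scenario.input_mass_ng, scenario.genome_mass_pg)
    tables: dict[str, AlleleCountTable] = {}
    if scenario.shared_input:
        alt, ref = sample_input_molecules(copies, scenario.true_aaf, rng)
        draws = [(alt, ref)] * len(scenario.panel.amplicons)
    else:
        draws = [
            sample_input_molecules(copies, scenario.true_aaf, rng)
            for _ in scenario.panel.amplicons
        ]
    for amp, (alt, ref) in zip(scenario.panel.amplicons, draws):
        tables[amp.id] = simulate_counts(
            amp,
            scenario.panel.target,
            alt,
            ref,
            scenario.depth_per_amplicon,
            scenario.error_model,
            rng,
        )
    return tables, draws[0]


# ---------------------------------------------------------------------------
# read-level path


@dataclass
class SimulatedRead:
    id: str
    bases: str
    qualities: np.ndarray  # Phred ints
    origin: str  # 'alt' or 'ref' (molecule class)

    def to_fastq(self) -> str:
        qual = "".join(chr(q + 33) for q in self.qualities)
        return f"@{self.id}\n{self.bases}\n+\n{qual}\n"


def _apply_variant_local(seq: str, var: TargetVariant, offset0: int) -> str:
    """Apply a variant to an amplicon-local sequence; ``offset0`` is the
    local offset of the variant's VCF anchor base."""
    s, e = offset0, offset0 + len(var.ref)
    return seq[:s] + var.alt + seq[e:]


def simulate_amplicon_reads(
    amplicon: AmpliconSet,
    target: TargetVariant | None,
    alt_copies: int,
    ref_copies: int,
    depth: int,
    error_model: ErrorModel | None = None,
    rng: np.random.Generator | int = 0,
    alt_extra: list[TargetVariant] | None = None,
    ref_extra: list[TargetVariant] | None = None,
) -> list[SimulatedRead]:
    """Simulate barcode+UMI-prefixed full-length reads of one amplicon.

    ``alt_extra``/``ref_extra`` place additional variants on the alt/ref
    molecule class (e.g. a germline SNP in cis or trans with the target).
    The molecule class of origin is recorded in the read name for truth
    evaluation.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if depth > 0 and alt_copies + ref_copies <= 0:
        raise SimulationError("no input molecules but depth > 0 requested")

    def build_haplotype(variants: list[TargetVariant]) -> str:
        seq = amplicon.amplicon_ref
        for v in sorted(variants, key=lambda v: -v.pos):
            off = v.span[0] - amplicon.start
            seq = _apply_variant_local(seq, v, off)
        return seq

    alt_vars = ([target] if target is not None else []) + (alt_extra or [])
    hap_alt = build_haplotype(alt_vars)
    hap_ref = build_haplotype(ref_extra or [])

    p_alt = alt_copies / (alt_copies + ref_copies) if depth else 0.0
    reads: list[SimulatedRead] = []
    for i in range(depth):
        is_alt = rng.random() < p_alt
        body = hap_alt if is_alt else hap_ref
        body = _mutate(body, em, rng)
        umi = "".join(BASES[j] for j in rng.integers(0, 4, amplicon.umi_scheme))
        bases = amplicon.barcode + umi + body
        quals = np.clip(
            np.rint(rng.normal(em.quality_mean, em.quality_sd, len(bases))), 2, 41
        ).astype(int)
        origin = "alt" if is_alt else "ref"
        reads.append(
            SimulatedRead(
                id=f"{amplicon.id}:{i}:{origin}",
                bases=bases,
                qualities=quals,
                origin=origin,
            )
        )
    return reads


def _mutate(seq: str, em: ErrorModel, rng: np.random.Generator) -> str:
    """Apply substitution and homopolymer-scaled indel errors to a read."""
    arr = list(seq)
    n = len(arr)
    subs = np.nonzero(rng.random(n) < em.total_sub_rate)[0]
    for i in subs:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    r_ind = em.indel_rates(seq)
    indels = np.nonzero(rng.random(n) < r_ind)[0]
    for i in sorted(indels, reverse=True):
        if rng.random() < 0.5 and len(arr) > 1:
            del arr[i]
        else:
            arr.insert(i + 1, seq[i])
    return "".join(arr)


def write_fastq(reads, path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(r.to_fastq())


# ---------------------------------------------------------------------------
# downsampling


def downsample_reads(reads: list, target_depth: int, rng: np.random.Generator | int = 0):
    """Uniform subsample without replacement; identity if enough already."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if target_depth < 0:
        raise ValueError("target_depth must be non-negative")
    if target_depth >= len(reads):
        return list(reads)
    idx = rng.choice(len(reads), size=target_depth, replace=False)
    return [reads[i] for i in sorted(idx)]


def downsample_counts(
    table: AlleleCountTable, target_depth: int, rng: np.random.Generator | int = 0
) -> AlleleCountTable:
    """Count-level equivalent of read downsampling: per position, a
    multivariate hypergeometric subsample of the allele counts."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = AlleleCountTable(
        amplicon_id=table.amplicon_id,
        insert_ref=table.insert_ref,
        insert_start=table.insert_start,
    )
    depth = table.depth
    for off in range(len(table)):
        total = int(depth[off])
        if total == 0:
            continue
        colors = np.append(table.acgt[:, off], table.dels[off])
        k = min(target_depth, total)
        drawn = rng.multivariate_hypergeometric(colors, k)
        out.acgt[:, off] = drawn[:4]
        out.dels[off] = drawn[4]
    # deletion events and insertions are thinned at the same per-position rate
    for (s, ln), n in table.del_events.items():
        frac = out.dels[s] / table.dels[s] if table.dels[s] else 0.0
        out.del_events[(s, ln)] = int(round(n * frac))
    for off, ctr in table.ins.items():
        tot = int(depth[off])
        if tot == 0:
            continue
        keep = min(target_depth, tot) / tot
        for seqk, n in ctr.items():
            kn = int(rng.binomial(n, keep))
            if kn:
                out.add_insertion(off, seqk, kn)
    return out
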