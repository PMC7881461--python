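"""Design of multiple independent PCR amplicons over a target variant.

The strategy implemented here validates or discovers low-fraction mosaic
variants by sequencing several *independent* amplicons over the same
locus: independent primer pairs with non-overlapping binding sites give
independent measurements of the allele fraction, so allelic dropout or a
primer-site polymorphism corrupts at most one measurement.

Two design modes are provided:

``design_panel``
    known-variant mode: >=3 non-overlapping amplicons over a single
    target variant, each placing the target at a different offset within
    the insert where feasible.
``design_tiling_panel``
    scanning mode (short-read/Illumina workflow): every base of a region
    is covered by a configurable number of independent amplicons
    (default 4), enabling k-of-n consensus calling of novel variants.

Primer placement is an exhaustive sliding-window search; candidate pairs
are ranked by total deviation of their melting temperatures from the
configured optimum. Coordinates are 0-based half-open internally;
VCF-facing positions are 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .dna import encode, revcomp
from .thermo import melting_temperature

PRIMER_MIN_LEN = 18
PRIMER_MAX_LEN = 27
SEARCH_RADIUS = 400  # bp around the target searched for primer sites

# Platform adapter constants prepended 5' of barcode+primer. Opaque to the
# rest of the pipeline.
ADAPTERS = {
    "ion": ("CCATCTCATCCCTGCGTGTCTCCGACTCAG", "CCTCTCTATGGGCAGTCGGTGAT"),
    "illumina": ("AATGATACGGCGACCACCGAGATCTACAC", "CAAGCAGAAGACGGCATACGAGAT"),
}
UMI_LENGTHS = {"ion": 10, "illumina": 5}


class CoordinateError(ValueError):
    """A variant position falls outside the supplied reference."""


class ReferenceMismatchError(ValueError):
    """A variant's stated reference allele disagrees with the reference."""


class PanelInfeasibleError(RuntimeError):
    """Too few mutually disjoint primer pairs exist for the request."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"only {achievable} non-overlapping amplicon(s) achievable "
            f"(requested {requested})"
        )


class TilingInfeasibleError(RuntimeError):
    """Region cannot be tiled at the requested coverage."""

    def __init__(self, uncovered: list[tuple[int, int]]):
        self.uncovered = uncovered
        super().__init__(f"uncoverable interval(s): {uncovered}")


class TaggingError(RuntimeError):
    """Barcode pool exhausted."""


@dataclass(frozen=True)
class TargetVariant:
    """A substitution or indel in VCF convention (1-based ``pos``; for
    indels ``pos`` is the base immediately left of the event)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or any(b not in "ACGT" for b in allele):
                raise ValueError(f"{name} allele must be non-empty over ACGT: {allele!r}")
        if self.pos < 1:
            raise CoordinateError(f"pos must be 1-based positive: {self.pos}")

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval of reference bases altered by the event."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    def check_reference(self, ref_seq: str) -> None:
        start, end = self.span
        if start < 0 or end > len(ref_seq):
            raise CoordinateError(f"{self} outside reference of length {len(ref_seq)}")
        if ref_seq[start:end].upper() != self.ref:
            raise ReferenceMismatchError(
                f"reference has {ref_seq[start:end]!r} at {self.contig}:{self.pos}, "
                f"variant states {self.ref!r}"
            )


@dataclass(frozen=True)
class DesignConfig:
    tm_target: float = 60.0
    tm_min: float = 59.0
    tm_max: float = 62.0
    amplicon_min: int = 225
    amplicon_max: int = 300
    mask_flank: int = 5
    n_amplicons: int = 3
    tiling_coverage: int = 4
    tiling_amplicon_max: int = 285  # including primers
    barcode_len: int = 10
    umi_len: int | None = None  # platform default when None
    offset_min_diff: int = 20  # preferred spread of target offsets across inserts

    def __post_init__(self):
        if not (self.tm_min <= self.tm_target <= self.tm_max):
            raise ValueError("require tm_min <= tm_target <= tm_max")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("require amplicon_min <= amplicon_max")
        if self.n_amplicons < 3:
            raise ValueError("independent-amplicon design requires n_amplicons >= 3")


@dataclass(frozen=True)
class PrimerCandidate:
    seq: str  # oligo sequence 5'->3'
    start: int  # 0-based half-open binding interval on the reference
    end: int
    strand: str  # '+' or '-'
    tm: float

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    score: float  # |TMf - tm_target| + |TMr - tm_target|; lower is better

    @property
    def amplicon_interval(self) -> tuple[int, int]:
        return self.forward.start, self.reverse.end

    @property
    def insert_interval(self) -> tuple[int, int]:
        return self.forward.end, self.reverse.start

    @property
    def length(self) -> int:
        return self.reverse.end - self.forward.start


@dataclass
class AmpliconSet:
    id: str
    contig: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_ref: str  # full unmasked amplicon sequence incl. primers
    barcode: str = ""
    umi_scheme: int = 0  # 0 = none, else fixed-length degenerate N prefix
    adapters: tuple[str, str] = ("", "")

    @property
    def start(self) -> int:
        return self.forward.start

    @property
    def end(self) -> int:
        return self.reverse.end

    @property
    def insert_start(self) -> int:
        return self.forward.end

    @property
    def insert_end(self) -> int:
        return self.reverse.start

    @property
    def insert_seq(self) -> str:
        a, b = self.insert_start - self.start, self.insert_end - self.start
        return self.amplicon_ref[a:b]

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_in_insert(self, span: tuple[int, int]) -> bool:
        return self.insert_start <= span[0] and span[1] <= self.insert_end

    def insert_offset(self, ref_pos0: int) -> int:
        """Map a 0-based reference coordinate to a 0-based insert offset."""
        if not (self.insert_start <= ref_pos0 < self.insert_end):
            raise CoordinateError(f"position {ref_pos0} outside insert of {self.id}")
        return ref_pos0 - self.insert_start


@dataclass
class PanelDesign:
    amplicons: list[AmpliconSet]
    target: TargetVariant | None = None
    region: tuple[int, int] | None = None
    config: DesignConfig = field(default_factory=DesignConfig)

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self):
        return len(self.amplicons)

    def primer_intervals(self) -> list[tuple[int, int]]:
        out = []
        for a in self.amplicons:
            out.extend([a.forward.interval, a.reverse.interval])
        return out

    def validate(self) -> None:
        """Assert the structural invariants of a finished design: amplicons
        belonging to a common covering group (overlapping inserts) must have
        mutually disjoint primer binding sites."""
        for a, b in itertools.combinations(self.amplicons, 2):
            if not _overlap((a.insert_start, a.insert_end), (b.insert_start, b.insert_end)):
                continue
            a_iv = [a.forward.interval, a.reverse.interval]
            b_iv = [b.forward.interval, b.reverse.interval]
            if _pair_conflicts(a_iv, b_iv):
                raise PanelInfeasibleError(len(self.amplicons), len(self.amplicons) - 1)
        for a in self.amplicons:
            if self.target is not None and not a.contains_in_insert(self.target.span):
                raise CoordinateError(f"target outside insert of {a.id}")


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def _pair_conflicts(pair_ivals, chosen_ivals) -> bool:
    return any(_overlap(p, c) for p in pair_ivals for c in chosen_ivals)


def mask_reference(
    ref_seq: str,
    known_variants: list[TargetVariant],
    target: TargetVariant | None,
    mask_flank: int = 5,
) -> str:
    """Replace known variant bases (and the target +/- ``mask_flank``) by N.

    Masking removes these positions from primer search: a polymorphism
    under a primer causes allelic dropout, and a primer over the target
    would prevent its measurement. Length is preserved; for indels the
    reference-allele span is masked.
    """
    out = np.frombuffer(ref_seq.upper().encode(), dtype="S1").copy()
    for v in known_variants:
        v.check_reference(ref_seq)
        s, e = v.span
        out[s:e] = b"N"
    if target is not None:
        target.check_reference(ref_seq)
        s, e = target.span
        out[max(0, s - mask_flank) : min(len(ref_seq), e + mask_flank)] = b"N"
    return out.tobytes().decode()


def _primer_windows(
    masked_seq: str, lo: int, hi: int, config: DesignConfig
) -> list[tuple[int, int, float]]:
    """All (start, end, tm) windows within [lo, hi) passing TM bounds with no
    masked base. TM is strand-symmetric so windows serve both orientations."""
    lo, hi = max(0, lo), min(len(masked_seq), hi)
    enc = encode(masked_seq)
    out = []
    for length in range(PRIMER_MIN_LEN, PRIMER_MAX_LEN + 1):
        if hi - lo < length:
            continue
        # positions whose window contains any non-ACGT base are excluded
        bad = np.convolve((enc[lo:hi] > 3).astype(int), np.ones(length, int), "valid")
        for off in np.nonzero(bad == 0)[0]:
            s = lo + int(off)
            tm = melting_temperature(masked_seq[s : s + length])
            if config.tm_min <= tm <= config.tm_max:
                out.append((s, s + length, tm))
    return out


def enumerate_candidates(
    masked_seq: str, target: TargetVariant, config: DesignConfig | None = None
) -> list[PrimerPair]:
    """Exhaustively enumerate primer pairs flanking the (masked) target.

    Every returned pair satisfies the TM bounds, the amplicon length
    bounds, contains no masked base in either primer, and places the
    target strictly within the insert. Pairs are sorted by total TM
    deviation from ``tm_target`` (ties broken by coordinates).
    """
    config = config or DesignConfig()
    t_start, t_end = target.span
    windows = _primer_windows(
        masked_seq, t_start - SEARCH_RADIUS, t_end + SEARCH_RADIUS, config
    )
    fwd = [w for w in windows if w[1] <= t_start]
    rev = [w for w in windows if w[0] >= t_end]
    rev_by_start = sorted(rev, key=lambda w: w[0])
    rev_starts = np.array([w[0] for w in rev_by_start], dtype=int)

    pairs: list[PrimerPair] = []
    for fs, fe, ftm in fwd:
        lo = np.searchsorted(rev_starts, fe)  # reverse site strictly right of insert start
        for rs, re, rtm in rev_by_start[lo:]:
            length = re - fs
            if length < config.amplicon_min:
                continue
            if length > config.amplicon_max:
                # rev sorted by start, not end; ends vary by <=9nt, so allow
                # slight overshoot before breaking out of the scan
                if rs - fs > config.amplicon_max:
                    break
                continue
            if rs < t_end:  # target must lie strictly inside the insert
                continue
            f = PrimerCandidate(masked_seq[fs:fe], fs, fe, "+", ftm)
            r = PrimerCandidate(revcomp(masked_seq[rs:re]), rs, re, "-", rtm)
            score = abs(ftm - config.tm_target) + abs(rtm - config.tm_target)
            pairs.append(PrimerPair(f, r, score))
    pairs.sort(key=lambda p: (p.score, p.forward.start, p.reverse.start))
    return pairs


def select_nonoverlapping(
    candidates: list[PrimerPair],
    n_amplicons: int,
    ref_seq: str,
    target: TargetVariant | None = None,
    config: DesignConfig | None = None,
    contig: str = "locus",
) -> PanelDesign:
    """Greedy selection of ``n_amplicons`` pairs with disjoint primer sites.

    Selection walks the score-sorted candidates; a first pass additionally
    prefers pairs whose target offset within the insert differs from every
    already-selected offset by at least ``config.offset_min_diff`` so that
    position-specific artifacts cannot hit the same insert offset twice.
    If that preference cannot be satisfied it is relaxed (best effort).
    """
    config = config or DesignConfig()
    t_pos = target.span[0] if target is not None else None

    def _greedy(offset_rule: bool) -> list[PrimerPair]:
        chosen: list[PrimerPair] = []
        ivals: list[tuple[int, int]] = []
        offsets: list[int] = []
        for pair in candidates:
            p_ivals = [pair.forward.interval, pair.reverse.interval]
            if _pair_conflicts(p_ivals, ivals):
                continue
            if offset_rule and t_pos is not None:
                off = t_pos - pair.insert_interval[0]
                if any(abs(off - o) < config.offset_min_diff for o in offsets):
                    continue
                offsets.append(off)
            chosen.append(pair)
            ivals.extend(p_ivals)
            if len(chosen) == n_amplicons:
                break
        return chosen

    chosen = _greedy(offset_rule=True)
    if len(chosen) < n_amplicons:
        chosen = _greedy(offset_rule=False)
    if len(chosen) < n_amplicons:
        raise PanelInfeasibleError(n_amplicons, len(chosen))

    amplicons = [
        _amplicon_from_pair(f"amp{i + 1:02d}", contig, pair, ref_seq)
        for i, pair in enumerate(chosen)
    ]
    return PanelDesign(amplicons=amplicons, target=target, config=config)


def _amplicon_from_pair(
    amp_id: str, contig: str, pair: PrimerPair, ref_seq: str
) -> AmpliconSet:
    s, e = pair.amplicon_interval
    return AmpliconSet(
        id=amp_id,
        contig=contig,
        forward=pair.forward,
        reverse=pair.reverse,
        amplicon_ref=ref_seq[s:e].upper(),
    )


# ---------------------------------------------------------------------------
# in-silico PCR uniqueness check


def _primer_hits(primer: str, enc_ref: np.ndarray) -> np.ndarray:
    """Start positions where the primer anneals under the mismatch rule:
    <=1 mismatch outside the 3'-terminal 5 nt and none within it."""
    L = len(primer)
    n = len(enc_ref) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=int)
    enc_p = encode(primer)
    mm_body = np.zeros(n, dtype=np.int32)
    mm_tail = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism = enc_ref[j : j + n] != enc_p[j]
        if j >= L - 5:
            mm_tail += mism
        else:
            mm_body += mism
    return np.nonzero((mm_tail == 0) & (mm_body <= 1))[0]


def check_uniqueness(
    pair: PrimerPair | AmpliconSet,
    references: dict[str, str] | list[str] | str,
    max_product: int | None = None,
    config: DesignConfig | None = None,
) -> bool:
    """True iff the primer pair forms exactly one in-silico PCR product.

    A product is any pairing of a plus-strand annealing site with a
    downstream minus-strand annealing site (either primer may provide
    either site) with product length <= 2x the configured amplicon
    maximum. Annealing tolerates one mismatch outside the 3'-terminal
    5 nt and none within it.
    """
    config = config or DesignConfig()
    if max_product is None:
        max_product = 2 * config.amplicon_max
    if isinstance(references, str):
        references = [references]
    seqs = references.values() if isinstance(references, dict) else references

    fwd_seq = pair.forward.seq
    rev_seq = pair.reverse.seq
    n_products = 0
    for ref in seqs:
        enc_plus = encode(ref.upper())
        # a primer anneals to the minus strand where its reverse complement
        # matches the plus strand
        plus_sites = []  # (start, len) of extension-rightward sites
        minus_sites = []  # (end, len) of extension-leftward sites, plus-strand coords
        for primer in (fwd_seq, rev_seq):
            for s in _primer_hits(primer, enc_plus):
                plus_sites.append(int(s))
            rc = encode(revcomp(primer))
            # 3' end of the minus-strand-annealed primer maps to the LEFT end
            # of the rc match on the plus strand; mismatch rule must be applied
            # on the primer orientation = reversed window
            minus_sites.extend(int(s) + len(primer) for s in _rc_hits(primer, enc_plus))
        for s in plus_sites:
            for e in minus_sites:
                if e > s and e - s <= max_product:
                    n_products += 1
                    if n_products > 1:
                        return False
    return n_products == 1


def _rc_hits(primer: str, enc_ref: np.ndarray) -> np.ndarray:
    """Plus-strand start positions where revcomp(primer) matches under the
    3'-anchored rule (the primer's 3' 5 nt map to the window's start)."""
    rc = revcomp(primer)
    L = len(rc)
    n = len(enc_ref) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=int)
    enc_p = encode(rc)
    mm_body = np.zeros(n, dtype=np.int32)
    mm_tail = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism = enc_ref[j : j + n] != enc_p[j]
        if j < 5:  # window start = primer 3' terminus
            mm_tail += mism
        else:
            mm_body += mism
    return np.nonzero((mm_tail == 0) & (mm_body <= 1))[0]


# ---------------------------------------------------------------------------
# tagging


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Sample ``n`` barcodes with pairwise Hamming distance >= 4, so that
    demultiplexing at <=3 mismatches cannot confuse two amplicons."""
    out: list[np.ndarray] = []
    for _ in range(200_000):
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != b).sum()) >= 4 for b in out):
            out.append(cand)
            if len(out) == n:
                return ["".join("ACGT"[i] for i in b) for b in out]
    raise TaggingError(f"barcode pool exhausted after sampling for {n} codes")


def attach_tags(
    panel: PanelDesign, platform: str = "ion", seed: int = 0
) -> PanelDesign:
    """Assign per-amplicon barcodes, a UMI scheme and platform adapters.

    Returns a new PanelDesign; the input is not modified.
    """
    if platform not in ADAPTERS:
        raise ValueError(f"unknown platform {platform!r}")
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(len(panel.amplicons), panel.config.barcode_len, rng)
    umi_len = panel.config.umi_len
    if umi_len is None:
        umi_len = UMI_LENGTHS[platform]
    tagged = [
        replace_amplicon(a, barcode=bc, umi_scheme=umi_len, adapters=ADAPTERS[platform])
        for a, bc in zip(panel.amplicons, barcodes)
    ]
    return PanelDesign(
        amplicons=tagged, target=panel.target, region=panel.region, config=panel.config
    )


def replace_amplicon(a: AmpliconSet, **kw) -> AmpliconSet:
    return replace(a, **kw)


# ---------------------------------------------------------------------------
# tiling mode


def design_tiling_panel(
    ref_seq: str,
    region: tuple[int, int],
    config: DesignConfig | None = None,
    known_variants: list[TargetVariant] | None = None,
    contig: str = "locus",
) -> PanelDesign:
    """Tile ``region`` (0-based half-open) so that every base is covered by
    >= ``config.tiling_coverage`` amplicon inserts whose primer binding
    sites are mutually non-overlapping wherever the amplicons overlap.

    The reference must extend past the region on both sides so that
    flanking primer sites exist. Amplicons obey ``tiling_amplicon_max``
    (length including primers). Degenerate regions shorter than a single
    insert are covered by a stack of whole-region amplicons; if even one
    covering amplicon cannot be placed a TilingInfeasibleError lists the
    uncovered intervals.
    """
    config = config or DesignConfig()
    masked = mask_reference(ref_seq, known_variants or [], None) if known_variants else ref_seq.upper()
    start, end = region
    if not (0 <= start < end <= len(ref_seq)):
        raise CoordinateError(f"region {region} outside reference")
    reach = config.tiling_amplicon_max
    wins = sorted(_primer_windows(masked, start - reach, end + reach, config))
    if not wins:
        raise TilingInfeasibleError([(start, end)])

    L = end - start
    cvg = config.tiling_coverage
    # chosen tiles as (fwd_window, rev_window); primers of two tiles must be
    # disjoint whenever their inserts share covered bases (a covering group)
    chosen: list[tuple] = []

    def pair_ok(fwd_w, rev_w) -> bool:
        f_iv, r_iv = (fwd_w[0], fwd_w[1]), (rev_w[0], rev_w[1])
        ins = (fwd_w[1], rev_w[0])
        for f2, r2 in chosen:
            if _overlap(ins, (f2[1], r2[0])):
                for a in (f_iv, r_iv):
                    if _overlap(a, (f2[0], f2[1])) or _overlap(a, (r2[0], r2[1])):
                        return False
        return True

    def place(x: int, cap: int | None):
        """Place a tile whose insert covers ``x``, extending as far right as
        the length bound allows (or to ``cap`` for the staggered first tile
        of a phase). Progressive relaxation: prefer full-length tiles and
        nearby forward sites, fall back to shorter tiles when crowded."""
        for back, lo_len in (
            (54, config.amplicon_min),
            (54, 120),
            (90, 40),
            (150, 40),
            (reach - 60, 40),
        ):
            fwd_opts = sorted(
                (w for w in wins if x - back <= w[1] <= x),
                key=lambda w: (x - w[1], w[1] - w[0], abs(w[2] - config.tm_target)),
            )
            for fw in fwd_opts:
                rev_opts = [
                    w
                    for w in wins
                    if w[0] > max(x, fw[1])
                    and w[1] <= fw[0] + reach
                    and w[1] - fw[0] >= lo_len
                ]
                if cap is not None:
                    rev_opts = [w for w in rev_opts if cap - 30 <= w[0] <= cap + 10]
                rev_opts.sort(
                    key=lambda w: (-w[0], w[1] - w[0], abs(w[2] - config.tm_target))
                )
                for rv in rev_opts:
                    if pair_ok(fw, rv):
                        chosen.append((fw, rv))
                        return rv[0]
        return None

    def coverage() -> np.ndarray:
        cov = np.zeros(L, dtype=int)
        for fw, rv in chosen:
            cov[np.clip(fw[1] - start, 0, L) : np.clip(rv[0] - start, 0, L)] += 1
        return cov

    # One tiling phase per unit of coverage; phases advance left to right,
    # always extending the phase that currently reaches least far. The first
    # tile of phase p is capped to end ~ (p+1) * step into the region so the
    # phases interleave with staggered boundaries.
    step = (reach - 2 * 22) // cvg
    front = [start] * cvg
    first_cap = [start + (p + 1) * step for p in range(cvg)]
    failures = 0
    while failures <= 8 * cvg:
        p = int(np.argmin(front))
        if front[p] >= end:
            break
        x = front[p]
        cap = first_cap[p] if x == start else None
        got = place(x, cap)
        if got is None and cap is not None:
            got = place(x, None)
        if got is None:
            failures += 1
            front[p] = x + step  # leave a hole for the patch pass
        else:
            front[p] = got

    # Patch pass: fill residual under-covered stretches.
    for _ in range(12 * cvg):
        cov = coverage()
        under = np.nonzero(cov < cvg)[0]
        if under.size == 0:
            break
        if place(start + int(under[0]), None) is None:
            break
    cov = coverage()
    if (cov < cvg).any():
        raise TilingInfeasibleError(_runs(np.nonzero(cov < cvg)[0], start))

    chosen.sort(key=lambda t: (t[0][0], t[1][0]))
    amplicons = []
    for i, (fw, rv) in enumerate(chosen):
        f = PrimerCandidate(masked[fw[0] : fw[1]], fw[0], fw[1], "+", fw[2])
        r = PrimerCandidate(revcomp(masked[rv[0] : rv[1]]), rv[0], rv[1], "-", rv[2])
        score = abs(fw[2] - config.tm_target) + abs(rv[2] - config.tm_target)
        amplicons.append(
            _amplicon_from_pair(f"tile{i + 1:02d}", contig, PrimerPair(f, r, score), ref_seq)
        )
    return PanelDesign(amplicons=amplicons, region=region, config=config)


def _runs(idx: np.ndarray, offset: int) -> list[tuple[int, int]]:
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return [(offset + int(s), offset + int(e) + 1) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# top-level known-variant design


def design_panel(
    ref_seq: str,
    target: TargetVariant,
    known_variants: list[TargetVariant] | None = None,
    config: DesignConfig | None = None,
    platform: str = "ion",
    seed: int = 0,
    require_unique: bool = True,
    contig: str | None = None,
) -> PanelDesign:
    """Full known-variant design: mask, enumerate, select, verify, tag."""
    config = config or DesignConfig()
    known_variants = known_variants or []
    contig = contig or target.contig
    masked = mask_reference(ref_seq, known_variants, target, config.mask_flank)
    candidates = enumerate_candidates(masked, target, config)
    # verify in-silico uniqueness lazily: only the pairs actually selected are
    # checked, and any failure is excluded before re-selecting
    rejected: set[PrimerPair] = set()
    while True:
        pool = [c for c in candidates if c not in rejected]
        panel = select_nonoverlapping(
            pool, config.n_amplicons, ref_seq, target, config, contig=contig
        )
        if not require_unique:
            break
        bad = [
            pair
            for pair in zip_panel_pairs(pool, panel)
            if not check_uniqueness(pair, ref_seq, config=config)
        ]
        if not bad:
            break
        rejected.update(bad)
    return attach_tags(panel, platform=platform, seed=seed)


def zip_panel_pairs(candidates: list[PrimerPair], panel: PanelDesign):
    """Recover the PrimerPair behind each selected amplicon (by primer
    coordinates), preserving panel order."""
    by_key = {(c.forward.start, c.forward.end, c.reverse.start, c.reverse.end): c for c in candidates}
    for a in panel.amplicons:
        key = (a.forward.start, a.forward.end, a.reverse.start, a.reverse.end)
        yield by_key[key]
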