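"""Pooling, significance testing and consensus calling of allele fractions.

Each amplicon yields an independent AAF measurement of the same variant;
the call pools them into a mean with a 95% confidence interval (Student
t, n-1 df) and tests the measurements against the amplicon-specific
background error estimated from flanking positions. A variant is
*detected* when the Welch two-sample t-test against the pooled flanking
fractions is significant (p < 0.05) AND the CI lower bound clears the
background error rate — both halves of the rule must agree, which is
deliberately conservative.

Novel-variant scanning uses a k-of-n consensus: sequencing/PCR artifacts
are random across independent amplicons, so requiring an allele to rise
above background in most amplicons (3 of 4 by default) suppresses false
positives without per-position multiple-testing corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import AmpliconSet, PanelDesign, TargetVariant
from .dna import BASES
from .quantify import (
    AlleleCountTable,
    FlankObservation,
    MIN_FLANK_POSITIONS,
    NotCoveredError,
    background_stats,
    flanking_error,
    variant_aaf,
)

_ALLELE_IDX = {b: i for i, b in enumerate(BASES)}

P_THRESHOLD = 0.05
# The CI lower bound must clear background mean + this many background SDs.
# 0 = the CI must exclude the background error rate itself; raising it (e.g.
# to 2) buys extra specificity at a real cost in detection limit, because at
# high depth the across-position background SD is dominated by counting
# noise ~ sqrt(bg/depth).
CI_BACKGROUND_SDS = 0.0
SCAN_BACKGROUND_SDS = 3.0  # per-amplicon support threshold in consensus scan
CONSENSUS_MIN_FRACTION = 3.0 / 4.0
DROPOUT_RELATIVE = 0.5  # >50% relative deviation from the others' median
PHASE_CIS_FRACTION = 0.9
MIN_INFORMATIVE_READS = 10


@dataclass
class AafCall:
    """Pooled per-target result across amplicons."""

    target: TargetVariant | None
    amplicon_ids: list[str]
    aafs: list[float]
    depths: list[int]
    mean_aaf: float
    ci95: tuple[float, float]  # (nan, nan) when undefined (n = 1)
    background_mean: float
    background_sd: float
    background_n: int
    p_value: float
    verdict: str  # {detected, not_detected, low_confidence}
    flags: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConsensusCall:
    offset: int  # insert-relative scan coordinate (genomic 0-based pos below)
    pos: int
    allele: str
    aafs: dict[str, float]
    n_supporting: int
    n_covering: int
    called: bool


@dataclass(frozen=True)
class PhaseResult:
    verdict: str  # {cis, trans, undetermined}
    cis_support: int
    trans_support: int
    n_informative: int
    reason: str | None = None


def summarize_aaf(per_amplicon_aafs: list[float]) -> tuple[float, tuple[float, float]]:
    """Mean and Student-t 95% CI of per-amplicon AAFs.

    With a single amplicon no spread is estimable: the CI is (nan, nan)
    and callers must fall back to a binomial interval.
    """
    vals = np.asarray(per_amplicon_aafs, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no AAF values to summarize")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, (float("nan"), float("nan"))
    half = stats.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
    return mean, (mean - float(half), mean + float(half))


def welch_t_test(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Welch p-value for mean(a) > mean(b)."""
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def significance_test(
    per_amplicon_aafs: list[float],
    flank_observations: list[FlankObservation],
    depths: list[int] | None = None,
    background_mode: str = "pooled",
) -> tuple[float, str, dict]:
    """Test per-amplicon AAFs against the pooled flanking background.

    Returns (p_value, verdict, flags). Verdict is ``detected`` iff the
    Welch test is significant at 0.05 AND the 95% CI lower bound exceeds
    the background error rate (mean + ``CI_BACKGROUND_SDS`` SDs). A
    single amplicon cannot support the t-based rule; its verdict comes
    from a binomial (Clopper-Pearson) CI on the alt count instead and is
    flagged ``single_amplicon``.
    """
    flags: dict = {}
    aafs = np.asarray(per_amplicon_aafs, dtype=float)
    aafs = aafs[~np.isnan(aafs)]
    if aafs.size == 0:
        raise ValueError("no per-amplicon AAFs supplied")
    bg_mean, bg_sd, bg_n = background_stats(flank_observations, mode=background_mode)
    if bg_n == 0:
        return float("nan"), "low_confidence", {"no_background": True}
    if bg_n < MIN_FLANK_POSITIONS:
        flags["truncated_flank"] = True

    bg_vals = np.array(
        [
            o.nonref_fraction if background_mode == "pooled" else o.alt_fraction
            for o in flank_observations
            if not o.excluded
        ]
    )
    bg_vals = bg_vals[~np.isnan(bg_vals)]
    threshold = bg_mean + CI_BACKGROUND_SDS * bg_sd

    if aafs.size == 1:
        flags["single_amplicon"] = True
        if depths is None or not depths:
            return float("nan"), "low_confidence", flags
        k = int(round(aafs[0] * depths[0]))
        ci = stats.binomtest(k, depths[0]).proportion_ci(0.95)
        verdict = "detected" if ci.low > threshold else "not_detected"
        return float("nan"), verdict, flags

    p = welch_t_test(aafs, bg_vals)
    _, (ci_low, _) = summarize_aaf(list(aafs))
    verdict = "detected" if (p < P_THRESHOLD and ci_low > threshold) else "not_detected"
    return p, verdict, flags


def call_target(
    tables: dict[str, AlleleCountTable],
    panel: PanelDesign,
    target: TargetVariant | None = None,
    germline_sites: set[int] | None = None,
    flank: int = 50,
    background_mode: str = "pooled",
    exclude_dropout: bool = False,
) -> AafCall:
    """Full per-target call: per-amplicon AAFs, pooled stats, verdict."""
    target = target or panel.target
    if target is None:
        raise ValueError("no target variant supplied")
    amp_ids, aafs, depths = [], [], []
    flanks: list[FlankObservation] = []
    flags: dict = {}
    for amp in panel.amplicons:
        table = tables.get(amp.id)
        if table is None:
            continue
        try:
            aaf, depth = variant_aaf(table, target)
        except NotCoveredError:
            flags.setdefault("not_covered", []).append(amp.id)
            continue
        amp_ids.append(amp.id)
        aafs.append(aaf)
        depths.append(depth)
        flanks.extend(flanking_error(table, target, flank, germline_sites))
    if not aafs:
        raise NotCoveredError("target not covered by any amplicon")

    if exclude_dropout and len(aafs) >= 3:
        dropped = detect_dropout(dict(zip(amp_ids, aafs)), panel)
        if dropped:
            flags["dropout"] = sorted(dropped)
            keep = [i for i, a in enumerate(amp_ids) if a not in dropped]
            amp_ids = [amp_ids[i] for i in keep]
            aafs = [aafs[i] for i in keep]
            depths = [depths[i] for i in keep]

    mean, ci = summarize_aaf(aafs)
    if len(aafs) == 1:
        flags["single_amplicon"] = True
    p, verdict, sflags = significance_test(aafs, flanks, depths, background_mode)
    flags.update(sflags)
    bg_mean, bg_sd, bg_n = background_stats(flanks, mode=background_mode)
    return AafCall(
        target=target,
        amplicon_ids=amp_ids,
        aafs=aafs,
        depths=depths,
        mean_aaf=mean,
        ci95=ci,
        background_mean=bg_mean,
        background_sd=bg_sd,
        background_n=bg_n,
        p_value=p,
        verdict=verdict,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# novel-variant consensus scan


def consensus_scan(
    tables: dict[str, AlleleCountTable],
    min_fraction: float = CONSENSUS_MIN_FRACTION,
    support_sds: float = SCAN_BACKGROUND_SDS,
    emit_all: bool = False,
) -> list[ConsensusCall]:
    """Scan every position covered by >=2 amplicons for non-reference
    alleles supported above background in >= ``min_fraction`` of the
    covering amplicons.

    An amplicon supports an allele at a position when the allele's
    fraction exceeds that amplicon's background mean + ``support_sds``
    SDs, where the background is the amplicon-wide per-position
    non-reference fraction distribution (leaving the scanned position
    out). Calls are returned for every (position, allele) with at least
    one supporting amplicon if ``emit_all``, else only consensus calls.
    """
    tabs = list(tables.values())
    if len(tabs) < 2:
        raise ValueError("consensus scan requires >=2 amplicons")
    # amplicon-level background over insert positions; kept as sufficient
    # statistics so each scanned position can be left out of its own
    # background (a real high-fraction allele must not lift its threshold)
    bg_stats: dict[str, tuple[int, float, float]] = {}
    nonref_arr: dict[str, np.ndarray] = {}
    for t in tabs:
        arr = t.nonref_fraction()
        nonref_arr[t.amplicon_id] = arr
        vals = arr[~np.isnan(arr)]
        bg_stats[t.amplicon_id] = (
            int(vals.size),
            float(vals.sum()),
            float((vals**2).sum()),
        )

    def loo_background(amp_id: str, value: float) -> tuple[float, float]:
        n, s1, s2 = bg_stats[amp_id]
        if n < 3 or np.isnan(value):
            n_, mean = n, s1 / max(n, 1)
            var = max(0.0, (s2 - n * mean**2) / max(n - 1, 1))
            return mean, float(np.sqrt(var))
        m = n - 1
        mean = (s1 - value) / m
        var = max(0.0, ((s2 - value**2) - m * mean**2) / (m - 1))
        return mean, float(np.sqrt(var))

    depth_arr = {t.amplicon_id: t.depth for t in tabs}
    lo = min(t.insert_start for t in tabs)
    hi = max(t.insert_start + len(t) for t in tabs)
    out: list[ConsensusCall] = []
    for pos in range(lo, hi):
        covering = [
            t
            for t in tabs
            if t.insert_start <= pos < t.insert_start + len(t)
            and depth_arr[t.amplicon_id][pos - t.insert_start] > 0
        ]
        if len(covering) < 2:
            continue
        ref_base = covering[0].insert_ref[pos - covering[0].insert_start]
        for allele in BASES:
            if allele == ref_base:
                continue
            aafs: dict[str, float] = {}
            n_sup = 0
            for t in covering:
                off = pos - t.insert_start
                frac = t.acgt[_ALLELE_IDX[allele], off] / depth_arr[t.amplicon_id][off]
                aafs[t.amplicon_id] = float(frac)
                nonref_here = float(nonref_arr[t.amplicon_id][off])
                mean_b, sd_b = loo_background(t.amplicon_id, nonref_here)
                if frac > mean_b + support_sds * sd_b:
                    n_sup += 1
            called = n_sup / len(covering) >= min_fraction
            if called or (emit_all and n_sup > 0):
                out.append(
                    ConsensusCall(
                        offset=pos - lo,
                        pos=pos,
                        allele=allele,
                        aafs=aafs,
                        n_supporting=n_sup,
                        n_covering=len(covering),
                        called=called,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# allelic dropout


def detect_dropout(
    per_amplicon_aafs: dict[str, float],
    panel: PanelDesign | None = None,
    known_variants: list[TargetVariant] | None = None,
) -> dict[str, str]:
    """Flag amplicons whose AAF is dramatically skewed against the others.

    An amplicon is flagged when its AAF deviates from the median of the
    remaining amplicons by more than 50% (relative) AND falls outside
    the others' 95% CI. A known variant under one of the amplicon's
    primers is annotated as the likely cause (polymorphism interfering
    with primer binding).
    """
    if len(per_amplicon_aafs) < 3:
        raise ValueError("dropout detection requires >=3 amplicons")
    flagged: dict[str, str] = {}
    amp_by_id = {a.id: a for a in panel.amplicons} if panel else {}
    for amp_id, aaf in per_amplicon_aafs.items():
        others = [v for k, v in per_amplicon_aafs.items() if k != amp_id]
        med = float(np.median(others))
        if med == 0:
            continue
        rel = abs(aaf - med) / med
        if rel <= DROPOUT_RELATIVE:
            continue
        _, (lo, hi) = summarize_aaf(others)
        if not (np.isnan(lo) or aaf < lo or aaf > hi):
            continue
        reason = "skewed_aaf"
        amp = amp_by_id.get(amp_id)
        if amp is not None and known_variants:
            for v in known_variants:
                s, e = v.span
                for p in (amp.forward, amp.reverse):
                    if s < p.end and p.start < e:
                        reason = f"variant_in_primer:{v.contig}:{v.pos}"
        flagged[amp_id] = reason
    return flagged


# ---------------------------------------------------------------------------
# phasing


def phase_with_germline(
    alignments: dict[str, list],
    panel: PanelDesign,
    target: TargetVariant,
    germline: TargetVariant,
    min_informative: int = MIN_INFORMATIVE_READS,
    min_base_q: int = 20,
) -> PhaseResult:
    """Determine cis/trans arrangement of a mosaic variant with a nearby
    germline variant from read co-occurrence.

    Informative reads are pass-filter reads covering both positions and
    carrying the mosaic alternate allele; the call is cis when >=90% of
    them also carry the germline alternate, trans when <=10% do.
    Amplicons whose inserts do not contain both sites are excluded.
    """
    t_pos = target.span[0]
    g_pos = germline.span[0]
    cis = trans = 0
    any_amp = False
    for amp in panel.amplicons:
        if not (
            amp.contains_in_insert(target.span) and amp.contains_in_insert(germline.span)
        ):
            continue
        any_amp = True
        for aln in alignments.get(amp.id, []):
            bt = _base_at(aln, amp, t_pos, min_base_q)
            bg_ = _base_at(aln, amp, g_pos, min_base_q)
            if bt is None or bg_ is None:
                continue
            if bt != target.alt:
                continue
            if bg_ == germline.alt:
                cis += 1
            elif bg_ == germline.ref:
                trans += 1
    n = cis + trans
    if not any_amp:
        return PhaseResult("undetermined", 0, 0, 0, reason="no_amplicon_covers_both")
    if n < min_informative:
        return PhaseResult("undetermined", cis, trans, n, reason="too_few_informative")
    frac = cis / n
    if frac >= PHASE_CIS_FRACTION:
        return PhaseResult("cis", cis, trans, n)
    if frac <= 1 - PHASE_CIS_FRACTION:
        return PhaseResult("trans", cis, trans, n)
    return PhaseResult("undetermined", cis, trans, n, reason="mixed_support")


def _base_at(aln, amp: AmpliconSet, genome_pos0: int, min_base_q: int) -> str | None:
    """Read base aligned to a reference position, or None if not covered
    (or below quality / deleted)."""
    local = genome_pos0 - amp.start
    ref_pos, read_pos = aln.aln_start, 0
    for op, ln in aln.ops:
        if op in ("M", "X"):
            if ref_pos <= local < ref_pos + ln:
                k = local - ref_pos
                if aln.read.qualities[read_pos + k] < min_base_q:
                    return None
                return aln.read.bases[read_pos + k]
            ref_pos += ln
            read_pos += ln
        elif op == "D":
            if ref_pos <= local < ref_pos + ln:
                return None
            ref_pos += ln
        else:
            read_pos += ln
    return None


# ---------------------------------------------------------------------------
# dilution-series evaluation


@dataclass
class SeriesReport:
    true_aafs: np.ndarray
    measured: np.ndarray  # pooled mean per point
    per_amplicon: dict[str, np.ndarray]
    verdicts: list[str]
    r_squared: float
    slope: float
    intercept: float
    per_amplicon_r2: dict[str, float]
    lowest_detected: float | None  # smallest true AAF with verdict 'detected'
    lowest_any_amplicon: float | None  # smallest AAF seen above background by >=1 amplicon


def evaluate_series(
    true_aafs: list[float],
    calls: list[AafCall],
    support_sds: float = SCAN_BACKGROUND_SDS,
) -> SeriesReport:
    """Regress measured on expected AAF over a dilution series.

    Reports pooled and per-amplicon R^2 (least squares), per-point
    verdicts, the smallest significantly detected AAF and the smallest
    AAF registered above background (mean + 3 SD) by at least one
    amplicon.
    """
    if len(true_aafs) != len(calls):
        raise ValueError("one call per series point required")
    if len(true_aafs) < 3:
        raise ValueError("series evaluation requires >=3 points")
    x = np.asarray(true_aafs, dtype=float)
    y = np.array([c.mean_aaf for c in calls])
    fit = stats.linregress(x, y)
    amp_ids = sorted({a for c in calls for a in c.amplicon_ids})
    per_amp: dict[str, np.ndarray] = {}
    per_r2: dict[str, float] = {}
    for amp_id in amp_ids:
        vals = np.array(
            [
                c.aafs[c.amplicon_ids.index(amp_id)] if amp_id in c.amplicon_ids else np.nan
                for c in calls
            ]
        )
        per_amp[amp_id] = vals
        ok = ~np.isnan(vals)
        if ok.sum() >= 3:
            per_r2[amp_id] = float(stats.linregress(x[ok], vals[ok]).rvalue ** 2)

    verdicts = [c.verdict for c in calls]
    detected = [t for t, c in zip(true_aafs, calls) if c.verdict == "detected"]
    above_bg = [
        t
        for t, c in zip(true_aafs, calls)
        if any(
            a > c.background_mean + support_sds * c.background_sd for a in c.aafs
        )
    ]
    return SeriesReport(
        true_aafs=x,
        measured=y,
        per_amplicon=per_amp,
        verdicts=verdicts,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        per_amplicon_r2=per_r2,
        lowest_detected=min(detected) if detected else None,
        lowest_any_amplicon=min(above_bg) if above_bg else None,
    )
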