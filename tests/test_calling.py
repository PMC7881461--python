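"""Pooling, significance, consensus, dropout, phasing, series regression."""

import math

import numpy as np
import pytest

from mippseq.calling import (
    call_target,
    consensus_scan,
    detect_dropout,
    evaluate_series,
    phase_with_germline,
    significance_test,
    summarize_aaf,
    welch_t_test,
)
from mippseq.design import PanelDesign, TargetVariant
from mippseq.quantify import AlleleCountTable, FlankObservation
from mippseq.simulate import ErrorModel, simulate_amplicon_reads, simulate_counts
from mippseq.readproc import process_reads


def _flanks(values, alt=None):
    return [
        FlankObservation(offset=i, ref_base="A", nonref_fraction=v,
                         alt_fraction=alt[i] if alt else v / 3, depth=10_000)
        for i, v in enumerate(values)
    ]


class TestSummarize:
    def test_constant_values_zero_width(self):
        mean, (lo, hi) = summarize_aaf([0.5, 0.5, 0.5])
        assert mean == 0.5 and lo == hi == 0.5

    def test_closed_form_t_interval(self):
        """[0.01, 0.02, 0.03]: half-width = t(0.975,2) * sd / sqrt(3)."""
        mean, (lo, hi) = summarize_aaf([0.01, 0.02, 0.03])
        assert mean == pytest.approx(0.02)
        half = 4.302652729911275 * 0.01 / math.sqrt(3)
        assert hi - mean == pytest.approx(half, rel=1e-9)
        assert mean - lo == pytest.approx(half, rel=1e-9)

    def test_single_value_undefined_interval(self):
        mean, (lo, hi) = summarize_aaf([0.5])
        assert mean == 0.5 and math.isnan(lo) and math.isnan(hi)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_aaf([])


class TestWelch:
    def test_matches_closed_form_oracle(self):
        """One-sided Welch p-value from the textbook formula, to 1e-10."""
        from scipy import stats as ss

        rng = np.random.default_rng(1)
        a = np.array([2.8e-4, 2.6e-4, 3.0e-4])
        b = rng.normal(7e-5, 3e-5, 100)
        p = welch_t_test(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p_oracle = float(ss.t.sf(t, df))
        assert p == pytest.approx(p_oracle, abs=1e-10)


class TestSignificance:
    def test_all_zero_not_detected(self):
        p, verdict, _ = significance_test([0.0, 0.0, 0.0], _flanks([0.0] * 100))
        assert verdict == "not_detected"

    def test_separated_by_orders_of_magnitude_detected(self):
        rng = np.random.default_rng(0)
        bg = list(np.abs(rng.normal(1e-4, 3e-5, 100)))
        p, verdict, _ = significance_test([0.5, 0.5, 0.49], _flanks(bg))
        # with n=3 amplicons the Welch df ~ 2 bounds how small p can get;
        # orders-of-magnitude separation still gives p far below 0.05
        assert verdict == "detected" and p < 1e-3

    def test_all_flanks_excluded_low_confidence(self):
        obs = [
            FlankObservation(offset=i, ref_base="A", nonref_fraction=0.0,
                             alt_fraction=0.0, depth=0, excluded=True,
                             reason="germline")
            for i in range(10)
        ]
        p, verdict, flags = significance_test([0.01, 0.01, 0.01], obs)
        assert verdict == "low_confidence"

    def test_single_amplicon_uses_binomial_ci(self):
        rng = np.random.default_rng(0)
        bg = list(np.abs(rng.normal(1e-4, 3e-5, 100)))
        p, verdict, flags = significance_test([0.01], _flanks(bg), depths=[10_000])
        assert flags.get("single_amplicon")
        assert verdict == "detected"

    def test_verdict_monotone_in_aaf(self):
        """Raising every per-amplicon AAF never flips detected -> not."""
        rng = np.random.default_rng(2)
        bg = list(np.abs(rng.normal(1e-4, 3e-5, 100)))
        prev_detected = False
        for scale in (0.5, 1, 2, 5, 20, 100):
            aafs = [scale * 2e-4, scale * 2.2e-4, scale * 1.9e-4]
            _, verdict, _ = significance_test(aafs, _flanks(bg))
            if prev_detected:
                assert verdict == "detected"
            prev_detected = prev_detected or verdict == "detected"
        assert prev_detected  # the largest signal is certainly detected


class TestConsensusScan:
    def _tables(self, panel, target, aaf, seed, n=4, depth=10_000):
        amps = panel.amplicons[:n]
        alt = int(aaf * 10_000)
        return {
            a.id: simulate_counts(a, target, alt, 10_000 - alt, depth,
                                  ErrorModel(), np.random.default_rng(seed + i))
            for i, a in enumerate(amps)
        }

    def test_strong_allele_called_by_all(self, panel, target):
        tables = self._tables(panel, target, 0.10, seed=1, n=3)
        calls = [c for c in consensus_scan(tables) if c.called]
        assert any(c.pos == target.span[0] and c.allele == target.alt for c in calls)
        hit = next(c for c in calls if c.pos == target.span[0])
        assert hit.n_supporting == hit.n_covering == 3

    def test_three_of_four_rule(self):
        """Synthetic tables: allele above background in exactly k amplicons
        is called iff k/4 >= 3/4."""
        ref = "ACGT" * 64
        for k, expect in ((2, False), (3, True), (4, True)):
            tables = {}
            for i in range(4):
                t = AlleleCountTable(f"a{i}", ref, 0)
                t.acgt["ACGT".index(ref[0]), :] = 10_000  # wrong for non-A cols
                for off, b in enumerate(ref):
                    t.acgt[:, off] = 0
                    t.acgt["ACGT".index(b), off] = 10_000
                # background noise: a few scattered errors
                rng = np.random.default_rng(i)
                for off in rng.integers(0, len(ref), 40):
                    b = ref[off]
                    alt = "ACGT"[("ACGT".index(b) + 1) % 4]
                    t.acgt["ACGT".index(alt), off] += 1
                    t.acgt["ACGT".index(b), off] -= 1
                if i < k:  # signal amplicons
                    t.acgt["ACGT".index("C" if ref[100] != "C" else "G"), 100] += 50
                    t.acgt["ACGT".index(ref[100]), 100] -= 50
                tables[f"a{i}"] = t
            calls = [c for c in consensus_scan(tables) if c.called and c.pos == 100]
            assert bool(calls) is expect, f"k={k}"

    def test_mutation_free_input_yields_no_calls(self, panel, target):
        """Type-I control: no consensus calls on null input in >=95% of seeds."""
        clean = 0
        n_seeds = 20
        for s in range(n_seeds):
            tables = {
                a.id: simulate_counts(a, None, 0, 10_000, 10_000, ErrorModel(),
                                      np.random.default_rng(1000 + s * 7 + i))
                for i, a in enumerate(panel.amplicons)
            }
            calls = [c for c in consensus_scan(tables, min_fraction=0.75) if c.called]
            clean += not calls
        assert clean >= 0.95 * n_seeds


class TestDropout:
    def test_skewed_amplicon_flagged(self):
        flagged = detect_dropout({"a": 0.50, "b": 0.49, "c": 0.02})
        assert set(flagged) == {"c"}

    def test_concordant_amplicons_unflagged(self):
        assert detect_dropout({"a": 0.50, "b": 0.50, "c": 0.50}) == {}

    def test_exclusion_restores_pooled_mean(self, panel, target, rng):
        """Simulated dropout: excluding the flagged amplicon moves the mean
        from ~0.337 back to ~0.495."""
        aafs = {"a": 0.50, "b": 0.49, "c": 0.02}
        assert np.mean(list(aafs.values())) == pytest.approx(0.337, abs=1e-3)
        flagged = detect_dropout(aafs)
        kept = [v for k, v in aafs.items() if k not in flagged]
        assert np.mean(kept) == pytest.approx(0.495, abs=1e-3)

    def test_requires_three_amplicons(self):
        with pytest.raises(ValueError):
            detect_dropout({"a": 0.5, "b": 0.1})


class TestPhasing:
    def _alignments(self, panel, target, germ, cis: bool, depth=120):
        amp = next(a for a in panel.amplicons
                   if a.contains_in_insert(target.span)
                   and a.contains_in_insert(germ.span))
        extra = dict(alt_extra=[germ]) if cis else dict(ref_extra=[germ])
        reads = simulate_amplicon_reads(
            amp, target, 300, 700, depth,
            ErrorModel(sub_rate=0, polymerase_rate=0, indel_rate=0),
            np.random.default_rng(3), **extra,
        )
        sub = PanelDesign(amplicons=[amp], target=target)
        aligned, _ = process_reads(reads, sub)
        return aligned

    def _germline_near(self, panel, target):
        amp = panel.amplicons[0]
        g_pos0 = target.span[0] + 12
        base = amp.insert_seq[g_pos0 - amp.insert_start]
        return TargetVariant("locus", g_pos0 + 1, base, "A" if base != "A" else "G")

    def test_cis_configuration(self, panel, target):
        germ = self._germline_near(panel, target)
        aligned = self._alignments(panel, target, germ, cis=True)
        res = phase_with_germline(aligned, panel, target, germ)
        assert res.verdict == "cis"

    def test_trans_configuration(self, panel, target):
        germ = self._germline_near(panel, target)
        aligned = self._alignments(panel, target, germ, cis=False)
        res = phase_with_germline(aligned, panel, target, germ)
        assert res.verdict == "trans"

    def test_too_few_informative_reads_undetermined(self, panel, target):
        germ = self._germline_near(panel, target)
        aligned = self._alignments(panel, target, germ, cis=True, depth=8)
        res = phase_with_germline(aligned, panel, target, germ)
        assert res.verdict == "undetermined"
        assert res.n_informative < 10

    def test_no_amplicon_covering_both(self, panel, target):
        far = TargetVariant("locus", 1, "A", "G") if panel.amplicons[0].start > 0 \
            else TargetVariant("locus", 1999, "A", "G")
        res = phase_with_germline({}, panel, target,
                                  TargetVariant("locus", 5, "A", "G")
                                  if panel.amplicons[0].start > 4 else far)
        assert res.verdict == "undetermined"
        assert res.reason == "no_amplicon_covers_both"


class TestSeries:
    def _call(self, aafs, true):
        from mippseq.calling import AafCall

        return AafCall(
            target=None, amplicon_ids=["a", "b", "c"], aafs=list(aafs),
            depths=[10_000] * 3, mean_aaf=float(np.mean(aafs)),
            ci95=(0.0, 1.0), background_mean=1e-4, background_sd=3e-5,
            background_n=100, p_value=0.01, verdict="detected", flags={},
        )

    def test_identity_series_perfect_fit(self):
        true = [0.5 / 2**k for k in range(6)]
        calls = [self._call([t, t, t], t) for t in true]
        rep = evaluate_series(true, calls)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in rep.per_amplicon_r2.values())

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            evaluate_series([0.5, 0.25], [self._call([0.5] * 3, 0.5)] * 2)

    def test_error_free_high_depth_slope_near_unity(self, panel, target, error_free):
        from mippseq.simulate import SimScenario, simulate_scenario

        true = [0.5 / 2**k for k in range(8)]
        calls = []
        for k, aaf in enumerate(true):
            sc = SimScenario(panel=panel, true_aaf=aaf, input_mass_ng=500,
                             depth_per_amplicon=20_000, error_model=error_free,
                             seed=50 + k)
            tables, _ = simulate_scenario(sc)
            calls.append(call_target(tables, panel))
        rep = evaluate_series(true, calls)
        assert 0.95 <= rep.slope <= 1.05
        assert rep.r_squared > 0.99
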