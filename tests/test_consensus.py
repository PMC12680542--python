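"""Flagging rules, per-column calling and whole-genome reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomito.alignio import (
    FORWARD,
    REVERSE,
    PileupColumn,
    PileupEntry,
    ReferenceSequence,
    build_pileup,
)
from paleomito.consensus import (
    CallingParams,
    ConfigurationError,
    DamageFlags,
    call_column,
    compare_to_truth,
    flag_polarization_free,
    flag_polarized,
    reconstruct,
)
from paleomito.damage import DamageProfile, estimate_profile
from paleomito.simulate import SimulationConfig, simulate_dataset

from oracle import OracleEntry, oracle_call


def _col(entries, ref_base="C", ref_pos=0):
    made = []
    for i, spec in enumerate(entries):
        base, orient = spec[0], spec[1]
        d5 = spec[2] if len(spec) > 2 else 10
        d3 = spec[3] if len(spec) > 3 else 20
        made.append(PileupEntry(base, orient, d5, d3, f"r{i}"))
    return PileupColumn(ref_pos, ref_base, made)


def _flags_for(col, method, ref_base=None):
    if method == "polarized":
        ref = ReferenceSequence("x", (ref_base or col.ref_base), circular=False)
        return flag_polarized([col], ref)
    return flag_polarization_free([col])


def _uniform_profile(d):
    full = np.full(25, float(d))
    return DamageProfile(25, full.copy(), full.copy(), full.copy(), full.copy(),
                         baseline_ct=float(d), baseline_ga=float(d))


class TestFlagging:
    def test_polarized_ct(self):
        col = _col([("T", FORWARD), ("C", FORWARD)], ref_base="C")
        flags = _flags_for(col, "polarized")
        assert flags.flag_ct[0] and not flags.flag_ga[0]

    def test_polarized_needs_reference_c(self):
        col = _col([("T", FORWARD)], ref_base="A")
        flags = _flags_for(col, "polarized")
        assert not flags.flag_ct[0] and not flags.flag_ga[0]

    def test_polarized_ga_reverse_only(self):
        col = _col([("A", REVERSE), ("A", FORWARD)], ref_base="G")
        assert _flags_for(col, "polarized").flag_ga[0]
        col2 = _col([("A", FORWARD)], ref_base="G")
        assert not _flags_for(col2, "polarized").flag_ga[0]

    def test_free_ct_any_orientation_c(self):
        col = _col([("T", FORWARD), ("C", REVERSE)], ref_base="A")
        assert _flags_for(col, "free").flag_ct[0]  # reference never consulted

    def test_free_requires_c_observed(self):
        col = _col([("T", FORWARD), ("T", FORWARD), ("T", REVERSE)], ref_base="C")
        flags = _flags_for(col, "free")
        assert not flags.flag_ct[0]

    def test_free_ga_analogue(self):
        col = _col([("A", REVERSE), ("G", FORWARD)], ref_base="T")
        assert _flags_for(col, "free").flag_ga[0]

    def test_damaged_positions_are_union(self):
        cols = [
            _col([("T", FORWARD), ("C", FORWARD)], ref_pos=0),
            _col([("A", REVERSE), ("G", REVERSE)], ref_pos=1),
            _col([("T", FORWARD), ("C", FORWARD), ("A", REVERSE), ("G", REVERSE)], ref_pos=2),
            _col([("A", FORWARD)], ref_pos=3),
        ]
        flags = flag_polarization_free(cols)
        assert flags.n_damaged_positions == 3


class TestCallColumn:
    def test_two_of_three_support_is_callable(self):
        col = _col([("A", FORWARD), ("A", FORWARD), ("T", REVERSE)])
        call = call_column(col, CallingParams(mode="none"))
        assert call.call == "A" and call.support == pytest.approx(2 / 3)

    def test_below_coverage_returns_n(self):
        col = _col([("A", FORWARD), ("A", FORWARD)])
        assert call_column(col, CallingParams(mode="none")).call == "N"

    def test_free_silence_drops_coverage_below_threshold(self):
        col = _col([("C", FORWARD), ("T", FORWARD), ("T", FORWARD)])
        flags = _flags_for(col, "free")
        call = call_column(col, CallingParams(mode="free_silence"), flags)
        assert flags.flag_ct[0]
        assert call.n_silenced == 2 and call.eff_cov == 1 and call.call == "N"

    def test_weighted_majority_flips_to_c(self):
        col = _col([("T", FORWARD, 0, 30), ("T", FORWARD, 0, 30), ("C", FORWARD, 0, 30)])
        flags = _flags_for(col, "free")
        call = call_column(col, CallingParams(mode="free_weight"), flags, _uniform_profile(0.7))
        assert call.eff_counts["T"] == pytest.approx(0.6)
        assert call.eff_counts["C"] == pytest.approx(1.7)
        assert call.support == pytest.approx(1.7 / 2.3)
        assert call.call == "C"

    def test_zero_damage_weighting_equals_plain_counting(self):
        col = _col([("T", FORWARD, 0, 30), ("T", FORWARD, 0, 30), ("C", FORWARD, 0, 30)])
        flags = _flags_for(col, "free")
        weighted = call_column(col, CallingParams(mode="free_weight"), flags, _uniform_profile(0.0))
        plain = call_column(col, CallingParams(mode="none"))
        assert weighted.call == plain.call == "T"

    def test_n_entries_never_count(self):
        col = _col([("A", FORWARD), ("A", FORWARD), ("A", FORWARD), ("N", FORWARD)])
        call = call_column(col, CallingParams(mode="none"))
        assert call.raw_cov == 3 and call.support == 1.0 and call.call == "A"

    def test_missing_requirements_rejected(self):
        col = _col([("A", FORWARD)] * 3)
        with pytest.raises(ConfigurationError):
            call_column(col, CallingParams(mode="free_silence"), flags=None)
        with pytest.raises(ConfigurationError):
            call_column(col, CallingParams(mode="free_weight"),
                        flags=_flags_for(col, "free"), profile=None)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CallingParams(mode="bogus")
        with pytest.raises(ValueError):
            CallingParams(min_support=0.5)
        with pytest.raises(ValueError):
            CallingParams(min_cov=0)


def _random_column(rng, size, ref_base=None):
    ref_base = ref_base or "ACGT"[rng.integers(4)]
    entries = []
    for i in range(size):
        base = "ACGTN"[rng.integers(5)]
        orient = FORWARD if rng.random() < 0.5 else REVERSE
        length = int(rng.integers(30, 50))
        d5 = int(rng.integers(length))
        entries.append(PileupEntry(base, orient, d5, length - 1 - d5, f"r{i}"))
    return PileupColumn(0, ref_base, entries)


def _realistic_profile():
    idx = np.arange(25)
    ct = 0.7 * np.exp(-idx / 3) + 0.02
    return DamageProfile(25, ct.copy(), 0.4 * np.exp(-idx / 3) + 0.02,
                         0.4 * np.exp(-idx / 3) + 0.02, ct.copy(),
                         baseline_ct=0.02, baseline_ga=0.02)


class TestAgainstOracle:
    """Dual-route check: call_column versus the brute-force tally oracle."""

    def test_sampled_columns_all_modes(self):
        rng = np.random.default_rng(42)
        profile = _realistic_profile()
        params = {m: CallingParams(mode=m) for m in
                  ("none", "pol_silence", "free_silence", "free_weight")}
        for _ in range(4000):
            col = _random_column(rng, int(rng.integers(1, 9)))
            oracle_entries = [OracleEntry(e.base, e.orientation, e.dist5, e.dist3)
                              for e in col.entries]
            for mode in params:
                method = "polarized" if mode == "pol_silence" else "free"
                flags = _flags_for(col, method)
                got = call_column(col, params[mode], flags, profile)
                want = oracle_call(oracle_entries, mode, col.ref_base, 3, 0.65, profile)
                assert got.call == want, (mode, col.ref_base, col.entries)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), size=st.integers(1, 10),
           support_lo=st.floats(0.51, 0.99))
    def test_n_calls_monotone_in_min_support(self, seed, size, support_lo):
        rng = np.random.default_rng(seed)
        col = _random_column(rng, size)
        profile = _realistic_profile()
        support_hi = min(1.0, support_lo + 0.2)
        for mode in ("none", "pol_silence", "free_silence", "free_weight"):
            method = "polarized" if mode == "pol_silence" else "free"
            flags = _flags_for(col, method)
            lo = call_column(col, CallingParams(mode=mode, min_support=support_lo),
                             flags, profile)
            hi = call_column(col, CallingParams(mode=mode, min_support=support_hi),
                             flags, profile)
            if lo.call == "N":
                assert hi.call == "N"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), size=st.integers(1, 10))
    def test_silencing_inert_at_unflagged_positions(self, seed, size):
        rng = np.random.default_rng(seed)
        col = _random_column(rng, size)
        plain = call_column(col, CallingParams(mode="none"))
        for mode in ("pol_silence", "free_silence"):
            method = "polarized" if mode == "pol_silence" else "free"
            flags = _flags_for(col, method)
            if flags.flag_ct[0] or flags.flag_ga[0]:
                continue
            assert call_column(col, CallingParams(mode=mode), flags).call == plain.call

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), size=st.integers(2, 8))
    def test_tied_top_counts_yield_n(self, seed, size):
        """A tied argmax implies support <= 0.5 < 0.65, so no tie-break rule is
        ever exercised: tied columns always come out N."""
        rng = np.random.default_rng(seed)
        col = _random_column(rng, size)
        call = call_column(col, CallingParams(mode="none"))
        counts = call.raw_counts
        if counts and list(counts.values()).count(max(counts.values())) > 1:
            assert call.call == "N"


class TestReconstruct:
    def test_clean_deep_data_reproduces_truth(self, small_ref):
        config = SimulationConfig(seed=8, target_cov=20.0, damage_amp5=0.0,
                                  damage_amp3=0.0, damage_baseline=0.0, seq_error=0.0)
        reads, truth = simulate_dataset(small_ref, config)
        result = reconstruct(build_pileup(reads, small_ref), small_ref, CallingParams())
        assert result.sequence == truth.true_genome
        assert result.summary["n_N"] == 0

    def test_uncovered_region_is_all_n(self):
        ref = ReferenceSequence("r", "ACGT" * 25, circular=False)
        reads = []
        result = reconstruct(build_pileup(reads, ref), ref, CallingParams())
        assert result.sequence == "N" * 100
        assert result.summary["n_N"] == 100
        assert result.summary["pct_N"] == 100.0

    def test_summary_counts_consistent(self, scen_dataset):
        pileup, ref, prof = (scen_dataset[k] for k in ("pileup", "ref", "profile"))
        for mode in ("none", "pol_silence", "free_silence", "free_weight"):
            res = reconstruct(pileup, ref, CallingParams(mode=mode),
                              prof if mode == "free_weight" else None)
            s = res.summary
            assert s["n_N"] == res.sequence.count("N")
            assert s["pct_N"] == pytest.approx(100.0 * s["n_N"] / ref.length)
            assert s["n_N_at_damaged"] <= min(s["n_N"], s["n_damaged_positions"])
            assert s["n_damaged_positions"] == sum(
                1 for c in res.calls if c.flagged
            )

    def test_free_weight_needs_profile(self, scen_dataset):
        with pytest.raises(ConfigurationError):
            reconstruct(scen_dataset["pileup"], scen_dataset["ref"],
                        CallingParams(mode="free_weight"), profile=None)


class TestCompareToTruth:
    def test_perfect_and_corrupted(self, small_ref):
        config = SimulationConfig(seed=8, target_cov=20.0, damage_amp5=0.0,
                                  damage_amp3=0.0, damage_baseline=0.0, seq_error=0.0,
                                  n_variants=5)
        reads, truth = simulate_dataset(small_ref, config)
        result = reconstruct(build_pileup(reads, small_ref), small_ref, CallingParams())
        report = compare_to_truth(result, truth)
        assert report.n_miscall == 0 and report.n_called == small_ref.length
        # planted variants are recovered as matches, not miscalls
        for pos, _, new in truth.variants:
            assert result.sequence[pos] == new

        # corrupt one call back to the pre-variant base: it must surface
        pos0, old_base, _ = truth.variants[0]
        result.calls[pos0].call = old_base
        result.sequence = result.sequence[:pos0] + old_base + result.sequence[pos0 + 1:]
        report2 = compare_to_truth(result, truth)
        assert pos0 in report2.miscall_positions

    def test_length_mismatch_rejected(self, scen_dataset):
        res = reconstruct(scen_dataset["pileup"], scen_dataset["ref"], CallingParams())
        with pytest.raises(ValueError):
            compare_to_truth(res, "ACGT")
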