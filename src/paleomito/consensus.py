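"""Damage flagging and consensus calling under four modes.

A confident base call requires a minimum coverage (default 3x) and a minimum
support fraction for the most frequent base (default 65%, inclusive); any
position failing either threshold is emitted as the non-informative base N.
Damage is handled in one of four ways:

``none``
    Plain coverage/frequency calling, no correction.
``pol_silence``
    Polarization-based silencing: where the *reference* shows a C, forward-read
    Ts are treated as N (and reverse-read As where the reference shows a G).
``free_silence``
    Polarization-free silencing: a position is flagged from the read stack
    alone — at least one forward-read T together with a C seen in any read
    (either orientation) — and forward-read Ts are silenced there; the G->A
    analogue applies to reverse-read As.
``free_weight``
    Polarization-free weighting: every base contributes its damage-profile
    weight to the tally (downweight putatively damaged Ts/As, upweight their
    C/G counterparts); nothing is discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from paleomito.alignio import (
    FORWARD,
    REVERSE,
    PileupColumn,
    ReferenceSequence,
)
from paleomito.damage import DamageProfile, base_weight

MODES = ("none", "pol_silence", "free_silence", "free_weight")


class ConfigurationError(ValueError):
    """A calling mode invoked without the inputs it requires."""


@dataclass(frozen=True)
class CallingParams:
    """Consensus-calling thresholds.

    Both thresholds are inclusive: a 2-of-3 column (66.7% support) is
    callable at the defaults.
    """

    mode: str = "none"
    min_cov: int = 3
    min_support: float = 0.65

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.5 < self.min_support <= 1:
            raise ValueError("min_support must lie in (0.5, 1]")


@dataclass
class DamageFlags:
    """Per-position putative-damage flags (C->T and G->A patterns)."""

    flag_ct: np.ndarray
    flag_ga: np.ndarray
    method: str  # "polarized" | "polarization_free"

    def __len__(self) -> int:
        return len(self.flag_ct)

    @property
    def any(self) -> np.ndarray:
        return self.flag_ct | self.flag_ga

    @property
    def n_damaged_positions(self) -> int:
        """Union count of positions flagged by either pattern."""
        return int(self.any.sum())


@dataclass
class ConsensusCall:
    """Audit record of one called position."""

    ref_pos: int
    ref_base: str
    call: str
    raw_cov: int
    eff_cov: float
    support: Optional[float]
    flag_ct: bool
    flag_ga: bool
    n_silenced: int
    raw_counts: dict[str, int] = field(default_factory=dict)
    eff_counts: dict[str, float] = field(default_factory=dict)

    @property
    def flagged(self) -> bool:
        return self.flag_ct or self.flag_ga


@dataclass
class ConsensusResult:
    """Called sequence plus per-position audit records and summary counts."""

    sequence: str
    calls: list[ConsensusCall]
    summary: dict

    def __post_init__(self) -> None:
        assert self.summary["n_N"] == self.sequence.count("N")


@dataclass
class AccuracyReport:
    """Consensus-versus-truth comparison on a simulated dataset."""

    n_called: int
    n_correct: int
    n_miscall: int
    n_N: int
    miscall_positions: list[int]
    miscalls_at_flagged: int

    @property
    def miscall_rate(self) -> float:
        return self.n_miscall / self.n_called if self.n_called else 0.0


def flag_polarized(pileup: list[PileupColumn], ref: ReferenceSequence) -> DamageFlags:
    """Reference-polarized damage flags.

    A position is CT-flagged when the reference base is C and at least one
    forward-mapping read shows a T there; GA-flagged when the reference base
    is G and at least one reverse-mapping read shows an A. No flag is raised
    when the reference base does not match the damage pattern.
    """
    n = len(pileup)
    flag_ct = np.zeros(n, dtype=bool)
    flag_ga = np.zeros(n, dtype=bool)
    for col in pileup:
        rb = ref.seq[col.ref_pos]
        if rb == "C":
            flag_ct[col.ref_pos] = any(
                e.base == "T" and e.orientation == FORWARD for e in col.entries
            )
        elif rb == "G":
            flag_ga[col.ref_pos] = any(
                e.base == "A" and e.orientation == REVERSE for e in col.entries
            )
    return DamageFlags(flag_ct, flag_ga, "polarized")


def flag_polarization_free(pileup: list[PileupColumn]) -> DamageFlags:
    """Damage flags from the read stack alone; the reference is never consulted.

    CT flag: at least one forward-read T and at least one C observed in any
    read regardless of orientation. GA flag: at least one reverse-read A and
    at least one G in any read.
    """
    n = len(pileup)
    flag_ct = np.zeros(n, dtype=bool)
    flag_ga = np.zeros(n, dtype=bool)
    for col in pileup:
        has_fwd_t = has_c = has_rev_a = has_g = False
        for e in col.entries:
            if e.base == "T" and e.orientation == FORWARD:
                has_fwd_t = True
            elif e.base == "C":
                has_c = True
            if e.base == "A" and e.orientation == REVERSE:
                has_rev_a = True
            elif e.base == "G":
                has_g = True
        flag_ct[col.ref_pos] = has_fwd_t and has_c
        flag_ga[col.ref_pos] = has_rev_a and has_g
    return DamageFlags(flag_ct, flag_ga, "polarization_free")


def _is_silenced(entry, ct: bool, ga: bool) -> bool:
    return (ct and entry.base == "T" and entry.orientation == FORWARD) or (
        ga and entry.base == "A" and entry.orientation == REVERSE
    )


def call_column(
    column: PileupColumn,
    params: CallingParams,
    flags: Optional[DamageFlags] = None,
    profile: Optional[DamageProfile] = None,
) -> ConsensusCall:
    """Call one pileup column under the configured mode.

    Entries with base N never count toward coverage or tallies. In silencing
    modes the coverage threshold applies to the post-silencing (effective)
    coverage; in the weighting mode the coverage gate uses the unweighted
    entry count — weights encode base-identity confidence, not molecule
    existence — while support is the weighted majority fraction.
    """
    mode = params.mode
    if mode in ("pol_silence", "free_silence") and flags is None:
        raise ConfigurationError(f"mode {mode} requires damage flags")
    if mode == "free_weight" and profile is None:
        raise ConfigurationError("mode free_weight requires a damage profile")

    informative = [e for e in column.entries if e.base != "N"]
    raw_cov = len(informative)
    raw_counts = Counter(e.base for e in informative)
    ct = bool(flags.flag_ct[column.ref_pos]) if flags is not None else False
    ga = bool(flags.flag_ga[column.ref_pos]) if flags is not None else False

    n_silenced = 0
    if mode in ("none", "pol_silence", "free_silence"):
        if mode == "none":
            surviving = informative
        else:
            surviving = [e for e in informative if not _is_silenced(e, ct, ga)]
            n_silenced = raw_cov - len(surviving)
        counts = Counter(e.base for e in surviving)
        eff_cov = float(len(surviving))
        eff_counts = {b: float(c) for b, c in counts.items()}
        total = eff_cov
        cov_ok = len(surviving) >= params.min_cov
    else:  # free_weight: nothing silenced, every entry contributes its weight
        eff_counts = {}
        for e in informative:
            eff_counts[e.base] = eff_counts.get(e.base, 0.0) + base_weight(e, profile)
        eff_cov = total = sum(eff_counts.values())
        cov_ok = raw_cov >= params.min_cov

    support: Optional[float] = None
    best: Optional[str] = None
    if total > 0:
        best = max(eff_counts, key=eff_counts.__getitem__)
        support = eff_counts[best] / total

    if cov_ok and support is not None and support >= params.min_support:
        call = best
    else:
        call = "N"

    return ConsensusCall(
        ref_pos=column.ref_pos,
        ref_base=column.ref_base,
        call=call,
        raw_cov=raw_cov,
        eff_cov=eff_cov,
        support=support,
        flag_ct=ct,
        flag_ga=ga,
        n_silenced=n_silenced,
        raw_counts=dict(raw_counts),
        eff_counts=eff_counts,
    )


def reconstruct(
    pileup: list[PileupColumn],
    ref: ReferenceSequence,
    params: CallingParams,
    profile: Optional[DamageProfile] = None,
) -> ConsensusResult:
    """Call every column and assemble the consensus with summary counts.

    Flags appropriate to the mode are computed first: the polarized mode needs
    the reference; the polarization-free modes (and mode ``none``, for
    reporting parity) flag from the read stack alone. In the weighting mode
    flags are reported but never alter calls. The summary counts damaged
    positions as the union of CT- and GA-flagged positions.
    """
    if len(pileup) != ref.length:
        raise ValueError(f"pileup has {len(pileup)} columns but reference length is {ref.length}")
    if params.mode == "pol_silence":
        flags = flag_polarized(pileup, ref)
    else:
        flags = flag_polarization_free(pileup)
    calls = [call_column(col, params, flags, profile) for col in pileup]
    sequence = "".join(c.call for c in calls)
    n_N = sequence.count("N")
    n_N_at_damaged = sum(1 for c in calls if c.call == "N" and c.flagged)
    summary = {
        "mode": params.mode,
        "n_N": n_N,
        "pct_N": 100.0 * n_N / ref.length,
        "n_damaged_positions": flags.n_damaged_positions,
        "n_N_at_damaged": n_N_at_damaged,
    }
    return ConsensusResult(sequence=sequence, calls=calls, summary=summary)


def compare_to_truth(result: ConsensusResult, truth) -> AccuracyReport:
    """Score a consensus against the simulator's true genome.

    ``truth`` is a :class:`~paleomito.simulate.SimulationTruth` (or anything
    with a ``true_genome`` string in the same coordinate system).
    """
    genome = truth.true_genome if hasattr(truth, "true_genome") else str(truth)
    if len(genome) != len(result.sequence):
        raise ValueError(
            f"consensus length {len(result.sequence)} != truth length {len(genome)}"
        )
    miscalls = []
    miscalls_flagged = 0
    n_called = n_correct = 0
    for call, true_base in zip(result.calls, genome):
        if call.call == "N":
            continue
        n_called += 1
        if call.call == true_base:
            n_correct += 1
        else:
            miscalls.append(call.ref_pos)
            if call.flagged:
                miscalls_flagged += 1
    return AccuracyReport(
        n_called=n_called,
        n_correct=n_correct,
        n_miscall=len(miscalls),
        n_N=result.summary["n_N"],
        miscall_positions=miscalls,
        miscalls_at_flagged=miscalls_flagged,
    )
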