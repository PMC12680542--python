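"""Single-stranded-library ancient-DNA read simulator with known truth.

The generative model mirrors the data this toolkit targets: short fragments
(right-skewed lengths around ~34 bp, nothing under 30 bp), heavy cytosine
deamination concentrated at both fragment ends of the original molecule
strand, uniform sequencing error, and a circular mitochondrial genome.
Molecules are drawn uniformly on the genome, assigned a mapping orientation,
and deaminated in molecule coordinates: each molecule-strand C at distance
``i`` from the 5' end and ``j`` from the 3' end becomes T with probability
``min(1, amp5*exp(-i/decay) + amp3*exp(-j/decay) + baseline)``. Reverse
molecules are emitted reverse-complemented, so their deamination appears as
G->A in reference orientation — exactly the asymmetry the calling modes
exploit. Every damage event is logged, making the simulator the oracle for
profile-recovery and consensus-accuracy tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional, Union

import numpy as np
import pysam
from scipy.optimize import brentq
from scipy.stats import norm

from paleomito.alignio import FORWARD, REVERSE, AlignedRead, ReferenceSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DamageEvent(NamedTuple):
    """One logged deamination: offset is in reference orientation within the
    read, kind is CT (forward read) or GA (reverse read)."""

    read_id: str
    offset: int
    kind: str  # "CT" | "GA"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulated library.

    Defaults emulate a deeply degraded single-stranded capture library:
    ~34 bp mean fragments (>=30 bp post-filter), ~72% terminal 5' C->T,
    an exponential positional decay, a small residual interior damage rate,
    and low uniform sequencing error. ``damage_amp3`` has no reported
    empirical anchor and is freely configurable.
    """

    seed: int
    target_cov: float = 10.0
    frag_mean: float = 34.0
    frag_shape: float = 0.25  # lognormal sigma
    min_len: int = 30
    damage_amp5: float = 0.72
    damage_amp3: float = 0.40
    damage_decay: float = 3.0
    damage_baseline: float = 0.02
    seq_error: float = 0.001
    p_forward: float = 0.5
    n_variants: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        for name in ("damage_amp5", "damage_amp3", "damage_baseline", "seq_error", "p_forward"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frag_mean <= self.min_len:
            raise ValueError(
                f"frag_mean ({self.frag_mean}) must exceed min_len ({self.min_len}): "
                "a length distribution truncated at min_len cannot have a smaller mean"
            )
        if self.target_cov <= 0 or self.damage_decay <= 0 or self.frag_shape <= 0:
            raise ValueError("target_cov, damage_decay and frag_shape must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    true_genome: str
    circular: bool
    variants: list[tuple[int, str, str]] = field(default_factory=list)
    damage_events: list[DamageEvent] = field(default_factory=list)


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate_reference(
    ref: ReferenceSequence,
    n_variants: int,
    seed: Union[int, np.random.Generator],
) -> SimulationTruth:
    """Plant ``n_variants`` substitutions at distinct positions of the reference.

    Each chosen position receives a uniformly drawn *different* base, so the
    Hamming distance between reference and truth is exactly ``n_variants``.
    """
    if n_variants > ref.length:
        raise ValueError(f"n_variants ({n_variants}) exceeds reference length ({ref.length})")
    rng = _as_rng(seed)
    genome = list(ref.seq)
    variants: list[tuple[int, str, str]] = []
    positions = rng.choice(ref.length, size=n_variants, replace=False)
    for pos in sorted(int(p) for p in positions):
        old = genome[pos]
        choices = [b for b in "ACGT" if b != old]
        new = choices[int(rng.integers(len(choices)))]
        genome[pos] = new
        variants.append((pos, old, new))
    return SimulationTruth(true_genome="".join(genome), circular=ref.circular, variants=variants)


def _calibrate_log_mu(frag_mean: float, sigma: float, min_len: float) -> float:
    """Location parameter of a lognormal whose min_len-truncated mean is frag_mean."""
    log_m = math.log(min_len)

    def trunc_mean(mu: float) -> float:
        surv = norm.sf((log_m - mu) / sigma)
        partial = math.exp(mu + sigma**2 / 2) * norm.sf((log_m - mu - sigma**2) / sigma)
        return partial / surv

    lo, hi = log_m - 10 * sigma, math.log(frag_mean) + 10 * sigma
    return brentq(lambda mu: trunc_mean(mu) - frag_mean, lo, hi, xtol=1e-10)


def _draw_lengths(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from the min_len-truncated lognormal length model."""
    mu = _calibrate_log_mu(config.frag_mean, config.frag_shape, config.min_len)
    sigma = config.frag_shape
    cdf_min = norm.cdf((math.log(config.min_len) - mu) / sigma)
    u = cdf_min + rng.random(n) * (1.0 - cdf_min)
    lengths = np.exp(mu + sigma * norm.ppf(u))
    return np.maximum(np.rint(lengths).astype(int), config.min_len)


def simulate_reads(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AlignedRead], list[DamageEvent]]:
    """Emit aligned reads from the true genome with logged damage events.

    Reads are drawn until the cumulative base count reaches ``target_cov``
    times the genome length, so realized coverage matches the target to
    within one fragment. The returned events are also stored on ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome = truth.true_genome
    n = len(genome)
    target_bases = config.target_cov * n

    lengths: list[int] = []
    total = 0
    while total < target_bases:
        batch = _draw_lengths(
            max(64, int(math.ceil((target_bases - total) / config.frag_mean))), config, rng
        )
        for length in batch:
            lengths.append(int(length))
            total += int(length)
            if total >= target_bases:
                break

    doubled = genome + genome  # substring extraction across the origin
    reads: list[AlignedRead] = []
    events: list[DamageEvent] = []
    amp5, amp3 = config.damage_amp5, config.damage_amp3
    decay, baseline = config.damage_decay, config.damage_baseline

    for idx, length in enumerate(lengths):
        if truth.circular:
            start = int(rng.integers(n))
        else:
            if length > n:
                raise ValueError(f"fragment of {length} bp exceeds linear genome of {n} bp")
            start = int(rng.integers(n - length + 1))
        sub = doubled[start : start + length]
        forward = bool(rng.random() < config.p_forward)
        molecule = sub if forward else _revcomp(sub)
        read_id = f"read{idx:06d}"

        # deamination acts on the molecule strand: C -> T, end-biased
        mol = list(molecule)
        for k, base in enumerate(mol):
            if base != "C":
                continue
            p = amp5 * math.exp(-k / decay) + amp3 * math.exp(-(length - 1 - k) / decay) + baseline
            if rng.random() < min(1.0, p):
                mol[k] = "T"
                offset = k if forward else length - 1 - k
                events.append(DamageEvent(read_id, offset, "CT" if forward else "GA"))
        damaged = "".join(mol)
        bases = damaged if forward else _revcomp(damaged)

        if config.seq_error > 0:
            err_mask = rng.random(length) < config.seq_error
            if err_mask.any():
                blist = list(bases)
                for k in np.flatnonzero(err_mask):
                    others = [b for b in "ACGT" if b != blist[k]]
                    blist[int(k)] = others[int(rng.integers(3))]
                bases = "".join(blist)

        reads.append(
            AlignedRead(
                read_id=read_id,
                ref_start=start,
                orientation=FORWARD if forward else REVERSE,
                bases=bases,
                mapq=60,
            )
        )

    truth.damage_events = events
    return reads, events


def simulate_dataset(
    ref: ReferenceSequence, config: SimulationConfig
) -> tuple[list[AlignedRead], SimulationTruth]:
    """Mutate the reference per ``config.n_variants`` and simulate a library.

    One RNG seeded from ``config.seed`` drives both steps, so the whole
    dataset is reproducible from the config alone.
    """
    rng = np.random.default_rng(config.seed)
    truth = mutate_reference(ref, config.n_variants, rng)
    reads, _ = simulate_reads(truth, config, rng)
    return reads, truth


def write_sam(reads: list[AlignedRead], ref: ReferenceSequence, path) -> None:
    """Write reads as a SAM file against ``ref``.

    A read spanning the origin of a circular reference is emitted as a single
    record whose CIGAR extends past the linear reference end (the wrap
    convention consumed by :func:`paleomito.alignio.build_pileup`).
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": ref.name, "LN": ref.length}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(header)
            rec.query_name = read.read_id
            rec.query_sequence = read.bases
            rec.flag = 16 if read.orientation == REVERSE else 0
            rec.reference_id = 0
            rec.reference_start = read.ref_start
            rec.mapping_quality = read.mapq if read.mapq is not None else 255
            rec.cigarstring = f"{read.length}M"
            out.write(rec)


def write_truth(truth: SimulationTruth, config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write truth FASTA, variant and damage-event TSVs, and the config JSON."""
    import json
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_fasta": str(out / "truth.fasta"),
        "variants": str(out / "variants.tsv"),
        "damage_events": str(out / "damage_events.tsv"),
        "config": str(out / "config.json"),
    }
    with open(paths["truth_fasta"], "w") as fh:
        SeqIO.write([SeqRecord(Seq(truth.true_genome), id="truth", description="")], fh, "fasta")
    with open(paths["variants"], "w") as fh:
        fh.write("pos\tref\talt\n")
        for pos, old, new in truth.variants:
            fh.write(f"{pos}\t{old}\t{new}\n")
    with open(paths["damage_events"], "w") as fh:
        fh.write("read_id\toffset\tkind\n")
        for ev in truth.damage_events:
            fh.write(f"{ev.read_id}\t{ev.offset}\t{ev.kind}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
    return paths
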