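"""Reference/alignment I/O and circular-aware pileup construction.

Coordinates are 0-based half-open throughout the library; the human-readable
call log is the only place 1-based positions appear. A read aligned near the
end of a circular reference may extend past the linear end of the sequence;
such alignments wrap around the origin at pileup time (the single-record
convention produced by circular-aware mappers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from paleomito.consensus import ConsensusResult

FORWARD = "forward"
REVERSE = "reverse"

_NON_ACGT = re.compile(r"[^ACGT]")

#: Column order of the per-base call log written by :func:`write_call_log`.
CALL_LOG_COLUMNS = [
    "pos",
    "ref",
    "raw_A",
    "raw_C",
    "raw_G",
    "raw_T",
    "eff_A",
    "eff_C",
    "eff_G",
    "eff_T",
    "raw_cov",
    "eff_cov",
    "support",
    "flag_ct",
    "flag_ga",
    "n_silenced",
    "call",
    "mode",
]


class FormatError(ValueError):
    """Malformed or unexpected input file content."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference sequence, optionally circular (mitochondrial convention).

    Attributes
    ----------
    name : str
        Sequence identifier (FASTA header word / SAM reference name).
    seq : str
        Uppercase sequence over ``{A, C, G, T, N}``.
    circular : bool
        Whether coordinates wrap around the origin.
    """

    name: str
    seq: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedRead:
    """One mapped molecule in reference orientation.

    ``bases`` is the read sequence as stored in the SAM record, i.e. already
    reverse-complemented for reverse-strand reads. ``ref_positions``, when
    present, maps each query base to its reference coordinate (``None`` for
    inserted/clipped bases); when absent the alignment is gapless and base
    ``i`` sits at ``ref_start + i`` (modulo the reference length for circular
    references).
    """

    read_id: str
    ref_start: int
    orientation: str
    bases: str
    mapq: Optional[int] = None
    ref_positions: Optional[tuple[Optional[int], ...]] = None

    @property
    def length(self) -> int:
        return len(self.bases)

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.ref_positions is not None and len(self.ref_positions) != len(self.bases):
            raise ValueError("ref_positions must parallel bases")


@dataclass(frozen=True, slots=True)
class PileupEntry:
    """One read base stacked on a reference position.

    ``dist5``/``dist3`` are offsets from the read's left and right alignment
    ends in reference orientation; ``dist5 + dist3 == read length - 1``.
    """

    base: str
    orientation: str
    dist5: int
    dist3: int
    read_id: str


@dataclass
class PileupColumn:
    """All read bases covering one reference position."""

    ref_pos: int
    ref_base: str
    entries: list[PileupEntry] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        """Raw coverage: number of stacked entries (including N bases)."""
        return len(self.entries)


def read_reference(path, circular: bool = False) -> ReferenceSequence:
    """Read a single-record FASTA reference.

    The sequence is uppercased and any non-ACGT character (IUPAC ambiguity
    codes included) is mapped to N.

    Raises
    ------
    FormatError
        If the file holds no record or more than one.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise FormatError(f"expected a single FASTA record in {path}, found {len(records)}")
    rec = records[0]
    seq = _NON_ACGT.sub("N", str(rec.seq).upper())
    return ReferenceSequence(name=rec.id, seq=seq, circular=circular)


def read_alignments(
    path,
    min_len: int = 30,
    min_mapq: Optional[int] = None,
    ref_name: Optional[str] = None,
) -> list[AlignedRead]:
    """Load mapped reads from a SAM/BAM file.

    Unmapped, secondary and supplementary records are dropped, as are reads
    shorter than ``min_len`` (post-adapter-removal fragment-length filter) and,
    if ``min_mapq`` is given, reads below that mapping quality. Orientation is
    taken from the reverse-strand flag; bases are kept as stored (reference
    orientation). No index is required; the file is scanned sequentially.

    Parameters
    ----------
    ref_name : str, optional
        If given, every mapped record must align to this reference name;
        a mismatch raises :class:`FormatError` naming both.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if ref_name is not None and rec.reference_name != ref_name:
                raise FormatError(
                    f"read {rec.query_name} aligned to {rec.reference_name!r}, "
                    f"expected reference {ref_name!r}"
                )
            seq = rec.query_sequence
            if seq is None or len(seq) < min_len:
                continue
            if min_mapq is not None and rec.mapping_quality < min_mapq:
                continue
            ref_positions: Optional[tuple[Optional[int], ...]] = None
            cig = rec.cigartuples
            # gapless alignments (pure M/=/X) use the implicit ref_start + i map
            if cig is not None and any(op not in (0, 7, 8) for op, _ in cig):
                pairs = rec.get_aligned_pairs(matches_only=False)
                by_query: list[Optional[int]] = [None] * len(seq)
                for qpos, rpos in pairs:
                    if qpos is not None:
                        by_query[qpos] = rpos
                ref_positions = tuple(by_query)
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_start=rec.reference_start,
                    orientation=REVERSE if rec.is_reverse else FORWARD,
                    bases=seq.upper(),
                    mapq=rec.mapping_quality,
                    ref_positions=ref_positions,
                )
            )
    return reads


def build_pileup(reads: list[AlignedRead], ref: ReferenceSequence) -> list[PileupColumn]:
    """Stack reads into one column per reference position.

    For a circular reference, reads extending past the linear end wrap around
    the origin and contribute to columns at both ends with end-distances
    computed from the read's own alignment ends. A read overhanging the end of
    a *linear* reference is an error: it signals the upstream mapping was not
    circular-aware.
    """
    n = ref.length
    columns = [PileupColumn(p, ref.seq[p]) for p in range(n)]
    for read in reads:
        last = read.length - 1
        if read.ref_positions is None:
            if not (0 <= read.ref_start < n):
                raise ValueError(
                    f"read {read.read_id} starts at {read.ref_start}, outside reference of length {n}"
                )
            if not ref.circular and read.ref_start + read.length > n:
                raise ValueError(
                    f"read {read.read_id} overhangs the end of linear reference "
                    f"{ref.name} ({read.ref_start}+{read.length} > {n}); was the "
                    "mapping circular-aware?"
                )
            for i, base in enumerate(read.bases):
                pos = (read.ref_start + i) % n
                columns[pos].entries.append(
                    PileupEntry(base, read.orientation, i, last - i, read.read_id)
                )
        else:
            for i, (base, rpos) in enumerate(zip(read.bases, read.ref_positions)):
                if rpos is None:
                    continue  # inserted base: no reference position
                columns[rpos % n].entries.append(
                    PileupEntry(base, read.orientation, i, last - i, read.read_id)
                )
    return columns


def write_consensus(result: "ConsensusResult", path, name: str = "consensus") -> None:
    """Write the called sequence as a single 60-column-wrapped FASTA record."""
    rec = SeqRecord(Seq(result.sequence), id=name, description=f"mode={result.summary['mode']}")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def write_call_log(result: "ConsensusResult", path) -> None:
    """Write the per-base call log as TSV, one row per reference position.

    Positions are 1-based in this output. ``raw_*`` are unweighted base counts
    before any correction; ``eff_*`` are post-silencing counts or weighted
    tallies depending on the mode; ``support`` is empty where undefined.
    """
    import pandas as pd

    mode = result.summary["mode"]
    rows = []
    for call in result.calls:
        row = {"pos": call.ref_pos + 1, "ref": call.ref_base}
        for b in "ACGT":
            row[f"raw_{b}"] = call.raw_counts.get(b, 0)
        for b in "ACGT":
            row[f"eff_{b}"] = round(call.eff_counts.get(b, 0.0), 6)
        row.update(
            raw_cov=call.raw_cov,
            eff_cov=round(call.eff_cov, 6),
            support="" if call.support is None else round(call.support, 6),
            flag_ct=call.flag_ct,
            flag_ga=call.flag_ga,
            n_silenced=call.n_silenced,
            call=call.call,
            mode=mode,
        )
        rows.append(row)
    pd.DataFrame(rows, columns=CALL_LOG_COLUMNS).to_csv(path, sep="\t", index=False)
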