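"""Reading, validating, assembling and deduplicating coding sequences.

Input is plain or gzipped FASTA with one CDS per record.  Sequences are
normalized to upper-case DNA (U -> T) on ingestion and must be in-frame
(length a positive multiple of 3) over the unambiguous A/C/G/T alphabet.
In strict mode (default) an offending record raises; in lenient mode it
is skipped and logged.

Also reads host reference codon-usage tables (two-column codon/value
text, CoCoPUTs/Kazusa style) and derives the per-family relative
adaptiveness weights used by the codon adaptation index.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    FAMILIES,
    STOP_CODONS,
    START_CODON,
    to_dna,
)

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: units accepted for reference usage tables
REFERENCE_UNITS = ("count", "per-thousand", "rscu")


class SequenceError(ValueError):
    """A record violates the coding-sequence invariants."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame nucleotide CDS with identifier and group label.

    The sequence is normalized to upper-case DNA on construction.
    Length must be a positive multiple of 3 and the alphabet is
    restricted to A/C/G/T (ambiguity codes are rejected).
    """

    id: str
    seq: str
    group: str = ""

    def __post_init__(self) -> None:
        norm = to_dna(self.seq)
        object.__setattr__(self, "seq", norm)
        if len(norm) == 0 or len(norm) % 3 != 0:
            raise SequenceError(
                f"record {self.id!r}: length {len(norm)} is not a positive multiple of 3"
            )
        bad = set(norm) - _VALID_BASES
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid characters {sorted(bad)} (ambiguity codes not allowed)"
            )

    def codons(self) -> list[str]:
        """Frame-0 non-overlapping triplets."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def __len__(self) -> int:
        return len(self.seq)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(
    path: str | Path, group: str = "", strict: bool = True
) -> list[CodingSequence]:
    """Read a FASTA file into a list of :class:`CodingSequence`.

    Record ids are the header up to the first whitespace.  ``strict``
    raises on any record failing the CDS invariants; otherwise such
    records are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[CodingSequence] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            try:
                out.append(CodingSequence(id=rec.id, seq=str(rec.seq), group=group))
            except SequenceError:
                if strict:
                    raise
                logger.warning("skipping invalid record %r in %s", rec.id, path)
    if not out:
        raise SequenceError(f"no valid FASTA records in {path}")
    return out


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write sequences as FASTA (DNA alphabet, 60-column wrap)."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.group or "")
        for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def concatenate_orf12(
    orf1: CodingSequence,
    orf2: CodingSequence,
    *,
    allow_nonstandard_boundaries: bool = False,
) -> CodingSequence:
    """Join two ORFs into the ORF12 analysis unit.

    The stop codon of ``orf1`` and the start codon of ``orf2`` are
    removed before joining, so the result has length
    ``len(orf1) + len(orf2) - 6``.  Boundary checks (orf1 ends in a
    stop, orf2 starts with ATG) can be bypassed with
    ``allow_nonstandard_boundaries`` for genomes whose ORF boundaries
    are not fully resolved (e.g. a truncated replicase ORF).
    """
    if not allow_nonstandard_boundaries:
        if orf1.seq[-3:] not in STOP_CODONS:
            raise SequenceError(
                f"ORF1 {orf1.id!r} does not end in a stop codon ({orf1.seq[-3:]})"
            )
        if orf2.seq[:3] != START_CODON:
            raise SequenceError(
                f"ORF2 {orf2.id!r} does not start with ATG ({orf2.seq[:3]})"
            )
    joined = orf1.seq[:-3] + orf2.seq[3:]
    return CodingSequence(
        id=f"{orf1.id}|{orf2.id}", seq=joined, group=orf1.group or orf2.group
    )


def deduplicate(seqs: Sequence[CodingSequence]) -> list[CodingSequence]:
    """Drop sequences with 100% identity to an earlier one.

    The key is the exact normalized nucleotide string; the first
    occurrence is retained and order is preserved.  Removals are
    logged with both ids.
    """
    seen: dict[str, str] = {}
    kept: list[CodingSequence] = []
    for s in seqs:
        if s.seq in seen:
            logger.info("dedup: %r identical to %r, removed", s.id, seen[s.seq])
            continue
        seen[s.seq] = s.id
        kept.append(s)
    return kept


@dataclass(frozen=True)
class ReferenceUsageTable:
    """Host codon usage normalized to per-family RSCU and weights.

    ``rscu`` holds one RSCU value per synonymous codon (DNA keys);
    ``weights`` holds the relative adaptiveness w(c) = RSCU(c) /
    max RSCU within the codon's family, so the best codon of each
    family has w == 1.  Within a covered family, codons absent from or
    zero in the source table receive ``min_weight`` so log-scores stay
    finite; a family with no entry at all is imputed as neutral (every
    codon w == 1) and logged.
    """

    rscu: dict[str, float]
    weights: dict[str, float]
    units: str
    min_weight: float = 0.01

    @classmethod
    def from_values(
        cls,
        values: dict[str, float],
        units: str = "count",
        min_weight: float = 0.01,
    ) -> "ReferenceUsageTable":
        if units not in REFERENCE_UNITS:
            raise ValueError(f"units must be one of {REFERENCE_UNITS}, got {units!r}")
        vals: dict[str, float] = {}
        for codon, v in values.items():
            c = to_dna(codon)
            if c in STOP_CODONS:
                continue
            if c in vals:
                raise ValueError(f"duplicate codon entry {codon!r}")
            known = any(c in fam for fam in FAMILIES.values()) or c in ("ATG", "TGG")
            if not known:
                raise ValueError(f"unknown codon string {codon!r}")
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"invalid value {v!r} for codon {codon!r}")
            vals[c] = float(v)

        rscu: dict[str, float] = {}
        for aa, fam in FAMILIES.items():
            if not any(c in vals for c in fam):
                # family not covered by the source table: impute neutral
                # usage so every codon gets weight 1 (no CAI contribution)
                logger.info("reference table lacks family %s; imputed neutral", aa)
                for c in fam:
                    rscu[c] = 1.0
                continue
            fam_vals = [vals.get(c, 0.0) for c in fam]
            total = sum(fam_vals)
            if total == 0.0:
                raise ValueError(f"all-zero family {aa} in reference table")
            if units == "rscu":
                for c, v in zip(fam, fam_vals):
                    rscu[c] = v
            else:
                for c, v in zip(fam, fam_vals):
                    rscu[c] = v * len(fam) / total

        weights: dict[str, float] = {}
        for fam in FAMILIES.values():
            best = max(rscu[c] for c in fam)
            for c in fam:
                w = rscu[c] / best
                weights[c] = w if w > 0 else min_weight
        return cls(rscu=rscu, weights=weights, units=units, min_weight=min_weight)


def read_reference_table(
    path: str | Path, units: str, min_weight: float = 0.01
) -> ReferenceUsageTable:
    """Read a two-column (codon, value) whitespace/TSV usage table.

    ``units`` declares what the value column holds: raw ``count``,
    frequency ``per-thousand``, or precomputed ``rscu``.  Lines
    starting with ``#`` are comments.  Stop codons are dropped.
    """
    values: dict[str, float] = {}
    with _open_maybe_gzip(Path(path)) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed reference-table line: {line!r}")
            codon = to_dna(parts[0])
            if codon in values:
                raise ValueError(f"duplicate codon entry {parts[0]!r}")
            values[codon] = float(parts[1])
    return ReferenceUsageTable.from_values(values, units=units, min_weight=min_weight)
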