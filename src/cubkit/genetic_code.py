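"""Standard nuclear genetic code tables and codon bookkeeping.

Everything downstream (RSCU, ENC, CAI, composition) operates on the 18
amino acids with degenerate codon families under the standard code.  Met
(AUG) and Trp (UGG) are single-codon families and are excluded from all
synonymous statistics; the three stop codons are excluded everywhere.

Leu, Ser and Arg are treated as single six-codon families (the CodonW
convention) rather than being split into their two-codon/four-codon
sub-boxes.

Sequences are stored internally in the DNA alphabet (T); all user-facing
tables print the RNA alphabet (U), which is how codon-usage tables are
conventionally published.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon (DNA alphabet) -> one-letter amino acid, stops excluded
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
START_CODON = "ATG"

#: amino acids with >1 synonymous codon, in the row order used by
#: published codon-usage tables (grouped by first/second codon base);
#: this fixes the column order of RSCU matrices so loadings are
#: comparable across runs.
DEGENERATE_AA_ORDER: tuple[str, ...] = (
    "F", "L", "I", "V", "S", "P", "T", "A",
    "Y", "H", "Q", "N", "K", "D", "E", "C", "R", "G",
)

#: amino acid -> alphabetically sorted codon family (DNA alphabet)
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in DEGENERATE_AA_ORDER
}

#: degeneracy (family size) per amino acid: 2-fold x9, 3-fold x1 (Ile),
#: 4-fold x5, 6-fold x3 (Leu/Ser/Arg as whole families)
DEGENERACY: dict[str, int] = {aa: len(f) for aa, f in FAMILIES.items()}

#: the 59 synonymous codons in fixed documented order (DNA alphabet)
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for aa in DEGENERATE_AA_ORDER for c in FAMILIES[aa]
)

#: codon -> its degenerate family's amino acid (59 entries)
SYNONYMOUS_CODON_TO_AA: dict[str, str] = {
    c: aa for aa in DEGENERATE_AA_ORDER for c in FAMILIES[aa]
}

#: codons excluded from synonymous third-position statistics
NON_SYNONYMOUS_CODONS: frozenset[str] = frozenset({"ATG", "TGG"}) | STOP_CODONS

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def to_rna(codon: str) -> str:
    """Render a codon in the RNA alphabet (AUG-style) for reports."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize a codon string to the internal DNA alphabet."""
    return codon.upper().replace("U", "T")


def sanity_check() -> None:
    """Internal consistency of the derived tables (cheap, import-safe)."""
    sizes = sorted(DEGENERACY.values())
    assert sizes == [2] * 9 + [3] + [4] * 5 + [6] * 3
    assert len(SYNONYMOUS_CODONS) == 59


sanity_check()
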