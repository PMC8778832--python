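"""Per-sequence and pooled codon-level statistics.

Implements the classical codon-usage toolbox:

* nucleotide composition, including synonymous third-position
  frequencies (A3s/C3s/G3s/U3s) and positional GC (GC1/GC2/GC3, GC12);
* relative synonymous codon usage (RSCU) and the preferred /
  over-represented (RSCU > 1.6) / under-represented (RSCU < 0.6)
  classification;
* Wright's effective number of codons (ENC) in the CodonW variant,
  together with the expected ENC-vs-GC3s null curve;
* the codon adaptation index (CAI) as the geometric mean of relative
  adaptiveness weights from a host reference table;
* Gravy (mean Kyte-Doolittle hydropathy) and Aroma (aromatic residue
  fraction) of the translated protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import (
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AA_ORDER,
    FAMILIES,
    NON_SYNONYMOUS_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    to_dna,
    to_rna,
)
from .sequence_io import CodingSequence, ReferenceUsageTable

AROMATIC_RESIDUES = frozenset("FYW")

#: RSCU thresholds for over-/under-representation (strict inequalities)
OVER_REPRESENTED_THRESHOLD = 1.6
UNDER_REPRESENTED_THRESHOLD = 0.6

#: degeneracy classes entering the ENC estimator: class size -> n families
ENC_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


# ---------------------------------------------------------------------------
# codon counting


@dataclass
class CodonCounts:
    """Occurrence counts for all 64 codons, for one CDS or a pooled set."""

    counts: dict[str, int]
    source: str = ""

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            c = to_dna(codon)
            if c not in full:
                raise ValueError(f"unknown codon {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon!r}")
            full[c] += int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        src = ",".join(x for x in (self.source, other.source) if x)
        return CodonCounts(counts=merged, source=src)

    def scaled(self, factor: int) -> "CodonCounts":
        """Counts multiplied by a positive integer (for invariance checks)."""
        if factor < 1:
            raise ValueError("factor must be a positive integer")
        return CodonCounts(
            counts={c: n * factor for c, n in self.counts.items()}, source=self.source
        )


def count_codons(seq: CodingSequence) -> CodonCounts:
    """Tally frame-0 non-overlapping triplets of a CDS."""
    counts: dict[str, int] = {}
    for codon in seq.codons():
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, source=seq.id)


def pool_counts(seqs: Iterable[CodingSequence], source: str = "") -> CodonCounts:
    """Pooled codon counts over a sequence set (e.g. one virus species)."""
    total = {c: 0 for c in ALL_CODONS}
    for s in seqs:
        for codon in s.codons():
            total[codon] += 1
    return CodonCounts(counts=total, source=source)


# ---------------------------------------------------------------------------
# composition


@dataclass(frozen=True)
class CompositionSummary:
    """Nucleotide composition of one CDS, in percent.

    ``a3s_pct`` etc. are third-position frequencies over synonymous
    codons only (AUG, UGG and stops excluded, the CodonW convention),
    so the four values sum to 100.  ``gc1_pct``/``gc2_pct``/``gc3_pct``
    are computed over all codons; ``gc12_pct`` is the mean of GC1 and
    GC2.  ``gc3s`` is the synonymous-third-position G+C fraction used
    as the abscissa of the ENC plot.  ``third_positions_defined`` is
    False for degenerate inputs with no synonymous codon at all, in
    which case the synonymous fields are NaN.
    """

    a_pct: float
    c_pct: float
    u_pct: float
    g_pct: float
    gc_pct: float
    a3s_pct: float
    c3s_pct: float
    u3s_pct: float
    g3s_pct: float
    gc1_pct: float
    gc2_pct: float
    gc3_pct: float
    gc12_pct: float
    gc3s: float
    third_positions_defined: bool = True


def composition_summary(seq: CodingSequence) -> CompositionSummary:
    """Whole-CDS and positional nucleotide composition of one sequence."""
    n = len(seq.seq)
    whole = {b: seq.seq.count(b) / n * 100.0 for b in "ACGT"}

    codons = seq.codons()
    pos_gc = [0, 0, 0]
    for codon in codons:
        for i, base in enumerate(codon):
            if base in "GC":
                pos_gc[i] += 1
    ncod = len(codons)
    gc1, gc2, gc3 = (x / ncod * 100.0 for x in pos_gc)

    syn3 = {b: 0 for b in "ACGT"}
    for codon in codons:
        if codon not in NON_SYNONYMOUS_CODONS:
            syn3[codon[2]] += 1
    nsyn = sum(syn3.values())
    if nsyn == 0:
        a3 = c3 = g3 = u3 = gc3s = float("nan")
        defined = False
    else:
        a3 = syn3["A"] / nsyn * 100.0
        c3 = syn3["C"] / nsyn * 100.0
        g3 = syn3["G"] / nsyn * 100.0
        u3 = syn3["T"] / nsyn * 100.0
        gc3s = (syn3["G"] + syn3["C"]) / nsyn
        defined = True

    return CompositionSummary(
        a_pct=whole["A"],
        c_pct=whole["C"],
        u_pct=whole["T"],
        g_pct=whole["G"],
        gc_pct=whole["G"] + whole["C"],
        a3s_pct=a3,
        c3s_pct=c3,
        u3s_pct=u3,
        g3s_pct=g3,
        gc1_pct=gc1,
        gc2_pct=gc2,
        gc3_pct=gc3,
        gc12_pct=(gc1 + gc2) / 2.0,
        gc3s=gc3s,
        third_positions_defined=defined,
    )


# ---------------------------------------------------------------------------
# RSCU


@dataclass(frozen=True)
class RSCUProfile:
    """RSCU values over the 59 synonymous codons (DNA keys).

    RSCU(c) = observed count of c, divided by the count expected if
    every codon of its family were used equally; 1 means no bias.
    Families never observed are NaN and listed in ``missing_families``.
    """

    values: dict[str, float]
    missing_families: frozenset[str] = frozenset()

    @classmethod
    def from_values(cls, values: Mapping[str, float]) -> "RSCUProfile":
        """Build a profile from published per-codon RSCU values."""
        vals = {to_dna(c): float(v) for c, v in values.items()}
        missing = {
            aa
            for aa, fam in FAMILIES.items()
            if any(c not in vals or math.isnan(vals[c]) for c in fam)
        }
        full = {
            c: vals.get(c, float("nan")) for c in SYNONYMOUS_CODONS
        }
        return cls(values=full, missing_families=frozenset(missing))

    def as_series(self) -> pd.Series:
        """RSCU values indexed by RNA-alphabet codon, documented order."""
        return pd.Series(
            {to_rna(c): self.values[c] for c in SYNONYMOUS_CODONS}, name="RSCU"
        )


def rscu_profile(counts: CodonCounts) -> RSCUProfile:
    """RSCU(c) = count(c) * degeneracy / family total, per family."""
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa, fam in FAMILIES.items():
        total = sum(counts.counts[c] for c in fam)
        if total == 0:
            missing.add(aa)
            for c in fam:
                values[c] = float("nan")
        else:
            for c in fam:
                values[c] = counts.counts[c] * len(fam) / total
    return RSCUProfile(values=values, missing_families=frozenset(missing))


@dataclass(frozen=True)
class RSCUClassification:
    """Preferred / over-represented / under-represented codon sets."""

    preferred: dict[str, str]  # amino acid -> codon with maximal RSCU
    over: frozenset[str]  # RSCU > 1.6, strictly
    under: frozenset[str]  # RSCU < 0.6, strictly

    @property
    def preferred_set(self) -> frozenset[str]:
        return frozenset(self.preferred.values())


def classify_rscu(
    profile: RSCUProfile,
    reference: RSCUProfile | ReferenceUsageTable | None = None,
) -> RSCUClassification:
    """Classify codons by RSCU.

    The preferred codon of each family is the RSCU argmax.  Ties
    (possible at the 2-decimal precision of published tables) are
    broken toward the codon with higher RSCU in ``reference`` when one
    is supplied, else toward the alphabetically first codon.
    """
    ref_vals: Mapping[str, float] = {}
    if isinstance(reference, RSCUProfile):
        ref_vals = reference.values
    elif isinstance(reference, ReferenceUsageTable):
        ref_vals = reference.rscu

    preferred: dict[str, str] = {}
    over: set[str] = set()
    under: set[str] = set()
    for aa, fam in FAMILIES.items():
        if aa in profile.missing_families:
            continue
        best = max(profile.values[c] for c in fam)
        tied = [c for c in fam if profile.values[c] == best]
        if len(tied) > 1 and ref_vals:
            tied.sort(key=lambda c: (-ref_vals.get(c, 0.0), c))
        preferred[aa] = tied[0]
        for c in fam:
            v = profile.values[c]
            if v > OVER_REPRESENTED_THRESHOLD:
                over.add(c)
            elif v < UNDER_REPRESENTED_THRESHOLD:
                under.add(c)
    return RSCUClassification(
        preferred=preferred, over=frozenset(over), under=frozenset(under)
    )


def shared_preferred(
    a: RSCUProfile,
    b: RSCUProfile,
    reference: RSCUProfile | ReferenceUsageTable | None = None,
) -> frozenset[str]:
    """Codons preferred by both profiles (e.g. a virus and its host)."""
    ca = classify_rscu(a, reference=reference)
    cb = classify_rscu(b, reference=reference)
    return ca.preferred_set & cb.preferred_set


# ---------------------------------------------------------------------------
# ENC


@dataclass(frozen=True)
class ENCResult:
    """Wright's effective number of codons with its class homozygosities."""

    enc: float
    f_by_class: dict[int, float]
    gc3s: float


def _family_homozygosity(counts: CodonCounts, fam: Sequence[str]) -> float | None:
    """F = (n * sum(p^2) - 1) / (n - 1); None if fewer than 2 codons seen."""
    ns = [counts.counts[c] for c in fam]
    n = sum(ns)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in ns)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, min_codons_warn: int = 100) -> ENCResult:
    """Effective number of codons, Wright's estimator as in CodonW.

    Homozygosity F is averaged within degeneracy classes (2-, 3-, 4-,
    6-fold); families with fewer than two observed codons are excluded
    from their class mean.  An empty Ile class (the only 3-fold family)
    is replaced by the mean of the 2- and 4-fold class means; any other
    empty class is an error.  ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,
    capped at 61.
    """
    if counts.total < min_codons_warn:
        warnings.warn(
            f"ENC on only {counts.total} codons is noisy", stacklevel=2
        )
    class_fs: dict[int, list[float]] = {k: [] for k in ENC_CLASSES}
    for aa, fam in FAMILIES.items():
        f = _family_homozygosity(counts, fam)
        if f is not None:
            class_fs[len(fam)].append(f)

    f_bar: dict[int, float] = {}
    for k, fs in class_fs.items():
        if fs:
            f_bar[k] = float(np.mean(fs))
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in ENC_CLASSES if k not in f_bar]
    if missing:
        raise ValueError(
            f"cannot estimate ENC: no usable families in degeneracy classes {missing}"
        )
    zero = [k for k, f in f_bar.items() if f <= 0.0]
    if zero:
        raise ValueError(
            f"cannot estimate ENC: zero mean homozygosity in classes {zero}"
        )

    value = 2.0 + sum(ENC_CLASSES[k] / f_bar[k] for k in ENC_CLASSES)
    value = min(value, 61.0)

    syn3_gc = sum(
        counts.counts[c]
        for c in SYNONYMOUS_CODONS
        if c[2] in "GC"
    )
    syn3_total = sum(counts.counts[c] for c in SYNONYMOUS_CODONS)
    gc3s = syn3_gc / syn3_total if syn3_total else float("nan")
    return ENCResult(enc=value, f_by_class=f_bar, gc3s=gc3s)


def expected_enc(s: float) -> float:
    """Null ENC under mutation pressure alone, at synonymous GC3 ``s``.

    ENC(s) = 2 + s + 29 / (s^2 + (1 - s)^2); the curve is the standard
    reference line of the ENC-vs-GC3s plot and peaks at s = 0.5 with
    value 60.5.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


# ---------------------------------------------------------------------------
# CAI


@dataclass(frozen=True)
class CAIResult:
    cai: float
    n_codons: int


def cai(counts: CodonCounts, ref: ReferenceUsageTable) -> CAIResult:
    """Codon adaptation index: geometric mean of reference weights.

    CAI = exp( sum_c count(c) ln w(c) / sum_c count(c) ) over the 59
    synonymous codons; Met, Trp and stops never enter.  w comes from
    the host reference table (best codon of each family has w = 1).
    """
    log_sum = 0.0
    n = 0
    for c in SYNONYMOUS_CODONS:
        k = counts.counts[c]
        if k:
            log_sum += k * math.log(ref.weights[c])
            n += k
    if n == 0:
        raise ValueError("no scorable codons for CAI")
    return CAIResult(cai=math.exp(log_sum / n), n_codons=n)


# ---------------------------------------------------------------------------
# protein-level indices


def translate(seq: CodingSequence) -> str:
    """Translate a CDS; a terminal stop is dropped, internal stops raise."""
    codons = seq.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {i} in {seq.id!r}")
        residues.append(CODON_TO_AA[codon])
    if not residues:
        raise ValueError(f"empty translation for {seq.id!r}")
    return "".join(residues)


def gravy(seq: CodingSequence) -> float:
    """Grand average of hydropathy (Kyte-Doolittle) of the translation."""
    protein = translate(seq)
    return sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)


def aroma(seq: CodingSequence) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp) in the translation."""
    protein = translate(seq)
    return sum(a in AROMATIC_RESIDUES for a in protein) / len(protein)


# ---------------------------------------------------------------------------
# per-sequence metrics table


def metrics_table(
    seqs: Sequence[CodingSequence],
    ref: ReferenceUsageTable | None = None,
) -> pd.DataFrame:
    """Per-sequence metrics table: composition, ENC, CAI, Gravy, Aroma.

    Columns follow the conventional per-sequence layout of codon-usage
    reports; CAI is included only when a reference table is given.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seqs:
            comp = composition_summary(s)
            counts = count_codons(s)
            try:
                enc_value = enc(counts).enc
            except ValueError:
                # e.g. an entire degeneracy class unused; ENC undefined
                enc_value = float("nan")
            row = {
                "id": s.id,
                "group": s.group,
                "A%": comp.a_pct,
                "C%": comp.c_pct,
                "U%": comp.u_pct,
                "G%": comp.g_pct,
                "GC%": comp.gc_pct,
                "A3s%": comp.a3s_pct,
                "C3s%": comp.c3s_pct,
                "U3s%": comp.u3s_pct,
                "G3s%": comp.g3s_pct,
                "GC1%": comp.gc1_pct,
                "GC2%": comp.gc2_pct,
                "GC3%": comp.gc3_pct,
                "GC12%": comp.gc12_pct,
                "GC3s": comp.gc3s,
                "ENC": enc_value,
                "Gravy": gravy(s),
                "Aroma": aroma(s),
            }
            if ref is not None:
                row["CAI"] = cai(counts, ref).cai
            rows.append(row)
    return pd.DataFrame(rows)
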