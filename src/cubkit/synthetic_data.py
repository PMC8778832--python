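"""Synthetic coding-sequence generation with controlled codon-usage structure.

Real codon-usage studies start from curated GenBank datasets; this
module generates coding sequences whose usage structure is known by
construction, so every analysis stage (RSCU, ENC, CAI, PR2, neutrality
regression, PCA) can be validated end to end.  It emulates only
codon-composition structure — per-amino-acid codon probabilities, a
target synonymous GC3, a linear GC12-GC3 relationship with noise, and
multi-population mixtures — not evolutionary processes.

All generators take an explicit integer seed and use a single local
`numpy` Generator; identical seeds give byte-identical output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import DEGENERATE_AA_ORDER, FAMILIES, STOP_CODONS, START_CODON
from .sequence_io import CodingSequence

logger = logging.getLogger(__name__)

#: amino acids whose two first codon positions are all A/U (weak) or all
#: G/C (strong); used by the neutrality generator so GC12 is set purely
#: by amino-acid choice while GC3 is set by the third base.
_WEAK_PREFIX_AAS = ("F", "I", "Y", "N", "K")  # UU-, AU-, UA-, AA-, AA-
_STRONG_PREFIX_AAS = ("P", "A", "G")  # CC-, GC-, GG-


@dataclass(frozen=True)
class UsageSpec:
    """A fully specified codon-usage population.

    ``codon_probs[aa]`` is a probability vector over ``FAMILIES[aa]``
    (alphabetical codon order); ``aa_probs`` is the amino-acid
    composition over the 18 degenerate families.  ``length`` is in
    codons (excluding the optional start/stop added at emission).
    """

    codon_probs: dict[str, tuple[float, ...]]
    aa_probs: dict[str, float]
    length: int = 300
    n_sequences: int = 20
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.n_sequences <= 0:
            raise ValueError("length and n_sequences must be positive")
        for aa, probs in self.codon_probs.items():
            if len(probs) != len(FAMILIES[aa]):
                raise ValueError(f"codon vector for {aa} has wrong length")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"codon probabilities for {aa} do not sum to 1")
        if abs(sum(self.aa_probs.values()) - 1.0) > 1e-12:
            raise ValueError("amino-acid probabilities do not sum to 1")

    def implied_rscu(self) -> dict[str, float]:
        """The RSCU values this spec converges to at large sample size."""
        out: dict[str, float] = {}
        for aa, fam in FAMILIES.items():
            for codon, p in zip(fam, self.codon_probs.get(aa, ())):
                out[codon] = p * len(fam)
        return out

    def spec_hash(self) -> str:
        """Short stable digest used as provenance in FASTA headers."""
        parts = [f"{aa}:{','.join(f'{p:.10f}' for p in v)}" for aa, v in sorted(self.codon_probs.items())]
        parts += [f"aa:{aa}:{p:.10f}" for aa, p in sorted(self.aa_probs.items())]
        parts += [f"L:{self.length}", f"n:{self.n_sequences}", f"seed:{self.seed}"]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:8]


def uniform_usage(
    seed: int = 0, length: int = 300, n_sequences: int = 20, label: str = "uniform"
) -> UsageSpec:
    """Every synonymous codon equally likely; ENC saturates at the cap."""
    return UsageSpec(
        codon_probs={
            aa: tuple(1.0 / len(fam) for _ in fam) for aa, fam in FAMILIES.items()
        },
        aa_probs={aa: 1.0 / len(DEGENERATE_AA_ORDER) for aa in DEGENERATE_AA_ORDER},
        length=length,
        n_sequences=n_sequences,
        label=label,
        seed=seed,
    )


def max_bias_usage(
    seed: int = 0,
    length: int = 300,
    n_sequences: int = 20,
    label: str = "maxbias",
    codon_index: int = 0,
) -> UsageSpec:
    """Exactly one codon per family (``codon_index``-th); ENC equals 20."""
    probs = {}
    for aa, fam in FAMILIES.items():
        v = [0.0] * len(fam)
        v[codon_index % len(fam)] = 1.0
        probs[aa] = tuple(v)
    return UsageSpec(
        codon_probs=probs,
        aa_probs={aa: 1.0 / len(DEGENERATE_AA_ORDER) for aa in DEGENERATE_AA_ORDER},
        length=length,
        n_sequences=n_sequences,
        label=label,
        seed=seed,
    )


def biased_usage(
    gc3_target: float,
    concentration: float,
    seed: int,
    length: int = 300,
    n_sequences: int = 20,
    label: str = "biased",
) -> UsageSpec:
    """Random usage spec tilted toward a target synonymous GC3.

    Within each family the mean probability of a codon is proportional
    to ``gc3_target`` if it ends in G/C and ``1 - gc3_target``
    otherwise, so at 0.5 the mean is uniform and the expected GC3s of
    a large generated sample tracks the target (exactly for the 17
    families with equally many G/C- and A/U-ending codons, to within
    ~0.005 overall because Ile has two A/U-ending codons).  Per-family
    vectors are drawn from a Dirichlet with that mean; ``concentration``
    (the Dirichlet alpha total) controls between-family variability —
    large values pin every family to its mean.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValueError(f"gc3_target must be in (0, 1), got {gc3_target}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    codon_probs: dict[str, tuple[float, ...]] = {}
    for aa, fam in FAMILIES.items():
        ends_gc = np.array([c[2] in "GC" for c in fam])
        if ends_gc.all() or (~ends_gc).all():
            logger.info("family %s has single-class third bases; left untilted", aa)
            mean = np.full(len(fam), 1.0 / len(fam))
        else:
            mean = np.where(ends_gc, gc3_target, 1.0 - gc3_target).astype(float)
            mean /= mean.sum()
        draw = rng.dirichlet(concentration * mean)
        draw = np.clip(draw, 1e-12, None)
        draw /= draw.sum()
        codon_probs[aa] = tuple(draw)
    return UsageSpec(
        codon_probs=codon_probs,
        aa_probs={aa: 1.0 / len(DEGENERATE_AA_ORDER) for aa in DEGENERATE_AA_ORDER},
        length=length,
        n_sequences=n_sequences,
        label=label,
        seed=seed,
    )


def generate_cds_set(
    spec: UsageSpec, include_start_stop: bool = True
) -> list[CodingSequence]:
    """Draw a coding-sequence set from a usage spec.

    Amino acids are i.i.d. from the composition vector and each codon
    i.i.d. from its family's vector.  With ``include_start_stop`` each
    sequence is wrapped in ATG ... TAA so FASTA round-trips look like
    real CDS records.  Output is deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    aas = list(spec.aa_probs)
    aa_p = np.array([spec.aa_probs[a] for a in aas])
    fam_codons = {aa: np.array(FAMILIES[aa]) for aa in aas}
    fam_p = {aa: np.array(spec.codon_probs[aa]) for aa in aas}
    tag = spec.spec_hash()

    out: list[CodingSequence] = []
    for i in range(spec.n_sequences):
        aa_idx = rng.choice(len(aas), size=spec.length, p=aa_p)
        codons = np.empty(spec.length, dtype=object)
        for j, aa in enumerate(aas):
            mask = aa_idx == j
            k = int(mask.sum())
            if k:
                codons[mask] = rng.choice(fam_codons[aa], size=k, p=fam_p[aa])
        body = "".join(codons)
        if include_start_stop:
            body = START_CODON + body + "TAA"
        out.append(
            CodingSequence(id=f"{spec.label}_{tag}_{i:04d}", seq=body, group=spec.label)
        )
    return out


def two_population_specs(
    seed: int,
    length: int = 300,
    n_sequences: int = 20,
    preference: float = 0.85,
) -> tuple[UsageSpec, UsageSpec]:
    """Two populations with disjoint preferred codons.

    Population A concentrates ``preference`` mass on the alphabetically
    first codon of each family, population B on the last; the remaining
    mass is spread evenly.  With a large preference the two clouds are
    linearly separable on PC1 of the RSCU matrix.
    """
    if not 0.5 < preference < 1.0:
        raise ValueError("preference must be in (0.5, 1)")

    def spec_for(index: int, label: str, pop_seed: int) -> UsageSpec:
        probs = {}
        for aa, fam in FAMILIES.items():
            k = len(fam)
            v = np.full(k, (1.0 - preference) / (k - 1))
            v[index] = preference
            probs[aa] = tuple(v)
        return UsageSpec(
            codon_probs=probs,
            aa_probs={aa: 1.0 / len(DEGENERATE_AA_ORDER) for aa in DEGENERATE_AA_ORDER},
            length=length,
            n_sequences=n_sequences,
            label=label,
            seed=pop_seed,
        )

    return spec_for(0, "popA", seed), spec_for(-1, "popB", seed + 1)


# ---------------------------------------------------------------------------
# neutrality-plot scenarios


@dataclass(frozen=True)
class NeutralityScenario:
    """A linear GC12-on-GC3 relationship to be embedded in sequences.

    GC3 is drawn uniformly from ``gc3_range`` per sequence, the GC12
    target is ``intercept + slope * GC3`` plus Gaussian noise, and a
    CDS matching both targets to within half a codon's worth (< 0.01
    at the default length) is constructed.
    """

    intercept: float
    slope: float
    noise_sd: float = 0.0
    n_sequences: int = 100
    gc3_range: tuple[float, float] = (0.2, 0.8)
    length: int = 300
    label: str = "neutrality"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gc3_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("gc3_range must satisfy 0 <= lo < hi <= 1")
        for g in (lo, hi):
            m = self.intercept + self.slope * g
            if not -0.5 < m < 1.5:
                raise ValueError("GC12 targets far outside [0,1]; scenario infeasible")


def generate_neutrality_set(scn: NeutralityScenario) -> list[CodingSequence]:
    """Construct sequences realizing a neutrality scenario exactly.

    Only amino acids whose first two codon positions are all-A/U
    (Phe/Ile/Tyr/Asn/Lys) or all-G/C (Pro/Ala/Gly) are used, so GC12
    is fixed by the amino-acid quota and GC3 by a third-base quota:
    both measured values hit their targets to within 1/(2 x length).
    Start/stop codons are not added (they would shift the measured
    composition off the constructed targets).
    """
    rng = np.random.default_rng(scn.seed)
    L = scn.length
    out: list[CodingSequence] = []
    for i in range(scn.n_sequences):
        gc3 = rng.uniform(*scn.gc3_range)
        gc12 = scn.intercept + scn.slope * gc3
        if scn.noise_sd > 0:
            gc12 += rng.normal(0.0, scn.noise_sd)
        gc12 = float(np.clip(gc12, 0.02, 0.98))

        k_strong = int(round(L * gc12))  # codons from GC-prefix families
        m_gc3 = int(round(L * gc3))  # codons with G/C third base

        aa_pool = np.concatenate(
            [
                rng.choice(_STRONG_PREFIX_AAS, size=k_strong),
                rng.choice(_WEAK_PREFIX_AAS, size=L - k_strong),
            ]
        )
        rng.shuffle(aa_pool)
        third_gc = np.zeros(L, dtype=bool)
        third_gc[rng.choice(L, size=m_gc3, replace=False)] = True

        codons = []
        for aa, want_gc in zip(aa_pool, third_gc):
            fam = FAMILIES[aa]
            options = [c for c in fam if (c[2] in "GC") == want_gc]
            codons.append(options[rng.integers(len(options))])
        out.append(
            CodingSequence(
                id=f"{scn.label}_{i:04d}", seq="".join(codons), group=scn.label
            )
        )
    return out


# ---------------------------------------------------------------------------
# presets


PRESETS = ("uniform", "maxbias", "two-pop", "neutrality")


def preset_sequences(name: str, seed: int) -> list[CodingSequence]:
    """Named scenario presets used by the `simulate` CLI subcommand."""
    if name == "uniform":
        return generate_cds_set(uniform_usage(seed=seed))
    if name == "maxbias":
        return generate_cds_set(max_bias_usage(seed=seed))
    if name == "two-pop":
        a, b = two_population_specs(seed=seed)
        return generate_cds_set(a) + generate_cds_set(b)
    if name == "neutrality":
        scn = NeutralityScenario(
            intercept=0.2, slope=0.5, noise_sd=0.01, n_sequences=100, seed=seed
        )
        return generate_neutrality_set(scn)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
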