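"""Principal component analysis of RSCU vectors across sequences.

Each sequence is a point in the 59-dimensional space of synonymous-codon
RSCU values; PCA of the mean-centered matrix (no variance scaling —
RSCU values already share a common scale) summarizes the dominant
codon-usage trends and separates populations with distinct preferences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codon_stats import CodonCounts, RSCUProfile, count_codons, rscu_profile
from .genetic_code import SYNONYMOUS_CODONS, to_rna
from .sequence_io import CodingSequence

#: fixed column order of RSCU matrices (RNA alphabet)
RSCU_COLUMNS: tuple[str, ...] = tuple(to_rna(c) for c in SYNONYMOUS_CODONS)

#: neutral RSCU used to impute families a sequence never uses
NEUTRAL_RSCU = 1.0


@dataclass(frozen=True)
class RSCUMatrix:
    """Sequences x 59 synonymous codons, RSCU values.

    ``values`` is indexed by sequence id with the documented fixed
    codon column order; ``groups`` maps ids to group labels;
    ``imputed`` flags cells whose family was unobserved and was filled
    with the neutral value 1.0.
    """

    values: pd.DataFrame
    groups: pd.Series
    imputed: pd.DataFrame

    @property
    def n_imputed(self) -> int:
        return int(self.imputed.to_numpy().sum())


def rscu_matrix(seqs: Sequence[CodingSequence]) -> RSCUMatrix:
    """Per-sequence RSCU matrix from a coding-sequence set."""
    rows, groups, imputed = [], {}, []
    for s in seqs:
        profile = rscu_profile(count_codons(s))
        series = profile.as_series()
        mask = series.isna()
        rows.append(series.fillna(NEUTRAL_RSCU).rename(s.id))
        imputed.append(mask.rename(s.id))
        groups[s.id] = s.group
    values = pd.DataFrame(rows)[list(RSCU_COLUMNS)]
    return RSCUMatrix(
        values=values,
        groups=pd.Series(groups, name="group"),
        imputed=pd.DataFrame(imputed)[list(RSCU_COLUMNS)],
    )


def rscu_matrix_from_profiles(
    profiles: Iterable[tuple[str, str, RSCUProfile]],
) -> RSCUMatrix:
    """RSCU matrix from (id, group, profile) triples (e.g. pooled groups)."""
    rows, groups, imputed = [], {}, []
    for seq_id, group, profile in profiles:
        series = profile.as_series()
        mask = series.isna()
        rows.append(series.fillna(NEUTRAL_RSCU).rename(seq_id))
        imputed.append(mask.rename(seq_id))
        groups[seq_id] = group
    values = pd.DataFrame(rows)[list(RSCU_COLUMNS)]
    return RSCUMatrix(
        values=values,
        groups=pd.Series(groups, name="group"),
        imputed=pd.DataFrame(imputed)[list(RSCU_COLUMNS)],
    )


@dataclass(frozen=True)
class PCAResult:
    """Scores, variance-explained fractions and loadings of an RSCU PCA."""

    scores: pd.DataFrame  # sequences x PCs
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # codons x PCs


def pca_rscu(matrix: RSCUMatrix, k: int = 2) -> PCAResult:
    """PCA of the mean-centered RSCU matrix.

    Columns are centered but not scaled.  The sign of each component is
    fixed so its largest-magnitude loading is positive, making scores
    reproducible across solvers.  Requires >= 3 rows and non-zero total
    variance.
    """
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs >= 3 sequences, have {n}")
    if k > min(n - 1, X.shape[1]):
        raise ValueError(f"k={k} exceeds min(rows-1, 59) = {min(n - 1, X.shape[1])}")
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("all RSCU rows identical: zero total variance")

    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # codons x PCs

    # deterministic sign: largest-|loading| entry of each PC is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=pcs),
        explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
        loadings=pd.DataFrame(loadings, index=matrix.values.columns, columns=pcs),
    )
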