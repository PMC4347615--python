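"""Evolutionary feature groups computed directly from the PSSM.

Semi-composition (PSSM-SC) is the per-amino-acid column mean of the
substitution probabilities — the PSSM analogue of amino-acid composition.
Auto-covariance (PSSM-AC) is the lagged, column-centered covariance of each
PSSM column up to a distance factor DF, capturing how each amino acid's
substitution profile co-varies with its sequence neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import PSSM


@dataclass
class PSSMFeatureBlock:
    """SC (20) and AC (20 x DF) features for one protein."""

    sc: np.ndarray
    ac: np.ndarray
    distance_factor: int

    def __post_init__(self) -> None:
        self.sc = np.asarray(self.sc, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        if self.sc.shape != (20,):
            raise ValueError("sc must have exactly 20 entries")
        if self.ac.shape != (20 * self.distance_factor,):
            raise ValueError("ac must have exactly 20 * DF entries")


def pssm_sc(pssm: PSSM) -> np.ndarray:
    """Semi-composition: column means of the substitution probabilities.

    For a row-stochastic PSSM the 20 values sum to 1.
    """
    return pssm.probs.mean(axis=0)


def pssm_ac(pssm: PSSM, distance_factor: int = 10) -> np.ndarray:
    """Auto-covariance of each PSSM column up to lag DF.

    For amino acid j and lag k the coefficient is the mean over i of
    (P_{i,j} - P̄_j)(P_{i+k,j} - P̄_j) with divisor L - k, where P̄_j is the
    column mean over the full sequence. Output is amino-acid-major,
    lag-minor: (j=1, k=1..DF), (j=2, k=1..DF), ... — 20 * DF values.

    A sequence with L <= DF cannot support the longest lag; that is a hard
    error (zero-padding would be indistinguishable from genuine zero
    covariance), so callers must lower DF or exclude the protein.
    """
    DF = distance_factor
    L = pssm.length
    if DF < 1:
        raise ValueError("distance factor must be >= 1")
    if L <= DF:
        raise ValueError(
            f"protein {pssm.protein_id!r} has length {L} <= distance factor {DF}; "
            "lower the distance factor or exclude the protein"
        )
    centered = pssm.probs - pssm.probs.mean(axis=0, keepdims=True)
    out = np.empty((20, DF))
    for k in range(1, DF + 1):
        out[:, k - 1] = np.einsum("ij,ij->j", centered[:-k], centered[k:]) / (L - k)
    return out.ravel()


def pssm_feature_block(pssm: PSSM, distance_factor: int = 10) -> PSSMFeatureBlock:
    return PSSMFeatureBlock(
        sc=pssm_sc(pssm),
        ac=pssm_ac(pssm, distance_factor),
        distance_factor=distance_factor,
    )
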