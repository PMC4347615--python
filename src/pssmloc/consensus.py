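"""Evolutionary consensus sequences and normalized attribute sequences.

The consensus sequence replaces each residue of the original protein with the
amino acid of maximum substitution probability at that position of the PSSM.
Physicochemical features downstream are computed on the consensus, not the
original sequence, so evolutionary and physicochemical information combine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import CANONICAL_AA, PSSM, AttributeScale


@dataclass(frozen=True)
class ConsensusSequence:
    """Length-L sequence of maximum-probability amino acids (I_1..I_L)."""

    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("consensus sequence must be non-empty")
        bad = set(self.residues) - set(CANONICAL_AA)
        if bad:
            raise ValueError(f"consensus contains non-canonical residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AttributeSequence:
    """Per-residue normalized physicochemical values R_1..R_L in [0, 1]."""

    protein_id: str
    attribute_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("attribute values must be a non-empty 1-D vector")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("normalized attribute values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


def consensus_sequence(pssm: PSSM) -> ConsensusSequence:
    """Per position, the column-order letter with maximum substitution probability.

    Ties are broken toward the lowest column index, so the result is
    deterministic and invariant to positive rescaling of each row.
    """
    idx = np.argmax(pssm.probs, axis=1)  # argmax takes the first maximum
    residues = "".join(pssm.column_order[j] for j in idx)
    return ConsensusSequence(protein_id=pssm.protein_id, residues=residues)


def _normalize_scale(scale: AttributeScale, normalization: str) -> dict[str, float]:
    raw = scale.as_array(CANONICAL_AA)
    if normalization == "minmax":
        lo, hi = raw.min(), raw.max()
        normed = (raw - lo) / (hi - lo)
    elif normalization == "zscore_clipped":
        z = (raw - raw.mean()) / raw.std(ddof=0)
        normed = (np.clip(z, -3.0, 3.0) + 3.0) / 6.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return dict(zip(CANONICAL_AA, normed))


def attribute_sequence(
    cons: ConsensusSequence,
    scale: AttributeScale,
    normalization: str = "minmax",
) -> AttributeSequence:
    """Map a consensus sequence through a normalized physicochemical scale.

    ``minmax`` (default) rescales the 20 scale values to span [0, 1] exactly,
    which the segment sums downstream implicitly assume; ``zscore_clipped``
    standardizes, clips at ±3 standard deviations and maps to [0, 1].
    The min-max variant is invariant to affine transforms v -> a*v + b (a > 0)
    of the published scale.
    """
    lut = _normalize_scale(scale, normalization)
    values = np.array([lut[aa] for aa in cons.residues], dtype=float)
    return AttributeSequence(
        protein_id=cons.protein_id,
        attribute_id=scale.attribute_id,
        values=values,
    )
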