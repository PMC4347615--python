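"""Overlapped segmented density (OSD) and autocorrelation (OSA) features.

Both feature groups segment the attribute sequence from each end with nested
boundaries that extend past the midpoint, so left- and right-hand segments
overlap in the middle of the protein. OSD sums attribute values over the
segments (plus a whole-sequence mean); OSA computes lagged products within
each segment up to a distance factor DF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import AttributeSequence


@dataclass(frozen=True)
class SegmentationConfig:
    """Segment grid and lag settings for the OSD/OSA feature groups.

    Defaults give the 31 + 150 feature layout: OSD boundaries at
    5%, 10%, ..., 75% of the sequence (15 per side), OSA boundaries at
    10%, ..., 70% (7 per side) with DF = 10 lags each.

    ``boundary_mode`` selects how a d% boundary is located:

    ``length_fraction``
        the first max(1, floor(d/100 * L)) residues from the given end.
    ``mass_fraction``
        the shortest prefix whose attribute-value sum reaches d% of the
        whole-sequence attribute mass.

    ``normalize_osd_by_length`` divides each OSD segment sum by its segment
    length, turning the raw sums into per-residue densities (off by default:
    the segment statistic is the plain sum of normalized attribute values).
    """

    osd_step_percent: int = 5
    osd_max_percent: int = 75
    osa_step_percent: int = 10
    osa_max_percent: int = 70
    distance_factor: int = 10
    boundary_mode: str = "length_fraction"
    normalize_osd_by_length: bool = False

    def __post_init__(self) -> None:
        for step, top in (
            (self.osd_step_percent, self.osd_max_percent),
            (self.osa_step_percent, self.osa_max_percent),
        ):
            if step <= 0 or top <= 0 or top >= 100 or top % step != 0:
                raise ValueError(
                    "segment step must divide the max percent and max must be < 100"
                )
        if self.distance_factor < 1:
            raise ValueError("distance factor must be >= 1")
        if self.boundary_mode not in ("length_fraction", "mass_fraction"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def osd_percents(self) -> list[int]:
        return list(range(self.osd_step_percent, self.osd_max_percent + 1, self.osd_step_percent))

    @property
    def osa_percents(self) -> list[int]:
        return list(range(self.osa_step_percent, self.osa_max_percent + 1, self.osa_step_percent))

    @property
    def n_osd_features(self) -> int:
        return 1 + 2 * len(self.osd_percents)

    @property
    def n_osa_features(self) -> int:
        return (2 * len(self.osa_percents) + 1) * self.distance_factor


@dataclass
class OSDFeatures:
    """31 density features: global mean + 15 left + 15 right segment sums."""

    global_density: float
    left: np.ndarray
    right: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.concatenate(([self.global_density], self.left, self.right))


@dataclass
class OSAFeatures:
    """150 autocorrelation features at DF=10: 7xDF left, 7xDF right, DF global."""

    left: np.ndarray
    right: np.ndarray
    global_ac: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.concatenate((self.left, self.right, self.global_ac))


def segment_boundary(
    attr_seq: AttributeSequence,
    percent: int,
    side: str = "left",
    mode: str = "length_fraction",
) -> int:
    """Number of residues in the d% segment counted from ``side``.

    ``length_fraction`` clamps floor(d/100 * L) to at least 1 so segments are
    never empty; ``mass_fraction`` takes the shortest prefix whose cumulative
    attribute value reaches d% of the total attribute mass.
    """
    if not 0 < percent < 100:
        raise ValueError("percent must be in (0, 100)")
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    values = attr_seq.values if side == "left" else attr_seq.values[::-1]
    L = values.size
    if mode == "length_fraction":
        return min(L, max(1, int(np.floor(percent / 100.0 * L))))
    if mode == "mass_fraction":
        total = values.sum()
        if total == 0:
            return max(1, int(np.floor(percent / 100.0 * L)))
        target = percent / 100.0 * total
        csum = np.cumsum(values)
        # searchsorted finds the first prefix whose mass reaches the target;
        # the epsilon guards against float round-off at exact multiples.
        return min(int(np.searchsorted(csum, target - 1e-12)) + 1, L)
    raise ValueError(f"unknown boundary mode {mode!r}")


def global_density(attr_seq: AttributeSequence) -> float:
    """Mean attribute value over the whole sequence; in [0, 1]."""
    return float(np.mean(attr_seq.values))


def _side_boundaries(attr_seq: AttributeSequence, percents: list[int], side: str, mode: str) -> list[int]:
    return [segment_boundary(attr_seq, p, side, mode) for p in percents]


def osd_features(attr_seq: AttributeSequence, cfg: SegmentationConfig | None = None) -> OSDFeatures:
    """Overlapped segmented density features.

    For each boundary percent d in the OSD grid, the left feature is the sum
    of the first ``segment_boundary(d)`` attribute values; right features are
    computed symmetrically from the sequence end. Output order is global
    density, then left features in ascending d, then right features.
    """
    cfg = cfg or SegmentationConfig()
    vals = attr_seq.values

    def side_sums(values: np.ndarray, boundaries: list[int]) -> np.ndarray:
        csum = np.concatenate(([0.0], np.cumsum(values)))
        sums = np.array([csum[b] for b in boundaries])
        if cfg.normalize_osd_by_length:
            sums = sums / np.array(boundaries, dtype=float)
        return sums

    left_b = _side_boundaries(attr_seq, cfg.osd_percents, "left", cfg.boundary_mode)
    right_b = _side_boundaries(attr_seq, cfg.osd_percents, "right", cfg.boundary_mode)
    return OSDFeatures(
        global_density=global_density(attr_seq),
        left=side_sums(vals, left_b),
        right=side_sums(vals[::-1], right_b),
    )


def _segment_autocorr(values: np.ndarray, D: int, DF: int) -> np.ndarray:
    """Lagged mean products (1/(D-i)) * sum_j R_j R_{j+i} for i = 1..DF.

    A lag longer than the segment (D - i <= 0) yields 0, keeping the feature
    vector length fixed for short proteins.
    """
    out = np.zeros(DF)
    seg = values[:D]
    for i in range(1, DF + 1):
        n = D - i
        if n > 0:
            out[i - 1] = float(seg[:n] @ seg[i:D]) / n
    return out


def osa_features(attr_seq: AttributeSequence, cfg: SegmentationConfig | None = None) -> OSAFeatures:
    """Overlapped segmented autocorrelation features.

    For each side and each boundary percent (7 at defaults), DF lagged
    coefficients are computed within the segment; the right-side block is the
    left-side block of the reversed sequence. A final block of DF coefficients
    uses the whole sequence. Output order: left (segment-major, lag-minor),
    right likewise, then global.
    """
    cfg = cfg or SegmentationConfig()
    DF = cfg.distance_factor
    vals = attr_seq.values
    left_b = _side_boundaries(attr_seq, cfg.osa_percents, "left", cfg.boundary_mode)
    right_b = _side_boundaries(attr_seq, cfg.osa_percents, "right", cfg.boundary_mode)
    left = np.concatenate([_segment_autocorr(vals, D, DF) for D in left_b])
    right = np.concatenate([_segment_autocorr(vals[::-1], D, DF) for D in right_b])
    global_ac = _segment_autocorr(vals, vals.size, DF)
    return OSAFeatures(left=left, right=right, global_ac=global_ac)
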