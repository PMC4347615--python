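"""Assembly of the combined 401-feature vector and per-corpus feature matrices.

The combined ("Comb") vector concatenates, in fixed order, the four feature
groups computed for one protein under one physicochemical attribute:
OSD (31) | OSA (150) | PSSM-SC (20) | PSSM-AC (200). Block boundaries are at
indices 31, 181 and 201 with the default segmentation settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import attribute_sequence, consensus_sequence
from .formats import CANONICAL_AA, PSSM, AttributeScale, SampleTable
from .pssm_features import pssm_ac, pssm_sc
from .segmented import SegmentationConfig, osa_features, osd_features


@dataclass
class FeatureVector:
    """One protein's combined feature vector with provenance metadata."""

    protein_id: str
    attribute_id: str
    values: np.ndarray
    names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("values and names must be aligned 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.protein_id!r}")


def feature_names(attribute_id: str, cfg: SegmentationConfig) -> list[str]:
    """Deterministic column names matching the Comb concatenation order."""
    names = [f"{attribute_id}_osd_global"]
    names += [f"{attribute_id}_osd_left_d{p}" for p in cfg.osd_percents]
    names += [f"{attribute_id}_osd_right_d{p}" for p in cfg.osd_percents]
    for side in ("left", "right"):
        for p in cfg.osa_percents:
            names += [
                f"{attribute_id}_osa_{side}_d{p}_lag{i}"
                for i in range(1, cfg.distance_factor + 1)
            ]
    names += [
        f"{attribute_id}_osa_global_lag{i}" for i in range(1, cfg.distance_factor + 1)
    ]
    names += [f"sc_{aa}" for aa in CANONICAL_AA]
    for aa in CANONICAL_AA:
        names += [f"ac_{aa}_lag{k}" for k in range(1, cfg.distance_factor + 1)]
    return names


def config_hash(cfg: SegmentationConfig, extra: dict | None = None) -> str:
    """Short stable hash of every tunable that shapes a feature matrix."""
    payload = {"segmentation": cfg.__dict__, **(extra or {})}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return digest[:12]


def build_comb_vector(
    pssm: PSSM,
    scale: AttributeScale,
    cfg: SegmentationConfig | None = None,
    normalization: str = "minmax",
) -> FeatureVector:
    """Compute the combined OSD | OSA | SC | AC vector for one protein.

    The PSSM-AC block needs lags up to the distance factor, so proteins with
    L <= DF are rejected by name rather than silently truncated.
    """
    cfg = cfg or SegmentationConfig()
    if pssm.length <= cfg.distance_factor:
        raise ValueError(
            f"protein {pssm.protein_id!r} (length {pssm.length}) is too short for "
            f"distance factor {cfg.distance_factor}"
        )
    cons = consensus_sequence(pssm)
    attr = attribute_sequence(cons, scale, normalization=normalization)

    # SC/AC are computed on the 20 PSSM columns in alphabetical order so the
    # blocks line up with the sc_/ac_ names regardless of the file's ordering.
    aa_order = [pssm.column_order.index(aa) for aa in CANONICAL_AA]
    reordered = PSSM(
        protein_id=pssm.protein_id,
        probs=pssm.probs[:, aa_order],
        residues=pssm.residues,
        column_order=CANONICAL_AA,
    )

    values = np.concatenate(
        (
            osd_features(attr, cfg).values,
            osa_features(attr, cfg).values,
            pssm_sc(reordered),
            pssm_ac(reordered, cfg.distance_factor),
        )
    )
    return FeatureVector(
        protein_id=pssm.protein_id,
        attribute_id=scale.attribute_id,
        values=values,
        names=feature_names(scale.attribute_id, cfg),
        metadata={
            "boundary_mode": cfg.boundary_mode,
            "normalization": normalization,
            "config_hash": config_hash(cfg, {"normalization": normalization}),
        },
    )


def build_feature_matrix(
    pssms: list[PSSM],
    samples: SampleTable,
    scale: AttributeScale,
    cfg: SegmentationConfig | None = None,
    normalization: str = "minmax",
) -> tuple[pd.DataFrame, list[str]]:
    """One feature row per sample, aligned to the sample-table order.

    Samples duplicated from a multi-location protein share one feature
    vector (computed once) but keep their distinct labels. Returns the
    feature DataFrame and the per-row protein ids.
    """
    if len(samples) == 0:
        raise ValueError("sample table is empty")
    cfg = cfg or SegmentationConfig()
    by_id = {p.protein_id: p for p in pssms}
    missing = sorted({pid for pid in samples.protein_ids if pid not in by_id})
    if missing:
        raise ValueError(f"no PSSM for protein(s): {', '.join(missing)}")

    cache: dict[str, FeatureVector] = {}
    rows = []
    for pid in samples.protein_ids:
        if pid not in cache:
            cache[pid] = build_comb_vector(by_id[pid], scale, cfg, normalization)
        rows.append(cache[pid].values)
    names = feature_names(scale.attribute_id, cfg)
    matrix = pd.DataFrame(np.vstack(rows), columns=names)
    return matrix, samples.protein_ids


def write_feature_matrix(
    matrix: pd.DataFrame,
    protein_ids: list[str],
    samples: SampleTable,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write a feature matrix CSV with provenance comment lines.

    Layout: ``#`` metadata lines, then a header row, then one row per sample
    with protein id and label columns followed by the features. Rebuilding
    from the same corpus and configuration reproduces the file byte for byte.
    """
    out = matrix.copy()
    out.insert(0, "protein_id", protein_ids)
    out.insert(1, "label", samples.labels)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, SampleTable]:
    """Read a feature matrix CSV back into features + sample table."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    samples = SampleTable(
        samples=list(zip(df["protein_id"].astype(str), df["label"].astype(str)))
    )
    features = df.drop(columns=["protein_id", "label"])
    return features, samples
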