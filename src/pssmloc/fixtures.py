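"""Synthetic PSSM corpora with controllable class structure.

Real benchmark corpora require PSI-BLAST runs against a large sequence
database, so every pipeline stage here is exercised instead on synthetic
PSSMs: row-stochastic L x 20 matrices whose rows are Dirichlet draws around a
class-specific base composition. The class signal is injected purely through
composition bias — at ``class_signal = 0`` all classes share the uniform
composition and are indistinguishable; raising the signal tilts each class's
composition in its own random direction, which separates classes through the
semi-composition features directly and through the consensus-sequence
features indirectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats import (
    CANONICAL_AA,
    PSIBLAST_COLUMNS,
    PSSM,
    AttributeScale,
    DatasetManifest,
    SampleTable,
    write_attribute_scale,
    write_manifest,
    write_pssm_ascii,
)

#: Per-class sample counts echoing the shape of a markedly imbalanced
#: 8-location corpus (two dominant classes, two classes of a handful of
#: samples), scaled down for fast tests of per-location reporting.
IMBALANCED_PRESET_SIZES = (56, 12, 41, 13, 4, 2, 2, 18)


@dataclass(frozen=True)
class FixtureSpec:
    """Settings for one synthetic labeled corpus.

    ``class_signal`` is the standard deviation of the per-class log-composition
    tilt: class c's base composition is softmax(class_signal * z_c) with z_c a
    fixed standard-normal 20-vector per class. ``concentration`` is the
    Dirichlet sharpness of individual PSSM rows around that base (larger =
    less per-position noise).
    """

    n_classes: int
    samples_per_class: int | tuple[int, ...] = 50
    length_range: tuple[int, int] = (50, 200)
    class_signal: float = 0.5
    concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.class_signal < 0:
            raise ValueError("class_signal must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        sizes = self.class_sizes
        if len(sizes) != self.n_classes or any(s < 1 for s in sizes):
            raise ValueError("samples_per_class must give >= 1 sample per class")

    @property
    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_class, int):
            return (self.samples_per_class,) * self.n_classes
        return tuple(self.samples_per_class)


def synth_attribute_scale(
    rng: np.random.Generator, attribute_id: str = "synthetic"
) -> AttributeScale:
    """A non-degenerate random scale: 20 distinct uniform(0, 1) values."""
    while True:
        vals = rng.uniform(0.0, 1.0, size=20)
        if np.unique(vals).size == 20:
            break
    return AttributeScale(
        attribute_id=attribute_id,
        values={aa: float(v) for aa, v in zip(CANONICAL_AA, vals)},
    )


def synth_pssm(
    L: int,
    base_composition: np.ndarray,
    concentration: float,
    rng: np.random.Generator,
    protein_id: str = "synthetic",
) -> PSSM:
    """Draw an L x 20 row-stochastic PSSM around a base composition.

    Rows are Dirichlet(concentration * base_composition); the query sequence
    is sampled residue-by-residue from the base composition.
    """
    base = np.asarray(base_composition, dtype=float)
    if base.shape != (20,) or np.any(base < 0) or abs(base.sum() - 1.0) > 1e-6:
        raise ValueError("base_composition must be a point on the 20-simplex")
    alpha = np.maximum(concentration * base, 1e-6)
    probs = rng.dirichlet(alpha, size=L)
    letters = np.array(list(PSIBLAST_COLUMNS))
    residues = "".join(rng.choice(letters, size=L, p=base / base.sum()))
    return PSSM(protein_id=protein_id, probs=probs, residues=residues)


def class_compositions(
    n_classes: int, class_signal: float, rng: np.random.Generator
) -> np.ndarray:
    """One base composition per class: softmax(class_signal * z), z ~ N(0, I)."""
    z = rng.standard_normal((n_classes, 20))
    logits = class_signal * z
    comp = np.exp(logits - logits.max(axis=1, keepdims=True))
    return comp / comp.sum(axis=1, keepdims=True)


def synth_dataset(spec: FixtureSpec) -> tuple[SampleTable, list[PSSM]]:
    """A labeled corpus: one single-location protein per sample.

    Returns the sample table and the PSSMs in the same order. Class labels
    are ``loc00``, ``loc01``, ... Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    comps = class_compositions(spec.n_classes, spec.class_signal, rng)
    samples: list[tuple[str, str]] = []
    pssms: list[PSSM] = []
    lo, hi = spec.length_range
    counter = 0
    for c, n_c in enumerate(spec.class_sizes):
        label = f"loc{c:02d}"
        for _ in range(n_c):
            pid = f"prot{counter:05d}"
            counter += 1
            L = int(rng.integers(lo, hi + 1))
            pssms.append(
                synth_pssm(L, comps[c], spec.concentration, rng, protein_id=pid)
            )
            samples.append((pid, label))
    return SampleTable(samples=samples), pssms


def synth_manifest(
    n_single: int,
    n_multi: int,
    labels: tuple[str, ...],
    rng: np.random.Generator,
) -> DatasetManifest:
    """A random manifest with ``n_single`` one-location and ``n_multi``
    two-location proteins, for exercising manifest expansion and group-aware CV."""
    if len(labels) < 2 and n_multi > 0:
        raise ValueError("need at least two labels for multi-location proteins")
    entries: list[tuple[str, frozenset[str]]] = []
    for i in range(n_single):
        entries.append((f"s{i:05d}", frozenset([str(rng.choice(labels))])))
    for i in range(n_multi):
        pair = rng.choice(labels, size=2, replace=False)
        entries.append((f"m{i:05d}", frozenset(map(str, pair))))
    return DatasetManifest(entries=entries, label_universe=list(labels))


def write_fixture_corpus(spec: FixtureSpec, outdir: str | Path) -> Path:
    """Materialize a synthetic corpus on disk in the exact external formats
    the readers consume: one ASCII PSSM per protein under ``pssm/``, a
    manifest TSV and an attribute-scale TSV."""
    outdir = Path(outdir)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    table, pssms = synth_dataset(spec)
    for pssm in pssms:
        write_pssm_ascii(pssm, pssm_dir / f"{pssm.protein_id}.pssm")
    entries = [(pid, frozenset([lab])) for pid, lab in table.samples]
    write_manifest(DatasetManifest(entries=entries), outdir / "manifest.tsv")
    rng = np.random.default_rng(spec.seed + 1)
    write_attribute_scale(synth_attribute_scale(rng), outdir / "scale.tsv")
    return outdir
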