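"""Readers and writers for the external formats the pipeline touches.

Covers multi-record FASTA, PSI-BLAST ASCII PSSM output (the ``-out_ascii_pssm``
dialect), physicochemical attribute scales (two-column TSV or AAindex flat
file), and tab-separated dataset manifests mapping protein IDs to one or more
subcellular-location labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Column order used by PSI-BLAST ASCII PSSM files.
PSIBLAST_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: Alphabetical canonical ordering used for attribute scales.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes tolerated in input sequences (never in consensus output).
AMBIGUITY_CODES = "XBZU"


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


class DegenerateScaleError(ValueError):
    """Raised when all 20 values of an attribute scale are identical."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (the original protein O_1..O_L)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of {self.id!r} must be non-empty")
        allowed = set(CANONICAL_AA + AMBIGUITY_CODES)
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass
class PSSM:
    """Position-specific scoring matrix for one protein.

    ``probs`` is an L x 20 row-stochastic matrix: row i gives the substitution
    probability of position i with each of the 20 amino acids, in
    ``column_order``. ``residues`` is the query sequence echoed by PSI-BLAST.
    """

    protein_id: str
    probs: np.ndarray
    residues: str
    column_order: str = PSIBLAST_COLUMNS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must be an L x 20 matrix")
        if self.probs.shape[0] == 0:
            raise ValueError("PSSM must have at least one row")
        if len(self.residues) != self.probs.shape[0]:
            raise ValueError("residues length must match row count")
        if len(self.column_order) != 20 or len(set(self.column_order)) != 20:
            raise ValueError("column_order must list the 20 amino acids once")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PSSM row must sum to 1 (±1e-9)")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class AttributeScale:
    """One physicochemical attribute: a real value per canonical amino acid."""

    attribute_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(CANONICAL_AA):
            missing = sorted(set(CANONICAL_AA) - set(self.values))
            extra = sorted(set(self.values) - set(CANONICAL_AA))
            raise FormatError(
                f"scale {self.attribute_id!r} must cover exactly the 20 canonical "
                f"amino acids (missing {missing}, unexpected {extra})"
            )
        vals = list(self.values.values())
        if max(vals) == min(vals):
            raise DegenerateScaleError(
                f"scale {self.attribute_id!r} has identical values for all residues"
            )

    def as_array(self, order: str = CANONICAL_AA) -> np.ndarray:
        return np.array([self.values[a] for a in order], dtype=float)


@dataclass
class DatasetManifest:
    """Protein IDs with one or more location labels each."""

    entries: list[tuple[str, frozenset[str]]]
    label_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, labels in self.entries:
            if not labels:
                raise ValueError(f"protein {pid!r} has no labels")
            if pid in seen:
                raise ValueError(f"duplicate protein id {pid!r} in manifest")
            seen.add(pid)
        if not self.label_universe:
            ordered: list[str] = []
            for _, labels in self.entries:
                for lab in sorted(labels):
                    if lab not in ordered:
                        ordered.append(lab)
            self.label_universe = ordered
        universe = set(self.label_universe)
        for pid, labels in self.entries:
            stray = labels - universe
            if stray:
                raise ValueError(f"protein {pid!r} uses unknown labels {sorted(stray)}")


@dataclass
class SampleTable:
    """One row per (protein, location) pair.

    Multi-location proteins contribute one sample per annotated location; all
    samples of a protein share the protein id as group key so cross-validation
    can keep them in the same fold.
    """

    samples: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.samples]

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.samples]

    @property
    def group_keys(self) -> list[str]:
        return self.protein_ids


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated and sequences are uppercased.
    Raises :class:`FormatError` for an empty file or for sequence data
    appearing before the first header.
    """
    path = Path(path)
    first_content_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content_line = (lineno, line)
                break
    if first_content_line is None:
        raise FormatError(f"{path}: empty FASTA file")
    lineno, line = first_content_line
    if not line.startswith(">"):
        raise FormatError(f"{path}: line {lineno}: sequence data before any '>' header")

    records = []
    ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        ids.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def _looks_like_pssm_row(tokens: list[str]) -> bool:
    return (
        len(tokens) >= 2
        and tokens[0].isdigit()
        and len(tokens[1]) == 1
        and tokens[1].isalpha()
    )


def parse_pssm(
    path: str | Path,
    prob_source: str = "percentages",
    protein_id: str | None = None,
) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` output).

    Each data row carries a position index, the query residue, 20 log-odds
    integers, 20 weighted-percentage integers, and trailing information
    columns. ``prob_source`` selects how substitution probabilities are built:

    ``percentages``
        percentage block / 100, then each row renormalized to sum 1
        (an all-zero row is replaced by the uniform distribution).
    ``sigmoid_logodds``
        logistic transform ``1/(1+exp(-s))`` of the log-odds block, then
        row-renormalized.
    """
    if prob_source not in ("percentages", "sigmoid_logodds"):
        raise ValueError(f"unknown prob_source {prob_source!r}")
    path = Path(path)
    logodds_rows: list[list[float]] = []
    pct_rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not _looks_like_pssm_row(tokens):
                continue
            # 42 = index + residue + 20 log-odds + 20 percentages; information
            # and gapless-match columns may follow.
            if len(tokens) < 42:
                raise FormatError(
                    f"{path}: line {lineno} (row {len(residues) + 1}): expected at "
                    f"least 42 columns, found {len(tokens)}"
                )
            try:
                logodds_rows.append([float(t) for t in tokens[2:22]])
                pct_rows.append([float(t) for t in tokens[22:42]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric matrix entry ({exc})"
                ) from None
            residues.append(tokens[1].upper())
    if not residues:
        raise FormatError(f"{path}: no PSSM data rows found")

    if prob_source == "percentages":
        raw = np.asarray(pct_rows, dtype=float) / 100.0
        zero_rows = raw.sum(axis=1) == 0
        raw[zero_rows] = 1.0 / 20.0
    else:
        raw = 1.0 / (1.0 + np.exp(-np.asarray(logodds_rows, dtype=float)))
    probs = raw / raw.sum(axis=1, keepdims=True)
    return PSSM(
        protein_id=protein_id if protein_id is not None else path.stem,
        probs=probs,
        residues="".join(residues),
    )


def write_pssm_ascii(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect that :func:`parse_pssm` reads.

    Percentages are the rounded probabilities x 100; log-odds integers are a
    rounded half-bit score against the uniform background. Intended for
    synthetic fixtures and round-trip tests, not byte-faithful PSI-BLAST output.
    """
    cols = pssm.column_order
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 11 + "  ".join(cols) + "   " + "  ".join(cols) + "\n")
        for i in range(pssm.length):
            p = pssm.probs[i]
            with np.errstate(divide="ignore"):
                logodds = np.where(p > 0, np.round(2 * np.log2(np.maximum(p, 1e-9) * 20)), -9)
            pct = np.round(p * 100)
            fields = [f"{i + 1:5d} {pssm.residues[i]}"]
            fields += [f"{int(v):4d}" for v in logodds]
            fields += [f"{int(v):4d}" for v in pct]
            entropy = -float(np.sum(p[p > 0] * np.log2(p[p > 0])))
            fields.append(f"  {math.log2(20) - entropy:5.2f} {1.0:5.2f}")
            fh.write("".join(fields) + "\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Attribute scales

# AAindex lists values in two rows of ten, in this residue order.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTVWY"


def _parse_aaindex(lines: list[str], path: Path, attribute_id: str | None) -> AttributeScale:
    accession = None
    values: dict[str, float] = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
        if line.startswith("I "):
            if i + 2 >= len(lines):
                raise FormatError(f"{path}: truncated AAindex value block")
            row1 = lines[i + 1].split()
            row2 = lines[i + 2].split()
            if len(row1) != 10 or len(row2) != 10:
                raise FormatError(
                    f"{path}: AAindex value rows must have 10 entries each"
                )
            try:
                for aa, tok in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, row1 + row2):
                    values[aa] = float(tok)
            except ValueError:
                raise FormatError(f"{path}: non-numeric AAindex value") from None
            break
        i += 1
    if not values:
        raise FormatError(f"{path}: no AAindex 'I' value block found")
    return AttributeScale(
        attribute_id=attribute_id or accession or path.stem, values=values
    )


def read_attribute_scale(path: str | Path, attribute_id: str | None = None) -> AttributeScale:
    """Read a physicochemical scale from a two-column TSV or an AAindex entry.

    The TSV dialect is ``<residue><TAB><value>`` with ``#`` comments. Exactly
    20 canonical residues are required; missing or duplicated residues raise
    :class:`FormatError`, an all-identical scale raises
    :class:`DegenerateScaleError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    stripped = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not stripped:
        raise FormatError(f"{path}: empty attribute-scale file")
    if any(ln.startswith(("H ", "I ")) for ln in stripped):
        return _parse_aaindex(stripped, path, attribute_id)

    values: dict[str, float] = {}
    for ln in stripped:
        parts = ln.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: expected '<residue> <value>' rows, got {ln!r}")
        aa, val = parts[0].upper(), parts[1]
        if aa in values:
            raise FormatError(f"{path}: residue {aa!r} listed twice")
        try:
            values[aa] = float(val)
        except ValueError:
            raise FormatError(f"{path}: non-numeric value {val!r} for {aa!r}") from None
    missing = sorted(set(CANONICAL_AA) - set(values))
    if missing:
        raise FormatError(f"{path}: missing residues {missing}")
    return AttributeScale(attribute_id=attribute_id or path.stem, values=values)


def write_attribute_scale(scale: AttributeScale, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# attribute scale {scale.attribute_id}\n")
        for aa in CANONICAL_AA:
            fh.write(f"{aa}\t{float(scale.values[aa])!r}\n")


# ---------------------------------------------------------------------------
# Dataset manifests


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a tab-separated manifest: ``protein_id<TAB>label[;label]``.

    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    entries: list[tuple[str, frozenset[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 'protein_id<TAB>labels', got {line!r}"
            )
        pid, labels = parts[0].strip(), parts[1].strip()
        labset = frozenset(l.strip() for l in labels.split(";") if l.strip())
        if not pid or not labset:
            raise FormatError(f"{path}: line {lineno}: empty protein id or label list")
        entries.append((pid, labset))
    if not entries:
        raise FormatError(f"{path}: manifest has no entries")
    return DatasetManifest(entries=entries)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tlabel[;label]\n")
        for pid, labels in manifest.entries:
            fh.write(f"{pid}\t{';'.join(sorted(labels))}\n")


def expand_manifest(manifest: DatasetManifest) -> SampleTable:
    """Expand a manifest into one sample per (protein, location) pair.

    A protein annotated to m locations contributes m samples, so the sample
    count is the sum of label-set sizes (e.g. 515 single- plus 4 dual-location
    proteins expand to 523 samples). All samples of a protein share its id as
    group key.
    """
    samples: list[tuple[str, str]] = []
    for pid, labels in manifest.entries:
        for lab in sorted(labels):
            samples.append((pid, lab))
    return SampleTable(samples=samples)
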