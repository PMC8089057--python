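"""Domain types and on-disk formats for contact prediction.

Covers protein records (FASTA), sequence-profile (PSSM) and coevolution (PLM)
feature tensors, binary/probabilistic contact maps derived from residue
coordinates, CASP RR prediction files, and a per-protein bundle container.

Conventions: residue indices are 0-based half-open internally; the RR text
format is 1-based inclusive (CASP convention). A residue pair (i, j) is a
contact when the Euclidean distance between the representative atoms (C-beta;
C-alpha for glycine) is strictly less than the threshold, 8.0 Angstrom by
default.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AMINO_ACIDS", "ProteinRecord", "Pssm", "PlmTensor", "ContactMap",
    "ResidueCoords", "FeatureSet", "SEPARATION_RANGES", "FormatError",
    "read_fasta", "write_fasta", "contacts_from_coords", "range_mask",
    "write_rr", "read_rr", "write_feature_bundle", "read_feature_bundle",
    "read_pssm_text",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS + "X")

#: sequence-separation bands: name -> (lower, upper) inclusive bounds on |i-j|
SEPARATION_RANGES: dict[str, tuple[int, float]] = {
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, float("inf")),
}


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError(f"{self.id}: sequence must have length >= 2")
        bad = set(self.sequence) - _VALID
        if bad:
            raise FormatError(
                f"{self.id}: illegal residue characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Pssm:
    """Position-specific scoring matrix, one 20-column row per residue."""

    values: np.ndarray  # (L, 20)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"PSSM must be (L, 20), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("PSSM contains non-finite entries")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class PlmTensor:
    """Pairwise coevolution coupling features, (L, L, C)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"PLM must be (L, L, C), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("PLM contains non-finite entries")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


@dataclass
class ContactMap:
    """L x L contact matrix: binary ground truth or probabilistic prediction."""

    values: np.ndarray
    kind: str  # "binary" | "probability"
    validity: np.ndarray | None = None  # pairs with defined ground truth

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"contact map must be square, got {self.values.shape}")
        if self.kind not in ("binary", "probability"):
            raise ValueError(f"unknown contact-map kind {self.kind!r}")
        if self.kind == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary map entries must be 0 or 1")
            if not np.allclose(self.values, self.values.T):
                raise ValueError("binary map must be symmetric")
            if np.diagonal(self.values).any():
                raise ValueError("binary map must have zero diagonal")
        else:
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError("probability map entries must lie in [0, 1]")
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != self.values.shape:
                raise ValueError("validity mask shape mismatch")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class ResidueCoords:
    """One representative atom per residue, Angstrom units."""

    coords: np.ndarray  # (L, 3)
    mask: np.ndarray | None = None  # True where the residue is resolved

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {self.coords.shape}")
        if self.mask is None:
            self.mask = np.ones(self.coords.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.isfinite(self.coords[self.mask]).all():
            raise ValueError("non-finite coordinates at resolved residues")

    @property
    def length(self) -> int:
        return self.coords.shape[0]


@dataclass
class FeatureSet:
    """The paired 1D and 2D inputs for one protein, plus optional truth."""

    pssm: Pssm
    plm: PlmTensor
    contacts: ContactMap | None = None

    def __post_init__(self):
        if self.pssm.length != self.plm.length:
            raise ValueError(
                f"PSSM length {self.pssm.length} != PLM length {self.plm.length}")
        if self.contacts is not None and self.contacts.length != self.pssm.length:
            raise ValueError("contact map length mismatch")

    @property
    def length(self) -> int:
        return self.pssm.length


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, strict: bool = False) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Sequences are upper-cased and internal whitespace is removed. With
    ``strict=True``, internal whitespace inside a sequence line is an error
    instead.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if strict:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.startswith(">") and re.search(r"\S\s+\S", line):
                raise FormatError(f"{path}:{lineno}: whitespace inside sequence")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = re.sub(r"\s+", "", str(rec.seq)).upper()
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Contacts and separation ranges

def contacts_from_coords(coords: ResidueCoords, threshold: float = 8.0) -> ContactMap:
    """Binary contact map: pairs of resolved residues closer than ``threshold``.

    Pairs involving unresolved residues are 0 and marked invalid in the
    returned map's validity mask, so they can be excluded from scoring.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = coords.length
    if int(coords.mask.sum()) < 2:
        raise ValueError("need at least 2 resolved residues")
    safe = np.where(coords.mask[:, None], coords.coords, 0.0)
    dist = squareform(pdist(safe))
    valid = np.outer(coords.mask, coords.mask)
    np.fill_diagonal(valid, False)
    values = ((dist < threshold) & valid).astype(np.float64)
    np.fill_diagonal(values, 0.0)
    return ContactMap(values=values, kind="binary", validity=valid)


def range_mask(L: int, range_name: str) -> np.ndarray:
    """Boolean (L, L) mask of pairs whose separation |i-j| is in the band."""
    if L < 2:
        raise ValueError("L must be >= 2")
    if range_name not in SEPARATION_RANGES:
        raise KeyError(f"unknown separation range {range_name!r}; "
                       f"expected one of {sorted(SEPARATION_RANGES)}")
    lo, hi = SEPARATION_RANGES[range_name]
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    return (sep >= lo) & (sep <= hi)


# ---------------------------------------------------------------------------
# CASP RR format

def _ranked_pairs(values: np.ndarray) -> Iterator[tuple[int, int, float]]:
    L = values.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    scores = values[iu, ju]
    # descending score, ties by (i, j) ascending
    order = np.lexsort((ju, iu, -scores))
    for idx in order:
        yield int(iu[idx]), int(ju[idx]), float(scores[idx])


def write_rr(pred: ContactMap, record: ProteinRecord, path: str | Path,
             top_k: int | None = None) -> None:
    """Write a CASP RR prediction file: sequence header then 'i j 0 8 p' lines.

    Pairs are 1-based with i < j, sorted by descending probability (ties by
    ascending (i, j)), at most ``top_k`` lines.
    """
    if pred.kind != "probability":
        raise ValueError("RR output requires a probability-kind map")
    if pred.length != record.length:
        raise ValueError("prediction length does not match record")
    lines = [record.sequence]
    for rank, (i, j, p) in enumerate(_ranked_pairs(pred.values)):
        if top_k is not None and rank >= top_k:
            break
        lines.append(f"{i + 1} {j + 1} 0 8 {p:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr(path: str | Path, length: int | None = None
            ) -> tuple[str, list[tuple[int, int, float]]]:
    """Read an RR file; returns (sequence, [(i, j, p)]) with 0-based i < j."""
    seq_parts: list[str] = []
    pairs: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("PFRMAT", "TARGET", "MODEL", "END")):
            continue
        fields = line.split()
        if len(fields) == 1 and not fields[0][0].isdigit():
            seq_parts.append(fields[0])
            continue
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 'i j d1 d2 p'")
        i, j = int(fields[0]) - 1, int(fields[1]) - 1
        if i >= j:
            raise FormatError(f"{path}:{lineno}: require i < j (1-based)")
        pairs.append((i, j, float(fields[4])))
    sequence = "".join(seq_parts)
    if length is not None and sequence and len(sequence) != length:
        raise FormatError(f"{path}: sequence length {len(sequence)} != {length}")
    return sequence, pairs


def rr_to_map(sequence: str, pairs: list[tuple[int, int, float]]) -> ContactMap:
    L = len(sequence)
    values = np.zeros((L, L))
    for i, j, p in pairs:
        values[i, j] = values[j, i] = p
    return ContactMap(values=values, kind="probability")


# ---------------------------------------------------------------------------
# Per-protein feature bundles

def write_feature_bundle(fs: FeatureSet, record: ProteinRecord,
                         path: str | Path) -> None:
    """Write one protein's features as a keyed-array container (.npz).

    Stores the PSSM, the PLM tensor, the optional true contact map with its
    validity mask, and a JSON metadata block (id, sequence). Lossless.
    """
    if fs.length != record.length:
        raise ValueError("feature set length does not match record")
    meta = {"id": record.id, "sequence": record.sequence,
            "has_contacts": fs.contacts is not None}
    arrays = {"pssm": fs.pssm.values, "plm": fs.plm.values,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if fs.contacts is not None:
        arrays["contacts"] = fs.contacts.values
        validity = fs.contacts.validity
        if validity is None:
            validity = ~np.eye(fs.length, dtype=bool)
        arrays["validity"] = validity
    np.savez(path, **arrays)


def read_feature_bundle(path: str | Path) -> tuple[ProteinRecord, FeatureSet]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        record = ProteinRecord(id=meta["id"], sequence=meta["sequence"])
        pssm = Pssm(values=data["pssm"])
        plm = PlmTensor(values=data["plm"])
        contacts = None
        if meta["has_contacts"]:
            contacts = ContactMap(values=data["contacts"], kind="binary",
                                  validity=data["validity"])
    if pssm.length != plm.length:
        raise FormatError(
            f"{path}: PSSM length {pssm.length} != PLM length {plm.length}")
    if pssm.length != record.length:
        raise FormatError(f"{path}: feature length != sequence length")
    return record, FeatureSet(pssm=pssm, plm=plm, contacts=contacts)


def read_pssm_text(path: str | Path) -> Pssm:
    """Read an externally produced PSSM as a plain whitespace-separated matrix."""
    values = np.loadtxt(path, ndmin=2)
    if values.shape[1] != 20:
        raise FormatError(f"{path}: expected 20 columns, got {values.shape[1]}")
    return Pssm(values=values)
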