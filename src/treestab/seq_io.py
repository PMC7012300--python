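"""Aligned-sequence I/O and label maps.

Alignments are stored column-wise as a small integer matrix over the DNA
alphabet ``{A, C, G, T, N, -}`` (case-folded to upper case on input). ``N``
and ``-`` are both treated as missing data by the distance code. Reading
supports aligned FASTA and relaxed sequential PHYLIP; writing is FASTA only.

A :class:`LabelMap` is a bijection between the sequence labels of two
homologous gene families (typically pairing paralogs by species); it is what
lets a subtree topology estimated in one family be looked up among the
bootstrap topologies of the other.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import AlignmentError, FormatError, LabelLookupError

#: integer codes for the alignment matrix; codes >= MISSING_CODE are missing
ALPHABET = "ACGTN-"
MISSING_CODE = 4  # N; gap is 5

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def _encode_sequence(label: str, seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        col = int(bad[0])
        raise FormatError(
            f"illegal character {seq[col]!r} in record {label!r} at column {col + 1}"
        )
    return codes


@dataclass(frozen=True, eq=False)
class Alignment:
    """An aligned set of DNA sequences with unique, ordered labels."""

    labels: tuple[str, ...]
    data: np.ndarray  # shape (n_seqs, n_sites), uint8 codes into ALPHABET

    def __post_init__(self) -> None:
        if len(self.labels) != self.data.shape[0]:
            raise AlignmentError("label count does not match sequence count")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate sequence label(s): {', '.join(dupes)}")
        if any(not l for l in self.labels):
            raise FormatError("empty sequence label")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        labels: list[str] = []
        rows: list[np.ndarray] = []
        for label, seq in records:
            labels.append(label)
            rows.append(_encode_sequence(label, seq))
        if not rows:
            raise FormatError("no sequence records")
        n_sites = rows[0].size
        for label, row in zip(labels, rows):
            if row.size != n_sites:
                raise AlignmentError(
                    f"record {label!r} has length {row.size}, expected {n_sites}"
                )
        return cls(tuple(labels), np.vstack(rows))

    @property
    def n_seqs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise LabelLookupError(label) from None
        return _decode_row(self.data[i])

    def records(self) -> Iterator[tuple[str, str]]:
        for i, label in enumerate(self.labels):
            yield label, _decode_row(self.data[i])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.data, other.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Alignment({self.n_seqs} seqs x {self.n_sites} sites)"


def _decode_row(row: np.ndarray) -> str:
    return _DECODE[row].tobytes().decode("ascii")


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order follows file order; sequences are case-folded to upper
    case. Ragged records raise :class:`AlignmentError`; duplicate labels or
    illegal characters raise :class:`FormatError`.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise FormatError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    return Alignment.from_records(records)


def read_phylip(path: str | Path) -> Alignment:
    """Read a relaxed sequential PHYLIP alignment."""
    try:
        msa = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable relaxed PHYLIP file ({exc})") from exc
    return Alignment.from_records((r.id, str(r.seq)) for r in msa)


def read_alignment(path: str | Path) -> Alignment:
    """Read FASTA or relaxed PHYLIP, sniffing the format from the first byte."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fasta(path) if first == ">" else read_phylip(path)


def write_fasta(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in alignment.records():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def subset(alignment: Alignment, labels: Sequence[str]) -> Alignment:
    """Extract the requested records, in the requested order; sites unchanged."""
    index = {l: i for i, l in enumerate(alignment.labels)}
    missing = [l for l in labels if l not in index]
    if missing:
        raise LabelLookupError(f"label(s) not in alignment: {', '.join(missing)}")
    rows = np.array([index[l] for l in labels], dtype=int)
    return Alignment(tuple(labels), alignment.data[rows])


class LabelMap:
    """A bijection from family-A sequence labels to family-B labels."""

    def __init__(self, pairs: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
        fwd: dict[str, str] = {}
        rev: dict[str, str] = {}
        for a, b in items:
            if a in fwd:
                raise FormatError(f"duplicate key in label map: {a!r}")
            if b in rev:
                raise FormatError(f"duplicate value in label map: {b!r}")
            fwd[a] = b
            rev[b] = a
        self._fwd = fwd
        self._rev = rev

    def __len__(self) -> int:
        return len(self._fwd)

    def __contains__(self, label: str) -> bool:
        return label in self._fwd

    def __getitem__(self, label: str) -> str:
        try:
            return self._fwd[label]
        except KeyError:
            raise LabelLookupError(label) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return self._fwd == other._fwd

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._fwd.items())

    def inverse(self) -> "LabelMap":
        return LabelMap(self._rev)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"LabelMap({len(self)} pairs)"


def read_label_map(path: str | Path) -> LabelMap:
    """Read a two-column TSV of (family A label, family B label) pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((row[0].strip(), row[1].strip()))
    if not pairs:
        raise FormatError(f"{path}: empty label map")
    return LabelMap(pairs)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for a, b in label_map.items():
            writer.writerow([a, b])


def species_token(label: str, delimiter: str = "_", index: int = -1) -> str:
    """Extract the species token from a label (default: last ``_``-field)."""
    parts = label.split(delimiter)
    return parts[index]


def build_species_map(
    labels_a: Iterable[str],
    labels_b: Iterable[str],
    delimiter: str = "_",
    index: int = -1,
) -> LabelMap:
    """Pair labels of two families that share a species token.

    Mirrors how paralog pairs are matched in practice: ``DPA_Hs`` ↔
    ``DPB_Hs`` by the shared ``Hs`` species field.
    """
    by_species_b: dict[str, str] = {}
    for b in labels_b:
        tok = species_token(b, delimiter, index)
        if tok in by_species_b:
            raise FormatError(f"species token {tok!r} is ambiguous in family B")
        by_species_b[tok] = b
    pairs = []
    for a in labels_a:
        tok = species_token(a, delimiter, index)
        if tok not in by_species_b:
            raise LabelLookupError(f"no family-B label with species token {tok!r}")
        pairs.append((a, by_species_b[tok]))
    return LabelMap(pairs)
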