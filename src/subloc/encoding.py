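"""Sequence representation: fixed-length per-residue feature encoding.

Each residue is represented by a 25-vector: five physicochemical
eigen-descriptor scores followed by a 20-component profile row. The profile
comes from a PSI-BLAST position-specific scoring matrix when one is
available and from the residue's BLOSUM62 substitution-score row otherwise.
Proteins are encoded at a fixed length (default 1000): shorter sequences are
zero-padded at the C-terminal end and masked; longer sequences keep the
first and last 500 residues.

All residue coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: canonical amino-acid order, identical to the PSI-BLAST PSSM header order
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: ambiguous or rare letters folded into X before encoding
NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}

ENCODE_LENGTH = 1000
FEATURE_DIM = 25


class EncodingError(ValueError):
    """Raised for malformed encoding inputs (tables, PSSM files, lengths)."""


@dataclass
class ProteinRecord:
    """A protein with its localization annotation and curation metadata."""

    accession: str
    sequence: str
    organelle_labels: set = field(default_factory=set)
    suborganelle_labels: set = field(default_factory=set)
    cleavage_site: int | None = None  # 1-based last residue of the targeting peptide
    created_year: int | None = None
    evidence_experimental: bool = False
    # curation metadata (optional; required only by the filters that use them)
    existence_level: str | None = None  # "protein" | "transcript" | ...
    is_fragment: bool | None = None
    organelle_encoded: bool | None = None
    cluster_id: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.cleavage_site is not None and not (
            1 <= self.cleavage_site < len(self.sequence)
        ):
            raise ValueError(
                f"{self.accession}: cleavage_site {self.cleavage_site} outside "
                f"[1, {len(self.sequence) - 1}]"
            )


@dataclass
class PhysChemTable:
    """Per-letter 5-component descriptor vectors with an X fallback."""

    vectors: dict  # letter -> np.ndarray(5)
    fallback: np.ndarray  # used for X / unknown letters

    def row(self, letter: str) -> np.ndarray:
        letter = NONSTANDARD.get(letter, letter)
        return self.vectors.get(letter, self.fallback)


@dataclass
class ProfileMatrix:
    """Per-residue 20-component profile rows (PSSM or BLOSUM62 fallback)."""

    rows: np.ndarray  # (L, 20) float
    source_flag: str  # "pssm" | "blosum62"


@dataclass
class EncodedProtein:
    """Fixed-length feature matrix with validity mask and coordinate map."""

    features: np.ndarray  # (encode_length, 25)
    mask: np.ndarray  # (encode_length,) uint8
    origin_map: np.ndarray  # (encode_length,) int, 1-based raw index; 0 = padding
    raw_length: int
    accession: str = ""


def load_physchem(table_path=None) -> PhysChemTable:
    """Load the 5-descriptor table (bundled default when no path given).

    The file is TSV: letter followed by five floats; '#' lines are comments.
    Every one of the 20 standard amino acids must be present.
    """
    if table_path is None:
        text = (
            resources.files("subloc").joinpath("data/physchem_pc5.tsv").read_text()
        )
    else:
        with open(table_path) as fh:
            text = fh.read()
    vectors = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise EncodingError(f"physchem table: expected 6 columns, got {line!r}")
        vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    for aa in AA_ORDER:
        if aa not in vectors:
            raise EncodingError(f"physchem table: missing amino acid {aa!r}")
    fallback = vectors.get("X", np.zeros(5))
    return PhysChemTable(vectors=vectors, fallback=fallback)


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(.*)$")


def read_pssm(pssm_path, sequence: str) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM and check it against `sequence`.

    Only the first 20 numeric columns (the log-odds block) are used, in the
    standard header order A R N D C Q E G H I L K M F P S T W Y V.
    """
    rows = []
    with open(pssm_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            m = _PSSM_ROW.match(line)
            if not m:
                continue
            fields = m.group(3).split()
            if len(fields) < 20:
                continue  # header or trailer line
            try:
                scores = [float(v) for v in fields[:20]]
            except ValueError as exc:
                raise EncodingError(
                    f"{pssm_path}: unparsable PSSM line {lineno}: {line!r}"
                ) from exc
            rows.append((int(m.group(1)), m.group(2).upper(), scores))
    if len(rows) != len(sequence):
        raise EncodingError(
            f"{pssm_path}: PSSM has {len(rows)} rows but sequence has "
            f"{len(sequence)} residues"
        )
    for (idx, letter, _), res in zip(rows, sequence):
        if letter != "X" and res != "X" and letter != res.upper():
            raise EncodingError(
                f"{pssm_path}: residue mismatch at position {idx}: "
                f"PSSM {letter} vs sequence {res}"
            )
    return ProfileMatrix(
        rows=np.array([r[2] for r in rows], dtype=float), source_flag="pssm"
    )


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def blosum_fallback(sequence: str) -> ProfileMatrix:
    """Profile rows from BLOSUM62: row i is residue i's substitution scores.

    Depends only on the residue letter, so identical residues anywhere get
    identical rows. Unknown letters receive the X row.
    """
    mat = _blosum62()
    rows = np.empty((len(sequence), 20))
    for i, res in enumerate(sequence):
        letter = NONSTANDARD.get(res.upper(), res.upper())
        if letter not in mat.alphabet:
            letter = "X"
        rows[i] = [mat[letter, aa] for aa in AA_ORDER]
    return ProfileMatrix(rows=rows, source_flag="blosum62")


def encode(
    record,
    profile: ProfileMatrix,
    physchem: PhysChemTable,
    normalize_profile: bool = True,
    encode_length: int = ENCODE_LENGTH,
) -> EncodedProtein:
    """Build the fixed-length (encode_length x 25) feature matrix.

    Sequences longer than `encode_length` keep the first and last
    `encode_length/2` residues; shorter ones are zero-padded at the C-terminal
    end with a zero mask. With `normalize_profile` the profile values are
    squashed through the logistic 1/(1+exp(-x)) before insertion; pass False
    for raw log-odds.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record)
    acc = record.accession if isinstance(record, ProteinRecord) else ""
    L = len(seq)
    if profile.rows.shape[0] != L:
        raise EncodingError(
            f"{acc or 'sequence'}: profile has {profile.rows.shape[0]} rows "
            f"but sequence has {L} residues"
        )
    half = encode_length // 2
    if L > encode_length:
        raw_idx = np.concatenate(
            [np.arange(1, half + 1), np.arange(L - (encode_length - half) + 1, L + 1)]
        )
    else:
        raw_idx = np.arange(1, L + 1)

    prof = profile.rows
    if normalize_profile:
        prof = 1.0 / (1.0 + np.exp(-prof))

    features = np.zeros((encode_length, FEATURE_DIM))
    mask = np.zeros(encode_length, dtype=np.uint8)
    origin = np.zeros(encode_length, dtype=np.int64)
    for pos, ri in enumerate(raw_idx):
        features[pos, :5] = physchem.row(seq[ri - 1].upper())
        features[pos, 5:] = prof[ri - 1]
        mask[pos] = 1
        origin[pos] = ri
    return EncodedProtein(
        features=features, mask=mask, origin_map=origin, raw_length=L, accession=acc
    )


def read_fasta(path) -> list:
    """Read a (possibly wrapped, multi-record) FASTA into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
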