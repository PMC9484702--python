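"""The five-dimensional E-descriptor encoding of amino acids.

Each of the 20 canonical residues is summarized by five orthogonal
principal-component scores of 237 physico-chemical properties
(E1 hydrophilicity, E2 size/length, E3 helix propensity, E4
abundance/dispersion, E5 beta-strand propensity).  The values ship as a
versioned text asset whose sha256 is pinned at transcription time: a
mismatch is a hard failure, never a silent substitution.  Alternative
descriptor sets (e.g. z-scales) can be supplied through the same table
contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io import CANONICAL_ALPHABET, ProteinRecord

N_DESCRIPTORS = 5

#: sha256 of the packaged descriptor asset, recorded when it was transcribed.
PACKAGED_TABLE_SHA256 = "2ce98bb05816266d1b3de1e2b1b79c6592823dad148eae66f6eee2dc43334194"

_PACKAGED_ASSET = "e_descriptors.tsv"


class DescriptorTableError(ValueError):
    """The descriptor asset is missing, malformed or corrupted."""


@dataclass(frozen=True)
class EDescriptorTable:
    """Lookup from each canonical residue to its (E1..E5) vector."""

    entries: dict[str, np.ndarray]
    source: str
    checksum: str

    def __post_init__(self) -> None:
        letters = set(self.entries)
        if letters != set(CANONICAL_ALPHABET):
            raise DescriptorTableError(
                f"table must cover exactly the 20 canonical residues; "
                f"missing {sorted(CANONICAL_ALPHABET - letters)}, "
                f"extra {sorted(letters - CANONICAL_ALPHABET)}"
            )
        for letter, vec in self.entries.items():
            if vec.shape != (N_DESCRIPTORS,) or not np.all(np.isfinite(vec)):
                raise DescriptorTableError(
                    f"entry for {letter!r} must be {N_DESCRIPTORS} finite values"
                )

    def vector(self, residue: str) -> np.ndarray:
        return self.entries[residue]

    def as_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        """Dense 20x5 matrix plus residue -> row index, in alphabetical order."""
        letters = sorted(self.entries)
        mat = np.vstack([self.entries[c] for c in letters])
        return mat, {c: i for i, c in enumerate(letters)}

    def scaled(self, factor: float) -> "EDescriptorTable":
        """A copy with every descriptor value multiplied by *factor*."""
        return EDescriptorTable(
            entries={c: v * factor for c, v in self.entries.items()},
            source=f"{self.source} (scaled x{factor})",
            checksum="",
        )


@dataclass(frozen=True)
class EncodedSequence:
    """An n x 5 matrix: row i is the descriptor vector of residue i."""

    record_id: str
    matrix: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _parse_table_text(text: str, source: str, checksum: str) -> EDescriptorTable:
    entries: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 1 + N_DESCRIPTORS:
            raise DescriptorTableError(
                f"{source}:{lineno}: expected residue + {N_DESCRIPTORS} values"
            )
        letter = parts[0].upper()
        if letter in entries:
            raise DescriptorTableError(f"{source}:{lineno}: duplicate residue {letter!r}")
        try:
            vec = np.array([float(x) for x in parts[1:]], dtype=float)
        except ValueError as exc:
            raise DescriptorTableError(f"{source}:{lineno}: {exc}") from exc
        entries[letter] = vec
    return EDescriptorTable(entries=entries, source=source, checksum=checksum)


def load_e_descriptor_table(path: str | None = None) -> EDescriptorTable:
    """Load the packaged E-descriptor table (or a user table from *path*).

    The packaged asset is checksum-verified against the value pinned at
    transcription time; a mismatch raises rather than returning altered
    descriptor values.  User tables use the same tab-separated format
    (letter, E1..E5) and are loaded with their own computed checksum.
    """
    if path is None:
        ref = resources.files("alleracc.data") / _PACKAGED_ASSET
        try:
            raw = ref.read_bytes()
        except FileNotFoundError as exc:
            raise DescriptorTableError("packaged descriptor asset is missing") from exc
        digest = hashlib.sha256(raw).hexdigest()
        if digest != PACKAGED_TABLE_SHA256:
            raise DescriptorTableError(
                "packaged descriptor asset failed its checksum "
                f"(got {digest}, expected {PACKAGED_TABLE_SHA256}); "
                "refusing to use possibly corrupted descriptor values"
            )
        return _parse_table_text(raw.decode(), source=_PACKAGED_ASSET, checksum=digest)
    with open(path, "rb") as fh:
        raw = fh.read()
    digest = hashlib.sha256(raw).hexdigest()
    return _parse_table_text(raw.decode(), source=str(path), checksum=digest)


def encode_sequence(record: ProteinRecord, table: EDescriptorTable) -> EncodedSequence:
    """Map a validated sequence to its n x 5 descriptor matrix (pure lookup)."""
    mat, index = table.as_matrix()
    try:
        rows = np.array([index[c] for c in record.sequence], dtype=np.intp)
    except KeyError:
        for pos, c in enumerate(record.sequence, start=1):
            if c not in index:
                raise KeyError(
                    f"record {record.id!r}: residue {c!r} at position {pos} "
                    "is absent from the descriptor table"
                ) from None
        raise  # pragma: no cover
    return EncodedSequence(record_id=record.id, matrix=mat[rows])
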