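"""FASTA ingestion, validation, deduplication and export of labeled protein datasets.

Sequences are held in one-letter amino-acid code, uppercased on ingest.
Validation is strict by default: any letter outside the 20-residue canonical
alphabet (so also B, J, O, U, X, Z and gap characters) rejects the record,
because downstream descriptor encoding is undefined for such letters.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Class labels used throughout the package (allergen is the positive class).
ALLERGEN = "allergen"
NON_ALLERGEN = "non_allergen"
LABELS = (NON_ALLERGEN, ALLERGEN)

VALIDATION_POLICIES = ("strict", "drop", "map_unknown")


class SequenceValidationError(ValueError):
    """A sequence violates the canonical-alphabet contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence in one-letter code."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """An ordered collection of records with optional parallel class labels."""

    records: list[ProteinRecord]
    labels: list[str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.records)} records"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | os.PathLike, label: str | None = None) -> SequenceDataset:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The header text up to the first whitespace becomes the record id; sequence
    lines are concatenated and uppercased.  Terminal/internal ``*`` stop
    characters are stripped with a warning.  If *label* is given every record
    carries it.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(path, "fasta"):
        seq = str(entry.seq).upper()
        if "*" in seq:
            logger.warning(
                "record %r: stripped %d '*' stop character(s)", entry.id, seq.count("*")
            )
            seq = seq.replace("*", "")
        if not seq:
            raise ValueError(f"FASTA entry {entry.id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    labels = [label] * len(records) if label is not None else None
    return SequenceDataset(records=records, labels=labels, provenance=f"read from {path}")


def validate_record(record: ProteinRecord, policy: str = "strict") -> ProteinRecord | None:
    """Apply the non-standard-residue policy to one record.

    strict
        reject (raise) on the first letter outside the canonical alphabet.
    drop
        return ``None`` and log a warning; caller excludes the record.
    map_unknown
        remove the non-standard letters and log how many were removed.
    """
    if policy not in VALIDATION_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {VALIDATION_POLICIES}")
    bad = [(i, c) for i, c in enumerate(record.sequence, start=1)
           if c not in CANONICAL_ALPHABET]
    if not bad:
        return record
    if policy == "strict":
        pos, char = bad[0]
        raise SequenceValidationError(
            f"record {record.id!r}: non-standard residue {char!r} at position {pos}"
        )
    if policy == "drop":
        logger.warning(
            "record %r dropped: %d non-standard residue(s), first %r at position %d",
            record.id, len(bad), bad[0][1], bad[0][0],
        )
        return None
    # map_unknown
    cleaned = "".join(c for c in record.sequence if c in CANONICAL_ALPHABET)
    logger.warning("record %r: removed %d non-standard residue(s)", record.id, len(bad))
    if not cleaned:
        logger.warning("record %r dropped: empty after removing non-standard residues",
                       record.id)
        return None
    return replace(record, sequence=cleaned)


def validate_dataset(dataset: SequenceDataset, policy: str = "strict") -> SequenceDataset:
    """Validate every record under *policy*, realigning labels with survivors."""
    kept_records: list[ProteinRecord] = []
    kept_labels: list[str] | None = [] if dataset.labels is not None else None
    for idx, record in enumerate(dataset.records):
        out = validate_record(record, policy=policy)
        if out is None:
            continue
        kept_records.append(out)
        if kept_labels is not None:
            kept_labels.append(dataset.labels[idx])
    if not kept_records:
        raise SequenceValidationError("no records survive validation")
    return SequenceDataset(records=kept_records, labels=kept_labels,
                           provenance=dataset.provenance)


@dataclass
class DeduplicationResult:
    dataset: SequenceDataset
    removed_count: int
    removed_ids: list[str] = field(default_factory=list)


def deduplicate(dataset: SequenceDataset) -> DeduplicationResult:
    """Remove exact duplicate sequences (case-insensitive), keeping the first.

    Duplicates carrying conflicting class labels are ambiguous ground truth
    and raise, listing the offending ids.
    """
    first_seen: dict[str, int] = {}
    kept_records: list[ProteinRecord] = []
    kept_labels: list[str] | None = [] if dataset.labels is not None else None
    removed_ids: list[str] = []
    conflicts: list[tuple[str, str]] = []
    for idx, record in enumerate(dataset.records):
        key = record.sequence.upper()
        if key in first_seen:
            removed_ids.append(record.id)
            if dataset.labels is not None:
                kept_idx = first_seen[key]
                if dataset.labels[idx] != dataset.labels[kept_idx]:
                    conflicts.append((dataset.records[kept_idx].id, record.id))
            continue
        first_seen[key] = idx
        kept_records.append(record)
        if kept_labels is not None:
            kept_labels.append(dataset.labels[idx])
    if conflicts:
        listing = "; ".join(f"{a} vs {b}" for a, b in conflicts)
        raise ValueError(f"duplicate sequences with conflicting labels: {listing}")
    if removed_ids:
        logger.info("deduplicate: removed %d duplicate record(s)", len(removed_ids))
    return DeduplicationResult(
        dataset=SequenceDataset(records=kept_records, labels=kept_labels,
                                provenance=dataset.provenance),
        removed_count=len(removed_ids),
        removed_ids=removed_ids,
    )


def write_fasta(dataset: SequenceDataset, path: str | os.PathLike,
                line_width: int = 60) -> None:
    """Write the dataset as wrapped FASTA; round-trip safe on (id, sequence)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = os.fspath(path)
    with open(path, "w") as fh:
        for record in dataset.records:
            fh.write(f">{record.id}\n")
            seq = record.sequence
            for start in range(0, len(seq), line_width):
                fh.write(seq[start:start + line_width] + "\n")


def read_label_table(path: str | os.PathLike, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (id, label) delimited table into a mapping."""
    path = os.fspath(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rec_id, label = parts
            if label not in LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            if rec_id in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            mapping[rec_id] = label
    return mapping


def attach_labels(dataset: SequenceDataset, mapping: dict[str, str]) -> SequenceDataset:
    """Attach labels from an (id -> label) mapping; every record must be covered."""
    missing = [r.id for r in dataset.records if r.id not in mapping]
    if missing:
        raise ValueError(f"no label for record(s): {missing[:5]}")
    return SequenceDataset(
        records=list(dataset.records),
        labels=[mapping[r.id] for r in dataset.records],
        provenance=dataset.provenance,
    )
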