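"""Aligned mitogenome datasets: reading, validation and column masking.

Sequences are stored exactly as read (over {A, C, G, T, N, -}); masked
columns are recorded as 0-based half-open intervals and excluded from every
downstream distance / haplotype computation without altering the sequence
text.  All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_SYMBOLS = frozenset("ACGTN-")
DETERMINED = frozenset("ACGT")


class AlignmentError(ValueError):
    """Base class for alignment validation failures."""


class LengthMismatchError(AlignmentError):
    pass


class DuplicateIdError(AlignmentError):
    pass


class UnknownSymbolError(AlignmentError):
    pass


class MissingMetadataError(AlignmentError):
    pass


class MaskError(AlignmentError):
    pass


@dataclass(frozen=True)
class AlignedDataset:
    """An alignment plus per-sample metadata and a set of masked intervals."""

    records: tuple[tuple[str, str], ...]  # (sample_id, aligned sequence)
    metadata: pd.DataFrame  # indexed by sample_id
    mask: tuple[tuple[int, int], ...] = ()  # 0-based half-open intervals

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("dataset has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise LengthMismatchError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sample ids: {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - VALID_SYMBOLS
            if bad:
                raise UnknownSymbolError(f"unknown symbols {sorted(bad)} in {sid!r}")
        missing = [sid for sid in ids if sid not in self.metadata.index]
        if missing:
            raise MissingMetadataError(f"samples missing from metadata: {missing}")
        L = self.length
        for start, end in self.mask:
            if not (0 <= start < end <= L):
                raise MaskError(f"mask interval ({start}, {end}) outside [0, {L})")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.records:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def unmasked_columns(self) -> np.ndarray:
        """Indices (0-based) of alignment columns not covered by the mask."""
        keep = np.ones(self.length, dtype=bool)
        for start, end in self.mask:
            keep[start:end] = False
        return np.flatnonzero(keep)

    def matrix(self) -> np.ndarray:
        """Alignment as an (n_samples, L) array of single-byte characters."""
        return np.array([list(seq) for _, seq in self.records], dtype="U1")


def read_alignment(fasta_path, metadata_path) -> AlignedDataset:
    """Read a FASTA alignment and a TSV metadata table into a validated dataset.

    The metadata TSV must have a ``sample_id`` column; ``age_calBP`` and
    ``location`` are used downstream when present.  Sequences are
    upper-cased; undetermined positions stay ``N``.
    """
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")
    )
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise MissingMetadataError("metadata must contain a 'sample_id' column")
    meta = meta.set_index("sample_id")
    return AlignedDataset(records=records, metadata=meta)


def mask_region(ds: AlignedDataset, intervals) -> AlignedDataset:
    """Mask alignment columns.  ``intervals`` are 1-based inclusive pairs.

    The sequence text is unchanged; masked columns are simply excluded from
    downstream haplotype and distance computations.
    """
    new = list(ds.mask)
    L = ds.length
    for start1, end1 in intervals:
        if not (1 <= start1 <= end1 <= L):
            raise MaskError(
                f"interval ({start1}, {end1}) out of bounds for a {L}-column alignment "
                "(1-based inclusive)"
            )
        new.append((start1 - 1, end1))  # store 0-based half-open
    return replace(ds, mask=tuple(sorted(new)))
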