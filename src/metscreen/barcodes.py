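"""Barcode library handling and read-to-barcode deconvolution.

Each pooled clone carries a fixed-length DNA barcode (24 nt by default)
embedded in the sequenced amplicon. A read is assigned to the unique
library barcode within ``max_mismatch`` Hamming distance at the
best-scoring offset of a sliding window; reads matching no barcode are
*unassigned* and reads equally close to two or more barcodes are
*ambiguous* (never counted). Unambiguous assignment at tolerance ``m``
is guaranteed when the library's minimum pairwise Hamming distance is at
least ``2 m + 1`` and the read overlaps a single barcode.
"""

from __future__ import annotations

import gzip
import warnings
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "BarcodeLibrary",
    "BarcodeCounts",
    "load_barcode_library",
    "count_barcodes",
    "read_fastq_sequences",
]


def encode_seq(seq: str) -> np.ndarray:
    """ASCII byte encoding of a sequence; any non-ACGT byte simply never matches."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class BarcodeLibrary:
    """ORF identifiers with their unique fixed-length DNA barcodes."""

    orf_ids: list[str]
    barcodes: list[str]
    length: int
    min_pairwise_distance: int | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.orf_ids) != len(self.barcodes):
            raise ValueError("orf_ids and barcodes differ in length")
        seen: dict[str, int] = {}
        for i, (orf, bc) in enumerate(zip(self.orf_ids, self.barcodes)):
            if len(bc) != self.length:
                raise ValueError(
                    f"row {i} ({orf}): barcode length {len(bc)} != expected {self.length}"
                )
            bad = set(bc) - DNA_ALPHABET
            if bad:
                raise ValueError(f"row {i} ({orf}): non-ACGT characters {sorted(bad)}")
            if bc in seen:
                raise ValueError(f"row {i} ({orf}): barcode duplicates row {seen[bc]}")
            seen[bc] = i
        if len(set(self.orf_ids)) != len(self.orf_ids):
            raise ValueError("duplicate orf_ids in library")
        if self.min_pairwise_distance is None:
            self.min_pairwise_distance = self._compute_min_distance()

    def _compute_min_distance(self) -> int | None:
        if len(self.barcodes) < 2:
            return None
        enc = self.encoded()
        best = self.length
        # all-pairs Hamming; library sizes are a few hundred so O(n^2) is cheap
        for i in range(len(self.barcodes) - 1):
            d = (enc[i + 1 :] != enc[i]).sum(axis=1).min()
            best = min(best, int(d))
        return best

    def encoded(self) -> np.ndarray:
        """(n_barcodes, length) uint8 matrix of barcode bytes."""
        return np.vstack([encode_seq(b) for b in self.barcodes])

    def __len__(self) -> int:
        return len(self.orf_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"orf_id": self.orf_ids, "barcode": self.barcodes})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_barcode_library(path: str | Path, expected_length: int = 24) -> BarcodeLibrary:
    """Read and validate an ``orf_id<TAB>barcode`` library table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("orf_id", "barcode"):
        if col not in df.columns:
            raise ValueError(f"library table lacks required column {col!r}")
    return BarcodeLibrary(
        orf_ids=df["orf_id"].tolist(),
        barcodes=df["barcode"].tolist(),
        length=expected_length,
    )


@dataclass
class BarcodeCounts:
    """Per-sample deconvolution result: counts plus the read bookkeeping."""

    counts: pd.Series  # index orf_id, integer read counts
    unassigned: int
    ambiguous: int
    total: int

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())

    def conserved(self) -> bool:
        """Read conservation: assigned + unassigned + ambiguous == total."""
        return self.assigned + self.unassigned + self.ambiguous == self.total


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a (possibly gzipped) FASTQ file.

    Malformed records raise ``ValueError`` carrying the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    record = 0
    with opener(path, "rt") as handle:
        try:
            for _, seq, _ in FastqGeneralIterator(handle):
                record += 1
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near record {record + 1}: {exc}") from exc


def count_barcodes(
    reads: Iterable[str] | str | Path,
    library: BarcodeLibrary,
    max_mismatch: int = 1,
    search_window: tuple[int, int] | None = None,
    allow_ambiguous_library: bool = False,
    chunk_size: int = 4096,
) -> BarcodeCounts:
    """Deconvolute reads against a barcode library by windowed Hamming matching.

    Parameters
    ----------
    reads
        FASTQ path (plain or ``.gz``) or any iterable of sequence strings.
    max_mismatch
        Per-barcode Hamming tolerance. Refused (unless
        ``allow_ambiguous_library``) when ``2*max_mismatch + 1`` exceeds
        the library's minimum pairwise distance, since assignments could
        then be systematically ambiguous.
    search_window
        ``(start, stop)`` half-open range of allowed barcode offsets;
        default scans every offset.

    Notes
    -----
    Per read, the minimum Hamming distance to every barcode over all
    allowed offsets is computed; the read is assigned to the single
    barcode attaining the global minimum if that minimum is within
    tolerance, flagged ambiguous if two or more barcodes attain it, and
    unassigned otherwise. Ties between offsets of the *same* barcode are
    irrelevant for counting (the leftmost such offset is the match site).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    min_dist = library.min_pairwise_distance
    if min_dist is not None and 2 * max_mismatch + 1 > min_dist and not allow_ambiguous_library:
        raise ValueError(
            f"max_mismatch={max_mismatch} needs library min pairwise distance "
            f">= {2 * max_mismatch + 1}, got {min_dist}; pass allow_ambiguous_library=True "
            "to override"
        )

    if isinstance(reads, (str, Path)):
        reads = read_fastq_sequences(reads)

    enc_lib = library.encoded()
    L = library.length
    n_bc = len(library)
    counts = np.zeros(n_bc, dtype=np.int64)
    unassigned = 0
    ambiguous = 0
    total = 0

    # group reads by length so each batch vectorises cleanly
    buffers: dict[int, list[str]] = {}

    def flush(length: int) -> None:
        nonlocal unassigned, ambiguous
        batch = buffers.pop(length, [])
        if not batch:
            return
        if length < L:
            unassigned += len(batch)
            return
        enc = np.vstack([encode_seq(s) for s in batch])
        n_off = length - L + 1
        lo, hi = 0, n_off
        if search_window is not None:
            lo = max(0, search_window[0])
            hi = min(n_off, search_window[1])
        if lo >= hi:
            unassigned += len(batch)
            return
        best = np.full((len(batch), n_bc), L + 1, dtype=np.int16)
        for off in range(lo, hi):
            window = enc[:, off : off + L]
            d = (window[:, None, :] != enc_lib[None, :, :]).sum(axis=2, dtype=np.int16)
            np.minimum(best, d, out=best)
        read_min = best.min(axis=1)
        within = read_min <= max_mismatch
        n_at_min = (best == read_min[:, None]).sum(axis=1)
        amb = within & (n_at_min > 1)
        hit = within & (n_at_min == 1)
        ambiguous += int(amb.sum())
        unassigned += int((~within).sum())
        if hit.any():
            winners = best[hit].argmin(axis=1)
            np.add.at(counts, winners, 1)

    for seq in reads:
        total += 1
        length = len(seq)
        buf = buffers.setdefault(length, [])
        buf.append(seq)
        if len(buf) >= chunk_size:
            flush(length)
    for length in list(buffers):
        flush(length)

    if total == 0:
        warnings.warn("no reads processed: returning a zero-count row", stacklevel=2)

    return BarcodeCounts(
        counts=pd.Series(counts, index=pd.Index(library.orf_ids, name="orf_id")),
        unassigned=unassigned,
        ambiguous=ambiguous,
        total=total,
    )
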