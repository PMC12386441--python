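"""Readers and writers for the external formats the predictor consumes.

All genomic coordinates are 0-based half-open (BED convention).  Signal
tracks are exposed through a single ``read_signal`` contract: one value per
base over a queried interval, with missing data reported as 0.  Both
BigWig-backed tracks and in-memory array-backed tracks satisfy it, so the
whole pipeline (and its tests) can run without any binary track file.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    EmptyInputError,
    FormatError,
    SignalLookupError,
    ValidationError,
)

DNA_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of +, -, . : {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class EPPair:
    """One enhancer-promoter instance: sequences, optional intervals, label."""

    pair_id: str
    enhancer_seq: str
    promoter_seq: str
    label: int
    enhancer: GenomicInterval | None = None
    promoter: GenomicInterval | None = None
    cell_line: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError(
                f"pair {self.pair_id}: label must be 0 or 1, got {self.label!r}"
            )
        for name, seq in (("enhancer", self.enhancer_seq),
                          ("promoter", self.promoter_seq)):
            if not seq:
                raise ValidationError(f"pair {self.pair_id}: empty {name} sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"pair {self.pair_id}: {name} sequence contains non-ACGTN "
                    f"characters {sorted(bad)}"
                )


def standardize_sequence(seq: str, target_len: int) -> str:
    """Center-crop or symmetrically N-pad ``seq`` to exactly ``target_len``."""
    if target_len <= 0:
        raise ValidationError("target_len must be positive")
    seq = seq.upper()
    n = len(seq)
    if n == target_len:
        return seq
    if n > target_len:
        off = (n - target_len) // 2
        return seq[off:off + target_len]
    pad = target_len - n
    left = pad // 2
    return "N" * left + seq + "N" * (pad - left)


# ---------------------------------------------------------------------------
# pairs table
# ---------------------------------------------------------------------------

def read_pairs_table(path: str | Path, dialect: str = "standard") -> list[EPPair]:
    """Read an EP-pair CSV table into :class:`EPPair` records, preserving order.

    The ``standard`` dialect expects at least ``pair_id``, ``label``,
    ``enhancer_seq`` and ``promoter_seq`` columns, with optional interval
    columns ``{enh,prom}_{chrom,start,end}`` and ``cell_line``.
    """
    if dialect != "standard":
        raise FormatError(f"unknown pairs-table dialect {dialect!r}")
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no pair rows")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing required 'label' column")
    for col in ("enhancer_seq", "promoter_seq"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required {col!r} column")
    has_intervals = {"enh_chrom", "enh_start", "enh_end",
                     "prom_chrom", "prom_start", "prom_end"} <= set(df.columns)
    pairs: list[EPPair] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        label = getattr(row, "label")
        if label not in (0, 1):
            raise ValidationError(
                f"{path}: row {row_no}: label must be 0/1, got {label!r}"
            )
        enh = prom = None
        if has_intervals:
            enh = GenomicInterval(str(row.enh_chrom), int(row.enh_start),
                                  int(row.enh_end))
            prom = GenomicInterval(str(row.prom_chrom), int(row.prom_start),
                                   int(row.prom_end))
        pairs.append(EPPair(
            pair_id=str(getattr(row, "pair_id", row_no)),
            enhancer_seq=str(row.enhancer_seq).upper(),
            promoter_seq=str(row.promoter_seq).upper(),
            label=int(label),
            enhancer=enh,
            promoter=prom,
            cell_line=str(getattr(row, "cell_line", "")),
        ))
    return pairs


def write_pairs_table(pairs: Sequence[EPPair], path: str | Path) -> None:
    """Write pairs in the ``standard`` CSV dialect (lossless round-trip)."""
    rows = []
    for p in pairs:
        row = {
            "pair_id": p.pair_id, "label": p.label, "cell_line": p.cell_line,
            "enhancer_seq": p.enhancer_seq, "promoter_seq": p.promoter_seq,
        }
        if p.enhancer is not None and p.promoter is not None:
            row.update(
                enh_chrom=p.enhancer.chrom, enh_start=p.enhancer.start,
                enh_end=p.enhancer.end,
                prom_chrom=p.promoter.chrom, prom_start=p.promoter.start,
                prom_end=p.promoter.end,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, allow_u: bool = False) -> dict[str, str]:
    """Read a DNA FASTA into ``{id: sequence}`` with uppercased sequences.

    ``U`` is rejected by default (DNA only); with ``allow_u=True`` it is
    mapped to ``T``.  Duplicate record IDs raise a :class:`FormatError`
    listing the offenders.
    """
    seqs: dict[str, str] = {}
    dups: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            if allow_u:
                seq = seq.replace("U", "T")
            else:
                raise ValidationError(
                    f"{path}: record {rec.id!r} contains U (RNA?); "
                    "pass allow_u=True to map U->T"
                )
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has non-ACGTN characters {sorted(bad)}"
            )
        if rec.id in seqs:
            dups.append(rec.id)
        else:
            seqs[rec.id] = seq
    if dups:
        raise FormatError(f"{path}: duplicate FASTA IDs: {sorted(set(dups))}")
    if not seqs:
        raise EmptyInputError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

class ArrayTrack:
    """In-memory per-base signal track backed by covered regions.

    Regions are ``(start, values)`` blocks per chromosome; queries outside
    any covered block return 0 (the convention for unmapped coverage).  A
    chromosome size, when declared, bounds queries the way a BigWig header
    would.
    """

    def __init__(self, chrom_sizes: Mapping[str, int] | None = None):
        self._regions: dict[str, list[tuple[int, int, np.ndarray]]] = {}
        self.chrom_sizes = dict(chrom_sizes or {})

    @classmethod
    def from_array(cls, chrom: str, values, start: int = 0) -> "ArrayTrack":
        values = np.asarray(values, dtype=float)
        track = cls({chrom: start + values.size})
        track.add(chrom, start, values)
        return track

    def add(self, chrom: str, start: int, values) -> None:
        values = np.asarray(values, dtype=float)
        blocks = self._regions.setdefault(chrom, [])
        end = start + values.size
        pos = bisect.bisect_left([b[0] for b in blocks], start)
        blocks.insert(pos, (start, end, values))
        if chrom in self.chrom_sizes:
            self.chrom_sizes[chrom] = max(self.chrom_sizes[chrom], end)

    def chroms(self) -> list[str]:
        return sorted(set(self._regions) | set(self.chrom_sizes))

    def values(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-base values over ``[start, end)`` plus a coverage mask."""
        if chrom not in self._regions and chrom not in self.chrom_sizes:
            raise SignalLookupError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes.get(chrom)
        if size is not None and (end > size or start < 0):
            raise SignalLookupError(
                f"interval {chrom}:{start}-{end} outside chromosome of size {size}"
            )
        out = np.zeros(end - start, dtype=float)
        covered = np.zeros(end - start, dtype=bool)
        for bstart, bend, vals in self._regions.get(chrom, []):
            lo, hi = max(start, bstart), min(end, bend)
            if lo < hi:
                out[lo - start:hi - start] = vals[lo - bstart:hi - bstart]
                covered[lo - start:hi - start] = True
        return out, covered


class BigWigTrack:
    """Thin BigWig adapter satisfying the :class:`ArrayTrack` query contract."""

    def __init__(self, path: str | Path):
        import pyBigWig  # optional dependency, imported on use

        self._bw = pyBigWig.open(str(path))
        self.chrom_sizes = dict(self._bw.chroms())

    def values(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.chrom_sizes:
            raise SignalLookupError(f"unknown chromosome {chrom!r}")
        if end > self.chrom_sizes[chrom] or start < 0:
            raise SignalLookupError(
                f"interval {chrom}:{start}-{end} outside chromosome of size "
                f"{self.chrom_sizes[chrom]}"
            )
        vals = np.asarray(self._bw.values(chrom, start, end), dtype=float)
        covered = ~np.isnan(vals)
        vals[~covered] = 0.0
        return vals, covered

    def close(self) -> None:
        self._bw.close()


def read_signal(track, interval: GenomicInterval) -> np.ndarray:
    """Per-base signal over ``interval``; missing values reported as 0."""
    vals, _ = track.values(interval.chrom, interval.start, interval.end)
    return vals


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(path: str | Path, pair_ids: Sequence[str],
                      scores: Iterable[float], folds: Iterable[int] | None = None,
                      n_submodels: int = 0) -> None:
    """Tab-separated prediction output: pair_id, score, fold, sub-model count."""
    scores = list(scores)
    folds = list(folds) if folds is not None else [0] * len(scores)
    with open(path, "w") as fh:
        fh.write("pair_id\tscore\tfold\tn_submodels\n")
        for pid, s, f in zip(pair_ids, scores, folds):
            fh.write(f"{pid}\t{s:.6f}\t{f}\t{n_submodels}\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"pair_id", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing prediction columns {sorted(missing)}")
    return df
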