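"""Sequence and alignment I/O plus CpG-island detection.

This module carries the front end of the pipeline: reading per-species
FASTA records, locating CpG islands (GC-rich, CpG-enriched intervals) on
unaligned sequences, concatenating the per-locus island sequences into one
record per species, and producing or loading a multiple sequence alignment.

Coordinate convention: 0-based, half-open intervals everywhere.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDES = set("ACGTN")
ALIGNED_ALPHABET = NUCLEOTIDES | {"-"}


class SeqFormatError(ValueError):
    """Malformed sequence input (bad characters, duplicate ids, empty file)."""


@dataclass
class SequenceRecord:
    """One nucleotide sequence with its species/assembly label.

    ``coords`` is an optional 0-based half-open interval on the source
    sequence; ``locus_boundaries`` records per-locus intervals after
    concatenation.
    """

    id: str
    seq: str
    source_locus: str | None = None
    coords: tuple[int, int] | None = None
    locus_boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqFormatError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise SeqFormatError(f"record {self.id!r}: empty sequence")


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise SeqFormatError("duplicate ids in alignment")
        n = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise ValueError(
                    f"row {sid!r} has length {len(row)}, expected {n}"
                )
            bad = set(row) - ALIGNED_ALPHABET
            if bad:
                raise SeqFormatError(f"row {sid!r}: illegal characters {sorted(bad)}")
            if set(row) == {"-"}:
                raise ValueError(f"row {sid!r} is all gaps")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise KeyError(f"id {sid!r} not in alignment") from None

    def degapped(self, sid: str) -> str:
        return self.row(sid).replace("-", "")


@dataclass
class CpgIsland:
    """A CpG island interval on an unaligned sequence."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize(seq: str, sid: str, offset_base: int = 0, allow_gaps: bool = True) -> str:
    s = seq.upper().replace("U", "T")
    allowed = ALIGNED_ALPHABET if allow_gaps else NUCLEOTIDES
    for off, c in enumerate(s):
        if c not in allowed:
            raise SeqFormatError(
                f"record {sid!r}: illegal character {c!r} at offset {offset_base + off}"
            )
    return s


def read_fasta(path: str | Path, allow_gaps: bool = True) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (uppercased, U→T, alphabet-checked).

    Raises :class:`SeqFormatError` on an empty file, duplicate ids, or
    characters outside {A,C,G,T,N,-}.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), rec.id, allow_gaps=allow_gaps)
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise SeqFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# CpG island detection
# ---------------------------------------------------------------------------

def _interval_stats(c_cum: np.ndarray, g_cum: np.ndarray, cg_cum: np.ndarray,
                    start: int, end: int) -> tuple[float, float]:
    """(gc_fraction, obs/exp CpG) for [start, end) from prefix sums."""
    length = end - start
    n_c = int(c_cum[end] - c_cum[start])
    n_g = int(g_cum[end] - g_cum[start])
    # CG dinucleotide starts strictly inside the interval
    n_cg = int(cg_cum[end - 1] - cg_cum[start]) if end - 1 > start else 0
    gc = (n_c + n_g) / length
    oe = (n_cg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def _prefix_sums(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_cg = np.zeros(len(seq), dtype=np.int64)
    if len(seq) > 1:
        is_cg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
    zero = np.zeros(1, dtype=np.int64)
    return (np.concatenate([zero, np.cumsum(is_c)]),
            np.concatenate([zero, np.cumsum(is_g)]),
            np.concatenate([zero, np.cumsum(is_cg)]))


def find_cpg_islands(record: SequenceRecord, min_gc: float = 0.50,
                     min_obs_exp: float = 0.60, min_len: int = 200) -> list[CpgIsland]:
    """Call CpG islands on an unaligned sequence.

    Sliding ``min_len``-bp windows (step 1) passing all thresholds are
    merged when overlapping; each merged interval is then trimmed one base
    at a time (right end first, then left) until the whole interval passes,
    in the spirit of the classic Takai–Jones procedure. N counts as
    non-C/non-G and never forms part of a CpG. Returns maximal
    non-overlapping intervals sorted by start.
    """
    seq = record.seq.upper()
    L = len(seq)
    if L < min_len:
        raise ValueError(f"sequence shorter than min_len ({L} < {min_len})")
    if set(seq) <= {"N"}:
        warnings.warn(f"record {record.id!r} is all N; no islands callable")
        return []
    c_cum, g_cum, cg_cum = _prefix_sums(seq)

    def passes(a: int, b: int) -> bool:
        gc, oe = _interval_stats(c_cum, g_cum, cg_cum, a, b)
        return gc >= min_gc and oe >= min_obs_exp

    # 1. scan windows
    passing = [s for s in range(L - min_len + 1) if passes(s, s + min_len)]
    # 2. merge overlapping windows into runs
    merged: list[tuple[int, int]] = []
    for s in passing:
        if merged and s <= merged[-1][1]:  # overlap (windows are min_len wide)
            merged[-1] = (merged[-1][0], max(merged[-1][1], s + min_len))
        else:
            merged.append((s, s + min_len))
    # 3. trim each merged interval until it passes as a whole
    islands: list[CpgIsland] = []
    for a, b in merged:
        while b - a >= min_len and not passes(a, b):
            if passes(a, b - 1) or not passes(a + 1, b):
                b -= 1
            else:
                a += 1
        if b - a >= min_len and passes(a, b):
            gc, oe = _interval_stats(c_cum, g_cum, cg_cum, a, b)
            islands.append(CpgIsland(start=a, end=b, gc_fraction=gc, obs_exp_cpg=oe))
    return islands


def island_report(record: SequenceRecord, islands: Sequence[CpgIsland]) -> str:
    """TSV report (0-based half-open coordinates)."""
    lines = ["id\tstart\tend\tlength\tgc_fraction\tobs_exp_cpg"]
    for isl in islands:
        lines.append(
            f"{record.id}\t{isl.start}\t{isl.end}\t{isl.length}"
            f"\t{isl.gc_fraction:.4f}\t{isl.obs_exp_cpg:.4f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Locus concatenation and alignment
# ---------------------------------------------------------------------------

def concatenate_loci(records_by_locus: Mapping[str, Mapping[str, SequenceRecord]],
                     order: Sequence[str]) -> list[SequenceRecord]:
    """Concatenate per-locus sequences into one record per species.

    ``records_by_locus`` maps species → locus → record. Per-locus interval
    boundaries on the concatenated sequence are stored in
    ``locus_boundaries``.
    """
    out: list[SequenceRecord] = []
    for species in records_by_locus:
        loci = records_by_locus[species]
        parts: list[str] = []
        bounds: dict[str, tuple[int, int]] = {}
        pos = 0
        for locus in order:
            if locus not in loci:
                raise KeyError(f"species {species!r} is missing locus {locus!r}")
            s = loci[locus].seq
            bounds[locus] = (pos, pos + len(s))
            parts.append(s)
            pos += len(s)
        out.append(SequenceRecord(id=species, seq="".join(parts),
                                  locus_boundaries=bounds))
    return out


def align_or_load(records: Sequence[SequenceRecord] | None = None,
                  path: str | Path | None = None,
                  mode: str = "preloaded",
                  aligner: str = "mafft",
                  aligner_args: Sequence[str] = ("--auto", "--quiet")) -> Msa:
    """Produce an Msa, either by loading a pre-aligned FASTA or by running
    an external aligner (MAFFT by default) on unaligned records.

    In either mode the degapped rows equal the input sequences exactly.
    """
    if mode == "preloaded":
        if path is None:
            raise ValueError("preloaded mode requires a path")
        recs = read_fasta(path, allow_gaps=True)
        return Msa(ids=[r.id for r in recs], rows=[r.seq for r in recs])
    if mode != "external":
        raise ValueError(f"unknown mode {mode!r}")
    if records is None:
        if path is None:
            raise ValueError("external mode requires records or a path")
        records = read_fasta(path, allow_gaps=False)
    exe = shutil.which(aligner)
    if exe is None:
        raise RuntimeError(f"aligner {aligner!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(records, infile)
        proc = subprocess.run([exe, *aligner_args, str(infile)],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"aligner failed: {proc.stderr[-2000:]}")
        outfile = Path(tmp) / "out.fasta"
        outfile.write_text(proc.stdout)
        recs = read_fasta(outfile, allow_gaps=True)
    msa = Msa(ids=[r.id for r in recs], rows=[r.seq for r in recs])
    by_id = {r.id: r.seq for r in records}
    for sid in msa.ids:
        if msa.degapped(sid) != by_id[sid]:
            raise RuntimeError(f"aligner altered sequence {sid!r}")
    return msa
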