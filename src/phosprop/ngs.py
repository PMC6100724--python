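"""Deconvolution of barcoded phage-selection FASTQ into per-entry counts.

The pipeline mirrors a standard amplicon workflow: demultiplex on sample
barcodes, locate the displayed insert between the annealing flanks, apply
a Phred-quality filter over the insert, map the insert to the library
design allowing a bounded number of nucleotide mismatches, and finally
keep only reads whose mismatches are synonymous (the displayed peptide is
exactly the designed one).  Every discarded read is accounted for in a
per-sample ledger so that reads in == mapped + discarded always holds.

Mapping is ungapped (Hamming distance).  The design index combines an
exact-match hash with a pigeonhole seed partition: the insert is split
into m+1 segments, so any read within m mismatches matches at least one
segment exactly, giving recall identical to brute-force Hamming search.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .codons import reverse_complement, translates_to
from .design import LibraryEntry

logger = logging.getLogger(__name__)

LEDGER_CATEGORIES = ("bad_barcode", "low_quality", "unmapped", "ambiguous", "nonsynonymous")


class NgsError(ValueError):
    pass


@dataclass(frozen=True)
class Read:
    read_id: str
    seq: str
    qual: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise NgsError(f"{self.read_id}: seq/qual length mismatch")

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    fwd_barcode: str
    rev_barcode: str
    bait: str
    replicate: int
    condition: str


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self) -> None:
        pairs = [(r.fwd_barcode, r.rev_barcode) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise NgsError("duplicate (fwd_barcode, rev_barcode) pairs in sample sheet")
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise NgsError("duplicate sample ids in sample sheet")
        for r in self.rows:
            for bc in (r.fwd_barcode, r.rev_barcode):
                if set(bc) - set("ACGT"):
                    raise NgsError(f"sample {r.sample_id}: barcode {bc!r} not over ACGT")
            if r.replicate < 1:
                raise NgsError(f"sample {r.sample_id}: replicate must be >= 1")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"sample_id", "fwd_barcode", "rev_barcode", "bait", "replicate", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise NgsError(f"sample sheet missing columns: {sorted(missing)}")
        rows = []
        for i, r in enumerate(df.itertuples(index=False)):
            try:
                rows.append(SampleRow(r.sample_id, r.fwd_barcode, r.rev_barcode,
                                      r.bait, int(r.replicate), r.condition))
            except (NgsError, ValueError) as exc:
                raise NgsError(f"sample sheet row {i + 1}: {exc}") from None
        return cls(rows)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.rows]).to_csv(path, sep="\t", index=False)

    def by_id(self, sample_id: str) -> SampleRow:
        for r in self.rows:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


@dataclass(frozen=True)
class MapParams:
    max_mismatch: int = 2
    max_barcode_mismatch: int = 0
    min_quality: float = 30.0
    quality_mode: str = "mean"  # or "min"
    barcode_offset: int = 0
    anchor_mismatch: int = 1  # tolerance when locating the 5' flank
    check_rev_barcode: bool = False  # also require revcomp(rev_barcode) suffix
    revcomp_reads: bool = False  # read covers the insert on the other strand

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.min_quality < 0:
            raise NgsError("max_mismatch and min_quality must be non-negative")
        if self.quality_mode not in ("mean", "min"):
            raise NgsError(f"unknown quality mode {self.quality_mode!r}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise NgsError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream a FASTQ file (gzip transparently handled, Phred+33)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield Read(title.split()[0], seq.upper(), qual)


# ---------------------------------------------------------------- demultiplex

def demultiplex(
    reads: Iterable[Read],
    samplesheet: SampleSheet,
    params: MapParams = MapParams(),
) -> tuple[dict[str, list[Read]], int]:
    """Assign reads to samples by barcode; returns (streams, n_bad_barcode).

    The forward barcode sits at ``barcode_offset`` from the read start and
    is stripped (together with any preceding bases) before downstream
    steps.  With ``max_barcode_mismatch`` > 0, a read matching two or more
    barcodes at the minimal distance is ambiguous and discarded.
    """
    streams: dict[str, list[Read]] = {r.sample_id: [] for r in samplesheet.rows}
    bad = 0
    off = params.barcode_offset
    bc_len = len(samplesheet.rows[0].fwd_barcode)
    if any(len(r.fwd_barcode) != bc_len for r in samplesheet.rows):
        raise NgsError("forward barcodes must share one length")
    exact = {r.fwd_barcode: r for r in samplesheet.rows}
    if len(exact) < len(samplesheet.rows) and not params.check_rev_barcode:
        raise NgsError("forward barcodes not unique; enable check_rev_barcode")

    for read in reads:
        seq = reverse_complement(read.seq) if params.revcomp_reads else read.seq
        qual = read.qual[::-1] if params.revcomp_reads else read.qual
        bc = seq[off : off + bc_len]
        row = None
        if len(bc) == bc_len:
            if params.max_barcode_mismatch == 0:
                row = exact.get(bc)
            else:
                dists = [(hamming(bc, r.fwd_barcode), r) for r in samplesheet.rows]
                dmin = min(d for d, _ in dists)
                hits = [r for d, r in dists if d == dmin]
                if dmin <= params.max_barcode_mismatch and len(hits) == 1:
                    row = hits[0]
        if row is not None and params.check_rev_barcode:
            tail = reverse_complement(row.rev_barcode)
            if not seq.endswith(tail):
                row = None
            else:
                seq, qual = seq[: -len(tail)], qual[: -len(tail)]
        if row is None:
            bad += 1
            continue
        cut = off + bc_len
        streams[row.sample_id].append(Read(read.read_id, seq[cut:], qual[cut:]))
    return streams, bad


# ---------------------------------------------------------------- quality

def insert_quality(read: Read, start: int, length: int, params: MapParams) -> float:
    q = read.phred()[start : start + length]
    if not q:
        return 0.0
    return float(min(q)) if params.quality_mode == "min" else sum(q) / len(q)


def quality_filter(read: Read, params: MapParams = MapParams(),
                   start: int = 0, length: int | None = None) -> bool:
    """Keep iff the aggregate Phred score over the insert region >= threshold."""
    length = len(read.seq) - start if length is None else length
    return insert_quality(read, start, length, params) >= params.min_quality


# ---------------------------------------------------------------- design index

class DesignIndex:
    """Mismatch-searchable index over the design's nucleotide inserts.

    Exact-match hash plus a pigeonhole partition into ``max_mismatch + 1``
    segments: a query within m mismatches of an entry must match at least
    one segment exactly, so candidate generation loses nothing relative to
    a linear Hamming scan.
    """

    def __init__(self, entries: list[LibraryEntry], max_mismatch: int = 2):
        if not entries:
            raise NgsError("empty design")
        self.entries = entries
        self.max_mismatch = max_mismatch
        lengths = {len(e.nt_seq) for e in entries}
        if len(lengths) != 1 or 0 in lengths:
            raise NgsError(f"design nt_seq lengths not uniform: {sorted(lengths)}")
        self.insert_len = lengths.pop()
        self.exact: dict[str, int] = {}
        for i, e in enumerate(entries):
            if e.nt_seq in self.exact:
                other = entries[self.exact[e.nt_seq]].entry_id
                raise NgsError(f"duplicate nt_seq for entries {other} and {e.entry_id}")
            self.exact[e.nt_seq] = i

        nseg = max_mismatch + 1
        bounds = [round(j * self.insert_len / nseg) for j in range(nseg + 1)]
        self.segments = list(zip(bounds[:-1], bounds[1:]))
        self.seg_tables: list[dict[str, list[int]]] = []
        for lo, hi in self.segments:
            table: dict[str, list[int]] = {}
            for i, e in enumerate(entries):
                table.setdefault(e.nt_seq[lo:hi], []).append(i)
            self.seg_tables.append(table)

    def lookup(self, insert: str, max_mismatch: int | None = None) -> tuple[str | None, str]:
        """Best-hit lookup; returns (entry_id or None, status).

        status is ``mapped``, ``unmapped`` (no entry within m) or
        ``ambiguous`` (two or more entries tie at the minimal distance).
        """
        m = self.max_mismatch if max_mismatch is None else max_mismatch
        if m > self.max_mismatch:
            raise NgsError("query mismatch budget exceeds index construction budget")
        if len(insert) != self.insert_len:
            return None, "unmapped"
        i = self.exact.get(insert)
        if i is not None:
            return self.entries[i].entry_id, "mapped"
        candidates: set[int] = set()
        for (lo, hi), table in zip(self.segments, self.seg_tables):
            candidates.update(table.get(insert[lo:hi], ()))
        best, best_d, tie = None, m + 1, False
        for i in candidates:
            d = hamming(insert, self.entries[i].nt_seq)
            if d < best_d:
                best, best_d, tie = i, d, False
            elif d == best_d:
                tie = True
        if best is None:
            return None, "unmapped"
        if tie:
            return None, "ambiguous"
        return self.entries[best].entry_id, "mapped"


def map_read(insert_nt: str, index: DesignIndex,
             params: MapParams = MapParams()) -> tuple[str | None, str]:
    """Map an extracted insert to the unique nearest design entry."""
    return index.lookup(insert_nt, params.max_mismatch)


def synonymous_filter(insert_nt: str, entry: LibraryEntry) -> bool:
    """Keep iff the insert still encodes the entry's exact peptide."""
    return translates_to(insert_nt, entry.aa_seq)


# ---------------------------------------------------------------- counting

@dataclass
class CountTable:
    """Per-(sample, entry) read counts with a discard ledger per sample."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    ledger: dict[str, dict[str, int]] = field(default_factory=dict)
    reads_in: dict[str, int] = field(default_factory=dict)
    samplesheet: SampleSheet | None = None

    def add(self, sample_id: str, entry_id: str, n: int = 1) -> None:
        self.counts[(sample_id, entry_id)] = self.counts.get((sample_id, entry_id), 0) + n

    def discard(self, sample_id: str, category: str, n: int = 1) -> None:
        led = self.ledger.setdefault(sample_id, dict.fromkeys(LEDGER_CATEGORIES, 0))
        led[category] += n

    def sample_total(self, sample_id: str) -> int:
        return sum(c for (s, _), c in self.counts.items() if s == sample_id)

    def check_conservation(self) -> None:
        """reads in == mapped + discarded, per sample."""
        for sid, n_in in self.reads_in.items():
            led = self.ledger.get(sid, {})
            n_out = self.sample_total(sid) + sum(led.values())
            if n_in != n_out:
                raise NgsError(f"sample {sid}: {n_in} reads in but {n_out} accounted for")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": s, "entry_id": e, "count": c}
                for (s, e), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["sample_id", "entry_id", "count"])

    def ledger_frame(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.reads_in):
            led = self.ledger.get(sid, dict.fromkeys(LEDGER_CATEGORIES, 0))
            rows.append({"sample_id": sid, "reads_in": self.reads_in[sid],
                         "mapped": self.sample_total(sid), **led})
        return pd.DataFrame(rows)

    def write(self, counts_path: str | Path, ledger_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index=False)
        if ledger_path is not None:
            self.ledger_frame().to_csv(ledger_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, ledger_path: str | Path | None = None,
             samplesheet: SampleSheet | None = None) -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", dtype={"sample_id": str, "entry_id": str})
        table = cls(samplesheet=samplesheet)
        for r in df.itertuples(index=False):
            table.add(r.sample_id, r.entry_id, int(r.count))
        if ledger_path is not None:
            led = pd.read_csv(ledger_path, sep="\t")
            for r in led.itertuples(index=False):
                table.reads_in[r.sample_id] = int(r.reads_in)
                for cat in LEDGER_CATEGORIES:
                    table.discard(r.sample_id, cat, int(getattr(r, cat)))
        else:
            for sid in {s for s, _ in table.counts}:
                table.reads_in[sid] = table.sample_total(sid)
        return table


def locate_insert(seq: str, flank5: str, insert_len: int, anchor_mismatch: int) -> int | None:
    """Start of the insert after the 5' flank anchor, or None.

    The flank is expected at the start of the barcode-stripped read; up to
    ``anchor_mismatch`` substitutions in the flank are tolerated.
    """
    if len(seq) < len(flank5) + insert_len:
        return None
    anchor = seq[: len(flank5)]
    if anchor == flank5 or hamming(anchor, flank5) <= anchor_mismatch:
        return len(flank5)
    return None


def count_reads(
    streams: dict[str, list[Read]],
    index: DesignIndex,
    flank5: str,
    params: MapParams = MapParams(),
    samplesheet: SampleSheet | None = None,
    n_bad_barcode: dict[str, int] | int | None = None,
) -> CountTable:
    """Run quality → mapping → synonymous filtering over demultiplexed streams.

    ``n_bad_barcode`` (from :func:`demultiplex`) is folded into the ledger
    of a pseudo-sample ``_undetermined`` when given as an int.
    """
    entries_by_id = {e.entry_id: e for e in index.entries}
    table = CountTable(samplesheet=samplesheet)
    for sid, reads in streams.items():
        table.reads_in[sid] = len(reads)
        table.ledger.setdefault(sid, dict.fromkeys(LEDGER_CATEGORIES, 0))
        for read in reads:
            start = locate_insert(read.seq, flank5, index.insert_len, params.anchor_mismatch)
            if start is None:
                table.discard(sid, "unmapped")
                continue
            if insert_quality(read, start, index.insert_len, params) < params.min_quality:
                table.discard(sid, "low_quality")
                continue
            insert = read.seq[start : start + index.insert_len]
            entry_id, status = map_read(insert, index, params)
            if entry_id is None:
                table.discard(sid, status)
                continue
            if not synonymous_filter(insert, entries_by_id[entry_id]):
                table.discard(sid, "nonsynonymous")
                continue
            table.add(sid, entry_id)
    if isinstance(n_bad_barcode, int) and n_bad_barcode:
        table.reads_in["_undetermined"] = n_bad_barcode
        table.discard("_undetermined", "bad_barcode", n_bad_barcode)
    table.check_conservation()
    return table
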