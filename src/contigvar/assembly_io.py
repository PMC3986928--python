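"""Padded-alignment data model and ACE / QUAL / sidecar I/O.

A contig is a padded multiple alignment as emitted by an assembler in
consed ACE format: every read is stored in contig orientation, gaps are
``*`` pads, and per-base quality scores live in a companion ``.qual``
file keyed by read id.  Organ of origin (leaf / stem / root) comes from a
separate two-column sidecar because MID-tag detection happens upstream of
this package; reads without a sidecar entry are ``untagged``.

Coordinates are 0-based half-open internally.  Reports emitted by the
downstream modules use 1-based inclusive positions in cleaned-column
space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Sequencing import Ace

ORGANS = ("leaf", "stem", "root", "untagged")

#: alphabet of padded-alignment states; ``*`` is the assembler pad (gap)
STATES = "ACGTN*"

#: deterministic state ordering used for majority tie-breaks
STATE_ORDER = {s: i for i, s in enumerate("ACGT*N")}


@dataclass
class AlignedRead:
    """One read placed in a contig's padded coordinate system.

    ``padded_seq`` is stored in contig orientation (already complemented
    for minus-strand reads) and ``padded_qual`` aligns 1:1 with it; pads
    carry an imputed quality (minimum of the nearest real neighbours).
    """

    read_id: str
    organ: str = "untagged"
    strand: str = "+"
    start_col: int = 0
    padded_seq: str = ""
    padded_qual: np.ndarray | None = None
    # unpadded bases trimmed at read ends when clipping to contig bounds;
    # needed to slice the QUAL vector consistently
    clipped_left: int = 0
    clipped_right: int = 0

    def __post_init__(self) -> None:
        if not self.padded_seq:
            raise ValueError(f"read {self.read_id}: empty padded sequence")
        if self.start_col < 0:
            raise ValueError(f"read {self.read_id}: negative start column")
        if self.organ not in ORGANS:
            raise ValueError(f"read {self.read_id}: unknown organ {self.organ!r}")
        if self.padded_qual is not None:
            self.padded_qual = np.asarray(self.padded_qual, dtype=np.int16)
            if len(self.padded_qual) != len(self.padded_seq):
                raise ValueError(
                    f"read {self.read_id}: quality length {len(self.padded_qual)}"
                    f" != sequence length {len(self.padded_seq)}"
                )

    @property
    def end_col(self) -> int:
        """Exclusive end column."""
        return self.start_col + len(self.padded_seq)

    def unpadded_len(self) -> int:
        return sum(1 for b in self.padded_seq if b != "*")


@dataclass
class ColumnProfile:
    """Per-column tally of states, with the qualities backing each state."""

    col: int
    counts: dict[str, int] = field(default_factory=dict)
    quals: dict[str, list[int]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class ContigAlignment:
    contig_id: str
    n_cols: int
    reads: list[AlignedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cols <= 0:
            raise ValueError(f"contig {self.contig_id}: non-positive length")
        for r in self.reads:
            if r.end_col > self.n_cols:
                raise ValueError(
                    f"contig {self.contig_id}: read {r.read_id} extends past column {self.n_cols}"
                )

    def column_entries(self) -> list[list[tuple[int, str, int]]]:
        """Per column, the list of ``(read_index, state, quality)`` triples.

        Qualities default to 0 when no QUAL file has been attached.
        """
        cols: list[list[tuple[int, str, int]]] = [[] for _ in range(self.n_cols)]
        for i, r in enumerate(self.reads):
            quals = r.padded_qual
            for k, base in enumerate(r.padded_seq):
                q = int(quals[k]) if quals is not None else 0
                cols[r.start_col + k].append((i, base, q))
        return cols

    def column_profiles(self) -> list[ColumnProfile]:
        profiles = []
        for j, entries in enumerate(self.column_entries()):
            p = ColumnProfile(col=j)
            for _, base, q in entries:
                p.counts[base] = p.counts.get(base, 0) + 1
                p.quals.setdefault(base, []).append(q)
            profiles.append(p)
        return profiles

    def coverage(self) -> np.ndarray:
        cov = np.zeros(self.n_cols, dtype=np.int32)
        for r in self.reads:
            cov[r.start_col : r.end_col] += 1
        return cov


def impute_pad_quals(padded_seq: str, base_quals: np.ndarray) -> np.ndarray:
    """Spread unpadded base qualities onto a padded sequence.

    Pads take the minimum of the nearest non-pad neighbour on each side
    (one-sided at the ends): a pad is never more trusted than its
    context.
    """
    base_quals = np.asarray(base_quals, dtype=np.int16)
    n = len(padded_seq)
    out = np.zeros(n, dtype=np.int16)
    idx = 0
    positions = []
    for k, b in enumerate(padded_seq):
        if b != "*":
            out[k] = base_quals[idx]
            idx += 1
            positions.append(k)
    if idx != len(base_quals):
        raise ValueError(
            f"quality vector length {len(base_quals)} != unpadded length {idx}"
        )
    if not positions:
        return out
    pos_arr = np.asarray(positions)
    for k, b in enumerate(padded_seq):
        if b != "*":
            continue
        right = pos_arr.searchsorted(k)
        left = right - 1
        cands = []
        if left >= 0:
            cands.append(out[pos_arr[left]])
        if right < len(pos_arr):
            cands.append(out[pos_arr[right]])
        out[k] = min(cands)
    return out


# ---------------------------------------------------------------------------
# ACE reading / writing
# ---------------------------------------------------------------------------


def read_ace(path: str | Path) -> list[ContigAlignment]:
    """Parse a consed-dialect ACE file into the padded-alignment model.

    ACE AF positions are 1-based; they are converted to 0-based
    ``start_col``.  Reads are stored exactly as the assembler aligned
    them (contig orientation); reads that protrude past the contig ends
    are clipped to the contig, recording how many unpadded bases were
    trimmed so qualities can later be sliced consistently.
    """
    with open(path) as handle:
        try:
            record = Ace.read(handle)
        except Exception as exc:  # Biopython raises bare ValueError on bad records
            raise ValueError(f"{path}: malformed ACE file: {exc}") from exc
    contigs = []
    for co in record.contigs:
        n_cols = len(co.sequence)
        rd_by_name = {r.rd.name: r for r in co.reads if r.rd is not None}
        reads = []
        for af in co.af:
            if af.name not in rd_by_name:
                raise ValueError(
                    f"{path}: contig {co.name}: read {af.name} listed in AF but has no RD record"
                )
            rd = rd_by_name[af.name].rd
            seq = rd.sequence.upper().replace("X", "N")
            start = af.padded_start - 1
            clipped_left = clipped_right = 0
            if start < 0:
                cut = -start
                clipped_left = sum(1 for b in seq[:cut] if b != "*")
                seq = seq[cut:]
                start = 0
            if start + len(seq) > n_cols:
                cut = start + len(seq) - n_cols
                clipped_right = sum(1 for b in seq[len(seq) - cut :] if b != "*")
                seq = seq[: len(seq) - cut]
            if not seq:
                continue
            reads.append(
                AlignedRead(
                    read_id=af.name,
                    strand="-" if af.coru == "C" else "+",
                    start_col=start,
                    padded_seq=seq,
                    clipped_left=clipped_left,
                    clipped_right=clipped_right,
                )
            )
        contigs.append(ContigAlignment(contig_id=co.name, n_cols=n_cols, reads=reads))
    return contigs


def write_ace(contigs: list[ContigAlignment], path: str | Path) -> None:
    """Write the model back out as a consed-dialect ACE file."""
    nreads = sum(len(c.reads) for c in contigs)
    with open(path, "w") as fh:
        fh.write(f"AS {len(contigs)} {nreads}\n\n")
        for c in contigs:
            cons = _majority_consensus(c)
            fh.write(f"CO {c.contig_id} {c.n_cols} {len(c.reads)} 0 U\n")
            for i in range(0, len(cons), 60):
                fh.write(cons[i : i + 60] + "\n")
            fh.write("\n")
            fh.write("BQ\n")
            unpadded = sum(1 for b in cons if b != "*")
            quals = ["20"] * unpadded
            for i in range(0, len(quals), 30):
                fh.write(" ".join(quals[i : i + 30]) + "\n")
            fh.write("\n")
            for r in c.reads:
                coru = "C" if r.strand == "-" else "U"
                fh.write(f"AF {r.read_id} {coru} {r.start_col + 1}\n")
            fh.write(f"BS 1 {c.n_cols} {c.reads[0].read_id if c.reads else c.contig_id}\n")
            fh.write("\n")
            for r in c.reads:
                fh.write(f"RD {r.read_id} {len(r.padded_seq)} 0 0\n")
                for i in range(0, len(r.padded_seq), 60):
                    fh.write(r.padded_seq[i : i + 60] + "\n")
                fh.write("\n")
                fh.write(f"QA 1 {len(r.padded_seq)} 1 {len(r.padded_seq)}\n")
                fh.write(f"DS CHROMAT_FILE: {r.read_id} PHD_FILE: {r.read_id}.phd.1 TIME: none\n\n")


def _majority_consensus(c: ContigAlignment) -> str:
    """Plain per-column majority call (pads included) for the CO line."""
    out = []
    for entries in c.column_entries():
        if not entries:
            out.append("N")
            continue
        counts: dict[str, int] = {}
        for _, b, _ in entries:
            counts[b] = counts.get(b, 0) + 1
        best = min(counts, key=lambda s: (-counts[s], STATE_ORDER.get(s, 99)))
        out.append(best)
    return "".join(out)


# ---------------------------------------------------------------------------
# Qualities, MID tags, TSV
# ---------------------------------------------------------------------------


def attach_qualities(contigs: list[ContigAlignment], qual_path: str | Path) -> list[ContigAlignment]:
    """Attach per-base qualities from a FASTA-style QUAL file (in place).

    The QUAL file stores unpadded scores in original read orientation.
    Minus-strand reads get their vector reversed; pads receive the
    imputed neighbour-minimum quality.
    """
    quals: dict[str, list[int]] = {}
    for rec in SeqIO.parse(str(qual_path), "qual"):
        quals[rec.id] = rec.letter_annotations["phred_quality"]
    for c in contigs:
        for r in c.reads:
            if r.read_id not in quals:
                raise KeyError(f"read {r.read_id} missing from QUAL file {qual_path}")
            q = list(quals[r.read_id])
            if r.strand == "-":
                q = q[::-1]
            # trimming recorded by read_ace is in contig orientation
            if r.clipped_left:
                q = q[r.clipped_left :]
            if r.clipped_right:
                q = q[: len(q) - r.clipped_right]
            if len(q) != r.unpadded_len():
                raise ValueError(
                    f"read {r.read_id}: QUAL length {len(q)} != unpadded read length {r.unpadded_len()}"
                )
            r.padded_qual = impute_pad_quals(r.padded_seq, np.asarray(q))
    return contigs


def write_qual(contigs: list[ContigAlignment], path: str | Path) -> None:
    """Write per-read qualities as a FASTA-style QUAL file.

    Inverse of :func:`attach_qualities`: pads dropped, minus-strand reads
    restored to original orientation.
    """
    records = []
    for c in contigs:
        for r in c.reads:
            if r.padded_qual is None:
                raise ValueError(f"read {r.read_id} has no qualities attached")
            q = [int(x) for b, x in zip(r.padded_seq, r.padded_qual) if b != "*"]
            if r.strand == "-":
                q = q[::-1]
            rec = SeqRecord(Seq("N" * len(q)), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = q
            records.append(rec)
    SeqIO.write(records, str(path), "qual")


def read_mids(path: str | Path) -> dict[str, str]:
    """Read the ``read_id<TAB>organ`` sidecar into a dict."""
    mids = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'read_id<TAB>organ'")
            read_id, organ = parts
            if organ not in ("leaf", "stem", "root"):
                raise ValueError(f"{path}:{ln}: unknown organ {organ!r}")
            mids[read_id] = organ
    return mids


def apply_mids(contigs: list[ContigAlignment], mids: dict[str, str]) -> list[ContigAlignment]:
    """Tag reads with their organ; reads absent from the sidecar stay untagged."""
    for c in contigs:
        for r in c.reads:
            r.organ = mids.get(r.read_id, "untagged")
    return contigs


def write_mids(contigs: list[ContigAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            for r in c.reads:
                if r.organ != "untagged":
                    fh.write(f"{r.read_id}\t{r.organ}\n")


def write_tsv(records: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a report table: tab-separated, header row, '.' decimals, deterministic order."""
    df = records
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_assembly(
    ace_path: str | Path,
    qual_path: str | Path | None = None,
    mids_path: str | Path | None = None,
) -> list[ContigAlignment]:
    """Convenience loader: ACE + optional QUAL + optional MID sidecar."""
    contigs = read_ace(ace_path)
    if qual_path is not None:
        attach_qualities(contigs, qual_path)
    if mids_path is not None:
        apply_mids(contigs, read_mids(mids_path))
    return contigs
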