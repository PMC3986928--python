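"""Masking, cleaning and IUPAC consensus editing of padded assemblies.

Three ordered per-column masking rules flag unreliable bases before any
variant is called:

1. *singleton*  — a variant state (differing from the column majority)
   supported by exactly one read;
2. *low_freq*   — a variant state whose frequency among the column's
   still-unmasked bases is below ``freq_min`` (default 0.1);
3. *low_qual*   — at columns still polymorphic after 1–2, any individual
   base with quality below ``qual_min`` (default 20).

``N`` bases are always masked.  Each rule sees the column as left by the
previous one; the rules run in a single pass, never to a fixpoint, so a
mask can never cascade beyond what the rules describe.

The *cleaning* step then deletes every column whose unmasked content is
pads only — the signature of 454 homopolymer over-calls — and the
consensus is edited over the surviving columns using IUPAC ambiguity
codes for states at frequency >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .assembly_io import ContigAlignment, STATE_ORDER


class MaskReason(IntEnum):
    NONE = 0
    SINGLETON = 1
    LOW_FREQ = 2
    LOW_QUAL = 3
    IS_N = 4


REASON_NAMES = {
    MaskReason.SINGLETON: "singleton",
    MaskReason.LOW_FREQ: "low_freq",
    MaskReason.LOW_QUAL: "low_qual",
    MaskReason.IS_N: "is_N",
}

IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class MaskedAssembly:
    """A contig alignment with per-base mask flags and cleaning provenance.

    ``mask[i][k]`` is the :class:`MaskReason` for base ``k`` of read
    ``i`` (0 = unmasked).  ``kept_cols`` lists, in increasing order, the
    original padded column indices that survive cleaning; report
    position ``p`` (1-based) corresponds to original column
    ``kept_cols[p-1]``.
    """

    contig: ContigAlignment
    mask: list[np.ndarray]
    kept_cols: list[int] = field(default_factory=list)
    consensus: str = ""
    _columns: list[list[tuple[int, str, int]]] | None = None

    def columns(self) -> list[list[tuple[int, str, int]]]:
        if self._columns is None:
            self._columns = self.contig.column_entries()
        return self._columns

    def reason_at(self, read_idx: int, col: int) -> MaskReason:
        r = self.contig.reads[read_idx]
        return MaskReason(int(self.mask[read_idx][col - r.start_col]))

    def unmasked_states(self, col: int) -> list[tuple[int, str, int]]:
        """Unmasked ``(read_idx, state, qual)`` entries at an original column."""
        out = []
        for i, b, q in self.columns()[col]:
            r = self.contig.reads[i]
            if self.mask[i][col - r.start_col] == MaskReason.NONE:
                out.append((i, b, q))
        return out

    def unmasked_counts(self, col: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, b, _ in self.unmasked_states(col):
            counts[b] = counts.get(b, 0) + 1
        return counts

    def n_unmasked(self) -> int:
        return int(sum((m == MaskReason.NONE).sum() for m in self.mask))


def _majority_state(counts: dict[str, int]) -> str:
    """Column majority; ties broken toward the earlier state in A<C<G<T<*."""
    return min(counts, key=lambda s: (-counts[s], STATE_ORDER[s]))


def mask_bases(c: ContigAlignment, freq_min: float = 0.1, qual_min: int = 20) -> MaskedAssembly:
    """Apply the three ordered masking rules to every column of a contig."""
    if not c.reads:
        raise ValueError(f"contig {c.contig_id} has no reads")
    mask = [np.zeros(len(r.padded_seq), dtype=np.int8) for r in c.reads]
    m = MaskedAssembly(contig=c, mask=mask)
    columns = m.columns()
    for col, entries in enumerate(columns):
        live = []  # (read_idx, offset, state, qual)
        for i, b, q in entries:
            off = col - c.reads[i].start_col
            if b == "N":
                mask[i][off] = MaskReason.IS_N
            else:
                live.append((i, off, b, q))
        if not live:
            continue

        # rule 1: singleton variants
        counts: dict[str, int] = {}
        for _, _, b, _ in live:
            counts[b] = counts.get(b, 0) + 1
        if len(counts) > 1:
            ref = _majority_state(counts)
            for i, off, b, _ in live:
                if b != ref and counts[b] == 1:
                    mask[i][off] = MaskReason.SINGLETON
            live = [e for e in live if mask[e[0]][e[1]] == MaskReason.NONE]

        # rule 2: low-frequency variants, frequency taken over the bases
        # left unmasked by rule 1
        counts = {}
        for _, _, b, _ in live:
            counts[b] = counts.get(b, 0) + 1
        denom = len(live)
        if len(counts) > 1 and denom > 0:
            ref = _majority_state(counts)
            for i, off, b, _ in live:
                if b != ref and counts[b] / denom < freq_min:
                    mask[i][off] = MaskReason.LOW_FREQ
            live = [e for e in live if mask[e[0]][e[1]] == MaskReason.NONE]

        # rule 3: per-base quality at still-polymorphic columns
        states = {b for _, _, b, _ in live}
        if len(states) >= 2:
            for i, off, b, q in live:
                if q < qual_min:
                    mask[i][off] = MaskReason.LOW_QUAL
    return m


def clean_columns(m: MaskedAssembly) -> MaskedAssembly:
    """Delete columns whose unmasked content is pads only (or empty)."""
    kept = []
    for col in range(m.contig.n_cols):
        if any(b in "ACGT" for _, b, _ in m.unmasked_states(col)):
            kept.append(col)
    m.kept_cols = kept
    return m


def edit_consensus(m: MaskedAssembly, freq_min: float = 0.1) -> str:
    """Edit the IUPAC consensus over the cleaned columns.

    Per column the consensus is the ambiguity code of the unmasked
    A/C/G/T states at frequency >= ``freq_min`` among unmasked real
    bases; it is lowercased when unmasked pads outnumber real bases
    (likely deletion), and 'N' when no real base qualifies.
    """
    if not m.kept_cols:
        clean_columns(m)
    out = []
    for col in m.kept_cols:
        counts = m.unmasked_counts(col)
        n_pad = counts.get("*", 0)
        real = {b: n for b, n in counts.items() if b in "ACGT"}
        total_real = sum(real.values())
        called = frozenset(b for b, n in real.items() if total_real and n / total_real >= freq_min)
        code = IUPAC.get(called, "N") if called else "N"
        if n_pad > total_real:
            code = code.lower()
        out.append(code)
    m.consensus = "".join(out)
    return m.consensus


def mask_and_clean(
    c: ContigAlignment, freq_min: float = 0.1, qual_min: int = 20
) -> MaskedAssembly:
    """Mask, clean and edit consensus in one call."""
    m = mask_bases(c, freq_min=freq_min, qual_min=qual_min)
    clean_columns(m)
    edit_consensus(m, freq_min=freq_min)
    return m


def mask_audit_rows(m: MaskedAssembly) -> list[dict]:
    """Flattened mask provenance for the audit TSV."""
    clean_of = {orig: i + 1 for i, orig in enumerate(m.kept_cols)}
    rows = []
    for i, r in enumerate(m.contig.reads):
        reasons = m.mask[i]
        for off in np.nonzero(reasons)[0]:
            col = r.start_col + int(off)
            rows.append(
                {
                    "contig": m.contig.contig_id,
                    "orig_col": col + 1,
                    "clean_col": clean_of.get(col, "NA"),
                    "read_id": r.read_id,
                    "base": r.padded_seq[off],
                    "qual": int(r.padded_qual[off]) if r.padded_qual is not None else "NA",
                    "reason": REASON_NAMES[MaskReason(int(reasons[off]))],
                }
            )
    return rows
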