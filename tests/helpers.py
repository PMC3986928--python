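"""Shared test utilities: alignment builders and independent oracles.

The oracles here deliberately re-derive expected results by the most
direct route available (per-column recounting, exact rational
arithmetic) and never call the code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from contigvar.assembly_io import AlignedRead, ContigAlignment


def make_contig(
    column_specs: list[list[tuple[str, int]]], contig_id: str = "ctg"
) -> ContigAlignment:
    """Build a contig from per-column (state, quality) stacks.

    ``column_specs[j]`` lists the bases of column ``j`` top to bottom;
    row ``i`` across all columns becomes read ``i`` (absent rows are
    simply shorter reads is not supported — pad the spec with entries).
    Every read spans all columns, so each column's depth equals the
    number of rows.
    """
    n_rows = len(column_specs[0])
    if any(len(col) != n_rows for col in column_specs):
        raise ValueError("all columns must list the same number of rows")
    reads = []
    for i in range(n_rows):
        seq = "".join(col[i][0] for col in column_specs)
        quals = np.array([col[i][1] for col in column_specs], dtype=np.int16)
        reads.append(
            AlignedRead(read_id=f"r{i}", start_col=0, padded_seq=seq, padded_qual=quals)
        )
    return ContigAlignment(contig_id=contig_id, n_cols=len(column_specs), reads=reads)


def column_from_counts(counts: dict[str, int], qual: int = 30, **qual_overrides) -> list:
    """One column spec from state counts; per-state quality overrides via
    e.g. ``C=[30, 15]``."""
    col = []
    for state in sorted(counts):
        qs = qual_overrides.get(state, [qual] * counts[state])
        if len(qs) != counts[state]:
            raise ValueError("override length mismatch")
        col.extend((state, q) for q in qs)
    return col


def random_alignment(rng: np.random.Generator, n_cols: int = 20, n_reads: int | None = None) -> ContigAlignment:
    """Random full-length alignment over {A,C,G,T,N,*} with random quals."""
    if n_reads is None:
        n_reads = int(rng.integers(2, 25))
    states = np.array(list("ACGTN*"))
    # skewed state draw so columns are usually near-monomorphic
    specs = []
    for _ in range(n_cols):
        major = states[rng.integers(0, 4)]
        col = []
        for _ in range(n_reads):
            if rng.random() < 0.75:
                b = major
            else:
                b = states[rng.integers(0, 6)]
            col.append((str(b), int(rng.integers(5, 41))))
        specs.append(col)
    return make_contig(specs)


# ---------------------------------------------------------------------------
# brute-force masking oracle
# ---------------------------------------------------------------------------

def brute_force_mask_column(
    entries: list[tuple[str, int]], freq_min: float = 0.1, qual_min: int = 20
) -> list[str]:
    """Expected mask reason per base of one column, by direct re-derivation.

    ``entries`` are (state, quality) pairs; returns one of
    ``none/singleton/low_freq/low_qual/is_N`` per entry, applying the
    three ordered rules literally.
    """
    order = {s: i for i, s in enumerate("ACGT*N")}
    reasons = ["none"] * len(entries)
    for i, (b, _) in enumerate(entries):
        if b == "N":
            reasons[i] = "is_N"

    def live():
        return [(i, b, q) for i, (b, q) in enumerate(entries) if reasons[i] == "none"]

    def counts(l):
        c: dict[str, int] = {}
        for _, b, _ in l:
            c[b] = c.get(b, 0) + 1
        return c

    def majority(c):
        return min(c, key=lambda s: (-c[s], order[s]))

    l = live()
    c = counts(l)
    if len(c) > 1:
        ref = majority(c)
        for i, b, _ in l:
            if b != ref and c[b] == 1:
                reasons[i] = "singleton"

    l = live()
    c = counts(l)
    if len(c) > 1:
        ref = majority(c)
        for i, b, _ in l:
            if b != ref and c[b] / len(l) < freq_min:
                reasons[i] = "low_freq"

    l = live()
    if len({b for _, b, _ in l}) >= 2:
        for i, b, q in l:
            if q < qual_min:
                reasons[i] = "low_qual"
    return reasons


def exact_binom_cdf(t: int, x: int, p: Fraction) -> Fraction:
    """Exact rational binomial CDF by direct summation."""
    return sum(
        Fraction(comb(x, k)) * p**k * (1 - p) ** (x - k) for k in range(t + 1)
    )
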