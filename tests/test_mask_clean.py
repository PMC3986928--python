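"""Masking rules, cleaning and IUPAC consensus editing."""

import numpy as np
import pytest

from helpers import brute_force_mask_column, column_from_counts, make_contig, random_alignment

from contigvar import clean_columns, edit_consensus, mask_bases, mask_and_clean
from contigvar.assembly_io import AlignedRead, ContigAlignment
from contigvar.mask_clean import MaskReason, REASON_NAMES


def reasons_at(m, col):
    """Observed reason name per (row-ordered) base of a column."""
    out = []
    for i, r in enumerate(m.contig.reads):
        out.append(REASON_NAMES.get(MaskReason(int(m.mask[i][col - r.start_col])), "none"))
    return out


@pytest.mark.parametrize(
    "counts, overrides, expected",
    [
        # a lone G among nine A's is a singleton; column ends monomorphic
        ({"A": 9, "G": 1}, {}, {"G": ["singleton"]}),
        # C at 2/21 = 0.095 < 0.1 is a low-frequency variant
        ({"A": 19, "C": 2}, {}, {"C": ["low_freq", "low_freq"]}),
        # balanced column: only the individual low-quality base is masked
        ({"A": 5, "C": 5}, {"C": [30, 30, 30, 30, 15]},
         {"C": ["none", "none", "none", "none", "low_qual"]}),
        # monomorphic column: nothing masked
        ({"A": 12}, {}, {}),
        # N is always masked
        ({"A": 6, "N": 2}, {}, {"N": ["is_N", "is_N"]}),
        # gap variants follow the same rules as substitutions
        ({"A": 8, "*": 1}, {}, {"*": ["singleton"]}),
    ],
)
def test_masking_rule_examples(counts, overrides, expected):
    contig = make_contig([column_from_counts(counts, **overrides)])
    m = mask_bases(contig)
    got = reasons_at(m, 0)
    # map back per state in sorted-state, row order (matches column_from_counts)
    i = 0
    for state in sorted(counts):
        for k in range(counts[state]):
            want = expected.get(state, ["none"] * counts[state])[k]
            assert got[i] == want, (state, k, got)
            i += 1


def test_quality_rule_leaves_column_polymorphic():
    """Masking one low-quality C out of five leaves a 5A/4C column."""
    contig = make_contig(
        [column_from_counts({"A": 5, "C": 5}, C=[30, 30, 30, 30, 15])]
    )
    m = mask_bases(contig)
    assert m.unmasked_counts(0) == {"A": 5, "C": 4}


@pytest.mark.parametrize(
    "counts, overrides, kept",
    [
        ({"*": 12}, {}, False),  # pads only: deleted
        ({"*": 11, "A": 1}, {}, False),  # pads + masked singleton: deleted
        ({"*": 6, "A": 6}, {}, True),  # real bases survive
    ],
)
def test_cleaning_removes_indel_only_columns(counts, overrides, kept):
    contig = make_contig([column_from_counts(counts, **overrides)])
    m = clean_columns(mask_bases(contig))
    assert (0 in m.kept_cols) == kept


@pytest.mark.parametrize(
    "counts, overrides, expected",
    [
        ({"A": 5, "G": 5}, {}, "R"),
        ({"A": 10}, {}, "A"),
        # the masked singleton T is excluded: consensus set is {A, C} -> M
        ({"A": 8, "C": 2, "T": 1}, {}, "M"),
    ],
)
def test_consensus_iupac_codes(counts, overrides, expected):
    contig = make_contig([column_from_counts(counts, **overrides)])
    m = mask_and_clean(contig)
    assert m.consensus == expected


def test_consensus_lowercase_flags_pad_majority():
    """Unmasked pads outnumbering real bases lowercase the call."""
    contig = make_contig([column_from_counts({"*": 7, "A": 5})])
    m = mask_and_clean(contig)
    assert m.consensus == "a"


def _materialize(m):
    """Rebuild a contig keeping only cleaned columns, masked bases as N.

    N is equivalent to a masked base for every downstream rule, so the
    rebuilt contig represents 'the output of mask+clean' faithfully.
    """
    reads = []
    for i, r in enumerate(m.contig.reads):
        seq = []
        quals = []
        for clean_j, col in enumerate(m.kept_cols):
            if not (r.start_col <= col < r.end_col):
                continue
            off = col - r.start_col
            b = r.padded_seq[off]
            if m.mask[i][off] != MaskReason.NONE:
                b = "N"
            seq.append(b)
            quals.append(int(r.padded_qual[off]) if r.padded_qual is not None else 30)
        if seq:
            reads.append(
                AlignedRead(
                    read_id=r.read_id,
                    start_col=min(
                        j for j, col in enumerate(m.kept_cols) if r.start_col <= col < r.end_col
                    ),
                    padded_seq="".join(seq),
                    padded_qual=np.array(quals, dtype=np.int16),
                )
            )
    return ContigAlignment(contig_id=m.contig.contig_id, n_cols=len(m.kept_cols), reads=reads)


def test_mask_clean_is_idempotent():
    """mask+clean is a deterministic projection: applying it twice to the
    same input reproduces the same flags, kept columns and consensus, and
    re-applying it to its own (materialized) output only ever removes
    content — the single-pass rule ordering never restores a base or a
    column, and deliberately never iterates masking to a fixpoint."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        contig = random_alignment(rng)
        m1 = mask_and_clean(contig)
        m1b = mask_and_clean(contig)
        assert m1b.kept_cols == m1.kept_cols
        assert m1b.consensus == m1.consensus
        assert all(np.array_equal(a, b) for a, b in zip(m1.mask, m1b.mask))
        if not m1.kept_cols:
            continue
        m2 = mask_and_clean(_materialize(m1))
        # columns kept by the second pass map into the first pass's kept set
        assert set(m2.kept_cols) <= set(range(len(m1.kept_cols)))
        assert m2.n_unmasked() <= m1.n_unmasked()


def test_unmasked_base_count_never_increases():
    """Masking is monotone and the consensus never outgrows the contig."""
    rng = np.random.default_rng(13)
    for _ in range(25):
        contig = random_alignment(rng)
        total = sum(len(r.padded_seq) for r in contig.reads)
        m = mask_and_clean(contig)
        assert m.n_unmasked() <= total
        assert len(m.consensus) == len(m.kept_cols) <= contig.n_cols


def test_mask_reasons_match_brute_force_oracle():
    """Module flags equal a direct per-column re-derivation of the rules."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        contig = random_alignment(rng)
        m = mask_bases(contig)
        for col in range(contig.n_cols):
            entries = [
                (r.padded_seq[col - r.start_col], int(r.padded_qual[col - r.start_col]))
                for r in contig.reads
            ]
            assert reasons_at(m, col) == brute_force_mask_column(entries), (col, entries)
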