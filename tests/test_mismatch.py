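"""Mismatch calling, binomial probabilities, post-filters and summaries."""

import copy
from fractions import Fraction

import numpy as np
import pytest

from helpers import column_from_counts, exact_binom_cdf, make_contig

from contigvar import (
    binom_cum_p,
    binom_point_p,
    call_mismatches,
    mask_and_clean,
    post_filter,
    summarize,
)
from contigvar.mismatch import MismatchRecord, classify


def _records_for(counts_list):
    contig = make_contig([column_from_counts(c) for c in counts_list])
    m = mask_and_clean(contig)
    return call_mismatches(m), m


def test_transition_record_fields():
    """6A/3G is a transition with maf 1/3 and minor count 3."""
    recs, _ = _records_for([{"A": 6, "G": 3}])
    assert len(recs) == 1
    r = recs[0]
    assert r.var_class == "transition"
    assert r.depth == 9
    assert r.t == 3
    assert r.maf == pytest.approx(1 / 3)
    assert r.n_states == 2


@pytest.mark.parametrize(
    "states, expected",
    [
        (["A", "G"], "transition"),
        (["C", "T"], "transition"),
        (["A", "C"], "transversion"),
        (["G", "T"], "transversion"),
        (["A", "*"], "indel"),
        (["A", "C", "G"], "multiallelic"),
        (["A", "C", "*"], "multiallelic"),
    ],
)
def test_variant_classification(states, expected):
    assert classify(states) == expected


def test_indel_and_monomorphic_columns():
    recs, _ = _records_for([{"A": 6, "*": 2}, {"C": 8}])
    assert len(recs) == 1
    assert recs[0].var_class == "indel"


def test_masked_singleton_never_becomes_a_record():
    recs, _ = _records_for([{"A": 9, "G": 1}])
    assert recs == []


# ---------------------------------------------------------------------------
# binomial probabilities
# ---------------------------------------------------------------------------


def test_binomial_worked_values():
    """Frozen values from exact rational summation."""
    # 3 or fewer of 29 at p=1/4: 0.0455054... — below the 0.05 discard line
    assert binom_cum_p(3, 29, 0.25) == pytest.approx(0.04550536, abs=1e-7)
    assert binom_cum_p(3, 29, 0.25) < 0.05
    # exactly 2 of 8 at p=1/4: 0.311462... — well above 5%
    assert binom_point_p(2, 8, 0.25) == pytest.approx(0.31146240, abs=1e-7)
    assert round(binom_point_p(2, 8, 0.25), 2) == 0.31
    # cumulative of the same configuration is comfortably non-significant
    assert binom_cum_p(2, 8, 0.25) == pytest.approx(0.67854, abs=1e-4)
    assert binom_cum_p(0, 8, 0.25) == pytest.approx(0.75**8)


def test_binomial_degenerate_cases():
    assert binom_cum_p(29, 29, 0.25) == pytest.approx(1.0)
    assert binom_point_p(0, 0, 0.25) == 1.0
    assert binom_point_p(1, 1, 0.25) == pytest.approx(0.25)


@pytest.mark.parametrize("bad", [(-1, 5, 0.25), (6, 5, 0.25), (1, 5, 0.0), (1, 5, 1.0)])
def test_binomial_rejects_invalid_arguments(bad):
    with pytest.raises((ValueError, TypeError)):
        binom_cum_p(*bad)


def test_cumulative_matches_exact_rationals_small_grid():
    p = Fraction(1, 4)
    for x in range(0, 26):
        for t in range(0, x + 1):
            exact = float(exact_binom_cdf(t, x, p))
            assert abs(binom_cum_p(t, x, 0.25) - exact) < 1e-12, (t, x)


# ---------------------------------------------------------------------------
# post-filters
# ---------------------------------------------------------------------------


def _rec(contig="c1", pos=1, t=2, depth=8, var_class="transition"):
    return MismatchRecord(
        contig_id=contig,
        clean_pos=pos,
        orig_col=pos - 1,
        variants={"A": (depth - t, 30.0), "G": (t, 30.0)},
        depth=depth,
        maf=t / depth,
        n_states=2,
        var_class=var_class,
        t=t,
    )


def test_adjacent_pair_both_flagged():
    recs = post_filter([_rec(pos=41, depth=20, t=5), _rec(pos=42, depth=20, t=5)])
    assert all("adjacent" in r.flags for r in recs)


def test_adjacent_run_flags_every_member():
    recs = post_filter([_rec(pos=p, depth=20, t=5) for p in (10, 11, 12, 20)])
    flagged = {r.clean_pos: "adjacent" in r.flags for r in recs}
    assert flagged == {10: True, 11: True, 12: True, 20: False}


def test_binomial_filter_flags_3_of_29():
    (r,) = post_filter([_rec(t=3, depth=29)])
    assert "binom_fail" in r.flags
    assert r.binom_p == pytest.approx(0.04551, abs=1e-4)


def test_2_of_8_passes_binomial_and_depth():
    (r,) = post_filter([_rec(t=2, depth=8)])
    assert r.passed
    assert r.binom_p >= 0.05
    assert "low_depth" not in r.flags


def test_depth_filter():
    (r,) = post_filter([_rec(t=2, depth=7)])
    assert "low_depth" in r.flags


def test_post_filter_monotone_in_alpha_and_depth():
    """Raising alpha or depth_min can only shrink the passed set."""
    rng = np.random.default_rng(3)
    base = []
    pos = 1
    for _ in range(200):
        pos += int(rng.integers(1, 4))
        depth = int(rng.integers(2, 40))
        t = int(rng.integers(1, depth // 2 + 1))
        base.append(_rec(pos=pos, t=t, depth=depth))
    passed = {}
    for alpha, dmin in [(0.01, 4), (0.05, 4), (0.05, 8), (0.10, 8), (0.10, 12)]:
        recs = post_filter(copy.deepcopy(base), alpha=alpha, depth_min=dmin)
        passed[(alpha, dmin)] = {r.clean_pos for r in recs if r.passed}
    assert passed[(0.05, 4)] <= passed[(0.01, 4)]
    assert passed[(0.05, 8)] <= passed[(0.05, 4)]
    assert passed[(0.10, 8)] <= passed[(0.05, 8)]
    assert passed[(0.10, 12)] <= passed[(0.10, 8)]


def test_flags_independent_of_input_order():
    recs = [_rec(pos=p, t=3, depth=29) for p in (5, 9, 2)]
    a = post_filter(copy.deepcopy(recs))
    b = post_filter(copy.deepcopy(recs[::-1]))
    fa = {r.clean_pos: sorted(r.flags) for r in a}
    fb = {r.clean_pos: sorted(r.flags) for r in b}
    assert fa == fb


def test_rejects_too_few_gametes():
    with pytest.raises(ValueError):
        post_filter([_rec()], n_gametes=1)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_density_formula_and_titv():
    # 20A/8G at two far-apart columns in a deep contig: both pass all filters
    specs = []
    for j in range(40):
        if j in (10, 30):
            specs.append(column_from_counts({"A": 20, "G": 8}))
        elif j == 20:
            specs.append(column_from_counts({"A": 20, "C": 8}))
        else:
            specs.append(column_from_counts({"A": 28}))
    contig = make_contig(specs)
    m = mask_and_clean(contig)
    recs = post_filter(call_mismatches(m))
    s = summarize(recs, [m], passed_only=True)
    assert s.denom_bases == 40
    assert s.n_mismatch == 3
    assert s.density_per_100bp == pytest.approx(100.0 * 3 / 40)
    assert s.n_transition == 2 and s.n_transversion == 1
    assert s.titv == pytest.approx(2.0)
    assert s.n_biallelic + s.n_multiallelic == s.n_mismatch


def test_post_filter_density_never_exceeds_prefilter(small_sim):
    cleaned = [mask_and_clean(c) for c in small_sim.contigs]
    recs = post_filter([r for m in cleaned for r in call_mismatches(m)])
    before = summarize(recs, cleaned, passed_only=False)
    after = summarize(recs, cleaned, passed_only=True)
    assert after.n_mismatch <= before.n_mismatch
    assert before.denom_bases == after.denom_bases
    if not np.isnan(before.density_per_100bp):
        assert after.density_per_100bp <= before.density_per_100bp


def test_summary_matches_brute_force_recount(small_sim):
    """Summary fields equal direct recounts over the record list."""
    cleaned = [mask_and_clean(c) for c in small_sim.contigs]
    recs = post_filter([r for m in cleaned for r in call_mismatches(m)])
    s = summarize(recs, cleaned, passed_only=True)
    sel = [r for r in recs if r.passed]
    assert s.n_mismatch == len(sel)
    assert s.n_variant_contigs == len({r.contig_id for r in sel})
    for cls, field in [
        ("transition", s.n_transition),
        ("transversion", s.n_transversion),
        ("indel", s.n_indel),
        ("multiallelic", s.n_multiallelic),
    ]:
        assert field == sum(1 for r in sel if r.var_class == cls)
    # denominator: brute-force recount of deep cleaned columns
    denom = 0
    for m in cleaned:
        for col in m.kept_cols:
            if sum(m.unmasked_counts(col).values()) >= 8:
                denom += 1
    assert s.denom_bases == denom
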