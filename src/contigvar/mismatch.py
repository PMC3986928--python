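"""Mismatch calling, binomial false-positive filtering and density summaries.

A *mismatch* is a cleaned column with at least two distinct unmasked
states — a candidate SNP or indel.  Three non-destructive post-filters
flag records rather than delete them:

- ``adjacent``   — both members of any pair of records at consecutive
  cleaned positions (runs flag every member); adjacent mismatches are
  typically assembly artefacts;
- ``binom_fail`` — the minor state count ``t`` at depth ``x`` is
  improbably low for a real pool variant.  With ``2N`` gametes in the
  sequencing pool a true variant has expected frequency at least
  ``p = 1/2N``, so the cumulative binomial probability of observing it
  ``t`` times or fewer, ``sum_{k<=t} C(x,k) p^k (1-p)^(x-k)``, below
  ``alpha`` marks a likely false positive;
- ``low_depth``  — column depth below ``depth_min`` (default 8).

Mismatch density is candidate variants per 100 bp, with the denominator
restricted to cleaned columns whose unmasked depth is at least
``depth_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binom as _binom

from .mask_clean import MaskedAssembly

TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class MismatchRecord:
    contig_id: str
    clean_pos: int  # 1-based position in cleaned-column space
    orig_col: int  # 0-based original padded column
    variants: dict[str, tuple[int, float]]  # state -> (count, mean qual)
    depth: int
    maf: float
    n_states: int
    var_class: str  # transition | transversion | indel | multiallelic
    t: int  # count of the rarest state
    binom_p: float = float("nan")
    flags: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.flags


@dataclass
class DensitySummary:
    n_mismatch: int
    n_variant_contigs: int
    pct_variant_contigs: float
    denom_bases: int
    density_per_100bp: float
    n_biallelic: int
    n_transition: int
    n_transversion: int
    titv: float
    n_indel: int
    n_multiallelic: int


def classify(states: list[str]) -> str:
    """Variant class of a set of states: >2 states is multiallelic, a pad
    among two states is an indel, else transition or transversion."""
    if len(states) > 2:
        return "multiallelic"
    if "*" in states:
        return "indel"
    pair = set(states)
    if pair in TRANSITIONS:
        return "transition"
    return "transversion"


def call_mismatches(m: MaskedAssembly) -> list[MismatchRecord]:
    """One record per cleaned column with >= 2 distinct unmasked states."""
    if not m.kept_cols:
        raise ValueError(
            f"contig {m.contig.contig_id}: clean_columns must run before mismatch calling"
        )
    records = []
    for pos, col in enumerate(m.kept_cols, start=1):
        entries = m.unmasked_states(col)
        counts: dict[str, int] = {}
        qsums: dict[str, int] = {}
        for _, b, q in entries:
            counts[b] = counts.get(b, 0) + 1
            qsums[b] = qsums.get(b, 0) + q
        if len(counts) < 2:
            continue
        depth = len(entries)
        t = min(counts.values())
        variants = {b: (n, qsums[b] / n) for b, n in counts.items()}
        records.append(
            MismatchRecord(
                contig_id=m.contig.contig_id,
                clean_pos=pos,
                orig_col=col,
                variants=variants,
                depth=depth,
                maf=t / depth,
                n_states=len(counts),
                var_class=classify(sorted(counts)),
                t=t,
            )
        )
    return records


def _check_binom_args(t: int, x: int, p: float) -> None:
    if not (isinstance(t, int) and isinstance(x, int)):
        raise TypeError("t and x must be integers")
    if not 0 <= t <= x:
        raise ValueError(f"need 0 <= t <= x, got t={t}, x={x}")
    if not 0 < p < 1:
        raise ValueError(f"need 0 < p < 1, got p={p}")


def binom_point_p(t: int, x: int, p: float) -> float:
    """P(X = t) for X ~ Binomial(x, p): C(x,t) p^t (1-p)^(x-t)."""
    if t == x == 0:
        return 1.0
    _check_binom_args(t, x, p)
    return float(_binom.pmf(t, x, p))


def binom_cum_p(t: int, x: int, p: float) -> float:
    """P(X <= t) for X ~ Binomial(x, p)."""
    _check_binom_args(t, x, p)
    return float(_binom.cdf(t, x, p))


def post_filter(
    records: list[MismatchRecord],
    n_gametes: int = 4,
    alpha: float = 0.05,
    depth_min: int = 8,
) -> list[MismatchRecord]:
    """Flag adjacent, binomially improbable and shallow records (in place).

    All records are returned with their flags set; nothing is deleted.
    """
    if n_gametes < 2:
        raise ValueError("n_gametes must be >= 2 (at least one diploid genotype)")
    p = 1.0 / n_gametes
    records = sorted(records, key=lambda r: (r.contig_id, r.clean_pos))
    for prev, cur in zip(records, records[1:]):
        if cur.contig_id == prev.contig_id and cur.clean_pos == prev.clean_pos + 1:
            prev.flags.add("adjacent")
            cur.flags.add("adjacent")
    for r in records:
        r.binom_p = binom_cum_p(r.t, r.depth, p)
        if r.binom_p < alpha:
            r.flags.add("binom_fail")
        if r.depth < depth_min:
            r.flags.add("low_depth")
    return records


def _denominator_bases(cleaned: list[MaskedAssembly], depth_min: int) -> int:
    denom = 0
    for m in cleaned:
        for col in m.kept_cols:
            if len(m.unmasked_states(col)) >= depth_min:
                denom += 1
    return denom


def summarize(
    records: list[MismatchRecord],
    cleaned: list[MaskedAssembly],
    depth_min: int = 8,
    passed_only: bool = False,
) -> DensitySummary:
    """Density / class summary over flagged records.

    The *before* block (``passed_only=False``) keeps records free of the
    adjacency and depth flags; the *after* block additionally requires
    the binomial filter to pass, so the two blocks differ exactly by the
    binomial test.  The denominator — cleaned columns with unmasked
    depth >= ``depth_min`` — is shared.
    """
    if passed_only:
        sel = [r for r in records if r.passed]
    else:
        sel = [r for r in records if not ({"adjacent", "low_depth"} & r.flags)]
    denom = _denominator_bases(cleaned, depth_min)
    n = len(sel)
    contigs_with = {r.contig_id for r in sel}
    n_ti = sum(1 for r in sel if r.var_class == "transition")
    n_tv = sum(1 for r in sel if r.var_class == "transversion")
    n_indel = sum(1 for r in sel if r.var_class == "indel")
    n_multi = sum(1 for r in sel if r.var_class == "multiallelic")
    return DensitySummary(
        n_mismatch=n,
        n_variant_contigs=len(contigs_with),
        pct_variant_contigs=len(contigs_with) / len(cleaned) if cleaned else float("nan"),
        denom_bases=denom,
        density_per_100bp=100.0 * n / denom if denom else float("nan"),
        n_biallelic=n - n_multi,
        n_transition=n_ti,
        n_transversion=n_tv,
        titv=n_ti / n_tv if n_tv else float("nan"),
        n_indel=n_indel,
        n_multiallelic=n_multi,
    )


def records_to_rows(records: list[MismatchRecord]) -> list[dict]:
    """Flatten records for the report TSV."""
    rows = []
    for r in sorted(records, key=lambda r: (r.contig_id, r.clean_pos)):
        states = sorted(r.variants, key=lambda s: (-r.variants[s][0], s))
        rows.append(
            {
                "contig": r.contig_id,
                "pos": r.clean_pos,
                "ref": states[0],
                "alt": ",".join(states[1:]),
                "counts": ",".join(str(r.variants[s][0]) for s in states),
                "depth": r.depth,
                "mean_quals": ",".join(f"{r.variants[s][1]:.1f}" for s in states),
                "maf": round(r.maf, 4),
                "class": r.var_class,
                "t": r.t,
                "binom_p": "NA" if math.isnan(r.binom_p) else round(r.binom_p, 6),
                "flags": ",".join(sorted(r.flags)) if r.flags else ".",
                "passed": int(r.passed),
            }
        )
    return rows


def summary_to_rows(before: DensitySummary, after: DensitySummary) -> list[dict]:
    """Two-block (before/after binomial filtering) summary table rows."""
    rows = []
    for block, s in (("before_binomial", before), ("after_binomial", after)):
        rows.append(
            {
                "block": block,
                "n_mismatch": s.n_mismatch,
                "n_variant_contigs": s.n_variant_contigs,
                "pct_variant_contigs": round(100 * s.pct_variant_contigs, 2),
                "denom_bases": s.denom_bases,
                "density_per_100bp": round(s.density_per_100bp, 4)
                if not math.isnan(s.density_per_100bp)
                else "NA",
                "n_biallelic": s.n_biallelic,
                "n_transition": s.n_transition,
                "n_transversion": s.n_transversion,
                "titv": round(s.titv, 3) if not math.isnan(s.titv) else "NA",
                "n_indel": s.n_indel,
                "n_multiallelic": s.n_multiallelic,
            }
        )
    return rows
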