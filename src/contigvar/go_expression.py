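"""Permutation test for organ-level over-expression of GO-term gene groups.

The number of reads a contig receives from an organ library is a rough
proxy for the expression level of the underlying gene.  For each GO
biological-process term and each organ:

1. the observed statistic is the mean read count over the term's
   contigs, excluding contigs with zero reads in that organ;
2. the organ's count vector is permuted over *all* contigs (zero counts
   included in the pool, excluded again after assignment) ``n_perm``
   times, recording the permuted mean and the difference
   observed - permuted;
3. the term is called over-expressed when the observed mean exceeds
   more than 95% of the permuted means.

Tests are one-sided (over-expression only), run separately per organ,
and — matching common practice for this screen — no multiple-testing
correction is applied by default; a Benjamini–Hochberg option exists.
All terms are evaluated against the same permutation stream, so results
are reproducible bit-for-bit given the seed but not independent across
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ORGAN_COLUMNS = ("leaf", "stem", "root")


@dataclass
class GOExpressionTable:
    """Contig -> GO associations plus the contig x organ read-count matrix."""

    contigs: list[str]
    go_map: dict[str, np.ndarray]  # term -> sorted array of contig indices
    counts: pd.DataFrame  # index = contigs, columns = organs

    def __post_init__(self) -> None:
        for term, idx in self.go_map.items():
            if len(idx) == 0:
                raise ValueError(f"GO term {term} maps to no contig")

    @classmethod
    def from_frames(cls, go_assoc: pd.DataFrame, counts: pd.DataFrame) -> "GOExpressionTable":
        """Build from a two-column (contig, go_term) table and a counts table."""
        contigs = list(counts.index)
        pos = {c: i for i, c in enumerate(contigs)}
        go_map: dict[str, list[int]] = {}
        for contig, term in zip(go_assoc.iloc[:, 0], go_assoc.iloc[:, 1]):
            if contig not in pos:
                raise KeyError(f"contig {contig} in GO map but not in counts table")
            go_map.setdefault(term, []).append(pos[contig])
        return cls(
            contigs=contigs,
            go_map={t: np.unique(np.asarray(ix)) for t, ix in sorted(go_map.items())},
            counts=counts,
        )

    @classmethod
    def from_files(cls, go_path: str | Path, counts_path: str | Path) -> "GOExpressionTable":
        go_assoc = pd.read_csv(go_path, sep="\t", header=None, names=["contig", "go_term"])
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        return cls.from_frames(go_assoc, counts)


@dataclass
class PermutationResult:
    go_term: str
    organ: str
    n_contigs_used: int  # contigs with nonzero counts behind the observed mean
    observed_mean: float
    perm_diffs: dict[str, float] = field(default_factory=dict)
    pctl_rank: float = float("nan")
    significant: bool = False
    seed: int = 0
    n_perm: int = 0


def observed_mean(table: GOExpressionTable, go_term: str, organ: str) -> float:
    """Zero-excluded mean read count of a term's contigs in one organ."""
    if go_term not in table.go_map:
        raise KeyError(f"unknown GO term {go_term}")
    v = table.counts[organ].to_numpy()[table.go_map[go_term]]
    nz = v[v > 0]
    return float(nz.mean()) if len(nz) else float("nan")


def _zero_excluded_means(values: np.ndarray, idx_pad: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-term zero-excluded means of ``values`` gathered at padded indices.

    Terms whose gathered sample is all zero get mean 0.0 (no expressed
    contig at all).
    """
    gathered = values[idx_pad]
    gathered = np.where(valid, gathered, 0)
    nz = (gathered > 0).sum(axis=1)
    sums = gathered.sum(axis=1)
    return np.where(nz > 0, sums / np.maximum(nz, 1), 0.0)


def permute_test(
    table: GOExpressionTable,
    organ: str,
    n_perm: int = 1000,
    seed: int = 0,
    pool: str = "all",
    bh_correct: bool = False,
) -> list[PermutationResult]:
    """Run the permutation screen for every GO term in one organ.

    ``pool`` chooses the permutation pool: ``"all"`` shuffles the count
    vector over every contig (the default, literal procedure);
    ``"nonzero"`` restricts the pool to contigs expressed in the organ.
    With ``bh_correct`` the per-term empirical p-values
    (1 - pctl_rank) are Benjamini–Hochberg adjusted and significance
    requires adjusted p < 0.05 as well.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if organ not in table.counts.columns:
        raise KeyError(f"organ {organ!r} not in counts table")
    if pool not in ("all", "nonzero"):
        raise ValueError("pool must be 'all' or 'nonzero'")
    rng = np.random.default_rng(seed)
    counts = table.counts[organ].to_numpy()
    terms = list(table.go_map)

    max_size = max(len(ix) for ix in table.go_map.values())
    idx_pad = np.zeros((len(terms), max_size), dtype=np.int64)
    valid = np.zeros((len(terms), max_size), dtype=bool)
    for row, term in enumerate(terms):
        ix = table.go_map[term]
        idx_pad[row, : len(ix)] = ix
        valid[row, : len(ix)] = True

    observed = _zero_excluded_means(counts, idx_pad, valid)
    obs_nz = np.array([(counts[table.go_map[t]] > 0).sum() for t in terms])

    if pool == "nonzero":
        pool_idx = np.nonzero(counts > 0)[0]
    else:
        pool_idx = np.arange(len(counts))

    n_exceed = np.zeros(len(terms), dtype=np.int64)
    diff_sum = np.zeros(len(terms))
    diff_sqsum = np.zeros(len(terms))
    base = counts.copy()
    for _ in range(n_perm):
        perm = base.copy()
        perm[pool_idx] = rng.permutation(perm[pool_idx])
        pm = _zero_excluded_means(perm, idx_pad, valid)
        d = observed - pm
        n_exceed += observed > pm
        diff_sum += d
        diff_sqsum += d * d

    pctl = n_exceed / n_perm
    significant = pctl > 0.95
    if bh_correct:
        pvals = 1.0 - pctl
        order = np.argsort(pvals, kind="mergesort")
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, pvals[i] * m / (rank + 1))
            adj[i] = running
        significant = significant & (adj < 0.05)

    results = []
    mean_diff = diff_sum / n_perm
    var_diff = np.maximum(diff_sqsum / n_perm - mean_diff**2, 0.0)
    for row, term in enumerate(terms):
        obs = observed[row] if obs_nz[row] else float("nan")
        results.append(
            PermutationResult(
                go_term=term,
                organ=organ,
                n_contigs_used=int(obs_nz[row]),
                observed_mean=float(obs),
                perm_diffs={
                    "mean": float(mean_diff[row]),
                    "sd": float(np.sqrt(var_diff[row])),
                },
                pctl_rank=float(pctl[row]),
                significant=bool(significant[row]) if obs_nz[row] else False,
                seed=seed,
                n_perm=n_perm,
            )
        )
    return results


def results_to_frame(results: list[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "go_term": [r.go_term for r in results],
            "organ": [r.organ for r in results],
            "n_contigs_used": [r.n_contigs_used for r in results],
            "observed_mean": [r.observed_mean for r in results],
            "perm_diff_mean": [r.perm_diffs.get("mean") for r in results],
            "perm_diff_sd": [r.perm_diffs.get("sd") for r in results],
            "pctl_rank": [r.pctl_rank for r in results],
            "significant": [int(r.significant) for r in results],
        }
    )
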