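"""Synthetic assemblies and GO/count tables with known ground truth.

The assembly simulator emulates pooled-diploid 454 cDNA sequencing: two
genotypes (four gametes, so every true pool variant has expected
frequency k/4 for some k >= 1), reads of a few hundred bases at low
per-contig coverage with a long right tail, phred-like qualities
decaying toward the 3' read end, random substitution errors, and —
the hallmark 454 artifact — homopolymer over- and under-calls that
surface as pad columns in the padded alignment.  Reads are emitted
pre-aligned: the simulator plays the role of the assembler, so the
padded alignment is exact and every planted event is recoverable from
the :class:`TruthSet`.

Defaults mirror the study conditions the package targets: mean contig
length ~460 bp, 6–7 reads per contig on average, root-heavy organ
proportions with a small untagged fraction, mean base quality ~30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly_io import (
    AlignedRead,
    ContigAlignment,
    impute_pad_quals,
    write_ace,
    write_mids,
    write_qual,
)
from .go_expression import GOExpressionTable

BASES = "ACGT"


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 20
    contig_len_mean: float = 460.0
    contig_len_sd: float = 60.0
    contig_len_min: int = 150
    n_genotypes: int = 2  # diploid genotypes pooled -> 2N = 4 gametes
    variant_rate: float = 0.004  # per reference base
    variant_gamete_counts: tuple[int, ...] | None = None  # default: 1..2N-1 uniform
    subst_error_rate: float = 0.005
    homopolymer_indel_rate: float = 0.05  # per read per run, scaled by run length
    min_homopolymer_len: int = 2
    read_len_mean: float = 220.0
    read_len_sd: float = 50.0
    read_len_min: int = 60
    reads_per_contig_mean: float = 6.5
    reads_per_contig_shape: float = 1.3  # negative-binomial dispersion (long tail)
    min_reads_per_contig: int = 3
    organ_props: tuple[float, float, float, float] = (0.30, 0.20, 0.48, 0.02)
    qual_mean: float = 30.0
    qual_sd: float = 5.0
    qual_end_decay: float = 8.0  # mean quality drop at the 3' read end
    qual_max: int = 40

    def __post_init__(self) -> None:
        for rate in (self.variant_rate, self.subst_error_rate, self.homopolymer_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.contig_len_min <= 0 or self.read_len_min <= 0:
            raise ValueError("lengths must be positive")
        if self.read_len_min > self.contig_len_min:
            raise ValueError("minimum read length exceeds minimum contig length")
        if self.n_genotypes < 1:
            raise ValueError("need at least one genotype")

    @property
    def n_gametes(self) -> int:
        return 2 * self.n_genotypes


@dataclass
class PlantedVariant:
    contig_id: str
    ref_pos: int  # 0-based position in the reference
    ref_col: int  # 0-based column in the emitted padded alignment
    ref_base: str
    alt: str
    gamete_count: int
    freq: float


@dataclass
class TruthSet:
    """Everything the simulator planted, for recovery tests."""

    variants: list[PlantedVariant] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)
    insertion_cols: dict[str, list[int]] = field(default_factory=dict)
    references: dict[str, str] = field(default_factory=dict)
    ref_col_map: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": [asdict(v) for v in self.variants],
            "errors": self.errors,
            "insertion_cols": self.insertion_cols,
            "references": self.references,
            "ref_col_map": self.ref_col_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedAssembly:
    contigs: list[ContigAlignment]
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write ACE + QUAL + MID sidecar + read assignments + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ace": outdir / "assembly.ace",
            "qual": outdir / "reads.qual",
            "mids": outdir / "mids.tsv",
            "assignments": outdir / "assignments.tsv",
            "truth": outdir / "truth.json",
        }
        write_ace(self.contigs, paths["ace"])
        write_qual(self.contigs, paths["qual"])
        write_mids(self.contigs, paths["mids"])
        rows = [
            {"read_id": r.read_id, "contig_id": c.contig_id, "organ": r.organ}
            for c in self.contigs
            for r in c.reads
        ]
        pd.DataFrame(rows).to_csv(paths["assignments"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _draw_read_len(rng: np.random.Generator, cfg: SimConfig, contig_len: int) -> int:
    rl = int(round(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
    return int(np.clip(rl, cfg.read_len_min, contig_len))


def _draw_n_reads(rng: np.random.Generator, cfg: SimConfig) -> int:
    shape = cfg.reads_per_contig_shape
    p = shape / (shape + cfg.reads_per_contig_mean)
    return max(cfg.min_reads_per_contig, int(rng.negative_binomial(shape, p)))


def _read_intervals(rng: np.random.Generator, cfg: SimConfig, L: int) -> list[tuple[int, int]]:
    """Place reads so every reference position is covered at least once."""
    intervals: list[tuple[int, int]] = []
    cover_end = 0
    while cover_end < L:
        if cover_end == 0:
            start = 0
        else:
            start = max(0, cover_end - int(rng.integers(10, 40)))
        rl = _draw_read_len(rng, cfg, L)
        end = min(L, start + rl)
        if end <= cover_end:  # too short to advance: stretch to bridge
            end = min(L, cover_end + cfg.read_len_min)
        intervals.append((start, end))
        cover_end = end
    n_extra = _draw_n_reads(rng, cfg) - len(intervals)
    for _ in range(max(0, n_extra)):
        rl = _draw_read_len(rng, cfg, L)
        start = int(rng.integers(0, max(1, L - rl + 1)))
        intervals.append((start, start + rl))
    return intervals


def _homopolymer_runs(ref: str, min_len: int) -> list[tuple[int, int]]:
    """(start, end) of maximal same-base runs of length >= min_len."""
    runs = []
    i = 0
    while i < len(ref):
        j = i
        while j < len(ref) and ref[j] == ref[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _simulate_contig(
    rng: np.random.Generator, cfg: SimConfig, contig_id: str, truth: TruthSet
) -> ContigAlignment:
    L = max(cfg.contig_len_min, int(round(rng.normal(cfg.contig_len_mean, cfg.contig_len_sd))))
    ref = "".join(rng.choice(list(BASES), size=L))
    twoN = cfg.n_gametes

    # plant pool variants; keep them non-adjacent so true variants never
    # trip the adjacency artefact filter among themselves
    var_pos: list[int] = []
    for p in np.nonzero(rng.random(L) < cfg.variant_rate)[0]:
        if not var_pos or p - var_pos[-1] > 1:
            var_pos.append(int(p))
    haplotypes = [list(ref) for _ in range(twoN)]
    planted = []
    for p in var_pos:
        alt = rng.choice([b for b in BASES if b != ref[p]])
        allowed = cfg.variant_gamete_counts or tuple(range(1, twoN))
        k = int(rng.choice(allowed))
        for g in rng.choice(twoN, size=k, replace=False):
            haplotypes[g][p] = alt
        planted.append((p, ref[p], str(alt), k))

    intervals = _read_intervals(rng, cfg, L)
    runs = _homopolymer_runs(ref, cfg.min_homopolymer_len)
    var_set = set(var_pos)

    # Coverage gates for homopolymer events.  A pad column only exists in
    # an assembler's padded alignment when other reads contradict the
    # over/under-call, so events are planted only where coverage allows
    # the artifact to surface as a (removable) mostly-pad column:
    # insertions need >= 3 reads spanning the insertion point, deletions
    # must leave the retaining reads in strict majority.
    cov = np.zeros(L, dtype=np.int32)
    cov_interior = np.zeros(L + 1, dtype=np.int32)
    for s, e in intervals:
        cov[s:e] += 1
        if e - s > 2:
            cov_interior[s + 1 : e] += 1  # reads with s < p <= e-1
    dels_at: dict[int, int] = {}

    # per-read event collection
    ins_events: list[tuple[int, int]] = []  # (ref_pos_before_which, read_idx)
    read_plans = []
    organs = ("leaf", "stem", "root", "untagged")
    for ridx, (s, e) in enumerate(intervals):
        g = int(rng.integers(twoN))
        seq = haplotypes[g][s:e]
        # substitution errors
        for k in np.nonzero(rng.random(e - s) < cfg.subst_error_rate)[0]:
            k = int(k)
            old = seq[k]
            seq[k] = str(rng.choice([b for b in BASES if b != old]))
            truth.errors.append(
                {"contig_id": contig_id, "read": ridx, "kind": "subst", "ref_pos": s + k}
            )
        # homopolymer over/under-calls, strictly interior to the read
        deletions: set[int] = set()
        insertions: list[int] = []
        for rs, re_ in runs:
            if rs <= s or re_ >= e:
                continue
            p_event = min(0.8, cfg.homopolymer_indel_rate * (re_ - rs - cfg.min_homopolymer_len + 1))
            if rng.random() >= p_event:
                continue
            d = re_ - 1
            want_del = rng.random() < 0.5
            can_del = d not in var_set and 2 * (dels_at.get(d, 0) + 1) < cov[d]
            can_ins = cov_interior[re_] >= 3
            if want_del and can_del:
                deletions.add(d)
                dels_at[d] = dels_at.get(d, 0) + 1
                truth.errors.append(
                    {"contig_id": contig_id, "read": ridx, "kind": "hp_del", "ref_pos": d}
                )
            elif can_ins:
                insertions.append(re_)
                ins_events.append((re_, ridx))
                truth.errors.append(
                    {"contig_id": contig_id, "read": ridx, "kind": "hp_ins", "ref_pos": re_}
                )
        organ = organs[int(rng.choice(4, p=cfg.organ_props))]
        strand = "+" if rng.random() < 0.5 else "-"
        read_plans.append(
            {
                "interval": (s, e),
                "seq": seq,
                "deletions": deletions,
                "insertions": insertions,
                "organ": organ,
                "strand": strand,
            }
        )

    # global column layout: reference columns plus one artifact column per
    # insertion event, placed just before the reference position it precedes
    keys: list[tuple[int, int, int]] = [(p, 0, 0) for p in range(L)]
    for serial, (p, ridx) in enumerate(sorted(ins_events)):
        keys.append((p, -1, serial + 1))
    keys.sort(key=lambda k: (k[0], k[1], k[2]))
    col_of = {k: i for i, k in enumerate(keys)}
    n_cols = len(keys)
    ins_col_of = {}
    for serial, (p, ridx) in enumerate(sorted(ins_events)):
        ins_col_of[(p, ridx)] = col_of[(p, -1, serial + 1)]

    truth.references[contig_id] = ref
    truth.ref_col_map[contig_id] = [col_of[(p, 0, 0)] for p in range(L)]
    truth.insertion_cols[contig_id] = sorted(ins_col_of.values())
    for p, ref_base, alt, k in planted:
        truth.variants.append(
            PlantedVariant(
                contig_id=contig_id,
                ref_pos=p,
                ref_col=col_of[(p, 0, 0)],
                ref_base=ref_base,
                alt=alt,
                gamete_count=k,
                freq=k / twoN,
            )
        )

    reads = []
    for ridx, plan in enumerate(read_plans):
        s, e = plan["interval"]
        span_keys = [k for k in keys if (s, 0, 0) <= k <= (e - 1, 0, 0)]
        padded = []
        for key in span_keys:
            p, tag, serial = key
            if tag == 0:
                padded.append("*" if p in plan["deletions"] else plan["seq"][p - s])
            else:
                owner = ins_col_of.get((p, ridx))
                padded.append(ref[p - 1] if owner == col_of[key] else "*")
        padded_seq = "".join(padded)
        n_real = sum(1 for b in padded_seq if b != "*")
        # quality decays toward the 3' end of the original read
        frac = np.arange(n_real) / max(1, n_real - 1)
        quals = rng.normal(cfg.qual_mean - cfg.qual_end_decay * frac, cfg.qual_sd)
        quals = np.clip(np.round(quals), 1, cfg.qual_max).astype(np.int16)
        if plan["strand"] == "-":
            quals_contig = quals[::-1]
        else:
            quals_contig = quals
        reads.append(
            AlignedRead(
                read_id=f"{contig_id}_r{ridx:03d}",
                organ=plan["organ"],
                strand=plan["strand"],
                start_col=col_of[(s, 0, 0)],
                padded_seq=padded_seq,
                padded_qual=impute_pad_quals(padded_seq, quals_contig),
            )
        )
    return ContigAlignment(contig_id=contig_id, n_cols=n_cols, reads=reads)


def simulate_assembly(cfg: SimConfig) -> SimulatedAssembly:
    """Simulate a padded assembly with planted variants and 454 artifacts."""
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet()
    contigs = [
        _simulate_contig(rng, cfg, f"contig{i + 1:04d}", truth) for i in range(cfg.n_contigs)
    ]
    return SimulatedAssembly(contigs=contigs, truth=truth)


# ---------------------------------------------------------------------------
# GO-term / read-count tables
# ---------------------------------------------------------------------------


@dataclass
class GOSimConfig:
    seed: int = 0
    n_contigs: int = 1000
    n_terms: int = 200
    term_size_min: int = 5
    term_size_max: int = 50
    lam_shape: float = 1.5  # gamma shape of per-contig expression rate
    lam_scale: float = 1.5  # gamma scale (mean reads/contig/organ = shape*scale)
    organs: tuple[str, ...] = ("leaf", "stem", "root")
    n_planted: int = 0
    planted_effect: float = 5.0
    planted_organ: str = "root"
    planted_size: int = 50


@dataclass
class GOTruth:
    planted: list[dict] = field(default_factory=list)


def simulate_go_table(cfg: GOSimConfig) -> tuple[GOExpressionTable, GOTruth]:
    """Poisson read-count table with optional planted over-expressed terms.

    Under the null every contig's counts are exchangeable within an
    organ (rates i.i.d. Gamma, counts Poisson); a planted term's member
    contigs have their rate multiplied by ``planted_effect`` in
    ``planted_organ`` only.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs = [f"c{i + 1:05d}" for i in range(cfg.n_contigs)]
    lam = rng.gamma(cfg.lam_shape, cfg.lam_scale, size=cfg.n_contigs)

    go_map: dict[str, np.ndarray] = {}
    truth = GOTruth()
    planted_members = np.zeros(cfg.n_contigs, dtype=bool)
    for t in range(cfg.n_planted):
        term = f"GO:P{t + 1:06d}"
        members = rng.choice(cfg.n_contigs, size=cfg.planted_size, replace=False)
        go_map[term] = np.sort(members)
        planted_members[members] = True
        truth.planted.append(
            {"term": term, "organ": cfg.planted_organ, "effect": cfg.planted_effect}
        )
    for t in range(cfg.n_terms - cfg.n_planted):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        go_map[term] = np.sort(rng.choice(cfg.n_contigs, size=size, replace=False))

    counts = {}
    for organ in cfg.organs:
        rate = lam.copy()
        if cfg.n_planted and organ == cfg.planted_organ:
            rate = np.where(planted_members, rate * cfg.planted_effect, rate)
        counts[organ] = rng.poisson(rate)
    table = GOExpressionTable(
        contigs=contigs,
        go_map=dict(sorted(go_map.items())),
        counts=pd.DataFrame(counts, index=contigs),
    )
    return table, truth


def write_go_table(table: GOExpressionTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"go": outdir / "go.tsv", "counts": outdir / "counts.tsv"}
    with open(paths["go"], "w") as fh:
        for term, idx in table.go_map.items():
            for i in idx:
                fh.write(f"{table.contigs[i]}\t{term}\n")
    table.counts.rename_axis("contig").to_csv(paths["counts"], sep="\t")
    return paths
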