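"""End-to-end orchestration: load -> mask/clean -> call -> filter -> summarize.

``run_all`` executes the per-contig pipeline and, when the optional
inputs are configured, the GO permutation screen and RaBoT comparisons,
writing TSV reports plus a machine-readable JSON run report.  Every
threshold used is logged in the report, and reruns with the same inputs
and seeds regenerate the report bit-identically.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly_io, go_expression, mask_clean, mismatch, rabot

log = logging.getLogger("contigvar")


@dataclass
class RunConfig:
    ace: str
    qual: str
    mids: str | None = None
    outdir: str = "contigvar_out"
    freq_min: float = 0.1
    qual_min: int = 20
    n_gametes: int = 4
    alpha: float = 0.05
    depth_min: int = 8
    # optional GO permutation screen
    go_map: str | None = None
    counts: str | None = None
    organs: tuple[str, ...] = ("leaf", "stem", "root")
    n_perm: int = 1000
    # optional RaBoT comparisons: list of [small_organ, large_organ]
    assignments: str | None = None
    rabot_pairs: tuple[tuple[str, str], ...] = ()
    n_boot: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rabot_pairs" in raw:
            raw["rabot_pairs"] = tuple(tuple(p) for p in raw["rabot_pairs"])
        if "organs" in raw:
            raw["organs"] = tuple(raw["organs"])
        return cls(**raw)


def explain_thresholds(cfg: RunConfig) -> dict[str, str]:
    """Human-readable rationale for every default threshold."""
    return {
        "freq_min": f"{cfg.freq_min}: variants below this within-column frequency are masked",
        "qual_min": f"{cfg.qual_min}: base-quality floor at polymorphic columns",
        "n_gametes": f"{cfg.n_gametes}: haploid genomes pooled; minimum variant frequency 1/{cfg.n_gametes}",
        "alpha": f"{cfg.alpha}: cumulative binomial threshold below which a minor count is a likely false positive",
        "depth_min": f"{cfg.depth_min}: minimum column depth for a trustworthy call and for the density denominator",
        "n_perm": f"{cfg.n_perm}: permutations for the GO over-expression screen",
        "n_boot": f"{cfg.n_boot}: RaBoT subsamples",
    }


def run_all(cfg: RunConfig) -> dict:
    """Run the configured pipeline; returns the JSON-serialisable report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "thresholds": explain_thresholds(cfg)}

    stage = "load"
    try:
        contigs = assembly_io.load_assembly(cfg.ace, cfg.qual, cfg.mids)
        report["n_contigs"] = len(contigs)
        report["n_reads"] = sum(len(c.reads) for c in contigs)
        log.info("loaded %d contigs, %d reads", report["n_contigs"], report["n_reads"])

        stage = "mask_clean"
        cleaned = [
            mask_clean.mask_and_clean(c, freq_min=cfg.freq_min, qual_min=cfg.qual_min)
            for c in contigs
        ]
        with open(outdir / "consensus.fasta", "w") as fh:
            for m in cleaned:
                fh.write(f">{m.contig.contig_id}\n{m.consensus}\n")

        stage = "call"
        records = [r for m in cleaned for r in mismatch.call_mismatches(m)]

        stage = "post_filter"
        records = mismatch.post_filter(
            records, n_gametes=cfg.n_gametes, alpha=cfg.alpha, depth_min=cfg.depth_min
        )
        assembly_io.write_tsv(
            pd.DataFrame(mismatch.records_to_rows(records)),
            outdir / "mismatches.tsv",
        )

        stage = "summarize"
        before = mismatch.summarize(records, cleaned, depth_min=cfg.depth_min, passed_only=False)
        after = mismatch.summarize(records, cleaned, depth_min=cfg.depth_min, passed_only=True)
        assembly_io.write_tsv(
            pd.DataFrame(mismatch.summary_to_rows(before, after)), outdir / "summary.tsv"
        )
        report["summary"] = {
            "before_binomial": _clean_nan(asdict(before)),
            "after_binomial": _clean_nan(asdict(after)),
        }

        if cfg.go_map and cfg.counts:
            stage = "go_permutation"
            table = go_expression.GOExpressionTable.from_files(cfg.go_map, cfg.counts)
            report["go"] = {}
            for organ in cfg.organs:
                results = go_expression.permute_test(
                    table, organ, n_perm=cfg.n_perm, seed=cfg.seed
                )
                assembly_io.write_tsv(
                    go_expression.results_to_frame(results),
                    outdir / f"goperm_{organ}.tsv",
                )
                report["go"][organ] = {
                    "n_terms": len(results),
                    "n_significant": sum(r.significant for r in results),
                }

        if cfg.assignments and cfg.rabot_pairs:
            stage = "rabot"
            assignments = rabot.read_assignments(cfg.assignments)
            report["rabot"] = {}
            for small, large in cfg.rabot_pairs:
                out = rabot.rabot_compare(
                    assignments, small, large, n_boot=cfg.n_boot, seed=cfg.seed
                )
                report["rabot"][f"{small}_vs_{large}"] = {
                    "empirical": out.empirical,
                    "p_value": out.p_value,
                    "boot_mean": sum(out.boots) / len(out.boots),
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _clean_nan(d: dict) -> dict:
    return {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in d.items()}
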