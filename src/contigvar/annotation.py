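"""Green-plant contaminant screen and best-hit annotation assignment.

Works on a precomputed BLASTX hit table (outfmt-6-like TSV with added
subject species / genus columns) plus a genus -> is-green-plant lookup.
A contig is kept as *clean* when at least one of its ``k`` lowest
e-value hits below ``e_max`` comes from a green-plant genus; when
informative hits exist but none of the top-``k`` is green-plant the
contig is a *contaminant*; contigs with no hit below ``e_max`` are
*no_informative_hit* (retained but unannotated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

HIT_COLUMNS = ["contig_id", "hit_rank", "subject_species", "subject_genus", "evalue", "description"]

UNINFORMATIVE_DEFAULT = ("unknown", "hypothetical", "predicted protein", "unnamed")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_taxonomy(path: str | Path) -> dict[str, bool]:
    """Read the ``genus<TAB>0|1`` green-plant lookup."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genus", "is_green_plant"])
    return {g: bool(v) for g, v in zip(df.genus, df.is_green_plant)}


def _check_taxonomy(hits: pd.DataFrame, tax: dict[str, bool]) -> None:
    unknown = sorted(set(hits.subject_genus) - set(tax))
    if unknown:
        raise KeyError(f"genera missing from taxonomy table: {unknown}")


def screen_contaminants(
    hits: pd.DataFrame,
    tax: dict[str, bool],
    e_max: float = 1e-25,
    k: int = 10,
) -> dict[str, str]:
    """Partition contigs into clean / contaminant / no_informative_hit."""
    _check_taxonomy(hits, tax)
    out: dict[str, str] = {}
    for contig, grp in hits.groupby("contig_id", sort=True):
        grp = grp.sort_values(["evalue", "hit_rank"], kind="mergesort")
        informative = grp[grp.evalue < e_max]
        if informative.empty:
            out[contig] = "no_informative_hit"
            continue
        topk = informative.head(k)
        if any(tax[g] for g in topk.subject_genus):
            out[contig] = "clean"
        else:
            out[contig] = "contaminant"
    return out


def assign_annotation(
    hits: pd.DataFrame,
    tax: dict[str, bool],
    e_max: float = 1e-25,
    uninformative: tuple[str, ...] = UNINFORMATIVE_DEFAULT,
) -> dict[str, str]:
    """Best informative green-plant description per clean contig.

    The lowest-e-value green-plant hit below ``e_max`` whose description
    does not match the uninformative-pattern blacklist wins; contigs
    without a qualifying hit are simply absent from the result.
    """
    _check_taxonomy(hits, tax)
    status = screen_contaminants(hits, tax, e_max=e_max)
    patterns = tuple(p.lower() for p in uninformative)
    out: dict[str, str] = {}
    for contig, grp in hits.groupby("contig_id", sort=True):
        if status.get(contig) != "clean":
            continue
        grp = grp.sort_values(["evalue", "hit_rank"], kind="mergesort")
        for _, row in grp.iterrows():
            if row.evalue >= e_max or not tax[row.subject_genus]:
                continue
            desc = str(row.description)
            if any(p in desc.lower() for p in patterns):
                continue
            out[contig] = desc
            break
    return out


def partition_to_frame(partition: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(partition.items()), columns=["contig_id", "status"]
    )
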