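"""RaBoT: rarefaction bootstrap comparison of contig counts between libraries.

Libraries sequenced to different depths show different numbers of
contigs simply because a smaller read sample reaches fewer transcripts.
RaBoT removes that ascertainment bias: the contig count of the smaller
library (the *empirical* value) is compared with the distribution of
contig counts obtained from ``n_boot`` equally sized subsamples drawn
without replacement from the larger library.  The reported P-value is
the fraction of bootstrapped values strictly above the empirical value;
ties count as not above.

Contig counts are computed through the fixed assembly's read -> contig
map rather than by reassembling each subsample; this equals the RaBoT
statistic whenever assembly membership is stable under subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RabotOutcome:
    empirical: int
    boots: list[int]
    p_value: float
    n_boot: int
    seed: int


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read the ``read_id, contig_id, organ`` table (assembled reads only)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"read_id", "contig_id", "organ"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    return df


def rabot_compare(
    assignments: pd.DataFrame,
    organ_small: str,
    organ_large: str,
    n_boot: int = 100,
    seed: int = 0,
) -> RabotOutcome:
    """Compare contig counts of a smaller vs a larger organ library."""
    small = assignments[assignments.organ == organ_small]
    large = assignments[assignments.organ == organ_large]
    if len(small) == 0 or len(large) == 0:
        raise ValueError("both organs need at least one assigned read")
    if len(small) > len(large):
        raise ValueError(
            f"{organ_small} has more reads ({len(small)}) than {organ_large} "
            f"({len(large)}); swap the arguments"
        )
    empirical = small.contig_id.nunique()
    large_contigs = large.contig_id.to_numpy()
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sub = rng.choice(large_contigs, size=len(small), replace=False)
        boots.append(int(len(np.unique(sub))))
    p_value = sum(b > empirical for b in boots) / n_boot
    return RabotOutcome(
        empirical=int(empirical), boots=boots, p_value=p_value, n_boot=n_boot, seed=seed
    )
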