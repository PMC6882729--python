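"""Gene retention (fractionation) profiles and tandem-array statistics.

Retention is profiled against a diploid reference gene order: each subgenome
contributes a binary presence vector over the ancestral gene ordinals, and
sliding windows (default 100 genes, step 1) give the smooth retention curves
used to compare subgenomes. Tandem duplicates are same-family genes within a
maximum ordinal distance (default 10 genes) of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def retention_windows(presence, window: int = 100, step: int = 1) -> np.ndarray:
    """Fraction of retained genes in sliding windows along a presence vector.

    Returns floor((N − window)/step) + 1 window fractions.
    """
    presence = np.asarray(presence, dtype=float)
    if presence.ndim != 1:
        raise ValueError("presence must be a 1-D vector")
    if not np.isin(presence, (0.0, 1.0)).all():
        raise ValueError("presence values must be 0 or 1")
    if window > len(presence):
        raise ValueError(f"window {window} exceeds vector length {len(presence)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    sw = np.lib.stride_tricks.sliding_window_view(presence, window)[::step]
    return sw.mean(axis=1)


def subgenome_content_summary(counts: dict[str, int]) -> pd.DataFrame:
    """Pairwise percent-more gene content between subgenomes.

    percent_more(d, s) = 100·(count_d − count_s)/count_s — e.g. 1200 vs 1000
    is 20% more.
    """
    if len(counts) < 2:
        raise ValueError("need at least two subgenomes")
    if any(c == 0 for c in counts.values()):
        raise ValueError("zero gene count for a subgenome")
    species = sorted(counts)
    rows = []
    for d in species:
        for s in species:
            if d == s:
                continue
            rows.append((d, s, counts[d], counts[s], 100.0 * (counts[d] - counts[s]) / counts[s]))
    return pd.DataFrame(rows, columns=["subgenome", "versus", "count", "count_versus", "percent_more"])


@dataclass(frozen=True)
class TandemArray:
    chromosome: str
    family_id: str
    ordinals: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.ordinals)


def tandem_arrays(genes: pd.DataFrame, max_gap: int = 10) -> list[TandemArray]:
    """Detect tandem arrays: same-family genes at most ``max_gap`` ordinals apart.

    ``genes`` needs columns chromosome, ordinal, family_id and must be sorted
    by ordinal within each chromosome. Maximal runs where successive family
    members are ≤ max_gap apart form an array; singletons are not arrays.
    """
    required = {"chromosome", "ordinal", "family_id"}
    if not required.issubset(genes.columns):
        raise ValueError(f"genes must have columns {sorted(required)}")
    arrays: list[TandemArray] = []
    for chrom, grp in genes.groupby("chromosome", sort=True):
        if not grp["ordinal"].is_monotonic_increasing:
            raise ValueError(f"genes on {chrom} are not sorted by ordinal")
        for fam, members in grp.groupby("family_id", sort=True):
            ords = members["ordinal"].to_numpy()
            if len(ords) < 2:
                continue
            breaks = np.where(np.diff(ords) > max_gap)[0] + 1
            for run in np.split(ords, breaks):
                if len(run) >= 2:
                    arrays.append(TandemArray(chrom, fam, tuple(int(o) for o in run)))
    return arrays


def tandem_summary(arrays: list[TandemArray]) -> pd.DataFrame:
    """Per-chromosome array counts and mean sizes."""
    if not arrays:
        return pd.DataFrame(columns=["chromosome", "n_arrays", "mean_size"])
    df = pd.DataFrame(
        [(a.chromosome, a.size) for a in arrays], columns=["chromosome", "size"]
    )
    out = df.groupby("chromosome").agg(n_arrays=("size", "size"), mean_size=("size", "mean"))
    return out.reset_index()
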