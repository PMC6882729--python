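"""Transposable-element density near genes and subgenome comparisons.

Density is the fraction of base pairs covered by TEs in a window spanning
the gene body plus a flank on each side (default ±2 kb, a promoter-scale
neighborhood). TE intervals are merged before measuring so fragmented
annotations never double-count. Comparative statistics: Spearman rank
correlation of density with expression, pairwise two-sample
Kolmogorov–Smirnov between subgenome density distributions, and a χ² test
(df = number of subgenomes − 1) for category counts against expected
weights.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def te_density(genes: pd.DataFrame, tes: pd.DataFrame, flank_bp: int = 2000) -> pd.DataFrame:
    """Per-gene TE density in [gene.start − flank, gene.end + flank).

    ``genes`` needs columns gene_id, seqid, start, end (0-based half-open);
    ``tes`` needs seqid, start, end. Genes on sequences absent from the TE
    table get density 0 with a warning.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seqid, grp in tes.groupby("seqid"):
        merged[seqid] = _merge_intervals(
            grp["start"].to_numpy(dtype=np.int64), grp["end"].to_numpy(dtype=np.int64)
        )
    missing = sorted(set(genes["seqid"]) - set(merged))
    if missing:
        warnings.warn(f"no TE intervals on sequences: {missing}; density 0 there", stacklevel=2)
    rows = []
    for r in genes.itertuples():
        ws = max(int(r.start) - flank_bp, 0)
        we = int(r.end) + flank_bp
        length = we - ws
        cov = 0
        if r.seqid in merged:
            ms, me = merged[r.seqid]
            lo = np.searchsorted(me, ws, side="right")
            hi = np.searchsorted(ms, we, side="left")
            if hi > lo:
                cov = int(np.sum(np.minimum(me[lo:hi], we) - np.maximum(ms[lo:hi], ws)))
        rows.append((r.gene_id, cov / length if length else 0.0))
    out = genes[["gene_id"]].copy()
    out["density"] = [d for _, d in rows]
    out["flank_bp"] = flank_bp
    return out


def spearman_expr_te(densities, expression) -> tuple[float, float]:
    """Spearman rank correlation between TE density and expression.

    Raises on constant input, where the coefficient is undefined.
    """
    d = np.asarray(densities, dtype=float)
    e = np.asarray(expression, dtype=float)
    if d.shape != e.shape or d.ndim != 1 or len(d) < 4:
        raise ValueError("need paired 1-D vectors of length >= 4")
    if np.ptp(d) == 0 or np.ptp(e) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(d, e)
    return float(rho), float(p)


def ks_subgenomes(samples: dict[str, np.ndarray], alpha: float = 0.01) -> tuple[pd.DataFrame, str, bool]:
    """Pairwise two-sample KS tests between subgenome density samples.

    Returns (pairwise table, lowest-mean subgenome, supported) where
    ``supported`` is True when the lowest-mean subgenome differs from every
    other subgenome at level ``alpha``.
    """
    if len(samples) < 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("need >= 2 samples with >= 2 values each")
    names = sorted(samples)
    rows = []
    for a, b in itertools.combinations(names, 2):
        d, p = stats.ks_2samp(samples[a], samples[b])
        rows.append((a, b, float(d), float(p)))
    table = pd.DataFrame(rows, columns=["subgenome_1", "subgenome_2", "ks_d", "p_value"])
    lowest = min(names, key=lambda n: float(np.mean(samples[n])))
    involving = table[(table["subgenome_1"] == lowest) | (table["subgenome_2"] == lowest)]
    supported = bool((involving["p_value"] <= alpha).all())
    return table, lowest, supported


def chisq_subgenome_bias(observed, weights=None) -> tuple[float, int, float]:
    """χ² goodness-of-fit of category counts against expected weights.

    ``weights`` default to uniform; pass subgenome gene-content proportions
    to test for bias beyond gene-number differences. Returns
    (statistic, df = k − 1, p).
    """
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise ValueError("observed counts must be nonnegative")
    k = len(obs)
    if weights is None:
        weights = np.full(k, 1.0 / k)
    w = np.asarray(weights, dtype=float)
    if len(w) != k:
        raise ValueError("weights length must match observed")
    if (w <= 0).any():
        raise ValueError("expected weights must be positive")
    w = w / w.sum()
    expected = w * obs.sum()
    if (expected < 5).any():
        warnings.warn("expected count < 5 in some category; χ² approximation is weak", stacklevel=2)
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), k - 1, float(p)
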