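"""Homoeolog expression bias (HEB): nested likelihood-ratio tests.

For a homoeolog pair (A, B) observed in T tissues, the per-tissue read count
of copy A is modelled as x_At ~ Binomial(n_t, p_t) with n_t = x_At + x_Bt.
Within a pair, sequencing depth cancels and gene length enters only through
the null proportion q = L_A / (L_A + L_B):

  H0: p_t = q for all t           — equal expression after length
                                    normalization (0 free parameters)
  H1: p_t = p for all t           — one homoeolog consistently scaled up or
                                    down; MLE p̂ = Σ x_At / Σ n_t (1 parameter)
  H2: p_t free per tissue         — inconsistent bias (T parameters)

The scaling factor ŝ = odds(p̂)/odds(q) measures how many-fold copy A is
expressed relative to the length-expected ratio. D01 = 2(ℓ1−ℓ0) is referred
to χ²(1) and D12 = 2(ℓ2−ℓ1) to χ²(T−1). The first-test p-values receive a
Benjamini–Hochberg correction; the second test is left uncorrected because
it asks whether a hypothesis can *not* be rejected. A pair is classified
consistently biased when the first test rejects (q-value ≤ α) and the second
does not (p > α); both tests default to the 1% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

LOW_COUNT_FLAG = 20  # pairs below this total are kept but flagged low-power


def fpkm(read_count: float, total_mapped_reads: float, gene_length_bp: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = (read count / 'per million' scaling factor) / gene length in kb.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    return (read_count / (total_mapped_reads / 1e6)) / (gene_length_bp / 1e3)


@dataclass(frozen=True)
class HEBModelFit:
    """Maximum-likelihood fits of the three nested models for one pair."""

    q: float
    p_common: float
    p_per_tissue: np.ndarray
    s_hat: float
    ll0: float
    ll1: float
    ll2: float


@dataclass(frozen=True)
class LRTResult:
    d01: float
    p01: float
    d12: float
    p12: float


def _kernel(x_a: np.ndarray, x_b: np.ndarray, p: np.ndarray | float) -> float:
    # binomial coefficients omitted: they cancel in every likelihood ratio
    return float(np.sum(xlogy(x_a, p) + xlogy(x_b, 1.0 - np.asarray(p, dtype=float))))


def fit_nested(
    x_a: np.ndarray,
    x_b: np.ndarray,
    length_a: float | None = None,
    length_b: float | None = None,
) -> HEBModelFit:
    """Fit H0/H1/H2 to one pair's per-tissue counts.

    When either length is missing the null proportion falls back to 0.5 with
    a warning (no length normalization possible).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1 or len(x_a) < 2:
        raise ValueError("x_a and x_b must be 1-D arrays of equal length >= 2")
    if (x_a < 0).any() or (x_b < 0).any():
        raise ValueError("counts must be nonnegative")
    if length_a is None or length_b is None:
        warnings.warn("missing homoeolog length(s); using q = 0.5", stacklevel=2)
        q = 0.5
    else:
        if length_a <= 0 or length_b <= 0:
            raise ValueError("lengths must be positive")
        q = length_a / (length_a + length_b)
    n = x_a + x_b
    total = n.sum()
    p_common = x_a.sum() / total if total > 0 else q
    with np.errstate(divide="ignore", invalid="ignore"):
        p_t = np.where(n > 0, x_a / np.where(n > 0, n, 1.0), q)
        s_hat = (p_common / (1.0 - p_common)) / (q / (1.0 - q)) if 0 < p_common < 1 else (
            np.inf if p_common >= 1 else 0.0
        )
    ll0 = _kernel(x_a, x_b, q)
    ll1 = _kernel(x_a, x_b, p_common)
    ll2 = _kernel(x_a, x_b, p_t)
    return HEBModelFit(q=q, p_common=p_common, p_per_tissue=p_t, s_hat=float(s_hat),
                       ll0=ll0, ll1=ll1, ll2=ll2)


def lrt(fit: HEBModelFit) -> LRTResult:
    """Likelihood-ratio statistics D01 ~ χ²(1) and D12 ~ χ²(T−1)."""
    t = len(fit.p_per_tissue)
    d01 = max(2.0 * (fit.ll1 - fit.ll0), 0.0)
    d12 = max(2.0 * (fit.ll2 - fit.ll1), 0.0)
    return LRTResult(
        d01=d01,
        p01=float(chi2.sf(d01, df=1)),
        d12=d12,
        p12=float(chi2.sf(d12, df=t - 1)),
    )


def bh_correct(pvalues, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q-values, rejection mask at ``alpha``)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return qvals, reject


PAIR_COLUMNS = [
    "pair_id", "gene_a", "gene_b", "subgenome_a", "subgenome_b",
    "length_a", "length_b", "support",
]


def testable_pairs(pairs: pd.DataFrame, x_a: np.ndarray, x_b: np.ndarray,
                   min_support: float = 80.0) -> np.ndarray:
    """Mask of pairs usable for the bias test.

    Keeps pairs whose subgenome call support exceeds ``min_support``
    (strictly) and that have at least one read (A+B) in every tissue.
    """
    support_ok = pairs["support"].to_numpy(dtype=float) > min_support
    reads_ok = (np.asarray(x_a) + np.asarray(x_b)).min(axis=1) >= 1
    return support_ok & reads_ok


def classify_heb(results: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Attach BH q-values and the consistent/inconsistent/unbiased class.

    consistent-bias: q01 ≤ α and p12 > α, direction toward the homoeolog
    with ŝ > 1 (copy A) or ŝ < 1 (copy B); inconsistent: q01 ≤ α and
    p12 ≤ α; unbiased otherwise.
    """
    out = results.copy()
    qvals, _ = bh_correct(out["p01"].to_numpy(), alpha=alpha)
    out["q01"] = qvals
    cls = np.full(len(out), "unbiased", dtype=object)
    sig1 = out["q01"].to_numpy() <= alpha
    sig2 = out["p12"].to_numpy() <= alpha
    cls[sig1 & ~sig2] = "consistent-bias"
    cls[sig1 & sig2] = "inconsistent"
    out["class"] = cls
    direction = np.where(out["s_hat"].to_numpy() > 1, out["subgenome_a"], out["subgenome_b"])
    out["direction"] = np.where(cls == "consistent-bias", direction, None)
    return out


def heb_analysis(
    pairs: pd.DataFrame,
    x_a: np.ndarray,
    x_b: np.ndarray,
    alpha: float = 0.01,
    filter_testable: bool = True,
) -> pd.DataFrame:
    """Full per-pair analysis: fit, LRTs, BH correction, classification.

    ``x_a`` and ``x_b`` are (n_pairs, T) count matrices aligned with
    ``pairs`` rows. Returns one row per (testable) pair with the fit
    statistics, p/q-values, class and direction.
    """
    x_a = np.asarray(x_a)
    x_b = np.asarray(x_b)
    if filter_testable and "support" in pairs.columns:
        mask = testable_pairs(pairs, x_a, x_b)
        pairs = pairs.loc[mask].reset_index(drop=True)
        x_a, x_b = x_a[mask], x_b[mask]
    rows = []
    for i in range(len(pairs)):
        fit = fit_nested(
            x_a[i], x_b[i],
            length_a=pairs["length_a"].iat[i], length_b=pairs["length_b"].iat[i],
        )
        res = lrt(fit)
        rows.append(
            (
                fit.q, fit.p_common, fit.s_hat, fit.ll0, fit.ll1, fit.ll2,
                res.d01, res.p01, res.d12, res.p12,
                (x_a[i] + x_b[i]).sum() < LOW_COUNT_FLAG,
            )
        )
    stats = pd.DataFrame(
        rows,
        columns=["q", "p_common", "s_hat", "ll0", "ll1", "ll2",
                 "d01", "p01", "d12", "p12", "low_count"],
    )
    out = pd.concat([pairs.reset_index(drop=True), stats], axis=1)
    return classify_heb(out, alpha=alpha)


def heb_summary(classed: pd.DataFrame, dominant: str, bins: int = 41) -> dict:
    """Histogram data of log2(ŝ) per subgenome pairing with bias counts.

    For every pairing of the dominant subgenome against another, reports the
    histogram of log2 scaling factors over testable pairs and the number of
    pairs significantly biased toward each side.
    """
    out: dict[str, dict] = {}
    others = sorted(set(classed["subgenome_b"]) | set(classed["subgenome_a"]))
    for other in others:
        if other == dominant:
            continue
        sel = classed[
            ((classed["subgenome_a"] == dominant) & (classed["subgenome_b"] == other))
            | ((classed["subgenome_a"] == other) & (classed["subgenome_b"] == dominant))
        ]
        if sel.empty:
            continue
        # orient ŝ so that values > 1 favor the dominant subgenome
        s = sel["s_hat"].to_numpy(dtype=float)
        flip = (sel["subgenome_a"] != dominant).to_numpy()
        with np.errstate(divide="ignore"):
            log2s = np.where(flip, -np.log2(s), np.log2(s))
        consistent = (sel["class"] == "consistent-bias").to_numpy()
        toward_dom = consistent & (sel["direction"] == dominant).to_numpy()
        toward_other = consistent & ~(sel["direction"] == dominant).to_numpy()
        finite = np.isfinite(log2s)
        counts, edges = np.histogram(log2s[finite], bins=bins)
        out[f"{dominant}_vs_{other}"] = {
            "n_pairs": int(len(sel)),
            "hist_counts": counts,
            "hist_edges": edges,
            "log2_s": log2s,
            "n_biased_dominant": int(toward_dom.sum()),
            "n_biased_other": int(toward_other.sum()),
        }
    return out
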