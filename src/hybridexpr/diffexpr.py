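"""Pairwise negative-binomial exact-test differential expression.

The model: counts for transcript i in sample j are NB with mean mu_ij and
dispersion phi (variance mu + phi * mu^2).  A single common dispersion is
estimated by conditional maximum likelihood after counts are
quantile-adjusted (expectation-matching rescaling) to a common effective
library size.  For each transcript the two group sums are compared with a
conditional exact test: given the total s = y_A + y_B, the probability of
every split (a, s - a) is computed from the NB convolution within each
group, and the two-sided p-value is the total probability of splits no
more likely than the observed one (edgeR's "minimum likelihood" method; a
"doubletail" variant doubles the smaller tail).

A transcript is a DET (differentially expressed transcript) when its
BH-adjusted q-value and absolute log2 fold change pass the configured
gates (defaults: q <= 0.001 and |log2FC| >= 5, i.e. 2^5-fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .normalization import CountMatrix, compute_tmm_factors

DEFAULT_FDR_MAX = 0.001
DEFAULT_MIN_ABS_LOG2FC = 5.0


@dataclass
class ComparisonSpec:
    """One pairwise comparison between two disjoint sample groups."""

    group_a: list[str]
    group_b: list[str]
    label: str = ""
    min_total_count: int = 10

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each comparison group needs >= 2 samples")


@dataclass
class DispersionEstimate:
    phi: float
    interval: tuple[float, float]
    loglik: float


@dataclass
class DEResult:
    """Per-transcript table plus the comparison's summary totals."""

    label: str
    table: pd.DataFrame  # transcript, logfc, p, q, is_det, direction
    n_expressed: int
    n_det: int
    pct_det: float
    n_up_a: int
    n_up_b: int
    dispersion: float | None = None

    def summary_row(self) -> dict:
        return {
            "label": self.label,
            "n_expressed": self.n_expressed,
            "n_det": self.n_det,
            "pct_det": self.pct_det,
            "n_up_a": self.n_up_a,
            "n_up_b": self.n_up_b,
        }


def format_pct(n_det: int, n_expressed: int) -> float:
    """Percentage of DETs among expressed transcripts, round-half-up to 2 dp."""
    if n_expressed <= 0:
        return 0.0
    pct = Decimal(100) * Decimal(n_det) / Decimal(n_expressed)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def equalize_counts(counts: np.ndarray, effective_sizes: np.ndarray) -> np.ndarray:
    """Rescale counts to the geometric-mean effective library size, rounded.

    Expectation-matching adjustment: each column is multiplied by
    target / effective_size and rounded to the nearest integer, putting
    all samples on one common library size before the conditional test.
    """
    eff = np.asarray(effective_sizes, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effective sizes must be positive")
    target = float(np.exp(np.mean(np.log(eff))))
    return np.rint(counts * (target / eff)[None, :]).astype(np.int64)


def _conditional_logpmf(s: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(y_A = a | y_A + y_B = s) for a = 0..s under NB group sums.

    With equal per-sample means the conditional law is negative
    hypergeometric with shape parameters r_a = n_A / phi, r_b = n_B / phi.
    """
    a = np.arange(s + 1, dtype=float)
    return (
        gammaln(a + r_a)
        - gammaln(a + 1.0)
        - gammaln(r_a)
        + gammaln(s - a + r_b)
        - gammaln(s - a + 1.0)
        - gammaln(r_b)
        - (gammaln(s + r_a + r_b) - gammaln(s + 1.0) - gammaln(r_a + r_b))
    )


def exact_test(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    phi: float,
    method: str = "minlike",
) -> float:
    """Two-sided conditional exact test p-value for one transcript.

    phi = 0 reduces to the binomial split Binom(s, n_a / (n_a + n_b)).
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    if phi == 0:
        logpmf = binom.logpmf(np.arange(s + 1), s, n_a / (n_a + n_b))
    else:
        logpmf = _conditional_logpmf(s, n_a / phi, n_b / phi)
    # normalize so the conditional pmf sums to exactly 1
    logpmf = logpmf - logsumexp(logpmf)
    log_obs = logpmf[int(sum_a)]
    if method == "minlike":
        # total probability of splits no more likely than the observed one;
        # the tolerance guards against ties lost to rounding
        mask = logpmf <= log_obs + 1e-10
        if mask.all():
            return 1.0  # observed split is the conditional mode
        p = float(np.exp(logpmf[mask]).sum())
    elif method == "doubletail":
        pmf = np.exp(logpmf)
        lower = pmf[: int(sum_a) + 1].sum()
        upper = pmf[int(sum_a):].sum()
        p = 2.0 * float(min(lower, upper))
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


def _conditional_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Summed qCML conditional log-likelihood over transcripts and groups.

    group_counts: per group, a transcripts x replicates array of
    equalized counts.  Terms independent of phi are dropped.
    """
    r = 1.0 / phi
    total = 0.0
    for y in group_counts:
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            - y.shape[0] * n * gammaln(r)
            + y.shape[0] * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    group_counts: list[np.ndarray],
    interval: tuple[float, float] = (1e-6, 10.0),
    tol: float = 1e-4,
) -> DispersionEstimate:
    """Maximize the conditional likelihood for phi by bounded 1-D search."""
    if not group_counts or all(y.size == 0 for y in group_counts):
        raise ValueError("no expressed transcripts to estimate dispersion from")
    res = minimize_scalar(
        lambda phi: -_conditional_loglik(phi, group_counts),
        bounds=interval,
        method="bounded",
        options={"xatol": tol},
    )
    return DispersionEstimate(
        phi=float(res.x), interval=interval, loglik=float(-res.fun)
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dets(
    table: pd.DataFrame,
    label: str = "",
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    dispersion: float | None = None,
) -> DEResult:
    """Apply the DET gates to a table with columns transcript, logfc, p, q.

    logfc is group B over group A, so positive log fold changes are
    up in B.
    """
    tab = table.copy()
    tab["is_det"] = (tab["q"] <= fdr_max) & (tab["logfc"].abs() >= min_abs_log2fc)
    direction = np.where(
        tab["is_det"], np.where(tab["logfc"] > 0, "up_in_B", "up_in_A"), "none"
    )
    tab["direction"] = direction
    n_expressed = len(tab)
    n_det = int(tab["is_det"].sum())
    n_up_a = int((tab["direction"] == "up_in_A").sum())
    n_up_b = int((tab["direction"] == "up_in_B").sum())
    return DEResult(
        label=label,
        table=tab,
        n_expressed=n_expressed,
        n_det=n_det,
        pct_det=format_pct(n_det, n_expressed),
        n_up_a=n_up_a,
        n_up_b=n_up_b,
        dispersion=dispersion,
    )


def run_exact_de(
    counts: CountMatrix,
    spec: ComparisonSpec,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    phi: float | None = None,
    method: str = "minlike",
) -> DEResult:
    """Full pairwise DE pass on the two groups of ``spec``.

    Normalization (TMM) is computed on the comparison's samples only;
    transcripts whose raw total across both groups falls below
    ``spec.min_total_count`` are excluded as not expressed.
    """
    sample_ids = list(spec.group_a) + list(spec.group_b)
    missing = [s for s in sample_ids if s not in counts.sample_ids]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")
    sub = counts.subset_samples(sample_ids)
    n_a, n_b = len(spec.group_a), len(spec.group_b)

    factors = compute_tmm_factors(sub)
    eff = sub.library_sizes().astype(float) * factors

    expressed = sub.counts.sum(axis=1) >= spec.min_total_count
    ids = [t for t, keep in zip(sub.transcript_ids, expressed) if keep]
    if not ids:
        raise ValueError("no expressed transcripts in comparison")
    adj = equalize_counts(sub.counts[expressed], eff)
    y_a, y_b = adj[:, :n_a], adj[:, n_a:]

    if phi is None:
        phi = estimate_common_dispersion([y_a, y_b]).phi

    sums_a = y_a.sum(axis=1)
    sums_b = y_b.sum(axis=1)
    pvals = np.array(
        [
            exact_test(sa, sb, n_a, n_b, phi, method=method)
            for sa, sb in zip(sums_a, sums_b)
        ]
    )
    # pseudocount keeps the fold change finite when one group sum is zero
    logfc = np.log2(((sums_b + 0.5) / n_b) / ((sums_a + 0.5) / n_a))
    table = pd.DataFrame(
        {"transcript": ids, "logfc": logfc, "p": pvals, "q": bh_adjust(pvals)}
    )
    return call_dets(
        table,
        label=spec.label,
        fdr_max=fdr_max,
        min_abs_log2fc=min_abs_log2fc,
        dispersion=phi,
    )
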