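"""Library normalization for transcript count matrices.

Implements trimmed-mean-of-M-values (TMM) scaling factors, effective
library sizes, FPKM, and the log2-transformed (optionally row-centered)
expression values consumed by every downstream stage.

TMM compares each sample against a reference sample on the (M, A) plane:
M is the library-size-adjusted log2 expression ratio and A the average
log2 abundance.  After discarding transcripts with a zero count in either
member of the pair, the most extreme 30% of M-values and 5% of A-values
are trimmed and the scaling factor is 2 raised to the precision-weighted
mean of the surviving M-values, with weights given by the inverse
asymptotic (delta-method) variance of M.  Factors are rescaled to have
geometric mean 1 so that they encode purely compositional differences;
sequencing depth itself lives in the library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CountMatrix:
    """Transcripts x samples integer counts plus per-transcript lengths (bp)."""

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths)
        n_t, n_s = self.counts.shape
        if len(self.transcript_ids) != n_t:
            raise ValueError("transcript_ids length does not match count rows")
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match count columns")
        if len(set(self.transcript_ids)) != n_t:
            raise ValueError("duplicate transcript ids")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.rint(self.counts)):
            raise ValueError("counts must be integral")
        if self.lengths.shape != (n_t,):
            raise ValueError("lengths must have one entry per transcript")
        if np.any(self.lengths < 1):
            raise ValueError("transcript lengths must be >= 1 bp")
        self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.astype(np.int64)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            transcript_ids=list(self.transcript_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            lengths=self.lengths.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.transcript_ids, columns=self.sample_ids
        )


@dataclass
class NormalizationResult:
    sample_ids: list[str]
    lib_sizes: np.ndarray
    tmm_factors: np.ndarray
    effective_sizes: np.ndarray
    fpkm: np.ndarray
    log_expression: np.ndarray
    pseudocount: float
    centered: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "lib_size": self.lib_sizes,
                "tmm_factor": self.tmm_factors,
                "effective_size": self.effective_sizes,
            }
        )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample.

    Transcripts with a zero count in either member of the pair are dropped
    from this pair's M/A computation only.
    """
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 1.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    log_r = np.log2((o / n_obs) / (r / n_ref))  # M-values
    abs_e = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2.0  # A-values
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(kept) or np.sum(1.0 / var[kept]) == 0:
        return 1.0
    f = np.sum(log_r[kept] / var[kept]) / np.sum(1.0 / var[kept])
    return float(2.0**f)


def choose_reference_sample(counts: CountMatrix) -> int:
    """Index of the sample whose depth-scaled 75th percentile is closest to the mean."""
    lib = counts.library_sizes().astype(float)
    f75 = np.array(
        [
            np.quantile(counts.counts[:, j].astype(float), 0.75) / lib[j]
            for j in range(counts.n_samples)
        ]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def compute_tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> np.ndarray:
    if counts.n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.library_sizes().astype(float)
    for j, size in enumerate(lib):
        if size == 0:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} has all-zero counts"
            )
    if ref_sample is None:
        ref_idx = choose_reference_sample(counts)
    else:
        ref_idx = counts.sample_ids.index(ref_sample)
    ref_col = counts.counts[:, ref_idx]
    factors = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair(
                counts.counts[:, j], ref_col, lib[j], lib[ref_idx], trim_m, trim_a
            )
    # compositional factors: geometric mean 1
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def compute_fpkm(counts: CountMatrix, effective_lib_sizes: np.ndarray) -> np.ndarray:
    """FPKM against effective (TMM-scaled) library sizes.

    fpkm[i, j] = counts[i, j] * 1e9 / (length_i * effective_size_j)
    """
    eff = np.asarray(effective_lib_sizes, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effective library sizes must be positive")
    if np.any(counts.lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    return counts.counts * 1e9 / (counts.lengths[:, None].astype(float) * eff[None, :])


def log_center(
    fpkm: np.ndarray, pseudocount: float = 1.0, center_rows: bool = True
) -> np.ndarray:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("fpkm values must be non-negative")
    out = np.log2(fpkm + pseudocount)
    if center_rows:
        out = out - out.mean(axis=1, keepdims=True)
    return out


def normalize(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    pseudocount: float = 1.0,
    center_rows: bool = True,
) -> NormalizationResult:
    """Full normalization pass: TMM factors -> effective sizes -> FPKM -> log2."""
    factors = compute_tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    lib = counts.library_sizes().astype(float)
    eff = lib * factors
    fpkm = compute_fpkm(counts, eff)
    log_expr = log_center(fpkm, pseudocount=pseudocount, center_rows=center_rows)
    return NormalizationResult(
        sample_ids=list(counts.sample_ids),
        lib_sizes=lib,
        tmm_factors=factors,
        effective_sizes=eff,
        fpkm=fpkm,
        log_expression=log_expr,
        pseudocount=pseudocount,
        centered=center_rows,
    )
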