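"""Count filtering and normalization.

Implements the preprocessing used ahead of signature derivation, scoring
and enrichment analysis: removal of all-zero genes, the minimum-read
filter, counts-per-million (CPM) scaling and trimmed-mean-of-M-values
(TMM) between-sample factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["remove_zero_genes", "filter_low_counts", "cpm", "tmm_factors"]

# TMM trim fractions and weighting follow the method's original definition.
TMM_TRIM_M = 0.30  # fraction of most extreme M (log ratio) values removed
TMM_TRIM_A = 0.05  # fraction of most extreme A (log abundance) values removed


def remove_zero_genes(m: CountMatrix) -> CountMatrix:
    """Drop genes whose count is zero in every sample, preserving order."""
    keep = m.data.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("remove_zero_genes: dropped %d of %d genes", n_dropped, m.shape[0])
    if not keep.any():
        raise ValueError("no expressed genes: all counts are zero")
    if n_dropped == 0:
        return m
    return CountMatrix(m.data.loc[keep])


def filter_low_counts(m: CountMatrix, min_reads: int = 5) -> CountMatrix:
    """Keep a gene only if every sample has at least ``min_reads`` reads for it.

    With ``min_reads=5`` this discards genes with fewer than 5 reads in at
    least one sample.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = (m.data >= min_reads).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_low_counts(min_reads=%d): dropped %d of %d genes",
            min_reads, n_dropped, m.shape[0],
        )
    if not keep.any():
        raise ValueError(f"no genes with >= {min_reads} reads in every sample")
    if n_dropped == 0:
        return m
    return CountMatrix(m.data.loc[keep])


def cpm(m: CountMatrix, log2_offset: float = 0.0,
        scale_factors: pd.Series | None = None) -> ExpressionMatrix:
    """Counts-per-million: count / library size x 1e6 per sample.

    If ``log2_offset`` > 0 the values are log2(cpm + offset) and the log
    flag is recorded. ``scale_factors`` (e.g. from :func:`tmm_factors`)
    multiply the library sizes before scaling.
    """
    if log2_offset < 0:
        raise ValueError("log2_offset must be >= 0")
    lib = m.library_sizes().astype(float)
    if scale_factors is not None:
        lib = lib * pd.Series(scale_factors).reindex(lib.index)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad[:5]}")
    values = m.data.to_numpy(dtype=float) / lib.to_numpy() * 1e6
    log_flag = log2_offset > 0
    if log_flag:
        values = np.log2(values + log2_offset)
    df = pd.DataFrame(values, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, units="cpm", log2=log_flag)


def _trim_keep(values: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask keeping values after symmetric rank-trimming ``frac`` total."""
    n = len(values)
    lo = int(np.floor(n * frac / 2))
    hi = n - lo
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[lo:hi]] = True
    return keep


def tmm_factors(m: CountMatrix, ref_sample: str = "auto") -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean rescaled to 1.

    For each sample against the reference, per-gene M (log2 ratio of
    library-size-scaled proportions) and A (mean log2 proportion) are
    computed over genes with positive counts in both samples; the 30% most
    extreme M and 5% most extreme A are trimmed symmetrically and the
    factor is 2 to the precision-weighted mean of the surviving M values.
    The "auto" reference is the sample whose upper-quartile count
    proportion is closest to the mean upper-quartile.
    """
    if m.shape[1] < 2:
        raise ValueError("tmm_factors requires at least 2 samples")
    counts = m.data.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    prop = counts / lib

    samples = list(m.data.columns)
    if ref_sample == "auto":
        uq = np.quantile(prop, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in samples:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref_idx = samples.index(ref_sample)

    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        both = (counts[:, j] > 0) & (counts[:, ref_idx] > 0)
        if not both.any():
            logger.warning("tmm_factors: no shared genes for %s; factor 1", samples[j])
            continue
        pj, pr = prop[both, j], prop[both, ref_idx]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        keep = _trim_keep(M, TMM_TRIM_M) & _trim_keep(A, TMM_TRIM_A)
        if not keep.any():
            logger.warning(
                "tmm_factors: no genes survive trimming for %s; factor 1",
                samples[j],
            )
            continue
        # inverse asymptotic variance of M as precision weight
        cj, cr = counts[both, j][keep], counts[both, ref_idx][keep]
        w = (lib[j] - cj) / (lib[j] * cj) + (lib[ref_idx] - cr) / (lib[ref_idx] * cr)
        with np.errstate(divide="ignore"):
            inv_w = np.where(w > 0, 1.0 / w, 0.0)
        if inv_w.sum() > 0:
            log_factors[j] = float(np.sum(M[keep] * inv_w) / inv_w.sum())
        else:
            log_factors[j] = float(np.mean(M[keep]))

    log_factors -= log_factors.mean()  # geometric mean of 2**lf becomes 1
    return pd.Series(np.exp2(log_factors), index=samples, name="tmm_factor")
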