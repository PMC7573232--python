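"""Differential-expression signature derivation.

A two-condition negative-binomial exact test with a single common
dispersion: samples are scaled to a common effective library size,
counts are summed per condition, and the two-sided p-value is the total
conditional probability of all splits of the grand total that are no
more probable than the observed split. Genes passing Benjamini-Hochberg
FDR control form the signature, with direction and log2 fold change on
CPM group means.

The NB is parameterized by mean mu and dispersion phi with
variance = mu + phi * mu^2; the sum of n iid such variables is NB with
mean n*mu and dispersion phi/n, which is what makes the group-sum
conditioning exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .matrix import CountMatrix, SampleMetadata
from .preprocess import cpm, remove_zero_genes

logger = logging.getLogger(__name__)

__all__ = [
    "DispersionEstimate",
    "SignatureGene",
    "Signature",
    "effective_lib_scale",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "derive_signature",
]

DISPERSION_GRID_LO = 1e-4
DISPERSION_GRID_HI = 5.0
LOG2_FC_OFFSET = 0.5  # CPM offset avoiding infinite fold changes


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str
    n_genes_used: int

    def __post_init__(self) -> None:
        if not (0 <= self.phi <= DISPERSION_GRID_HI):
            raise ValueError("dispersion outside search range")


@dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    log2_fc: float
    p_value: float
    q_value: float
    direction: str

    def __post_init__(self) -> None:
        expected = "up_in_nohelp" if self.log2_fc >= 0 else "down_in_nohelp"
        if self.direction != expected:
            raise ValueError("direction inconsistent with log2_fc sign")
        if not (0 <= self.q_value <= 1 and 0 <= self.p_value <= 1):
            raise ValueError("p/q value outside [0, 1]")


@dataclass
class Signature:
    """Ordered differentially-expressed gene list defining the signature."""

    genes: list[SignatureGene]
    fdr_threshold: float
    reference_conditions: tuple[str, str]  # (numerator, denominator)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene in signature")
        if any(g.q_value >= self.fdr_threshold for g in self.genes):
            raise ValueError("signature gene with q >= threshold")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "log2_fc": [g.log2_fc for g in self.genes],
                "p_value": [g.p_value for g in self.genes],
                "q_value": [g.q_value for g in self.genes],
                "direction": [g.direction for g in self.genes],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n",
                               float_format="%.10g")

    @classmethod
    def read(cls, path, fdr_threshold: float | None = None) -> "Signature":
        df = pd.read_csv(path, sep="\t")
        genes = [
            SignatureGene(str(r.gene_id), float(r.log2_fc), float(r.p_value),
                          float(r.q_value), str(r.direction))
            for r in df.itertuples()
        ]
        if fdr_threshold is None:
            qmax = max((g.q_value for g in genes), default=0.0)
            fdr_threshold = float(np.nextafter(qmax, np.inf)) if genes else 0.01
        return cls(genes, fdr_threshold, ("unknown", "unknown"))


def effective_lib_scale(m: CountMatrix,
                        tmm: pd.Series | None = None) -> pd.Series:
    """Per-sample scale factors placing samples on a common scale.

    Library size, multiplied by a TMM factor when one is supplied.
    """
    lib = m.library_sizes().astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if tmm is not None:
        lib = lib * pd.Series(tmm).reindex(lib.index)
    return lib


def _pseudo_counts(counts: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Counts rescaled to the geometric-mean scale, rounded half-up."""
    common = np.exp(np.mean(np.log(scales)))
    scaled = counts * (common / scales)
    return np.floor(scaled + 0.5).astype(np.int64)


def _nb_logpmf(k: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log pmf, mean/dispersion parameterization; Poisson at phi=0.

    mu = 0 is a point mass at 0.
    """
    k, mu = np.broadcast_arrays(
        np.asarray(k, dtype=float), np.asarray(mu, dtype=float)
    )
    out = np.full(k.shape, -np.inf)
    out[(mu <= 0) & (k == 0)] = 0.0
    pos = mu > 0
    if np.any(pos):
        kp, mp = k[pos], mu[pos]
        if phi == 0:
            val = kp * np.log(mp) - mp - gammaln(kp + 1)
        else:
            r = 1.0 / phi
            val = (
                gammaln(kp + r) - gammaln(r) - gammaln(kp + 1)
                + r * np.log(r / (r + mp)) + kp * np.log(mp / (r + mp))
            )
        out[pos] = val
    return out


def _cml_group_loglik(counts: np.ndarray, phi: float) -> float:
    """Within-group NB log-likelihood conditional on the group sum.

    Conditioning removes the per-gene mean as a nuisance parameter, which
    with few replicates would otherwise bias the dispersion downward (the
    profile-likelihood variance uses divisor n instead of n - 1). Valid
    for samples on a common scale. ``counts``: genes x replicates.
    """
    n = counts.shape[1]
    z = counts.sum(axis=1)
    if phi <= 0:
        raise ValueError("conditional likelihood needs phi > 0")
    r = 1.0 / phi
    ll = (
        gammaln(counts + r).sum(axis=1)
        - n * gammaln(r)
        - gammaln(counts + 1).sum(axis=1)
        - (gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1))
    )
    return float(ll.sum())


def estimate_common_dispersion(m: CountMatrix, meta: SampleMetadata,
                               tmm: pd.Series | None = None) -> DispersionEstimate:
    """Maximize the pooled within-group conditional NB likelihood over phi.

    Samples are scaled to a common effective library size (pseudo-counts,
    half-up rounding); the likelihood of each gene's within-group counts
    given their sum is summed over genes and groups, and phi is searched
    on a log-spaced grid over [1e-4, 5] refined by golden-section.
    Deterministic.
    """
    meta.check_against(m)
    cond_a, cond_b = meta.require_two_conditions()
    samples_a = meta.samples_in(cond_a)
    samples_b = meta.samples_in(cond_b)
    if len(samples_a) < 2 and len(samples_b) < 2:
        raise ValueError("dispersion not estimable: need >= 2 replicates in a group")

    scales = effective_lib_scale(m, tmm)
    pseudo = _pseudo_counts(
        m.data.to_numpy(dtype=float), scales.reindex(m.data.columns).to_numpy()
    )
    cols = list(m.data.columns)
    idx_a = [cols.index(s) for s in samples_a]
    idx_b = [cols.index(s) for s in samples_b]
    groups = [g for g in (pseudo[:, idx_a], pseudo[:, idx_b]) if g.shape[1] >= 2]

    def neg_loglik(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_cml_group_loglik(g.astype(float), phi) for g in groups)

    lo, hi = np.log(DISPERSION_GRID_LO), np.log(DISPERSION_GRID_HI)
    grid = np.linspace(lo, hi, 25)
    values = [neg_loglik(x) for x in grid]
    best = int(np.argmin(values))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]

    # golden-section refinement on [a, b]
    invphi = (np.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = neg_loglik(c), neg_loglik(d)
    for _ in range(60):
        if b - a < 1e-8:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = neg_loglik(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = neg_loglik(d)
    phi = float(np.exp((a + b) / 2))
    return DispersionEstimate(
        phi=phi, method="common_conditional_ml", n_genes_used=pseudo.shape[0]
    )


def nb_exact_test(counts_a, counts_b, phi: float, scales=None) -> float:
    """Two-sided exact NB test on group sums, conditional on the grand total.

    ``scales`` (optional) is one positive scale per sample of group A then
    group B; counts are rescaled to their geometric mean and rounded
    half-up before summation, so the conditional enumeration stays on
    integers. With phi = 0 the conditional law is binomial and the test
    coincides with the exact binomial test.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative count")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if scales is not None:
        scales = np.asarray(scales, dtype=float)
        if len(scales) != len(a) + len(b):
            raise ValueError("scales length must equal total sample count")
        if (scales <= 0).any():
            raise ValueError("scales must be positive")
        pseudo = _pseudo_counts(np.concatenate([a, b]), scales)
        a, b = pseudo[: len(a)].astype(float), pseudo[len(a):].astype(float)
    sa, sb = int(round(a.sum())), int(round(b.sum()))
    return _exact_test_sums(sa, sb, len(a), len(b), phi)


def _exact_test_sums(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """p-value from group sums; see :func:`nb_exact_test`."""
    total = sa + sb
    if total == 0:
        logger.debug("nb_exact_test: zero total, p = 1 by convention")
        return 1.0
    k = np.arange(total + 1, dtype=float)
    mu = total / (na + nb)  # per-sample null mean at the common scale
    if phi == 0:
        # Poisson group sums => binomial conditional law
        logp = (
            gammaln(total + 1) - gammaln(k + 1) - gammaln(total - k + 1)
            + k * np.log(na / (na + nb)) + (total - k) * np.log(nb / (na + nb))
        )
    else:
        logp = (
            _nb_logpmf(k, np.full_like(k, na * mu), phi / na)
            + _nb_logpmf(total - k, np.full_like(k, nb * mu), phi / nb)
        )
        logp -= logsumexp(logp)
    log_obs = logp[sa]
    # include splits whose probability is <= observed, with a float-tie margin
    mask = logp <= log_obs + 1e-12
    p = float(np.exp(logsumexp(logp[mask])))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, reported in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def de_table(
    m: CountMatrix,
    meta: SampleMetadata,
    conditions: tuple[str, str] | None = None,
    min_reads: int = 0,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Per-gene NB exact-test results for the two-condition contrast.

    Zero genes are removed, a common dispersion estimated, each gene
    tested with the NB exact test and q-values computed by BH. Returns a
    DataFrame with columns gene_id, log2_fc, p_value, q_value in matrix
    gene order, with the dispersion and contrast in ``attrs``.
    ``conditions`` orders the contrast as (numerator, denominator) for
    the fold change — by default the condition whose label contains "no"
    (case-insensitive, e.g. "NoHelp") is the numerator, otherwise
    first-appearance order is used. Fold changes are log2 ratios of CPM
    group means with offset 0.5.

    TMM factors are applied to the effective library sizes by default:
    when a sizable fraction of genes is truly differential, plain library
    size carries their compositional shift onto every null gene, which
    inflates false discoveries; the trimmed factors restore the null
    genes' scale.
    """
    meta.check_against(m)
    cond1, cond2 = meta.require_two_conditions()
    if conditions is None:
        if "no" in cond2.lower() and "no" not in cond1.lower():
            conditions = (cond2, cond1)
        else:
            conditions = (cond1, cond2)
    num_cond, den_cond = conditions
    if {num_cond, den_cond} != {cond1, cond2}:
        raise ValueError(f"conditions {conditions} do not match metadata labels")

    m = remove_zero_genes(m)
    if min_reads > 0:
        from .preprocess import filter_low_counts

        m = filter_low_counts(m, min_reads)

    tmm = None
    if use_tmm:
        from .preprocess import tmm_factors

        tmm = tmm_factors(m)
    scales = effective_lib_scale(m, tmm)

    dispersion = estimate_common_dispersion(m, meta, tmm)
    logger.info("common dispersion estimate: phi = %.4g", dispersion.phi)

    samples_num = meta.samples_in(num_cond)
    samples_den = meta.samples_in(den_cond)
    counts = m.data
    pseudo = _pseudo_counts(
        counts.to_numpy(dtype=float), scales.reindex(counts.columns).to_numpy()
    )
    cols = list(counts.columns)
    idx_num = [cols.index(s) for s in samples_num]
    idx_den = [cols.index(s) for s in samples_den]
    sums_num = pseudo[:, idx_num].sum(axis=1)
    sums_den = pseudo[:, idx_den].sum(axis=1)

    # identical (sa, sb) pairs share one enumeration
    cache: dict[tuple[int, int], float] = {}
    p_values = np.empty(len(counts))
    for i, (sa, sb) in enumerate(zip(sums_num, sums_den)):
        key = (int(sa), int(sb))
        if key not in cache:
            cache[key] = _exact_test_sums(
                key[0], key[1], len(idx_num), len(idx_den), dispersion.phi
            )
        p_values[i] = cache[key]

    q_values = bh_fdr(p_values)

    expr = cpm(m)
    mean_num = expr.data[samples_num].mean(axis=1).to_numpy()
    mean_den = expr.data[samples_den].mean(axis=1).to_numpy()
    log2_fc = np.log2(mean_num + LOG2_FC_OFFSET) - np.log2(mean_den + LOG2_FC_OFFSET)

    table = pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2_fc": log2_fc,
            "p_value": p_values,
            "q_value": q_values,
        }
    ).reset_index(drop=True)
    table.attrs.update(
        {
            "dispersion_phi": dispersion.phi,
            "conditions": (num_cond, den_cond),
            "use_tmm": use_tmm,
            "min_reads": min_reads,
        }
    )
    return table


def derive_signature(
    m: CountMatrix,
    meta: SampleMetadata,
    fdr_threshold: float = 0.01,
    conditions: tuple[str, str] | None = None,
    min_reads: int = 0,
    use_tmm: bool = True,
) -> Signature:
    """Signature of genes differential at BH FDR below ``fdr_threshold``.

    Runs :func:`de_table` and keeps q < threshold, ordered by q
    ascending, then |log2_fc| descending, then gene id.
    """
    table = de_table(m, meta, conditions=conditions, min_reads=min_reads,
                     use_tmm=use_tmm)
    num_cond, den_cond = table.attrs["conditions"]
    hits = table[table["q_value"] < fdr_threshold].copy()
    hits["abs_fc"] = hits["log2_fc"].abs()
    hits = hits.sort_values(
        ["q_value", "abs_fc", "gene_id"], ascending=[True, False, True],
        kind="stable",
    )
    if hits.empty:
        logger.warning("derive_signature: empty signature at FDR < %g", fdr_threshold)

    genes = [
        SignatureGene(
            gene_id=str(r.gene_id),
            log2_fc=float(r.log2_fc),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            direction="up_in_nohelp" if r.log2_fc >= 0 else "down_in_nohelp",
        )
        for r in hits.itertuples()
    ]
    return Signature(
        genes=genes,
        fdr_threshold=fdr_threshold,
        reference_conditions=(num_cond, den_cond),
        provenance={
            "dispersion_phi": table.attrs["dispersion_phi"],
            "n_genes_tested": int(len(table)),
            "use_tmm": use_tmm,
            "min_reads": min_reads,
        },
    )
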