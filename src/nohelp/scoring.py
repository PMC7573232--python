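"""Nearest-centroid No Help scoring and group-comparison statistics.

The No Help score of a query expression profile is the difference of its
Pearson correlations with the No-Help and Help reference centroids,
computed over the signature genes shared by query and reference:

    score = r(profile, centroid_nohelp) - r(profile, centroid_help)

A higher score means the query transcriptome is closer to the
helper-deprived reference state. Scores are compared between query
populations with an unpaired pooled-variance t-test or, for matched
designs, a repeated-measures one-way ANOVA with Tukey pairwise tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import Signature
from .io import GeneMapping, normalize_gene_id
from .matrix import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "Centroids",
    "ScoreResult",
    "GroupComparison",
    "pearson",
    "compute_centroids",
    "no_help_score",
    "score_samples",
    "map_profile",
    "compare_two_groups",
    "compare_matched_groups",
]

MIN_OVERLAP_DEFAULT = 10


@dataclass
class Centroids:
    """Per-gene mean normalized expression of the two reference conditions."""

    gene_ids: list[str]
    centroid_nohelp: np.ndarray
    centroid_help: np.ndarray
    units: str = "cpm"
    log2: bool = False

    def __post_init__(self) -> None:
        self.centroid_nohelp = np.asarray(self.centroid_nohelp, dtype=float)
        self.centroid_help = np.asarray(self.centroid_help, dtype=float)
        n = len(self.gene_ids)
        if self.centroid_nohelp.shape != (n,) or self.centroid_help.shape != (n,):
            raise ValueError("centroid length does not match gene list")
        if not (np.all(np.isfinite(self.centroid_nohelp))
                and np.all(np.isfinite(self.centroid_help))):
            raise ValueError("non-finite centroid value")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene in centroids")

    def swapped(self) -> "Centroids":
        return Centroids(self.gene_ids, self.centroid_help.copy(),
                         self.centroid_nohelp.copy(), self.units, self.log2)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ScoreResult:
    sample_id: str
    r_nohelp: float
    r_help: float
    no_help_score: float
    n_genes_used: int

    def __post_init__(self) -> None:
        if abs(self.no_help_score - (self.r_nohelp - self.r_help)) > 1e-12:
            raise ValueError("score is not the difference of its correlations")


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "students_t" or "rm_anova_tukey"
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # Tukey table for matched designs


def pearson(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length vectors")
    if len(x) < 3:
        raise ValueError("pearson requires length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("degenerate profile: zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def compute_centroids(
    ref_expr: ExpressionMatrix,
    meta: SampleMetadata,
    signature: Signature,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> Centroids:
    """Condition-wise mean expression over the signature genes.

    The gene list is signature ∩ reference genes, matched on normalized
    ids; signature genes absent from the reference are dropped with a
    logged count.
    """
    meta.check_against(ref_expr)
    nohelp_cond, help_cond = signature.reference_conditions
    for cond in (nohelp_cond, help_cond):
        if not meta.samples_in(cond):
            raise ValueError(f"no reference samples for condition {cond!r}")

    ref_norm = {normalize_gene_id(g): g for g in ref_expr.gene_ids}
    kept: list[str] = []
    rows: list[str] = []
    for g in signature.gene_ids:
        key = normalize_gene_id(g)
        if key in ref_norm:
            kept.append(g)
            rows.append(ref_norm[key])
    dropped = len(signature) - len(kept)
    if dropped:
        logger.info("compute_centroids: %d signature genes absent from reference",
                    dropped)
    if len(kept) < min_overlap:
        raise ValueError(
            f"signature/reference overlap {len(kept)} below minimum {min_overlap}"
        )
    sub = ref_expr.data.loc[rows]
    c_nohelp = sub[meta.samples_in(nohelp_cond)].mean(axis=1).to_numpy()
    c_help = sub[meta.samples_in(help_cond)].mean(axis=1).to_numpy()
    return Centroids(kept, c_nohelp, c_help, ref_expr.units, ref_expr.log2)


def no_help_score(
    profile: pd.Series,
    centroids: Centroids,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    sample_id: str | None = None,
) -> ScoreResult:
    """Score one query profile (a per-gene expression Series) against the centroids.

    Both correlations are computed on the identical overlap gene set.
    """
    prof_norm: dict[str, float] = {}
    for g, v in profile.items():
        prof_norm.setdefault(normalize_gene_id(str(g)), float(v))
    idx, values = [], []
    for i, g in enumerate(centroids.gene_ids):
        key = normalize_gene_id(g)
        if key in prof_norm:
            idx.append(i)
            values.append(prof_norm[key])
    if len(idx) < min_overlap:
        raise ValueError(
            f"profile/centroid overlap {len(idx)} below minimum {min_overlap}"
        )
    v = np.asarray(values)
    r_n = pearson(v, centroids.centroid_nohelp[idx])
    r_h = pearson(v, centroids.centroid_help[idx])
    return ScoreResult(
        sample_id=sample_id or str(profile.name or "query"),
        r_nohelp=r_n,
        r_help=r_h,
        no_help_score=r_n - r_h,
        n_genes_used=len(idx),
    )


def score_samples(
    expr: ExpressionMatrix,
    centroids: Centroids,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> pd.DataFrame:
    """No Help score for every sample of an expression matrix, as a table."""
    rows = []
    for s in expr.sample_ids:
        r = no_help_score(expr.profile(s), centroids, min_overlap, sample_id=s)
        rows.append(
            {
                "sample_id": r.sample_id,
                "r_nohelp": r.r_nohelp,
                "r_help": r.r_help,
                "no_help_score": r.no_help_score,
                "n_genes_used": r.n_genes_used,
            }
        )
    return pd.DataFrame(rows)


def map_profile(profile: pd.Series, mapping: list[GeneMapping]) -> pd.Series:
    """Translate a profile's gene ids through a one-to-one mapping.

    Unmapped genes are dropped with a logged count.
    """
    lut = {normalize_gene_id(m.source_id): m.target_id for m in mapping}
    ids, values = [], []
    for g, v in profile.items():
        key = normalize_gene_id(str(g))
        if key in lut:
            ids.append(lut[key])
            values.append(v)
    dropped = len(profile) - len(ids)
    if dropped:
        logger.info("map_profile: dropped %d unmapped genes", dropped)
    if not ids:
        raise ValueError("no genes survive mapping")
    return pd.Series(values, index=ids, name=profile.name)


def compare_two_groups(scores_a, scores_b,
                       labels: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """Unpaired two-tailed Student's t-test (pooled variance)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            return GroupComparison("students_t", labels, 0.0, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison("students_t", labels, float(t_stat), float(p))


def compare_matched_groups(score_table: pd.DataFrame) -> GroupComparison:
    """Repeated-measures one-way ANOVA with Tukey pairwise comparisons.

    ``score_table`` has one row per subject, one column per condition,
    complete. The subject x condition interaction is the error term;
    Tukey p-values come from the studentized-range distribution of the
    condition means over the same error.
    """
    if score_table.isna().any().any():
        raise ValueError("incomplete table: every subject needs every condition")
    n_subj, k = score_table.shape
    if n_subj < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    x = score_table.to_numpy(dtype=float)
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n_subj * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n_subj - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ss_cond == 0:
            return GroupComparison(
                "rm_anova_tukey", tuple(score_table.columns), 0.0, 1.0,
                pairwise=_tukey_table(score_table.columns, cond_means,
                                      np.inf, k, df_err, n_subj, degenerate=True),
            )
        raise ValueError("zero error variance")
    f_stat = (ss_cond / df_cond) / ms_err
    p = float(stats.f.sf(f_stat, df_cond, df_err))
    pairwise = _tukey_table(score_table.columns, cond_means, ms_err, k, df_err,
                            n_subj)
    return GroupComparison(
        "rm_anova_tukey", tuple(score_table.columns), float(f_stat), p, pairwise
    )


def _tukey_table(conditions, cond_means, ms_err, k, df_err, n_subj,
                 degenerate: bool = False) -> pd.DataFrame:
    rows = []
    conds = list(conditions)
    se = np.sqrt(ms_err / n_subj) if not degenerate else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = cond_means[i] - cond_means[j]
            if degenerate:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_1": conds[i],
                    "group_2": conds[j],
                    "mean_diff": float(diff),
                    "q_statistic": float(q),
                    "p_value": min(max(p, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)
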