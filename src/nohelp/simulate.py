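"""Synthetic two-condition RNA-seq data with known ground truth.

Emulates the structure of a small Help / No-Help bulk RNA-seq reference
(a handful of replicates per condition, negative-binomial counts with a
shared dispersion, a fixed fraction of genes truly differential) and of
query populations that are graded mixtures of the two reference
centroids plus multiplicative noise. Every generator is a pure function
of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneMapping, GeneSet, write_counts, write_gmt, write_mapping, \
    write_metadata
from .matrix import CountMatrix, ExpressionMatrix, SampleMetadata
from .scoring import Centroids

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_reference",
    "simulate_query",
    "rename_species",
    "make_default_fixture",
    "DEFAULT_CONFIG",
]

CONDITION_NOHELP = "NoHelp"
CONDITION_HELP = "Help"
GENERATOR_VERSION = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-condition reference simulation.

    Baseline per-gene means are log-normal on the natural-log scale
    (``mean_log_mu``, ``sd_log_mu``); differential genes get the
    configured log2 fold change applied to the No-Help condition, half
    up and half down; counts are negative-binomial with dispersion
    ``dispersion_phi`` (variance = mu + phi mu^2) around expected counts
    proportional to library size.
    """

    n_genes: int = 2000
    n_reps_per_condition: int = 3
    de_fraction: float = 0.10
    log2_fc_magnitude: float = 2.0
    dispersion_phi: float = 0.1
    mean_log_mu: float = 3.3
    sd_log_mu: float = 1.2
    libsize_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps_per_condition < 1:
            raise ValueError("n_genes and n_reps_per_condition must be >= 1")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.log2_fc_magnitude < 0 or self.dispersion_phi < 0:
            raise ValueError("log2_fc_magnitude and dispersion_phi must be >= 0")
        if self.sd_log_mu <= 0:
            raise ValueError("sd_log_mu must be > 0")
        lo, hi = self.libsize_range
        if lo < 1 or hi < lo:
            raise ValueError("libsize_range must be positive and ordered")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated reference dataset."""

    de_genes: pd.DataFrame  # columns gene_id, direction, log2_fc
    library_sizes: pd.Series

    @property
    def de_gene_ids(self) -> list[str]:
        return list(self.de_genes["gene_id"])

    @property
    def up_gene_ids(self) -> list[str]:
        mask = self.de_genes["direction"] == "up_in_nohelp"
        return list(self.de_genes.loc[mask, "gene_id"])

    @property
    def down_gene_ids(self) -> list[str]:
        mask = self.de_genes["direction"] == "down_in_nohelp"
        return list(self.de_genes.loc[mask, "gene_id"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             phi: float) -> np.ndarray:
    """NB(mu, phi) counts via the gamma-Poisson mixture; Poisson at phi=0."""
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleMetadata, SimulationTruth]:
    """Simulate the Help / No-Help reference counts with known DE truth."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    reps = config.n_reps_per_condition

    base_mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, size=g))
    gene_ids = np.array([f"gene{i:05d}" for i in range(g)])

    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    de_idx.sort()
    n_up = n_de // 2 + n_de % 2  # half up, half down (extra one goes up)
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]

    mu_help = base_mu.copy()
    mu_nohelp = base_mu.copy()
    mu_nohelp[up_idx] *= 2.0 ** config.log2_fc_magnitude
    mu_nohelp[down_idx] *= 2.0 ** (-config.log2_fc_magnitude)

    lo, hi = config.libsize_range
    lib_sizes = rng.integers(lo, hi + 1, size=2 * reps)

    sample_ids, conditions, columns = [], [], []
    for c, mu_cond in ((CONDITION_HELP, mu_help), (CONDITION_NOHELP, mu_nohelp)):
        prop = mu_cond / mu_cond.sum()
        for r in range(reps):
            j = len(sample_ids)
            expected = prop * lib_sizes[j]
            columns.append(_nb_draw(rng, expected, config.dispersion_phi))
            sample_ids.append(f"{c}_{r + 1}")
            conditions.append(c)

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    matrix = CountMatrix(counts)
    meta = SampleMetadata(
        pd.DataFrame({"sample_id": sample_ids, "condition": conditions})
    )
    truth = SimulationTruth(
        de_genes=pd.DataFrame(
            {
                "gene_id": gene_ids[de_idx],
                "direction": [
                    "up_in_nohelp" if i in set(up_idx) else "down_in_nohelp"
                    for i in de_idx
                ],
                "log2_fc": [
                    config.log2_fc_magnitude if i in set(up_idx)
                    else -config.log2_fc_magnitude
                    for i in de_idx
                ],
            }
        ),
        library_sizes=pd.Series(lib_sizes, index=sample_ids, name="library_size"),
    )
    return matrix, meta, truth


def simulate_query(
    centroids: Centroids,
    w: float,
    noise_sd: float,
    n_samples: int,
    seed: int,
    sample_prefix: str | None = None,
) -> ExpressionMatrix:
    """Query samples as centroid mixtures: w*no-help + (1-w)*help + noise.

    Noise is gene-wise Gaussian with sd ``noise_sd`` times the mixed
    centroid magnitude, floored at 0 so expression stays non-negative.
    The true mixture weight is recorded on the result (``true_w``).
    """
    if not (0 <= w <= 1):
        raise ValueError("w must lie in [0, 1]")
    if noise_sd < 0 or n_samples < 1:
        raise ValueError("noise_sd must be >= 0 and n_samples >= 1")
    rng = np.random.default_rng(seed)
    base = w * centroids.centroid_nohelp + (1 - w) * centroids.centroid_help
    scale = noise_sd * np.abs(base)
    values = np.maximum(
        base[:, None] + rng.normal(0.0, 1.0, (len(base), n_samples)) * scale[:, None],
        0.0,
    )
    prefix = sample_prefix or f"q_w{w:g}"
    df = pd.DataFrame(
        values,
        index=centroids.gene_ids,
        columns=[f"{prefix}_{i + 1}" for i in range(n_samples)],
    )
    expr = ExpressionMatrix(df, units=centroids.units, log2=centroids.log2)
    expr.true_w = w
    return expr


def rename_species(
    m: CountMatrix | ExpressionMatrix, prefix: str
) -> tuple[CountMatrix | ExpressionMatrix, list[GeneMapping]]:
    """Rewrite gene ids with a prefix, returning the exact one-to-one mapping.

    Fixture for the cross-species scoring path: the renamed matrix plays
    the role of an ortholog-labelled dataset, and the mapping translates
    it back.
    """
    old = [str(g) for g in m.data.index]
    new = [f"{prefix}{g}" for g in old]
    mapping = [GeneMapping(source_id=n, target_id=o) for n, o in zip(new, old)]
    df = m.data.copy()
    df.index = pd.Index(new)
    if isinstance(m, CountMatrix):
        return CountMatrix(df), mapping
    return ExpressionMatrix(df, m.units, m.log2), mapping


DEFAULT_CONFIG = SimulationConfig()
MIXTURE_WEIGHTS = (0.0, 0.25, 0.5, 0.75, 1.0)
MIXTURE_SAMPLES_PER_LEVEL = 4
MIXTURE_NOISE_SD = 0.2


def make_default_fixture(out_dir: str | Path,
                         config: SimulationConfig = DEFAULT_CONFIG) -> dict:
    """Write the standard end-to-end fixture files and return their paths.

    Contents: the reference counts/metadata with truth tables, a
    five-level mixture query panel, a renamed-species copy of that panel
    with its mapping file, and a GMT holding the true up/down DE sets.
    Deterministic: rerunning yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, meta, truth = simulate_reference(config)
    paths = {
        "ref_counts": out / "ref_counts.tsv",
        "ref_meta": out / "ref_meta.tsv",
        "truth_de": out / "truth_de_genes.tsv",
        "truth_libsizes": out / "truth_library_sizes.tsv",
        "query": out / "query_mixtures.tsv",
        "query_truth": out / "query_truth.tsv",
        "query_species": out / "query_mixtures_speciesB.tsv",
        "mapping": out / "speciesB_to_ref_mapping.tsv",
        "gmt": out / "true_de_sets.gmt",
    }
    write_counts(matrix, paths["ref_counts"])
    write_metadata(meta, paths["ref_meta"])
    truth.de_genes.to_csv(paths["truth_de"], sep="\t", index=False,
                          lineterminator="\n")
    truth.library_sizes.rename_axis("sample_id").reset_index().to_csv(
        paths["truth_libsizes"], sep="\t", index=False, lineterminator="\n"
    )

    # mixture panel over the true condition centroids (CPM scale)
    from .preprocess import cpm

    expr = cpm(matrix)
    helps = meta.samples_in(CONDITION_HELP)
    nohelps = meta.samples_in(CONDITION_NOHELP)
    centroids = Centroids(
        gene_ids=[str(g) for g in expr.data.index],
        centroid_nohelp=expr.data[nohelps].mean(axis=1).to_numpy(),
        centroid_help=expr.data[helps].mean(axis=1).to_numpy(),
    )
    panels, rows = [], []
    for i, w in enumerate(MIXTURE_WEIGHTS):
        q = simulate_query(
            centroids, w, MIXTURE_NOISE_SD, MIXTURE_SAMPLES_PER_LEVEL,
            seed=config.seed + 1000 + i,
        )
        panels.append(q.data)
        rows.extend({"sample_id": s, "true_w": w} for s in q.data.columns)
    panel = pd.concat(panels, axis=1)
    panel.index.name = "gene_id"
    panel.to_csv(paths["query"], sep="\t", lineterminator="\n",
                 float_format="%.6f")
    pd.DataFrame(rows).to_csv(paths["query_truth"], sep="\t", index=False,
                              lineterminator="\n")

    species_expr, mapping = rename_species(
        ExpressionMatrix(panel.round(6)), "spB:"
    )
    species_expr.data.index.name = "gene_id"
    species_expr.data.to_csv(paths["query_species"], sep="\t",
                             lineterminator="\n", float_format="%.6f")
    write_mapping(mapping, paths["mapping"])

    write_gmt(
        [
            GeneSet("true_up_in_nohelp", "simulated up-regulated genes",
                    frozenset(truth.up_gene_ids)),
            GeneSet("true_down_in_nohelp", "simulated down-regulated genes",
                    frozenset(truth.down_gene_ids)),
        ],
        paths["gmt"],
    )
    return {k: str(v) for k, v in paths.items()}
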