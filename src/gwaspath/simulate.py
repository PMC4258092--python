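"""Synthetic data generation and the type-I-error experiment.

Everything the pipeline consumes can be generated here: LD-structured
reference genotype panels, null or enriched case-control summary statistics
consistent with that LD, case-control cohorts with individual-level
genotypes for phenotype permutation, gene universes and GMT-style pathway
databases.

Genotype model
--------------
Each gene carries ``s`` SNPs. A haplotype is generated from a latent AR(1)
Gaussian process with within-gene correlation ``ld_rho``: SNP ``j`` carries
the minor allele when the latent value falls below the allele-frequency
quantile. A genotype is the sum of two independent haplotypes, so dosages
take values {0, 1, 2} and the latent inter-SNP correlation decays as
``rho^|i-j|`` (the realised dosage correlation is the tetrachoric-thresholded
value, smaller in magnitude). Genes sit 200 kb apart on one synthetic
chromosome with SNPs spaced 1 kb, so the 50 kb assignment window never
bridges neighbouring genes.

Effect model
------------
A causal SNP with per-allele log-odds ``effect`` shifts the mean of its
Z-statistic by the trend-test noncentrality
``delta = effect * sqrt(2 f (1 - f) * n * phi * (1 - phi))`` where ``f`` is
the allele frequency, ``n`` the total sample size and ``phi`` the case
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from .genestats import (
    adjust_genes_by_permutation,
    adjust_genes_by_simulation,
    estimate_ld,
    trend_test_pvalues,
)
from .io import (
    GeneAnnotation,
    GeneAssignment,
    GenotypePanel,
    Pathway,
    PathwayDB,
    SummaryStats,
)
from .pathways import RankedGeneUniverse, artp_test

logger = logging.getLogger("gwaspath")

GENE_SPACING = 200_000   # bp between gene starts on the synthetic chromosome
SNP_SPACING = 1_000      # bp between SNPs within a gene
MAX_SNPS_PER_GENE = 50   # keeps gene spans well inside the spacing
CHROM = "1"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    ``snps_per_gene`` is either a constant or ``("geometric", mean)``;
    geometric draws are capped at :data:`MAX_SNPS_PER_GENE`. ``effect`` is
    the per-causal-SNP per-allele log-odds shift, applied to the first
    ``causal_snps_per_gene`` SNPs of every gene in ``causal_genes``.
    """

    n_samples: int = 1_350
    n_genes: int = 2_000
    snps_per_gene: int | tuple[str, float] = ("geometric", 3.0)
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 1_000
    n_controls: int = 1_000
    effect: float = 0.0
    causal_genes: tuple[str, ...] = ()
    causal_snps_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_cases, self.n_controls) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


def gene_id(gi: int) -> str:
    return f"g{gi:05d}"


def snp_id(gi: int, si: int) -> str:
    return f"g{gi:05d}_s{si:02d}"


def snp_position(gi: int, si: int) -> int:
    return 1 + gi * GENE_SPACING + si * SNP_SPACING


def _snp_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.snps_per_gene
    if isinstance(spec, int):
        return np.full(config.n_genes, spec, dtype=int)
    kind, mean = spec
    if kind != "geometric":
        raise ValueError(f"unknown snps_per_gene spec {spec!r}")
    counts = rng.geometric(1.0 / mean, size=config.n_genes)
    return np.minimum(counts, MAX_SNPS_PER_GENE)


def _gene_mafs(counts: np.ndarray, config: SimulationConfig,
               rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = config.maf_range
    return [rng.uniform(lo, hi, size=s) for s in counts]


def _haplotypes(n_hap: int, mafs: np.ndarray, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """(n_hap, s) 0/1 alleles from the latent AR(1) threshold model."""
    s = mafs.size
    x = np.empty((n_hap, s))
    x[:, 0] = rng.standard_normal(n_hap)
    if s > 1:
        innov = rng.standard_normal((n_hap, s - 1))
        c = np.sqrt(1.0 - rho**2)
        for j in range(1, s):
            x[:, j] = rho * x[:, j - 1] + c * innov[:, j - 1]
    return (x < sps.norm.ppf(mafs)).astype(np.int8)


def _genotypes(n: int, mafs: np.ndarray, rho: float,
               rng: np.random.Generator) -> np.ndarray:
    h = _haplotypes(2 * n, mafs, rho, rng)
    return (h[:n] + h[n:]).astype(float)


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Reference genotype panel of ``n_samples`` under the latent AR(1) model.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    counts = _snp_counts(config, rng)
    mafs = _gene_mafs(counts, config, rng)
    cols, ids = [], []
    for gi, (s, f) in enumerate(zip(counts, mafs)):
        cols.append(_genotypes(config.n_samples, f, config.ld_rho, rng))
        ids.extend(snp_id(gi, si) for si in range(s))
    return GenotypePanel(
        samples=[f"ref{i:05d}" for i in range(config.n_samples)],
        snp_ids=ids,
        dosages=np.concatenate(cols, axis=1),
    )


# --- structure helpers (the generator's SNP ids encode gene membership) ----

def panel_gene_structure(panel: GenotypePanel) -> dict[str, list[str]]:
    """gene_id -> ordered SNP ids, parsed from the generator's id scheme."""
    structure: dict[str, list[str]] = {}
    for s in panel.snp_ids:
        structure.setdefault(s.split("_")[0], []).append(s)
    return structure


def assignment_from_panel(panel: GenotypePanel, window: int = 50_000) -> GeneAssignment:
    """Ground-truth SNP-to-gene assignment for a simulated panel."""
    return GeneAssignment(panel_gene_structure(panel), window=window)


def gene_annotations_for(panel: GenotypePanel) -> list[GeneAnnotation]:
    """Gene spans covering each simulated gene's SNPs (1-based closed)."""
    out = []
    for g, snps in panel_gene_structure(panel).items():
        gi = int(g[1:])
        out.append(GeneAnnotation(g, CHROM, snp_position(gi, 0),
                                  snp_position(gi, len(snps) - 1)))
    return out


def _snp_table(panel: GenotypePanel) -> pd.DataFrame:
    rows = []
    for s in panel.snp_ids:
        g, si = s.split("_")
        rows.append((s, CHROM, snp_position(int(g[1:]), int(si[1:]))))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _noncentrality(f: float, config: SimulationConfig) -> float:
    n = config.n_cases + config.n_controls
    phi = config.n_cases / n
    return config.effect * np.sqrt(2.0 * f * (1.0 - f) * n * phi * (1.0 - phi))


def simulate_summary_stats(
    config: SimulationConfig,
    panel: GenotypePanel,
    seed: int | None = None,
) -> SummaryStats:
    """Case-control summary statistics consistent with the panel's LD.

    Per gene, a Z-vector is drawn from MVN(0, Sigma) with Sigma estimated
    from the panel; causal SNPs receive the trend-test noncentrality shift.
    Two-sided P-values come from the standard normal. Deterministic for a
    fixed seed (defaults to ``config.seed + 1``).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    causal = set(config.causal_genes)
    structure = panel_gene_structure(panel)

    records = []
    for g, snps in structure.items():
        ld = estimate_ld(panel, snps)
        z = ld.cholesky() @ rng.standard_normal(len(snps))
        freqs = np.nanmean(panel.columns(snps), axis=0) / 2.0
        if g in causal and config.effect != 0.0:
            for j in range(min(config.causal_snps_per_gene, len(snps))):
                z[j] += _noncentrality(freqs[j], config)
        p = 2.0 * sps.norm.sf(np.abs(z))
        for s, zj, pj, fj in zip(snps, z, p, freqs):
            records.append((s, zj, pj, min(fj, 1 - fj)))

    df = pd.DataFrame(records, columns=["snp_id", "z", "p_value", "maf"])
    df = df.merge(_snp_table(panel), on="snp_id")
    df["call_rate"] = 1.0
    return SummaryStats(
        df[["snp_id", "chrom", "pos", "p_value", "z", "maf", "call_rate"]]
    )


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> GenotypePanel:
    """Individual-level case-control cohort with phenotype labels.

    Genotypes follow the same latent model as :func:`simulate_panel` (fresh
    draws); disease status is sampled from a logistic model whose intercept
    targets the configured case fraction, so realised case counts vary
    around the target. With ``effect = 0`` labels are independent of
    genotype (the global null).
    """
    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    n = config.n_cases + config.n_controls
    cfg_n = replace(config, n_samples=n)
    counts = _snp_counts(cfg_n, rng)
    mafs = _gene_mafs(counts, cfg_n, rng)

    cols, ids = [], []
    eta = np.full(n, logit(config.n_cases / n))
    causal = set(config.causal_genes)
    for gi, (s, f) in enumerate(zip(counts, mafs)):
        g = _genotypes(n, f, config.ld_rho, rng)
        if gene_id(gi) in causal and config.effect != 0.0:
            for j in range(min(config.causal_snps_per_gene, s)):
                eta += config.effect * (g[:, j] - 2 * f[j])
        cols.append(g)
        ids.extend(snp_id(gi, si) for si in range(s))

    y = (rng.random(n) < expit(eta)).astype(float)
    return GenotypePanel(
        samples=[f"ind{i:05d}" for i in range(n)],
        snp_ids=ids,
        dosages=np.concatenate(cols, axis=1),
        phenotypes=y,
    )


def summary_stats_from_cohort(cohort: GenotypePanel) -> SummaryStats:
    """Trend-test summary statistics for a cohort with phenotype labels."""
    if cohort.phenotypes is None:
        raise ValueError("cohort has no phenotype labels")
    p = trend_test_pvalues(cohort.dosages, cohort.phenotypes)
    df = _snp_table(cohort)
    df["p_value"] = p
    df["maf"] = np.minimum(
        np.nanmean(cohort.dosages, axis=0) / 2.0,
        1 - np.nanmean(cohort.dosages, axis=0) / 2.0,
    )
    df["call_rate"] = 1.0
    return SummaryStats(df[["snp_id", "chrom", "pos", "p_value", "maf", "call_rate"]])


# ---------------------------------------------------------------------------
# Pathway database generator
# ---------------------------------------------------------------------------

def simulate_pathway_db(
    n_pathways: int,
    size_distribution: int | tuple[str, float] | Sequence[int],
    universe: Sequence[str],
    seed: int = 0,
    planted: dict[str, Sequence[str]] | None = None,
) -> PathwayDB:
    """Random pathway database over ``universe`` (sampling without replacement).

    ``size_distribution`` is a constant, ``("geometric", mean)`` (truncated to
    [1, |universe|]; the default calibration elsewhere uses mean 17, matching
    a typical curated-database average), or an explicit size per pathway.
    ``planted`` adds pathways with the given gene sets, flagged ``planted``
    in their name.
    """
    rng = np.random.default_rng(seed)
    uni = list(universe)
    if isinstance(size_distribution, int):
        sizes = np.full(n_pathways, size_distribution, dtype=int)
    elif isinstance(size_distribution, tuple):
        kind, mean = size_distribution
        if kind != "geometric":
            raise ValueError(f"unknown size distribution {size_distribution!r}")
        sizes = np.minimum(rng.geometric(1.0 / mean, size=n_pathways), len(uni))
    else:
        sizes = np.asarray(size_distribution, dtype=int)
        if len(sizes) != n_pathways:
            raise ValueError("explicit sizes must match n_pathways")
    if np.any(sizes > len(uni)) or np.any(sizes < 1):
        raise ValueError("pathway sizes must lie in [1, |universe|]")

    pathways: dict[str, Pathway] = {}
    for i, m in enumerate(sizes):
        pid = f"pw{i:04d}"
        genes = frozenset(rng.choice(uni, size=m, replace=False))
        pathways[pid] = Pathway(pid, f"random pathway {i} (m={m})", genes)
    for pid, genes in (planted or {}).items():
        pathways[pid] = Pathway(pid, f"planted {pid}", frozenset(genes))
    return PathwayDB(pathways)


# ---------------------------------------------------------------------------
# Null-universe pipelines and the type-I-error experiment
# ---------------------------------------------------------------------------

def universe_by_simulation(
    config: SimulationConfig,
    n_sim: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene results for a null study adjusted by reference-panel simulation.

    Runs the full route: simulate a panel, draw null summary statistics
    consistent with its LD, and adjust both gene statistics by the MVN
    simulation null using the same panel.
    """
    panel = simulate_panel(config)
    stats = simulate_summary_stats(config, panel, seed=config.seed + 1)
    assignment = assignment_from_panel(panel)
    pmap = stats.table.set_index("snp_id")["p_value"]
    return adjust_genes_by_simulation(pmap, assignment, panel, n_sim=n_sim, seed=seed)


def universe_by_permutation(
    config: SimulationConfig,
    B: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene results for a null cohort adjusted by phenotype permutation."""
    cohort = simulate_cohort(config)
    assignment = assignment_from_panel(cohort)
    return adjust_genes_by_permutation(cohort, assignment, B=B, seed=seed)


def type1_error_experiment(
    universe: RankedGeneUniverse,
    pathway_size: int,
    n_random_pathways: int = 1_000,
    alpha: float = 0.05,
    test: Literal["fm", "artp"] = "fm",
    seed: int = 0,
    artp_B: int = 500,
    H_set: Sequence[int] | None = None,
) -> dict:
    """Empirical type-I error of a pathway test on random gene sets.

    Draws ``n_random_pathways`` random gene sets of ``pathway_size`` from the
    universe (without replacement within each set), computes the chosen
    pathway P-value for each, and returns the fraction below ``alpha`` with
    its binomial Monte-Carlo standard error.
    """
    K = universe.K
    m = int(pathway_size)
    if m > K:
        raise ValueError(f"pathway size {m} exceeds universe size {K}")
    rng = np.random.default_rng(seed)

    if test == "fm":
        logq = np.log(universe.q)
        keys = rng.random((n_random_pathways, K))
        subs = np.argpartition(keys, m - 1, axis=1)[:, :m]
        stat = -2.0 * logq[subs].sum(axis=1)
        pvals = sps.chi2.sf(stat, df=2 * m)
    elif test == "artp":
        gene_arr = np.asarray(universe.gene_ids)
        pvals = np.empty(n_random_pathways)
        for i in range(n_random_pathways):
            genes = gene_arr[rng.choice(K, size=m, replace=False)]
            pvals[i], _ = artp_test(universe, genes, H_set=H_set, B=artp_B, seed=rng)
    else:
        raise ValueError(f"unknown test {test!r}")

    err = float(np.mean(pvals < alpha))
    se = float(np.sqrt(alpha * (1 - alpha) / n_random_pathways))
    return {"error": err, "mc_se": se, "n": n_random_pathways,
            "pathway_size": m, "alpha": alpha, "test": test}
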