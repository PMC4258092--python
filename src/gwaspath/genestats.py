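"""Gene statistics and their null-distribution adjustment.

Two gene statistics summarise the association of all SNPs assigned to a gene:

* minimum P-value: ``min(p_1, ..., p_n)``;
* Fisher statistic: ``T = -2 * sum(log p_i)``.

Both are confounded by gene size (number of SNPs) and by linkage
disequilibrium between the SNPs, so raw statistics are converted to adjusted
P-values against a gene-specific null distribution obtained in one of two
ways:

* **phenotype permutation** — with individual-level genotypes, case-control
  labels are permuted B times and single-SNP association (1-df allelic trend
  test) is recomputed for every permutation;
* **reference-panel simulation** — with only summary statistics, Z-scores for
  the gene's SNPs are drawn repeatedly from MVN(0, Sigma) where Sigma is the
  SNP correlation (LD) matrix estimated from a reference genotype panel with
  unit diagonal, converted to two-sided P-values via the standard normal.

In both cases the adjusted P-value uses the smoothed counting estimator
``(1 + #{null at least as extreme}) / (B + 1)``, which is never zero.

Bulk results are returned as a DataFrame with columns ``gene_id``,
``n_snps``, ``stat_min_p``, ``stat_fisher``, ``adj_p_min``, ``adj_p_fisher``,
``method``, ``n_null``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneAssignment, GenotypePanel

logger = logging.getLogger("gwaspath")

#: Eigenvalue floor used when repairing non-positive-definite sample LD matrices.
PSD_FLOOR = 1e-8

GENE_RESULT_COLUMNS = [
    "gene_id", "n_snps", "stat_min_p", "stat_fisher",
    "adj_p_min", "adj_p_fisher", "method", "n_null",
]


# ---------------------------------------------------------------------------
# Raw gene statistics
# ---------------------------------------------------------------------------

def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value list (gene should not exist in the assignment)")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must be in (0, 1]")
    return p


def gene_stat_min_p(p_values: Sequence[float]) -> float:
    """Minimum P-value over the SNPs assigned to a gene."""
    return float(np.min(_check_pvalues(np.asarray(p_values))))


def gene_stat_fisher(p_values: Sequence[float]) -> float:
    """Fisher gene statistic ``-2 * sum(log p_i)`` (larger = more significant)."""
    return float(-2.0 * np.sum(np.log(_check_pvalues(np.asarray(p_values)))))


def adjust_by_permutation(
    observed_stat: float,
    null_stats: Sequence[float],
    direction: Literal["smaller_is_extreme", "larger_is_extreme"],
    smoothed: bool = True,
) -> float:
    """Empirical P-value of ``observed_stat`` against ``null_stats``.

    Returns ``(1 + c) / (B + 1)`` where ``c`` counts null statistics at least
    as extreme as the observed one (``smoothed=False`` gives the raw
    proportion ``c / B``). The minimum-P statistic uses
    ``smaller_is_extreme``; the Fisher statistic uses ``larger_is_extreme``.
    """
    null = np.asarray(null_stats, dtype=float)
    if null.size == 0:
        raise ValueError("null_stats must be nonempty")
    if direction == "smaller_is_extreme":
        c = int(np.sum(null <= observed_stat))
    elif direction == "larger_is_extreme":
        c = int(np.sum(null >= observed_stat))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if smoothed:
        return (1 + c) / (null.size + 1)
    return c / null.size


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """SNP correlation (LD) matrix with unit diagonal and a PSD-repair log."""

    snp_ids: list[str]
    corr: np.ndarray
    repair_log: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.snp_ids)

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.corr)


def _repair_psd(corr: np.ndarray, psd_floor: float) -> tuple[np.ndarray, dict]:
    """Clip eigenvalues at ``psd_floor`` and rescale back to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    log = {"min_eigenvalue": float(w.min()), "repaired": False}
    if w.min() < psd_floor:
        w_clipped = np.clip(w, psd_floor, None)
        a = (v * w_clipped) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        np.fill_diagonal(a, 1.0)
        corr = (a + a.T) / 2.0
        log.update(repaired=True,
                   n_clipped=int(np.sum(w < psd_floor)),
                   min_eigenvalue_after=float(np.linalg.eigvalsh(corr).min()))
    return corr, log


def estimate_ld(
    panel: GenotypePanel,
    snp_ids: Sequence[str],
    psd_floor: float = PSD_FLOOR,
) -> LdMatrix:
    """Pairwise Pearson correlation of panel dosages for ``snp_ids``.

    Missing dosages are handled pairwise-complete; a monomorphic SNP has
    undefined correlations, which are set to 0 with a warning. The diagonal
    is forced to 1 and, when the smallest eigenvalue of the sample matrix
    falls below ``psd_floor``, eigenvalues are clipped at the floor and the
    matrix rescaled to unit diagonal (logged in ``repair_log``).
    """
    if panel.n_samples < 2:
        raise ValueError("need >=2 samples to estimate LD")
    d = panel.columns(snp_ids)
    if np.isnan(d).any():
        corr = pd.DataFrame(d).corr(min_periods=2).to_numpy()  # pairwise complete
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(d, rowvar=False)
        corr = np.atleast_2d(corr)

    undefined = np.isnan(corr)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        mono = sorted({snp_ids[i] for i in np.unique(np.nonzero(undefined)[0])})
        logger.warning("estimate_ld: undefined correlations (monomorphic or no "
                       "overlap) set to 0 for SNPs %s", mono[:5])
        corr[undefined] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0

    corr, log = _repair_psd(corr, psd_floor)
    if log["repaired"]:
        logger.info("estimate_ld: PSD repair for %d SNPs (min eigenvalue %.3g)",
                    len(snp_ids), log["min_eigenvalue"])
    return LdMatrix(list(snp_ids), corr, log)


# ---------------------------------------------------------------------------
# Reference-panel MVN simulation adjustment
# ---------------------------------------------------------------------------

def _simulate_null_stats(
    chol: np.ndarray, n_sim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Null (min-P, Fisher) statistics from MVN(0, Sigma) Z-score draws.

    Two-sided P-values are computed on the log scale
    (``log p = log 2 + log Phi(-|z|)``) so the Fisher statistic keeps full
    precision for extreme draws.
    """
    m = chol.shape[0]
    z = rng.standard_normal((n_sim, m)) @ chol.T
    logp = np.log(2.0) + sps.norm.logsf(np.abs(z))
    null_min = np.exp(logp.min(axis=1))
    null_fisher = -2.0 * logp.sum(axis=1)
    return null_min, null_fisher


def adjust_by_simulation(
    p_values: Sequence[float],
    ld: LdMatrix,
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Adjusted (min-P, Fisher) gene P-values via the reference-panel MVN null.

    Draws ``n_sim`` replicates of Z ~ MVN(0, Sigma) with Sigma the repaired
    LD matrix, converts each Z to a two-sided P against Normal(0, 1),
    computes both gene statistics per replicate, and applies the smoothed
    counting rule with B = ``n_sim``. Invariant to the order of SNPs.
    """
    p = _check_pvalues(np.asarray(p_values))
    if len(p) != ld.n:
        raise ValueError(f"{len(p)} P-values but LD matrix has {ld.n} SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    null_min, null_fisher = _simulate_null_stats(ld.cholesky(), n_sim, rng)
    obs_min = gene_stat_min_p(p)
    obs_fisher = gene_stat_fisher(p)
    adj_min = adjust_by_permutation(obs_min, null_min, "smaller_is_extreme")
    adj_fisher = adjust_by_permutation(obs_fisher, null_fisher, "larger_is_extreme")
    return adj_min, adj_fisher


def adjust_genes_by_simulation(
    stats_p: pd.Series | dict[str, float],
    assignment: GeneAssignment,
    panel: GenotypePanel,
    n_sim: int = 10_000,
    seed: int = 0,
    psd_floor: float = PSD_FLOOR,
) -> pd.DataFrame:
    """Simulation-adjusted gene results for every gene in ``assignment``.

    ``stats_p`` maps snp_id -> observed P-value (e.g.
    ``summary.table.set_index("snp_id")["p_value"]``). Only SNPs present in
    both the assignment and the panel enter each gene's statistic; genes with
    no shared SNPs are dropped with a warning.
    """
    if isinstance(stats_p, pd.Series):
        stats_p = stats_p.to_dict()
    panel_snps = set(panel.snp_ids)
    rng = np.random.default_rng(seed)

    rows = []
    dropped = []
    for gene_id, snp_ids in assignment.mapping.items():
        shared = [s for s in snp_ids if s in stats_p and s in panel_snps]
        if not shared:
            dropped.append(gene_id)
            continue
        p = np.array([stats_p[s] for s in shared])
        ld = estimate_ld(panel, shared, psd_floor=psd_floor)
        adj_min, adj_fisher = adjust_by_simulation(p, ld, n_sim=n_sim, seed=rng)
        rows.append((gene_id, len(shared), gene_stat_min_p(p), gene_stat_fisher(p),
                     adj_min, adj_fisher, "simulation", n_sim))
    if dropped:
        logger.warning("adjust_genes_by_simulation: %d gene(s) had no SNPs shared "
                       "with the panel and were dropped", len(dropped))
    return pd.DataFrame(rows, columns=GENE_RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Phenotype permutation adjustment
# ---------------------------------------------------------------------------

def trend_test_pvalues(dosages: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Two-sided P-values of the 1-df allelic trend test, one per SNP column.

    The Armitage trend chi-square equals ``n * r^2`` with ``r`` the Pearson
    correlation between dosage and the 0/1 phenotype. Missing dosages are
    mean-imputed; a constant dosage column yields P = 1 with a warning.
    """
    y = np.asarray(phenotypes, dtype=float)
    p, _ = _trend_matrix(np.asarray(dosages, dtype=float), y[:, None])
    return p[:, 0]


def _trend_matrix(g: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trend-test P-values for every (SNP column, phenotype column) pair.

    Returns (P, constant_mask): P has shape (n_snps, n_phenotype_columns);
    constant SNPs get P = 1 everywhere.
    """
    n = g.shape[0]
    g = g.copy()
    col_mean = np.nanmean(g, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(g))
    g[nan_r, nan_c] = col_mean[nan_c]
    g -= g.mean(axis=0)
    sd_g = g.std(axis=0)
    constant = sd_g == 0
    if constant.any():
        logger.warning("trend test: %d constant genotype column(s); P set to 1",
                       int(constant.sum()))
        sd_g[constant] = 1.0
    g /= sd_g

    y = ys - ys.mean(axis=0)
    sd_y = y.std(axis=0)
    if np.any(sd_y == 0):
        raise ValueError("phenotype is constant")
    y = y / sd_y

    r = (g.T @ y) / n
    chi2 = n * r**2
    p = sps.chi2.sf(chi2, df=1)
    p[constant, :] = 1.0
    return p, constant


def _gene_blocks(
    assignment: GeneAssignment, snp_index: dict[str, int]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Flatten the assignment into (gene ids, concatenated SNP indices, block starts)."""
    gene_ids, idx, starts = [], [], []
    pos = 0
    for gene_id, snp_ids in assignment.mapping.items():
        cols = [snp_index[s] for s in snp_ids if s in snp_index]
        if not cols:
            continue
        gene_ids.append(gene_id)
        starts.append(pos)
        idx.extend(cols)
        pos += len(cols)
    return gene_ids, np.asarray(idx, dtype=np.intp), np.asarray(starts, dtype=np.intp)


def run_phenotype_permutation(
    panel: GenotypePanel,
    assignment: GeneAssignment,
    B: int,
    seed: int = 0,
    phenotypes: np.ndarray | None = None,
) -> dict:
    """Observed and permutation-null gene statistics from individual-level data.

    Permutes the case-control labels ``B`` times, recomputes the 1-df trend
    test for every SNP under every permutation, and records both gene
    statistics. Reproducible under a fixed seed.

    Returns a dict with ``gene_ids``, ``n_snps``, ``obs_min``, ``obs_fisher``
    (arrays of length G) and ``null_min``, ``null_fisher`` (G x B matrices).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = panel.phenotypes if phenotypes is None else np.asarray(phenotypes)
    if y is None:
        raise ValueError("panel has no phenotypes and none were supplied")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    ys = np.empty((panel.n_samples, B + 1))
    ys[:, 0] = y
    for b in range(1, B + 1):
        ys[:, b] = rng.permutation(y)

    p, _ = _trend_matrix(panel.dosages, ys)  # (S, B+1)

    snp_index = {s: i for i, s in enumerate(panel.snp_ids)}
    gene_ids, idx, starts = _gene_blocks(assignment, snp_index)
    logp = np.log(p[idx, :])
    min_p = np.exp(np.minimum.reduceat(logp, starts, axis=0))
    fisher = -2.0 * np.add.reduceat(logp, starts, axis=0)
    n_snps = np.diff(np.append(starts, len(idx)))

    return {
        "gene_ids": gene_ids,
        "n_snps": n_snps,
        "obs_min": min_p[:, 0],
        "obs_fisher": fisher[:, 0],
        "null_min": min_p[:, 1:],
        "null_fisher": fisher[:, 1:],
    }


def adjust_genes_by_permutation(
    panel: GenotypePanel,
    assignment: GeneAssignment,
    B: int = 1_000,
    seed: int = 0,
    phenotypes: np.ndarray | None = None,
    smoothed: bool = True,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Permutation-adjusted gene results for every gene in ``assignment``.

    ``cache_dir``, when given, stores the null-replicate matrices in a binary
    sidecar keyed by (gene-set hash, B, seed) so reruns skip the permutation
    engine.
    """
    null = None
    cache_path = None
    if cache_dir is not None:
        key = hashlib.sha256(
            ("|".join(f"{g}:{','.join(s)}" for g, s in sorted(assignment.mapping.items()))
             + f"|B={B}|seed={seed}").encode()
        ).hexdigest()[:16]
        cache_path = Path(cache_dir) / f"permnull_{key}.npz"
        if cache_path.exists():
            data = np.load(cache_path, allow_pickle=False)
            null = {k: data[k] for k in data.files}
            null["gene_ids"] = [str(g) for g in null["gene_ids"]]
            logger.info("permutation null loaded from cache %s", cache_path)
    if null is None:
        null = run_phenotype_permutation(panel, assignment, B=B, seed=seed,
                                         phenotypes=phenotypes)
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(cache_path,
                                **{k: (np.array(v) if k == "gene_ids" else v)
                                   for k, v in null.items()})

    adj_min = np.array([
        adjust_by_permutation(o, row, "smaller_is_extreme", smoothed=smoothed)
        for o, row in zip(null["obs_min"], null["null_min"])
    ])
    adj_fisher = np.array([
        adjust_by_permutation(o, row, "larger_is_extreme", smoothed=smoothed)
        for o, row in zip(null["obs_fisher"], null["null_fisher"])
    ])
    return pd.DataFrame({
        "gene_id": null["gene_ids"],
        "n_snps": np.asarray(null["n_snps"], dtype=int),
        "stat_min_p": null["obs_min"],
        "stat_fisher": null["obs_fisher"],
        "adj_p_min": adj_min,
        "adj_p_fisher": adj_fisher,
        "method": "permutation",
        "n_null": B,
    })[GENE_RESULT_COLUMNS]
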