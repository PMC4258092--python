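"""Competitive pathway enrichment tests.

The competitive null states that pathway genes are no more associated than
non-pathway genes. Genes are ranked by their adjusted P-value and each gene
receives the statistic ``q = rank / K`` (K = number of genes in the study,
average ranks for ties), which is Uniform(0, 1) under the null.

* **Fisher's method (FM)** — ``-2 * sum(log q_g)`` over the pathway's m
  genes, compared with its exact chi-square distribution with 2m df.
* **Adaptive rank truncated product (ARTP)** — the product ``W(H)`` of the H
  smallest pathway q-statistics, minimised over candidate truncation points
  H, calibrated against an empirical null of random gene sets drawn from the
  universe; the minimum-over-H layer is calibrated on the same replicate pool
  (no nested simulation).

Benjamini-Hochberg FDR is applied across pathways within each method column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import PathwayDB

logger = logging.getLogger("gwaspath")

PATHWAY_RESULT_COLUMNS = [
    "pathway_id", "name", "m", "fm_stat", "fm_p", "fdr_fm",
    "artp_p", "best_H", "fdr_artp",
]


@dataclass
class RankedGeneUniverse:
    """Genes of the study with their rank-based competitive statistics.

    ``q[i]`` is the (average, for ties) ascending rank of gene ``gene_ids[i]``
    divided by K; the most associated gene has the smallest q and max(q) <= 1.
    """

    gene_ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if len(self.gene_ids) != self.q.size:
            raise ValueError("gene_ids and q differ in length")
        if self.q.size and (self.q.max() > 1.0 + 1e-12 or self.q.min() <= 0.0):
            raise ValueError("q statistics must lie in (0, 1]")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def K(self) -> int:
        return self.q.size

    def q_for(self, genes: Iterable[str]) -> np.ndarray:
        """q-statistics for the subset of ``genes`` present in the universe."""
        idx = [self._index[g] for g in genes if g in self._index]
        return self.q[idx]


def rank_genes(
    gene_results: pd.DataFrame,
    which: Literal["min_p", "fisher"] = "min_p",
) -> RankedGeneUniverse:
    """Rank genes ascending by adjusted P-value and return q = rank / K.

    ``which`` selects the adjusted column (``adj_p_min`` or ``adj_p_fisher``).
    Ties receive average ranks; the result is invariant to input order.
    """
    col = {"min_p": "adj_p_min", "fisher": "adj_p_fisher"}[which]
    if len(gene_results) < 2:
        raise ValueError("need K >= 2 genes")
    p = gene_results[col].to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError(f"{col} contains missing values")
    ranks = sps.rankdata(p, method="average")
    return RankedGeneUniverse(gene_results["gene_id"].tolist(), ranks / p.size)


# ---------------------------------------------------------------------------
# Fisher's method
# ---------------------------------------------------------------------------

def fm_test(universe: RankedGeneUniverse, pathway_genes: Iterable[str]) -> tuple[float, float]:
    """FM statistic and its exact chi-square(2m) upper-tail P-value.

    m counts the pathway genes present in the universe; an empty intersection
    is an error (callers drop such pathways with a warning).
    """
    q = universe.q_for(pathway_genes)
    if q.size == 0:
        raise ValueError("pathway has no genes in the universe")
    stat = float(-2.0 * np.sum(np.log(q)))
    return stat, float(sps.chi2.sf(stat, df=2 * q.size))


# ---------------------------------------------------------------------------
# Adaptive rank truncated product
# ---------------------------------------------------------------------------

def _sample_subsets(rng: np.random.Generator, B: int, K: int, m: int) -> np.ndarray:
    """B random m-subsets of {0..K-1} without replacement, as a (B, m) array."""
    keys = rng.random((B, K))
    return np.argpartition(keys, m - 1, axis=1)[:, :m]


def artp_test(
    universe: RankedGeneUniverse,
    pathway_genes: Iterable[str],
    H_set: Sequence[int] | None = None,
    B: int = 1_000,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
) -> tuple[float, int]:
    """ARTP P-value and the selected truncation point.

    The rank truncated product ``W(H)`` multiplies the H smallest pathway
    q-statistics; for each H in ``H_set`` an empirical P-value is computed
    against B competitive-null replicates (random m-subsets of the universe,
    without replacement unless ``replace``). The ARTP statistic is the
    minimum of these per-H P-values; its own P-value is calibrated on the
    same replicate pool by ranking each replicate's minimum alongside the
    observed one.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    q_obs = np.sort(universe.q_for(pathway_genes))
    m = q_obs.size
    if m == 0:
        raise ValueError("pathway has no genes in the universe")
    if H_set is None:
        H_set = list(range(1, min(m, 10) + 1))
    H_use = [h for h in H_set if 1 <= h <= m]
    if len(H_use) < len(H_set):
        logger.warning("artp_test: dropped truncation points > m=%d from H_set", m)
    if not H_use:
        raise ValueError("no valid truncation points")
    h_idx = np.asarray(H_use, dtype=int) - 1

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if replace:
        subs = rng.integers(0, universe.K, size=(B, m))
    else:
        subs = _sample_subsets(rng, B, universe.K, m)
    q_null = np.sort(universe.q[subs], axis=1)

    # log W(H) for the observed pathway (row 0) and every null replicate.
    logw = np.cumsum(np.log(np.vstack([q_obs, q_null])), axis=1)[:, h_idx]

    # Per-H empirical P by within-pool ranking: smaller W is more extreme.
    # rank "max" counts entries <= self, i.e. 1 + #{others at least as extreme}.
    p_h = np.apply_along_axis(lambda c: sps.rankdata(c, method="max"), 0, logw) / (B + 1)
    s = p_h.min(axis=1)
    best_H = int(np.asarray(H_use)[np.argmin(p_h[0])])
    artp_p = float((1 + np.sum(s[1:] <= s[0])) / (B + 1))
    return artp_p, best_H


# ---------------------------------------------------------------------------
# FDR and the analysis driver
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value list")
    return multipletests(p, method="fdr_bh")[1]


def run_pathway_analysis(
    gene_results: pd.DataFrame,
    pathway_db: PathwayDB,
    which: Literal["min_p", "fisher"] = "min_p",
    do_artp: bool = True,
    H_set: Sequence[int] | None = None,
    B: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """FM (and optionally ARTP) enrichment for every pathway with m >= 1.

    Pathways are intersected with the gene universe before their size m is
    fixed; empty pathways are dropped with a warning. FDR is computed down
    each P-value column. Returns one row per pathway.
    """
    universe = rank_genes(gene_results, which=which)
    db = pathway_db.intersect_universe(universe.gene_ids)
    rng = np.random.default_rng(seed)

    rows = []
    for pw in db:
        fm_stat, fm_p = fm_test(universe, pw.genes)
        if do_artp:
            artp_p, best_H = artp_test(universe, pw.genes, H_set=H_set, B=B, seed=rng)
        else:
            artp_p, best_H = np.nan, 0
        rows.append((pw.pathway_id, pw.name, len(pw.genes), fm_stat, fm_p,
                     np.nan, artp_p, best_H, np.nan))
    out = pd.DataFrame(rows, columns=PATHWAY_RESULT_COLUMNS)
    if len(out):
        out["fdr_fm"] = bh_fdr(out["fm_p"])
        if do_artp:
            out["fdr_artp"] = bh_fdr(out["artp_p"])
    return out


#: The eight method variants: pathway test x gene statistic x null procedure.
METHOD_GRID = [
    "FM-(MIN)", "FM-(FM)", "FM-(MIN_S)", "FM-(FM_S)",
    "ARTP-(MIN)", "ARTP-(FM)", "ARTP-(MIN_S)", "ARTP-(FM_S)",
]


def parse_method(name: str) -> tuple[str, str, str]:
    """Split a grid name into (pathway test, gene statistic, procedure).

    ``FM-(MIN_S)`` -> ("fm", "min_p", "simulation"); the ``_S`` suffix marks
    the reference-panel simulation null, its absence phenotype permutation.
    """
    name = name.strip()
    test, _, rest = name.partition("-")
    if test not in {"FM", "ARTP"} or not (rest.startswith("(") and rest.endswith(")")):
        raise ValueError(f"unknown method name {name!r}")
    inner = rest[1:-1]
    procedure = "simulation" if inner.endswith("_S") else "permutation"
    stat = inner[:-2] if inner.endswith("_S") else inner
    if stat not in {"MIN", "FM"}:
        raise ValueError(f"unknown gene statistic in {name!r}")
    return test.lower(), {"MIN": "min_p", "FM": "fisher"}[stat], procedure


def run_method_grid(
    gene_results_by_procedure: dict[str, pd.DataFrame],
    pathway_db: PathwayDB,
    methods: Sequence[str] = tuple(METHOD_GRID),
    H_set: Sequence[int] | None = None,
    B: int = 1_000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the requested method variants and return one result table per name.

    ``gene_results_by_procedure`` maps "permutation"/"simulation" to the
    corresponding adjusted gene results (only procedures actually requested
    need to be present).
    """
    out: dict[str, pd.DataFrame] = {}
    for name in methods:
        test, which, procedure = parse_method(name)
        if procedure not in gene_results_by_procedure:
            raise ValueError(f"method {name!r} needs {procedure}-adjusted gene results")
        res = run_pathway_analysis(
            gene_results_by_procedure[procedure], pathway_db, which=which,
            do_artp=(test == "artp"), H_set=H_set, B=B, seed=seed,
        )
        if test == "artp":
            res = res.drop(columns=["fm_stat", "fm_p", "fdr_fm"])
        else:
            res = res.drop(columns=["artp_p", "best_H", "fdr_artp"])
        out[name] = res
    return out


def grid_concordance(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Spearman correlations of pathway P-values across method variants."""
    pcols = {}
    for name, df in results.items():
        col = "fm_p" if "fm_p" in df.columns else "artp_p"
        pcols[name] = df.set_index("pathway_id")[col]
    names = list(pcols)
    rows = []
    for i, a in enumerate(names):
        for b_name in names[i + 1:]:
            joined = pd.concat([pcols[a], pcols[b_name]], axis=1, join="inner")
            rho = sps.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
            rows.append((a, b_name, rho))
    return pd.DataFrame(rows, columns=["method_a", "method_b", "spearman_rho"])
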