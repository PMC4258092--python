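"""SNP prioritization from enriched pathways and replication meta-analysis.

Enriched pathways (FDR below a threshold) raise the prior for association of
their member genes, so each such gene whose best SNP passes a discovery
P-value threshold — and which is not an already-established locus — yields a
candidate SNP. Candidates are then tested in additional cohorts: per-SNP
effect estimates are combined by fixed-effect inverse-variance meta-analysis,
and discovery and replication evidence are combined with Fisher's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneAssignment, PathwayDB, SummaryStats, normalize_chrom

logger = logging.getLogger("gwaspath")


@dataclass
class CandidateSnp:
    """A prioritized SNP with its discovery/replication/combined evidence."""

    snp_id: str
    gene_ids: list[str]
    discovery_p: float
    pathway_ids: list[str]
    replication_p: float | None = None
    combined_p: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.pathway_ids:
            raise ValueError(f"{self.snp_id}: pathway_ids must be nonempty")


@dataclass
class KnownLoci:
    """Established loci to exclude: gene ids and/or genomic regions.

    ``regions`` entries are (chrom, start, end, label), 1-based closed. When
    regions carry coordinates, candidates get a note recording the distance
    to the nearest known locus.
    """

    gene_ids: frozenset[str] = frozenset()
    regions: list[tuple[str, int, int, str]] = field(default_factory=list)

    def excludes_gene(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def excludes_snp(self, chrom: str, pos: int) -> bool:
        c = normalize_chrom(chrom)
        return any(normalize_chrom(rc) == c and s <= pos <= e
                   for rc, s, e, _ in self.regions)

    def nearest(self, chrom: str, pos: int) -> str:
        c = normalize_chrom(chrom)
        best = None
        for rc, s, e, label in self.regions:
            if normalize_chrom(rc) != c:
                continue
            dist = 0 if s <= pos <= e else min(abs(pos - s), abs(pos - e))
            if best is None or dist < best[0]:
                best = (dist, label)
        if best is None:
            return ""
        return f"nearest known locus {best[1]} at {best[0]} bp"


def best_snp_per_gene(stats: SummaryStats, assignment: GeneAssignment) -> pd.DataFrame:
    """Most significant SNP (and its P) within each gene's assigned SNPs."""
    p = stats.table.set_index("snp_id")["p_value"]
    rows = []
    for gene_id, snp_ids in assignment.mapping.items():
        sub = p.reindex(snp_ids).dropna()
        if sub.empty:
            continue
        best = sub.idxmin()
        rows.append((gene_id, best, float(sub.loc[best])))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "p_value"])


def select_candidates(
    pathway_results: pd.DataFrame,
    gene_best: pd.DataFrame,
    pathway_db: PathwayDB,
    fdr_max: float = 0.05,
    snp_p_min: float = 1e-4,
    known_loci: KnownLoci | Iterable[str] | None = None,
    fdr_column: str = "fdr_fm",
    snp_positions: pd.DataFrame | None = None,
) -> list[CandidateSnp]:
    """Candidate SNPs from genes of enriched pathways.

    A gene in any pathway with ``fdr_column <= fdr_max`` is selected when its
    best SNP's discovery P-value is below ``snp_p_min`` and the gene (or the
    SNP's position) is not on the ``known_loci`` exclusion list. The best SNP
    of each selected gene is emitted; a SNP shared by several selected genes
    appears once with all gene ids attached. Output order is deterministic
    (sorted by snp_id) and independent of pathway or gene input order.

    ``snp_positions`` (columns snp_id, chrom, pos) enables region-based
    exclusion and the nearest-locus note.
    """
    if known_loci is None:
        known_loci = KnownLoci()
    elif not isinstance(known_loci, KnownLoci):
        known_loci = KnownLoci(gene_ids=frozenset(known_loci))

    enriched = pathway_results.loc[
        pathway_results[fdr_column] <= fdr_max, "pathway_id"
    ].tolist()
    gene_to_pathways: dict[str, set[str]] = {}
    for pid in enriched:
        for g in pathway_db.pathways[pid].genes:
            gene_to_pathways.setdefault(g, set()).add(pid)

    pos_lookup = None
    if snp_positions is not None:
        pos_lookup = snp_positions.set_index("snp_id")[["chrom", "pos"]]

    by_snp: dict[str, dict] = {}
    for row in gene_best.itertuples(index=False):
        pathways = gene_to_pathways.get(row.gene_id)
        if not pathways or row.p_value >= snp_p_min:
            continue
        if known_loci.excludes_gene(row.gene_id):
            continue
        note = ""
        if pos_lookup is not None and row.snp_id in pos_lookup.index:
            chrom, pos = pos_lookup.loc[row.snp_id]
            if known_loci.excludes_snp(str(chrom), int(pos)):
                continue
            note = known_loci.nearest(str(chrom), int(pos))
        entry = by_snp.setdefault(row.snp_id, {
            "genes": set(), "pathways": set(), "p": row.p_value, "note": note,
        })
        entry["genes"].add(row.gene_id)
        entry["pathways"].update(pathways)

    return [
        CandidateSnp(
            snp_id=snp,
            gene_ids=sorted(e["genes"]),
            discovery_p=e["p"],
            pathway_ids=sorted(e["pathways"]),
            note=e["note"],
        )
        for snp, e in sorted(by_snp.items())
    ]


def ivw_meta(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, float, float]:
    """Fixed-effect inverse-variance meta-analysis.

    Returns (beta, se, z, two-sided P). Weights are 1/se^2; a single study is
    returned unchanged (up to the derived z and P).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.size == 0:
        raise ValueError("betas and ses must be equal-length and nonempty")
    if np.any(s <= 0):
        raise ValueError("standard errors must be > 0")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return beta, se, float(z), p


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher combination of independent P-values: chi-square(2k) upper tail."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must be nonempty and in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x, df=2 * p.size))


def meta_analyze_replication(
    candidates: list[CandidateSnp],
    replication: pd.DataFrame,
) -> list[CandidateSnp]:
    """Fill in replication and combined P-values from per-cohort effects.

    ``replication`` needs columns snp_id, cohort, beta, se (one row per SNP
    per cohort; family cohorts must be pre-reduced to a beta/se pair). The
    replication P is the IVW meta-analysis of the cohorts; the combined P is
    the Fisher combination of discovery and replication P-values. Candidates
    without replication data are left untouched.
    """
    grouped = replication.groupby("snp_id")
    out = []
    for c in candidates:
        if c.snp_id in grouped.groups:
            sub = grouped.get_group(c.snp_id)
            _, _, _, rep_p = ivw_meta(sub["beta"].to_numpy(), sub["se"].to_numpy())
            comb = fisher_combine([c.discovery_p, rep_p])
            c = CandidateSnp(c.snp_id, c.gene_ids, c.discovery_p, c.pathway_ids,
                             replication_p=rep_p, combined_p=comb, note=c.note)
        out.append(c)
    return out


def replication_summary(
    candidates: Sequence[CandidateSnp] | pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[int, int, float]:
    """Count replicated candidates and the chance of that count.

    Counts unique SNPs carrying a replication P-value, those below ``alpha``,
    and the exact binomial tail P(X >= n_replicated) for
    X ~ Binomial(n_tested, alpha). SNPs shared by two genes are counted once.
    """
    if isinstance(candidates, pd.DataFrame):
        df = candidates[["snp_id", "replication_p"]]
    else:
        df = pd.DataFrame(
            [(c.snp_id, c.replication_p) for c in candidates],
            columns=["snp_id", "replication_p"],
        )
    df = df.dropna(subset=["replication_p"]).drop_duplicates("snp_id")
    n_tested = len(df)
    n_replicated = int((df["replication_p"] < alpha).sum())
    if n_tested == 0:
        return 0, 0, 1.0
    tail = float(sps.binom.sf(n_replicated - 1, n_tested, alpha))
    return n_tested, n_replicated, tail


def load_t1d_replication() -> pd.DataFrame:
    """Bundled replication P-values of the 22 T1D candidate SNPs (worked example)."""
    from importlib.resources import files

    path = files("gwaspath.data").joinpath("t1d_replication.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def candidates_to_frame(candidates: Sequence[CandidateSnp]) -> pd.DataFrame:
    """Candidate table with one row per SNP (gene/pathway ids comma-joined)."""
    return pd.DataFrame([
        {
            "snp_id": c.snp_id,
            "gene_ids": ",".join(c.gene_ids),
            "discovery_p": c.discovery_p,
            "replication_p": c.replication_p,
            "combined_p": c.combined_p,
            "pathway_ids": ",".join(c.pathway_ids),
            "note": c.note,
        }
        for c in candidates
    ])
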