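"""Domain types, file readers/writers, QC filtering and SNP-to-gene assignment.

Conventions
-----------
* Genomic coordinates are 1-based with closed intervals throughout; BED input
  (0-based, half-open) is converted on read and the conversion is logged.
* Chromosome names are normalised by stripping a leading ``chr``/``Chr`` so
  that ``chr6`` and ``6`` compare equal.
* Summary statistics live in a :class:`SummaryStats` wrapper around a pandas
  DataFrame with canonical column names (``snp_id``, ``chrom``, ``pos``,
  ``allele_ref``, ``allele_alt``, ``p_value`` plus optional ``beta_<cohort>``,
  ``se_<cohort>``, ``maf``, ``call_rate``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("gwaspath")

#: Extended MHC region excluded from pathway analysis (chrom, start, end; 1-based closed).
MHC_REGION = ("6", 25_000_000, 35_000_000)

#: Smallest positive normal double; optional floor for P-values of exactly 0.
P_FLOOR = np.finfo(float).tiny


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """A single SNP's association result."""

    snp_id: str
    chrom: str
    pos: int
    allele_ref: str | None = None
    allele_alt: str | None = None
    p_value: float = np.nan
    beta: float | None = None
    se: float | None = None
    maf: float | None = None
    call_rate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")


@dataclass
class SummaryStats:
    """Per-SNP association results for one or more cohorts.

    ``table`` holds one row per SNP with canonical columns; ``cohorts`` lists
    cohort labels for which ``beta_<label>`` / ``se_<label>`` columns exist
    (empty when only P-values are available).
    """

    table: pd.DataFrame
    cohorts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "p_value"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"SummaryStats table missing columns: {sorted(missing)}")
        dup = self.table["snp_id"][self.table["snp_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate snp_id values: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def records(self) -> Iterable[SnpRecord]:
        for row in self.table.itertuples(index=False):
            yield SnpRecord(
                snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos),
                allele_ref=getattr(row, "allele_ref", None),
                allele_alt=getattr(row, "allele_alt", None),
                p_value=float(row.p_value),
                maf=getattr(row, "maf", None),
                call_rate=getattr(row, "call_rate", None),
            )

    def subset(self, keep: pd.Series | np.ndarray) -> "SummaryStats":
        return SummaryStats(self.table.loc[keep].reset_index(drop=True), list(self.cohorts))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's genomic span (1-based, closed)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GeneAssignment:
    """Many-to-many SNP-to-gene map from the positional window rule.

    ``mapping`` is gene_id -> position-ordered list of snp_id; genes with no
    assigned SNPs are absent.
    """

    mapping: dict[str, list[str]]
    window: int = 50_000

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mapping)

    def n_snps(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.mapping.items()}


@dataclass
class GenotypePanel:
    """Reference sample x SNP dosage matrix, used only for LD estimation.

    ``dosages`` is a float array of shape (n_samples, n_snps) with values in
    {0, 1, 2} and NaN for missing calls. ``phenotypes`` (optional 0/1 array)
    is populated for case-control cohorts used in phenotype permutation.
    """

    samples: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    phenotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_ids)} SNPs"
            )
        all_missing = np.all(np.isnan(self.dosages), axis=0)
        if all_missing.any():
            bad = [self.snp_ids[i] for i in np.flatnonzero(all_missing)]
            raise ValueError(f"SNP columns entirely missing: {bad}")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Dosage submatrix for ``snp_ids``, in that order."""
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in panel") from None
        return self.dosages[:, idx]


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]


@dataclass
class PathwayDB:
    """Collection of gene sets keyed by pathway id."""

    pathways: dict[str, Pathway]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def intersect_universe(self, universe: Iterable[str]) -> "PathwayDB":
        """Restrict every pathway to genes present in ``universe``.

        Pathways left empty are dropped with a logged warning; the remaining
        sizes are the per-study sizes used by the tests.
        """
        uni = set(universe)
        kept: dict[str, Pathway] = {}
        dropped = []
        for pw in self.pathways.values():
            genes = pw.genes & uni
            if genes:
                kept[pw.pathway_id] = Pathway(pw.pathway_id, pw.name, frozenset(genes))
            else:
                dropped.append(pw.pathway_id)
        if dropped:
            logger.warning(
                "%d pathway(s) dropped: no genes in the study universe (%s%s)",
                len(dropped), ", ".join(dropped[:5]), "..." if len(dropped) > 5 else "",
            )
        return PathwayDB(kept)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_DEFAULT_DIALECT = {
    "snp": "snp", "chrom": "chrom", "pos": "pos", "p": "p",
    "ref": "ref", "alt": "alt", "maf": "maf", "call_rate": "call_rate",
}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    floor_p: bool = False,
) -> SummaryStats:
    """Read per-SNP summary statistics from a delimited text file.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    dialect
        Map from logical names (``snp``, ``chrom``, ``pos``, ``p``, optionally
        ``ref``, ``alt``, ``maf``, ``call_rate``) to the column names used in
        the file. Per-cohort effect columns are discovered automatically from
        headers of the form ``beta_<cohort>`` / ``se_<cohort>``.
    floor_p
        When True, P-values of exactly 0 are floored to the smallest positive
        normal double instead of being rejected. Off by default: a zero
        P-value usually signals an upstream formatting problem.
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={d["snp"]: str, d["chrom"]: str})

    for logical in ("snp", "chrom", "pos", "p"):
        if d[logical] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {d[logical]!r} (for {logical!r})"
            )

    rename = {d["snp"]: "snp_id", d["chrom"]: "chrom", d["pos"]: "pos", d["p"]: "p_value"}
    for logical, canon in (("ref", "allele_ref"), ("alt", "allele_alt"),
                           ("maf", "maf"), ("call_rate", "call_rate")):
        if d.get(logical) in df.columns:
            rename[d[logical]] = canon
    df = df.rename(columns=rename)

    cohorts = sorted(
        c[len("beta_"):] for c in df.columns
        if c.startswith("beta_") and f"se_{c[len('beta_'):]}" in df.columns
    )

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    if floor_p:
        df.loc[df["p_value"] == 0.0, "p_value"] = P_FLOOR

    ok = (
        df["pos"].notna() & (df["pos"] >= 1)
        & df["p_value"].notna() & (df["p_value"] > 0) & (df["p_value"] <= 1)
    )
    if not ok.all():
        bad_rows = [i + 2 for i in np.flatnonzero(~ok.to_numpy())]  # 1-based + header
        logger.warning(
            "%s: rejected %d row(s) with non-numeric or out-of-range pos/P "
            "(file line numbers %s%s)",
            path, len(bad_rows), bad_rows[:10], "..." if len(bad_rows) > 10 else "",
        )
        df = df[ok]

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)

    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate snp_id values: {sorted(set(dup))}")
    return SummaryStats(df, cohorts)


def read_gene_annotation(path: str | Path, zero_based: bool = True) -> list[GeneAnnotation]:
    """Read gene spans from a BED-like TSV (chrom, start, end, gene_id).

    ``zero_based=True`` (the BED convention: 0-based, half-open) converts to
    the internal 1-based closed convention by adding 1 to start.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    offset = 1 if zero_based else 0
    if zero_based:
        logger.info("%s: converting BED 0-based half-open spans to 1-based closed", path)
    return [
        GeneAnnotation(r.gene_id, normalize_chrom(r.chrom), int(r.start) + offset, int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_dosage_tsv(path: str | Path) -> GenotypePanel:
    """Read a headered numeric dosage matrix (rows = samples, cols = SNPs).

    First column holds sample ids; remaining columns are SNP dosages with SNP
    ids in the header. Empty cells or ``NA`` are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypePanel(
        samples=[str(s) for s in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf_panel(path: str | Path) -> GenotypePanel:
    """Read a VCF into a dosage panel (GT field; dosage = count of ALT alleles)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, cols = [], []
    for i, var in enumerate(vcf):
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        cols.append(gt)
    if not cols:
        raise FormatError(f"{path}: no variants")
    return GenotypePanel(samples, snp_ids, np.column_stack(cols))


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT pathway file: name, description, then gene ids, tab-separated.

    Duplicate genes within a line are deduplicated with a warning; a line with
    fewer than three fields is a format error reported with its line number.
    """
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            pid, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} lists no genes")
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in pathway %r deduplicated",
                               path, lineno, pid)
            if pid in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = Pathway(pid, name, frozenset(genes))
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in db:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a stable column order."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC filtering and region exclusion
# ---------------------------------------------------------------------------

def hwe_z2(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg departure as the 1-df goodness-of-fit chi-square.

    Computed from genotype counts with the allele frequency estimated from the
    same counts; with 1 df this equals a squared Z-statistic. Returns 0 for a
    monomorphic SNP (no departure is measurable).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    return float(np.sum((obs - exp) ** 2 / exp))


def _genotype_counts(panel: GenotypePanel, snp_ids: Sequence[str]) -> np.ndarray:
    """(n_snps, 3) counts of hard genotypes 0/1/2 per SNP (NaN ignored)."""
    d = panel.columns(snp_ids)
    counts = np.empty((len(snp_ids), 3), dtype=np.int64)
    rounded = np.round(d)
    for g in (0, 1, 2):
        counts[:, g] = np.nansum(rounded == g, axis=0)
    return counts


def apply_qc(
    stats: SummaryStats,
    maf_min: float = 0.01,
    missing_max: float = 0.05,
    hwe_z2_max: float = 25.0,
    genotypes: GenotypePanel | None = None,
) -> tuple[SummaryStats, dict[str, int]]:
    """Apply standard GWAS quality-control filters.

    Removes SNPs with MAF <= ``maf_min``, with a missing-data fraction above
    ``missing_max`` (from the ``call_rate`` column), or with a control HWE
    goodness-of-fit chi-square (1 df, i.e. squared Z) >= ``hwe_z2_max``.
    The HWE filter needs genotype counts and runs only when ``genotypes``
    (a control panel) is supplied. Filters whose inputs are unavailable are
    skipped with a warning.

    Returns the filtered stats and a per-filter removal count.
    """
    df = stats.table
    keep = np.ones(len(df), dtype=bool)
    removed = {"maf": 0, "missing": 0, "hwe": 0}

    if "maf" in df.columns and df["maf"].notna().any():
        fail = ~(df["maf"].to_numpy() > maf_min)
        fail &= df["maf"].notna().to_numpy()
        removed["maf"] = int((fail & keep).sum())
        keep &= ~fail
    else:
        logger.warning("apply_qc: no maf column; MAF filter skipped")

    if "call_rate" in df.columns and df["call_rate"].notna().any():
        missing = 1.0 - df["call_rate"].to_numpy()
        fail = (missing > missing_max) & df["call_rate"].notna().to_numpy()
        removed["missing"] = int((fail & keep).sum())
        keep &= ~fail
    else:
        logger.warning("apply_qc: no call_rate column; missing-data filter skipped")

    if genotypes is not None:
        in_panel = df["snp_id"].isin(genotypes.snp_ids).to_numpy()
        ids = df["snp_id"].to_numpy()[in_panel]
        if len(ids):
            counts = _genotype_counts(genotypes, list(ids))
            z2 = np.array([hwe_z2(*c) for c in counts])
            fail = np.zeros(len(df), dtype=bool)
            fail[np.flatnonzero(in_panel)] = z2 >= hwe_z2_max
            removed["hwe"] = int((fail & keep).sum())
            keep &= ~fail
        if not in_panel.all():
            logger.warning("apply_qc: %d SNP(s) absent from the control panel; "
                           "HWE filter skipped for them", int((~in_panel).sum()))
    else:
        logger.warning("apply_qc: no genotype panel; HWE filter skipped")

    logger.info("apply_qc: removed %s; %d SNPs retained",
                removed, int(keep.sum()))
    return stats.subset(keep), removed


def exclude_region(stats: SummaryStats, chrom: str, start: int, end: int) -> SummaryStats:
    """Remove all SNPs with ``start <= pos <= end`` on ``chrom`` (closed interval)."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    df = stats.table
    chrom = normalize_chrom(chrom)
    inside = (df["chrom"].map(normalize_chrom) == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
    n = int(inside.sum())
    if n:
        logger.info("exclude_region %s:%d-%d removed %d SNPs", chrom, start, end, n)
    return stats.subset(~inside.to_numpy())


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    stats: SummaryStats,
    genes: Sequence[GeneAnnotation],
    window: int = 50_000,
) -> GeneAssignment:
    """Map each SNP to every gene whose span overlaps a window around the SNP.

    SNP ``s`` maps to gene ``g`` iff ``[pos(s)-window, pos(s)+window]``
    intersects ``[start(g), end(g)]`` on the same chromosome, both closed
    intervals (touching counts as overlap). The mapping is many-to-many;
    genes with zero SNPs are omitted and each gene's SNP list is ordered by
    position.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; widen by the window and +1 on the end.
        trees.setdefault(normalize_chrom(g.chrom), IntervalTree()).addi(
            g.start - window, g.end + window + 1, g.gene_id
        )

    mapping: dict[str, list[tuple[int, str]]] = {}
    df = stats.table
    for snp_id, chrom, pos in zip(df["snp_id"], df["chrom"], df["pos"]):
        tree = trees.get(normalize_chrom(chrom))
        if tree is None:
            continue
        for iv in tree.at(int(pos)):
            mapping.setdefault(iv.data, []).append((int(pos), snp_id))

    ordered = {
        g: [s for _, s in sorted(pairs)] for g, pairs in sorted(mapping.items())
    }
    n_genes_with = len(ordered)
    logger.info("assign_snps_to_genes: %d of %d genes received >=1 SNP (window %d bp)",
                n_genes_with, len(genes), window)
    return GeneAssignment(ordered, window=window)
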