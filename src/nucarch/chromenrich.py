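"""Chromosomal enrichment statistics for genomic interval sets.

Given a peak table and a genome table, the module compares observed
per-chromosome peak counts with the counts expected if peaks fell at
random proportionally to chromosome size (or to gene count), scores each
chromosome by observed/expected, and tests the global fit with Pearson's
X² — either against the chi-square distribution or against an exact
multinomial Monte-Carlo null.  With ~100 peaks over ~21 chromosomes the
expected counts drop below 5 and the asymptotic chi-square approximation
is unsafe, so ``method="auto"`` switches to Monte Carlo whenever any
expected count is < 5.

Peak coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeTable",
    "GofResult",
    "ChromEnrichmentResult",
    "OverlapResult",
    "read_bed",
    "write_bed",
    "validate_peaks",
    "count_peaks_per_chrom",
    "expected_counts",
    "goodness_of_fit",
    "chrom_enrichment",
    "differential_overlap",
    "annotate_peaks",
    "mouse_genome",
]

# mm10 (GRCm38) chromosome sizes in bp, UCSC chrom.sizes values.
MM10_CHROM_SIZES: dict[str, int] = {
    "chr1": 195471971,
    "chr2": 182113224,
    "chr3": 160039680,
    "chr4": 156508116,
    "chr5": 151834684,
    "chr6": 149736546,
    "chr7": 145441459,
    "chr8": 129401213,
    "chr9": 124595110,
    "chr10": 130694993,
    "chr11": 122082543,
    "chr12": 120129022,
    "chr13": 120421639,
    "chr14": 124902244,
    "chr15": 104043685,
    "chr16": 98207768,
    "chr17": 94987271,
    "chr18": 90702639,
    "chr19": 61431566,
    "chrX": 171031299,
    "chrY": 91744698,
}


@dataclass
class GenomeTable:
    """Per-chromosome sizes and optional gene counts."""

    table: pd.DataFrame  # columns: name, size[, gene_count]

    def __post_init__(self) -> None:
        t = self.table
        if not {"name", "size"}.issubset(t.columns):
            raise ValueError("genome table needs 'name' and 'size' columns")
        if t["name"].duplicated().any():
            dups = t.loc[t["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate chromosome names: {dups}")
        if (t["size"] <= 0).any():
            raise ValueError("chromosome sizes must be > 0")
        self.table = t.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def sizes(self) -> pd.Series:
        return self.table.set_index("name")["size"]

    @property
    def gene_counts(self) -> pd.Series:
        if "gene_count" not in self.table.columns:
            raise ValueError("genome table has no gene_count column")
        return self.table.set_index("name")["gene_count"]

    def weights(self, kind: str = "size") -> pd.Series:
        if kind == "size":
            return self.sizes.astype(float)
        if kind in ("genes", "gene_count"):
            return self.gene_counts.astype(float)
        raise ValueError(f"unknown weight kind {kind!r}")

    @classmethod
    def from_chrom_sizes(cls, path_or_buf) -> "GenomeTable":
        df = pd.read_csv(
            path_or_buf, sep="\t", header=None, names=["name", "size"],
            usecols=[0, 1],
        )
        return cls(df)

    @classmethod
    def from_dict(
        cls, sizes: dict[str, int], gene_counts: dict[str, int] | None = None
    ) -> "GenomeTable":
        df = pd.DataFrame({"name": list(sizes), "size": list(sizes.values())})
        if gene_counts is not None:
            df["gene_count"] = [gene_counts[n] for n in sizes]
        return cls(df)


def mouse_genome() -> GenomeTable:
    """Mouse (mm10) chromosome sizes as a GenomeTable."""
    return GenomeTable.from_dict(MM10_CHROM_SIZES)


# ---------------------------------------------------------------------------
# Peak table I/O and validation


def read_bed(path_or_buf, direction: bool = False) -> pd.DataFrame:
    """Read a 3–7 column BED file into a peak table.

    With ``direction=True`` a direction label is attached: from a 7th
    column when present (values 'gain'/'loss'), otherwise from the sign of
    the score column (positive ⇒ gain).
    """
    df = pd.read_csv(path_or_buf, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    cols = ["chrom", "start", "end", "name", "score", "strand", "direction"]
    df.columns = cols[:ncol]
    if direction:
        if "direction" not in df.columns:
            if "score" not in df.columns:
                raise ValueError(
                    "direction requested but the BED has neither a 7th "
                    "column nor a score column"
                )
            df["direction"] = np.where(df["score"] >= 0, "gain", "loss")
    return validate_peaks(df)


def write_bed(peaks: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand", "direction") if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def validate_peaks(peaks: pd.DataFrame, genome: GenomeTable | None = None) -> pd.DataFrame:
    """Check BED invariants (start < end, sorted, known chromosomes)."""
    if not {"chrom", "start", "end"}.issubset(peaks.columns):
        raise ValueError("peak table needs chrom, start, end columns")
    if len(peaks) and (peaks["start"] >= peaks["end"]).any():
        bad = peaks[peaks["start"] >= peaks["end"]]
        raise ValueError(f"start >= end for {len(bad)} records")
    if genome is not None and len(peaks):
        unknown = sorted(set(peaks["chrom"]) - set(genome.names))
        if unknown:
            raise ValueError(f"peaks on chromosomes absent from genome: {unknown}")
    return peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Counting and expectation


def count_peaks_per_chrom(peaks: pd.DataFrame, genome: GenomeTable) -> pd.Series:
    """Observed peak counts per chromosome, indexed in genome order."""
    if len(peaks):
        unknown = sorted(set(peaks["chrom"]) - set(genome.names))
        if unknown:
            raise ValueError(
                f"peaks on chromosomes absent from the genome table: {unknown}"
            )
    counts = peaks["chrom"].value_counts() if len(peaks) else pd.Series(dtype=int)
    return pd.Series(
        [int(counts.get(n, 0)) for n in genome.names],
        index=genome.names,
        name="observed",
    )


def expected_counts(total: int, weights: pd.Series) -> pd.Series:
    """Expected counts proportional to positive weights, summing exactly
    to ``total`` (no rounding)."""
    if total < 0:
        raise ValueError("total must be >= 0")
    w = pd.Series(weights, dtype=float)
    if (w <= 0).any():
        bad = w.index[w <= 0].tolist()
        raise ValueError(f"nonpositive weights for {bad}")
    return (total * w / w.sum()).rename("expected")


# ---------------------------------------------------------------------------
# Goodness of fit


@dataclass
class GofResult:
    statistic: float
    df: int
    p_value: float
    method: str


def _chi2_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(((observed - expected) ** 2 / expected).sum())


def goodness_of_fit(
    observed: pd.Series,
    expected: pd.Series,
    method: str = "auto",
    n_sim: int = 10000,
    seed: int | None = None,
) -> GofResult:
    """Pearson X² goodness-of-fit of observed counts to expectation.

    ``method='chi-square'`` uses the asymptotic chi-square distribution
    with k−1 degrees of freedom; ``'monte-carlo'`` simulates ``n_sim``
    multinomial draws with probabilities proportional to the expectation
    and reports p = (1 + #{X²_sim ≥ X²_obs}) / (1 + n_sim); ``'auto'``
    chooses Monte Carlo whenever any expected count is < 5.
    """
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float)
    if set(obs.index) != set(exp.index):
        raise ValueError("observed and expected must share the same keys")
    exp = exp.reindex(obs.index)
    if ((exp == 0) & (obs > 0)).any():
        bad = obs.index[(exp == 0) & (obs > 0)].tolist()
        raise ValueError(f"zero expectation with observed counts on {bad}")
    total_obs, total_exp = obs.sum(), exp.sum()
    if total_exp <= 0 or abs(total_obs - total_exp) > 1e-6 * max(total_exp, 1.0):
        raise ValueError(
            f"totals differ: observed {total_obs}, expected {total_exp}"
        )

    o = obs.to_numpy()
    e = exp.to_numpy()
    x2 = _chi2_statistic(o, e)
    k = len(o)

    if method == "auto":
        method = "monte-carlo" if (e < 5).any() else "chi-square"
    if method in ("chi-square", "chisq"):
        p = float(stats.chi2.sf(x2, df=k - 1))
        return GofResult(statistic=x2, df=k - 1, p_value=p, method="chi-square")
    if method in ("monte-carlo", "mc"):
        if n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        rng = np.random.default_rng(seed)
        total = int(round(total_obs))
        sims = rng.multinomial(total, e / e.sum(), size=n_sim)
        x2_sim = ((sims - e) ** 2 / e).sum(axis=1)
        p = float((1 + (x2_sim >= x2).sum()) / (1 + n_sim))
        return GofResult(statistic=x2, df=k - 1, p_value=p, method="monte-carlo")
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ChromEnrichmentResult:
    """Per-chromosome observed/expected analysis of a peak set."""

    table: pd.DataFrame  # columns: observed, expected, enrichment_score
    statistic: float
    df: int
    p_value: float
    method: str
    weights: str

    @property
    def top_chromosome(self) -> str:
        return str(self.table["enrichment_score"].idxmax())


def chrom_enrichment(
    peaks: pd.DataFrame,
    genome: GenomeTable,
    weights: str = "size",
    method: str = "auto",
    n_sim: int = 10000,
    seed: int | None = None,
) -> ChromEnrichmentResult:
    """Observed vs expected per-chromosome counts with goodness-of-fit.

    ``weights='size'`` tests against expectation proportional to
    chromosome size; ``'genes'`` against gene counts.
    """
    obs = count_peaks_per_chrom(peaks, genome)
    exp = expected_counts(int(obs.sum()), genome.weights(weights))
    gof = goodness_of_fit(obs, exp, method=method, n_sim=n_sim, seed=seed)
    table = pd.DataFrame(
        {
            "observed": obs,
            "expected": exp,
            "enrichment_score": obs / exp,
        }
    )
    return ChromEnrichmentResult(
        table=table,
        statistic=gof.statistic,
        df=gof.df,
        p_value=gof.p_value,
        method=gof.method,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# Differential-peak overlap


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_same_direction: int


def differential_overlap(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1
) -> OverlapResult:
    """Count A peaks overlapping B, and how many agree in direction.

    Both tables must carry a ``direction`` column ('gain'/'loss').  An A
    peak overlaps when some same-chromosome B interval shares at least
    ``min_overlap_bp`` bases; each A peak is counted once, paired with its
    first overlapping B partner in coordinate order for the direction
    comparison.
    """
    for name, t in (("A", a), ("B", b)):
        if "direction" not in t.columns:
            raise ValueError(f"table {name} has no 'direction' column")
    a = validate_peaks(a)
    b = validate_peaks(b)
    n_overlap = 0
    n_same = 0
    b_by_chrom = {c: g.reset_index(drop=True) for c, g in b.groupby("chrom")}
    for row in a.itertuples(index=False):
        bg = b_by_chrom.get(row.chrom)
        if bg is None:
            continue
        ov = np.minimum(bg["end"], row.end) - np.maximum(bg["start"], row.start)
        hits = np.flatnonzero(ov >= min_overlap_bp)
        if hits.size:
            n_overlap += 1
            partner = bg.iloc[hits[0]]
            if partner["direction"] == row.direction:
                n_same += 1
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_overlap=n_overlap, n_same_direction=n_same
    )


# ---------------------------------------------------------------------------
# Genomic annotation


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_bp: int = 1000,
    tss_bp: int = 100,
) -> tuple[pd.Series, dict[str, int]]:
    """Assign each peak one genomic category by its midpoint.

    ``genes`` needs columns (chrom, txStart, txEnd, strand).  Categories by
    precedence: ``tss`` (midpoint within ±``tss_bp`` of the strand-aware
    TSS), ``promoter`` (within ``promoter_bp`` upstream of the TSS),
    ``gene_body`` (inside [txStart, txEnd)), else ``intergenic``.  Returns
    the per-peak category Series and the category counts (which sum to the
    table size).
    """
    req = {"chrom", "txStart", "txEnd", "strand"}
    if not req.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(req)}")
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    categories = []
    for row in peaks.itertuples(index=False):
        mid = (row.start + row.end) // 2
        g = genes_by_chrom.get(row.chrom)
        cat = "intergenic"
        if g is not None:
            plus = g["strand"] == "+"
            tss = np.where(plus, g["txStart"], g["txEnd"] - 1)
            if (np.abs(mid - tss) <= tss_bp).any():
                cat = "tss"
            else:
                upstream = np.where(
                    plus,
                    (tss - promoter_bp <= mid) & (mid < tss),
                    (tss < mid) & (mid <= tss + promoter_bp),
                )
                if upstream.any():
                    cat = "promoter"
                elif ((g["txStart"] <= mid) & (mid < g["txEnd"])).any():
                    cat = "gene_body"
        categories.append(cat)
    cats = pd.Series(categories, index=peaks.index, name="category")
    counts = {
        k: int((cats == k).sum())
        for k in ("tss", "promoter", "gene_body", "intergenic")
    }
    return cats, counts
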