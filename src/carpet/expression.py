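"""Gene-level analysis: regulated-gene selection, CA-repeat and mCAC covariates,
binned fold-change curves, and per-class repeat-content summaries.

Differential-expression results are consumed, not computed: the input is a
DESeq2-style table (gene id, log2FoldChange, pvalue, padj).  Genes passing
the significance threshold (strict ``< alpha``) split into up- and
down-regulated classes; a seeded random subset of the remaining genes of
matched size serves as the non-regulated comparison class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .intervals import IntervalSet
from .stats import BinSummary, CorrelationResult, spearman_r2, summarize_bins

#: accepted column synonyms for the DE table
DE_SYNONYMS = {
    "gene_id": ("gene_id", "gene", "id"),
    "log2fc": ("log2fc", "log2foldchange", "lfc"),
    "pvalue": ("pvalue", "pval", "p_value"),
    "padj": ("padj", "p_adj", "qvalue", "fdr"),
}


def read_de_table(path) -> pd.DataFrame:
    """Read a DESeq2-style TSV, normalizing column names."""
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, names in DE_SYNONYMS.items():
        for name in names:
            if name in lower:
                rename[lower[name]] = canon
                break
    df = df.rename(columns=rename)
    missing = {"gene_id", "log2fc"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"DE table missing columns: {sorted(missing)}")
    return df


@dataclass
class RegulationClasses:
    up: pd.DataFrame
    down: pd.DataFrame
    nonreg: pd.DataFrame               # all non-significant genes
    nonreg_sample: pd.DataFrame = field(default=None)  # seeded subset
    seed: int | None = None

    @property
    def regulated(self) -> pd.DataFrame:
        return pd.concat([self.up, self.down], ignore_index=True)


def select_regulated(records: pd.DataFrame, alpha: float = 0.05, criterion: str = "padj") -> RegulationClasses:
    """Split genes into up / down / non-regulated by strict ``stat < alpha``."""
    if criterion not in ("padj", "pvalue"):
        raise InvalidInputError(f"criterion must be padj or pvalue, not {criterion!r}")
    if criterion not in records.columns:
        raise InvalidInputError(f"DE table has no {criterion!r} column")
    stat = records[criterion]
    sig = stat.notna() & (stat < alpha)
    up = records[sig & (records["log2fc"] > 0)].reset_index(drop=True)
    down = records[sig & (records["log2fc"] < 0)].reset_index(drop=True)
    nonreg = records[~(sig & (records["log2fc"] != 0))].reset_index(drop=True)
    return RegulationClasses(up=up, down=down, nonreg=nonreg)


def sample_nonregulated(
    classes: RegulationClasses, seed: int = 0, k: int | None = None
) -> RegulationClasses:
    """Draw the matched-size non-regulated subset (uniform, without replacement).

    ``k`` defaults to ``|up| + |down|``; if fewer non-regulated genes exist,
    all of them are taken (degraded mode).
    """
    if k is None:
        k = len(classes.up) + len(classes.down)
    rng = np.random.default_rng(seed)
    n = len(classes.nonreg)
    if k >= n:
        sample = classes.nonreg.copy()
    else:
        idx = rng.choice(n, size=k, replace=False)
        sample = classes.nonreg.iloc[np.sort(idx)].reset_index(drop=True)
    classes.nonreg_sample = sample
    classes.seed = seed
    return classes


def pct_ca_in_gene(genes: pd.DataFrame, ca_set: IntervalSet) -> np.ndarray:
    """Percent of gene-body bases covered by CA arrays (clipped to the gene)."""
    lens = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    if (lens <= 0).any():
        raise InvalidInputError("zero-length gene body")
    out = np.zeros(len(genes))
    for chrom, idx in genes.groupby("chrom", sort=False).indices.items():
        s = genes["start"].to_numpy()[idx]
        e = genes["end"].to_numpy()[idx]
        out[idx] = ca_set.overlap_bp(chrom, s, e)
    return 100.0 * out / lens


def binned_fc_analysis(
    genes: pd.DataFrame,
    covariate_key: str,
    n_bins: int = 30,
    include_undefined: bool = True,
) -> tuple[list[BinSummary], CorrelationResult]:
    """Sort the analyzed genes by a covariate, bin, and correlate.

    Returns the 30-bin (by default) mean +/- SEM fold-change curve plus the
    squared Spearman correlation computed on the *unbinned* (covariate,
    log2fc) pairs of the same gene set.  Genes with an undefined covariate
    are included with covariate 0 by default (flagged upstream), or dropped.

    Ties in the covariate are broken by stable gene-id order, so results are
    reproducible across runs.
    """
    if covariate_key not in genes.columns:
        raise InvalidInputError(f"unknown covariate {covariate_key!r}")
    df = genes.sort_values("gene_id", kind="stable").reset_index(drop=True)
    cov = df[covariate_key].to_numpy(dtype=float)
    if not include_undefined:
        keep = np.isfinite(cov)
        if "uncovered" in df.columns:
            keep &= ~df["uncovered"].to_numpy(dtype=bool)
        df, cov = df[keep].reset_index(drop=True), cov[keep]
    else:
        cov = np.where(np.isfinite(cov), cov, 0.0)
    if len(df) < n_bins:
        raise InvalidInputError(f"{len(df)} genes < {n_bins} bins")
    lfc = df["log2fc"].to_numpy(dtype=float)
    bins = summarize_bins(cov, lfc, n_bins)
    r2 = spearman_r2(cov, lfc, input_kind="unbinned")
    return bins, r2


def class_pct_ca_summary(classes: RegulationClasses, ca_set: IntervalSet) -> pd.DataFrame:
    """Five-number summary (box-plot statistics) of %CA per regulation class."""
    rows = []
    for name, df in (
        ("up", classes.up),
        ("down", classes.down),
        ("nonreg_sample", classes.nonreg_sample if classes.nonreg_sample is not None else classes.nonreg),
    ):
        if df is None or not len(df):
            rows.append({"class": name, "n": 0, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan})
            continue
        pct = pct_ca_in_gene(df, ca_set)
        q = np.percentile(pct, [0, 25, 50, 75, 100])  # linear interpolation
        rows.append({"class": name, "n": len(df), "min": q[0], "q1": q[1],
                     "median": q[2], "q3": q[3], "max": q[4]})
    return pd.DataFrame(rows)
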