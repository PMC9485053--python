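"""Per-cytosine bisulfite calls: contexts, coverage filters, aggregation.

Sites live in a pandas DataFrame with one row per cytosine per strand:

======== =======================================================
column   meaning
======== =======================================================
chrom    contig name
pos      0-based plus-strand coordinate of the base (C on +, G on -)
strand   "+" or "-"
context3 trinucleotide starting at the C, read 5'->3' on its own strand
meth     methylated read count
total    total read count (0 = uncovered)
ratio    meth/total, NaN when uncovered
======== =======================================================

Context membership is hierarchical: every CAC site is a CA site; CG and CA
are disjoint.  Means are unweighted means of per-site ratios over covered
sites (ratios first, then average), matching how bisulfite methylation levels
are conventionally summarized.  Inside repeat loci the trinucleotide filter
can be dropped (``context=None``) so that all cytosines on both strands are
aggregated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, UndefinedMeanError
from .intervals import IntervalSet, tile_contigs
from .seq import revcomp

SITE_COLUMNS = ["chrom", "pos", "strand", "context3", "meth", "total", "ratio"]

#: named context matchers over the context3 column
_CONTEXT_NAMES = ("CAC", "CA", "CG", "CAH", "CAN")


def context_mask(sites: pd.DataFrame, context: str | None) -> np.ndarray:
    """Boolean mask of sites matching a named cytosine context (None = all)."""
    if context is None:
        return np.ones(len(sites), dtype=bool)
    ctx = sites["context3"].to_numpy()
    if context == "CAC":
        return ctx == "CAC"
    if context == "CA":
        return np.char.startswith(ctx.astype("U3"), "CA")
    if context == "CG":
        return np.char.startswith(ctx.astype("U3"), "CG")
    if context == "CAH":  # CA but not CAC
        c3 = ctx.astype("U3")
        return np.char.startswith(c3, "CA") & (c3 != "CAC")
    if context == "CAN":  # any CA trinucleotide (== CA dinucleotide context)
        return np.char.startswith(ctx.astype("U3"), "CA")
    raise InvalidInputError(f"unknown context {context!r}; one of {_CONTEXT_NAMES}")


def assign_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Trinucleotide context of the cytosine at (chrom, pos, strand).

    On the minus strand the context is the reverse complement of the
    plus-strand 3-mer *ending* at ``pos``.  Within 2 bp of a contig end the
    context is padded with N.
    """
    seq = str(genome[chrom])
    if strand == "+":
        base = seq[pos].upper()
        ctx = seq[pos : pos + 3].upper()
    elif strand == "-":
        base = revcomp(seq[pos].upper())
        ctx = revcomp(seq[max(pos - 2, 0) : pos + 1].upper())
    else:
        raise InvalidInputError(f"bad strand {strand!r}")
    if base != "C":
        raise InvalidInputError(f"{chrom}:{pos}({strand}) is {base}, not C")
    return (ctx + "NN")[:3]


def sites_in_scope(
    sites: pd.DataFrame,
    scope: IntervalSet | None,
    outside: bool = False,
) -> np.ndarray:
    """Mask of sites whose plus-strand position lies inside (or outside) a set."""
    if scope is None:
        return np.ones(len(sites), dtype=bool)
    mask = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy()
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        mask[idx] = scope.contains_points(chrom, pos[idx])
    return ~mask if outside else mask


# ---------------------------------------------------------------------------
# cytosine report I/O (Bismark CX dialect: 1-based, no header)
# ---------------------------------------------------------------------------

_REPORT_COLS = ["chrom", "pos1", "strand", "meth", "unmeth", "context_class", "context3"]


def read_cytosine_report(path, genome: Mapping[str, str] | None = None, strict: bool = False) -> pd.DataFrame:
    """Read a Bismark-style cytosine report (TSV, 1-based positions).

    Uncovered sites (0 reads) are retained with ratio NaN.  When a genome is
    supplied the stored trinucleotide is cross-checked; mismatches warn, or
    raise under ``strict=True``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=_REPORT_COLS,
        dtype={"chrom": str, "strand": str, "context_class": str, "context3": str},
    )
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError("negative read counts in cytosine report")
    total = df["meth"] + df["unmeth"]
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos1"].to_numpy(dtype=np.int64) - 1,
            "strand": df["strand"],
            "context3": df["context3"].str.upper(),
            "meth": df["meth"].to_numpy(dtype=np.int64),
            "total": total.to_numpy(dtype=np.int64),
        }
    )
    sites["ratio"] = np.where(sites["total"] > 0, sites["meth"] / sites["total"].replace(0, 1), np.nan)
    if genome is not None:
        n_checked = 0
        mismatches = []
        for i, row in sites.head(10_000).iterrows():  # spot check, full check too slow on big files
            expect = assign_context(genome, row["chrom"], int(row["pos"]), row["strand"])
            n_checked += 1
            if expect != row["context3"]:
                mismatches.append(i)
        if mismatches:
            msg = f"{len(mismatches)}/{n_checked} context mismatches vs genome (first at row {mismatches[0]})"
            if strict:
                raise FormatError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
    return sites


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    """Write sites back to the Bismark-style dialect (round-trips with the reader)."""
    ctx = sites["context3"].to_numpy().astype("U3")
    second = ctx.view("U1").reshape(-1, 3)[:, 1]
    third = ctx.view("U1").reshape(-1, 3)[:, 2]
    cls = np.where(
        np.char.startswith(ctx, "CG"),
        "CpG",
        np.where(
            np.char.find(ctx, "N") >= 0,
            "Unknown",
            np.where((third == "G") & (second != "G"), "CHG", "CHH"),
        ),
    )
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos1": sites["pos"] + 1,
            "strand": sites["strand"],
            "meth": sites["meth"],
            "unmeth": sites["total"] - sites["meth"],
            "context_class": cls,
            "context3": sites["context3"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filters and aggregates
# ---------------------------------------------------------------------------


def filter_by_coverage(sites: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    """Retain sites with total reads >= min_reads."""
    if min_reads < 1:
        raise InvalidInputError("min_reads must be >= 1")
    return sites[sites["total"] >= min_reads].reset_index(drop=True)


def mean_methylation(
    sites: pd.DataFrame,
    context: str | None = "CAC",
    scope: IntervalSet | None = None,
    outside: bool = False,
) -> float:
    """Unweighted mean per-site methylation ratio over covered, matching sites.

    ``context=None`` disables the trinucleotide filter (used inside repeat
    loci, where all cytosines on both strands are aggregated).
    """
    mask = (
        (sites["total"] > 0).to_numpy()
        & context_mask(sites, context)
        & sites_in_scope(sites, scope, outside=outside)
    )
    if not mask.any():
        raise UndefinedMeanError(
            f"no covered {context or 'C'} sites in the requested scope"
        )
    return float(sites.loc[mask, "ratio"].mean())


def coverage_fraction(
    sites_all: pd.DataFrame,
    context: str | None,
    min_reads: int,
    scope: IntervalSet | None = None,
    outside: bool = False,
) -> float:
    """Fraction of context-matching sites in scope with adequate coverage."""
    mask = context_mask(sites_all, context) & sites_in_scope(sites_all, scope, outside=outside)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedMeanError(f"no {context or 'C'} sites in the requested scope")
    covered = int((sites_all.loc[mask, "total"] >= min_reads).sum())
    return covered / n


def window_mcac_track(
    sites: pd.DataFrame,
    contig_sizes: Mapping[str, int],
    width: int = 1000,
    context: str | None = "CAC",
) -> pd.DataFrame:
    """Tile the genome and summarize methylation per window.

    Per window: ``value`` = sum of covered-site ratios scaled to per kb
    (the browser-track quantity, final partial window scaled by its true
    length); ``level`` = mean per-site ratio; ``n_sites`` covered matching
    sites; ``covered`` flag.
    """
    windows = tile_contigs(contig_sizes, width)
    mask = (sites["total"] > 0).to_numpy() & context_mask(sites, context)
    sub = sites[mask]
    sums = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=np.int64)
    offsets = {}
    off = 0
    for chrom in sorted(contig_sizes):
        offsets[chrom] = off
        off += int(np.ceil(contig_sizes[chrom] / width)) if contig_sizes[chrom] else 0
    for chrom, grp in sub.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise InvalidInputError(f"sites on unknown contig {chrom!r}")
        widx = grp["pos"].to_numpy() // width + offsets[chrom]
        sums += np.bincount(widx, weights=grp["ratio"].to_numpy(), minlength=len(windows))
        counts += np.bincount(widx, minlength=len(windows))
    true_len = (windows["end"] - windows["start"]).to_numpy()
    windows = windows.assign(
        n_sites=counts,
        sum_ratio=sums,
        value=sums * (1000.0 / true_len),
        level=np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
        covered=counts > 0,
    )
    return windows


def repeat_chunk_methylation(
    sites: pd.DataFrame,
    loci: pd.DataFrame,
    target_len: int = 1000,
    context: str | None = "CAC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group consecutive repeat loci into ~1 kb chunks and summarize methylation.

    Loci are walked in genome order per contig; a chunk closes as soon as its
    cumulative repeat length reaches ``target_len`` (the trailing chunk keeps
    its true length).  Per chunk: methylation ratios of covered matching sites
    inside member loci are summed and scaled to per kb of repeat sequence
    (``per_kb``); ``level`` is the mean per-site ratio.

    Returns ``(chunks, loci_with_chunk)`` where the second frame is a copy of
    ``loci`` with a ``chunk_id`` column.
    """
    loci = loci.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    chunk_id = np.full(len(loci), -1, dtype=np.int64)
    next_chunk = 0
    for chrom, idx in loci.groupby("chrom", sort=True).indices.items():
        acc = 0
        for i in idx:
            chunk_id[i] = next_chunk
            acc += int(loci.at[i, "end"] - loci.at[i, "start"])
            if acc >= target_len:
                next_chunk += 1
                acc = 0
        if acc > 0:
            next_chunk += 1
    loci = loci.assign(chunk_id=chunk_id)

    mask = (sites["total"] > 0).to_numpy() & context_mask(sites, context)
    sub = sites[mask]
    n_chunks = int(chunk_id.max()) + 1 if len(loci) else 0
    sum_ratio = np.zeros(n_chunks)
    n_sites = np.zeros(n_chunks, dtype=np.int64)
    for chrom, lidx in loci.groupby("chrom", sort=False).indices.items():
        starts = loci["start"].to_numpy()[lidx]
        ends = loci["end"].to_numpy()[lidx]
        cids = chunk_id[lidx]
        grp = sub[sub["chrom"] == chrom]
        if not len(grp):
            continue
        pos = grp["pos"].to_numpy()
        ratio = grp["ratio"].to_numpy()
        li = np.searchsorted(starts, pos, side="right") - 1
        inside = (li >= 0) & (pos < ends[np.clip(li, 0, None)])
        if inside.any():
            target = cids[li[inside]]
            sum_ratio += np.bincount(target, weights=ratio[inside], minlength=n_chunks)
            n_sites += np.bincount(target, minlength=n_chunks)
    agg = loci.groupby("chunk_id").agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        repeat_bases=("end", lambda e: 0),  # placeholder, filled below
        n_loci=("start", "size"),
    )
    agg["repeat_bases"] = loci.assign(length=loci["end"] - loci["start"]).groupby("chunk_id")["length"].sum()
    agg = agg.reset_index()
    agg["n_sites"] = n_sites[agg["chunk_id"].to_numpy()]
    agg["sum_ratio"] = sum_ratio[agg["chunk_id"].to_numpy()]
    agg["per_kb"] = agg["sum_ratio"] * 1000.0 / agg["repeat_bases"]
    agg["level"] = np.where(agg["n_sites"] > 0, agg["sum_ratio"] / agg["n_sites"].replace(0, 1), np.nan)
    return agg, loci


def gene_mcac_covariates(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    ca_set: IntervalSet,
    hard_calls: bool = False,
) -> pd.DataFrame:
    """Per-gene methylation covariates for the expression analysis.

    * ``mcac_incl`` - summed ratios of covered CAC sites in the gene body;
    * ``mcac_excl`` - same, excluding sites inside CA arrays;
    * ``mca_in_arrays`` - summed ratios of covered CA-context sites inside
      CA arrays within the gene body;
    * ``mcac_per_kb`` - mcac_incl scaled by gene length;
    * ``n_cac_covered`` and an ``uncovered`` flag.

    ``hard_calls=True`` counts sites with ratio >= 0.5 instead of summing
    ratios (sensitivity-analysis switch).
    """
    covered = sites[sites["total"] > 0]
    cac = covered[context_mask(covered, "CAC")]
    ca_ctx = covered[context_mask(covered, "CA")]
    in_arrays_cac = sites_in_scope(cac, ca_set)
    in_arrays_ca = sites_in_scope(ca_ctx, ca_set)

    def score(df: pd.DataFrame) -> np.ndarray:
        r = df["ratio"].to_numpy()
        return (r >= 0.5).astype(float) if hard_calls else r

    rows = []
    for _, g in genes.iterrows():
        chrom, gs, ge = g["chrom"], int(g["start"]), int(g["end"])
        if ge <= gs:
            raise InvalidInputError(f"zero-length gene {g.get('gene_id', '?')}")
        m_cac = (cac["chrom"] == chrom).to_numpy() & (cac["pos"].to_numpy() >= gs) & (cac["pos"].to_numpy() < ge)
        m_ca = (ca_ctx["chrom"] == chrom).to_numpy() & (ca_ctx["pos"].to_numpy() >= gs) & (ca_ctx["pos"].to_numpy() < ge)
        s_all = float(score(cac[m_cac]).sum())
        s_excl = float(score(cac[m_cac & ~in_arrays_cac]).sum())
        s_arr = float(score(ca_ctx[m_ca & in_arrays_ca]).sum())
        n_cov = int(m_cac.sum())
        rows.append(
            {
                "gene_id": g.get("gene_id", f"{chrom}:{gs}-{ge}"),
                "chrom": chrom,
                "start": gs,
                "end": ge,
                "gene_len": ge - gs,
                "mcac_incl": s_all,
                "mcac_excl": s_excl,
                "mca_in_arrays": s_arr,
                "mcac_per_kb": s_all * 1000.0 / (ge - gs),
                "n_cac_covered": n_cov,
                "uncovered": n_cov == 0,
            }
        )
    return pd.DataFrame(rows)


def local_inside_outside(
    sites: pd.DataFrame,
    arrays: pd.DataFrame,
    ca_set: IntervalSet,
    flank: int = 2000,
    context: str | None = "CAC",
    min_sites: int = 3,
) -> dict:
    """Paired comparison of methylation inside each array vs its local flanks.

    For every repeat locus the mean covered-site ratio inside the locus is
    compared with the mean over its +/- ``flank`` bp of surrounding sequence
    (array bases excluded from the flank).  Pairing against the local
    neighbourhood cancels regional methylation variation, so the standard
    error over arrays is an honest yardstick for the inside-vs-outside
    difference.  Returns per-array values and a summary with the mean paired
    difference, its SE over arrays, and the pooled inside/outside ratio.
    """
    covered = sites[(sites["total"] > 0).to_numpy() & context_mask(sites, context)]
    rows = []
    for chrom, grp in covered.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ratio = grp["ratio"].to_numpy()[order]
        in_ca = ca_set.contains_points(chrom, pos)
        arr = arrays[arrays["chrom"] == chrom]
        for _, a in arr.iterrows():
            s, e = int(a["start"]), int(a["end"])
            lo, hi = np.searchsorted(pos, [s, e])
            inside = ratio[lo:hi]
            flo, fhi = np.searchsorted(pos, [max(s - flank, 0), e + flank])
            fmask = np.ones(fhi - flo, dtype=bool)
            fmask[(pos[flo:fhi] >= s) & (pos[flo:fhi] < e)] = False
            fmask &= ~in_ca[flo:fhi]  # exclude any CA-array bases, incl. neighbours
            outside = ratio[flo:fhi][fmask]
            if inside.size >= min_sites and outside.size >= min_sites:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": s,
                        "end": e,
                        "mean_inside": float(inside.mean()),
                        "mean_flank": float(outside.mean()),
                        "n_inside": int(inside.size),
                        "n_flank": int(outside.size),
                    }
                )
    per_array = pd.DataFrame(rows)
    if not len(per_array):
        raise UndefinedMeanError("no arrays with enough covered sites inside and in flanks")
    diff = per_array["mean_inside"] - per_array["mean_flank"]
    n = len(per_array)
    se = float(diff.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    mean_in = float(per_array["mean_inside"].mean())
    mean_out = float(per_array["mean_flank"].mean())
    return {
        "per_array": per_array,
        "n_arrays": n,
        "mean_inside": mean_in,
        "mean_flank": mean_out,
        "mean_diff": float(diff.mean()),
        "se_diff": se,
        "ratio": mean_in / mean_out if mean_out > 0 else float("nan"),
    }
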