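"""ChIP enrichment over region sets and the binned occupancy-vs-methylation analysis.

Coverage tracks are step functions read from / written to bedGraph (0-based
half-open, 4 columns).  Enrichment per region is
``log2((wt_mean + p) / (ref_mean + p))`` after optional library-size scaling,
where the reference is either a knockout ChIP or input chromatin.  Regions of
the three-category analysis (CA-repeat chunks, other-repeat chunks, random
background windows) are binned by their mean CAC methylation level and each
curve is summarized by the squared Spearman correlation of its binned means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, PlacementImpossibleError
from .intervals import IntervalSet, check_same_contigs
from .methylome import context_mask, repeat_chunk_methylation
from .stats import BinSummary, CorrelationResult, spearman_r2, summarize_bins


class CoverageTrack:
    """Per-chromosome step-function coverage (boundaries + values)."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values); intervals sorted, non-overlapping
        self._d = {c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64), np.asarray(v, dtype=float))
                   for c, (s, e, v) in data.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._d)

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        d = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start", kind="stable")
            d[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy(), grp["value"].to_numpy())
        return cls(d)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                s, e, v = self._d[chrom]
                for i in range(s.size):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:.6g}\n")

    def total_signal(self) -> float:
        return float(sum(((e - s) * v).sum() for s, e, v in self._d.values()))

    def mean_over(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Length-weighted mean value over each query interval (0 where no data)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._d:
            return np.zeros(starts.shape)
        ts, te, tv = self._d[chrom]
        seg = np.concatenate([[0.0], np.cumsum((te - ts) * tv)])

        def integral_before(pos: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(ts, pos, side="right") - 1
            idxc = np.clip(idx, 0, None)
            base = seg[idxc]
            base = np.where(idx < 0, 0.0, base)
            partial = np.clip(pos - ts[idxc], 0, te[idxc] - ts[idxc]) * tv[idxc]
            partial = np.where(idx < 0, 0.0, partial)
            return base + partial

        total = integral_before(ends) - integral_before(starts)
        return total / np.maximum(ends - starts, 1)


def log2_enrichment(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    regions: pd.DataFrame,
    pseudocount: float = 1.0,
    normalize_depth: bool = True,
) -> np.ndarray:
    """log2 enrichment of numerator over denominator per region.

    ``normalize_depth`` scales the numerator so both tracks integrate to the
    same total signal before taking the ratio.  The pseudocount (in mean-value
    units) keeps every value finite.
    """
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be > 0")
    check_same_contigs(numerator.chroms, denominator.chroms, "enrichment tracks")
    scale = 1.0
    if normalize_depth:
        tn, td = numerator.total_signal(), denominator.total_signal()
        if tn <= 0 or td <= 0:
            raise InvalidInputError("cannot depth-normalize a zero-signal track")
        scale = td / tn
    out = np.empty(len(regions))
    for chrom, idx in regions.groupby("chrom", sort=False).indices.items():
        s = regions["start"].to_numpy()[idx]
        e = regions["end"].to_numpy()[idx]
        num = numerator.mean_over(chrom, s, e) * scale
        den = denominator.mean_over(chrom, s, e)
        out[idx] = np.log2((num + pseudocount) / (den + pseudocount))
    return out


def log2_ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 1.0,
    normalize_depth: bool = True,
) -> CoverageTrack:
    """Per-segment log2 ratio track (the browser-style enrichment signal).

    Requires both tracks to share segment boundaries (e.g. the simulator's
    fixed tiles).  Averaging *this* track over a region set gives the mean of
    log ratios, which is how enrichment is conventionally summarized over
    genomic locations from a log2 signal bigWig.
    """
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be > 0")
    check_same_contigs(numerator.chroms, denominator.chroms, "enrichment tracks")
    scale = 1.0
    if normalize_depth:
        tn, td = numerator.total_signal(), denominator.total_signal()
        if tn <= 0 or td <= 0:
            raise InvalidInputError("cannot depth-normalize a zero-signal track")
        scale = td / tn
    d = {}
    for chrom in numerator.chroms:
        ns, ne, nv = numerator._d[chrom]
        ds, de, dv = denominator._d[chrom]
        if ns.size != ds.size or np.any(ns != ds) or np.any(ne != de):
            raise InvalidInputError(f"track segments differ on {chrom!r}")
        d[chrom] = (ns, ne, np.log2((nv * scale + pseudocount) / (dv + pseudocount)))
    return CoverageTrack(d)


def grouped_track_mean(
    track: CoverageTrack, loci: pd.DataFrame, group_col: str
) -> pd.Series:
    """Base-weighted mean track value over each group's member loci."""
    lens = (loci["end"] - loci["start"]).to_numpy(dtype=float)
    sums = np.zeros(len(loci))
    for chrom, idx in loci.groupby("chrom", sort=False).indices.items():
        s = loci["start"].to_numpy()[idx]
        e = loci["end"].to_numpy()[idx]
        sums[idx] = track.mean_over(chrom, s, e) * lens[idx]
    tmp = pd.DataFrame({"g": loci[group_col].to_numpy(), "s": sums, "L": lens}).groupby("g").sum()
    return tmp["s"] / tmp["L"]


def grouped_log2_enrichment(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    loci: pd.DataFrame,
    group_col: str,
    pseudocount: float = 1.0,
    normalize_depth: bool = True,
) -> pd.Series:
    """log2 enrichment where the mean is taken over a *group* of loci.

    Used for repeat chunks: the numerator/denominator means are computed over
    the union of each group's member bases (base-weighted), then one log2
    ratio per group is returned (indexed by group id).
    """
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be > 0")
    scale = 1.0
    if normalize_depth:
        tn, td = numerator.total_signal(), denominator.total_signal()
        if tn <= 0 or td <= 0:
            raise InvalidInputError("cannot depth-normalize a zero-signal track")
        scale = td / tn
    lens = (loci["end"] - loci["start"]).to_numpy(dtype=float)
    num_sum = np.zeros(len(loci))
    den_sum = np.zeros(len(loci))
    for chrom, idx in loci.groupby("chrom", sort=False).indices.items():
        s = loci["start"].to_numpy()[idx]
        e = loci["end"].to_numpy()[idx]
        num_sum[idx] = numerator.mean_over(chrom, s, e) * lens[idx]
        den_sum[idx] = denominator.mean_over(chrom, s, e) * lens[idx]
    tmp = pd.DataFrame(
        {"g": loci[group_col].to_numpy(), "n": num_sum, "d": den_sum, "L": lens}
    ).groupby("g").sum()
    num_mean = tmp["n"] * scale / tmp["L"]
    den_mean = tmp["d"] / tmp["L"]
    return np.log2((num_mean + pseudocount) / (den_mean + pseudocount))


def sample_background_windows(
    contig_sizes: Mapping[str, int],
    n: int,
    width: int = 1000,
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """``n`` windows of exactly ``width`` bp, uniform over all valid placements.

    A placement is valid when the window lies within a contig and overlaps no
    excluded interval.  Sampling is with replacement (windows may overlap each
    other) and exactly uniform: valid start positions are enumerated as
    segments and indexed directly, so no rejection loop is needed.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exclude = exclude or IntervalSet()
    segments = []  # (chrom, seg_start, n_valid_starts)
    for chrom in sorted(contig_sizes):
        size = contig_sizes[chrom]
        if size < width:
            continue
        # dilate each excluded interval left by width-1: those starts would overlap
        pairs = exclude.pairs(chrom)
        if pairs.size:
            n_starts = size - width + 1
            dil = np.column_stack(
                [
                    np.minimum(np.maximum(pairs[:, 0] - (width - 1), 0), n_starts),
                    np.minimum(pairs[:, 1], n_starts),
                ]
            )
            dil = dil[dil[:, 0] < dil[:, 1]]
            dilated = IntervalSet({chrom: dil}) if dil.size else IntervalSet()
        else:
            dilated = IntervalSet()
        valid = dilated.complement({chrom: size - width + 1})
        for s, e in valid.pairs(chrom):
            segments.append((chrom, int(s), int(e - s)))
    if not segments:
        raise PlacementImpossibleError(
            f"no {width} bp window placement avoids the excluded regions"
        )
    counts = np.array([c for _, _, c in segments], dtype=np.int64)
    cum = np.cumsum(counts)
    draws = rng.integers(0, cum[-1], size=n)
    seg_idx = np.searchsorted(cum, draws, side="right")
    offset = draws - np.concatenate([[0], cum])[seg_idx]
    rows = [
        (segments[i][0], segments[i][1] + int(o))
        for i, o in zip(seg_idx, offset)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start"])
    df["end"] = df["start"] + width
    return df


@dataclass
class CategoryBinnedResult:
    category: str  # CA_repeats | repeats_excl_CA | background_windows
    bins: list[BinSummary]
    r2: CorrelationResult
    n_regions: int
    n_dropped: int  # regions without a defined covariate
    covariate: np.ndarray | None = None  # region-level values behind the bins
    response: np.ndarray | None = None

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.category,
                "bin": [b.bin_index for b in self.bins],
                "n": [b.n_members for b in self.bins],
                "mean_mcac": [b.mean_covariate for b in self.bins],
                "mean_log2": [b.mean_response for b in self.bins],
                "sem_log2": [b.sem_response for b in self.bins],
            }
        )


def binned_enrichment_vs_mcac(
    covariate: np.ndarray,
    log2_ratio: np.ndarray,
    n_bins: int,
    category: str = "category",
) -> CategoryBinnedResult:
    """Equal-count bins of the methylation covariate; mean +/- SEM enrichment per
    bin; squared Spearman over the (mean covariate, mean enrichment) pairs."""
    covariate = np.asarray(covariate, dtype=float)
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    defined = np.isfinite(covariate) & np.isfinite(log2_ratio)
    n_dropped = int((~defined).sum())
    cov, resp = covariate[defined], log2_ratio[defined]
    if cov.size < n_bins:
        raise InvalidInputError(
            f"{cov.size} regions with defined values < {n_bins} bins"
        )
    bins = summarize_bins(cov, resp, n_bins)
    r2 = spearman_r2(
        [b.mean_covariate for b in bins],
        [b.mean_response for b in bins],
        input_kind="binned_means",
    )
    return CategoryBinnedResult(category, bins, r2, int(cov.size), n_dropped, cov, resp)


def binned_curve_agreement(
    reference: CategoryBinnedResult,
    other: CategoryBinnedResult,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Compare a binned curve against a reference curve at matched covariates.

    The reference curve (mean response vs mean covariate, with SEM) is
    linearly interpolated at each of the other category's bin covariates;
    bins outside the reference covariate range are marked not comparable.

    The per-bin standard error combines the reference curve's interpolated
    SEM with the other category's *pooled* region-level deviation SD (all
    regions' residuals around the reference curve, scaled by 1/sqrt(bin
    members)); pooling keeps the yardstick stable even when bins hold only a
    handful of repeat chunks, while a genuine category offset still shifts
    every bin in the same direction.  When region-level values are missing,
    the bin's own SEM is used instead.

    Returns one row per bin of ``other`` with the interpolated reference
    value, the combined SEM, the z score and an ``agrees`` flag.
    """
    ref_x = np.array([b.mean_covariate for b in reference.bins])
    ref_y = np.array([b.mean_response for b in reference.bins])
    ref_s = np.array([b.sem_response for b in reference.bins])
    order = np.argsort(ref_x, kind="stable")
    ref_x, ref_y, ref_s = ref_x[order], ref_y[order], ref_s[order]

    pooled_sd = None
    if other.covariate is not None and other.covariate.size >= 3:
        in_range = (other.covariate >= ref_x[0]) & (other.covariate <= ref_x[-1])
        if in_range.sum() >= 3:
            dev = other.response[in_range] - np.interp(
                other.covariate[in_range], ref_x, ref_y
            )
            pooled_sd = float(dev.std(ddof=1))

    rows = []
    for b in other.bins:
        in_range = ref_x[0] <= b.mean_covariate <= ref_x[-1]
        if in_range:
            y_hat = float(np.interp(b.mean_covariate, ref_x, ref_y))
            s_hat = float(np.interp(b.mean_covariate, ref_x, ref_s))
            own = (
                pooled_sd / np.sqrt(b.n_members)
                if pooled_sd is not None
                else b.sem_response
            )
            sem = float(np.hypot(own, s_hat))
            z = (b.mean_response - y_hat) / sem if sem > 0 else np.inf
        else:
            y_hat, sem, z = np.nan, np.nan, np.nan
        rows.append(
            {
                "bin": b.bin_index,
                "mean_mcac": b.mean_covariate,
                "mean_log2": b.mean_response,
                "ref_log2": y_hat,
                "combined_sem": sem,
                "z": z,
                "comparable": in_range,
                "agrees": bool(in_range and abs(z) <= z_threshold),
            }
        )
    return pd.DataFrame(rows)


def window_mcac_levels(sites: pd.DataFrame, windows: pd.DataFrame, context: str = "CAC") -> np.ndarray:
    """Mean covered-site methylation level per (possibly overlapping) window."""
    covered = sites[(sites["total"] > 0).to_numpy() & context_mask(sites, context)]
    out = np.full(len(windows), np.nan)
    for chrom, widx in windows.groupby("chrom", sort=False).indices.items():
        grp = covered[covered["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cum = np.concatenate([[0.0], np.cumsum(grp["ratio"].to_numpy()[order])])
        s = windows["start"].to_numpy()[widx]
        e = windows["end"].to_numpy()[widx]
        lo = np.searchsorted(pos, s)
        hi = np.searchsorted(pos, e)
        n = hi - lo
        with np.errstate(invalid="ignore"):
            out[widx] = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), np.nan)
    return out


def run_three_category_analysis(
    partition,
    sites: pd.DataFrame,
    wt_track: CoverageTrack,
    ref_track: CoverageTrack,
    n_windows: int = 5000,
    n_bins: int = 30,
    seed: int = 0,
    window_width: int = 1000,
    chunk_target: int = 1000,
    pseudocount: float = 1.0,
) -> dict[str, CategoryBinnedResult]:
    """The Fig 2C-style analysis over the three genomic categories.

    Repeat categories are grouped into ~1 kb chunks of cumulative repeat
    length; the background is ``n_windows`` random 1 kb windows avoiding CA
    arrays.  Each category's regions are binned by mean CAC methylation level.
    A category with fewer regions than ``n_bins`` is binned into pairs of
    regions instead (minimum three bins), trading bin-mean precision for
    curve resolution; the pooled-SD agreement check stays calibrated either
    way.

    Enrichment per region is the base-weighted mean of the log2 WT/reference
    ratio *track* over the region's bases (mean of log ratios), the same
    summary for chunks and windows.
    """
    results: dict[str, CategoryBinnedResult] = {}
    ratio = log2_ratio_track(wt_track, ref_track, pseudocount=pseudocount)

    for name, loci in (
        ("CA_repeats", partition.ca_arrays),
        ("repeats_excl_CA", partition.other_repeats),
    ):
        chunks, loci_tagged = repeat_chunk_methylation(
            sites, loci, target_len=chunk_target, context="CAC"
        )
        log2 = grouped_track_mean(ratio, loci_tagged, "chunk_id")
        cov = chunks.set_index("chunk_id")["level"].reindex(log2.index).to_numpy()
        n_defined = int(np.isfinite(cov).sum())
        bins_cat = n_bins if n_defined >= 2 * n_bins else max(min(n_defined, 3), n_defined // 2)
        results[name] = binned_enrichment_vs_mcac(cov, log2.to_numpy(), bins_cat, category=name)

    windows = sample_background_windows(
        partition.contig_sizes, n_windows, width=window_width,
        exclude=partition.ca_set, seed=seed,
    )
    cov = window_mcac_levels(sites, windows)
    log2 = np.empty(len(windows))
    for chrom, idx in windows.groupby("chrom", sort=False).indices.items():
        log2[idx] = ratio.mean_over(
            chrom, windows["start"].to_numpy()[idx], windows["end"].to_numpy()[idx]
        )
    bins_bg = min(n_bins, int(np.isfinite(cov).sum()))
    results["background_windows"] = binned_enrichment_vs_mcac(
        cov, log2, bins_bg, category="background_windows"
    )
    return results
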