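"""Synthetic study generator: genome, repeats, methylome, ChIP tracks, DE table.

The generator emulates the statistical structure the analysis assumes, at
desk scale, so every pipeline stage is testable without downloads:

* a random genome with planted perfect [CA]n arrays (>= 10 bp), CAN-family
  trinucleotide arrays and other simple repeats, plus non-overlapping genes;
* a regional methylation field: a lognormal multiplier, piecewise constant
  on blocks, shared by all CA-context cytosines of a block.  This is what
  couples methylation between a repeat array and its neighbourhood and gives
  ChIP occupancy something to track, mimicking the broad regional variation
  of non-CG methylation in neuronal genomes;
* per-cytosine true methylation probabilities by context (CAC >> CA-other;
  CG high; other ~ 0), with an ``array_enrichment`` knob multiplying the CAC
  rate inside CA arrays (1.0 = equal rates inside and out, the null);
* binomial read counts at Poisson coverage;
* ChIP tracks on fixed tiles whose expected log2(WT/ref) is
  ``slope * (local mean CAC methylation level / genome mean level)`` plus
  Gaussian noise -- occupancy depends only on methylation, never on repeat
  membership;
* a DESeq2-style differential-expression table in which regulated genes'
  log2 fold-change follows the gene's true mCAC content (standardized) with
  slope ``expr_slope``, and p-values are calibrated (uniform for unregulated
  genes) with BH-consistent adjusted values.

Everything is deterministic given (seed, config); each stage draws from its
own child generator so stages can be re-simulated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .chip import CoverageTrack
from .errors import InvalidInputError, PlacementImpossibleError
from .intervals import IntervalSet, tile_contigs
from .io import (
    write_contig_sizes,
    write_fasta,
    loci_to_bed,
    write_bed,
)
from .methylome import write_cytosine_report
from .repeats import GenomePartition, partition_genome, scan_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b
_A, _C, _G, _T, _N = (ord(x) for x in "ACGTN")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    # genome
    n_contigs: int = 2
    contig_len: int = 500_000
    n_ca_arrays: int = 200
    array_unit_count_range: tuple[int, int] = (30, 90)
    n_can_arrays: int = 40
    can_units: tuple[str, ...] = ("CAA", "CAG", "CAT")
    can_unit_count_range: tuple[int, int] = (10, 40)
    n_other_repeats: int = 300
    other_units: tuple[str, ...] = ("CACG", "CACT")  # CAC-bearing, so the binned
    # covariate is defined for every other-repeat chunk
    other_unit_count_range: tuple[int, int] = (20, 50)
    # methylome
    array_enrichment: float = 1.0        # 1.0 = the null: equal CAC rates in/out
    rate_mcac: float = 0.06
    rate_mca_other: float = 0.01
    rate_mcg: float = 0.8
    rate_other: float = 0.002
    region_block_len: int = 25_000       # regional methylation field block size
    region_sd_log: float = 0.7           # lognormal sigma of the field
    coverage_mean: float = 10.0          # Poisson mean reads per cytosine
    # ChIP
    chip_tile: int = 100
    chip_slope: float = 1.0              # log2 units per unit of normalized level
    chip_noise_sd: float = 0.3
    chip_depth: float = 100.0
    chip_depth_jitter: float = 0.02      # lognormal sigma of track depth noise
    # expression
    n_genes: int = 300
    gene_len_range: tuple[int, int] = (1000, 3000)
    p_repeat_in_gene: float = 0.25       # repeat placements inside genes are
    # accepted with this probability (simple repeats are gene-depleted)
    expr_slope: float = 0.5              # log2FC units per SD of true gene mCAC
    expr_noise_sd: float = 0.25
    frac_regulated: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kwargs = dict(d)
        for key in ("array_unit_count_range", "can_unit_count_range",
                    "other_unit_count_range", "gene_len_range",
                    "can_units", "other_units"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _place_elements(rng, contig_len, lengths, genic=None, p_in_gene=1.0,
                    margin=1000, gap=200, max_tries=400):
    """Random non-overlapping placements (start positions) with a safety gap.

    When ``genic`` (an IntervalSet for one contig) is given, candidate
    placements overlapping a gene body are accepted only with probability
    ``p_in_gene`` -- emulating the depletion of simple repeats within
    transcription units, so arrays carry a modest share of per-gene
    methylation rather than dominating it.
    """
    placed: list[tuple[int, int]] = []
    starts = []
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(margin, contig_len - margin - L))
            if not all(s >= e + gap or s + L + gap <= b for b, e in placed):
                continue
            if genic is not None and p_in_gene < 1.0:
                chrom = genic.chroms[0] if genic.chroms else None
                overlaps = (
                    chrom is not None
                    and genic.overlap_bp(chrom, np.array([s]), np.array([s + L]))[0] > 0
                )
                if overlaps and rng.random() >= p_in_gene:
                    continue
            placed.append((s, s + L))
            starts.append(s)
            ok = True
            break
        if not ok:
            raise PlacementImpossibleError(
                f"could not place a {L} bp element after {max_tries} tries"
            )
    return starts


def simulate_genome(config: SimConfig):
    """Random genome with planted repeats and genes.

    Returns ``(genome, planted, genes, contig_sizes)``.  Planted repeat
    flanks are forced to ``TT`` breaker bases so every planted array is a
    maximal perfect run recoverable at its exact coordinates.
    """
    rng = _stage_rng(config, 1)
    contig_sizes = {f"chr{i + 1}": config.contig_len for i in range(config.n_contigs)}
    genome: dict[str, str] = {}
    planted_rows = []

    # element specs: (unit, n_units) tuples, shuffled across contigs
    specs: list[tuple[str, int]] = []
    lo, hi = config.array_unit_count_range
    for _ in range(config.n_ca_arrays):
        specs.append(("CA", int(rng.integers(lo, hi + 1))))
    lo, hi = config.can_unit_count_range
    for _ in range(config.n_can_arrays):
        unit = config.can_units[int(rng.integers(len(config.can_units)))]
        specs.append((unit, int(rng.integers(lo, hi + 1))))
    lo, hi = config.other_unit_count_range
    for _ in range(config.n_other_repeats):
        unit = config.other_units[int(rng.integers(len(config.other_units)))]
        specs.append((unit, int(rng.integers(lo, hi + 1))))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    per_contig = np.array_split(np.arange(len(specs)), config.n_contigs)

    from .repeats import classify_unit

    # genes first: non-overlapping, placed by partitioning each contig's slack
    glo, ghi = config.gene_len_range
    gene_rows = []
    gid = 0
    genes_per_contig = np.array_split(np.arange(config.n_genes), config.n_contigs)
    for ci, chrom in enumerate(sorted(contig_sizes)):
        n_c = len(genes_per_contig[ci])
        lens = rng.integers(glo, ghi + 1, size=n_c)
        slack = config.contig_len - int(lens.sum())
        if slack < 0:
            raise PlacementImpossibleError("genes do not fit in the contig")
        gaps = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for j in range(n_c):
            pos += int(gaps[j])
            gene_rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + int(lens[j]),
                    "strand": "+",
                    "gene_id": f"g{gid:04d}",
                }
            )
            pos += int(lens[j])
            gid += 1
    genes = pd.DataFrame(gene_rows)

    for ci, chrom in enumerate(sorted(contig_sizes)):
        seq = rng.choice(_BASES, size=config.contig_len).astype(np.uint8)
        my = [specs[i] for i in per_contig[ci]]
        lengths = [len(u) * n for u, n in my]
        sub = genes[genes["chrom"] == chrom]
        genic = IntervalSet.from_frame(sub) if len(sub) else None
        starts = _place_elements(
            rng, config.contig_len, lengths,
            genic=genic, p_in_gene=config.p_repeat_in_gene,
        )
        for (unit, n_units), s in zip(my, starts):
            L = len(unit) * n_units
            rep = np.frombuffer((unit * n_units).encode(), dtype=np.uint8)
            seq[s : s + L] = rep
            seq[max(s - 2, 0) : s] = _T  # breaker flanks
            seq[s + L : s + L + 2] = _T
            planted_rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": s + L,
                    "strand": ".",
                    "unit": unit,
                    "unit_count": n_units,
                    "repeat_class": classify_unit(unit),
                }
            )
        genome[chrom] = seq.tobytes().decode("ascii")

    planted = (
        pd.DataFrame(planted_rows)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    return genome, planted, genes, contig_sizes


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def simulate_region_field(config: SimConfig, contig_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Block-wise lognormal regional multiplier (mean 1) for CA-context rates."""
    rng = _stage_rng(config, 2)
    sigma = config.region_sd_log
    field_ = {}
    for chrom in sorted(contig_sizes):
        n_blocks = int(np.ceil(contig_sizes[chrom] / config.region_block_len))
        field_[chrom] = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_blocks))
    return field_


def simulate_methylome(
    genome: Mapping[str, str],
    ca_set: IntervalSet,
    config: SimConfig,
    m_field: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-cytosine true probabilities, coverage and read counts, both strands."""
    rng = _stage_rng(config, 3)
    if m_field is None:
        m_field = simulate_region_field(config, {c: len(genome[c]) for c in genome})
    frames = []
    for chrom in sorted(genome):
        b = np.frombuffer(str(genome[chrom]).encode("ascii"), dtype=np.uint8)
        n = b.size
        pad = np.concatenate([b, np.full(2, _N, dtype=np.uint8)])
        padf = np.concatenate([np.full(2, _N, dtype=np.uint8), b])

        plus_pos = np.nonzero(b == _C)[0]
        minus_pos = np.nonzero(b == _G)[0]

        def build(pos, strand):
            if strand == "+":
                c0 = pad[pos]
                c1 = pad[pos + 1]
                c2 = pad[pos + 2]
            else:
                c0 = _COMP[padf[pos + 2]]
                c1 = _COMP[padf[pos + 1]]
                c2 = _COMP[padf[pos]]
            tri = np.stack([c0, c1, c2], axis=1).copy().view("S3").reshape(-1)
            is_ca = (c1 == _A)
            is_cac = is_ca & (c2 == _C)
            is_cg = (c1 == _G)
            p = np.full(pos.size, config.rate_other)
            p[is_cg] = config.rate_mcg
            p[is_ca] = config.rate_mca_other
            p[is_cac] = config.rate_mcac
            # regional field on CA-context rates
            m = m_field[chrom][np.minimum(pos // config.region_block_len,
                                          m_field[chrom].size - 1)]
            p = np.where(is_ca, p * m, p)
            # planted enrichment inside CA arrays (CAC sites only)
            in_arr = ca_set.contains_points(chrom, pos)
            p = np.where(is_cac & in_arr, p * config.array_enrichment, p)
            p = np.clip(p, 0.0, 1.0)
            return pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context3": tri.astype("U3"),
                    "true_p": p,
                }
            )

        frames.append(build(plus_pos, "+"))
        frames.append(build(minus_pos, "-"))
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    total = rng.poisson(config.coverage_mean, size=len(sites))
    meth = rng.binomial(total, sites["true_p"].to_numpy())
    sites["meth"] = meth
    sites["total"] = total
    sites["ratio"] = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return sites


# ---------------------------------------------------------------------------
# ChIP
# ---------------------------------------------------------------------------


def simulate_chip(
    sites: pd.DataFrame,
    contig_sizes: Mapping[str, int],
    config: SimConfig,
    m_field: Mapping[str, np.ndarray] | None = None,
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame]:
    """WT and reference (KO/input) coverage tracks on fixed tiles.

    Expected log2(WT/ref) per tile is ``chip_slope`` times the tile's mean
    *true* CAC methylation level normalized by the genome-wide mean level,
    plus Gaussian noise.  True probabilities (not observed ratios) drive the
    signal so coverage noise and binding noise stay separable.
    """
    rng = _stage_rng(config, 4)
    tiles = tile_contigs(contig_sizes, config.chip_tile)
    cac = sites[sites["context3"] == "CAC"]
    mean_level = float(cac["true_p"].mean())
    level = np.full(len(tiles), np.nan)
    offsets = {}
    off = 0
    for chrom in sorted(contig_sizes):
        offsets[chrom] = off
        off += int(np.ceil(contig_sizes[chrom] / config.chip_tile))
    sums = np.zeros(len(tiles))
    counts = np.zeros(len(tiles), dtype=np.int64)
    for chrom, grp in cac.groupby("chrom", sort=False):
        tidx = grp["pos"].to_numpy() // config.chip_tile + offsets[chrom]
        sums += np.bincount(tidx, weights=grp["true_p"].to_numpy(), minlength=len(tiles))
        counts += np.bincount(tidx, minlength=len(tiles))
    has = counts > 0
    level[has] = sums[has] / counts[has]
    if m_field is not None:  # tiles without any CAC site: expected local level
        for chrom, widx in tiles.groupby("chrom", sort=False).indices.items():
            mids = ((tiles["start"].to_numpy()[widx] + tiles["end"].to_numpy()[widx]) // 2)
            blk = np.minimum(mids // config.region_block_len, m_field[chrom].size - 1)
            fallback = config.rate_mcac * m_field[chrom][blk]
            level[widx] = np.where(np.isnan(level[widx]), fallback, level[widx])
    level = np.where(np.isnan(level), mean_level, level)

    log2_true = config.chip_slope * (level / mean_level) + rng.normal(
        0.0, config.chip_noise_sd, size=len(tiles)
    )
    jitter_ref = np.exp(rng.normal(0.0, config.chip_depth_jitter, size=len(tiles)))
    jitter_wt = np.exp(rng.normal(0.0, config.chip_depth_jitter, size=len(tiles)))
    ref_val = config.chip_depth * jitter_ref
    wt_val = config.chip_depth * np.power(2.0, log2_true) * jitter_wt
    tiles = tiles.assign(level=level, log2_true=log2_true, wt=wt_val, ref=ref_val)

    def track(col):
        d = {}
        for chrom, grp in tiles.groupby("chrom", sort=True):
            d[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy(), grp[col].to_numpy())
        return CoverageTrack(d)

    return track("wt"), track("ref"), tiles


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def true_gene_mcac(sites: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Per-gene sum of true CAC methylation probabilities (both strands)."""
    cac = sites[sites["context3"] == "CAC"]
    out = np.zeros(len(genes))
    for chrom, gidx in genes.groupby("chrom", sort=False).indices.items():
        grp = cac[cac["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cum = np.concatenate([[0.0], np.cumsum(grp["true_p"].to_numpy()[order])])
        s = genes["start"].to_numpy()[gidx]
        e = genes["end"].to_numpy()[gidx]
        out[gidx] = cum[np.searchsorted(pos, e)] - cum[np.searchsorted(pos, s)]
    return out


def simulate_expression(
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """DESeq2-style DE table with fold-changes driven by true gene mCAC."""
    rng = _stage_rng(config, 5)
    mcac = true_gene_mcac(sites, genes)
    sd = mcac.std(ddof=0)
    z = (mcac - mcac.mean()) / sd if sd > 0 else np.zeros_like(mcac)
    n = len(genes)
    regulated = rng.random(n) < config.frac_regulated
    lfc = rng.normal(0.0, config.expr_noise_sd, size=n)
    lfc[regulated] += config.expr_slope * z[regulated]
    pvalue = rng.uniform(0.0, 1.0, size=n)
    pvalue[regulated] = rng.uniform(0.0, 1e-8, size=int(regulated.sum()))
    padj = false_discovery_control(pvalue, method="bh")
    base_mean = np.exp(rng.normal(5.0, 1.0, size=n))
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "baseMean": base_mean,
            "log2fc": lfc,
            "pvalue": pvalue,
            "padj": padj,
            "true_regulated": regulated,
            "true_mcac": mcac,
        }
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: dict[str, str]
    contig_sizes: dict[str, int]
    planted: pd.DataFrame            # planted repeat loci, all classes
    ca_arrays: pd.DataFrame          # CA-class arrays as detected by the scanner
    repeats_non_ca: pd.DataFrame     # planted non-CA repeat annotation
    genes: pd.DataFrame
    m_field: dict[str, np.ndarray]
    sites: pd.DataFrame
    wt_track: CoverageTrack
    ref_track: CoverageTrack
    tiles: pd.DataFrame
    de_table: pd.DataFrame
    partition: GenomePartition = field(default=None)

    @property
    def ca_set(self) -> IntervalSet:
        return self.partition.ca_set


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every stage of the generator and assemble the in-memory study."""
    genome, planted, genes, contig_sizes = simulate_genome(config)
    ca_arrays = scan_genome(genome, units=("CA",), min_len=10)
    repeats_non_ca = planted[planted["repeat_class"] != "CA_repeat"].reset_index(drop=True)
    all_repeats = pd.concat([ca_arrays, repeats_non_ca], ignore_index=True)
    partition = partition_genome(ca_arrays, all_repeats, contig_sizes)
    m_field = simulate_region_field(config, contig_sizes)
    sites = simulate_methylome(genome, partition.ca_set, config, m_field)
    wt, ref, tiles = simulate_chip(sites, contig_sizes, config, m_field)
    de = simulate_expression(genes, sites, config)
    return SimulatedStudy(
        config=config,
        genome=genome,
        contig_sizes=contig_sizes,
        planted=planted,
        ca_arrays=ca_arrays,
        repeats_non_ca=repeats_non_ca,
        genes=genes,
        m_field=m_field,
        sites=sites,
        wt_track=wt,
        ref_track=ref,
        tiles=tiles,
        de_table=de,
        partition=partition,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Serialize the study to its on-disk formats; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "contig_sizes": out / "contigs.tsv",
        "ca_bed": out / "ca_arrays.bed",
        "repeats_bed": out / "repeats_non_ca.bed",
        "genes_bed": out / "genes.bed",
        "cytosine_report": out / "cytosine_report.tsv",
        "wt_bedgraph": out / "chip_wt.bedgraph",
        "ref_bedgraph": out / "chip_ref.bedgraph",
        "de_table": out / "de_table.tsv",
        "config": out / "sim_config.json",
    }
    write_fasta(study.genome, paths["genome"])
    write_contig_sizes(study.contig_sizes, paths["contig_sizes"])
    loci_to_bed(study.ca_arrays, paths["ca_bed"])
    loci_to_bed(study.repeats_non_ca, paths["repeats_bed"])
    write_bed(study.genes, paths["genes_bed"], name_col="gene_id")
    write_cytosine_report(study.sites, paths["cytosine_report"])
    study.wt_track.to_bedgraph(paths["wt_bedgraph"])
    study.ref_track.to_bedgraph(paths["ref_bedgraph"])
    de = study.de_table[["gene_id", "baseMean", "log2fc", "pvalue", "padj"]].rename(
        columns={"log2fc": "log2FoldChange"}
    )
    de.to_csv(paths["de_table"], sep="\t", index=False, float_format="%.10g")
    with open(paths["config"], "w") as fh:
        json.dump(study.config.to_dict(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
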