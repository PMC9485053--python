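"""End-to-end orchestration: simulate -> annotate -> aggregate -> correlate -> report.

Each report stage writes plain TSV tables whose every number is traceable to
one library operation; a JSON manifest (config, seeds, package version,
output digests) makes a run reproducible byte-for-byte.  The three report
groups mirror the three questions of the analysis:

* ``run_fig1_report``  - is modified cytosine enriched in CA repeats?
  (motif occurrence fractions, context means inside/outside arrays, the
  paired local inside-vs-flank comparison, per-gene mCAC vs array mCA
  correlation, bisulfite coverage fractions)
* ``run_fig2_report``  - is MeCP2 occupancy elevated at CA repeats beyond
  what their mCAC explains?  (three-category binned enrichment curves,
  squared Spearman per category, cross-category curve agreement, browser
  tracks)
* ``run_fig4_report``  - does misregulation track CA-repeat content or mCAC?
  (per-covariate binned fold-change curves with unbinned rank correlations,
  regulation-class repeat-content summaries)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chip import CoverageTrack, binned_curve_agreement, run_three_category_analysis
from .errors import UndefinedMeanError
from .expression import (
    class_pct_ca_summary,
    pct_ca_in_gene,
    read_de_table,
    sample_nonregulated,
    select_regulated,
    binned_fc_analysis,
)
from .intervals import IntervalSet
from .io import bed_to_loci, load_genome, read_bed, read_contig_sizes
from .methylome import (
    coverage_fraction,
    filter_by_coverage,
    gene_mcac_covariates,
    local_inside_outside,
    mean_methylation,
    read_cytosine_report,
    window_mcac_track,
)
from .repeats import count_motif_occurrences, fraction_of_motifs_in_regions, partition_genome
from .simulate import SimConfig, simulate_study, write_study
from .stats import pearson_r2

FC_COVARIATES = ("pct_ca", "mcac_incl", "mcac_excl", "mca_in_arrays", "mcac_per_kb")


@dataclass
class RunConfig:
    outdir: str = "carpet_run"
    sim: SimConfig = field(default_factory=SimConfig)
    min_reads: int = 5               # 5 (hypothalamus/forebrain-like) or 10 (cortex-like)
    n_bins: int = 30
    n_background_windows: int = 5000
    window_width: int = 1000
    chunk_target: int = 1000
    pseudocount: float = 1.0
    flank: int = 2000
    alpha: float = 0.05
    de_criterion: str = "padj"
    analysis_seed: int = 0           # background windows + non-regulated sampling

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.pop("sim", {}))
        return cls(sim=sim, **d)


@dataclass
class LoadedInputs:
    genome: dict
    contig_sizes: dict
    ca_arrays: pd.DataFrame
    repeats_non_ca: pd.DataFrame
    genes: pd.DataFrame
    sites_all: pd.DataFrame
    wt_track: CoverageTrack
    ref_track: CoverageTrack
    de_table: pd.DataFrame


def load_inputs(paths: dict) -> LoadedInputs:
    """Read every analysis input back from its on-disk format."""
    genome = load_genome(paths["genome"])
    contig_sizes = read_contig_sizes(paths["contig_sizes"])
    genes = read_bed(paths["genes_bed"]).rename(columns={"name": "gene_id"})
    return LoadedInputs(
        genome=genome,
        contig_sizes=contig_sizes,
        ca_arrays=bed_to_loci(paths["ca_bed"]),
        repeats_non_ca=bed_to_loci(paths["repeats_bed"]),
        genes=genes[["chrom", "start", "end", "gene_id"]],
        sites_all=read_cytosine_report(paths["cytosine_report"]),
        wt_track=CoverageTrack.from_bedgraph(paths["wt_bedgraph"]),
        ref_track=CoverageTrack.from_bedgraph(paths["ref_bedgraph"]),
        de_table=read_de_table(paths["de_table"]),
    )


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_fig1_report(inputs: LoadedInputs, config: RunConfig, outdir) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    partition = partition_genome(
        inputs.ca_arrays,
        pd.concat([inputs.ca_arrays, inputs.repeats_non_ca], ignore_index=True),
        inputs.contig_sizes,
    )
    ca_set = partition.ca_set
    sites = filter_by_coverage(inputs.sites_all, config.min_reads)

    # motif occurrences (Fig 1A analog)
    total = count_motif_occurrences(inputs.genome, "CAC")
    in_ca = count_motif_occurrences(inputs.genome, "CAC", ca_set, inputs.contig_sizes)
    motif = pd.DataFrame(
        [{"motif": "CAC", "total": total, "in_ca_arrays": in_ca,
          "fraction_in_ca": fraction_of_motifs_in_regions(total, in_ca)}]
    )
    _write_tsv(motif, out / "motif_occurrences.tsv")

    # context means (Fig 1B analog); all cytosines inside repeat loci
    can_set = IntervalSet.from_frame(
        inputs.repeats_non_ca[inputs.repeats_non_ca["repeat_class"] == "CAN_repeat"]
    ) if (inputs.repeats_non_ca["repeat_class"] == "CAN_repeat").any() else IntervalSet()
    rows = []
    for label, ctx, scope, outside in (
        ("CAC_genome", "CAC", None, False),
        ("CAC_outside_CA_arrays", "CAC", ca_set, True),
        ("CA_arrays_all_C", None, ca_set, False),
        ("CAN_arrays_all_C", None, can_set, False),
        ("CA_genome", "CA", None, False),
        ("CG_genome", "CG", None, False),
    ):
        try:
            value = mean_methylation(sites, ctx, scope, outside=outside)
        except UndefinedMeanError:
            value = np.nan
        rows.append({"category": label, "mean_methylation": value})
    _write_tsv(pd.DataFrame(rows), out / "context_means.tsv")

    # paired local inside-vs-flank comparison
    local = local_inside_outside(sites, inputs.ca_arrays, ca_set, flank=config.flank)
    _write_tsv(local["per_array"], out / "array_local_comparison.tsv")
    summary = pd.DataFrame([{k: v for k, v in local.items() if k != "per_array"}])
    _write_tsv(summary, out / "array_local_summary.tsv")

    # per-gene mCAC vs mCA-in-arrays (Fig 1C analog)
    cov = gene_mcac_covariates(sites, inputs.genes, ca_set)
    _write_tsv(cov, out / "gene_covariates.tsv")
    with_arrays = cov[cov["mca_in_arrays"] > 0]
    if len(with_arrays) >= 3:
        r2 = pearson_r2(with_arrays["mcac_incl"], with_arrays["mca_in_arrays"])
        gene_r2 = pd.DataFrame(
            [{"x": "mca_in_arrays", "y": "mcac_incl", "pearson_r2": r2.r_squared,
              "n_genes": r2.n_points}]
        )
    else:
        gene_r2 = pd.DataFrame(
            [{"x": "mca_in_arrays", "y": "mcac_incl", "pearson_r2": np.nan, "n_genes": len(with_arrays)}]
        )
    _write_tsv(gene_r2, out / "gene_mcac_pearson.tsv")

    # coverage fractions (Fig 1D analog)
    frac_rows = []
    for label, scope, outside in (("CA_arrays", ca_set, False), ("genome", None, False)):
        try:
            f = coverage_fraction(inputs.sites_all, "CAC", config.min_reads, scope, outside)
        except UndefinedMeanError:
            f = np.nan
        frac_rows.append({"scope": label, "min_reads": config.min_reads, "covered_fraction": f})
    _write_tsv(pd.DataFrame(frac_rows), out / "coverage_fraction.tsv")
    return {"partition": partition, "sites": sites, "gene_covariates": cov, "local": local}


def run_fig2_report(inputs: LoadedInputs, config: RunConfig, outdir, partition=None, sites=None) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if partition is None:
        partition = partition_genome(
            inputs.ca_arrays,
            pd.concat([inputs.ca_arrays, inputs.repeats_non_ca], ignore_index=True),
            inputs.contig_sizes,
        )
    if sites is None:
        sites = filter_by_coverage(inputs.sites_all, config.min_reads)

    results = run_three_category_analysis(
        partition, sites, inputs.wt_track, inputs.ref_track,
        n_windows=config.n_background_windows, n_bins=config.n_bins,
        seed=config.analysis_seed, window_width=config.window_width,
        chunk_target=config.chunk_target, pseudocount=config.pseudocount,
    )
    bins = pd.concat([r.bins_frame() for r in results.values()], ignore_index=True)
    _write_tsv(bins, out / "category_bins.tsv")
    r2 = pd.DataFrame(
        [{"category": name, "spearman_r2_binned": r.r2.r_squared,
          "n_bins": len(r.bins), "n_regions": r.n_regions, "n_dropped": r.n_dropped}
         for name, r in results.items()]
    )
    _write_tsv(r2, out / "category_r2.tsv")
    agree_frames = []
    for name in ("CA_repeats", "repeats_excl_CA"):
        a = binned_curve_agreement(results["background_windows"], results[name])
        a.insert(0, "category", name)
        agree_frames.append(a)
    _write_tsv(pd.concat(agree_frames, ignore_index=True), out / "curve_agreement.tsv")

    # browser-style tracks (Fig 2A/B analog)
    track = window_mcac_track(sites, inputs.contig_sizes, width=config.window_width)
    with open(out / "mcac_per_kb.bedgraph", "w") as fh:
        for _, row in track.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['value']:.6g}\n")
    from .chip import log2_enrichment

    windows = track[["chrom", "start", "end"]]
    enr = log2_enrichment(inputs.wt_track, inputs.ref_track, windows,
                          pseudocount=config.pseudocount)
    with open(out / "enrichment.bedgraph", "w") as fh:
        for (_, row), v in zip(windows.iterrows(), enr):
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{v:.6g}\n")
    return {"results": results}


def run_fig4_report(inputs: LoadedInputs, config: RunConfig, outdir,
                    partition=None, gene_covariates=None, sites=None) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if partition is None:
        partition = partition_genome(
            inputs.ca_arrays,
            pd.concat([inputs.ca_arrays, inputs.repeats_non_ca], ignore_index=True),
            inputs.contig_sizes,
        )
    if sites is None:
        sites = filter_by_coverage(inputs.sites_all, config.min_reads)
    if gene_covariates is None:
        gene_covariates = gene_mcac_covariates(sites, inputs.genes, partition.ca_set)
    gene_covariates = gene_covariates.assign(
        pct_ca=pct_ca_in_gene(gene_covariates, partition.ca_set)
    )
    merged = inputs.de_table.merge(gene_covariates, on="gene_id", how="inner")
    classes = select_regulated(merged, alpha=config.alpha, criterion=config.de_criterion)
    classes = sample_nonregulated(classes, seed=config.analysis_seed)

    regulated = classes.regulated
    bin_frames, r2_rows = [], []
    for key in FC_COVARIATES:
        bins, r2 = binned_fc_analysis(regulated, key, n_bins=min(config.n_bins, len(regulated)))
        bf = pd.DataFrame(
            {
                "covariate": key,
                "bin": [b.bin_index for b in bins],
                "n": [b.n_members for b in bins],
                "mean_covariate": [b.mean_covariate for b in bins],
                "mean_log2fc": [b.mean_response for b in bins],
                "sem_log2fc": [b.sem_response for b in bins],
            }
        )
        bin_frames.append(bf)
        r2_rows.append({"covariate": key, "spearman_r2_unbinned": r2.r_squared,
                        "n_genes": r2.n_points})
    _write_tsv(pd.concat(bin_frames, ignore_index=True), out / "fc_bins.tsv")
    _write_tsv(pd.DataFrame(r2_rows), out / "fc_r2.tsv")
    _write_tsv(class_pct_ca_summary(classes, partition.ca_set), out / "class_pct_ca.tsv")
    counts = pd.DataFrame(
        [{"up": len(classes.up), "down": len(classes.down),
          "nonreg_sample": len(classes.nonreg_sample), "seed": classes.seed}]
    )
    _write_tsv(counts, out / "class_counts.tsv")
    return {"classes": classes, "r2": {r["covariate"]: r["spearman_r2_unbinned"] for r in r2_rows}}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Simulate a study, write its inputs, run all three reports, manifest it."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config.sim)
    paths = write_study(study, out / "inputs")
    inputs = load_inputs(paths)
    fig1 = run_fig1_report(inputs, config, out / "fig1")
    fig2 = run_fig2_report(inputs, config, out / "fig2",
                           partition=fig1["partition"], sites=fig1["sites"])
    fig4 = run_fig4_report(inputs, config, out / "fig4",
                           partition=fig1["partition"],
                           gene_covariates=fig1["gene_covariates"],
                           sites=fig1["sites"])
    report_files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.suffix in (".tsv", ".bedgraph")
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "outputs": {str(p.relative_to(out)): _digest(p) for p in report_files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"paths": paths, "fig1": fig1, "fig2": fig2, "fig4": fig4, "manifest": manifest}
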