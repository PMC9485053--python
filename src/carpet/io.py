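"""Readers and writers for the standard flat formats the pipeline speaks.

FASTA access goes through pyfaidx; everything else (BED6, bedGraph, TSV) is
plain pandas.  Coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from pyfaidx import Fasta

from .errors import FormatError


def load_genome(path) -> dict[str, str]:
    """Load a FASTA into memory as upper-case strings keyed by contig name."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = str(genome[name])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into chrom/start/end (+ name/score/strand when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    if df.shape[1] < 3:
        raise FormatError("BED needs at least 3 columns")
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None, score_col: str | None = None) -> None:
    """Write loci as BED6 (name/score columns configurable, strand defaults '.')."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df[name_col] if name_col else ".",
            "score": df[score_col] if score_col else 0,
            "strand": df["strand"] if "strand" in df.columns else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_contig_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_contig_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def loci_to_bed(loci: pd.DataFrame, path) -> None:
    """Repeat arrays as BED6: name = unit, score = unit count."""
    write_bed(loci, path, name_col="unit", score_col="unit_count")


def bed_to_loci(path) -> pd.DataFrame:
    """Inverse of :func:`loci_to_bed` (repeat class re-derived from the unit)."""
    from .repeats import classify_unit

    df = read_bed(path)
    df = df.rename(columns={"name": "unit", "score": "unit_count"})
    df["repeat_class"] = df["unit"].map(lambda u: classify_unit(str(u)))
    return df
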