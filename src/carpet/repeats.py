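"""Tandem-repeat detection, RepeatMasker annotation import and motif counting.

A *repeat array* here is a maximal, perfect, in-phase run of a short unit
(e.g. ``CACACACACACACA`` = 7 x CA).  Runs of a unit and of its reverse
complement are both reported as plus-strand arrays: a TG run is a CA-class
array on the opposite strand.  Partial trailing units never count, so
``length == unit_count * len(unit)`` always holds for scanned arrays.

Loci are carried as pandas DataFrames with columns
``chrom, start, end, strand, unit, unit_count, repeat_class`` (0-based
half-open coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .intervals import IntervalSet, subtract_loci
from .seq import motif_positions, revcomp, seq_to_bytes, validate_dna

CA_UNITS = frozenset({"CA", "TG"})
CAN_UNITS = frozenset({"CAA", "TTG", "CAG", "CTG", "CAT", "ATG"})

LOCUS_COLUMNS = ["chrom", "start", "end", "strand", "unit", "unit_count", "repeat_class"]


def classify_unit(unit: str) -> str:
    if unit in CA_UNITS:
        return "CA_repeat"
    if unit in CAN_UNITS:
        return "CAN_repeat"
    return "other_repeat"


def classify_label(label: str) -> tuple[str, str]:
    """RepeatMasker label like ``(TG)n`` -> (unit, repeat_class)."""
    if not (label.startswith("(") and label.endswith(")n")):
        return label, "other_repeat"
    unit = label[1:-2].upper()
    return unit, classify_unit(unit)


def empty_loci() -> pd.DataFrame:
    return pd.DataFrame(columns=LOCUS_COLUMNS).astype(
        {"start": np.int64, "end": np.int64, "unit_count": np.int64}
    )


def _expand_units(units: Iterable[str]) -> list[str]:
    """Add reverse complements, deduplicate, keep deterministic order."""
    seen: dict[str, None] = {}
    for u in units:
        u = validate_dna(u)
        if "N" in u or not u:
            raise InvalidInputError(f"invalid repeat unit {u!r}")
        for v in (u, revcomp(u)):
            seen.setdefault(v)
    return list(seen)


def _runs_for_unit(seq_bytes: np.ndarray, unit: str) -> list[tuple[int, int]]:
    """Maximal in-phase runs of ``unit``: list of (start, n_units)."""
    k = len(unit)
    hits = motif_positions(seq_bytes, unit)
    if hits.size == 0:
        return []
    runs = []
    # group hits by phase (start mod k); within a phase, consecutive hits k apart chain
    for phase in range(k):
        ph = hits[hits % k == phase]
        if ph.size == 0:
            continue
        breaks = np.nonzero(np.diff(ph) != k)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [ph.size - 1]])
        for a, b in zip(starts, ends):
            runs.append((int(ph[a]), int(b - a + 1)))
    return runs


def scan_tandem_arrays(
    sequence: str,
    units: Iterable[str] = ("CA",),
    min_len: int = 10,
    chrom: str = "seq",
) -> pd.DataFrame:
    """All maximal perfect tandem runs of the given units (plus their reverse
    complements) with run length >= ``min_len`` base pairs.

    Runs interrupted by N are split (N matches nothing).  When runs of two
    different units overlap, the longer one wins (ties: leftmost, then unit
    lexicographic) so the output never overlaps itself.
    """
    seq = validate_dna(sequence)
    expanded = _expand_units(units)
    if min_len < max(len(u) for u in expanded):
        raise InvalidInputError("min_len shorter than the repeat unit")
    sb = seq_to_bytes(seq)
    candidates = []
    for unit in expanded:
        for start, n_units in _runs_for_unit(sb, unit):
            length = n_units * len(unit)
            if length >= min_len:
                candidates.append((start, length, n_units, unit))
    # greedy overlap resolution: longest first, deterministic tie-break
    candidates.sort(key=lambda c: (-c[1], c[0], c[3]))
    kept: list[tuple[int, int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        s, length = cand[0], cand[1]
        e = s + length
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        kept.append(cand)
        occupied.append((s, e))
    kept.sort(key=lambda c: c[0])
    if not kept:
        return empty_loci()
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c[0] for c in kept],
            "end": [c[0] + c[1] for c in kept],
            "strand": ".",
            "unit": [c[3] for c in kept],
            "unit_count": [c[2] for c in kept],
            "repeat_class": [classify_unit(c[3]) for c in kept],
        }
    )


def scan_genome(
    genome: Mapping[str, str],
    units: Iterable[str] = ("CA",),
    min_len: int = 10,
) -> pd.DataFrame:
    """Run :func:`scan_tandem_arrays` over every contig of a genome."""
    frames = [
        scan_tandem_arrays(str(genome[chrom]), units, min_len, chrom=chrom)
        for chrom in sorted(genome)
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return empty_loci()
    return pd.concat(frames, ignore_index=True)


def read_repeatmasker_table(
    path,
    label_set: set[str] | None = None,
    one_based: bool = False,
) -> pd.DataFrame:
    """Read a UCSC-table-browser style RepeatMasker TSV.

    Expects (at least) columns ``chrom``, ``start``, ``end``, ``repeat_label``
    (header row required).  ``one_based=True`` converts 1-based inclusive
    starts to the internal 0-based convention.  When ``label_set`` is given,
    only rows whose label is in the set are returned.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "repeat_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"RepeatMasker table missing columns: {sorted(missing)}")
    if one_based:
        df["start"] = df["start"] - 1
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise FormatError(f"malformed coordinates at data line(s) {list(bad + 2)}")
    if label_set is not None:
        df = df[df["repeat_label"].isin(label_set)]
    units, classes = zip(*df["repeat_label"].map(classify_label)) if len(df) else ((), ())
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(dtype=np.int64),
            "end": df["end"].to_numpy(dtype=np.int64),
            "strand": ".",
            "unit": list(units),
            "unit_count": [
                int((e - s) // len(u)) if u else 0
                for s, e, u in zip(df["start"], df["end"], units)
            ],
            "repeat_class": list(classes),
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def count_motif_occurrences(
    genome: Mapping[str, str],
    motif: str,
    regions: IntervalSet | None = None,
    contig_sizes: Mapping[str, int] | None = None,
) -> int:
    """Occurrences of ``motif`` on both strands, counted on the plus strand.

    Overlapping occurrences all count (``CACAC`` holds two CACs).  The reverse
    complement is counted as an independent plus-strand motif unless the motif
    is its own reverse complement.  An occurrence belongs to a region iff its
    first (plus-strand) base lies inside it.
    """
    motif = validate_dna(motif)
    if "N" in motif:
        raise InvalidInputError("motif must be over A/C/G/T")
    probes = [motif]
    rc = revcomp(motif)
    if rc != motif:
        probes.append(rc)
    if regions is not None and contig_sizes is not None:
        for chrom in regions.chroms:
            if chrom not in contig_sizes:
                raise InvalidInputError(f"region on unknown contig {chrom!r}")
            if regions.pairs(chrom)[:, 1].max(initial=0) > contig_sizes[chrom]:
                raise InvalidInputError(f"region outside contig {chrom!r}")
    total = 0
    for chrom in sorted(genome):
        sb = seq_to_bytes(validate_dna(str(genome[chrom])))
        for probe in probes:
            pos = motif_positions(sb, probe)
            if regions is None:
                total += int(pos.size)
            else:
                total += int(regions.contains_points(chrom, pos).sum())
    return total


def fraction_of_motifs_in_regions(total: int, in_regions: int) -> float:
    if total <= 0:
        raise InvalidInputError("total motif count must be positive")
    if not 0 <= in_regions <= total:
        raise InvalidInputError("in_regions must lie in [0, total]")
    return in_regions / total


@dataclass
class GenomePartition:
    """The three sequence categories of the occupancy analysis."""

    ca_arrays: pd.DataFrame         # CA-class loci
    other_repeats: pd.DataFrame     # all other repeat loci, CA bases subtracted
    ca_set: IntervalSet             # merged shadow of ca_arrays
    background: IntervalSet         # genome minus ca_arrays
    contig_sizes: dict[str, int]


def partition_genome(
    ca_arrays: pd.DataFrame,
    all_repeats: pd.DataFrame,
    contig_sizes: Mapping[str, int],
) -> GenomePartition:
    """Split the genome into CA arrays, other repeats, and background.

    ``other_repeats`` is ``all_repeats`` minus any base covered by a CA array
    (fragments keep their metadata); ``background`` is the genomic complement
    of the CA arrays.
    """
    for df, what in ((ca_arrays, "ca_arrays"), (all_repeats, "all_repeats")):
        unknown = set(df["chrom"]) - set(contig_sizes)
        if unknown:
            raise InvalidInputError(f"{what} on unknown contigs: {sorted(unknown)}")
    ca_set = IntervalSet.from_frame(ca_arrays) if len(ca_arrays) else IntervalSet()
    non_ca = all_repeats[all_repeats["repeat_class"] != "CA_repeat"]
    other = subtract_loci(non_ca, ca_set)
    background = ca_set.complement(contig_sizes)
    return GenomePartition(
        ca_arrays=ca_arrays.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True),
        other_repeats=other,
        ca_set=ca_set,
        background=background,
        contig_sizes=dict(contig_sizes),
    )
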