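"""A small genomic-interval engine.

Coordinates are 0-based half-open (BED convention) throughout.  An
:class:`IntervalSet` holds, per chromosome, a sorted, merged ``(N, 2)`` array of
``[start, end)`` pairs and supports the set algebra the pipeline needs:
union, base-wise subtraction, complement against contig sizes, point
membership and per-interval overlap counting.  Locus *lists* (repeat arrays,
genes), which carry metadata and may legitimately touch each other, live in
pandas DataFrames; an IntervalSet is the merged, anonymous shadow of such a
list used for set arithmetic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError


def _normalize(pairs: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or adjacent [start, end) pairs."""
    if pairs.size == 0:
        return pairs.reshape(0, 2).astype(np.int64)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if np.any(pairs[:, 0] >= pairs[:, 1]):
        raise InvalidInputError("interval with start >= end")
    if np.any(pairs[:, 0] < 0):
        raise InvalidInputError("negative interval coordinate")
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    merged_start = [pairs[0, 0]]
    merged_end = [pairs[0, 1]]
    for s, e in pairs[1:]:
        if s <= merged_end[-1]:
            merged_end[-1] = max(merged_end[-1], e)
        else:
            merged_start.append(s)
            merged_end.append(e)
    return np.column_stack([merged_start, merged_end]).astype(np.int64)


class IntervalSet:
    """Sorted, merged intervals per chromosome."""

    def __init__(self, by_chrom: Mapping[str, np.ndarray] | None = None):
        self._d: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, pairs in by_chrom.items():
                arr = _normalize(np.asarray(pairs))
                if arr.size:
                    self._d[chrom] = arr

    # -- construction -------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        """Build from a DataFrame with ``chrom``/``start``/``end`` columns."""
        d: dict[str, list] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            d[chrom] = np.column_stack([sub["start"].to_numpy(), sub["end"].to_numpy()])
        return cls(d)

    @classmethod
    def whole_genome(cls, contig_sizes: Mapping[str, int]) -> "IntervalSet":
        return cls({c: np.array([[0, n]]) for c, n in contig_sizes.items() if n > 0})

    # -- basics --------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self._d)

    def pairs(self, chrom: str) -> np.ndarray:
        return self._d.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(a.shape[0] for a in self._d.values())

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._d.values()))

    def is_empty(self) -> bool:
        return not self._d

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, int(s), int(e))
            for chrom in self.chroms
            for s, e in self._d[chrom]
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # -- set algebra ---------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        d: dict[str, np.ndarray] = {}
        for chrom in set(self._d) | set(other._d):
            d[chrom] = np.vstack([self.pairs(chrom), other.pairs(chrom)])
        return IntervalSet(d)

    def complement(self, contig_sizes: Mapping[str, int]) -> "IntervalSet":
        d: dict[str, list] = {}
        for chrom, size in contig_sizes.items():
            pairs = self.pairs(chrom)
            out = []
            prev = 0
            for s, e in pairs:
                if s > size or e > size:
                    raise InvalidInputError(
                        f"interval [{s},{e}) exceeds contig {chrom} size {size}"
                    )
                if s > prev:
                    out.append((prev, s))
                prev = max(prev, e)
            if prev < size:
                out.append((prev, size))
            if out:
                d[chrom] = np.array(out)
        return IntervalSet(d)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        d: dict[str, list] = {}
        for chrom, pairs in self._d.items():
            cut = other.pairs(chrom)
            if cut.size == 0:
                d[chrom] = pairs
                continue
            out = []
            for s, e in pairs:
                pos = s
                # cut intervals overlapping [s, e)
                lo = np.searchsorted(cut[:, 1], s, side="right")
                for cs, ce in cut[lo:]:
                    if cs >= e:
                        break
                    if cs > pos:
                        out.append((pos, cs))
                    pos = max(pos, ce)
                if pos < e:
                    out.append((pos, e))
            if out:
                d[chrom] = np.array(out)
        return IntervalSet(d)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return self.subtract(self.subtract(other))

    # -- queries -------------------------------------------------------
    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: is each 0-based position inside the set?"""
        pairs = self.pairs(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if pairs.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(pairs[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < pairs[idx[ok], 1]
        return res

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Base pairs of overlap between the set and each query [start, end)."""
        pairs = self.pairs(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(starts.shape, dtype=np.int64)
        if pairs.size == 0:
            return out
        # prefix sums of merged interval lengths
        lens = pairs[:, 1] - pairs[:, 0]
        cum = np.concatenate([[0], np.cumsum(lens)])

        def covered_before(pos: np.ndarray) -> np.ndarray:
            """Total covered bases in [0, pos)."""
            idx = np.searchsorted(pairs[:, 0], pos, side="right") - 1
            base = cum[np.clip(idx, 0, None)]
            base = np.where(idx < 0, 0, base)
            partial = np.clip(pos - pairs[np.clip(idx, 0, None), 0], 0, None)
            partial = np.minimum(partial, lens[np.clip(idx, 0, None)])
            partial = np.where(idx < 0, 0, partial)
            return base + partial

        return covered_before(ends) - covered_before(starts)


def subtract_loci(loci: pd.DataFrame, cut: IntervalSet) -> pd.DataFrame:
    """Base-wise subtract ``cut`` from each locus, keeping per-locus metadata.

    A locus overlapping the cut set is replaced by its uncovered fragments
    (possibly none); all other columns are copied onto each fragment.
    """
    rows = []
    for _, row in loci.iterrows():
        single = IntervalSet({row["chrom"]: np.array([[row["start"], row["end"]]])})
        remainder = single.subtract(cut)
        for s, e in remainder.pairs(row["chrom"]):
            new = row.copy()
            new["start"], new["end"] = int(s), int(e)
            rows.append(new)
    if not rows:
        return loci.iloc[0:0].copy()
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def tile_contigs(contig_sizes: Mapping[str, int], width: int) -> pd.DataFrame:
    """Non-overlapping tiling windows covering every contig (last may be short)."""
    rows = []
    for chrom in sorted(contig_sizes):
        size = contig_sizes[chrom]
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def check_same_contigs(a: Iterable[str], b: Iterable[str], what: str) -> None:
    sa, sb = set(a), set(b)
    if not sa & sb:
        raise InvalidInputError(f"contig mismatch in {what}: {sorted(sa)} vs {sorted(sb)}")
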