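"""Tandem-array scanner, RepeatMasker reader, motif counting, partition."""

import re

import numpy as np
import pandas as pd
import pytest

from carpet.errors import FormatError, InvalidInputError
from carpet.intervals import IntervalSet
from carpet.repeats import (
    classify_label,
    count_motif_occurrences,
    fraction_of_motifs_in_regions,
    partition_genome,
    read_repeatmasker_table,
    scan_tandem_arrays,
)
from carpet.seq import revcomp


def regex_oracle(seq, units, min_len):
    """Maximal perfect runs via regex, the independent route."""
    hits = []
    expanded = set()
    for u in units:
        expanded |= {u, revcomp(u)}
    for u in sorted(expanded):
        k = max(1, (min_len + len(u) - 1) // len(u))
        for m in re.finditer(f"(?:{u}){{{k},}}", seq):
            hits.append((m.start(), m.end(), u, (m.end() - m.start()) // len(u)))
    # resolve overlaps: longest first, then leftmost, then unit
    hits.sort(key=lambda h: (-(h[1] - h[0]), h[0], h[2]))
    kept = []
    for h in hits:
        if all(h[1] <= k[0] or k[1] <= h[0] for k in kept):
            kept.append(h)
    return sorted(kept)


class TestScanner:
    def test_below_threshold(self):
        assert len(scan_tandem_arrays("CACACACAC", ("CA",), 10)) == 0

    def test_simple_array_with_trailing_partial(self):
        # CACACACACAC = 5 full CA units + trailing C
        df = scan_tandem_arrays("TTCACACACACACTT", ("CA",), 10)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["start"], row["end"], row["unit_count"]) == (2, 12, 5)
        assert row["end"] - row["start"] == row["unit_count"] * 2

    def test_tg_run_is_ca_class(self):
        df = scan_tandem_arrays("AATGTGTGTGTGAA", ("CA",), 10)
        assert len(df) == 1
        assert df.iloc[0]["unit"] == "TG"
        assert df.iloc[0]["repeat_class"] == "CA_repeat"

    def test_caga_tract_has_no_ca_array(self):
        assert len(scan_tandem_arrays("CAGACAGACAGACA", ("CA",), 10)) == 0

    def test_n_truncates_runs(self):
        df = scan_tandem_arrays("CACACACACANCACACACACA", ("CA",), 10)
        assert df["start"].tolist() == [0, 11]
        assert df["unit_count"].tolist() == [5, 5]

    def test_invalid_characters(self):
        with pytest.raises(InvalidInputError):
            scan_tandem_arrays("CACAXCACA", ("CA",), 10)

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            got = scan_tandem_arrays(seq, ("CA",), 10)
            expect = regex_oracle(seq, ("CA",), 10)
            assert [
                (r["start"], r["end"], r["unit"], r["unit_count"])
                for _, r in got.iterrows()
            ] == expect

    def test_no_self_overlap_and_maximality(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.3, 0.1, 0.2], size=500))
            df = scan_tandem_arrays(seq, ("CA", "CAA"), 9)
            rows = sorted((r["start"], r["end"], r["unit"]) for _, r in df.iterrows())
            for (s1, e1, _), (s2, e2, _) in zip(rows, rows[1:]):
                assert e1 <= s2  # disjoint
            for s, e, u in rows:
                k = len(u)
                assert seq[s : s + k] == u  # phase anchored
                assert seq[s:e] == u * ((e - s) // k)
                # extending a full unit on either side breaks the repeat
                if s - k >= 0:
                    assert seq[s - k : s] != u
                assert seq[e : e + k] != u

    def test_reverse_complement_mirror(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd = scan_tandem_arrays(seq, ("CA",), 10)
        rev = scan_tandem_arrays(revcomp(seq), ("CA",), 10)
        n = len(seq)
        mirrored = sorted((n - r["end"], n - r["start"]) for _, r in fwd.iterrows())
        assert sorted((r["start"], r["end"]) for _, r in rev.iterrows()) == mirrored


class TestRepeatMaskerReader:
    def _write(self, tmp_path, rows, header="chrom\tstart\tend\trepeat_label\n"):
        p = tmp_path / "rm.tsv"
        p.write_text(header + "".join(rows))
        return p

    def test_label_filtering_and_classes(self, tmp_path):
        p = self._write(
            tmp_path,
            ["chr1\t100\t130\t(TG)n\n", "chr1\t200\t230\t(CAG)n\n", "chr1\t300\t350\t(AT)n\n"],
        )
        ca = read_repeatmasker_table(p, label_set={"(CA)n", "(TG)n"})
        assert len(ca) == 1
        assert ca.iloc[0]["repeat_class"] == "CA_repeat"
        assert ca.iloc[0]["unit_count"] == 15  # 30 bp of TG
        everything = read_repeatmasker_table(p)
        assert everything["repeat_class"].tolist() == ["CA_repeat", "CAN_repeat", "other_repeat"]

    def test_one_based_flag(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t101\t130\t(CA)n\n"])
        assert read_repeatmasker_table(p, one_based=True).iloc[0]["start"] == 100

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart\tend\nchr1\t1\t2\n")
        with pytest.raises(FormatError):
            read_repeatmasker_table(p)

    def test_malformed_coordinates(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t130\t100\t(CA)n\n"])
        with pytest.raises(FormatError):
            read_repeatmasker_table(p)

    def test_label_classification(self):
        assert classify_label("(TTG)n") == ("TTG", "CAN_repeat")
        assert classify_label("(AT)n") == ("AT", "other_repeat")
        assert classify_label("L1Md_F2") == ("L1Md_F2", "other_repeat")


def sliding_window_count(seq, motif, region=None):
    rc = revcomp(motif)
    probes = {motif, rc}
    n = 0
    for p in probes:
        for i in range(len(seq) - len(p) + 1):
            if seq[i : i + len(p)] == p and (region is None or region[0] <= i < region[1]):
                n += 1
    return n


class TestMotifCounting:
    @pytest.mark.parametrize(
        "seq, motif, expected",
        [
            ("CACAC", "CAC", 2),    # overlapping occurrences both count
            ("GTGGTG", "CAC", 2),   # reverse-complement occurrences count
            ("AAAA", "CAC", 0),
        ],
    )
    def test_examples(self, seq, motif, expected):
        assert count_motif_occurrences({"c": seq}, motif) == expected

    def test_palindromic_motif_not_double_counted(self):
        assert count_motif_occurrences({"c": "ACGT"}, "ACGT") == 1

    def test_matches_sliding_oracle(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.3, 0.2, 0.2], size=300))
            assert count_motif_occurrences({"c": seq}, "CAC") == sliding_window_count(seq, "CAC")

    def test_region_assignment_by_first_base(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        region = (100, 200)
        rs = IntervalSet({"c": np.array([region])})
        got = count_motif_occurrences({"c": seq}, "CAC", rs, {"c": len(seq)})
        assert got == sliding_window_count(seq, "CAC", region)

    def test_partition_conservation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        inside = IntervalSet({"c": np.array([[100, 300], [600, 650]])})
        outside = inside.complement({"c": 1000})
        total = count_motif_occurrences({"c": seq}, "CAC")
        a = count_motif_occurrences({"c": seq}, "CAC", inside, {"c": 1000})
        b = count_motif_occurrences({"c": seq}, "CAC", outside, {"c": 1000})
        assert a + b == total

    def test_region_outside_contig(self):
        rs = IntervalSet({"c": np.array([[0, 50]])})
        with pytest.raises(InvalidInputError):
            count_motif_occurrences({"c": "ACGT"}, "CAC", rs, {"c": 4})


class TestFraction:
    def test_definition(self):
        assert fraction_of_motifs_in_regions(100, 6) == pytest.approx(0.06)
        assert fraction_of_motifs_in_regions(100, 0) == 0.0

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            fraction_of_motifs_in_regions(0, 0)
        with pytest.raises(InvalidInputError):
            fraction_of_motifs_in_regions(10, 11)


class TestPartition:
    def test_subtraction_example(self):
        ca = pd.DataFrame(
            [{"chrom": "c", "start": 120, "end": 160, "strand": ".", "unit": "CA",
              "unit_count": 20, "repeat_class": "CA_repeat"}]
        )
        rep = pd.DataFrame(
            [{"chrom": "c", "start": 100, "end": 150, "strand": ".", "unit": "AT",
              "unit_count": 25, "repeat_class": "other_repeat"}]
        )
        part = partition_genome(ca, pd.concat([ca, rep]), {"c": 1000})
        assert len(part.other_repeats) == 1
        assert (part.other_repeats.iloc[0]["start"], part.other_repeats.iloc[0]["end"]) == (100, 120)
        # background excludes the array
        assert not part.background.contains_points("c", np.array([130]))[0]
        assert part.background.contains_points("c", np.array([110]))[0]

    def test_base_disjointness_on_random_sets(self, rng):
        def random_loci(n, cls):
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), size=n, replace=False))
            return pd.DataFrame(
                {
                    "chrom": "c",
                    "start": starts,
                    "end": starts + rng.integers(5, 40, size=n),
                    "strand": ".",
                    "unit": "CA" if cls == "CA_repeat" else "AT",
                    "unit_count": 5,
                    "repeat_class": cls,
                }
            )

        ca = random_loci(30, "CA_repeat")
        other = random_loci(40, "other_repeat")
        part = partition_genome(ca, pd.concat([ca, other]), {"c": 6000})
        other_set = IntervalSet.from_frame(part.other_repeats)
        assert other_set.intersect(part.ca_set).total_length() == 0
        assert part.background.intersect(part.ca_set).total_length() == 0

    def test_contig_mismatch(self):
        ca = pd.DataFrame(
            [{"chrom": "weird", "start": 0, "end": 10, "strand": ".", "unit": "CA",
              "unit_count": 5, "repeat_class": "CA_repeat"}]
        )
        with pytest.raises(InvalidInputError):
            partition_genome(ca, ca, {"c": 100})
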