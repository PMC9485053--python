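"""Pulldown-assay oligonucleotide probes, parsed as worked examples.

Biotin-tagged double-stranded oligonucleotide probes for a MeCP2 pulldown
assay: a [CA]7 tract with 0, 1 or 4 methylated cytosines, a CAGA-repeat
control in which CA never forms a pure dinucleotide run, two unrelated
controls, and CAC/CG probes with and without methyl marks.  In the raw
strings ``m`` marks a methylated cytosine (the following base), ``B`` the
biotin tag; whitespace is line-wrapping noise.

:func:`parse_probe` strips the decorations and returns the clean plus-strand
DNA together with the 0-based positions of methylated cytosines, so the
probes double as exact fixtures for the repeat scanner and motif counter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError
from .seq import validate_dna

RAW_PROBES: dict[str, str] = {
    "C1": (
        "5'-B-tgcgctatgcacttgcgctatgcactttgcgctaatgcacttgcgcttattgcgcacttgcacttttgcacacgcg"
        "cacgatgcgcttaatgcgcgattgcacacgctgcacacacgcgctttgca-3'"
    ),
    "[CA]7": (
        "5'-B-tgcgctatgcacttgcgctatgcactttgcgctaatgcacttgcgCACACACACACACActtattgcgcacttgca"
        "cttttgcacacgcgcacgatgcgcttaatgcgcgattgcacacgctgcacacacgcgctttgca-3'"
    ),
    "[CA]7-1mC": (
        "5'-B-tgcgctatgcacttgcgctatgcactttgcgctaatgcacttgcgCACAmCACACACACActtattgcgcacttgca"
        "cttttgcacacgcgcacgatgcgcttaatgcgcgattgcacacgctgcacacacgcgctttgca-3'"
    ),
    "[CA]7-4mC": (
        "5'-B-tgcgctatgcacttgcgctatgcactttgcgctaatgcacttgcgmCACAmCACAmCACAmCActtattgcgcacttg"
        "cacttttgcacacgcgcacgatgcgcttaatgcgcgattgcacacgctgcacacacgcgctttgca-3'"
    ),
    "C2": (
        "5'-B-tgcgctatgcacttgcgctatgcactttgcgctaatgcacttgcgCAGACAGACAGACActtattgcgca"
        "cttgcacttttgcacacgcgcacgatgcgcttaatgcgcgattgcacacgctgcacacacgcgctttgca-3'"
    ),
    "CAC": (
        "5'-B-cgcactttgcactatgcacttgcactatgcactttgcactaatgcacttgcacttattgcacacttgca"
        "cttttgcacacacgcacgatgcacttaatgcacgattgcacacactgcacacacgcactttgcacactgca-3'"
    ),
    "mCAC": (
        "5'-B-cgcactttgmCACtatgcacttgmCACtatgcactttgmCACtaatgcacttgmCACttattgmCACacttgcac"
        "ttttgcacamCACgcacgatgmCACttaatgmCACgattgcacamCACtgcacacacgmCACtttgcacactgca-3'"
    ),
    "CG": (
        "5'-B-cgcactttgCGctatgcacttgCGctatgcactttgCGctaatgcacttgCGcttattgCGcacttgcacttttg"
        "cacaCGcgcacgatgCGcttaatgCGcgattgcacaCGctgcacacacgCGctttgcacactgca-3'"
    ),
    "mCG": (
        "5'-B-cgcactttgmCGctatgcacttgmCGctatgcactttgmCGctaatgcacttgmCGgcttattgmCGcacttgcac"
        "ttttgcacamCGcgcacgatgmCGcttaatgmCGcgattgcacamCGctgcacacacgmCGctttgcacactgca-3'"
    ),
}


@dataclass(frozen=True)
class Probe:
    name: str
    sequence: str              # clean upper-case plus-strand DNA
    methylated_positions: tuple[int, ...]  # 0-based positions of methylated Cs

    @property
    def n_methylated(self) -> int:
        return len(self.methylated_positions)


def parse_probe(name: str, raw: str | None = None) -> Probe:
    """Parse a raw probe string into clean DNA plus methyl-C positions."""
    if raw is None:
        try:
            raw = RAW_PROBES[name]
        except KeyError:
            raise FormatError(f"unknown probe {name!r}") from None
    s = raw.replace(" ", "").replace("\n", "")
    for tag in ("5'-B-", "5'-"):
        if s.startswith(tag):
            s = s[len(tag) :]
            break
    if s.endswith("-3'"):
        s = s[: -len("-3'")]
    bases = []
    methylated = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "m":
            if i + 1 >= len(s) or s[i + 1].upper() != "C":
                raise FormatError(f"probe {name!r}: methyl mark not followed by C at {i}")
            methylated.append(len(bases))
            i += 1
            continue
        bases.append(ch)
        i += 1
    seq = validate_dna("".join(bases))
    return Probe(name, seq, tuple(methylated))


def all_probes() -> dict[str, Probe]:
    return {name: parse_probe(name) for name in RAW_PROBES}
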