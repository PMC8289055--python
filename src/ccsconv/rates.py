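"""Molecular-rate analyses: Tajima's relative rate test, fourfold-degenerate
site extraction from codon alignments, and Kimura two-parameter distances.

Tajima's relative rate test compares two ingroup sequences against an
outgroup: m1 counts sites where only ingroup 1 differs from the other two,
m2 where only ingroup 2 differs.  Under equal rates m1 and m2 have the
same expectation, so (m1 - m2)^2 / (m1 + m2) is referred to chi-square on
1 df (the approximation used by MEGA); an exact two-sided binomial test is
available as an alternative.

Fourfold-degenerate (4D) sites are third codon positions whose codon
family encodes the same amino acid for every nucleotide — a standard proxy
for neutrally evolving sequence.  A codon column is retained only when all
taxa share the identical two-nucleotide prefix and that prefix heads a 4D
family of the standard genetic code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binomtest
from scipy.stats import chi2 as chi2_dist

from .io_formats import OrthologAlignment

#: dinucleotide prefixes whose four codons encode one amino acid
#: (standard genetic code): Ser, Leu, Pro, Arg, Thr, Val, Ala, Gly
FOURFOLD_PREFIXES = frozenset(
    ["TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"]
)

_NUC = frozenset("ACGT")
_PURINES = frozenset("AG")


@dataclass
class RRTResult:
    """Tajima relative-rate test outcome for one (ingroup1, ingroup2,
    outgroup) triple."""

    m1: int
    m2: int
    n_sites_used: int
    chi2: float
    p_value: float


@dataclass
class FourfoldAlignment:
    """Third-codon-position alignment restricted to 4D codon columns."""

    source_id: str
    positions: list[int]  # 1-based codon indices retained
    sequences: dict[str, str]

    @property
    def length(self) -> int:
        return len(self.positions)


def tajima_rrt(
    ingroup1: str, ingroup2: str, outgroup: str, exact: bool = False
) -> RRTResult:
    """Tajima's relative rate test on three equal-length sequences
    (amino acid or nucleotide); sites with any gap/'X'/'N' are excluded."""
    if not (len(ingroup1) == len(ingroup2) == len(outgroup)):
        raise ValueError("the three sequences must have equal length")
    m1 = m2 = used = 0
    for a, b, o in zip(ingroup1.upper(), ingroup2.upper(), outgroup.upper()):
        if any(c in "-XN?" for c in (a, b, o)):
            continue
        used += 1
        if a != b and b == o:
            m1 += 1
        elif a != b and a == o:
            m2 += 1
    if m1 + m2 == 0:
        return RRTResult(m1, m2, used, 0.0, 1.0)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    if exact:
        p = binomtest(m1, m1 + m2, 0.5).pvalue
    else:
        p = float(chi2_dist.sf(chi2, df=1))
    return RRTResult(m1, m2, used, float(chi2), p)


def extract_4d(
    codon_alignment: OrthologAlignment,
    relaxed_reference: str | None = None,
) -> FourfoldAlignment:
    """Extract third positions of fourfold-degenerate codon columns.

    Default (strict) rule: a codon column is kept iff in every taxon the
    codon is unambiguous (ACGT only), all taxa share the identical first
    two nucleotides, and that prefix is a 4D family.  With
    ``relaxed_reference=<taxon>`` the family test uses that taxon's prefix
    only, and other taxa merely need unambiguous codons (per-reference
    behaviour of some extraction tools).
    """
    length = codon_alignment.length
    if length % 3 != 0:
        raise ValueError(
            f"{codon_alignment.gene_id}: alignment length {length} is not a "
            "multiple of 3"
        )
    taxa = codon_alignment.taxa
    if relaxed_reference is not None and relaxed_reference not in taxa:
        raise ValueError(f"reference taxon '{relaxed_reference}' not in alignment")
    positions: list[int] = []
    thirds: dict[str, list[str]] = {t: [] for t in taxa}
    for c in range(length // 3):
        codons = {t: codon_alignment.sequences[t][3 * c: 3 * c + 3] for t in taxa}
        if any(set(cod) - _NUC for cod in codons.values()):
            continue
        if relaxed_reference is None:
            prefixes = {cod[:2] for cod in codons.values()}
            if len(prefixes) != 1 or next(iter(prefixes)) not in FOURFOLD_PREFIXES:
                continue
        else:
            if codons[relaxed_reference][:2] not in FOURFOLD_PREFIXES:
                continue
        positions.append(c + 1)
        for t in taxa:
            thirds[t].append(codons[t][2])
    return FourfoldAlignment(
        codon_alignment.gene_id,
        positions,
        {t: "".join(v) for t, v in thirds.items()},
    )


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance in substitutions/site:
    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions.  Sites with non-ACGT characters in either
    sequence are excluded pairwise; saturated pairs return infinity."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _NUC or b not in _NUC:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    arg = (1.0 - 2.0 * P - Q) * math.sqrt(max(1.0 - 2.0 * Q, 0.0))
    if arg <= 0.0:
        import logging

        logging.getLogger(__name__).warning(
            "k2p_distance: saturated pair (P=%.3f, Q=%.3f)", P, Q
        )
        return math.inf
    return -0.5 * math.log(arg)
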