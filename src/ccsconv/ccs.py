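"""Convergence-at-conservative-sites (CCS) caller.

A column is *conservative for the foreground* when every background control
taxon carries, unambiguously, the same residue as the outgroup O; the
ancestral state of both foreground clusters is then assumed to be O.  A
foreground convergent substitution is called when a single derived residue
d != O is shared by at least ``min_shared_per_cluster`` taxa (default 3 of
4, i.e. at least 6 of the 8) in EACH of the two foreground clusters.  The
rule is symmetric: exchanging the foreground and background roles exchanges
the calls.  Columns where the outgroup is gapped or ambiguous are skipped,
and a gap never counts as matching O.

Foreground and background totals are compared with a two-cell Pearson
goodness-of-fit test against the equal expectation implied by the
symmetric design: chi2 = (f - b)^2 / (f + b) on 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .io_formats import OrthologAlignment, SpeciesDesign
from .models import N_STATES, decode_residues, encode_residues

logger = logging.getLogger(__name__)


@dataclass
class SiteCall:
    """Classification of one alignment column under the symmetric design."""

    gene_id: str
    column: int  # 1-based
    direction: str  # 'foreground' | 'background' | 'none'
    ancestral_state: str | None
    derived_state: str | None
    supporting_taxa: list[str]
    is_convergent: bool

    @property
    def substitution_label(self) -> str | None:
        """Protein-style label like ``D401E`` for a convergent call."""
        if not self.is_convergent:
            return None
        return f"{self.ancestral_state}{self.column}{self.derived_state}"


@dataclass
class ConvergenceReport:
    """Study-level tally of convergent substitutions and the symmetric
    chi-square comparison of foreground vs background totals."""

    per_gene: dict[str, dict[str, list[SiteCall]]]
    foreground_count: int
    background_count: int
    genes_with_foreground: int
    multi_site_genes: int
    chi2_stat: float | None
    p_value: float | None


def _cluster_matrix(
    alignment_codes: dict[str, np.ndarray], taxa: list[str]
) -> np.ndarray:
    return np.stack([alignment_codes[t] for t in taxa])


def _support_ok(
    counts1: np.ndarray, counts2: np.ndarray, threshold: int, mode: str
) -> np.ndarray:
    """Boolean (n_cols, 20): does residue d meet the support rule?"""
    if mode == "per-cluster":
        return (counts1 >= threshold) & (counts2 >= threshold)
    if mode == "total":
        return (counts1 + counts2) >= 2 * threshold
    raise ValueError(f"unknown support mode: {mode!r}")


def _scan_codes(
    codes: dict[str, np.ndarray],
    design: SpeciesDesign,
    min_shared_per_cluster: int,
    support_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised caller over all columns.

    Returns (direction, derived, ambiguous, conservative_both) where
    direction is 0 none / 1 foreground / 2 background, derived is the
    called residue code (-1 where no call), ambiguous flags columns
    rejected because two residues met the threshold.
    """
    out = codes[design.outgroup]
    n = out.shape[0]
    fg1 = _cluster_matrix(codes, design.foreground_clusters[0])
    fg2 = _cluster_matrix(codes, design.foreground_clusters[1])
    bg1 = _cluster_matrix(codes, design.background_clusters[0])
    bg2 = _cluster_matrix(codes, design.background_clusters[1])

    out_ok = out >= 0
    # conservativeness: every control taxon determinate and equal to O
    bg_all = np.concatenate([bg1, bg2])
    fg_all = np.concatenate([fg1, fg2])
    cons_fg = out_ok & ((bg_all == out[None, :]) & (bg_all >= 0)).all(axis=0)
    cons_bg = out_ok & ((fg_all == out[None, :]) & (fg_all >= 0)).all(axis=0)

    states = np.arange(N_STATES, dtype=np.int8)

    def residue_counts(cluster: np.ndarray) -> np.ndarray:
        return (cluster[:, :, None] == states[None, None, :]).sum(axis=0)

    not_o = states[None, :] != np.where(out_ok, out, 100)[:, None]

    direction = np.zeros(n, dtype=np.int8)
    derived = np.full(n, -1, dtype=np.int8)
    ambiguous = np.zeros(n, dtype=bool)

    for dir_code, cons, c1, c2 in (
        (1, cons_fg & ~cons_bg, fg1, fg2),
        (2, cons_bg & ~cons_fg, bg1, bg2),
    ):
        ok = _support_ok(
            residue_counts(c1), residue_counts(c2), min_shared_per_cluster,
            support_mode,
        ) & not_o & cons[:, None]
        n_cand = ok.sum(axis=1)
        ambiguous |= n_cand > 1
        hit = cons & (n_cand == 1)
        direction[cons] = dir_code
        derived[hit] = np.int8(np.argmax(ok[hit], axis=1))

    conservative_both = cons_fg & cons_bg
    direction[conservative_both] = 0  # counted toward neither category
    return direction, derived, ambiguous, conservative_both


def classify_site(
    column: dict[str, str],
    design: SpeciesDesign,
    min_shared_per_cluster: int = 3,
    support_mode: str = "per-cluster",
    gene_id: str = "",
    column_index: int = 1,
) -> SiteCall:
    """Classify a single column (taxon -> residue) under the design."""
    for t in design.all_taxa:
        if t not in column:
            raise KeyError(f"design taxon '{t}' absent from column")
    codes = {t: encode_residues(column[t]) for t in design.all_taxa}
    direction, derived, ambiguous, _ = _scan_codes(
        codes, design, min_shared_per_cluster, support_mode
    )
    return _build_call(
        gene_id, column_index, column, design,
        int(direction[0]), int(derived[0]), bool(ambiguous[0]),
    )


def _build_call(
    gene_id: str,
    column_index: int,
    column: dict[str, str],
    design: SpeciesDesign,
    direction: int,
    derived: int,
    ambiguous: bool,
) -> SiteCall:
    dir_name = {0: "none", 1: "foreground", 2: "background"}[direction]
    anc = column[design.outgroup]
    anc = anc if anc in "ACDEFGHIKLMNPQRSTVWY" else None
    if ambiguous:
        logger.info(
            "%s column %d: two derived residues meet the threshold; "
            "rejected as ambiguous", gene_id, column_index,
        )
    if derived < 0:
        return SiteCall(gene_id, column_index, dir_name, anc, None, [], False)
    d = decode_residues(np.array([derived]))
    clusters = (
        design.foreground_clusters if direction == 1 else design.background_clusters
    )
    supporters = [t for cl in clusters for t in cl if column[t] == d]
    return SiteCall(gene_id, column_index, dir_name, anc, d, supporters, True)


def scan_gene(
    alignment: OrthologAlignment,
    design: SpeciesDesign,
    min_shared_per_cluster: int = 3,
    support_mode: str = "per-cluster",
    drop_gapped_columns: bool = False,
) -> list[SiteCall]:
    """All convergent calls in one gene, 1-based columns, vectorised.

    With ``drop_gapped_columns`` any column holding a gap/X in a design
    taxon is skipped before calling (alignment-trimming behaviour).
    """
    missing = [t for t in design.all_taxa if t not in alignment.sequences]
    if missing:
        raise KeyError(f"{alignment.gene_id}: design taxa missing: {missing}")
    if alignment.length == 0:
        return []
    codes = {t: encode_residues(alignment.sequences[t]) for t in design.all_taxa}
    keep = np.ones(alignment.length, dtype=bool)
    if drop_gapped_columns:
        keep = np.all([c >= 0 for c in codes.values()], axis=0)
        codes = {t: c[keep] for t, c in codes.items()}
    direction, derived, ambiguous, _ = _scan_codes(
        codes, design, min_shared_per_cluster, support_mode
    )
    original_cols = np.flatnonzero(keep) + 1
    for j in np.flatnonzero(ambiguous):
        logger.info(
            "%s column %d: two derived residues meet the threshold; "
            "rejected as ambiguous", alignment.gene_id, int(original_cols[j]),
        )
    calls = []
    for j in np.flatnonzero(derived >= 0):
        col = int(original_cols[j])
        calls.append(
            _build_call(
                alignment.gene_id, col, alignment.column(col), design,
                int(direction[j]), int(derived[j]), bool(ambiguous[j]),
            )
        )
    return calls


def aggregate(gene_calls: dict[str, list[SiteCall]]) -> ConvergenceReport:
    """Tally per-gene calls into a study-level report with the symmetric
    chi-square test of foreground vs background totals."""
    per_gene: dict[str, dict[str, list[SiteCall]]] = {}
    f_total = b_total = 0
    genes_with_fg = multi = 0
    for gene, calls in gene_calls.items():
        fg = [c for c in calls if c.is_convergent and c.direction == "foreground"]
        bg = [c for c in calls if c.is_convergent and c.direction == "background"]
        per_gene[gene] = {"foreground": fg, "background": bg}
        f_total += len(fg)
        b_total += len(bg)
        genes_with_fg += bool(fg)
        multi += len(fg) >= 2
    if f_total + b_total == 0:
        stat = p = None
    else:
        stat, p = symmetric_chi2(f_total, b_total)
    return ConvergenceReport(
        per_gene, f_total, b_total, genes_with_fg, multi, stat, p
    )


def symmetric_chi2(
    foreground_count: int, background_count: int
) -> tuple[float, float]:
    """Two-cell Pearson goodness-of-fit against equal expectation:
    chi2 = (f - b)^2 / (f + b), p from chi-square with 1 df."""
    f, b = foreground_count, background_count
    if f < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if f + b == 0:
        raise ValueError("both counts zero: test undefined")
    stat = (f - b) ** 2 / (f + b)
    return float(stat), float(chi2_dist.sf(stat, df=1))
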