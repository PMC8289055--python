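"""Desk-scale synthetic study inputs: 17-taxon design, tree, and per-gene
alignments with optional planted convergent substitutions.

The default topology mirrors the study layout for syngnathid/placental
convergence: an outgroup (elephant shark) sister to two clades, each
pairing a four-taxon foreground cluster with a four-taxon aplacental
background cluster — placental mammals with aplacental tetrapods, and
syngnathids with aplacental teleosts.  Background columns evolve neutrally
under JTT+Gamma; planted columns are written to satisfy the strict
conservative-convergent pattern exactly, giving truth labels for recall
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import OrthologAlignment, PhyloTree, SpeciesDesign
from .models import AA_ORDER, SubstitutionModel, build_model
from .simulate import simulate_gene

FG1 = ["Homo_sapiens", "Pongo_abelii", "Mus_musculus", "Canis_familiaris"]
FG2 = ["Hippocampus_comes", "Hippocampus_erectus", "Syngnathus_scovelli",
       "Microphis_manadensis"]
BG1 = ["Gallus_gallus", "Meleagris_gallopavo", "Taeniopygia_guttata",
       "Anolis_carolinensis"]
BG2 = ["Oryzias_latipes", "Xiphophorus_maculatus", "Oreochromis_niloticus",
       "Gasterosteus_aculeatus"]
OUTGROUP = "Callorhinchus_milii"


@dataclass
class SyntheticStudy:
    """A complete generated study: design, tree, gene alignments and the
    planted-site truth table."""

    design: SpeciesDesign
    tree: PhyloTree
    genes: list[OrthologAlignment]
    truth: dict[str, list[tuple[int, str, str]]]  # gene -> (col, direction, derived)
    params: dict


def default_topology(scale: float = 0.1) -> tuple[PhyloTree, SpeciesDesign]:
    """The 17-leaf study tree and its design.

    Every branch has length *scale* (default 0.1 expected substitutions per
    site), which makes the foreground and background clusters mirror images
    of each other — the symmetry the caller's chi-square comparison relies
    on.
    """

    def clade(taxa: list[str]) -> str:
        a, b, c, d = taxa
        return (f"(({a}:{scale:g},{b}:{scale:g}):{scale:g},"
                f"({c}:{scale:g},{d}:{scale:g}):{scale:g})")

    newick = (
        f"({OUTGROUP}:{scale:g},"
        f"(({clade(FG1)}:{scale:g},{clade(BG1)}:{scale:g}):{scale:g},"
        f"({clade(FG2)}:{scale:g},{clade(BG2)}:{scale:g}):{scale:g}):{scale:g});"
    )
    tree = PhyloTree.from_newick(newick)
    design = SpeciesDesign(OUTGROUP, (list(FG1), list(FG2)), (list(BG1), list(BG2)))
    return tree, design


def _plant_column(
    rng: np.random.Generator,
    freqs: np.ndarray,
    design: SpeciesDesign,
    direction: str,
    support: str,
) -> tuple[dict[str, str], str]:
    """Column satisfying the conservative-convergent pattern by design.

    ``support='strict'``: all 8 target taxa carry the derived residue;
    ``'minimal'``: 3 per cluster carry it, the remaining taxon per cluster
    keeps the ancestral state.  Ancestral O and derived d are both drawn
    from the equilibrium frequencies (d excluding O) so planted columns
    stay compositionally similar to neutral ones.
    """
    o = int(rng.choice(20, p=freqs))
    p = freqs.copy()
    p[o] = 0.0
    d = int(rng.choice(20, p=p / p.sum()))
    O, D = AA_ORDER[o], AA_ORDER[d]
    column = {t: O for t in design.all_taxa}
    clusters = (
        design.foreground_clusters if direction == "foreground"
        else design.background_clusters
    )
    n_carriers = 4 if support == "strict" else 3
    for cluster in clusters:
        for t in cluster[:n_carriers]:
            column[t] = D
    return column, D


def generate_study(
    n_genes: int = 20,
    gene_length: int = 300,
    alpha: float = 0.8,
    planted_fg: int = 0,
    planted_bg: int = 0,
    seed: int = 0,
    scale: float = 0.1,
    k: int = 4,
    support: str = "strict",
    model: SubstitutionModel | None = None,
) -> SyntheticStudy:
    """Generate a reproducible synthetic study.

    Neutral columns evolve under JTT+Gamma(alpha) on the default topology;
    ``planted_fg``/``planted_bg`` columns are overwritten with exact
    conservative-convergent patterns at collision-free positions drawn
    uniformly over all genes, and recorded in the truth table.
    """
    if support not in ("strict", "minimal"):
        raise ValueError(f"unknown support mode: {support!r}")
    capacity = n_genes * gene_length
    if planted_fg + planted_bg > capacity:
        raise ValueError(
            f"cannot plant {planted_fg + planted_bg} sites in "
            f"{capacity} columns"
        )
    tree, design = default_topology(scale)
    if model is None:
        model = build_model("jtt-default", alpha=alpha, k=k)
    rng = np.random.default_rng(seed)

    genes = []
    for g in range(n_genes):
        sim = simulate_gene(tree, model, gene_length, rng)
        genes.append(sim.to_alignment(gene_id=f"gene{g + 1:04d}"))

    flat = rng.choice(capacity, size=planted_fg + planted_bg, replace=False)
    directions = ["foreground"] * planted_fg + ["background"] * planted_bg
    truth: dict[str, list[tuple[int, str, str]]] = {a.gene_id: [] for a in genes}
    for pos, direction in zip(flat, directions):
        gi, col = divmod(int(pos), gene_length)
        aln = genes[gi]
        column, derived = _plant_column(rng, model.freqs, design, direction, support)
        seqs = {
            t: s[:col] + (column[t] if t in column else s[col]) + s[col + 1:]
            for t, s in aln.sequences.items()
        }
        genes[gi] = OrthologAlignment(aln.gene_id, aln.taxa, seqs)
        truth[aln.gene_id].append((col + 1, direction, derived))
    for sites in truth.values():
        sites.sort()

    params = dict(
        n_genes=n_genes, gene_length=gene_length, alpha=alpha,
        planted_fg=planted_fg, planted_bg=planted_bg, seed=seed,
        scale=scale, k=k, support=support,
    )
    return SyntheticStudy(design, tree, genes, truth, params)
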