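"""Fixed-topology likelihood and ML estimation of alpha and branch lengths.

Likelihoods are computed by Felsenstein pruning over unique site patterns,
mixed over the k discrete gamma categories with equal weights.  Gap and 'X'
characters are missing data and contribute a flat partial likelihood.
Fitting is by coordinate ascent: each branch length and the gamma shape are
optimised one at a time with bounded Brent searches until the
log-likelihood gain per sweep drops below tolerance.  Equilibrium
frequencies are the observed residue proportions (the usual "+F" practice),
not free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io_formats import OrthologAlignment, PhyloTree
from .models import (
    N_STATES,
    SubstitutionModel,
    build_model,
    empirical_frequencies,
    encode_residues,
)

logger = logging.getLogger(__name__)

BRANCH_BOUNDS = (1e-8, 20.0)
ALPHA_BOUNDS = (0.02, 50.0)


@dataclass
class FittedParameters:
    """Result of a fixed-topology fit: tree with ML branch lengths, gamma
    shape, empirical frequencies and the attained log-likelihood."""

    tree: PhyloTree
    alpha: float
    freqs: np.ndarray
    log_likelihood: float
    converged: bool = True
    n_iterations: int = 0


def _encode_matrix(alignment: OrthologAlignment) -> np.ndarray:
    """(n_taxa, n_sites) int8 state matrix in alignment taxon order."""
    return np.stack([encode_residues(alignment.sequences[t]) for t in alignment.taxa])


def _patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique columns and their multiplicities."""
    cols, weights = np.unique(matrix, axis=1, return_counts=True)
    return cols, weights.astype(float)


def _pattern_log_likelihoods(
    patterns: np.ndarray,
    leaf_rows: dict[int, int],
    tree: PhyloTree,
    model: SubstitutionModel,
) -> np.ndarray:
    """Log-likelihood of each pattern, gamma-mixed.

    patterns: (n_taxa, n_pat) int matrix; leaf_rows maps tree node index ->
    row of the pattern matrix.
    """
    n_pat = patterns.shape[1]
    per_cat = np.empty((model.k, n_pat))
    post = tree.postorder()
    for ci, rate in enumerate(model.rates):
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for node in post:
            if tree.is_leaf(node):
                states = patterns[leaf_rows[node]]
                L = np.zeros((n_pat, N_STATES))
                obs = states >= 0
                L[obs, states[obs]] = 1.0
                L[~obs] = 1.0  # missing data: flat partial
            else:
                L = np.ones((n_pat, N_STATES))
                for child in tree.children[node]:
                    P = model.transition_matrix(tree.lengths[child], rate)
                    L *= partial.pop(child) @ P.T
                scale = L.max(axis=1)
                tiny = scale <= 0
                scale[tiny] = 1.0
                L /= scale[:, None]
                logscale += np.log(scale)
            partial[node] = L
        site = (partial[tree.root] * model.freqs[None, :]).sum(axis=1)
        per_cat[ci] = np.log(np.maximum(site, 1e-300)) + logscale
    return logsumexp(per_cat, axis=0) - np.log(model.k)


def log_likelihood(
    alignment: OrthologAlignment, tree: PhyloTree, model: SubstitutionModel
) -> float:
    """Total log-likelihood of the alignment on the tree under the model."""
    if alignment.length == 0:
        raise ValueError("empty alignment")
    leaf_rows = {tree.leaf(t): r for r, t in enumerate(alignment.taxa)}
    patterns, weights = _patterns(_encode_matrix(alignment))
    lnl = _pattern_log_likelihoods(patterns, leaf_rows, tree, model)
    return float(lnl @ weights)


def observed_frequencies(alignment: OrthologAlignment) -> np.ndarray:
    """Residue proportions over the whole alignment, missing data excluded."""
    counts = np.zeros(N_STATES)
    for t in alignment.taxa:
        codes = encode_residues(alignment.sequences[t])
        counts += np.bincount(codes[codes >= 0], minlength=N_STATES)
    return empirical_frequencies(counts)


def fit_parameters(
    alignment: OrthologAlignment,
    tree: PhyloTree,
    optimize: tuple[str, ...] = ("alpha", "branch_lengths"),
    alpha0: float = 1.0,
    k: int = 4,
    tol: float = 1e-6,
    max_iter: int = 200,
    use_empirical_freqs: bool = True,
) -> FittedParameters:
    """Coordinate-ascent ML fit of gamma shape and/or branch lengths on a
    fixed topology.

    Zero initial lengths on optimised branches are re-initialised to 0.05.
    Branch lengths are bounded to [1e-8, 20] and alpha to [0.02, 50].  The
    returned log-likelihood is never below the initial one.
    """
    tree = tree.copy()
    freqs = observed_frequencies(alignment) if use_empirical_freqs else "jtt-default"
    alpha = float(alpha0)
    model = build_model(freqs, alpha=alpha, k=k)

    leaf_rows = {tree.leaf(t): r for r, t in enumerate(alignment.taxa)}
    patterns, weights = _patterns(_encode_matrix(alignment))

    def total(tr: PhyloTree, m: SubstitutionModel) -> float:
        return float(_pattern_log_likelihoods(patterns, leaf_rows, tr, m) @ weights)

    current = total(tree, model)
    if not optimize:
        return FittedParameters(tree, alpha, model.freqs, current, True, 0)

    branch_nodes = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    if "branch_lengths" in optimize:
        for i in branch_nodes:
            if tree.lengths[i] <= 0:
                tree.lengths[i] = 0.05
        current = total(tree, model)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        before = current
        if "branch_lengths" in optimize:
            for i in branch_nodes:
                def neg(t: float, i: int = i) -> float:
                    tree.lengths[i] = t
                    return -total(tree, model)

                res = minimize_scalar(
                    neg, bounds=BRANCH_BOUNDS, method="bounded",
                    options={"xatol": 1e-6},
                )
                tree.lengths[i] = float(res.x)
                current = -res.fun
        if "alpha" in optimize:
            def neg_alpha(a: float) -> float:
                return -total(tree, build_model(freqs, alpha=a, k=k))

            res = minimize_scalar(
                neg_alpha, bounds=ALPHA_BOUNDS, method="bounded",
                options={"xatol": 1e-4},
            )
            alpha = float(res.x)
            model = build_model(freqs, alpha=alpha, k=k)
            current = -res.fun
        if current - before < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "fit_parameters: no convergence after %d sweeps (last gain %.3g)",
            it, current - before,
        )
    return FittedParameters(tree, alpha, model.freqs, current, converged, it)
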