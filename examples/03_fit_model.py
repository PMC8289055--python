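"""Recover substitution-model parameters from simulated data.

Simulates 20,000 sites on a 5-taxon tree under JTT+Gamma(alpha=0.8), then
re-estimates the gamma shape and all branch lengths by maximum likelihood
on the fixed topology — the parameter-estimation step that feeds the
simulation calibration.
"""

from ccsconv import PhyloTree, build_model, fit_parameters, simulate_gene

tree = PhyloTree.from_newick("((a:0.1,b:0.2):0.08,(c:0.15,d:0.25):0.12,e:0.3);")
true_alpha = 0.8
model = build_model("jtt-default", alpha=true_alpha, k=4)
sim = simulate_gene(tree, model, n_sites=20000, seed=7)

fit = fit_parameters(sim.to_alignment(), tree, alpha0=1.0)
print(f"true alpha  = {true_alpha}")
print(f"fitted alpha = {fit.alpha:.4f}")
print(f"log-likelihood = {fit.log_likelihood:.2f} "
      f"(converged after {fit.n_iterations} sweeps)")
print("\nbranch   true    fitted")
for i in range(1, tree.n_nodes):
    name = tree.names[i] or tree.labels[i]
    print(f"{name:>6}   {tree.lengths[i]:.3f}   {fit.tree.lengths[i]:.4f}")
print("\nFitted values should track the truth closely at this sequence")
print("length; residual error shrinks as 1/sqrt(n_sites).")
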