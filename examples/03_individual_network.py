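"""Build a per-condition association network and summarize its topology.

Each of the K = M(M-1)/2 partial correlations is tested against zero and
edges are drawn at the Bonferroni-corrected threshold 0.05 / K.
"""

import diffpcor as dp

spec = dp.lipoprotein_panel_spec(n_a=2000, n_b=400, seed=11)
data = dp.sample_dataset(spec)

fit = dp.fit_group(data, "A")
pvals = dp.edge_pvalues(fit, kappa="auto")
threshold = dp.bonferroni_threshold(0.05, data.n_pairs)
net = dp.build_network(pvals, threshold, nodes=data.variable_names)

print(f"lambda = {fit.lambda_hat:.4f}, kappa = {pvals.attrs['kappa']:.0f} "
      f"({pvals.attrs['kappa_method']}), threshold = {threshold:.3g}")
summary = dp.global_summary(net)
print(dp.format_summary(summary))
print("Density is 2E/(N(N-1)); average degree 2E/N counts isolated nodes; "
      "the slope is the log-log least-squares fit of P(k) vs k.")
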