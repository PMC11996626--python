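"""Biogeography statistics: the lanthanide fraction fLn, its logistic
relationship with phosphate, and a correspondence-analysis ordination.

fLn is the share of complete-domain PQQ-dehydrogenase abundance (RPKM) in
each sample carried by genes with the lanthanide-binding motif.  In ocean
data it declines with phosphate; the generator builds that relationship in,
and the fit below recovers it.
"""

import lanthascope as ls

cfg = ls.SyntheticConfig(n_queries=300, n_samples=60, seed=3)
sim = ls.simulate(cfg)

table = ls.compute_rpkm(ls.AbundanceTable(
    values=sim.tables.counts,
    gene_lengths=sim.tables.gene_lengths,
    library_sizes=sim.tables.library_sizes,
))
fln = ls.compute_fln(table, sim.truth.genes.true_class.to_dict())
print("per-sample fLn: min %.3f, median %.3f, max %.3f"
      % (fln.fln.min(), fln.fln.median(), fln.fln.max()))

fit = ls.fit_fractional_logistic(fln.fln, sim.metadata.phosphate)
print(f"logistic fit: b0 = {fit.b0:.3f}, b1 = {fit.b1:.3f} per (umol/kg), "
      f"SE(b1) = {fit.se_b1:.3f}, Wald p = {fit.p_b1:.2e}")
print(f"(generator truth: b0 = {cfg.logit_intercept}, b1 = {cfg.logit_slope}; "
      "a negative b1 means lanthanide use declines toward high-phosphate, "
      "HNLC-like waters)")

clade_table = table.values.groupby(sim.truth.genes.true_clade).sum().T
ca = ls.correspondence_analysis(
    clade_table, env=sim.metadata[["phosphate", "temperature"]])
print("\ncorrespondence analysis: total inertia %.4f; first two axes carry "
      "%.1f%% and %.1f%% of it" % (
          ca.total_inertia,
          100 * ca.inertia_fraction[0],
          100 * ca.inertia_fraction[1] if len(ca.inertia_fraction) > 1 else 0.0))
print("environmental arrows (correlation with sample scores):")
print(ca.env_arrows.iloc[:, :2].round(3).to_string())
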