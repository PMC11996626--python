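"""Screen a protein catalog against the reference panel and call cofactors.

Runs the identification stage (strict length filter, greedy 95%
dereplication, best-hit homology screen) and then projects each candidate's
active-site motif from its nearest reference to call the metal cofactor:
D-x-D marks lanthanide coordination, D-x-{A,T,S} calcium.
"""

import lanthascope as ls
from lanthascope.screen import passing_records

cfg = ls.SyntheticConfig(n_queries=120, n_samples=5, seed=7)
sim = ls.simulate(cfg)

kept = ls.filter_by_length(sim.queries, min_len=300)
clusters = ls.dereplicate_greedy(kept, threshold=0.95)
hits = ls.screen_candidates(kept, sim.panel, min_identity=0.25, min_coverage=0.5)
retained = passing_records(kept, hits)
print(f"{len(sim.queries)} proteins -> {len(kept)} over 300 aa -> "
      f"{len(clusters)} clusters at 95% identity -> {len(retained)} screened in")

calls = ls.classify_catalog(retained, sim.panel)
print("\ncofactor calls:", calls.call.value_counts().to_dict())
print("clade assignments:", calls.clade.value_counts().to_dict())

merged = calls.join(sim.truth.genes)
print(f"\nagainst generator truth: class accuracy "
      f"{(merged.call == merged.true_class).mean():.3f}, clade accuracy "
      f"{(merged.clade == merged.true_clade).mean():.3f}")
print("Each call is auditable: e.g.",
      calls.iloc[0][["motif_residues", "ref_id", "clade"]].to_dict(),
      "for", calls.index[0])
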