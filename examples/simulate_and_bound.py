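"""Forward-simulate a gene family, then reconcile it.

The simulator evolves one lineage down a random species tree with
per-vertex duplication/transfer/loss draws and per-edge rearrangements,
recording the true history.  Parsimony can never cost more than the truth,
and usually recovers something close to it.
"""

from dtlor import GeneratorConfig, simulate_history, solve
from dtlor.model import event_counts

for seed in range(5):
    config = GeneratorConfig(seed=seed, species_leaves=5,
                             p_dup=0.15, p_transfer=0.1, p_loss=0.15,
                             p_rearr=0.1)
    history = simulate_history(config)
    opt, _ = solve(history.instance)
    true_counts = event_counts(history.events)
    print(f"seed {seed}: genes {len(history.instance.gene_tree.leaves):2d}  "
          f"true cost {str(history.true_cost):>3}  parsimony {str(opt):>3}  "
          f"true events {true_counts}")

# Every parsimony value is <= its true cost; equality means the maximum
# parsimony reconciliation is exactly as expensive as what actually
# happened (though not necessarily the same history).
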