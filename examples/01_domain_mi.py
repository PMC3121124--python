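"""Compute the coevolution score M_mn for a pair of domain alignments.

Builds two small synthetic domain alignments whose first columns coevolve
through a 5-symbol coupling, then scores the pair: M_mn is the maximum over
non-gappy column pairs of (MI - shuffle-null mean), in nats. A background
(non-coevolving) domain pair is scored for contrast.
"""

from domcrf import MIConfig, compute_domain_mi
from domcrf.synthetic import SyntheticConfig, generate_alignments

cfg = SyntheticConfig(
    n_domains=4, n_organisms=100, n_cols=8, coevolve_q=5, target_mi=1.5, seed=42
)
alignments = generate_alignments(cfg, coevolving={("D000", "D001"): cfg.target_mi})

mi_cfg = MIConfig(eta=1.0, gap_threshold=0.2, n_shuffles=400, seed=42)
coupled = compute_domain_mi(alignments["D000"], alignments["D001"], mi_cfg)
background = compute_domain_mi(alignments["D002"], alignments["D003"], mi_cfg)

print(f"coevolving pair   M_mn = {coupled.m_mn:.3f} nats "
      f"(best columns {coupled.best_positions}, {coupled.M} paired rows)")
print(f"background pair   M_mn = {background.m_mn:.3f} nats")
print()
print("The coevolving pair scores an order of magnitude above background;")
print("the eta=1 pseudocount and the shuffle null shrink the raw 1.5-nat")
print("population coupling to the corrected scale printed here.")
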