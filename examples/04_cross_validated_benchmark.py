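"""Run a reduced synthetic recovery study end to end.

Generates a small interactome (80 proteins, 24 domains, 3 true domain pairs
with 1.5-nat column coupling), computes shuffle-corrected domain MI, and
cross-validates the CRF (with and without MI), EM, and association methods.
Takes ~15 s. The full-size study lives behind
`domcrf.pipeline.run_benchmark()` with default `SyntheticConfig()`.
"""

from domcrf.pipeline import run_benchmark
from domcrf.synthetic import SyntheticConfig

cfg = SyntheticConfig(
    n_proteins=80, n_domains=24, n_true_pairs=3, min_support=20,
    n_positive=60, n_negative=60, n_organisms=60, seed=7,
)
res = run_benchmark(cfg)

print(res.run.to_dataframe().to_string(float_format=lambda v: f"{v:.4f}"))
print()
print(f"mean M_mn of true domain pairs:       {res.mi_true_mean():.3f} nats")
print(f"mean M_mn of background domain pairs: {res.mi_background_mean():.3f} nats")
print()
print("Training AUCs are near 1 (all methods memorize); test AUCs separate")
print("the discriminative CRF variants from the generative EM/association")
print("baselines, and the true domain pairs carry an order-of-magnitude")
print("higher coevolution score than background pairs.")
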