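"""Association and EM baselines on a small factor graph.

The association method estimates each domain pair's interaction probability
as I_mn / N_mn; EM refines it under the noisy-OR observation model with a
false-negative rate. Predictions combine the per-domain-pair probabilities
through Pr(P_ij = 1) = 1 - prod(1 - lambda_mn).
"""

from domcrf import (
    Protein,
    ProteinPairLabel,
    association,
    baseline_predict,
    build_factor_graph,
    em_train,
)

proteins = {
    "p1": Protein("p1", ("A", "C")),
    "p2": Protein("p2", ("B",)),
    "p3": Protein("p3", ("C",)),
    "p4": Protein("p4", ("B", "C")),
}
labels = [
    ProteinPairLabel(("p1", "p2"), 1),  # contains (A,B) and (B,C)
    ProteinPairLabel(("p1", "p4"), 1),
    ProteinPairLabel(("p3", "p4"), 0),  # contains (B,C) and (C,C)
]
fg = build_factor_graph(proteins, labels)

assoc = association(fg)
print("association lambda_mn = I_mn / N_mn:")
for dp in fg.domain_pairs:
    print(f"  {dp}: {assoc.lambdas[dp]:.3f}  (I={fg.I[dp]}, N={fg.N[dp]})")

em = em_train(fg, fn=0.8, fp=1e-4)
print(f"\nEM ({em.iterations} iterations, fn={em.fn}):")
for dp in fg.domain_pairs:
    print(f"  {dp}: {em.lambdas[dp]:.3f}")

p = baseline_predict(proteins["p1"], proteins["p2"], assoc)
print(f"\nnoisy-OR prediction for (p1, p2) under association: {p:.3f}")
print("EM shrinks probabilities toward what the fn=0.8 observation model")
print("can explain; the association estimate is its initial value.")
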