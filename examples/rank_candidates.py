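"""Rank candidate diseases for one drug among its unknown pairs.

After fitting, every drug-disease pair gets a reconstructed score; the
candidate pool for a drug is every disease it has no known link to, and
the top of that pool is the repositioning hypothesis list.
"""

import simnmf as sn

bundle, _, _ = sn.generate(
    sn.SyntheticSpec(n=60, m=40, k_true=5, density=0.12, seed=7)
)
h = sn.Hyperparameters(k=5, mu=0.1, lam=0.1, max_iter=500, tol=1e-6, seed=7)
factors, _ = sn.fit(bundle.A, bundle.Sd, bundle.Se, h)
scores = sn.predict(factors, bundle.A.drug_ids, bundle.A.disease_ids)

drug = bundle.A.drug_ids[0]
known = [d for d, v in zip(bundle.A.disease_ids, bundle.A.values[0]) if v == 1]
print(f"drug {drug} has {len(known)} known links: {', '.join(known) or '(none)'}")
print(f"top 5 candidate diseases (no known link, highest scores first):")
for rank, (disease, score) in enumerate(sn.rank_candidates(scores, bundle.A, drug, 5), 1):
    print(f"  {rank}. {disease}  score {score:.3f}")
print("(scores are reconstruction weights; higher = stronger predicted association)")
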