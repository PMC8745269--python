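"""Train a likelihood ranking model on synthetic data and rank conditions.

Generates a rule-labeled hydrogenation dataset, trains the full pipeline
(CGR -> fragment counts -> PCA -> multi-label network), then ranks all 2088
condition combinations for one held-out nitro reduction.  The score is
L = -ln(geometric mean of the six component probabilities); lower is better,
and exp(-L) in (0, 1] reads as a confidence.
"""

import math

from condrank import (
    GeneratorConfig,
    LRMConfig,
    ModelBundle,
    PipelineConfig,
    generate_dataset,
    split_by_transformation,
)

data = generate_dataset(GeneratorConfig(n_reactions=300, seed=5, noise_rate=0.1))
train_idx, test_idx = split_by_transformation(data.lines, data.records, (0.8, 0.2), seed=5)

bundle = ModelBundle.train(
    [data.lines[i] for i in train_idx],
    [data.records[i] for i in train_idx],
    PipelineConfig(lrm=LRMConfig(hidden_size=256, epochs=150, seed=5), seed=5),
)

query = next(
    data.lines[i] for i in test_idx
    if data.meta[i]["template"] == "nitro_to_amine"
)
print("query reaction:", query)

ranked, in_domain = bundle.rank(query, ranker="lrm")
print(f"in applicability domain: {in_domain}")
print(f"\ntop 5 of {len(ranked)} condition combinations:")
print(f"{'rank':>4} {'T':>7} {'P':>7} {'catalyst':>10} {'additives':>10} "
      f"{'L':>7} {'conf':>6}")
for r, (combo, score) in enumerate(
    zip(ranked.combinations[:5], ranked.scores[:5]), start=1
):
    additives = "".join(
        flag for flag, on in zip("ABP", (combo.acid, combo.base, combo.poison)) if on
    ) or "-"
    print(f"{r:>4} {combo.temperature_bin:>7} {combo.pressure_bin:>7} "
          f"{bundle.cond_vocab.catalysts[combo.catalyst]:>10} {additives:>10} "
          f"{score:>7.3f} {math.exp(-score):>6.3f}")
print("\n(the generating rule for nitro reductions is Pd/C, medium T, low P,"
      " no additives)")
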