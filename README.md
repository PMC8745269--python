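# condrank

Ranking of reaction conditions for catalytic hydrogenation.

Choosing the temperature, pressure, catalyst and additives for a
hydrogenation is a many-to-many problem: one transformation may work under
several conditions, negative results are rarely published, and exact
correspondence between a structure and "its" condition does not exist.
`condrank` therefore treats condition recommendation as a *ranking* problem:
for a query reaction it orders every enumerable condition combination by a
likelihood score, so that conditions under which the transformation has the
best chance to proceed appear at the top of the list.

It is aimed at synthetic and medicinal chemists (and the people building
tools for them) who have a corpus of atom-mapped, condition-annotated
hydrogenation reactions and want structure-aware condition suggestions with
an applicability-domain safeguard.

## The model

1. **Condensed Graph of Reaction (CGR).** The mapped reactant and product
   graphs are superposed into one pseudomolecule whose bonds carry an order
   pair *(before, after)*; pairs that differ are *dynamic* bonds (broken,
   formed, or order-changed) and localize the transformation.
2. **Descriptors.** Atom-centered linear fragments of 2–4 atoms are
   enumerated over the CGR (dynamic bonds included), rare fragments
   (corpus frequency < 5) are dropped, and the count vectors are compressed
   by PCA (up to 1500 components).
3. **Conditions.** Each record is normalized ("rt" → 25 °C, "atmospheric
   pressure" → 1 atm, small ranges averaged), binned — temperature
   low (< 0 °C) / medium (0–50 °C) / high (> 50 °C); pressure
   low (0–3 atm] / medium (3–10 atm] / high (> 10 atm) — and encoded as a
   38-bit vector: one-hot temperature (3), pressure (3), free additive flags
   acid/base/poison (3), one-hot catalyst (29). The one-hot constraints admit
   3 × 3 × 2³ × 29 = **2088** enumerable condition combinations.
4. **Likelihood ranking.** A feed-forward network (one ReLU hidden layer,
   38 sigmoid outputs, multi-label binary cross-entropy, Adam at lr 0.001
   multiplied by 0.99 each epoch) predicts per-bit probabilities. Every
   combination *c* is scored by

   ℒ(c) = −(1/6) · [ln q_T + ln q_P + ln q_cat + ln q_acid + ln q_base + ln q_poison],

   the negative log of the geometric mean of its six component
   probabilities, where an additive contributes its Bernoulli probability
   (P if selected, 1 − P otherwise). Combinations are ranked ascending in ℒ;
   exp(−ℒ) ∈ (0, 1] reads as a confidence.
5. **Baselines and evaluation.** A ranking kNN (conditions of the k nearest
   training reactions in PCA space, nearer duplicate kept) and a frequency
   null model (training conditions by frequency, identical for every query)
   are evaluated with MRR@K and P@K, plus per-component accuracy breakdowns.
6. **Applicability domain (fragment control).** A query whose CGR contains
   any fragment never seen in the training CGRs is flagged out-of-domain —
   it is still ranked, but the flag warns that the prediction extrapolates.

Real condition-annotated corpora of this kind are proprietary, so the
package ships a rule-based synthetic generator (`condrank.synthetic`) that
emulates their structure — six hydrogenation transformation classes, a
dominant condition mode, label noise, many-to-many multiplicity — and lets
the whole pipeline be exercised and tested end to end.

## Worked example

```bash
python examples/rank_conditions.py
```

trains on 300 synthetic records and ranks all 2088 combinations for a
held-out nitro reduction:

```
in applicability domain: True

top 5 of 2088 condition combinations:
rank       T       P   catalyst  additives       L   conf
   1  medium     low       pd-c          -   0.134  0.874
   2  medium     low   raney-ni          -   0.252  0.777
   3  medium  medium       pd-c          -   0.314  0.730
   4  medium  medium   raney-ni          -   0.433  0.649
   5  medium     low       pd-c          A   0.590  0.554
```

The top-1 (Pd/C, medium temperature, low pressure, no additives, confidence
0.874) is exactly the generating rule for nitro reductions; rank 2 is the
rule table's secondary condition (Raney nickel). `examples/evaluate_rankers.py`
compares the three rankers on a 500-record benchmark (likelihood model
P@1 = 66.7 % vs. 59.3 % for the frequency null and 51.9 % for kNN;
P@5 = 92.6 %), and `examples/applicability_check.py` shows a selenoether
query being flagged out-of-domain. `examples/build_cgr_and_fragments.py`
prints a CGR adjacency dump, one bond per line as `O0-N1 [2>0]` — atom
symbol + index on each end, `[order_before>order_after]` label, so `[2>0]`
is a broken double bond and `[a>a]` an untouched aromatic bond.

## Command line

```bash
condrank generate --n-reactions 500 --seed 7 --out data/        # synthetic corpus + split
condrank train data/train.smi data/train.csv --out bundle/      # fit + persist
condrank rank bundle/ data/test.smi --top 5 --ranker lrm        # ranked CSV with ℒ, exp(−ℒ), in_domain
condrank evaluate bundle/ data/test.smi data/test.csv --ks 1,3,5,10
```

Reaction files hold one atom-mapped reaction SMILES
(`reactants>agents>products`, `:n` maps) per line; condition tables are CSV
with columns `temperature,pressure,catalyst,acid,base,poison` aligned row by
row with the reaction file.

## Layout

- `src/condrank/` — `reactions` (SMILES/CSV I/O), `cgr`, `fragments`,
  `conditions`, `rankers`, `metrics`, `applicability`, `synthetic`,
  `bundle` (pipeline + persistence), `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, conventions, parameter defaults and
  limitations.
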