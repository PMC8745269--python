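# Methods

## Problem framing

A *transformation* is a reactant/product pair; a *reaction* is a
transformation carried out under specific conditions. Because one
transformation can proceed under several conditions and untested conditions
are not negatives, condition recommendation is framed as ranking: the model
scores every enumerable condition combination for a query reaction and the
experimentally observed combinations should surface near the top. All
quality metrics are computed at the transformation level — one query per
unique transformation, with every observed condition combination of that
transformation as its relevant set.

## Reaction representation

**Input contract.** Reactions arrive as atom-mapped reaction SMILES.
Aromaticity is taken as written (no re-aromatization), stereochemistry is
parsed and discarded (the condition components modeled here do not resolve
it), and explicit hydrogens are removed after parsing; H₂ in the agents slot
is kept as a reagent entry but contributes no heavy atoms. A reactant
molecule none of whose atoms map into any product is moved to the reagents
list; this rule is idempotent. Map numbers must be unique within each side —
multi-molecule products that reuse a map number are rejected rather than
guessed at. A mapped atom whose element differs between the two sides is a
mapping error and raises rather than silently producing a chimeric atom.

**CGR.** The condensed graph of reaction merges atoms by map number. Each
atom pair carries the order pair *(order in reactants or 0, order in
products or 0)*; aromatic order is a distinct symbol `a`, not 1.5. Atoms
present only on the reactant side (leaving groups — e.g. the nitro oxygens
of a reduction, or a displaced halide) are retained with their bonds as
order→0 dynamic bonds, because broken-bond information is what
distinguishes, say, a debenzylation from an alkene reduction. Formal charge
is kept as a per-atom *(reactant, product)* pair and is dynamic when the two
differ. Transformation identity (used by the data split) is the
Weisfeiler–Lehman hash of the CGR over element/charge node labels and order-pair
edge labels, which is invariant to atom renumbering.

## Fragment descriptors

Fragments are simple paths (no repeated atoms) of 2–4 atoms enumerated from
every atom of the CGR, so each undirected path is generated once per
endpoint; a path is rendered forward and backward and the lexicographically
smaller string is kept. This atom-centered convention doubles every count
relative to counting undirected paths once — a pure scaling that is
consistent between training and inference. The string syntax is defined by
this package: atom token = element plus charge suffix (`N+`, `Fe+2`) or
dynamic-charge group (`N[+1>0]`); bond token = `-`, `=`, `#`, `:` for static
orders or `[r>p]` with r, p ∈ {0, 1, 2, 3, a} for dynamic bonds. Fragment
lengths are configurable; 2–4 atoms is the default used everywhere,
including the applicability domain.

Fragments with corpus frequency below 5 are removed when the vocabulary is
fitted (a noise filter; the threshold is the `min_frequency` parameter).
Count vectors are compressed with PCA; the default width of 1500 components
is automatically capped at min(n_samples, n_features), which is what
desk-scale synthetic corpora hit in practice. PCA is computed by full SVD
(data fit comfortably in memory at the intended scales); the explained
variance is logged, never asserted, because it is dataset-specific.

## Conditions

Normalization maps room-temperature synonyms to 25 °C and
atmospheric-pressure synonyms to 1 atm; ranges `a–b` are averaged when their
spread is at most 20 °C / 2 atm (configurable) and rejected otherwise.
Binning: temperature low (< 0 °C), medium (0–50 °C inclusive), high
(> 50 °C); pressure low (0–3 atm], medium (3–10 atm], high (> 10 atm).
The boundary convention is right-closed — 3 atm is *low*, 10 atm is
*medium* — chosen for consistency with "high means strictly above 10" and
documented here because the bin edges otherwise overlap on paper.

The bit vector is `[T(3) | P(3) | acid,base,poison | catalyst(n)]` with
one-hot temperature, pressure and catalyst and free additive bits — 38 bits
for the default 29-catalyst vocabulary, giving 9 · 8 · n_catalysts
enumerable combinations (2088 by default). Encoding and decoding are a
bijection on valid vectors. Records whose catalyst is outside the
vocabulary are dropped with a log entry (the vocabulary is meant to contain
only the corpus's common catalysts). The default 29-name catalyst list is a
synthetic stand-in sized like a typical common-catalyst vocabulary; real
applications supply their own list in bit order (`catalysts.yaml`).

## Rankers

**Likelihood model.** One ReLU hidden layer (default 2000 units) into 38
sigmoid outputs. The loss is multi-label binary cross-entropy — the
canonical pairing for independent sigmoid targets; the output slices are
deliberately *not* softmaxed, since additive bits are genuinely independent
and the one-hot blocks are enforced at combination-scoring time, not in the
network. Training uses Adam (lr 0.001) with the learning rate multiplied by
0.99 after every epoch, 200 epochs, minibatches of 32, He/Glorot
initialization, all seeded. The network is implemented directly in NumPy —
it is small enough that a framework adds nothing, and the per-epoch
multiplicative decay falls outside what scikit-learn's MLP exposes.

A combination's score is ℒ = −(1/6)·Σ ln q over the six component
probabilities (temperature bin, pressure bin, catalyst, and one Bernoulli
term per additive: q = P if the combination selects the additive, 1 − P
otherwise). Probabilities are clipped to [1e−9, 1] before the log —
numerical safety only; it cannot reorder well-separated combinations.
Combinations are sorted ascending in ℒ with ties broken by bit-vector
lexicographic order (the enumeration order), making the full ranking a
deterministic total order. ℒ is reported together with exp(−ℒ) ∈ (0, 1],
which is the more intuitive "confidence" reading (higher = more confident);
both scales are exposed because either may be meant when a single
"log-likelihood" number is quoted.

**Ranking kNN.** Euclidean distances in PCA space (scikit-learn
`NearestNeighbors`); the k nearest training reactions contribute their
condition combinations in ascending distance order, and a combination that
recurs at a farther neighbor is dropped. Default k = 10 — small enough to
stay local, large enough to survive deduplication; it is a config field and
`evaluate` makes cross-validating it straightforward. k larger than the
training set is truncated with a warning.

**Null model.** Unique training combinations by descending frequency, ties
again by bit-vector order, identical for every query. It is the floor any
structure-aware model must beat, and on skewed corpora it is a high floor.

## Metrics

MRR@K averages 1/(best rank of a relevant combination within the top K);
ranks are 1-based, and a query with no relevant combination in the top K
contributes 0 — the information-retrieval convention, which keeps MRR@K in
[0, 1] and monotone in K. P@K is the percentage of queries with at least
one relevant combination in the top K. Per-component accuracy marginalizes
the match to a chosen subset of {temperature, pressure, catalyst,
additives}; with all four it reduces exactly to P@K.

## Applicability domain

Fragment control: the universe is the unfiltered union of all training CGR
fragments (same 2–4 atom lengths as the descriptors, no frequency cut, hence
always a superset of the model vocabulary). A query is out-of-domain iff it
contains any fragment absent from the universe. Out-of-domain queries are
still ranked — the model produces an answer for any parseable reaction —
but downstream users should treat the flag as "the model has never seen this
chemistry". The flag is monotone in the universe: adding training data can
only move queries into the domain.

## Synthetic data generator

The generator emulates the structure of a curated hydrogenation corpus
without reproducing any real data. Six transformation templates (nitro
reduction, alkene and hindered-alkene saturation, partial alkyne reduction,
benzyl-ether hydrogenolysis, aryl-halide dehalogenation) are instantiated on
randomized small scaffolds (≤ ~20 heavy atoms) with correct atom maps. Each
template has a rule table of up to three conditions in preference order
(e.g. nitro ⇒ Pd/C, medium T, low P; hindered alkene ⇒ Pt/C, high P;
dehalogenation ⇒ base flag; partial alkyne reduction ⇒ poisoned Lindlar
catalyst). Defaults: 500 records, noise rate 0.1 (one condition component of
a noisy record is replaced at random), multiplicity distribution
(0.6, 0.3, 0.1) over 1–3 conditions per transformation, frequency skew 4.0
on the two templates sharing the dominant mode — which makes the modal
combination (Pd/C, medium T, low P, no additives) cover roughly 40–50 % of
records, a realistically skewed regime in which the frequency null model is
already strong. About 15 % of medium-temperature / low-pressure values are
written as the synonym tokens "rt" / "atmospheric pressure" so that
normalization is exercised end to end.

What the generator does **not** emulate: real structure–condition
correlations beyond the rule table (no substrate-specific selectivity
within a template), solvent identity, yields, temperature/pressure
interactions, multistep entries, or the long tail of rare catalysts.
Passing the recovery benchmark therefore shows that the pipeline can learn
a clean structure→condition mapping through its full representation stack
under label noise and a strong frequency mode — not that it reproduces any
particular literature-scale accuracy.

The train/test split operates on transformation keys, so reactions of the
same transformation never straddle the split, and duplicate
(transformation, condition-vector) pairs are removed within each side.

## Problem sizes and defaults used by the tests

The shipped test suite and examples run the pipeline at desk scale: 500
generated records, an 80/20 transformation-level split, fragment vocabulary
of a few hundred entries, PCA capped by the data, and a 256-unit hidden
layer trained for 200 epochs (the library default stays at the full-scale
2000/200). At this scale training takes on the order of a second and the
recovery benchmark shows the expected ordering — likelihood model above the
frequency null at K = 1 and above 80 % P@5 — with the residual misses
traceable to queries whose only records are noise-corrupted.

## Known limitations

- Input reactions must already be atom-mapped and reasonably aromatized;
  no mapping or normalization is performed.
- The likelihood ranking requires the condition space to be enumerable; it
  scales linearly in the number of combinations and would need constrained
  enumeration for richer condition vocabularies.
- Additives are predicted as classes (acid/base/poison), not as compound
  identities; solvents are not modeled.
- The independence assumption behind the six-factor geometric mean ignores
  correlations between condition components (e.g. catalyst–pressure
  coupling); the ranking can only recover those through the shared hidden
  layer.
- Linear path fragments cannot distinguish all branching patterns; two CGRs
  with identical path multisets receive identical descriptors.
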