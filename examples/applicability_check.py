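"""Fragment-control applicability domain in action.

A reaction is out of the model's domain when its CGR contains any fragment
never seen among the training CGRs.  The model still produces a full
ranking for such reactions — the flag warns that the prediction rests on
chemistry the model has never observed.
"""

from condrank import (
    GeneratorConfig,
    LRMConfig,
    ModelBundle,
    PipelineConfig,
    build_cgr,
    generate_dataset,
    in_domain,
    parse_reaction_smiles,
    split_by_transformation,
)

data = generate_dataset(GeneratorConfig(n_reactions=300, seed=5))
train_idx, _ = split_by_transformation(data.lines, data.records, (0.8, 0.2), seed=5)
bundle = ModelBundle.train(
    [data.lines[i] for i in train_idx],
    [data.records[i] for i in train_idx],
    PipelineConfig(lrm=LRMConfig(hidden_size=128, epochs=50, seed=5), seed=5),
)

familiar = data.lines[train_idx[0]]
exotic = "[CH2:1]=[CH:2][Se:3][CH3:4]>[H][H]>[CH3:1][CH2:2][Se:3][CH3:4]"

for name, line in (("training reaction", familiar), ("selenoether query", exotic)):
    ok, novel = in_domain(build_cgr(parse_reaction_smiles(line)), bundle.universe)
    print(f"{name}: in domain = {ok}" + (f", {len(novel)} novel fragments, e.g. "
          f"{novel[0]}" if novel else ""))

ranked, ok = bundle.rank(exotic, "lrm")
top = ranked.combinations[0]
print(f"\nout-of-domain reactions are still ranked: top-1 = "
      f"({top.temperature_bin} T, {top.pressure_bin} P, "
      f"{bundle.cond_vocab.catalysts[top.catalyst]}) — treat with caution.")
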