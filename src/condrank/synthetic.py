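"""Rule-based synthetic hydrogenation data.

Real condition-annotated reaction data of the kind this package models are
proprietary, so this module generates atom-mapped hydrogenation reactions
with condition labels assigned by an explicit, published rule table.  The
generator emulates the structural features such corpora show:

* several hydrogenation transformation classes — nitro reduction, alkene and
  hindered-alkene saturation, partial alkyne reduction, benzyl-ether
  hydrogenolysis, aryl-halide dehalogenation — on randomized small scaffolds
  (<= ~20 heavy atoms) with correct atom maps;
* many-to-many transformation/condition correspondence: a transformation may
  be reported under one, two or three distinct conditions;
* a skewed condition frequency distribution with a dominant mode (palladium
  on carbon, medium temperature, low pressure);
* label noise: a configurable fraction of records has one condition
  component replaced at random;
* raw-value quirks: numeric temperatures/pressures, occasional "rt" and
  "atmospheric pressure" synonym tokens.

The rule table is exported alongside the data (``rules.json``) so oracle
tests can re-derive every clean label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .cgr import build_cgr, transformation_key
from .conditions import (
    BINS,
    ConditionCombination,
    ConditionVocabulary,
    binned_combination,
)
from .reactions import ConditionRecord, parse_reaction_smiles

# --- rule table --------------------------------------------------------------
# (temperature_bin, pressure_bin, catalyst_name, acid, base, poison), in
# decreasing preference order; the first entry is the canonical condition.
RULES: dict[str, list[tuple]] = {
    "nitro_to_amine": [
        ("medium", "low", "pd-c", 0, 0, 0),
        ("medium", "medium", "raney-ni", 0, 0, 0),
        ("high", "medium", "pd-c", 0, 0, 0),
    ],
    "alkene_to_alkane": [
        ("medium", "low", "pd-c", 0, 0, 0),
        ("medium", "low", "pt-c", 0, 0, 0),
        ("medium", "medium", "pd-c", 0, 0, 0),
    ],
    "hindered_alkene_to_alkane": [
        ("medium", "high", "pt-c", 0, 0, 0),
        ("high", "high", "pto2", 0, 0, 0),
        ("high", "high", "pt-c", 0, 0, 0),
    ],
    "alkyne_to_cis_alkene": [
        ("medium", "low", "lindlar", 0, 0, 1),
        ("low", "low", "lindlar", 0, 0, 1),
        ("medium", "low", "pd-baso4", 0, 0, 1),
    ],
    "benzyl_ether_hydrogenolysis": [
        ("medium", "low", "pd-c", 1, 0, 0),
        ("medium", "medium", "pd-oh-c", 1, 0, 0),
        ("medium", "low", "pd-black", 1, 0, 0),
    ],
    "aryl_halide_dehalogenation": [
        ("high", "medium", "pd-c", 0, 1, 0),
        ("medium", "medium", "raney-ni", 0, 1, 0),
        ("high", "medium", "pd-c", 0, 1, 1),
    ],
}

#: templates whose canonical condition is the dominant mode; frequency_skew
#: multiplies their sampling weight
_MODAL_TEMPLATES = ("nitro_to_amine", "alkene_to_alkane")

_ALKYL = ("C", "CC", "CCC", "C(C)C", "OC", "CO", "F")
# numeric value ranges per bin (sampled uniformly)
_T_RANGE = {"low": (-40.0, -5.0), "medium": (5.0, 45.0), "high": (55.0, 120.0)}
_P_RANGE = {"low": (1.0, 3.0), "medium": (3.5, 10.0), "high": (11.0, 50.0)}


@dataclass
class GeneratorConfig:
    n_reactions: int = 500
    seed: int = 42
    noise_rate: float = 0.1
    #: probabilities of a transformation being reported under 1, 2, 3 conditions
    multiplicity_distribution: tuple[float, ...] = (0.6, 0.3, 0.1)
    #: sampling-weight multiplier for the dominant-mode templates
    frequency_skew: float = 4.0
    #: fraction of 25 °C / 1 atm values written as synonym tokens
    synonym_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if abs(sum(self.multiplicity_distribution) - 1.0) > 1e-9:
            raise ValueError("multiplicity_distribution must sum to 1")
        if self.frequency_skew <= 0:
            raise ValueError("frequency_skew must be positive")


@dataclass
class SyntheticDataset:
    """Aligned reaction lines + condition records, with generation metadata."""

    lines: list[str]
    records: list[ConditionRecord]
    #: per record: template, transformation serial, rule index, noisy flag
    meta: list[dict] = field(default_factory=list)
    rules: dict[str, list[tuple]] = field(default_factory=lambda: dict(RULES))

    def write(self, directory: str | Path) -> None:
        from .reactions import write_condition_table

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "reactions.smi").write_text("\n".join(self.lines) + "\n")
        write_condition_table(d / "conditions.csv", self.records)
        (d / "rules.json").write_text(json.dumps(self.rules, indent=1))


# --- scaffold builders --------------------------------------------------------

def _aryl(rng: np.random.Generator, head: str) -> str:
    """A benzene ring carrying ``head`` plus 0-2 random inert substituents."""
    forms = (
        "{h}c1ccccc1",
        "{h}c1ccc({a})cc1",
        "{h}c1cccc({a})c1",
        "{h}c1ccc({a})c({b})c1",
    )
    form = forms[rng.integers(len(forms))]
    return form.format(h=head, a=rng.choice(_ALKYL), b=rng.choice(_ALKYL))


#: substituents flanking an unsaturation; written as SMILES prefix/suffix
_SIDES = ("C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "c1ccccc1", "CCO")


def _chain(rng: np.random.Generator) -> str:
    return "C" * int(rng.integers(1, 5))


def _build_reactant(template: str, rng: np.random.Generator) -> str:
    if template == "nitro_to_amine":
        return _aryl(rng, "O=[N+]([O-])")
    if template == "alkene_to_alkane":
        return f"{rng.choice(_SIDES)}C=C{rng.choice(_SIDES)}"
    if template == "hindered_alkene_to_alkane":
        return f"CC(C)=C(C){rng.choice(_SIDES)}"
    if template == "alkyne_to_cis_alkene":
        return f"{rng.choice(_SIDES)}C#C{rng.choice(_SIDES)}"
    if template == "benzyl_ether_hydrogenolysis":
        return f"{_aryl(rng, '')}CO{_chain(rng)}"
    if template == "aryl_halide_dehalogenation":
        return _aryl(rng, "Cl")
    raise ValueError(f"unknown template {template!r}")


def _transform(template: str, mol: Chem.RWMol) -> Chem.Mol:
    """Apply the hydrogenation edit to a fully mapped reactant molecule."""
    if template == "nitro_to_amine":
        nitro_n = next(
            a.GetIdx() for a in mol.GetAtoms()
            if a.GetSymbol() == "N" and a.GetFormalCharge() == 1
        )
        oxygens = sorted(
            (n.GetIdx() for n in mol.GetAtomWithIdx(nitro_n).GetNeighbors()
             if n.GetSymbol() == "O"),
            reverse=True,
        )
        mol.GetAtomWithIdx(nitro_n).SetFormalCharge(0)
        for o in oxygens:
            mol.RemoveAtom(o)
    elif template in ("alkene_to_alkane", "hindered_alkene_to_alkane"):
        bond = next(
            b for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE and not b.GetIsAromatic()
        )
        bond.SetBondType(Chem.BondType.SINGLE)
    elif template == "alkyne_to_cis_alkene":
        bond = next(
            b for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE
        )
        bond.SetBondType(Chem.BondType.DOUBLE)
    elif template == "benzyl_ether_hydrogenolysis":

        def _is_benzylic_ether(b: Chem.Bond) -> bool:
            a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
            if {a1.GetSymbol(), a2.GetSymbol()} != {"C", "O"}:
                return False
            c = a1 if a1.GetSymbol() == "C" else a2
            # benzylic: sp3 carbon attached to an aromatic ring
            return not c.GetIsAromatic() and any(
                nb.GetIsAromatic() for nb in c.GetNeighbors()
            )

        bond = next(b for b in mol.GetBonds() if _is_benzylic_ether(b))
        mol.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    elif template == "aryl_halide_dehalogenation":
        cl = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "Cl")
        mol.RemoveAtom(cl)
    else:
        raise ValueError(f"unknown template {template!r}")
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def make_reaction(template: str, rng: np.random.Generator) -> str:
    """One atom-mapped reaction SMILES line for the given template."""
    reactant = Chem.MolFromSmiles(_build_reactant(template, rng))
    for i, atom in enumerate(reactant.GetAtoms()):
        atom.SetAtomMapNum(i + 1)
    product = _transform(template, Chem.RWMol(reactant))
    return f"{Chem.MolToSmiles(reactant)}>[H][H]>{Chem.MolToSmiles(product)}"


# --- record emission ----------------------------------------------------------

def _emit_record(
    combo: tuple, rng: np.random.Generator, synonym_rate: float
) -> ConditionRecord:
    t_bin, p_bin, catalyst, acid, base, poison = combo
    t = round(float(rng.uniform(*_T_RANGE[t_bin])), 1)
    p = round(float(rng.uniform(*_P_RANGE[p_bin])), 1)
    temperature: float | str = t
    pressure: float | str = p
    if t_bin == "medium" and rng.random() < synonym_rate:
        temperature = "rt"
    if p_bin == "low" and rng.random() < synonym_rate:
        pressure = "atmospheric pressure"
    return ConditionRecord(temperature, pressure, catalyst,
                           bool(acid), bool(base), bool(poison))


def _corrupt(
    combo: tuple, rng: np.random.Generator, catalysts: tuple[str, ...]
) -> tuple:
    """Replace one condition component with a different random value."""
    t, p, cat, acid, base, poison = combo
    which = rng.integers(4)
    if which == 0:
        t = str(rng.choice([b for b in BINS if b != t]))
    elif which == 1:
        p = str(rng.choice([b for b in BINS if b != p]))
    elif which == 2:
        cat = str(rng.choice([c for c in catalysts if c != cat]))
    else:
        flag = rng.integers(3)
        acid, base, poison = (
            (1 - acid, base, poison) if flag == 0
            else (acid, 1 - base, poison) if flag == 1
            else (acid, base, 1 - poison)
        )
    return (t, p, cat, acid, base, poison)


def generate_dataset(
    config: GeneratorConfig,
    vocab: ConditionVocabulary | None = None,
) -> SyntheticDataset:
    """Generate ``config.n_reactions`` condition records with their reactions.

    A transformation (one reaction SMILES) may be emitted under several
    distinct conditions, each as its own aligned (line, record) pair — the
    many-to-many correspondence.  Reproducible for a fixed config.
    """
    vocab = vocab or ConditionVocabulary()
    rng = np.random.default_rng(config.seed)
    templates = list(RULES)
    weights = np.array(
        [config.frequency_skew if t in _MODAL_TEMPLATES else 1.0 for t in templates]
    )
    weights = weights / weights.sum()
    mult = np.asarray(config.multiplicity_distribution)

    lines: list[str] = []
    records: list[ConditionRecord] = []
    meta: list[dict] = []
    serial = 0
    while len(records) < config.n_reactions:
        template = str(rng.choice(templates, p=weights))
        line = make_reaction(template, rng)
        n_conditions = 1 + int(rng.choice(len(mult), p=mult))
        for rule_idx in range(n_conditions):
            if len(records) == config.n_reactions:
                break
            combo = RULES[template][rule_idx]
            noisy = bool(rng.random() < config.noise_rate)
            if noisy:
                combo = _corrupt(combo, rng, vocab.catalysts)
            lines.append(line)
            records.append(_emit_record(combo, rng, config.synonym_rate))
            meta.append({
                "template": template,
                "transformation": serial,
                "rule_index": rule_idx,
                "noisy": noisy,
            })
        serial += 1
    return SyntheticDataset(lines, records, meta)


# --- transformation-level splitting -------------------------------------------

def split_by_transformation(
    lines: list[str],
    records: list[ConditionRecord],
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    vocab: ConditionVocabulary | None = None,
) -> tuple[list[int], list[int]]:
    """Split aligned (line, record) pairs so that no transformation straddles
    train and test, then drop duplicate (transformation, condition-vector)
    pairs within each side.  Returns index lists into the inputs.
    """
    if len(lines) != len(records):
        raise ValueError("lines and records must be aligned")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    vocab = vocab or ConditionVocabulary()

    keys = [transformation_key(build_cgr(parse_reaction_smiles(l))) for l in lines]
    unique_keys = sorted(set(keys))
    rng = np.random.default_rng(seed)
    rng.shuffle(unique_keys)
    n_train = int(round(fractions[0] * len(unique_keys)))
    train_keys = set(unique_keys[:n_train])

    def dedup(indices: list[int]) -> list[int]:
        seen: set[tuple] = set()
        out = []
        for i in indices:
            combo = binned_combination(records[i], vocab)
            pair = (keys[i], combo)
            if pair in seen:
                continue
            seen.add(pair)
            out.append(i)
        return out

    train = dedup([i for i, k in enumerate(keys) if k in train_keys])
    test = dedup([i for i, k in enumerate(keys) if k not in train_keys])
    return train, test


def rule_combination(
    template: str, rule_index: int, vocab: ConditionVocabulary
) -> ConditionCombination:
    """The clean ConditionCombination the rule table assigns — the oracle."""
    t, p, cat, acid, base, poison = RULES[template][rule_index]
    return ConditionCombination(
        t, p, vocab.catalyst_index[cat], bool(acid), bool(base), bool(poison)
    )
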