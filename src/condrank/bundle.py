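"""End-to-end pipeline: featurize, train, persist, rank, evaluate.

A :class:`ModelBundle` holds everything a trained recommender needs —
condition vocabulary, fragment vocabulary, PCA projector, network weights,
training descriptors/conditions (for the kNN and null baselines) and the
fragment universe (for the applicability domain) — and can be saved to /
loaded from a directory with a versioned manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .applicability import FragmentUniverse, fit_universe, in_domain
from .cgr import CGR, build_cgr, transformation_key
from .conditions import (
    ConditionCombination,
    ConditionValueError,
    ConditionVocabulary,
    binned_combination,
    enumerate_combinations,
)
from .fragments import (
    FragmentVocabulary,
    Projector,
    build_vocabulary,
    enumerate_fragments,
    fit_pca,
    vectorize_counts,
)
from .metrics import RelevanceJudgment, evaluation_report
from .rankers import (
    KNNIndex,
    LikelihoodRankingModel,
    LRMConfig,
    RankedConditions,
    rank_knn,
    rank_null,
    rank_probabilities,
)
from .reactions import ConditionRecord, parse_reaction_smiles

logger = logging.getLogger("condrank")

MANIFEST_VERSION = 1


@dataclass
class PipelineConfig:
    """Descriptor + model settings for one training run.

    Defaults mirror the full-scale recommended architecture (fragments of 2-4
    atoms, rare-fragment cutoff 5, 1500 principal components, hidden layer of
    2000, 200 epochs, Adam lr 0.001 with x0.99 per-epoch decay); the PCA
    width is automatically capped at min(n_samples, n_features) so the same
    config runs on desk-scale corpora.
    """

    min_len: int = 2
    max_len: int = 4
    min_frequency: int = 5
    n_components: int = 1500
    knn_k: int = 10
    lrm: LRMConfig = field(default_factory=LRMConfig)
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        data["lrm"] = LRMConfig(**data["lrm"])
        return cls(**data)


def prepare_pairs(
    lines: list[str],
    records: list[ConditionRecord],
    vocab: ConditionVocabulary,
) -> tuple[list[CGR], list[str], list[ConditionCombination], list[int]]:
    """Parse reactions and bin conditions, dropping pairs whose record cannot
    be encoded (unknown catalyst, rejected value); returns aligned CGRs,
    transformation keys, combinations and the kept indices."""
    if len(lines) != len(records):
        raise ValueError(f"{len(lines)} reactions vs {len(records)} condition rows")
    cgrs, keys, combos, kept = [], [], [], []
    for i, (line, rec) in enumerate(zip(lines, records)):
        try:
            combo = binned_combination(rec, vocab)
        except (KeyError, ConditionValueError) as e:
            logger.info("dropping record %d: %s", i, e)
            continue
        cgr = build_cgr(parse_reaction_smiles(line))
        cgrs.append(cgr)
        keys.append(transformation_key(cgr))
        combos.append(combo)
        kept.append(i)
    if not kept:
        raise ValueError("no usable (reaction, condition) pairs")
    return cgrs, keys, combos, kept


@dataclass
class ModelBundle:
    config: PipelineConfig
    cond_vocab: ConditionVocabulary
    frag_vocab: FragmentVocabulary
    projector: Projector
    model: LikelihoodRankingModel
    universe: FragmentUniverse
    train_X: np.ndarray  # PCA-space training descriptors
    train_conditions: list[ConditionCombination]

    def __post_init__(self) -> None:
        self.combos = enumerate_combinations(self.cond_vocab)
        self._knn = KNNIndex(self.train_X, self.train_conditions, self.config.knn_k)
        self._null = rank_null(self.train_conditions, self.cond_vocab)

    # --- training -----------------------------------------------------------

    @classmethod
    def train(
        cls,
        lines: list[str],
        records: list[ConditionRecord],
        config: PipelineConfig | None = None,
        cond_vocab: ConditionVocabulary | None = None,
    ) -> "ModelBundle":
        config = config or PipelineConfig()
        cond_vocab = cond_vocab or ConditionVocabulary()
        cgrs, _, combos, _ = prepare_pairs(lines, records, cond_vocab)

        fragment_counts = [
            enumerate_fragments(c, config.min_len, config.max_len) for c in cgrs
        ]
        frag_vocab = build_vocabulary(fragment_counts, config.min_frequency)
        logger.info("fragment vocabulary: %d fragments", len(frag_vocab))
        counts = np.array([vectorize_counts(fc, frag_vocab) for fc in fragment_counts])

        n_components = min(config.n_components, *counts.shape)
        projector = fit_pca(counts, n_components)
        logger.info(
            "PCA: %d components, %.1f%% explained variance",
            n_components, 100 * projector.explained_variance_ratio.sum(),
        )
        X = projector.apply(counts)
        Y = np.array([cond_vocab.encode_combination(c) for c in combos], dtype=float)

        lrm_cfg = LRMConfig(**{**asdict(config.lrm), "seed": config.seed})
        model = LikelihoodRankingModel(X.shape[1], Y.shape[1], lrm_cfg).fit(X, Y)
        if model.loss_history:
            logger.info("final training loss %.4f", model.loss_history[-1])

        universe = fit_universe(cgrs, config.min_len, config.max_len)
        return cls(config, cond_vocab, frag_vocab, projector, model,
                   universe, X, combos)

    # --- inference ------------------------------------------------------------

    def featurize(self, line: str) -> tuple[np.ndarray, CGR]:
        cgr = build_cgr(parse_reaction_smiles(line))
        counts = vectorize_counts(
            enumerate_fragments(cgr, self.config.min_len, self.config.max_len),
            self.frag_vocab,
        )
        return self.projector.apply(counts), cgr

    def rank(self, line: str, ranker: str = "lrm") -> tuple[RankedConditions, bool]:
        """Ranked conditions for one reaction plus its in-domain flag.

        Out-of-domain reactions are still ranked; the flag warns that the
        query contains fragments never seen in training.
        """
        x, cgr = self.featurize(line)
        ok, _ = in_domain(cgr, self.universe)
        if ranker == "lrm":
            probs = self.model.predict_proba(x)[0]
            return rank_probabilities(probs, self.combos, self.cond_vocab), ok
        if ranker == "knn":
            return rank_knn(self._knn, x), ok
        if ranker == "null":
            return self._null, ok
        raise ValueError(f"unknown ranker {ranker!r} (expected lrm, knn or null)")

    # --- evaluation -------------------------------------------------------------

    def make_queries(
        self, lines: list[str], records: list[ConditionRecord]
    ) -> tuple[list[str], list[set[ConditionCombination]], list[bool]]:
        """Group a test set by transformation: one query per transformation,
        its relevant set = all observed combinations, plus in-domain flags."""
        cgrs, keys, combos, kept = prepare_pairs(lines, records, self.cond_vocab)
        by_key: dict[str, int] = {}
        queries: list[str] = []
        relevant: list[set[ConditionCombination]] = []
        flags: list[bool] = []
        for cgr, key, combo, idx in zip(cgrs, keys, combos, kept):
            if key not in by_key:
                by_key[key] = len(queries)
                queries.append(lines[idx])
                relevant.append(set())
                flags.append(in_domain(cgr, self.universe)[0])
            relevant[by_key[key]].add(combo)
        return queries, relevant, flags

    def evaluate(
        self,
        lines: list[str],
        records: list[ConditionRecord],
        ks: tuple[int, ...] = (1, 3, 5, 10),
        rankers: tuple[str, ...] = ("lrm", "knn", "null"),
        in_domain_only: bool = False,
        component_subsets: tuple = (),
    ) -> list[dict]:
        """MRR@K / P@K report rows per ranker over transformation-level queries."""
        queries, relevant, flags = self.make_queries(lines, records)
        if in_domain_only:
            keep = [i for i, ok in enumerate(flags) if ok]
            queries = [queries[i] for i in keep]
            relevant = [relevant[i] for i in keep]
        judgments = RelevanceJudgment(relevant)
        rankings_by_model = {
            name: [self.rank(q, name)[0] for q in queries] for name in rankers
        }
        return evaluation_report(rankings_by_model, judgments, ks, component_subsets)

    # --- persistence ---------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cond_vocab.save(d / "catalysts.yaml")
        self.frag_vocab.save(d / "fragments.txt")
        self.projector.save(d / "pca.npz")
        self.model.save(d / "lrm.npz")
        self.universe.save(d / "universe.txt")
        Y = np.array(
            [self.cond_vocab.encode_combination(c) for c in self.train_conditions],
            dtype=np.uint8,
        )
        np.savez(d / "train.npz", X=self.train_X, Y=Y)
        manifest = {
            "format_version": MANIFEST_VERSION,
            "package_version": __import__("condrank").__version__,
            "config": self.config.to_dict(),
            "files": ["catalysts.yaml", "fragments.txt", "pca.npz",
                      "lrm.npz", "universe.txt", "train.npz"],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        manifest_path = d / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.json in {d}")
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("format_version") != MANIFEST_VERSION:
            raise ValueError(
                f"bundle format {manifest.get('format_version')} != {MANIFEST_VERSION}"
            )
        missing = [f for f in manifest["files"] if not (d / f).exists()]
        if missing:
            raise ValueError(f"corrupt bundle: missing files {missing}")
        config = PipelineConfig.from_dict(manifest["config"])
        cond_vocab = ConditionVocabulary.load(d / "catalysts.yaml")
        train = np.load(d / "train.npz")
        conditions = [cond_vocab.decode(row) for row in train["Y"]]
        return cls(
            config,
            cond_vocab,
            FragmentVocabulary.load(d / "fragments.txt"),
            Projector.load(d / "pca.npz"),
            LikelihoodRankingModel.load(d / "lrm.npz"),
            FragmentUniverse.load(d / "universe.txt"),
            train["X"],
            conditions,
        )
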