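"""Atom-centered fragment descriptors over CGRs.

Fragments are linear atom/bond paths of bounded length (default 2–4 atoms,
i.e. 1–3 bonds) enumerated from every atom of a CGR, in the spirit of ISIDA
sequence fragments.  Because the underlying graph is a CGR, a fragment may
contain dynamic bond tokens and thereby describe the chemical transformation
itself, not just the substrate.

Fragment string syntax (defined by this package):

* atom token — element symbol; a charge suffix when nonzero and static
  (``N+``, ``O-``, ``Fe+2``); a dynamic-charge suffix ``[r>p]`` when the
  formal charge changes across the reaction (``N[+1>0]``);
* bond token — ``-`` ``=`` ``#`` ``:`` for static orders 1/2/3/aromatic, or
  ``[r>p]`` with r, p in {0, 1, 2, 3, a} for dynamic bonds (0 = absent);
* a path is rendered in both directions and the lexicographically smaller
  string is kept, so each undirected path contributes one canonical fragment
  per start atom (both endpoints generate it — the atom-centered convention).

Rare fragments (corpus frequency below ``min_frequency``, default 5) are
dropped when the vocabulary is fitted.  Count vectors are compressed by PCA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .cgr import CGR, CGRAtom

_BOND_SYMBOL = {1: "-", 2: "=", 3: "#", "a": ":"}


def _charge_suffix(c: int) -> str:
    if c == 0:
        return ""
    sign = "+" if c > 0 else "-"
    return sign if abs(c) == 1 else f"{sign}{abs(c)}"


def _fmt_charge(c: int) -> str:
    return f"{'+' if c > 0 else ''}{c}" if c != 0 else "0"


def atom_token(atom: CGRAtom) -> str:
    if atom.reactant_charge == atom.product_charge:
        return atom.element + _charge_suffix(atom.reactant_charge)
    return (
        f"{atom.element}[{_fmt_charge(atom.reactant_charge)}"
        f">{_fmt_charge(atom.product_charge)}]"
    )


def bond_token(label: tuple) -> str:
    r, p = label
    if r == p:
        return _BOND_SYMBOL[r]
    return f"[{r}>{p}]"


def _render(path: Sequence[int], labels: Sequence[tuple], cgr: CGR) -> str:
    parts = [atom_token(cgr.atoms[path[0]])]
    for atom_idx, label in zip(path[1:], labels):
        parts.append(bond_token(label))
        parts.append(atom_token(cgr.atoms[atom_idx]))
    return "".join(parts)


def canonical_fragment(path: Sequence[int], labels: Sequence[tuple], cgr: CGR) -> str:
    fwd = _render(path, labels, cgr)
    rev = _render(list(reversed(path)), list(reversed(labels)), cgr)
    return min(fwd, rev)


def enumerate_fragments(cgr: CGR, min_len: int = 2, max_len: int = 4) -> Counter:
    """Multiset of canonical fragment strings for all simple paths of
    ``min_len``..``max_len`` atoms starting at every atom of the CGR."""
    if not 2 <= min_len <= max_len:
        raise ValueError(f"need 2 <= min_len <= max_len, got {min_len}..{max_len}")
    adj = cgr.adjacency()
    out: Counter = Counter()

    def extend(path: list[int], labels: list[tuple], on_path: set[int]) -> None:
        if len(path) >= min_len:
            out[canonical_fragment(path, labels, cgr)] += 1
        if len(path) == max_len:
            return
        for nxt, label in adj[path[-1]]:
            if nxt in on_path:
                continue
            path.append(nxt)
            labels.append(label)
            on_path.add(nxt)
            extend(path, labels, on_path)
            on_path.remove(nxt)
            labels.pop()
            path.pop()

    for start in range(len(cgr.atoms)):
        extend([start], [], {start})
    return out


@dataclass
class FragmentVocabulary:
    """Ordered fragment list retained after the rare-fragment filter."""

    fragments: list[str]
    min_frequency: int
    counts: dict[str, int]  # corpus frequency of each retained fragment

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.fragments)}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# min_frequency={self.min_frequency}\n")
            for f in self.fragments:
                fh.write(f"{f}\t{self.counts[f]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "FragmentVocabulary":
        lines = Path(path).read_text().splitlines()
        min_freq = int(lines[0].split("=", 1)[1])
        fragments, counts = [], {}
        for line in lines[1:]:
            frag, cnt = line.rsplit("\t", 1)
            fragments.append(frag)
            counts[frag] = int(cnt)
        return cls(fragments, min_freq, counts)


def build_vocabulary(
    corpora: Iterable[Counter], min_frequency: int = 5
) -> FragmentVocabulary:
    """Pool fragment multisets and keep fragments seen >= ``min_frequency``
    times, in lexicographic order (deterministic regardless of corpus order)."""
    total: Counter = Counter()
    n = 0
    for c in corpora:
        total.update(c)
        n += 1
    if n == 0:
        raise ValueError("empty fragment corpus")
    kept = sorted(f for f, cnt in total.items() if cnt >= min_frequency)
    return FragmentVocabulary(kept, min_frequency, {f: total[f] for f in kept})


def vectorize_counts(counts: Counter, vocab: FragmentVocabulary) -> np.ndarray:
    vec = np.zeros(len(vocab), dtype=np.int64)
    idx = vocab.index
    for frag, cnt in counts.items():
        i = idx.get(frag)
        if i is not None:
            vec[i] = cnt
    return vec


def vectorize(cgr: CGR, vocab: FragmentVocabulary, min_len: int = 2, max_len: int = 4) -> np.ndarray:
    """Count vector of in-vocabulary fragments; out-of-vocabulary fragments
    are ignored here (the applicability module flags them)."""
    return vectorize_counts(enumerate_fragments(cgr, min_len, max_len), vocab)


@dataclass
class Projector:
    """PCA projection fitted on training count matrices."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def apply(self, counts: np.ndarray) -> np.ndarray:
        x = np.asarray(counts, dtype=float)
        return (x - self.mean) @ self.components.T

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            explained_variance_ratio=self.explained_variance_ratio,
        )

    @classmethod
    def load(cls, path: str | Path) -> "Projector":
        data = np.load(path)
        return cls(
            data["mean"], data["components"], data["explained_variance_ratio"]
        )


def fit_pca(count_matrix: np.ndarray, n_components: int) -> Projector:
    """Fit a PCA projector on a (n_samples, n_features) count matrix.

    ``n_components`` must be positive and at most min(n_samples, n_features);
    callers with small corpora cap it themselves.
    """
    X = np.asarray(count_matrix, dtype=float)
    limit = min(X.shape)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for a {X.shape} matrix, "
            f"got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return Projector(pca.mean_, pca.components_, pca.explained_variance_ratio_)
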