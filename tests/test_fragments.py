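"""Fragment enumeration against a brute-force path oracle, vocabulary
filtering, vectorization, and PCA against a dense SVD oracle."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from condrank.cgr import CGR, CGRAtom, build_cgr
from condrank.fragments import (
    FragmentVocabulary,
    atom_token,
    bond_token,
    build_vocabulary,
    canonical_fragment,
    enumerate_fragments,
    fit_pca,
    vectorize,
    vectorize_counts,
)
from condrank.reactions import parse_reaction_smiles


def chain_cgr(n, label=(1, 1)):
    atoms = [CGRAtom("C", 0, 0) for _ in range(n)]
    bonds = [(i, i + 1, label) for i in range(n - 1)]
    return CGR(atoms, bonds)


def brute_force_fragments(cgr, min_len=2, max_len=4):
    """Independent oracle: enumerate simple paths with networkx and render
    each with the package's token functions."""
    g = nx.Graph()
    for i, j, label in cgr.bonds:
        g.add_edge(i, j, label=label)
    g.add_nodes_from(range(len(cgr.atoms)))
    out = Counter()
    for source in g.nodes:
        for target in g.nodes:
            if target == source:
                continue
            for path in nx.all_simple_paths(g, source, target, cutoff=max_len - 1):
                if not (min_len <= len(path) <= max_len):
                    continue
                labels = [g.edges[a, b]["label"] for a, b in zip(path, path[1:])]
                out[canonical_fragment(path, labels, cgr)] += 1
    return out


class TestEnumeration:
    def test_two_atom_chain(self):
        assert enumerate_fragments(chain_cgr(2)) == Counter({"C-C": 2})

    def test_three_atom_path_counts(self):
        frags = enumerate_fragments(chain_cgr(3))
        assert frags == Counter({"C-C": 4, "C-C-C": 2})

    def test_dynamic_bond_token_in_fragment(self):
        cgr = build_cgr(parse_reaction_smiles("[CH2:1]=[CH2:2]>[H][H]>[CH3:1][CH3:2]"))
        assert "C[2>1]C" in enumerate_fragments(cgr)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        atoms = [
            CGRAtom(str(rng.choice(["C", "N", "O"])), 0, 0) for _ in range(n)
        ]
        bonds = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    label = (int(rng.integers(0, 3)), int(rng.integers(0, 3)))
                    if label == (0, 0):
                        label = (1, 1)
                    bonds.append((i, j, label))
        cgr = CGR(atoms, bonds)
        assert enumerate_fragments(cgr) == brute_force_fragments(cgr)

    def test_bond_token_count_property(self):
        """Every fragment of k atoms contains exactly k-1 bond tokens."""
        import re

        # charge-free CGR so every bracket group is a bond token
        cgr = build_cgr(
            parse_reaction_smiles(
                "[CH2:1]=[CH:2][CH2:3][O:4][CH3:5]"
                ">[H][H]>[CH3:1][CH2:2][CH3:3].[OH:4][CH3:5]"
            )
        )
        atom_re = re.compile(r"[A-Z][a-z]?")
        bond_re = re.compile(r"\[[0-9a]>[0-9a]\]|[-=#:]")
        frags = enumerate_fragments(cgr)
        assert frags  # non-degenerate input
        for frag in frags:
            n_atoms = len(atom_re.findall(frag))
            n_bonds = len(bond_re.findall(frag))
            assert 2 <= n_atoms <= 4
            assert n_bonds == n_atoms - 1

    def test_isomorphic_cgrs_same_multiset(self):
        cgr = chain_cgr(4, label=(2, 1))
        # reverse the atom order
        n = len(cgr.atoms)
        rev = CGR(
            list(reversed(cgr.atoms)),
            sorted(
                (n - 1 - j, n - 1 - i, l) for i, j, l in cgr.bonds
            ),
        )
        assert enumerate_fragments(cgr) == enumerate_fragments(rev)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            enumerate_fragments(chain_cgr(3), min_len=1)

    def test_charge_tokens(self):
        assert atom_token(CGRAtom("N", 1, 1)) == "N+"
        assert atom_token(CGRAtom("O", -1, -1)) == "O-"
        assert atom_token(CGRAtom("Fe", 2, 2)) == "Fe+2"
        assert atom_token(CGRAtom("N", 1, 0)) == "N[+1>0]"
        assert bond_token((2, 1)) == "[2>1]"
        assert bond_token(("a", "a")) == ":"


class TestVocabulary:
    def test_rare_fragment_filter_boundary(self):
        corpora = [Counter({"f": 4, "g": 5, "h": 9})]
        vocab = build_vocabulary(corpora, min_frequency=5)
        assert "f" not in vocab.fragments  # frequency 4 < 5: removed
        assert "g" in vocab.fragments     # exactly 5: retained
        assert "h" in vocab.fragments

    def test_counts_pool_across_corpora(self):
        corpora = [Counter({"f": 3}), Counter({"f": 2})]
        vocab = build_vocabulary(corpora, min_frequency=5)
        assert vocab.fragments == ["f"]

    def test_order_invariance(self):
        a = [Counter({"x": 5}), Counter({"y": 6})]
        v1 = build_vocabulary(a, 5)
        v2 = build_vocabulary(list(reversed(a)), 5)
        assert v1.fragments == v2.fragments

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([], 5)

    def test_save_load_roundtrip(self, tmp_path):
        vocab = build_vocabulary([Counter({"C-C": 7, "C[2>1]C": 5})], 5)
        vocab.save(tmp_path / "frags.txt")
        back = FragmentVocabulary.load(tmp_path / "frags.txt")
        assert back.fragments == vocab.fragments
        assert back.counts == vocab.counts
        assert back.min_frequency == 5


class TestVectorize:
    def test_zero_vector_when_nothing_in_vocabulary(self):
        vocab = build_vocabulary([Counter({"X": 5})], 5)
        assert vectorize(chain_cgr(2), vocab).sum() == 0

    def test_sum_conservation_and_determinism(self):
        cgr = chain_cgr(3)
        frags = enumerate_fragments(cgr)
        vocab = build_vocabulary([frags], min_frequency=1)
        v1, v2 = vectorize(cgr, vocab), vectorize(cgr, vocab)
        assert (v1 == v2).all()
        assert v1.sum() == sum(frags.values())

    def test_linear_over_disconnected_union(self):
        g1, g2 = chain_cgr(3), chain_cgr(2, label=(2, 1))
        union = CGR(
            g1.atoms + g2.atoms,
            g1.bonds + [(i + 3, j + 3, l) for i, j, l in g2.bonds],
        )
        vocab = build_vocabulary(
            [enumerate_fragments(g1), enumerate_fragments(g2)], min_frequency=1
        )
        assert (
            vectorize(union, vocab) == vectorize(g1, vocab) + vectorize(g2, vocab)
        ).all()


class TestPCA:
    def test_exact_planar_data(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(30, 2)) @ basis  # exactly rank 2
        proj = fit_pca(X, 2)
        assert proj.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_against_svd_oracle(self):
        """Projection equals the centered-data SVD projection (up to column
        sign), and reconstruction error matches the trailing singular values."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        k = 3
        proj = fit_pca(X, k)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        expected = Xc @ Vt[:k].T
        got = proj.apply(X)
        for col in range(k):
            assert np.allclose(got[:, col], expected[:, col]) or np.allclose(
                got[:, col], -expected[:, col]
            )
        recon_err = ((Xc - got @ proj.components).__pow__(2)).sum()
        assert recon_err == pytest.approx((s[k:] ** 2).sum())

    @pytest.mark.parametrize("bad_k", [0, 11, 21])
    def test_out_of_range_components_rejected(self, bad_k):
        X = np.zeros((20, 10))
        with pytest.raises(ValueError):
            fit_pca(X, bad_k)

    def test_projector_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 8))
        proj = fit_pca(X, 4)
        proj.save(tmp_path / "pca.npz")
        from condrank.fragments import Projector

        back = Projector.load(tmp_path / "pca.npz")
        assert np.allclose(back.apply(X), proj.apply(X))
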