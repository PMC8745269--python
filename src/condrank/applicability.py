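"""Fragment Control applicability domain.

A query reaction is out of the model's applicability domain (AD) when its
CGR contains any fragment never observed among the training CGRs.  The
fragment universe is the *unfiltered* union of all training fragments — no
minimum-frequency cut — so it is always a superset of the model vocabulary.
The model still ranks conditions for out-of-domain reactions; the flag is a
reliability warning, not a refusal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .cgr import CGR
from .fragments import enumerate_fragments


@dataclass
class FragmentUniverse:
    """All canonical fragment strings seen across the training CGRs."""

    fragments: set[str]
    min_len: int = 2
    max_len: int = 4

    def __len__(self) -> int:
        return len(self.fragments)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# lengths={self.min_len}..{self.max_len}\n")
            for f in sorted(self.fragments):
                fh.write(f + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FragmentUniverse":
        lines = Path(path).read_text().splitlines()
        lo, hi = lines[0].split("=", 1)[1].split("..")
        return cls(set(lines[1:]), int(lo), int(hi))


def fit_universe(
    training_cgrs: Iterable[CGR], min_len: int = 2, max_len: int = 4
) -> FragmentUniverse:
    fragments: set[str] = set()
    n = 0
    for cgr in training_cgrs:
        fragments |= set(enumerate_fragments(cgr, min_len, max_len))
        n += 1
    if n == 0:
        raise ValueError("cannot fit a fragment universe on an empty training set")
    return FragmentUniverse(fragments, min_len, max_len)


def in_domain(cgr: CGR, universe: FragmentUniverse) -> tuple[bool, list[str]]:
    """(is_in_domain, sorted list of fragments unseen in training)."""
    query = set(enumerate_fragments(cgr, universe.min_len, universe.max_len))
    novel = sorted(query - universe.fragments)
    return (not novel, novel)
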