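"""Condition normalization, binning, bit-vector encoding and enumeration.

A reaction's conditions are reduced to four components:

* temperature bin — low (< 0 °C), medium (0–50 °C), high (> 50 °C);
* pressure bin — low (0–3 atm], medium (3–10 atm], high (> 10 atm);
* catalyst identity — one name from a fixed vocabulary (29 by default);
* additive classes — acid, base, catalytic poison, each an independent flag.

Bin boundaries are right-closed by convention: 0 °C and 50 °C are medium
temperature; 3 atm is low and 10 atm is medium pressure.

A condition is encoded as a bit vector ordered
``[temperature(3) | pressure(3) | additives(3) | catalyst(n)]`` — 38 bits for
the default 29-catalyst vocabulary — with exactly one bit set in each of the
temperature, pressure and catalyst blocks and free additive bits.  With three
bins per axis, 2^3 additive states and 29 catalysts, 3 x 3 x 8 x 29 = 2088
distinct condition combinations are enumerable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .reactions import ConditionRecord

BINS = ("low", "medium", "high")

#: Default catalyst vocabulary: 29 generic hydrogenation catalyst names, a
#: synthetic stand-in sized to the usual count of common catalysts; real
#: applications supply their own list.
DEFAULT_CATALYSTS = (
    "pd-c", "pt-c", "raney-ni", "rh-c", "lindlar", "pd-baso4", "pd-caco3",
    "pto2", "pd-oh-c", "ru-c", "rh-al2o3", "pd-al2o3", "pt-al2o3", "ir-c",
    "ni-sio2", "pd-sio4", "ru-al2o3", "pdcl2", "pd-acetate", "ni-boride",
    "rh-ptfe", "pt-black", "pd-black", "ru-black", "co-raney", "cu-cr-oxide",
    "fe-oxide", "os-c", "wilkinson",
)


class ConditionValueError(ValueError):
    """Unparseable or rejected raw condition value."""


_TEMPERATURE_SYNONYMS = {
    "rt", "r.t.", "room temperature", "ambient temperature", "ambient",
    "room temp",
}
_PRESSURE_SYNONYMS = {
    "atm", "atmospheric", "atmospheric pressure", "ambient pressure",
    "1 atm", "normal pressure",
}
_RANGE_RE = re.compile(
    r"^\s*(-?\d+(?:\.\d+)?)\s*(?:-|–|—|to)\s*(-?\d+(?:\.\d+)?)\s*$"
)

#: maximum range spread that is still averaged instead of rejected
RANGE_SPREAD = {"temperature": 20.0, "pressure": 2.0}


def normalize_value(
    token: float | int | str,
    kind: str,
    max_spread: float | None = None,
) -> float:
    """Normalize one raw temperature (°C) or pressure (atm) value.

    Numbers pass through; room-temperature / atmospheric-pressure synonyms
    map to 25 °C / 1 atm; ranges ``a-b`` are averaged when their spread does
    not exceed ``max_spread`` (defaults: 20 °C, 2 atm) and rejected otherwise.
    """
    if kind not in RANGE_SPREAD:
        raise ValueError(f"kind must be 'temperature' or 'pressure', got {kind!r}")
    if max_spread is None:
        max_spread = RANGE_SPREAD[kind]
    if isinstance(token, (int, float)):
        if not math.isfinite(token):
            raise ConditionValueError(f"non-finite {kind} value {token!r}")
        return float(token)

    text = token.strip().lower()
    if kind == "temperature" and text in _TEMPERATURE_SYNONYMS:
        return 25.0
    if kind == "pressure" and text in _PRESSURE_SYNONYMS:
        return 1.0
    m = _RANGE_RE.match(text)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        if abs(b - a) > max_spread:
            raise ConditionValueError(
                f"{kind} range {token!r} spread {abs(b - a):g} exceeds {max_spread:g}"
            )
        return (a + b) / 2.0
    try:
        return float(text)
    except ValueError:
        raise ConditionValueError(f"unrecognized {kind} token {token!r}") from None


def bin_temperature(t: float) -> str:
    """low iff t < 0 °C; medium iff 0 <= t <= 50; high iff t > 50."""
    if not math.isfinite(t):
        raise ConditionValueError(f"non-finite temperature {t!r}")
    if t < 0:
        return "low"
    if t <= 50:
        return "medium"
    return "high"


def bin_pressure(p: float) -> str:
    """low iff 0 < p <= 3 atm; medium iff 3 < p <= 10; high iff p > 10."""
    if not math.isfinite(p) or p <= 0:
        raise ConditionValueError(f"pressure must be a positive finite number, got {p!r}")
    if p <= 3:
        return "low"
    if p <= 10:
        return "medium"
    return "high"


@dataclass(frozen=True, order=True)
class ConditionCombination:
    """One fully specified condition assignment — the ranking unit."""

    temperature_bin: str
    pressure_bin: str
    catalyst: int  # vocabulary index
    acid: bool = False
    base: bool = False
    poison: bool = False

    def bits_key(self, vocab: "ConditionVocabulary") -> tuple:
        """Bit-vector as a tuple; the deterministic tie-break sort key."""
        return tuple(vocab.encode_combination(self).tolist())


@dataclass
class ConditionVocabulary:
    """Catalyst list plus the fixed bin/additive layout of the bit vector."""

    catalysts: Sequence[str] = DEFAULT_CATALYSTS
    additive_flags: Sequence[str] = ("acid", "base", "poison")

    def __post_init__(self) -> None:
        self.catalysts = tuple(self.catalysts)
        if len(set(self.catalysts)) != len(self.catalysts):
            raise ValueError("catalyst names must be unique")

    @property
    def n_bits(self) -> int:
        return 9 + len(self.catalysts)

    @property
    def catalyst_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.catalysts)}

    # --- bit layout ------------------------------------------------------
    # [0:3] temperature one-hot, [3:6] pressure one-hot,
    # [6:9] additives (acid, base, poison), [9:] catalyst one-hot
    slices = {
        "temperature": slice(0, 3),
        "pressure": slice(3, 6),
        "additives": slice(6, 9),
    }

    @property
    def catalyst_slice(self) -> slice:
        return slice(9, self.n_bits)

    def encode_combination(self, c: ConditionCombination) -> np.ndarray:
        bits = np.zeros(self.n_bits, dtype=np.uint8)
        bits[BINS.index(c.temperature_bin)] = 1
        bits[3 + BINS.index(c.pressure_bin)] = 1
        bits[6] = c.acid
        bits[7] = c.base
        bits[8] = c.poison
        if not 0 <= c.catalyst < len(self.catalysts):
            raise ValueError(f"catalyst index {c.catalyst} out of range")
        bits[9 + c.catalyst] = 1
        return bits

    def decode(self, bits: np.ndarray) -> ConditionCombination:
        bits = np.asarray(bits)
        if bits.shape != (self.n_bits,):
            raise ValueError(f"expected {self.n_bits} bits, got shape {bits.shape}")
        t = np.flatnonzero(bits[0:3])
        p = np.flatnonzero(bits[3:6])
        cat = np.flatnonzero(bits[9:])
        if len(t) != 1 or len(p) != 1 or len(cat) != 1:
            raise ValueError("temperature, pressure and catalyst must be one-hot")
        return ConditionCombination(
            BINS[t[0]], BINS[p[0]], int(cat[0]),
            bool(bits[6]), bool(bits[7]), bool(bits[8]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"catalysts": list(self.catalysts)}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ConditionVocabulary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(catalysts=tuple(data["catalysts"]))


def binned_combination(
    rec: ConditionRecord, vocab: ConditionVocabulary
) -> ConditionCombination:
    """Normalize + bin a raw record into a ConditionCombination.

    Raises :class:`KeyError` for a catalyst outside the vocabulary (callers
    drop such records, mirroring the restriction to common catalysts) and
    :class:`ConditionValueError` for unusable T/P values.
    """
    idx = vocab.catalyst_index
    if rec.catalyst not in idx:
        raise KeyError(f"catalyst {rec.catalyst!r} not in vocabulary")
    t = normalize_value(rec.temperature, "temperature")
    p = normalize_value(rec.pressure, "pressure")
    return ConditionCombination(
        bin_temperature(t), bin_pressure(p), idx[rec.catalyst],
        rec.acid, rec.base, rec.poison,
    )


def encode_condition(rec: ConditionRecord, vocab: ConditionVocabulary) -> np.ndarray:
    """Raw record -> bit vector (length 9 + |catalysts|, 38 by default)."""
    return vocab.encode_combination(binned_combination(rec, vocab))


def enumerate_combinations(vocab: ConditionVocabulary) -> list[ConditionCombination]:
    """All |T-bins| x |P-bins| x 2^3 x |catalysts| combinations, in the
    deterministic order of their bit vectors."""
    if not vocab.catalysts:
        raise ValueError("catalyst vocabulary is empty")
    combos = [
        ConditionCombination(t, p, cat, bool(a), bool(b), bool(q))
        for t in BINS
        for p in BINS
        for a in (0, 1)
        for b in (0, 1)
        for q in (0, 1)
        for cat in range(len(vocab.catalysts))
    ]
    combos.sort(key=lambda c: c.bits_key(vocab))
    return combos
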