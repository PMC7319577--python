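"""Pseudoknot-aware dot-bracket notation and base-pair consensus.

A secondary structure is a set of base pairs ``(i, j)`` with ``1 <= i < j``
over a sequence of known length; no position may pair twice, but pairs may
cross (pseudoknots).  Dot-bracket text encodes crossing pairs with extra
bracket families — ``()``, ``[]``, ``{}``, ``<>``, then letter pairs
``Aa``, ``Bb``, ... — each family balanced independently.

The consensus of a collection of predictions keeps the base pairs present in
at least a threshold fraction (default 50%) of them.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field

from .errors import CapacityError, DotBracketError, InputCountError, ReconciliationError

_PAREN_FAMILIES = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_LETTER_FAMILIES = [(u, u.lower()) for u in string.ascii_uppercase]
#: Families in the order the writer assigns them to crossing layers.
FAMILIES: list[tuple[str, str]] = _PAREN_FAMILIES + _LETTER_FAMILIES

_OPEN_TO_FAMILY = {o: k for k, (o, _) in enumerate(FAMILIES)}
_CLOSE_TO_FAMILY = {c: k for k, (_, c) in enumerate(FAMILIES)}


@dataclass(frozen=True)
class SecondaryStructure:
    """A base-pair set over ``length`` positions; crossing pairs permitted."""

    length: int
    pairs: frozenset[tuple[int, int]]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position reused by pair ({i},{j})")
            seen.update((i, j))

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def is_crossing(self) -> bool:
        ps = sorted(self.pairs)
        for a in range(len(ps)):
            for b in range(a + 1, len(ps)):
                if _crosses(ps[a], ps[b]):
                    return True
        return False


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


@dataclass
class ConsensusStructure:
    """A consensus structure plus the occurrence fraction of each kept pair."""

    structure: SecondaryStructure
    frequency: dict[tuple[int, int], float] = field(default_factory=dict)
    n_inputs: int = 0


def parse_dotbracket(
    text: str, length: int | None = None, label: str = ""
) -> SecondaryStructure:
    """Parse dot-bracket text (possibly pseudoknotted) into a structure.

    Each bracket family is matched with its own stack.  ``length``, when
    given, is checked against the text length.
    """
    s = text.strip()
    if length is not None and len(s) != length:
        raise DotBracketError(
            f"dot-bracket length {len(s)} does not match expected length {length}"
        )
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s, start=1):
        if ch == ".":
            continue
        if ch in _OPEN_TO_FAMILY:
            stacks.setdefault(_OPEN_TO_FAMILY[ch], []).append(pos)
        elif ch in _CLOSE_TO_FAMILY:
            fam = _CLOSE_TO_FAMILY[ch]
            stack = stacks.get(fam, [])
            if not stack:
                o, c = FAMILIES[fam]
                raise DotBracketError(
                    f"unmatched closing {c!r} at position {pos}",
                    position=pos, family=o + c,
                )
            pairs.add((stack.pop(), pos))
        else:
            raise DotBracketError(
                f"illegal character {ch!r} at position {pos}", position=pos
            )
    for fam, stack in stacks.items():
        if stack:
            o, c = FAMILIES[fam]
            raise DotBracketError(
                f"unclosed {o!r} at position {stack[0]}",
                position=stack[0], family=o + c,
            )
    return SecondaryStructure(length=len(s), pairs=frozenset(pairs), label=label)


def write_dotbracket(structure: SecondaryStructure) -> str:
    """Serialize a structure to dot-bracket text.

    Pairs are processed in ascending ``i`` and placed greedily in the first
    bracket family where they cross no already-placed pair of that family, so
    non-crossing structures come out using ``()`` only.
    """
    layers: list[list[tuple[int, int]]] = []
    for pair in sorted(structure.pairs):
        for layer in layers:
            if not any(_crosses(pair, q) for q in layer):
                layer.append(pair)
                break
        else:
            if len(layers) >= len(FAMILIES):
                raise CapacityError(
                    f"structure needs more than {len(FAMILIES)} bracket families"
                )
            layers.append([pair])
    chars = ["."] * structure.length
    for fam, layer in enumerate(layers):
        o, c = FAMILIES[fam]
        for i, j in layer:
            chars[i - 1] = o
            chars[j - 1] = c
    return "".join(chars)


def consensus(
    structures, threshold: float = 0.5
) -> ConsensusStructure:
    """Base-pair consensus over two or more equal-length predictions.

    A pair is a candidate when its occurrence fraction is at least
    ``threshold`` (default 50%: "present in at least half").  Candidates that
    share a position are resolved by higher frequency, then smaller ``(i, j)``
    lexicographically, so the result is a valid structure.
    """
    structs = list(structures)
    if len(structs) < 2:
        raise InputCountError("consensus needs at least two input structures")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    length = structs[0].length
    for s in structs:
        if s.length != length:
            raise ReconciliationError(
                f"structure {s.label or '?'} has length {s.length}, expected {length}"
            )
    n = len(structs)
    counts: Counter[tuple[int, int]] = Counter()
    for s in structs:
        counts.update(s.pairs)
    # count/n >= threshold, robust to float representation of the ratio
    candidates = [
        (pair, cnt / n) for pair, cnt in counts.items() if cnt >= threshold * n - 1e-9
    ]
    candidates.sort(key=lambda pf: (-pf[1], pf[0]))
    used: set[int] = set()
    kept: dict[tuple[int, int], float] = {}
    for (i, j), freq in candidates:
        if i in used or j in used:
            continue
        kept[(i, j)] = freq
        used.update((i, j))
    structure = SecondaryStructure(
        length=length, pairs=frozenset(kept), label="consensus"
    )
    return ConsensusStructure(structure=structure, frequency=kept, n_inputs=n)
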