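"""Alphabets, symbol subsets and the tagged element alphabet.

An implied alignment works over an *extended* alphabet: every column element
produced while aligning along the guide tree is a nonempty subset of the base
alphabet together with a two-bit provenance tag recording whether the element
originated from both subtrees of a node (``BOTH``), only its left subtree
(``LEFT``), only its right subtree (``RIGHT``), or from elsewhere in the tree
(``GAPPED``).  Subsets are stored as integer bitmasks under the alphabet's
declared symbol order, so an element costs one machine word plus two tag bits
of information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "Alphabet",
    "TaggedElement",
    "Tag",
    "BOTH",
    "LEFT",
    "RIGHT",
    "GAPPED",
    "GAPPED_ELEMENT",
    "encode_tag",
    "decode_tag",
    "both",
    "left",
    "right",
]

# Provenance tags, deliberately small ints so a tag fits in two bits.
BOTH = 0
LEFT = 1
RIGHT = 2
GAPPED = 3

Tag = int

_TAG_NAMES = {BOTH: "BOTH", LEFT: "LEFT", RIGHT: "RIGHT", GAPPED: "GAPPED"}


def encode_tag(tag: Tag) -> int:
    """Return the 2-bit code of a tag (the identity on {0,1,2,3})."""
    if tag not in _TAG_NAMES:
        raise ValueError(f"not a tag: {tag!r}")
    return tag


def decode_tag(code: int) -> Tag:
    """Inverse of :func:`encode_tag`; rejects values outside two bits."""
    if code not in _TAG_NAMES:
        raise ValueError(f"tag code out of range [0,3]: {code!r}")
    return code


class TaggedElement(NamedTuple):
    """One element of the extended alphabet.

    ``first``/``second`` are symbol-subset bitmasks.  A ``BOTH`` element
    carries two payloads (first-argument side, second-argument side); ``LEFT``
    and ``RIGHT`` carry one payload in ``first``; ``GAPPED`` carries none.
    Unused payload slots are 0 (the empty mask, which is never a valid
    symbol subset).
    """

    tag: Tag
    first: int = 0
    second: int = 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        name = _TAG_NAMES[self.tag]
        if self.tag == BOTH:
            return f"{name}({self.first:#x},{self.second:#x})"
        if self.tag == GAPPED:
            return name
        return f"{name}({self.first:#x})"


GAPPED_ELEMENT = TaggedElement(GAPPED)


def both(first: int, second: int) -> TaggedElement:
    if first == 0 or second == 0:
        raise ValueError("BOTH payloads must be nonempty symbol sets")
    return TaggedElement(BOTH, first, second)


def left(payload: int) -> TaggedElement:
    if payload == 0:
        raise ValueError("LEFT payload must be a nonempty symbol set")
    return TaggedElement(LEFT, payload)


def right(payload: int) -> TaggedElement:
    if payload == 0:
        raise ValueError("RIGHT payload must be a nonempty symbol set")
    return TaggedElement(RIGHT, payload)


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol alphabet with a designated gap symbol.

    The symbol order is total and fixed: it defines bit positions of subset
    bitmasks and thereby every lexical comparison made downstream.  The gap
    symbol is an ordinary member of the alphabet (transition costs to and
    from it encode indel costs).  At least three symbols, gap included, are
    required.
    """

    symbols: tuple[str, ...]
    gap: str
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) < 3:
            raise ValueError(
                f"alphabet needs at least 3 symbols including the gap, "
                f"got {len(self.symbols)}"
            )
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")
        if self.gap not in self.symbols:
            raise ValueError(f"gap symbol {self.gap!r} not in alphabet")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None

    @property
    def gap_mask(self) -> int:
        return 1 << self._index[self.gap]

    @property
    def full_mask(self) -> int:
        return (1 << len(self.symbols)) - 1

    def mask(self, symbols: Iterable[str]) -> int:
        """Bitmask of a nonempty collection of symbols."""
        m = 0
        for s in symbols:
            m |= 1 << self.index(s)
        if m == 0:
            raise ValueError("symbol set must be nonempty")
        return m

    def unmask(self, mask: int) -> tuple[str, ...]:
        """Symbols of a bitmask, in alphabet order."""
        if mask <= 0 or mask > self.full_mask:
            raise ValueError(f"invalid symbol-set mask {mask!r}")
        return tuple(
            s for i, s in enumerate(self.symbols) if mask >> i & 1
        )

    def iter_subsets(self) -> Iterator[int]:
        """All nonempty subset bitmasks, in numeric (lexical) order."""
        return iter(range(1, self.full_mask + 1))


def tagged_space_size(alphabet_size: int) -> int:
    """Number of distinct tagged elements over an alphabet of given size.

    Counts (2^x - 1)^2 BOTH pairs, 2*(2^x - 1) LEFT/RIGHT elements and the
    single GAPPED element; the total collapses to 4^x.
    """
    p = (1 << alphabet_size) - 1
    return p * p + 2 * p + 1
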