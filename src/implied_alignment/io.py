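"""FASTA input/output and IUPAC ambiguity handling.

Sequences come in as plain FASTA; each residue is mapped to a nonempty
symbol subset of the alphabet.  On nucleotide-like alphabets the standard
IUPAC ambiguity codes expand to their symbol sets (R -> {A,G} and so on).
The gap character is rejected in input sequences by default — an unaligned
input should not contain alignment gaps — with options to strip gaps or to
admit the character as an ordinary residue when it is a genuine member of
the alphabet.
"""

from __future__ import annotations

from io import StringIO
from typing import Mapping, Sequence

from Bio import SeqIO

from .alphabet import Alphabet

__all__ = [
    "IUPAC_CODES",
    "parse_fasta",
    "write_fasta",
    "iupac_code_for",
]

#: IUPAC nucleotide ambiguity codes (gap excluded; U is not admitted).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE_BY_SET = {v: k for k, v in IUPAC_CODES.items()}


def _is_nucleotide(alphabet: Alphabet) -> bool:
    return {"A", "C", "G", "T"} <= set(alphabet.symbols)


def iupac_code_for(symbols: frozenset[str]) -> str | None:
    """IUPAC letter for a set of nucleotide symbols, if one exists."""
    if len(symbols) == 1:
        return next(iter(symbols))
    return _CODE_BY_SET.get(symbols)


def parse_fasta(
    text: str,
    alphabet: Alphabet,
    *,
    degap: bool = False,
    keep_gap_symbol: bool = False,
) -> dict[str, list[int]]:
    """Parse FASTA text into residue-set sequences keyed by header.

    Residues must be alphabet symbols or, on nucleotide alphabets, IUPAC
    ambiguity codes.  The alignment gap character is an error by default;
    ``degap=True`` strips it (for inputs cut out of an existing alignment)
    and ``keep_gap_symbol=True`` admits it as a literal residue when the
    alphabet treats it as an ordinary symbol.
    """
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise ValueError("empty FASTA input (no records)")
    nucleotide = _is_nucleotide(alphabet)
    out: dict[str, list[int]] = {}
    for rec in records:
        name = rec.id
        if name in out:
            raise ValueError(f"duplicate FASTA header: {name!r}")
        seq: list[int] = []
        for ch in str(rec.seq):
            c = ch.upper()
            if c == alphabet.gap:
                if degap:
                    continue
                if not keep_gap_symbol:
                    raise ValueError(
                        f"gap character {c!r} in sequence {name!r}; pass "
                        "degap=True to strip gaps or keep_gap_symbol=True "
                        "to treat it as a literal residue"
                    )
                seq.append(alphabet.gap_mask)
                continue
            if c in alphabet:
                seq.append(1 << alphabet.index(c))
            elif nucleotide and c in IUPAC_CODES:
                seq.append(alphabet.mask(IUPAC_CODES[c]))
            else:
                raise ValueError(
                    f"unknown residue {ch!r} in sequence {name!r} for "
                    f"alphabet {''.join(alphabet.symbols)!r}"
                )
        out[name] = seq
    return out


def write_fasta(
    rows: Mapping[str, str] | Sequence[tuple[str, str]], width: int = 70
) -> str:
    """Render named sequences as FASTA text with fixed line wrapping."""
    items = rows.items() if isinstance(rows, Mapping) else rows
    parts: list[str] = []
    for name, seq in items:
        parts.append(f">{name}")
        if seq:
            for i in range(0, len(seq), width):
                parts.append(seq[i : i + width])
        else:
            parts.append("")
    return "\n".join(parts) + "\n"
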