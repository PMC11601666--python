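"""Parsing of IEDB-style epitope names with modification annotations.

An epitope name is a plain peptide sequence of one-letter codes, optionally
followed by modification annotations in the ``SEQ + CODE(R#)`` notation, e.g.
``GILGFVFTL + OTH(L9)``: the text between the ``+`` and the parentheses is a
short uppercase modification code, and each ``R#`` inside the parentheses
names the modified residue (one-letter code) and its 1-based position from
the N-terminus.  Residues carrying a modification are non-canonical amino
acids (NCAAs) and are tokenized as ``<letter>-<CODE>``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Modification",
    "ModifiedPeptide",
    "NotationError",
    "parse_epitope_name",
    "render_epitope_name",
    "tokenize",
    "read_peptide_list",
]

CANONICAL_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: token grammar: a single canonical letter, or letter-CODE for an NCAA
TOKEN_RE = re.compile(r"^[A-Z](-[A-Z0-9]{2,6})?$")

_CODE_RE = re.compile(r"^[A-Z0-9]{2,6}$")
_SITE_RE = re.compile(r"^([A-Z])(\d+)$")
# one annotation group: CODE(site[, site...])
_GROUP_RE = re.compile(r"([A-Z0-9]{2,6})\s*\(([^()]*)\)")


class NotationError(ValueError):
    """Raised for malformed or inconsistent epitope-name notation."""


@dataclass(frozen=True)
class Modification:
    """A single residue modification: ``code`` applied to ``residue`` at ``position`` (1-based)."""

    code: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise NotationError(f"invalid modification code {self.code!r}")
        if self.residue not in CANONICAL_LETTERS:
            raise NotationError(f"invalid residue letter {self.residue!r}")
        if self.position < 1:
            raise NotationError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence together with its positional modifications."""

    base_sequence: str
    mods: tuple[Modification, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.base_sequence
        if not (8 <= len(seq) <= 11):
            raise NotationError(
                f"peptide length {len(seq)} outside supported range 8-11: {seq!r}"
            )
        bad = sorted(set(seq) - CANONICAL_LETTERS)
        if bad:
            raise NotationError(f"non-canonical letters {bad} in sequence {seq!r}")
        seen: set[int] = set()
        for m in self.mods:
            if m.position > len(seq):
                raise NotationError(
                    f"modification position {m.position} beyond sequence length {len(seq)}"
                )
            if seq[m.position - 1] != m.residue:
                raise NotationError(
                    f"modification {m.code}({m.residue}{m.position}) inconsistent: "
                    f"residue at position {m.position} is {seq[m.position - 1]!r}"
                )
            if m.position in seen:
                raise NotationError(
                    f"duplicate modification at position {m.position}"
                )
            seen.add(m.position)

    def __len__(self) -> int:
        return len(self.base_sequence)


def parse_epitope_name(name: str) -> ModifiedPeptide:
    """Parse an epitope name like ``"GILGFVFTL + OTH(L9)"`` into a :class:`ModifiedPeptide`.

    The part before the first ``+`` is the base sequence; each ``CODE(R#)``
    group after it becomes one :class:`Modification`.  Both the
    ``CODE1(R#), CODE2(R#)`` and the ``CODE(R#, R#)`` multi-modification
    shapes are accepted.  Whitespace around ``+``, ``,`` and parentheses is
    ignored.  Lowercase sequence letters are upcased with a warning.
    """
    if not isinstance(name, str) or not name.strip():
        raise NotationError("empty epitope name")
    text = name.strip()
    if "+" in text:
        seq_part, _, mod_part = text.partition("+")
    else:
        seq_part, mod_part = text, ""
    seq = seq_part.strip()
    if seq != seq.upper():
        warnings.warn(f"lowercase letters in sequence {seq!r} upcased", stacklevel=2)
        seq = seq.upper()

    mods: list[Modification] = []
    mod_part = mod_part.strip()
    if mod_part:
        consumed = []
        for match in _GROUP_RE.finditer(mod_part):
            consumed.append(match.span())
            code, inner = match.group(1), match.group(2)
            sites = [s.strip() for s in inner.split(",")]
            if not any(sites):
                raise NotationError(f"empty site list in {match.group(0)!r}")
            for site in sites:
                sm = _SITE_RE.match(site)
                if sm is None:
                    raise NotationError(
                        f"malformed modification site {site!r} in {name!r}"
                    )
                mods.append(Modification(code, sm.group(1), int(sm.group(2))))
        # everything between groups must be separators only
        leftover = _GROUP_RE.sub("", mod_part).replace(",", "").strip()
        if leftover or not consumed:
            raise NotationError(
                f"malformed modification annotation {mod_part!r} in {name!r}"
            )
    return ModifiedPeptide(seq, tuple(sorted(mods, key=lambda m: m.position)))


def render_epitope_name(peptide: ModifiedPeptide) -> str:
    """Render back to the ``SEQ + CODE(R#)`` notation (inverse of :func:`parse_epitope_name`)."""
    if not peptide.mods:
        return peptide.base_sequence
    groups = ", ".join(f"{m.code}({m.residue}{m.position})" for m in peptide.mods)
    return f"{peptide.base_sequence} + {groups}"


def tokenize(peptide: ModifiedPeptide) -> list[str]:
    """Emit one residue token per position, N to C terminus.

    Unmodified positions yield the single letter; modified positions yield
    ``<letter>-<CODE>``.  A token containing ``-`` therefore denotes an NCAA.
    """
    by_pos = {m.position: m for m in peptide.mods}
    out = []
    for i, letter in enumerate(peptide.base_sequence, start=1):
        m = by_pos.get(i)
        out.append(f"{letter}-{m.code}" if m else letter)
    return out


def is_ncaa_token(token: str) -> bool:
    return "-" in token


def read_peptide_list(path) -> list[ModifiedPeptide]:
    """Read a plain-text file of one epitope name per line (blank lines and ``#`` comments skipped)."""
    peptides = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                peptides.append(parse_epitope_name(line))
            except NotationError as exc:
                raise NotationError(f"{path}:{lineno}: {exc}") from exc
    return peptides
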