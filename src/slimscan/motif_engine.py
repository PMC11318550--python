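"""Motif compilation, proteome scanning and pattern probabilities.

A motif is a regular expression over the 20-letter amino-acid alphabet,
restricted to the subset that admits exact length bounds and an analytical
match probability: literals, character classes (including negation and
``A-Z`` ranges), ``.``, bounded quantifiers ``{m}`` / ``{m,n}`` / ``?``,
capturing groups and alternation.  Unbounded quantifiers, look-around and
back-references are rejected at compile time.

Patterns are parsed into a small AST from which we derive the capturing
group count, the minimum/maximum match length, the set of residues
admissible inside each group (used for PSSM score normalisation) and the
per-position probability that the pattern matches a random i.i.d. sequence
under a background residue distribution.  Scanning itself is delegated to
the stdlib ``re`` engine on a normalised form of the pattern in which ``.``
and negated classes are expanded to explicit 20-letter classes, so that
non-standard residues (X, U, B, Z) never satisfy an amino-acid class.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import Dataset

__all__ = [
    "AA_ALPHABET",
    "AA_INDEX",
    "BackgroundFrequencies",
    "MotifDefinition",
    "MotifMatch",
    "MotifSyntaxError",
    "compile_motif",
    "scan",
    "count_matches",
    "filter_identical",
    "pattern_probability",
    "load_motifs_tsv",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_AA_SET = frozenset(AA_ALPHABET)

# SwissProt-like average composition (alphabetical order), a standard
# reference table for vertebrate proteomes; normalised to sum to 1.
_SWISSPROT_FREQS = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0591, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


class MotifSyntaxError(ValueError):
    """Raised when a pattern uses a construct outside the supported subset."""


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Per-amino-acid probabilities over the 20-letter alphabet."""

    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.freqs) != 20:
            raise ValueError("need exactly 20 frequencies (alphabetical order)")
        if any(f < 0 for f in self.freqs):
            raise ValueError("frequencies must be non-negative")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 within 1e-9")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(tuple([1.0 / 20] * 20))

    @classmethod
    def swissprot(cls) -> "BackgroundFrequencies":
        total = sum(_SWISSPROT_FREQS.values())
        return cls(tuple(_SWISSPROT_FREQS[a] / total for a in AA_ALPHABET))

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "BackgroundFrequencies":
        return cls(tuple(mapping[a] for a in AA_ALPHABET))

    def of(self, residue: str) -> float:
        """Probability of one residue; 0 for non-standard letters."""
        idx = AA_INDEX.get(residue)
        return 0.0 if idx is None else self.freqs[idx]

    def class_prob(self, members: frozenset[str]) -> float:
        return sum(self.of(a) for a in members)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.freqs)


# --------------------------------------------------------------------------
# pattern AST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Atom:
    elem: object            # frozenset[str] (character class) or _Group
    min_rep: int = 1
    max_rep: int = 1


@dataclass(frozen=True)
class _Group:
    index: int              # 1-based capturing group number
    alt: tuple              # tuple of branches; branch = tuple[_Atom, ...]


class _Parser:
    """Recursive-descent parser for the supported regex subset."""

    def __init__(self, pattern: str) -> None:
        self.pattern = pattern
        self.pos = 0
        self.n_groups = 0

    def fail(self, message: str) -> None:
        raise MotifSyntaxError(
            f"pattern {self.pattern!r}, position {self.pos}: {message}")

    def peek(self) -> str | None:
        return self.pattern[self.pos] if self.pos < len(self.pattern) else None

    def parse(self) -> tuple:
        alt = self.parse_alt()
        if self.peek() == ")":
            self.fail("unbalanced ')'")
        if self.pos != len(self.pattern):
            self.fail(f"unexpected character {self.peek()!r}")
        return alt

    def parse_alt(self) -> tuple:
        branches = [self.parse_seq()]
        while self.peek() == "|":
            self.pos += 1
            branches.append(self.parse_seq())
        return tuple(branches)

    def parse_seq(self) -> tuple:
        atoms = []
        while True:
            ch = self.peek()
            if ch is None or ch in "|)":
                return tuple(atoms)
            atoms.append(self.parse_atom())

    def parse_atom(self) -> _Atom:
        elem = self.parse_element()
        return self.parse_quantifier(elem)

    def parse_element(self):
        ch = self.peek()
        if ch == "(":
            self.pos += 1
            if self.peek() == "?":
                self.fail("unsupported construct: '(?' extension (look-around / non-capturing)")
            self.n_groups += 1
            index = self.n_groups
            alt = self.parse_alt()
            if self.peek() != ")":
                self.fail("unbalanced '('")
            self.pos += 1
            return _Group(index, alt)
        if ch == "[":
            return self.parse_class()
        if ch == ".":
            self.pos += 1
            return _AA_SET
        if ch in "*+":
            self.fail(f"unsupported construct: unbounded quantifier {ch!r}")
        if ch == "\\":
            self.fail("unsupported construct: escape / back-reference '\\'")
        if ch in "^$":
            self.fail(f"unsupported construct: anchor {ch!r}")
        if ch in "?{}]":
            self.fail(f"unexpected character {ch!r}")
        self.pos += 1
        return frozenset(ch.upper())

    def parse_class(self) -> frozenset:
        assert self.peek() == "["
        self.pos += 1
        negated = self.peek() == "^"
        if negated:
            self.pos += 1
        members: set[str] = set()
        if self.peek() is None:
            self.fail("unterminated character class")
        while self.peek() != "]":
            ch = self.peek()
            if ch is None:
                self.fail("unterminated character class")
            if ch == "\\":
                self.fail("unsupported construct: escape inside character class")
            self.pos += 1
            if (self.peek() == "-" and self.pos + 1 < len(self.pattern)
                    and self.pattern[self.pos + 1] != "]"):
                self.pos += 1
                hi = self.pattern[self.pos]
                self.pos += 1
                if ord(hi) < ord(ch):
                    self.fail(f"invalid range {ch}-{hi}")
                members.update(chr(c) for c in range(ord(ch), ord(hi) + 1))
            else:
                members.add(ch.upper())
        self.pos += 1
        if negated:
            return _AA_SET - members
        return frozenset(members)

    def parse_quantifier(self, elem) -> _Atom:
        ch = self.peek()
        if ch == "?":
            self.pos += 1
            return _Atom(elem, 0, 1)
        if ch != "{":
            return _Atom(elem, 1, 1)
        end = self.pattern.find("}", self.pos)
        if end < 0:
            self.fail("unterminated '{' quantifier")
        body = self.pattern[self.pos + 1:end]
        self.pos = end + 1
        m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
        if not m:
            self.fail(f"unsupported quantifier {{{body}}} (only {{m}} and {{m,n}})")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            self.fail(f"quantifier {{{lo},{hi}}} has max < min")
        return _Atom(elem, lo, hi)


def _regex_of_alt(alt: tuple) -> str:
    return "|".join("".join(_regex_of_atom(a) for a in seq) for seq in alt)


def _regex_of_atom(atom: _Atom) -> str:
    elem = atom.elem
    if isinstance(elem, _Group):
        base = "(" + _regex_of_alt(elem.alt) + ")"
    else:
        members = sorted(elem)
        base = members[0] if len(members) == 1 else "[" + "".join(members) + "]"
    lo, hi = atom.min_rep, atom.max_rep
    if (lo, hi) == (1, 1):
        quant = ""
    elif (lo, hi) == (0, 1):
        quant = "?"
    elif lo == hi:
        quant = f"{{{lo}}}"
    else:
        quant = f"{{{lo},{hi}}}"
    return base + quant


def _len_bounds_alt(alt: tuple) -> tuple[int, int]:
    bounds = [_len_bounds_seq(seq) for seq in alt]
    return min(b[0] for b in bounds), max(b[1] for b in bounds)


def _len_bounds_seq(seq: tuple) -> tuple[int, int]:
    lo = hi = 0
    for atom in seq:
        if isinstance(atom.elem, _Group):
            elo, ehi = _len_bounds_alt(atom.elem.alt)
        else:
            elo = ehi = 1
        lo += elo * atom.min_rep
        hi += ehi * atom.max_rep
    return lo, hi


def _expansion_count_alt(alt: tuple) -> int:
    return sum(_expansion_count_seq(seq) for seq in alt)


def _expansion_count_seq(seq: tuple) -> int:
    total = 1
    for atom in seq:
        if isinstance(atom.elem, _Group):
            base = _expansion_count_alt(atom.elem.alt)
        else:
            base = 1
        total *= sum(base ** r for r in range(atom.min_rep, atom.max_rep + 1))
    return total


def _prob_alt(alt: tuple, bg: BackgroundFrequencies) -> float:
    return sum(_prob_seq(seq, bg) for seq in alt)


def _prob_seq(seq: tuple, bg: BackgroundFrequencies) -> float:
    total = 1.0
    for atom in seq:
        if isinstance(atom.elem, _Group):
            p = _prob_alt(atom.elem.alt, bg)
        else:
            p = bg.class_prob(atom.elem)
        total *= sum(p ** r for r in range(atom.min_rep, atom.max_rep + 1))
    return total


def _collect_group_residues(alt: tuple, out: dict[int, set[str]],
                            enclosing: list[int]) -> None:
    for seq in alt:
        for atom in seq:
            if isinstance(atom.elem, _Group):
                out.setdefault(atom.elem.index, set())
                enclosing.append(atom.elem.index)
                _collect_group_residues(atom.elem.alt, out, enclosing)
                enclosing.pop()
            else:
                for g in enclosing:
                    out.setdefault(g, set()).update(atom.elem & _AA_SET)


# --------------------------------------------------------------------------
# public types
# --------------------------------------------------------------------------

@dataclass
class MotifDefinition:
    """A named, compiled motif pattern.

    ``group_residues[g]`` is the set of standard residues that can occur
    inside capturing group ``g+1``; PSSM normalisation restricts column
    extrema to these sets so the 0-100 score range is attainable.
    """

    name: str
    pattern: str
    n_groups: int
    min_len: int
    max_len: int
    pssm: object | None = None
    probability: float | None = None
    group_residues: tuple[frozenset, ...] = ()
    _ast: tuple = field(default=(), repr=False)
    _compiled: object = field(default=None, repr=False)

    @property
    def compiled(self):
        return self._compiled


@dataclass
class MotifMatch:
    """One motif hit, with 1-based inclusive residue coordinates."""

    accession: str
    motif: str
    start: int
    end: int
    matched: str
    groups: tuple | None = None       # per-group matched text ('' if empty)
    group_spans: tuple | None = None  # per-group (start, end), 1-based incl.
    score: float | None = None
    flank_left: str = ""
    flank_right: str = ""
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.end - self.start + 1


def compile_motif(name: str, pattern: str) -> MotifDefinition:
    """Validate and compile a motif pattern.

    Rejects constructs outside the supported subset with an error naming
    the construct.  The compiled form normalises ``.`` and negated classes
    to explicit 20-letter classes so X/U/B/Z never satisfy them.
    """
    if not pattern:
        raise MotifSyntaxError("empty pattern")
    parser = _Parser(pattern)
    ast = parser.parse()
    min_len, max_len = _len_bounds_alt(ast)
    residues: dict[int, set[str]] = {}
    _collect_group_residues(ast, residues, [])
    group_residues = tuple(frozenset(residues.get(g, set()))
                           for g in range(1, parser.n_groups + 1))
    compiled = re.compile(_regex_of_alt(ast))
    return MotifDefinition(
        name=name, pattern=pattern, n_groups=parser.n_groups,
        min_len=min_len, max_len=max_len, group_residues=group_residues,
        _ast=ast, _compiled=compiled,
    )


# --------------------------------------------------------------------------
# scanning
# --------------------------------------------------------------------------

def _match_to_motifmatch(m: "re.Match", rec_accession: str, seq: str,
                         motif: MotifDefinition, flank_n: int) -> MotifMatch:
    start0, end0 = m.start(), m.end()
    groups = []
    spans = []
    for g in range(1, motif.n_groups + 1):
        gs, ge = m.span(g)
        if gs < 0:
            groups.append(None)
            spans.append(None)
        else:
            groups.append(m.group(g))
            spans.append((gs + 1, ge))  # empty participating group: end < start
    return MotifMatch(
        accession=rec_accession, motif=motif.name,
        start=start0 + 1, end=end0, matched=m.group(0),
        groups=tuple(groups), group_spans=tuple(spans),
        flank_left=seq[max(0, start0 - flank_n):start0],
        flank_right=seq[end0:end0 + flank_n],
    )


def scan(dataset: Dataset, motif: MotifDefinition, *, flank_n: int = 0,
         overlapping: bool = True, filter_identical_matches: bool = False,
         ) -> list[MotifMatch]:
    """Scan every record of a dataset for a motif.

    With ``overlapping=True`` a match attempt is made at every start
    position (leftmost-greedy per start); with ``overlapping=False``
    scanning resumes after each match end.  Matches come back in
    (record order, start) order.  Zero-width matches are never reported.
    """
    if flank_n < 0:
        raise ValueError("flank_n must be >= 0")
    rx = motif._compiled
    matches: list[MotifMatch] = []
    for rec in dataset:
        seq = rec.sequence
        pos = 0
        while pos <= len(seq):
            m = rx.search(seq, pos)
            if m is None:
                break
            if m.end() == m.start():
                pos = m.start() + 1
                continue
            matches.append(_match_to_motifmatch(m, rec.accession, seq, motif, flank_n))
            pos = m.start() + 1 if overlapping else m.end()
    if filter_identical_matches:
        matches = filter_identical(matches)
    return matches


def count_matches(dataset: Dataset, motif: MotifDefinition, *,
                  overlapping: bool = True) -> int:
    """Match count only — same semantics as :func:`scan`, no match objects."""
    rx = motif._compiled
    n = 0
    for rec in dataset:
        seq = rec.sequence
        pos = 0
        while pos <= len(seq):
            m = rx.search(seq, pos)
            if m is None:
                break
            if m.end() == m.start():
                pos = m.start() + 1
                continue
            n += 1
            pos = m.start() + 1 if overlapping else m.end()
    return n


def filter_identical(matches: Sequence[MotifMatch]) -> list[MotifMatch]:
    """Keep one match per distinct matched string.

    The survivor is the highest-scoring occurrence (unscored matches rank
    equal; ties keep the first in scan order); output preserves scan order
    of the survivors.
    """
    best: dict[str, tuple[int, MotifMatch]] = {}
    for i, m in enumerate(matches):
        key = m.matched
        score = m.score if m.score is not None else float("-inf")
        if key not in best:
            best[key] = (i, m)
        else:
            _, cur = best[key]
            cur_score = cur.score if cur.score is not None else float("-inf")
            if score > cur_score:
                best[key] = (i, m)
    return [m for _, m in sorted(best.values(), key=lambda t: t[0])]


def pattern_probability(motif: MotifDefinition,
                        background: BackgroundFrequencies | None = None,
                        *, max_expansions: int = 10 ** 6) -> float:
    """Analytical per-position probability of a pattern match.

    Sums, over every fixed-length expansion of the quantifiers and
    alternations, the product of the per-position class probabilities
    (a class probability being the summed background frequency of its
    members; ``.`` covers the whole alphabet and contributes 1).  The sum
    is taken without inclusion-exclusion, so for patterns whose expansions
    overlap it can exceed the true union probability (and even 1); a
    warning is emitted in that case.
    """
    if background is None:
        background = BackgroundFrequencies.uniform()
    n_exp = _expansion_count_alt(motif._ast)
    if n_exp > max_expansions:
        raise ValueError(
            f"pattern {motif.pattern!r} has {n_exp} expansions "
            f"(cap {max_expansions}); simplify the pattern")
    p = _prob_alt(motif._ast, background)
    if p > 1.0 + 1e-9:
        warnings.warn(
            f"pattern probability {p:.3g} exceeds 1: overlapping expansions "
            "are summed without inclusion-exclusion")
    return p


def load_motifs_tsv(path) -> list[MotifDefinition]:
    """Load motif definitions from a TSV with columns name, pattern
    and an optional PSSM file reference (resolved relative to the TSV)."""
    import os

    from .pssm import read_pssm

    motifs = []
    base = os.path.dirname(os.fspath(path))
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "name" and fields[1] == "pattern":
                continue
            motif = compile_motif(fields[0], fields[1])
            if len(fields) > 2 and fields[2]:
                motif.pssm = read_pssm(os.path.join(base, fields[2]))
            motifs.append(motif)
    return motifs
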