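"""Position-specific scoring matrices over regex capturing groups.

One PSSM column per capturing group.  Training counts residues observed
inside each group across a set of matching instances; residues in a
variable-length group are down-weighted by the group length in that
instance, so every instance contributes one unit of mass per column
("variable length motif regions" with length-invariant columns).  Counts
are Laplace-smoothed and converted to log-odds (bits) against a background
distribution.

Scoring averages column weights over the residues of each group and
min-max normalises the group sum to a 0-100 scale.  The normalisation
extrema are taken over the residues admissible under each group's
character class, so a consensus-of-consensus match scores exactly 100 and
the worst pattern-compatible match scores 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .motif_engine import (AA_ALPHABET, AA_INDEX, BackgroundFrequencies,
                           MotifDefinition, MotifMatch, compile_motif)

__all__ = ["PSSM", "train_pssm", "score_match", "score_matches",
           "write_pssm", "read_pssm", "PssmFormatError"]


class PssmFormatError(ValueError):
    """Raised for malformed PSSM files (names the offending row)."""


@dataclass
class PSSM:
    """Log-odds weight matrix, one column per capturing group.

    ``weights`` has shape (n_columns, 20) in alphabetical amino-acid order.
    ``s_min``/``s_max`` are the normalisation constants: the extreme raw
    scores attainable by pattern-compatible content (``group_residues``
    restricts each column's extrema to its character class).
    """

    weights: np.ndarray
    background: BackgroundFrequencies
    pseudocount: float
    s_min: float
    s_max: float
    pattern: str | None = None
    group_residues: tuple[frozenset, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 20:
            raise ValueError("weights must have shape (n_columns, 20)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not self.s_min < self.s_max:
            raise ValueError("s_min must be < s_max (degenerate score range)")

    @property
    def n_columns(self) -> int:
        return self.weights.shape[0]


def _score_extrema(weights: np.ndarray,
                   group_residues: Sequence[frozenset]) -> tuple[float, float]:
    """(s_min, s_max) over pattern-compatible residues, column by column."""
    s_min = 0.0
    s_max = 0.0
    for g in range(weights.shape[0]):
        permitted = group_residues[g] if g < len(group_residues) else frozenset()
        idx = [AA_INDEX[a] for a in sorted(permitted)] or list(range(20))
        col = weights[g, idx]
        s_min += float(col.min())
        s_max += float(col.max())
    return s_min, s_max


def train_pssm(instances: Sequence[str], motif: MotifDefinition,
               pseudocount: float = 1.0,
               background: BackgroundFrequencies | None = None) -> PSSM:
    """Train a PSSM from instances aligned by the motif's capturing groups.

    Every instance must fully match the motif pattern; a non-matching
    instance raises ``ValueError`` naming it.  For group g and amino acid
    a, the count c(g,a) sums 1/len(group) per residue, then
    f(g,a) = (c + k) / (sum_a c + 20 k) with pseudocount k, and
    w(g,a) = log2(f(g,a) / background(a)).
    """
    if not instances:
        raise ValueError("need at least one training instance")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if motif.n_groups == 0:
        raise ValueError("motif has no capturing groups to train on")
    if background is None:
        background = BackgroundFrequencies.uniform()
    counts = np.zeros((motif.n_groups, 20))
    rx = motif._compiled
    for inst in instances:
        m = rx.fullmatch(inst.upper())
        if m is None:
            raise ValueError(
                f"training instance {inst!r} does not match pattern {motif.pattern!r}")
        for g in range(1, motif.n_groups + 1):
            text = m.group(g)
            if not text:
                continue
            unit = 1.0 / len(text)
            for ch in text:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[g - 1, idx] += unit
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (totals + 20.0 * pseudocount)
    weights = np.log2(freqs / background.as_array()[None, :])
    s_min, s_max = _score_extrema(weights, motif.group_residues)
    return PSSM(weights=weights, background=background, pseudocount=pseudocount,
                s_min=s_min, s_max=s_max, pattern=motif.pattern,
                group_residues=motif.group_residues)


def score_match(pssm: PSSM, match: MotifMatch) -> float:
    """Normalised 0-100 score of one match.

    Raw score S sums, per group, the mean column weight of the group's
    residues (empty groups contribute 0; residues outside the 20-letter
    alphabet take the column minimum).  The result is
    100 * (S - s_min) / (s_max - s_min), clipped to [0, 100].
    """
    if match.groups is None:
        raise ValueError("match carries no group texts; rescan with the motif")
    if len(match.groups) != pssm.n_columns:
        raise ValueError(
            f"match has {len(match.groups)} groups but PSSM has "
            f"{pssm.n_columns} columns")
    raw = 0.0
    for g, text in enumerate(match.groups):
        if not text:
            continue
        col = pssm.weights[g]
        col_min = float(col.min())
        vals = [float(col[AA_INDEX[ch]]) if ch in AA_INDEX else col_min
                for ch in text]
        if len(vals) == 1:
            raw += vals[0]
        else:
            raw += sum(vals) / len(vals)
    score = 100.0 * (raw - pssm.s_min) / (pssm.s_max - pssm.s_min)
    return min(100.0, max(0.0, score))


def score_matches(pssm: PSSM, matches: Iterable[MotifMatch]) -> list[MotifMatch]:
    """Attach scores in place; returns the list for chaining."""
    matches = list(matches)
    for m in matches:
        m.score = score_match(pssm, m)
    return matches


def write_pssm(pssm: PSSM, path) -> None:
    """Write the plain-text PSSM format.

    '#' metadata lines (pattern, background, pseudocount, s_min, s_max),
    then one row per column with 20 tab-separated weights in alphabetical
    amino-acid order.  ``read_pssm(write_pssm(x))`` is the identity to 1e-9.
    """
    with open(path, "w") as out:
        if pssm.pattern:
            out.write(f"# pattern={pssm.pattern}\n")
        bg = ",".join(f"{a}:{f:.10g}" for a, f in
                      zip(AA_ALPHABET, pssm.background.freqs))
        out.write(f"# background={bg}\n")
        out.write(f"# pseudocount={pssm.pseudocount!r}\n")
        out.write(f"# s_min={pssm.s_min!r}\n")
        out.write(f"# s_max={pssm.s_max!r}\n")
        out.write(f"# columns={AA_ALPHABET}\n")
        for row in pssm.weights:
            out.write("\t".join(repr(float(w)) for w in row) + "\n")


def read_pssm(path) -> PSSM:
    """Read the plain-text PSSM format written by :func:`write_pssm`.

    Missing s_min/s_max are recomputed from the weights (restricted by the
    pattern's group classes when a pattern header is present) with a
    notice.  A weight row with other than 20 fields is a parse error
    naming the row.
    """
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) != 20:
                raise PssmFormatError(
                    f"{path}: line {lineno}: expected 20 weights, got {len(fields)}")
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise PssmFormatError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise PssmFormatError(f"{path}: no weight rows found (truncated file?)")
    weights = np.asarray(rows)
    if "background" in meta:
        bg_map = {}
        for item in meta["background"].split(","):
            aa, _, freq = item.partition(":")
            bg_map[aa.strip()] = float(freq)
        background = BackgroundFrequencies.from_dict(bg_map)
    else:
        background = BackgroundFrequencies.uniform()
    pseudocount = float(meta.get("pseudocount", 1.0))
    pattern = meta.get("pattern")
    group_residues: tuple[frozenset, ...] = ()
    if pattern:
        motif = compile_motif("pssm-pattern", pattern)
        if motif.n_groups != weights.shape[0]:
            raise PssmFormatError(
                f"{path}: pattern declares {motif.n_groups} groups but file "
                f"has {weights.shape[0]} weight rows")
        group_residues = motif.group_residues
    if "s_min" in meta and "s_max" in meta:
        s_min = float(meta["s_min"])
        s_max = float(meta["s_max"])
    else:
        s_min, s_max = _score_extrema(weights, group_residues)
        warnings.warn(f"{path}: s_min/s_max missing; recomputed from weights")
    return PSSM(weights=weights, background=background, pseudocount=pseudocount,
                s_min=s_min, s_max=s_max, pattern=pattern,
                group_residues=group_residues)
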