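"""PTM, disorder and feature annotation of motif matches.

Joins motif matches with experimental PTM site tables (PhosphoSitePlus
and dbPTM dialects), intrinsically-disordered-region and generic feature
intervals, and hits of an auxiliary motif in the same protein.  All
containment tests use 1-based inclusive coordinates: a site at the first
or last residue of a span is inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .motif_engine import MotifDefinition, MotifMatch, scan
from .sequence_io import Dataset

__all__ = [
    "PtmSite",
    "FeatureInterval",
    "load_ptm_psp",
    "load_ptm_dbptm",
    "load_features",
    "write_features",
    "annotate_ptm",
    "filter_without_connections",
    "annotate_idr",
    "annotate_features",
    "annotate_auxiliary",
]

# MOD_RSD suffix codes used by the PhosphoSitePlus site tables
_PSP_MOD_CODES = {
    "p": "phosphorylation",
    "ub": "ubiquitination",
    "ac": "acetylation",
    "me": "methylation",
    "m1": "methylation",
    "m2": "methylation",
    "m3": "methylation",
    "gl": "o-glcnac",
    "ga": "o-galnac",
    "sm": "sumoylation",
    "ne": "neddylation",
    "pa": "palmitoylation",
}

# Plausible acceptor residues per modification (used to flag suspicious
# database entries such as phosphorylation recorded on alanine).
_ACCEPTORS = {
    "phosphorylation": set("STYH"),
    "ubiquitination": set("KCST"),
    "acetylation": set("KSTM"),
    "methylation": set("KRQ"),
    "o-glcnac": set("ST"),
    "sumoylation": set("K"),
}


@dataclass
class PtmSite:
    """One experimentally observed modification site."""

    accession: str
    position: int           # 1-based residue index
    residue: str            # single letter ('' when unknown)
    modification: str       # controlled lower-case term
    source: str = "other"   # psp | dbptm | other
    ambiguous: bool = False
    flags: tuple = ()       # e.g. ("implausible_residue",), ("out_of_bounds",)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if len(self.residue) > 1:
            raise ValueError("residue must be a single letter or empty")


@dataclass
class FeatureInterval:
    """A positional annotation (Disordered, Domain, Region, ...)."""

    accession: str
    start: int
    end: int
    type: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start},{self.end}]")


def _find_psp_header(path) -> int:
    """Index of the PSP header row; leading non-tabular preamble tolerated."""
    with open(path) as handle:
        for i, line in enumerate(handle):
            if "\t" in line and "MOD_RSD" in line:
                return i
    raise ValueError(f"{path}: no header row with a MOD_RSD column found")


def load_ptm_psp(path, modification_filter: str | None = None,
                 drop_ambiguous: bool = True) -> list[PtmSite]:
    """Load a PhosphoSitePlus modification-site table.

    MOD_RSD entries of the form ``S25-p`` are decoded into residue,
    position and modification; rows flagged in the Ambiguous_Site column
    (mass-spectrometry peptides matching multiple proteins) are dropped by
    default.  Unparseable MOD_RSD rows are skipped with a counted warning.
    """
    header_row = _find_psp_header(path)
    table = pd.read_csv(path, sep="\t", skiprows=header_row, dtype=str)
    if "ACC_ID" not in table.columns:
        raise ValueError(f"{path}: missing required ACC_ID column")
    skipped = 0
    sites: list[PtmSite] = []
    for row in table.itertuples(index=False):
        mod_rsd = getattr(row, "MOD_RSD", None)
        if not isinstance(mod_rsd, str):
            skipped += 1
            continue
        core, _, code = mod_rsd.partition("-")
        modification = _PSP_MOD_CODES.get(code.strip().lower())
        if modification is None or len(core) < 2 or not core[1:].isdigit():
            skipped += 1
            continue
        ambiguous = str(getattr(row, "Ambiguous_Site", "0")).strip() in ("1", "1.0", "True")
        if drop_ambiguous and ambiguous:
            continue
        if modification_filter and modification != modification_filter.lower():
            continue
        sites.append(PtmSite(
            accession=row.ACC_ID, position=int(core[1:]), residue=core[0],
            modification=modification, source="psp", ambiguous=ambiguous))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} rows with unparseable MOD_RSD")
    return sites


_DBPTM_DEFAULT_COLUMNS = ["identifier", "accession", "position",
                          "modification", "evidence"]


def load_ptm_dbptm(path, validate_residue: bool = False,
                   proteome: Dataset | None = None, strict: bool = False,
                   column_names: Sequence[str] | None = None,
                   modification_filter: str | None = None) -> list[PtmSite]:
    """Load a dbPTM-style modification-site table (headerless TSV).

    With ``validate_residue`` and a proteome, sites whose residue is
    implausible for the modification (e.g. phosphorylation on alanine) or
    whose position exceeds the sequence length are flagged — and dropped
    only when ``strict`` is set.
    """
    names = list(column_names or _DBPTM_DEFAULT_COLUMNS)
    table = pd.read_csv(path, sep="\t", header=None, names=names,
                        comment="#", dtype=str)
    sites: list[PtmSite] = []
    skipped = 0
    for row in table.itertuples(index=False):
        try:
            position = int(row.position)
            modification = str(row.modification).strip().lower()
            accession = str(row.accession)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if position < 1 or not accession:
            skipped += 1
            continue
        if modification_filter and modification != modification_filter.lower():
            continue
        residue = ""
        flags: list[str] = []
        if validate_residue and proteome is not None:
            rec = proteome.get(accession)
            if rec is not None:
                if position > len(rec):
                    flags.append("out_of_bounds")
                else:
                    residue = rec.sequence[position - 1]
                    acceptors = _ACCEPTORS.get(modification)
                    if acceptors and residue not in acceptors:
                        flags.append("implausible_residue")
        if strict and flags:
            continue
        sites.append(PtmSite(accession=accession, position=position,
                             residue=residue, modification=modification,
                             source="dbptm", flags=tuple(flags)))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} unparseable rows")
    return sites


def load_features(path) -> list[FeatureInterval]:
    """Load a feature TSV: accession, start, end, type, description."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"accession", "start", "end", "type"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return [FeatureInterval(
                accession=row.accession, start=int(row.start), end=int(row.end),
                type=row.type,
                description=getattr(row, "description", None) or None)
            for row in table.itertuples(index=False)]


def write_features(features: Iterable[FeatureInterval], path) -> None:
    pd.DataFrame([{"accession": f.accession, "start": f.start, "end": f.end,
                   "type": f.type, "description": f.description or ""}
                  for f in features]).to_csv(path, sep="\t", index=False)


def _scope_span(match: MotifMatch, scope) -> tuple[int, int] | None:
    if scope == "whole_match":
        return match.start, match.end
    g = int(scope)
    if match.group_spans is None or not 1 <= g <= len(match.group_spans):
        raise ValueError(f"capturing group index {g} out of range")
    span = match.group_spans[g - 1]
    if span is None or span[1] < span[0]:
        return None
    return span


def annotate_ptm(matches: Sequence[MotifMatch], sites: Sequence[PtmSite],
                 modification_filter: str | None = None,
                 scope="whole_match") -> list[MotifMatch]:
    """Attach PTM sites lying inside each match's scope span.

    ``scope`` is ``"whole_match"`` or a 1-based capturing group index (for
    modified-residue motifs with a defined acceptor group).  Sets
    ``annotations["ptm_sites"]`` (list of sites), ``"ptm_connected"``
    (bool) and ``"ptm_count"``.
    """
    by_acc: dict[str, list[PtmSite]] = {}
    for site in sites:
        if modification_filter and site.modification != modification_filter.lower():
            continue
        by_acc.setdefault(site.accession, []).append(site)
    for m in matches:
        span = _scope_span(m, scope)
        hits = []
        if span is not None:
            lo, hi = span
            hits = [s for s in by_acc.get(m.accession, ())
                    if lo <= s.position <= hi]
        m.annotations["ptm_sites"] = hits
        m.annotations["ptm_connected"] = bool(hits)
        m.annotations["ptm_count"] = len(hits)
    return list(matches)


def filter_without_connections(matches: Sequence[MotifMatch]) -> list[MotifMatch]:
    """Keep only matches with at least one connected PTM site.

    Must run after :func:`annotate_ptm`; order is preserved.
    """
    for m in matches:
        if "ptm_connected" not in m.annotations:
            raise ValueError(
                "filter_without_connections requires annotate_ptm first")
    return [m for m in matches if m.annotations["ptm_connected"]]


def annotate_idr(matches: Sequence[MotifMatch],
                 features: Sequence[FeatureInterval],
                 idr_type: str = "Disordered") -> list[MotifMatch]:
    """Percentage of each match overlapping an intrinsically disordered
    region, reported to 0.1% as ``annotations["idr_overlap_percent"]``."""
    by_acc: dict[str, list[FeatureInterval]] = {}
    for feat in features:
        if feat.type == idr_type:
            by_acc.setdefault(feat.accession, []).append(feat)
    for m in matches:
        intervals = by_acc.get(m.accession, ())
        covered = 0
        for pos in range(m.start, m.end + 1):
            if any(f.start <= pos <= f.end for f in intervals):
                covered += 1
        m.annotations["idr_overlap_percent"] = round(100.0 * covered / len(m), 1)
    return list(matches)


def annotate_features(matches: Sequence[MotifMatch],
                      features: Sequence[FeatureInterval]) -> list[MotifMatch]:
    """List all feature intervals intersecting each match span, sorted by
    (start, type), as ``annotations["features"]``."""
    by_acc: dict[str, list[FeatureInterval]] = {}
    for feat in features:
        by_acc.setdefault(feat.accession, []).append(feat)
    for m in matches:
        hits = [f for f in by_acc.get(m.accession, ())
                if f.start <= m.end and f.end >= m.start]
        m.annotations["features"] = sorted(hits, key=lambda f: (f.start, f.type))
    return list(matches)


def annotate_auxiliary(primary_matches: Sequence[MotifMatch],
                       dataset: Dataset, aux_motif: MotifDefinition,
                       aux_threshold: float = 0.0,
                       keep_only_aux: bool = False) -> list[MotifMatch]:
    """Co-search an auxiliary motif and annotate primary matches.

    For every primary match, records whether its protein carries at least
    one auxiliary match with score >= ``aux_threshold`` (``aux_found``),
    the number of passing auxiliary matches (``aux_count``) and the best
    auxiliary score (``aux_best_score``).  With ``keep_only_aux`` only
    primaries whose protein has a passing auxiliary match are returned.
    """
    aux_matches = scan(dataset, aux_motif)
    if aux_threshold > 0:
        if aux_motif.pssm is None:
            raise ValueError(
                "aux_threshold > 0 requires a PSSM on the auxiliary motif")
        from .pssm import score_matches
        score_matches(aux_motif.pssm, aux_matches)
    by_acc: dict[str, list[MotifMatch]] = {}
    for am in aux_matches:
        by_acc.setdefault(am.accession, []).append(am)
    out = []
    for m in primary_matches:
        aux = by_acc.get(m.accession, [])
        if aux_threshold > 0:
            passing = [a for a in aux if a.score is not None and a.score >= aux_threshold]
            best = max((a.score for a in aux), default=None)
        else:
            passing = aux
            best = max((a.score for a in aux if a.score is not None), default=None)
        m.annotations["aux_found"] = bool(passing)
        m.annotations["aux_count"] = len(passing)
        m.annotations["aux_best_score"] = best
        if not keep_only_aux or passing:
            out.append(m)
    return out
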