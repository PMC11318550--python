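"""Protein sequence and identifier I/O.

Reads and writes FASTA datasets, resolves accession / gene-symbol lists
against a locally loaded proteome, and exports motif-match and enrichment
results as FASTA or TSV.  All coordinates written to disk are 1-based
inclusive, matching UniProt conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .enrichment import EnrichmentRecord
    from .motif_engine import MotifMatch

__all__ = [
    "ProteinRecord",
    "Dataset",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_id_list",
    "resolve_identifiers",
    "write_matches_fasta",
    "write_matches_tsv",
    "write_enrichment_tsv",
    "write_results_tsv",
    "read_matches_tsv",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (names the offending line)."""


@dataclass
class ProteinRecord:
    """One protein: accession, optional gene symbol, amino-acid sequence.

    ``sequence`` is stored upper-case.  Non-standard residues (X, U, B, Z)
    are retained but never match any amino-acid class during scanning.
    """

    accession: str
    sequence: str
    gene: str | None = None
    description: str | None = None
    raw_header: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of :class:`ProteinRecord`.

    ``total_aa`` (the summed residue count) is the denominator used when
    match counts are normalised to database length in amino acids.
    """

    records: list[ProteinRecord] = field(default_factory=list)
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.accession] = counts.get(r.accession, 0) + 1
        dups = sorted(a for a, c in counts.items() if c > 1)
        if dups:
            raise ValueError(f"duplicate accessions in dataset: {', '.join(dups)}")
        self._index = {r.accession: r for r in self.records}

    @property
    def total_aa(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def get(self, accession: str) -> ProteinRecord | None:
        return self._index.get(accession)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    """Extract (accession, gene, description) from a FASTA header line.

    Supports the UniProt ``db|ACC|NAME desc GN=GENE`` convention; otherwise
    the first whitespace-delimited token is the accession.
    """
    token, _, rest = header.partition(" ")
    parts = token.split("|")
    accession = parts[1] if len(parts) >= 3 and parts[1] else token
    gene = None
    for word in rest.split():
        if word.startswith("GN="):
            gene = word[3:]
            break
    return accession, gene, (rest or None)


def read_fasta(path, name: str | None = None) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Raises :class:`FastaParseError` when sequence data precedes the first
    ``>`` header (naming the line) or when accessions are duplicated.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
    records = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            accession, gene, description = _parse_header(header)
            seq = seq.replace(" ", "").upper()
            if not seq:
                raise FastaParseError(f"{path}: record '{accession}' has an empty sequence")
            records.append(ProteinRecord(accession, seq, gene=gene,
                                         description=description, raw_header=header))
    return Dataset(records, name=name or str(path))


def write_fasta(dataset: Dataset, path, line_width: int = 60) -> None:
    """Write a dataset back to FASTA, preserving raw headers when known."""
    with open(path, "w") as out:
        for rec in dataset:
            header = rec.raw_header
            if header is None:
                header = rec.accession
                if rec.description:
                    header += f" {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                out.write(rec.sequence[i:i + line_width] + "\n")


def read_id_list(path) -> list[str]:
    """Read a plain-text identifier list (one per line, '#' comments ignored)."""
    ids = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def resolve_identifiers(
    ids: Sequence[str], proteome: Dataset
) -> tuple[Dataset, list[str]]:
    """Resolve accessions / gene symbols against a local proteome copy.

    Accession matching is exact; gene-symbol matching is case-insensitive.
    Isoform accessions (``P04637-2``) fall back to the base accession with a
    warning when the exact isoform is absent.  Every input id ends up either
    matched or in ``missing`` (duplicates collapsed, order preserved).
    """
    gene_index: dict[str, ProteinRecord] = {}
    for rec in proteome:
        if rec.gene and rec.gene.casefold() not in gene_index:
            gene_index[rec.gene.casefold()] = rec
    seen_ids: set[str] = set()
    hit_accessions: set[str] = set()
    hits: list[ProteinRecord] = []
    missing: list[str] = []
    for ident in ids:
        if ident in seen_ids:
            continue
        seen_ids.add(ident)
        rec = proteome.get(ident)
        if rec is None and "-" in ident:
            base = ident.rsplit("-", 1)[0]
            rec = proteome.get(base)
            if rec is not None:
                warnings.warn(
                    f"isoform accession {ident!r} not found; using base accession {base!r}"
                )
        if rec is None:
            rec = gene_index.get(ident.casefold())
        if rec is None:
            missing.append(ident)
        elif rec.accession not in hit_accessions:
            hit_accessions.add(rec.accession)
            hits.append(rec)
    return Dataset(hits, name=f"{proteome.name}:subset"), missing


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "NA"
    return f"{score:.2f}"


def write_matches_fasta(matches: Iterable["MotifMatch"], path) -> None:
    """Export matched substrings (without flanks) as FASTA.

    Header layout: ``>ACCESSION_start-end motif=NAME score=S`` with
    1-based inclusive coordinates.  The layout is a tool convention; the
    first token stays unique and free of ``|`` so the file re-reads
    cleanly as plain FASTA.
    """
    with open(path, "w") as out:
        for m in matches:
            out.write(f">{m.accession}_{m.start}-{m.end} "
                      f"motif={m.motif} score={_fmt_score(m.score)}\n")
            out.write(m.matched + "\n")


_MATCH_COLUMNS = ["accession", "motif", "start", "end", "matched", "score",
                  "flank_left", "flank_right"]


def _metadata_lines(metadata: dict | None) -> list[str]:
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_matches_tsv(matches: Iterable["MotifMatch"], path,
                      metadata: dict | None = None) -> None:
    """Write match rows as TSV with a '#'-prefixed metadata preamble.

    Fixed columns first, then any annotation keys present on the matches,
    in sorted order.
    """
    matches = list(matches)
    ann_keys = sorted({k for m in matches for k in m.annotations
                       if not isinstance(m.annotations[k], (list, dict))})
    with open(path, "w") as out:
        for line in _metadata_lines(metadata):
            out.write(line + "\n")
        out.write("\t".join(_MATCH_COLUMNS + ann_keys) + "\n")
        for m in matches:
            row = [m.accession, m.motif, str(m.start), str(m.end), m.matched,
                   _fmt_score(m.score), m.flank_left, m.flank_right]
            row += [str(m.annotations.get(k, "")) for k in ann_keys]
            out.write("\t".join(row) + "\n")


_ENRICHMENT_COLUMNS = ["motif", "n_target", "n_decoy", "ratio", "log2_ratio",
                       "p", "q", "class"]


def write_enrichment_tsv(records: Iterable["EnrichmentRecord"], path,
                         metadata: dict | None = None) -> None:
    """Write per-motif enrichment rows as TSV (volcano-plot-ready)."""
    with open(path, "w") as out:
        for line in _metadata_lines(metadata):
            out.write(line + "\n")
        out.write("\t".join(_ENRICHMENT_COLUMNS) + "\n")
        for r in records:
            log2r = r.log2_ratio
            out.write("\t".join([
                r.motif, str(r.n_target), str(r.n_decoy),
                f"{r.ratio:.6g}",
                "-inf" if math.isinf(log2r) and log2r < 0 else f"{log2r:.6g}",
                f"{r.p_value:.6g}", f"{r.q_value:.6g}", r.classification,
            ]) + "\n")


def write_results_tsv(items, path, metadata: dict | None = None) -> None:
    """Dispatch to the match or enrichment TSV writer based on row type."""
    items = list(items)
    if items and hasattr(items[0], "classification"):
        write_enrichment_tsv(items, path, metadata)
    else:
        write_matches_tsv(items, path, metadata)


def read_matches_tsv(path) -> list["MotifMatch"]:
    """Read a match TSV written by :func:`write_matches_tsv`.

    Group-level information (group texts and spans) is not serialised and
    comes back as ``None``; scores and the fixed columns round-trip.
    """
    from .motif_engine import MotifMatch

    matches = []
    with open(path) as handle:
        header = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            score = None if row["score"] in ("", "NA") else float(row["score"])
            ann = {k: row[k] for k in header if k not in _MATCH_COLUMNS}
            matches.append(MotifMatch(
                accession=row["accession"], motif=row["motif"],
                start=int(row["start"]), end=int(row["end"]),
                matched=row["matched"], groups=None, group_spans=None,
                score=score, flank_left=row["flank_left"],
                flank_right=row["flank_right"], annotations=ann,
            ))
    return matches
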