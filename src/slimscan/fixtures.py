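"""Synthetic proteomes, planted motifs, PTM tables and IDR annotations.

Everything here is generated data with controlled statistical structure:
i.i.d. sequences from a chosen residue composition (uniform or a
SwissProt-like table), motif instances planted at known positions with a
truth table, modification sites placed on planted acceptor residues with
configurable coverage and spurious-site noise, and disordered-region
intervals covering a target fraction of residues.  All outputs are
byte-reproducible under a fixed seed and parse through the corresponding
loaders of the I/O and annotation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureInterval
from .motif_engine import AA_ALPHABET, BackgroundFrequencies
from .sequence_io import Dataset, ProteinRecord

__all__ = [
    "FixtureSpec",
    "synth_proteome",
    "plant_motifs",
    "categorical_instance_sampler",
    "synth_ptm_table",
    "write_psp_table",
    "write_dbptm_table",
    "synth_idr_annotations",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic proteome.

    ``length`` is a fixed integer or an inclusive (min, max) range drawn
    uniformly per protein.  The mandatory seed makes every derived file
    reproducible.
    """

    n_proteins: int
    length: int | tuple[int, int]
    seed: int
    composition: BackgroundFrequencies = field(
        default_factory=BackgroundFrequencies.uniform)
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = (self.length, self.length) if isinstance(self.length, int) \
            else self.length
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length distribution {self.length!r}")


def synth_proteome(spec: FixtureSpec) -> Dataset:
    """Generate i.i.d. sequences from the composition, each starting 'M'.

    Accessions run SYN00001, SYN00002, ...
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)
    probs = spec.composition.as_array()
    lo, hi = (spec.length, spec.length) if isinstance(spec.length, int) \
        else spec.length
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        body = rng.choice(alphabet, size=length - 1, p=probs)
        seq = "M" + body.tobytes().decode("ascii")
        records.append(ProteinRecord(accession=f"SYN{i + 1:05d}", sequence=seq))
    return Dataset(records, name=spec.name,
                   metadata={"seed": spec.seed, "n_proteins": spec.n_proteins})


def categorical_instance_sampler(
    columns: Sequence[tuple[str, Sequence[float]]],
) -> Callable[[np.random.Generator], str]:
    """Sampler drawing each position independently from a categorical
    distribution ``(residues, probabilities)`` — one tuple per position."""
    parsed = []
    for residues, probs in columns:
        probs = np.asarray(probs, dtype=float)
        if len(residues) != len(probs):
            raise ValueError("residues and probabilities differ in length")
        parsed.append((list(residues), probs / probs.sum()))

    def sample(rng: np.random.Generator) -> str:
        return "".join(residues[rng.choice(len(residues), p=probs)]
                       for residues, probs in parsed)

    return sample


def plant_motifs(dataset: Dataset, sampler: Callable[[np.random.Generator], str],
                 fraction: float, seed: int,
                 acceptor_offset: int | None = None,
                 ) -> tuple[Dataset, pd.DataFrame]:
    """Overwrite one sampled instance into round(fraction * n) proteins.

    The planted span is uniform over positions 2..L-len+1 (never covering
    the initial residue).  Returns the modified dataset and a truth table
    with accession, start, end, sequence and — when ``acceptor_offset``
    (0-based offset within the instance) is given — the acceptor position.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_plant = round(fraction * len(dataset))
    chosen = sorted(rng.choice(len(dataset), size=n_plant, replace=False))
    rows = []
    records = list(dataset.records)
    for idx in chosen:
        rec = records[idx]
        instance = sampler(rng)
        if len(instance) > len(rec) - 1:
            raise ValueError(
                f"{rec.accession}: no room to plant a {len(instance)}-mer "
                f"in a {len(rec)}-residue sequence")
        start0 = int(rng.integers(1, len(rec) - len(instance) + 1))
        seq = rec.sequence[:start0] + instance + rec.sequence[start0 + len(instance):]
        records[idx] = ProteinRecord(accession=rec.accession, sequence=seq,
                                     gene=rec.gene, description=rec.description)
        row = {"accession": rec.accession, "start": start0 + 1,
               "end": start0 + len(instance), "sequence": instance}
        if acceptor_offset is not None:
            row["acceptor_pos"] = start0 + 1 + acceptor_offset
        rows.append(row)
    truth = pd.DataFrame(rows, columns=["accession", "start", "end", "sequence"]
                         + (["acceptor_pos"] if acceptor_offset is not None else []))
    planted = Dataset(records, name=dataset.name,
                      metadata={**dataset.metadata, "planted_seed": seed,
                                "planted_fraction": fraction})
    return planted, truth


def synth_ptm_table(truth: pd.DataFrame, dataset: Dataset, coverage: float,
                    noise: float, seed: int,
                    modification: str = "phosphorylation") -> pd.DataFrame:
    """Synthetic modification sites keyed to planted instances.

    Each planted acceptor position (truth['acceptor_pos']) receives a site
    with probability ``coverage``; each protein additionally receives
    Poisson(``noise``) spurious sites at random positions.  Returns a
    tidy table (accession, position, residue, modification) writable in
    either dialect.
    """
    if "acceptor_pos" not in truth.columns and len(truth):
        raise ValueError("truth table lacks an acceptor_pos column")
    rng = np.random.default_rng(seed)
    rows = []
    for row in truth.itertuples(index=False):
        if rng.random() < coverage:
            rec = dataset[row.accession]
            pos = int(row.acceptor_pos)
            rows.append({"accession": row.accession, "position": pos,
                         "residue": rec.sequence[pos - 1],
                         "modification": modification})
    if noise > 0:
        for rec in dataset:
            for _ in range(rng.poisson(noise)):
                pos = int(rng.integers(1, len(rec) + 1))
                rows.append({"accession": rec.accession, "position": pos,
                             "residue": rec.sequence[pos - 1],
                             "modification": modification})
    return pd.DataFrame(rows, columns=["accession", "position", "residue",
                                       "modification"])


_MOD_TO_PSP_CODE = {"phosphorylation": "p", "ubiquitination": "ub",
                    "acetylation": "ac", "methylation": "me",
                    "o-glcnac": "gl", "sumoylation": "sm"}


def write_psp_table(sites: pd.DataFrame, path) -> None:
    """Write sites in the PhosphoSitePlus dialect (with a preamble line)."""
    with open(path, "w") as out:
        out.write("synthetic modification-site table\n")
        out.write("\n")
        out.write("GENE\tACC_ID\tMOD_RSD\tAmbiguous_Site\n")
        for row in sites.itertuples(index=False):
            code = _MOD_TO_PSP_CODE[row.modification.lower()]
            out.write(f"{row.accession}\t{row.accession}\t"
                      f"{row.residue}{row.position}-{code}\t0\n")


def write_dbptm_table(sites: pd.DataFrame, path) -> None:
    """Write sites in the dbPTM dialect (headerless TSV)."""
    with open(path, "w") as out:
        for row in sites.itertuples(index=False):
            out.write(f"{row.accession}_SYN\t{row.accession}\t{row.position}\t"
                      f"{row.modification.capitalize()}\tsynthetic\n")


def synth_idr_annotations(dataset: Dataset, fraction: float, seed: int,
                          mean_len: int = 40) -> list[FeatureInterval]:
    """Non-overlapping Disordered intervals covering ~``fraction`` of
    residues per protein."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    features: list[FeatureInterval] = []
    for rec in dataset:
        target = fraction * len(rec)
        covered = 0
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while covered < target and attempts < 200:
            attempts += 1
            length = max(5, int(rng.poisson(mean_len)))
            if length >= len(rec):
                length = len(rec)
                start = 1
            else:
                start = int(rng.integers(1, len(rec) - length + 2))
            end = start + length - 1
            if any(s <= end and e >= start for s, e in occupied):
                continue
            occupied.append((start, end))
            covered += length
            features.append(FeatureInterval(accession=rec.accession,
                                            start=start, end=end,
                                            type="Disordered"))
    features.sort(key=lambda f: (f.accession, f.start))
    return features
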