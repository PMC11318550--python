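"""Shared fixtures: a kinase-substrate-style 7-group motif, a peaked
instance sampler for it, and a random generator for patterns in the
supported regex subset."""

from __future__ import annotations

import numpy as np
import pytest

from slimscan import (BackgroundFrequencies, Dataset, ProteinRecord,
                      categorical_instance_sampler, compile_motif)
from slimscan.motif_engine import AA_ALPHABET

# A 7-position phospho-acceptor motif with one PSSM column per position:
# two free positions, an exclusion class, the S/T acceptor, two bulky
# hydrophobics and one free position.
KINASE_PATTERN = "(.)(.)([^IRFW])([ST])([ILMVFWY])([ILMVFWY])(.)"
KINASE_ACCEPTOR_GROUP = 4          # the [ST] capturing group
KINASE_ACCEPTOR_OFFSET = 3         # 0-based offset within a 7-mer instance

# Peaked per-position distributions over class-compatible residues, used to
# sample consensus-like instances of the motif above.
KINASE_COLUMNS = [
    ("KRAS", (0.7, 0.1, 0.1, 0.1)),
    ("KEAG", (0.7, 0.1, 0.1, 0.1)),
    ("DENQ", (0.7, 0.1, 0.1, 0.1)),
    ("ST", (0.8, 0.2)),
    ("LIVM", (0.7, 0.1, 0.1, 0.1)),
    ("LFVM", (0.7, 0.1, 0.1, 0.1)),
    ("EDKR", (0.25, 0.25, 0.25, 0.25)),
]


@pytest.fixture
def kinase_motif():
    return compile_motif("kinase7", KINASE_PATTERN)


@pytest.fixture
def kinase_sampler():
    return categorical_instance_sampler(KINASE_COLUMNS)


@pytest.fixture
def tiny_proteome():
    return Dataset([
        ProteinRecord("P04637", "MEEPQSDPSV", gene="TP53",
                      raw_header="sp|P04637|P53_HUMAN Cellular tumor antigen p53 GN=TP53"),
        ProteinRecord("Q00001", "MAAASTLLAKRKR", gene="DEMO1"),
        ProteinRecord("Q00002", "MSTSTSTST", gene="DEMO2"),
    ], name="tiny")


def random_supported_pattern(rng: np.random.Generator) -> str:
    """A random pattern from the supported subset (classes, negation, '.',
    literals, '?', bounded quantifiers, capturing groups)."""
    n_atoms = int(rng.integers(2, 6))
    parts = []
    for _ in range(n_atoms):
        kind = int(rng.integers(0, 4))
        if kind == 0:
            elem = AA_ALPHABET[rng.integers(0, 20)]
        elif kind == 1:
            k = int(rng.integers(2, 7))
            members = rng.choice(list(AA_ALPHABET), size=k, replace=False)
            elem = "[" + "".join(sorted(members)) + "]"
        elif kind == 2:
            k = int(rng.integers(1, 5))
            members = rng.choice(list(AA_ALPHABET), size=k, replace=False)
            elem = "[^" + "".join(sorted(members)) + "]"
        else:
            elem = "."
        if rng.random() < 0.3:
            elem = "(" + elem + ")"
        r = rng.random()
        if r < 0.10:
            elem += "?"
        elif r < 0.20:
            elem += "{1,2}"
        elif r < 0.25:
            elem += "{2}"
        parts.append(elem)
    return "".join(parts)


def random_sequence(rng: np.random.Generator, length: int,
                    background: BackgroundFrequencies | None = None) -> str:
    bg = background or BackgroundFrequencies.uniform()
    letters = rng.choice(list(AA_ALPHABET), size=length, p=bg.as_array())
    return "".join(letters)
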