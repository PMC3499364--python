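"""Shared record types, exceptions and small I/O helpers."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("duoproteome")


class DuoproteomeError(Exception):
    """Base class for package errors."""


class ConfigError(DuoproteomeError):
    """Invalid configuration values."""


class InputError(DuoproteomeError):
    """Invalid or inconsistent input data."""


class ParseError(DuoproteomeError):
    """Malformed input file."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with its species and gene id."""

    gene_id: str
    species: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein or nucleotide FASTA into ProteinRecords.

    ``species`` tags every record; sequence is upper-cased.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, species, str(rec.seq).upper()))
    if not records:
        raise InputError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord] | Sequence[tuple[str, str]],
                path: str | Path) -> None:
    """Write records (ProteinRecord or (id, seq) tuples) as wrapped FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            seqrecs.append(SeqRecord(Seq(rec.seq), id=rec.gene_id, description=""))
        else:
            name, seq = rec
            seqrecs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a single user seed out into ``n`` independent 31-bit stage seeds.

    Uses numpy's SeedSequence spawning so stages are statistically
    independent and the derivation is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint32)[0] % (2**31)) for child in ss.spawn(n)]
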