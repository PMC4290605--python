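"""Lysine-centered sequence windows and the consensus-motif baseline.

Sumoylation attaches a SUMO protein to a lysine residue, most often inside
the canonical context PsiKxE/D: a large aliphatic hydrophobic residue (Psi),
the modified lysine, any residue, then glutamate or aspartate. This module
extracts the 7-residue window around every lysine of a protein (three
upstream slots ``w-_1..3`` and three downstream slots ``w+_1..3``, with
``w-_3`` and ``w+_1`` adjacent to the central K), decides consensus status,
and provides the regular-expression baseline scanner ``[IVLMAP]K.[DE]``.

Coordinates are 1-based in all files and public interfaces.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Large aliphatic hydrophobic residues accepted at the Psi position.
PSI_RESIDUES = frozenset("IVLMAP")
#: Acidic residues accepted two positions downstream of the lysine.
ACIDIC_RESIDUES = frozenset("DE")
#: The consensus-motif pattern; the lookahead lets overlapping contexts all match.
CONSENSUS_PATTERN = re.compile(r"(?=[IVLMAP]K.[DE])")

#: Placeholder stored in window slots that fall beyond the protein termini.
PAD = "-"

#: Flank width on each side of the central lysine (w_n upstream, w_c downstream).
UPSTREAM_SLOTS = 3
DOWNSTREAM_SLOTS = 3

VALID_LABELS = ("positive", "negative", "unknown")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA entries (empty sequence, missing header)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    The sequence is upper-case; the 20 standard residues plus ambiguity
    codes (X, B, Z, U, ...) are accepted. Ambiguity codes never satisfy any
    character class downstream.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise FastaFormatError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position, or the pad placeholder outside [1, L]."""
        if 1 <= position <= self.length:
            return self.sequence[position - 1]
        return PAD


@dataclass(frozen=True)
class SiteWindow:
    """A 7-residue window centered on a lysine.

    ``upstream`` holds slots (w-_1, w-_2, w-_3) in N→C order, so the last
    element is adjacent to the central K; ``downstream`` holds
    (w+_1, w+_2, w+_3) with the first element adjacent to K. Slots beyond
    the protein termini hold the pad placeholder.
    """

    protein_id: str
    position: int  # 1-based index of the central lysine
    upstream: tuple[str, str, str]
    downstream: tuple[str, str, str]
    label: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.upstream) != UPSTREAM_SLOTS or len(self.downstream) != DOWNSTREAM_SLOTS:
            raise ValueError("windows carry exactly 3 upstream and 3 downstream slots")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def pad_mask(self) -> tuple[bool, ...]:
        """Per-slot padding flags, ordered (w-_1, w-_2, w-_3, w+_1, w+_2, w+_3)."""
        return tuple(s == PAD for s in self.upstream + self.downstream)

    def slot(self, name: str) -> str:
        """Residue in a named slot, e.g. ``w-_3`` or ``w+_2``."""
        side, idx = name.split("_")
        i = int(idx) - 1
        if side == "w-":
            return self.upstream[i]
        if side == "w+":
            return self.downstream[i]
        raise KeyError(name)


@dataclass(frozen=True)
class ConsensusStatus:
    """Whether a window matches the PsiKxE/D consensus motif."""

    is_consensus: bool


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated and sequences upper-cased; the
    record id is the first whitespace-delimited token of the header. An
    empty file yields an empty list with a logged warning.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise FastaFormatError(f"{path}: entry with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {entry.id!r} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def window_at(protein: ProteinRecord, position: int, label: str = "unknown") -> SiteWindow:
    """Build the 7-residue window around a lysine at a 1-based position."""
    if protein.residue(position) != "K":
        raise ValueError(
            f"protein {protein.id!r} position {position}: central residue is "
            f"{protein.residue(position)!r}, expected 'K'"
        )
    upstream = tuple(protein.residue(position - d) for d in (3, 2, 1))
    downstream = tuple(protein.residue(position + d) for d in (1, 2, 3))
    return SiteWindow(protein.id, position, upstream, downstream, label)


def extract_lysine_windows(protein: ProteinRecord) -> list[SiteWindow]:
    """One window per lysine, ordered by position; terminal lysines are padded."""
    return [
        window_at(protein, i + 1)
        for i, residue in enumerate(protein.sequence)
        if residue == "K"
    ]


def consensus_status(window: SiteWindow) -> ConsensusStatus:
    """Consensus iff w-_3 is a Psi residue and w+_2 is D or E (neither padded)."""
    return ConsensusStatus(
        window.slot("w-_3") in PSI_RESIDUES and window.slot("w+_2") in ACIDIC_RESIDUES
    )


def scan_regex(protein: ProteinRecord) -> list[int]:
    """1-based positions of lysines matching ``[IVLMAP]K.[DE]``.

    Each lysine is judged on its own 4-mer context, so overlapping motifs
    are all reported.
    """
    return [m.start() + 2 for m in CONSENSUS_PATTERN.finditer(protein.sequence)]


# ---------------------------------------------------------------------------
# Site-label TSV: protein_id <tab> position (1-based) <tab> label
# ---------------------------------------------------------------------------

def read_site_labels(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a site-label TSV; '#'-prefixed lines are comments."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            pid, pos, label = parts[0], int(parts[1]), parts[2]
            if label not in VALID_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            sites.append((pid, pos, label))
    return sites


def write_site_labels(sites: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tposition\tlabel\n")
        for pid, pos, label in sites:
            fh.write(f"{pid}\t{pos}\t{label}\n")


def windows_from_labels(
    proteins: Sequence[ProteinRecord], sites: Iterable[tuple[str, int, str]]
) -> list[SiteWindow]:
    """Materialize labeled windows, validating the central-lysine invariant."""
    by_id = {p.id: p for p in proteins}
    windows = []
    for pid, pos, label in sites:
        if pid not in by_id:
            raise KeyError(f"site references unknown protein {pid!r}")
        windows.append(window_at(by_id[pid], pos, label=label))
    return windows
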