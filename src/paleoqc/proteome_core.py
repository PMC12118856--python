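"""Protein sequence model, FASTA I/O, in-silico digestion and peptide
physical chemistry.

This module supplies the coordinate system the rest of the package maps
peptides into. A :class:`ProteinRecord` is one FASTA entry; peptides are
located in proteins as :class:`PeptideMatch` intervals (1-based, inclusive
ends) carrying the flanking residue context needed to decide whether each
terminus is consistent with tryptic cleavage. On top of that sit the two
physicochemical descriptors used throughout protocol comparison:

* GRAVY — the grand average of hydropathy, i.e. the arithmetic mean of
  per-residue Kyte-Doolittle hydropathy values; positive means hydrophobic.
* pI — the isoelectric point, found by bisection on the Henderson-
  Hasselbalch net-charge curve for a configurable set of pKa values
  (default: the peptide-optimised ``IPC_peptide`` set shipped with the
  package).

Trypsin is modelled as cleaving C-terminal to Lys/Arg, with cleavage
suppressed before Pro when ``proline_rule`` is on (the default, matching
the common "Trypsin, not Trypsin/P" search convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .util import load_data_table

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Sentinel flanking "residue" for a peptide starting at the protein N-terminus.
START = "^"
#: Sentinel flanking "residue" for a peptide ending at the protein C-terminus.
END = "$"

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|\s]+)\|")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry. ``nonstandard`` flags letters outside the 20-residue
    alphabet (B/Z/X/U/O...); such records are kept but excluded from
    physicochemical aggregates by callers."""

    accession: str
    description: str
    sequence: str
    nonstandard: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideMatch:
    """Location of a peptide in a protein (1-based, inclusive end) plus the
    flanking residues, with :data:`START`/:data:`END` sentinels at the chain
    termini."""

    protein_accession: str
    start: int
    end: int
    preceding: str
    following: str


@dataclass(frozen=True)
class Peptide:
    sequence: str
    missed_cleavages: int
    match: PeptideMatch


class TerminusClass(str, Enum):
    TRYPTIC = "tryptic"
    SEMI_TRYPTIC = "semi_tryptic"
    NON_TRYPTIC = "non_tryptic"


# ---------------------------------------------------------------------------
# FASTA I/O


def parse_accession(header: str) -> str:
    """First whitespace-delimited token; for UniProt ``sp|ACC|NAME`` headers
    the middle token."""
    token = header.split()[0]
    m = _UNIPROT_HEADER.match(token)
    return m.group(1) if m else token


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Order is preserved. Duplicate accessions raise; sequences containing
    letters outside the standard alphabet are flagged and a warning logged.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = parse_accession(entry.description or entry.id)
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession}")
        seen.add(accession)
        seq = str(entry.seq).upper()
        nonstandard = not set(seq) <= STANDARD_AA
        if nonstandard:
            logger.warning(
                "protein %s contains nonstandard residues: %s",
                accession,
                sorted(set(seq) - STANDARD_AA),
            )
        records.append(
            ProteinRecord(accession, entry.description, seq, nonstandard)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def as_database(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Accession-keyed lookup preserving insertion order."""
    db: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.accession in db:
            raise ValueError(f"duplicate accession: {rec.accession}")
        db[rec.accession] = rec
    return db


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices ``i`` such that trypsin cleaves the bond after residue
    ``i`` (C-terminal to K/R, suppressed before P iff ``proline_rule``).
    Only internal bonds qualify."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR"
        and not (proline_rule and sequence[i + 1] == "P")
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    min_len: int = 1,
    max_len: int = 10**9,
    proline_rule: bool = True,
) -> list[Peptide]:
    """All fully tryptic peptides with 0..``max_missed`` retained internal
    sites, filtered to [``min_len``, ``max_len``]."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("require 1 <= min_len <= max_len")
    seq = protein.sequence
    cuts = [0] + [s + 1 for s in cleavage_sites(seq, proline_rule)] + [len(seq)]
    fragments = list(zip(cuts[:-1], cuts[1:]))
    peptides: list[Peptide] = []
    for k in range(len(fragments)):
        for m in range(min(max_missed, len(fragments) - 1 - k) + 1):
            a, b = fragments[k][0], fragments[k + m][1]
            if not min_len <= b - a <= max_len:
                continue
            match = PeptideMatch(
                protein.accession,
                a + 1,
                b,
                seq[a - 1] if a > 0 else START,
                seq[b] if b < len(seq) else END,
            )
            peptides.append(Peptide(seq[a:b], m, match))
    return peptides


def count_theoretical_peptides(
    protein: ProteinRecord,
    min_len: int = 7,
    max_len: int = 30,
    proline_rule: bool = True,
) -> int:
    """Number of distinct zero-missed-cleavage tryptic peptides within the
    length bounds — the iBAQ divisor."""
    return len(
        {p.sequence for p in digest(protein, 0, min_len, max_len, proline_rule)}
    )


def count_missed_cleavages(peptide: str, proline_rule: bool = True) -> int:
    """Internal (non-C-terminal) K/R positions that are cleavage sites under
    the rule — i.e. sites trypsin failed to cut."""
    return len(cleavage_sites(peptide, proline_rule))


# ---------------------------------------------------------------------------
# Hydropathy


@lru_cache(maxsize=1)
def kyte_doolittle_scale() -> Mapping[str, float]:
    table = load_data_table("kyte_doolittle.tsv")
    return dict(zip(table["residue"], table["hydropathy"]))


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    scale = kyte_doolittle_scale()
    bad = [i + 1 for i, r in enumerate(sequence) if r not in scale]
    if not sequence:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(
            f"nonstandard residue(s) at position(s) {bad} in {sequence!r}"
        )
    return sum(scale[r] for r in sequence) / len(sequence)


# ---------------------------------------------------------------------------
# Isoelectric point


@dataclass(frozen=True)
class PkaSet:
    """Named pKa values for the peptide's ionizable groups: the two chain
    termini and the D/E/C/Y (acidic) and H/K/R (basic) side chains."""

    name: str
    positive: tuple[tuple[str, float], ...]
    negative: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for _, pka in self.positive + self.negative:
            if not 0 < pka < 14:
                raise ValueError(f"pKa out of (0, 14): {pka}")


@lru_cache(maxsize=None)
def load_pka_set(name: str = "IPC_peptide") -> PkaSet:
    table = load_data_table("pka_sets.tsv")
    sub = table[table["set"] == name]
    if sub.empty:
        raise KeyError(
            f"unknown pKa set {name!r}; available: {sorted(table['set'].unique())}"
        )
    pos = tuple(
        (row.group, float(row.pka))
        for row in sub.itertuples()
        if row.sign == "+"
    )
    neg = tuple(
        (row.group, float(row.pka))
        for row in sub.itertuples()
        if row.sign == "-"
    )
    return PkaSet(name, pos, neg)


def _group_counts(sequence: str) -> dict[str, int]:
    counts = {"n_term": 1, "c_term": 1}
    for aa in "DECYHKR":
        n = sequence.count(aa)
        if n:
            counts[aa] = n
    return counts


def net_charge(sequence: str, pH, pka_set: PkaSet | None = None):
    """Henderson-Hasselbalch net charge at ``pH`` (scalar or array)."""
    pka_set = pka_set or load_pka_set()
    counts = _group_counts(sequence)
    pH = np.asarray(pH, dtype=float)
    charge = np.zeros_like(pH)
    for group, pka in pka_set.positive:
        n = counts.get(group, 0)
        if n:
            charge = charge + n / (1.0 + 10.0 ** (pH - pka))
    for group, pka in pka_set.negative:
        n = counts.get(group, 0)
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pka - pH))
    return float(charge) if charge.ndim == 0 else charge


@lru_cache(maxsize=100_000)
def _pi_from_counts(
    counts: tuple[tuple[str, int], ...], set_name: str, tolerance: float
) -> float:
    pka_set = load_pka_set(set_name)
    groups = dict(counts)

    def q(pH: float) -> float:
        total = 0.0
        for group, pka in pka_set.positive:
            n = groups.get(group, 0)
            if n:
                total += n / (1.0 + 10.0 ** (pH - pka))
        for group, pka in pka_set.negative:
            n = groups.get(group, 0)
            if n:
                total -= n / (1.0 + 10.0 ** (pka - pH))
        return total

    lo, hi = 0.0, 14.0
    # Net charge is strictly decreasing in pH, so the root is unique.
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if q(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def isoelectric_point(
    sequence: str,
    pka_set: PkaSet | None = None,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the peptide's Henderson-Hasselbalch net charge is zero,
    found by bisection on [0, 14] to within ``tolerance``."""
    if not sequence:
        raise ValueError("empty sequence")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    bad = sorted(set(sequence) - STANDARD_AA)
    if bad:
        raise ValueError(f"nonstandard residue(s) {bad} in {sequence!r}")
    pka_set = pka_set or load_pka_set()
    counts = _group_counts(sequence)
    named = {g for g, _ in pka_set.positive} | {g for g, _ in pka_set.negative}
    if not named & set(counts):
        raise ValueError("no ionizable group: pI undefined")
    return _pi_from_counts(
        tuple(sorted(counts.items())), pka_set.name, tolerance
    )


# ---------------------------------------------------------------------------
# Peptide-to-protein mapping and terminus classification


def map_peptide(
    peptide: str, database: Mapping[str, ProteinRecord]
) -> list[PeptideMatch]:
    """All exact substring occurrences of ``peptide`` across the database,
    ordered by (accession, start)."""
    matches: list[PeptideMatch] = []
    for accession in sorted(database):
        seq = database[accession].sequence
        pos = seq.find(peptide)
        while pos != -1:
            end = pos + len(peptide)
            matches.append(
                PeptideMatch(
                    accession,
                    pos + 1,
                    end,
                    seq[pos - 1] if pos > 0 else START,
                    seq[end] if end < len(seq) else END,
                )
            )
            pos = seq.find(peptide, pos + 1)
    return matches


def classify_terminus(
    peptide: str, match: PeptideMatch, proline_rule: bool = True
) -> TerminusClass:
    """Tryptic / semi-tryptic / non-tryptic classification of one match.

    The N side conforms when the preceding residue is K/R (and the peptide
    does not start with P under the proline rule), at the chain start, or at
    residue 2 behind an initiator Met (Met-excised mature N-termini count as
    conforming). The C side conforms when the peptide ends in K/R (and is
    not followed by P under the proline rule) or runs to the chain end.
    """
    n_ok = (
        match.preceding == START
        or (match.start == 2 and match.preceding == "M")
        or (
            match.preceding in "KR"
            and not (proline_rule and peptide[0] == "P")
        )
    )
    c_ok = match.following == END or (
        peptide[-1] in "KR"
        and not (proline_rule and match.following == "P")
    )
    if n_ok and c_ok:
        return TerminusClass.TRYPTIC
    if n_ok or c_ok:
        return TerminusClass.SEMI_TRYPTIC
    return TerminusClass.NON_TRYPTIC


def sequence_coverage(
    protein: ProteinRecord, matches: Iterable[PeptideMatch]
) -> float:
    """Percent of protein residues covered by the union of match intervals."""
    covered = np.zeros(len(protein), dtype=bool)
    for m in matches:
        if m.protein_accession != protein.accession:
            raise ValueError(
                f"match on {m.protein_accession} does not belong to "
                f"{protein.accession}"
            )
        covered[m.start - 1 : m.end] = True
    return 100.0 * covered.sum() / len(protein)
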