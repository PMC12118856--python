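"""Read identification report tables (DIA-NN and MaxQuant dialects),
normalise them to a canonical precursor table, and apply the
identification-confidence filters.

The canonical table has one row per observed precursor with columns
``run, protein_group, leader, stripped_sequence, modified_sequence, mods,
charge, intensity, precursor_q, protein_group_q, pep, reverse,
contaminant, ms1, ms2`` (plus ``missed_cleavages`` when available).
``mods`` holds parsed modification tokens as :class:`Mod` tuples with
1-based peptide site indices. Decoy and contaminant rows are recognised by
``REV__`` / ``CON__`` accession prefixes or by MaxQuant's ``+`` flags.

Filtering follows the conventional stringent policy for degraded samples:
remove decoys and contaminants, apply q-value and posterior error
probability thresholds, then require a minimum number of unique peptides
(distinct stripped sequences) per protein group. The order is pinned —
flags, then confidence thresholds, then unique-peptide support — because
the per-criterion removal counts depend on it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synthetic_diagenesis import CONTAMINANT_PREFIX, REVERSE_PREFIX

logger = logging.getLogger(__name__)

UNIMOD_NAMES = {
    1: "Acetyl",
    4: "Carbamidomethyl",
    7: "Deamidation",
    35: "Oxidation",
}

#: Placeholder name for modification tokens that could not be annotated.
UNANNOTATED = "unannotated"


class Mod(NamedTuple):
    site: int | None  # 1-based within the peptide; None when unlocalised
    name: str


_TOKEN = re.compile(r"\(([^()]*(?:\([^()]*\)[^()]*)*)\)|\[([^\[\]]*)\]")


def _annotate(token: str) -> tuple[str, bool]:
    m = re.fullmatch(r"UniMod:(\d+)", token.strip())
    if m:
        uid = int(m.group(1))
        if uid in UNIMOD_NAMES:
            return UNIMOD_NAMES[uid], True
        return UNANNOTATED, False
    base = token.split("(")[0].strip()
    if base in UNIMOD_NAMES.values():
        return base, True
    return UNANNOTATED, False


def parse_modified_sequence(modseq: str) -> tuple[str, tuple[Mod, ...], bool]:
    """Parse a modified sequence with bracketed tokens following the
    affected residue (DIA-NN ``(UniMod:n)`` or MaxQuant ``(Name (X))``
    grammar, ``_`` padding tolerated).

    Returns (stripped sequence, mods, all_tokens_annotated).
    """
    s = modseq.strip("_")
    stripped_chars: list[str] = []
    mods: list[Mod] = []
    ok = True
    pos = 0
    while pos < len(s):
        ch = s[pos]
        if ch in "([":
            m = _TOKEN.match(s, pos)
            if m is None:
                # Unbalanced bracket: treat remainder as one bad token.
                logger.warning("unparsable modification token in %r", modseq)
                mods.append(Mod(len(stripped_chars) or None, UNANNOTATED))
                ok = False
                break
            token = m.group(1) if m.group(1) is not None else m.group(2)
            name, annotated = _annotate(token)
            if not annotated:
                logger.warning(
                    "unannotated modification token %r in %r", token, modseq
                )
                ok = False
            site = len(stripped_chars) if stripped_chars else None
            mods.append(Mod(site, name))
            pos = m.end()
        else:
            stripped_chars.append(ch)
            pos += 1
    return "".join(stripped_chars), tuple(mods), ok


def _mods_from_count_grammar(text: str) -> tuple[Mod, ...]:
    """Parse a MaxQuant ``Modifications`` summary such as
    ``"2 Deamidation (NQ), Oxidation (M)"`` into unlocalised tokens."""
    if not text or text == "Unmodified":
        return ()
    mods: list[Mod] = []
    for part in text.split(","):
        part = part.strip()
        m = re.match(r"(\d+)\s+(.*)", part)
        count, label = (int(m.group(1)), m.group(2)) if m else (1, part)
        name, annotated = _annotate(label)
        if not annotated:
            logger.warning("unannotated modification %r", label)
        mods.extend([Mod(None, name)] * count)
    return tuple(mods)


def _leader(protein_group: str) -> str:
    first = protein_group.split(";")[0].strip()
    for prefix in (REVERSE_PREFIX, CONTAMINANT_PREFIX):
        first = first.removeprefix(prefix)
    return first


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df["leader"] = df["protein_group"].map(_leader)
    for col in ("precursor_q", "protein_group_q", "pep"):
        bad = df[col].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def read_diann_report(path) -> pd.DataFrame:
    """Read a DIA-NN style precursor report TSV into the canonical table."""
    raw = pd.read_csv(path, sep="\t", dtype={"Run": str})
    required = [
        "Run",
        "Protein.Group",
        "Stripped.Sequence",
        "Modified.Sequence",
        "Precursor.Charge",
        "Precursor.Quantity",
        "Q.Value",
        "PG.Q.Value",
    ]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    optional = {"PEP": 0.0, "Ms1.Area": np.nan, "Ms2.Area": np.nan}
    for col, default in optional.items():
        if col not in raw.columns:
            logger.info("optional column %s absent; defaulting to %r", col, default)
            raw[col] = default

    parsed = [
        parse_modified_sequence(m) if isinstance(m, str) else ("", (), True)
        for m in raw["Modified.Sequence"].fillna(raw["Stripped.Sequence"])
    ]
    df = pd.DataFrame(
        {
            "run": raw["Run"],
            "protein_group": raw["Protein.Group"].astype(str),
            "stripped_sequence": raw["Stripped.Sequence"],
            "modified_sequence": raw["Modified.Sequence"].fillna(
                raw["Stripped.Sequence"]
            ),
            "mods": [p[1] for p in parsed],
            "mods_annotated": [p[2] for p in parsed],
            "charge": raw["Precursor.Charge"].astype(int),
            "intensity": pd.to_numeric(raw["Precursor.Quantity"]),
            "precursor_q": pd.to_numeric(raw["Q.Value"]),
            "protein_group_q": pd.to_numeric(raw["PG.Q.Value"]),
            "pep": pd.to_numeric(raw["PEP"]),
            "reverse": raw["Protein.Group"].str.startswith(REVERSE_PREFIX),
            "contaminant": raw["Protein.Group"].str.startswith(
                CONTAMINANT_PREFIX
            ),
            "ms1": pd.to_numeric(raw["Ms1.Area"]),
            "ms2": pd.to_numeric(raw["Ms2.Area"]),
        }
    )
    mismatch = [
        (a, b)
        for a, b, p in zip(df["stripped_sequence"], parsed, parsed)
        if isinstance(a, str) and b[0] and a != b[0]
    ]
    if mismatch:
        logger.warning(
            "%d rows where Modified.Sequence does not strip to "
            "Stripped.Sequence (kept as reported)",
            len(mismatch),
        )
    return _finalize(df)


def read_maxquant_tables(
    evidence_path, peptides_path=None, proteingroups_path=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read MaxQuant ``evidence.txt`` (plus optional ``peptides.txt`` /
    ``proteinGroups.txt``) into (canonical precursor table, protein table).

    MaxQuant evidence carries PEP but no precursor q-value; the q-value
    defaults to 0 (logged) so q-thresholds pass and PEP governs confidence.
    """
    ev = pd.read_csv(evidence_path, sep="\t")
    required = ["Sequence", "Proteins", "Intensity", "PEP"]
    missing = [c for c in required if c not in ev.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    n = len(ev)

    def col(name, default):
        if name in ev.columns:
            return ev[name]
        logger.info("optional column %s absent; defaulting to %r", name, default)
        return pd.Series([default] * n)

    modseq = col("Modified sequence", "")
    mods_summary = col("Modifications", "Unmodified")
    parsed_mods: list[tuple[Mod, ...]] = []
    annotated_flags: list[bool] = []
    for ms, summary in zip(modseq, mods_summary):
        if isinstance(ms, str) and ms:
            _, mods, ok = parse_modified_sequence(ms)
        else:
            mods = _mods_from_count_grammar(
                summary if isinstance(summary, str) else ""
            )
            ok = all(m.name != UNANNOTATED for m in mods)
        parsed_mods.append(mods)
        annotated_flags.append(ok)

    logger.info("MaxQuant evidence: precursor q-value not reported; using 0")
    df = pd.DataFrame(
        {
            "run": col("Raw file", "run1"),
            "protein_group": ev["Proteins"].astype(str),
            "stripped_sequence": ev["Sequence"],
            "modified_sequence": [
                ms if isinstance(ms, str) and ms else seq
                for ms, seq in zip(modseq, ev["Sequence"])
            ],
            "mods": parsed_mods,
            "mods_annotated": annotated_flags,
            "charge": pd.to_numeric(col("Charge", 2)).astype(int),
            "intensity": pd.to_numeric(ev["Intensity"]),
            "precursor_q": 0.0,
            "protein_group_q": 0.0,
            "pep": pd.to_numeric(ev["PEP"]),
            "reverse": (col("Reverse", "").fillna("") == "+"),
            "contaminant": (col("Potential contaminant", "").fillna("") == "+"),
            "ms1": np.nan,
            "ms2": np.nan,
        }
    )
    if "Missed cleavages" in ev.columns:
        df["missed_cleavages"] = pd.to_numeric(ev["Missed cleavages"])
    df = _finalize(df)

    if proteingroups_path is not None:
        pg = pd.read_csv(proteingroups_path, sep="\t")
        proteins = pd.DataFrame(
            {
                "protein_group": pg["Protein IDs"].astype(str),
                "protein_group_q": pd.to_numeric(
                    pg.get("Q-value", pd.Series([0.0] * len(pg)))
                ),
                "reverse": (pg.get("Reverse", "").fillna("") == "+")
                if "Reverse" in pg.columns
                else False,
                "contaminant": (
                    pg.get("Potential contaminant", "").fillna("") == "+"
                )
                if "Potential contaminant" in pg.columns
                else False,
            }
        )
        q_by_group = dict(zip(proteins["protein_group"], proteins["protein_group_q"]))
        df["protein_group_q"] = (
            df["protein_group"].map(q_by_group).fillna(df["protein_group_q"])
        )
    else:
        proteins = pd.DataFrame(
            columns=["protein_group", "protein_group_q", "reverse", "contaminant"]
        )
    return df, proteins


# ---------------------------------------------------------------------------
# Filters


@dataclass
class FilterPolicy:
    """Identification-level filter thresholds. Defaults implement the
    stringent global policy: decoys and contaminants removed, q-value and
    PEP at or below 1%, at least two unique peptides per protein group.
    ``per_protocol`` applies the unique-peptide rule within each run rather
    than across the pooled dataset."""

    precursor_q: float = 0.01
    protein_group_q: float = 0.01
    pep: float = 0.01
    min_unique_peptides: int = 2
    remove_reverse: bool = True
    remove_contaminants: bool = True
    per_protocol: bool = True


@dataclass
class FilterReport:
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": k, "removed": v} for k, v in self.removed.items()
        ]
        rows.append({"criterion": "TOTAL", "removed": self.n_input - self.n_output})
        return pd.DataFrame(rows)


def apply_identification_filters(
    rows: pd.DataFrame, policy: FilterPolicy | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the identification filters in pinned order (flags, then
    confidence thresholds, then unique-peptide support) and report the
    removal count per criterion. Missing confidence values pass their
    threshold (logged), missing intensities are retained as left-censored
    observations."""
    policy = policy or FilterPolicy()
    report = FilterReport(n_input=len(rows))
    df = rows

    def drop(mask: pd.Series, criterion: str) -> None:
        nonlocal df
        report.removed[criterion] = int(mask.sum())
        df = df[~mask]

    drop(
        df["reverse"] if policy.remove_reverse else pd.Series(False, df.index),
        "reverse",
    )
    drop(
        df["contaminant"]
        if policy.remove_contaminants
        else pd.Series(False, df.index),
        "contaminant",
    )
    for col, thr in (
        ("precursor_q", policy.precursor_q),
        ("protein_group_q", policy.protein_group_q),
        ("pep", policy.pep),
    ):
        drop(df[col].fillna(0.0) > thr, col)

    group_cols = (
        ["run", "leader"] if policy.per_protocol else ["leader"]
    )
    support = df.groupby(group_cols)["stripped_sequence"].transform("nunique")
    drop(support < policy.min_unique_peptides, "min_unique_peptides")

    report.n_output = len(df)
    return df.copy(), report


@dataclass
class ModifiedPeptidePolicy:
    """Looser thresholds used for modified-peptide lists, plus the
    requirement that each modification type be supported by a minimum
    number of unique peptides."""

    precursor_q: float = 0.05
    pep: float = 0.05
    min_unique_peptides: int = 2


def modified_peptide_filter(
    rows: pd.DataFrame, policy: ModifiedPeptidePolicy | None = None
) -> pd.DataFrame:
    """Filter modified peptides: apply q/PEP thresholds, drop unannotated
    modification tokens, then drop modification types supported by fewer
    than ``min_unique_peptides`` distinct stripped sequences. Rows with no
    surviving modification token are excluded from the result."""
    policy = policy or ModifiedPeptidePolicy()
    df = rows[
        (rows["precursor_q"].fillna(0.0) <= policy.precursor_q)
        & (rows["pep"].fillna(0.0) <= policy.pep)
    ].copy()
    df["mods"] = df["mods"].map(
        lambda mods: tuple(m for m in mods if m.name != UNANNOTATED)
    )
    support: dict[str, set[str]] = {}
    for mods, seq in zip(df["mods"], df["stripped_sequence"]):
        for m in mods:
            support.setdefault(m.name, set()).add(seq)
    keep_types = {
        name
        for name, seqs in support.items()
        if len(seqs) >= policy.min_unique_peptides
    }
    df["mods"] = df["mods"].map(
        lambda mods: tuple(m for m in mods if m.name in keep_types)
    )
    return df[df["mods"].map(len) > 0].copy()
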