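"""Diagenesis-facing QC summaries per extraction protocol.

Ancient proteins accumulate two signatures this module quantifies from an
identification report: non-enzymatic backbone cleavage, visible as
semi-/non-tryptic peptide termini and a characteristic C-terminal residue
spectrum, and deamidation of Asn/Gln/Arg, visible as modification tokens.
Alongside these sit the standard bottom-up QC measures — missed tryptic
cleavages, MS1/MS2 signal ratio, protein sequence coverage — and the
physicochemical profile (GRAVY hydropathy and isoelectric point) of the
recovered peptides, optionally referenced against the "common proteome":
the proteins identified by every protocol.

Definitions pinned here (the field has no single convention):

* each distinct peptide is classified once, against its protein-group
  leader where it maps there, otherwise against its first database match;
* the mean missed-cleavage count is averaged over precursor rows (the
  search-engine report convention), with a toggle for distinct peptides;
* percent deamidated peptides is computed over distinct modified
  sequences, separately for contaminant-flagged and endogenous rows, and
  the per-row (PSM-level) figure is reported alongside;
* the MS1/MS2 ratio is the ratio of summed MS1 to summed MS2 intensity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .proteome_core import (
    END,
    ProteinRecord,
    TerminusClass,
    classify_terminus,
    count_missed_cleavages,
    gravy,
    isoelectric_point,
    map_peptide,
    sequence_coverage,
    PeptideMatch,
    STANDARD_AA,
)
from .util import percentage

logger = logging.getLogger(__name__)

DEAMIDATABLE = set("NQR")


# ---------------------------------------------------------------------------
# Terminus spectrum


@dataclass
class TerminusSpectrum:
    class_counts: dict[str, int]
    cterm_residue_counts: dict[str, int]
    n_classified: int
    n_cterm_internal: int  # peptides whose C-terminus is not the chain end
    n_unmapped: int

    @property
    def class_fractions(self) -> dict[str, float]:
        total = self.n_classified
        return {
            k: (v / total if total else 0.0)
            for k, v in self.class_counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        """Numerator/denominator table of the C-terminal residue spectrum."""
        rows = [
            {
                "cterm_residue": res,
                "count": n,
                "total": self.n_cterm_internal,
                "pct": percentage(n, self.n_cterm_internal),
            }
            for res, n in sorted(
                self.cterm_residue_counts.items(), key=lambda kv: -kv[1]
            )
        ]
        return pd.DataFrame(
            rows, columns=["cterm_residue", "count", "total", "pct"]
        )


def _match_for(
    peptide: str, leader: str, database: Mapping[str, ProteinRecord]
) -> PeptideMatch | None:
    if leader in database:
        hits = map_peptide(peptide, {leader: database[leader]})
        if hits:
            return hits[0]
    hits = map_peptide(peptide, database)
    return hits[0] if hits else None


def terminus_spectrum(
    rows: pd.DataFrame,
    database: Mapping[str, ProteinRecord],
    proline_rule: bool = True,
) -> TerminusSpectrum:
    """Classify each distinct peptide as tryptic / semi-tryptic /
    non-tryptic and tabulate the C-terminal residue spectrum (chain-end
    termini excluded from the residue tally). Unmapped peptides are
    counted and excluded."""
    distinct = rows.drop_duplicates("stripped_sequence")
    class_counts: Counter = Counter()
    residue_counts: Counter = Counter()
    n_internal = 0
    n_unmapped = 0
    for pep, leader in zip(distinct["stripped_sequence"], distinct["leader"]):
        match = _match_for(pep, leader, database)
        if match is None:
            n_unmapped += 1
            continue
        cls = classify_terminus(pep, match, proline_rule)
        class_counts[cls.value] += 1
        if match.following != END:
            residue_counts[pep[-1]] += 1
            n_internal += 1
    if n_unmapped:
        logger.warning("%d peptide(s) not mappable to the database", n_unmapped)
    for cls in TerminusClass:
        class_counts.setdefault(cls.value, 0)
    return TerminusSpectrum(
        dict(class_counts),
        dict(residue_counts),
        sum(class_counts.values()),
        n_internal,
        n_unmapped,
    )


# ---------------------------------------------------------------------------
# Deamidation accounting


@dataclass
class DeamidationTally:
    n_peptides: int  # distinct modified sequences
    n_deamidated: int
    n_rows: int  # precursor rows (PSM-level)
    n_rows_deamidated: int
    site_counts: dict[str, int]

    @property
    def pct_deamidated(self) -> float | None:
        if self.n_peptides == 0:
            return None
        return percentage(self.n_deamidated, self.n_peptides)

    @property
    def pct_rows_deamidated(self) -> float | None:
        if self.n_rows == 0:
            return None
        return percentage(self.n_rows_deamidated, self.n_rows)

    @property
    def site_mix(self) -> dict[str, float]:
        total = sum(self.site_counts.values())
        if total == 0:
            return {}
        return {res: n / total for res, n in sorted(self.site_counts.items())}


@dataclass
class DeamidationSummary:
    endogenous: DeamidationTally
    contaminant: DeamidationTally

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for origin, tally in (
            ("endogenous", self.endogenous),
            ("contaminant", self.contaminant),
        ):
            rows.append(
                {
                    "origin": origin,
                    "n_peptides": tally.n_peptides,
                    "n_deamidated": tally.n_deamidated,
                    "pct_deamidated": tally.pct_deamidated,
                    "n_rows": tally.n_rows,
                    "n_rows_deamidated": tally.n_rows_deamidated,
                    "pct_rows_deamidated": tally.pct_rows_deamidated,
                    **{
                        f"sites_{res}": tally.site_counts.get(res, 0)
                        for res in "NQR"
                    },
                }
            )
        return pd.DataFrame(rows)


def _tally(sub: pd.DataFrame) -> DeamidationTally:
    distinct = sub.drop_duplicates("modified_sequence")
    site_counts: Counter = Counter()
    n_deam = 0
    for stripped, mods in zip(distinct["stripped_sequence"], distinct["mods"]):
        deam = [m for m in mods if m.name == "Deamidation"]
        if deam:
            n_deam += 1
        for m in deam:
            if m.site is None:
                logger.info(
                    "unlocalised deamidation token on %s excluded from "
                    "site mix",
                    stripped,
                )
                continue
            res = stripped[m.site - 1]
            if res not in DEAMIDATABLE:
                raise ValueError(
                    f"deamidation annotated on residue {res!r} "
                    f"(site {m.site} of {stripped}); only N/Q/R deamidate"
                )
            site_counts[res] += 1
    rows_deam = sum(
        1
        for mods in sub["mods"]
        if any(m.name == "Deamidation" for m in mods)
    )
    return DeamidationTally(
        n_peptides=len(distinct),
        n_deamidated=n_deam,
        n_rows=len(sub),
        n_rows_deamidated=rows_deam,
        site_counts=dict(site_counts),
    )


def deamidation_accounting(rows: pd.DataFrame) -> DeamidationSummary:
    """Deamidation extent (percent of deamidated peptides, endogenous and
    contaminant separately) and the site-type mix over N/Q/R."""
    endo = _tally(rows[~rows["contaminant"]])
    cont = _tally(rows[rows["contaminant"]])
    return DeamidationSummary(endo, cont)


# ---------------------------------------------------------------------------
# Signal and physicochemistry


def ms_signal_ratio(rows: pd.DataFrame) -> pd.Series | None:
    """Summed MS1 / summed MS2 intensity per run; ``None`` when the report
    carries no MS-level intensities."""
    if "ms1" not in rows or rows["ms1"].dropna().empty:
        logger.info("MS1/MS2 intensities unavailable; ratio not computed")
        return None
    ratios = {}
    for run, sub in rows.groupby("run"):
        s1 = sub["ms1"].sum(skipna=True)
        s2 = sub["ms2"].sum(skipna=True)
        if s2 == 0:
            raise ValueError(f"zero total MS2 signal in run {run}")
        ratios[run] = s1 / s2
    return pd.Series(ratios, name="ms1_ms2_ratio").sort_index()


@dataclass
class PhyschemSummary:
    level: str
    n: int
    gravy_mean: float
    gravy_sd: float
    pct_hydrophobic: float
    pi_mean: float
    pi_sd: float
    n_excluded_nonstandard: int = 0


def _physchem_of(seqs: list[str], level: str) -> PhyschemSummary:
    ok = [s for s in seqs if set(s) <= STANDARD_AA]
    excluded = len(seqs) - len(ok)
    if excluded:
        logger.warning(
            "%d sequence(s) with nonstandard residues excluded from "
            "physicochemical profile",
            excluded,
        )
    g = np.array([gravy(s) for s in ok])
    p = np.array([isoelectric_point(s) for s in ok])
    if len(ok) == 0:
        return PhyschemSummary(level, 0, np.nan, np.nan, np.nan, np.nan, np.nan, excluded)
    return PhyschemSummary(
        level=level,
        n=len(ok),
        gravy_mean=float(g.mean()),
        gravy_sd=float(g.std(ddof=1)) if len(ok) > 1 else 0.0,
        pct_hydrophobic=percentage(int((g > 0).sum()), len(ok)),
        pi_mean=float(p.mean()),
        pi_sd=float(p.std(ddof=1)) if len(ok) > 1 else 0.0,
        n_excluded_nonstandard=excluded,
    )


def common_proteome(rows: pd.DataFrame) -> set[str]:
    """Protein leaders identified in every run; errors with per-run
    presence counts when empty."""
    per_run = {
        run: set(sub["leader"].unique()) for run, sub in rows.groupby("run")
    }
    common = set.intersection(*per_run.values()) if per_run else set()
    if not common:
        counts = {run: len(s) for run, s in sorted(per_run.items())}
        raise ValueError(
            f"common proteome is empty; per-protocol protein counts: {counts}"
        )
    return common


def physchem_profile(
    rows: pd.DataFrame,
    level: str = "peptide",
    database: Mapping[str, ProteinRecord] | None = None,
) -> dict[str, PhyschemSummary]:
    """GRAVY / pI distribution summaries.

    ``peptide``: per run over distinct recovered peptides.
    ``protein``: per run over the sequences of identified proteins
    (requires ``database``).
    ``common_proteome``: one protein-level reference summary over the
    proteins present in every run.
    """
    if level == "peptide":
        return {
            run: _physchem_of(
                sorted(sub["stripped_sequence"].unique()), "peptide"
            )
            for run, sub in rows.groupby("run")
        }
    if database is None:
        raise ValueError(f"level {level!r} requires a protein database")
    if level == "protein":
        out = {}
        for run, sub in rows.groupby("run"):
            seqs = [
                database[acc].sequence
                for acc in sorted(sub["leader"].unique())
                if acc in database
            ]
            out[run] = _physchem_of(seqs, "protein")
        return out
    if level == "common_proteome":
        shared = common_proteome(rows)
        seqs = [database[acc].sequence for acc in sorted(shared) if acc in database]
        return {"common_proteome": _physchem_of(seqs, "common_proteome")}
    raise ValueError(
        "level must be 'peptide', 'protein' or 'common_proteome'"
    )


# ---------------------------------------------------------------------------
# Aggregate summary


@dataclass
class MetricsSummary:
    protocol: str
    n_precursors: int
    n_peptides: int
    n_proteins: int
    mean_missed_cleavages: float
    ms1_ms2_ratio: float
    terminus: TerminusSpectrum | None
    deamidation: DeamidationSummary | None
    coverage_median: float
    coverage_mean: float
    coverage_q1: float
    coverage_q3: float
    physchem: PhyschemSummary | None
    empty: bool = False

    def to_row(self) -> dict:
        row = {
            "protocol": self.protocol,
            "n_precursors": self.n_precursors,
            "n_peptides": self.n_peptides,
            "n_proteins": self.n_proteins,
            "mean_missed_cleavages": self.mean_missed_cleavages,
            "ms1_ms2_ratio": self.ms1_ms2_ratio,
            "coverage_median": self.coverage_median,
            "coverage_mean": self.coverage_mean,
            "coverage_q1": self.coverage_q1,
            "coverage_q3": self.coverage_q3,
        }
        if self.terminus is not None:
            for cls in TerminusClass:
                row[f"frac_{cls.value}"] = self.terminus.class_fractions[
                    cls.value
                ]
            row["n_terminus_classified"] = self.terminus.n_classified
        if self.deamidation is not None:
            endo = self.deamidation.endogenous
            cont = self.deamidation.contaminant
            row["pct_deamidated_endogenous"] = endo.pct_deamidated
            row["pct_deamidated_contaminant"] = cont.pct_deamidated
            for res in "NQR":
                row[f"deamidation_sites_{res}"] = endo.site_counts.get(res, 0)
        if self.physchem is not None:
            row.update(
                gravy_mean=self.physchem.gravy_mean,
                gravy_sd=self.physchem.gravy_sd,
                pct_hydrophobic=self.physchem.pct_hydrophobic,
                pi_mean=self.physchem.pi_mean,
                pi_sd=self.physchem.pi_sd,
            )
        return row


def _coverage_stats(
    sub: pd.DataFrame, database: Mapping[str, ProteinRecord]
) -> tuple[float, float, float, float]:
    values = []
    for acc, prot_rows in sub.groupby("leader"):
        rec = database.get(acc)
        if rec is None:
            continue
        matches = []
        for pep in prot_rows["stripped_sequence"].unique():
            hits = map_peptide(pep, {acc: rec})
            matches.extend(hits)
        values.append(sequence_coverage(rec, matches))
    if not values:
        return (np.nan,) * 4
    arr = np.array(values)
    return (
        float(np.median(arr)),
        float(arr.mean()),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


def summarize_protocol(
    rows: pd.DataFrame,
    database: Mapping[str, ProteinRecord],
    proline_rule: bool = True,
    missed_over_distinct: bool = False,
) -> MetricsSummary:
    """Full :class:`MetricsSummary` for the rows of one protocol; composes
    the individual metric operations."""
    if rows.empty:
        return MetricsSummary(
            "(empty)", 0, 0, 0, np.nan, np.nan, None, None,
            np.nan, np.nan, np.nan, np.nan, None, empty=True,
        )
    protocols = rows["run"].unique()
    protocol = protocols[0] if len(protocols) == 1 else "pooled"
    endo = rows[~rows["contaminant"] & ~rows["reverse"]]
    basis = (
        endo.drop_duplicates("stripped_sequence")
        if missed_over_distinct
        else endo
    )
    mc = float(
        np.mean(
            [
                count_missed_cleavages(s, proline_rule)
                for s in basis["stripped_sequence"]
            ]
        )
    ) if len(basis) else np.nan
    ratio = ms_signal_ratio(rows)
    ratio_value = float(ratio.iloc[0]) if ratio is not None and len(ratio) == 1 else (
        float(ratio.mean()) if ratio is not None else np.nan
    )
    cov = _coverage_stats(endo, database)
    return MetricsSummary(
        protocol=protocol,
        n_precursors=len(endo),
        n_peptides=endo["stripped_sequence"].nunique(),
        n_proteins=endo["leader"].nunique(),
        mean_missed_cleavages=mc,
        ms1_ms2_ratio=ratio_value,
        terminus=terminus_spectrum(endo, database, proline_rule),
        deamidation=deamidation_accounting(rows[~rows["reverse"]]),
        coverage_median=cov[0],
        coverage_mean=cov[1],
        coverage_q1=cov[2],
        coverage_q3=cov[3],
        physchem=_physchem_of(
            sorted(endo["stripped_sequence"].unique()), "peptide"
        ),
    )


def summarize_experiment(
    rows: pd.DataFrame,
    database: Mapping[str, ProteinRecord],
    proline_rule: bool = True,
) -> pd.DataFrame:
    """One MetricsSummary row per run label."""
    out = [
        summarize_protocol(sub, database, proline_rule).to_row()
        for _, sub in rows.groupby("run")
    ]
    return pd.DataFrame(out)
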