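"""Generative model of an ancient-proteome extraction experiment.

The simulator emulates the statistical structure of a degraded (diagenetic)
proteome as seen through a bottom-up LC-MS/MS identification report:

1. a toy proteome with database-average residue composition;
2. log-normal protein abundances shared across protocols;
3. diagenetic damage per protein — a Poisson number of non-enzymatic
   backbone-hydrolysis events placed with residue-specific propensities
   (elevated for Leu and Phe, the cleavage contexts most often seen in
   degraded tissue), deamidation of Asn/Gln/Arg side chains, and oxidation
   of Met/Pro;
4. tryptic digestion of the damaged fragments with stochastic missed
   cleavages;
5. protocol-specific recovery: each candidate peptide is detected with
   probability proportional to a softmax over
   ``log(abundance) + bias_gravy * GRAVY + bias_pi * pI``, with expected
   total detections ``depth * faims_gain``;
6. acquisition noise, confidence scores (q-value / PEP mixtures), decoy
   and contaminant rows, and left-censoring of low intensities.

Ground truth (all parameters, true abundances, true damage-site counts) is
recorded alongside every simulated table so downstream estimators can be
validated by parameter recovery. Re-running with the same seed reproduces
tables byte-identically.

Default deamidation rates are calibrated so that, on sequences with the
shipped background residue composition, the expected site-type mix of
deamidation events is 51.4% Asn : 30.2% Gln : 18.3% Arg — the profile
typical of archaeological soft tissue. Because Asn, Gln and Arg occur at
different background frequencies, the per-site rates are the target mix
divided by residue frequency (see docs/methods.md for the derivation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteome_core import (
    END,
    START,
    ProteinRecord,
    cleavage_sites,
    gravy,
    isoelectric_point,
)
from .util import load_data_table

DEAMIDATION = "Deamidation"
OXIDATION = "Oxidation"
#: UniMod accessions used when writing DIA-NN style modified sequences.
UNIMOD_IDS = {DEAMIDATION: 7, OXIDATION: 35}

CONTAMINANT_PREFIX = "CON__"
REVERSE_PREFIX = "REV__"

#: Column order of the canonical in-memory precursor table.
CANONICAL_COLUMNS = [
    "run",
    "protein_group",
    "stripped_sequence",
    "modified_sequence",
    "charge",
    "intensity",
    "precursor_q",
    "protein_group_q",
    "pep",
    "reverse",
    "contaminant",
    "ms1",
    "ms2",
    "missed_cleavages",
]


def _default_propensity() -> dict[str, float]:
    prop = {aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    prop["L"] = 5.0  # hydrolysis favours cleavage C-terminal to Leu ...
    prop["F"] = 5.0  # ... and Phe
    return prop


def _default_deamidation_rates() -> dict[str, float]:
    # Target site-type mix 0.514:0.302:0.183 over N:Q:R divided by the
    # background residue frequencies (N 4.06%, Q 3.93%, R 5.53%), scaled so
    # the Asn rate is 0.30.
    return {"N": 0.300, "Q": 0.1821, "R": 0.0784}


@dataclass
class DiagenesisParams:
    """Rates of the generative damage model.

    hydrolysis_intensity
        Expected non-enzymatic backbone cleavage events per 100 residues.
    residue_propensity
        Relative weight of cleaving C-terminal to each residue.
    deamidation_site_rate
        Per-site deamidation probability for N, Q and R.
    oxidation_rate
        Per-site oxidation probability for M and P.
    contaminant_damage_scale
        Factor applied to deamidation/oxidation rates for spiked (modern)
        contaminants, whose damage stems from sample preparation only;
        contaminants receive no backbone hydrolysis.
    """

    hydrolysis_intensity: float = 1.5
    residue_propensity: Mapping[str, float] = field(
        default_factory=_default_propensity
    )
    deamidation_site_rate: Mapping[str, float] = field(
        default_factory=_default_deamidation_rates
    )
    oxidation_rate: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.10, "P": 0.05}
    )
    contaminant_damage_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.hydrolysis_intensity < 0:
            raise ValueError("hydrolysis_intensity must be >= 0")
        for name, rates in (
            ("deamidation_site_rate", self.deamidation_site_rate),
            ("oxidation_rate", self.oxidation_rate),
        ):
            for res, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"{name}[{res}] outside [0, 1]: {r}")
        props = list(self.residue_propensity.values())
        if any(p < 0 for p in props) or not any(p > 0 for p in props):
            raise ValueError(
                "residue propensities must be >= 0 with at least one > 0"
            )


@dataclass
class ProtocolProfile:
    """Simulator parameters for one extraction protocol.

    ``depth`` is the expected number of detected precursors;
    ``bias_gravy`` / ``bias_pi`` are log-odds recovery coefficients per
    GRAVY / pI unit (the generative counterpart of a protocol's estimated
    effect on peptide physicochemistry); ``missed_cleavage_rate`` is the
    per-site probability that a tryptic site is retained (missed);
    ``faims_gain`` is a multiplicative depth factor standing in for
    ion-mobility filtering; ``ms1_ms2_ratio`` sets the expected ratio of
    the MS1 to MS2 summed signal.
    """

    name: str
    depth: float = 2000.0
    bias_gravy: float = 0.0
    bias_pi: float = 0.0
    missed_cleavage_rate: float = 0.12
    contaminant_load: float = 0.03
    faims_gain: float = 1.0
    ms1_ms2_ratio: float = 1.3

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.faims_gain <= 0:
            raise ValueError("faims_gain must be > 0")
        for attr in ("missed_cleavage_rate", "contaminant_load"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValueError(f"{attr} outside [0, 1]: {v}")


@dataclass
class AbundanceModel:
    """Log-normal protein abundance: ``exp(Normal(log_mean, log_sd))``.
    ``log_sd`` defaults to 2 natural-log units, a typical proteome dynamic
    range. Fixed per-protein abundances may be supplied to share one
    abundance draw across protocols."""

    log_mean: float = 13.8
    log_sd: float = 2.0
    abundances: Mapping[str, float] | None = None


@dataclass
class GroundTruth:
    """Per-run record of the generative state, serialised next to every
    simulated table."""

    seed: int
    profile: dict
    params: dict
    abundances: dict[str, float]
    n_hydrolysis_events: int
    deamidation_sites_true: dict[str, int]
    deamidation_sites_detected: dict[str, int]
    n_candidates: int
    n_detected: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class DamagedFragment:
    """A maximal backbone fragment after hydrolysis, with its location in
    the parent protein (1-based inclusive) and side-chain modification
    annotations (1-based site within the fragment)."""

    protein_accession: str
    sequence: str
    start: int
    end: int
    mods: tuple[tuple[int, str, str], ...]  # (site, mod name, residue)


# ---------------------------------------------------------------------------
# Proteome generation


@lru_cache(maxsize=1)
def residue_frequencies() -> tuple[tuple[str, ...], tuple[float, ...]]:
    table = load_data_table("residue_frequencies.tsv")
    freq = table["frequency"].to_numpy(float)
    freq = freq / freq.sum()
    return tuple(table["residue"]), tuple(freq)


def make_toy_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 400),
    seed: int = 0,
    prefix: str = "SYN",
) -> list[ProteinRecord]:
    """Random protein sequences with database-average residue composition."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length_range")
    residues, freq = residue_frequencies()
    rng = np.random.default_rng(seed)
    records = []
    width = max(4, len(str(n_proteins)))
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=freq))
        acc = f"{prefix}{i + 1:0{width}d}"
        records.append(ProteinRecord(acc, f"{acc} synthetic protein", seq))
    return records


def make_contaminant_proteome(
    seed: int = 0, length_range: tuple[int, int] = (80, 200)
) -> list[ProteinRecord]:
    """Synthetic stand-ins for the default laboratory-contaminant targets,
    one protein per entry of the shipped contaminant list."""
    names = load_data_table("contaminant_list.tsv")["name"].tolist()
    residues, freq = residue_frequencies()
    rng = np.random.default_rng(np.random.SeedSequence([7_654_321, seed]))
    lo, hi = length_range
    records = []
    for name in names:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=freq))
        acc = f"{CONTAMINANT_PREFIX}{name}"
        records.append(ProteinRecord(acc, f"{acc} synthetic contaminant", seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.description}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k : k + 60] + "\n")


def draw_abundances(
    proteome: Sequence[ProteinRecord],
    model: AbundanceModel,
    seed: int,
) -> dict[str, float]:
    if model.abundances is not None:
        return dict(model.abundances)
    rng = np.random.default_rng(np.random.SeedSequence([1_234_567, seed]))
    accs = sorted(r.accession for r in proteome)
    vals = np.exp(rng.normal(model.log_mean, model.log_sd, size=len(accs)))
    return dict(zip(accs, vals))


# ---------------------------------------------------------------------------
# Damage


def simulate_damage(
    protein: ProteinRecord,
    params: DiagenesisParams,
    rng: np.random.Generator,
    damage_scale: float = 1.0,
    hydrolysis: bool = True,
) -> list[DamagedFragment]:
    """Apply backbone hydrolysis and side-chain modifications to one protein.

    The number of cleavage events is Poisson with mean
    ``hydrolysis_intensity * len / 100``; event positions are drawn without
    replacement over internal bonds with probability proportional to the
    propensity of the residue N-terminal to the bond. Deamidation and
    oxidation are independent Bernoulli draws per candidate site.
    """
    seq = protein.sequence
    n_bonds = len(seq) - 1
    cut_after: np.ndarray
    if hydrolysis and n_bonds > 0 and params.hydrolysis_intensity > 0:
        lam = params.hydrolysis_intensity * len(seq) / 100.0
        n_events = min(int(rng.poisson(lam)), n_bonds)
        weights = np.array(
            [params.residue_propensity.get(seq[i], 1.0) for i in range(n_bonds)]
        )
        weights = weights / weights.sum()
        cut_after = np.sort(
            rng.choice(n_bonds, size=n_events, replace=False, p=weights)
        )
    else:
        cut_after = np.empty(0, dtype=int)

    # Side-chain events, protein-wide, then distributed onto fragments.
    mods: list[tuple[int, str, str]] = []  # (0-based position, name, residue)
    deam = {
        res: rate * damage_scale
        for res, rate in params.deamidation_site_rate.items()
    }
    oxid = {
        res: rate * damage_scale for res, rate in params.oxidation_rate.items()
    }
    u = rng.random(len(seq))
    for i, res in enumerate(seq):
        if res in deam and u[i] < deam[res]:
            mods.append((i, DEAMIDATION, res))
        elif res in oxid and u[i] < oxid[res]:
            mods.append((i, OXIDATION, res))

    starts = [0] + [int(c) + 1 for c in cut_after]
    ends = [int(c) + 1 for c in cut_after] + [len(seq)]
    fragments = []
    for a, b in zip(starts, ends):
        frag_mods = tuple(
            (pos - a + 1, name, res) for pos, name, res in mods if a <= pos < b
        )
        fragments.append(
            DamagedFragment(
                protein.accession, seq[a:b], a + 1, b, frag_mods
            )
        )
    return fragments


# ---------------------------------------------------------------------------
# Run simulation


def _stochastic_digest(
    fragment: DamagedFragment,
    protein_seq: str,
    missed_rate: float,
    rng: np.random.Generator,
    min_len: int,
    max_len: int,
    proline_rule: bool,
) -> list[dict]:
    """Cut a damaged fragment at tryptic sites, each independently retained
    (missed) with probability ``missed_rate``; returns candidate peptides
    with modification annotations remapped to peptide coordinates.

    A K/R whose side chain is modified (deamidated Arg has lost the charge
    trypsin recognises) is never cleaved after: such sites are forced
    misses."""
    seq = fragment.sequence
    modified_positions = {site for site, _name, _res in fragment.mods}
    sites = cleavage_sites(seq, proline_rule)
    kept_cuts = [
        s
        for s in sites
        if s + 1 not in modified_positions and rng.random() >= missed_rate
    ]
    cuts = [0] + [s + 1 for s in kept_cuts] + [len(seq)]
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if not min_len <= b - a <= max_len:
            continue
        pep = seq[a:b]
        pep_mods = tuple(
            (site - a, name, res)
            for site, name, res in fragment.mods
            if a < site <= b
        )
        # flanking context in the parent protein (1-based fragment offsets)
        g_start = fragment.start + a  # 1-based start of peptide in protein
        g_end = fragment.start + b - 1
        preceding = protein_seq[g_start - 2] if g_start > 1 else START
        following = protein_seq[g_end] if g_end < len(protein_seq) else END
        out.append(
            {
                "sequence": pep,
                "mods": pep_mods,
                "missed": sum(1 for s in sites if a <= s < b - 1),
                "start": g_start,
                "end": g_end,
                "preceding": preceding,
                "following": following,
            }
        )
    return out


def modified_sequence_diann(stripped: str, mods) -> str:
    """DIA-NN style modified sequence with ``(UniMod:n)`` tokens after the
    affected residue."""
    by_site = sorted(mods, key=lambda m: m[0])
    parts = []
    prev = 0
    for site, name, _res in by_site:
        parts.append(stripped[prev:site])
        parts.append(f"(UniMod:{UNIMOD_IDS[name]})")
        prev = site
    parts.append(stripped[prev:])
    return "".join(parts)


def simulate_run(
    proteome: Sequence[ProteinRecord],
    profile: ProtocolProfile,
    params: DiagenesisParams | None = None,
    abundance_model: AbundanceModel | None = None,
    seed: int = 0,
    *,
    contaminants: Sequence[ProteinRecord] | None = None,
    min_len: int = 7,
    max_len: int = 30,
    proline_rule: bool = True,
    censor_quantile: float = 0.15,
    confident_fraction: float = 0.95,
    decoy_fraction: float = 0.01,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one protocol's precursor report table plus ground truth.

    Returns a DataFrame in the canonical column layout (see
    :data:`CANONICAL_COLUMNS`) and the :class:`GroundTruth` record. The
    random stream is fully determined by ``seed``: one sub-stream per
    protein (so two profiles differing only in recovery bias see identical
    damaged candidate pools under the same seed) plus dedicated streams for
    detection and noise.
    """
    if not proteome:
        raise ValueError("empty proteome")
    params = params or DiagenesisParams()
    abundance_model = abundance_model or AbundanceModel()

    proteome = sorted(proteome, key=lambda r: r.accession)
    abundances = draw_abundances(proteome, abundance_model, seed)

    root = np.random.SeedSequence([20_240_501, seed])
    n_named = 3
    children = root.spawn(len(proteome) + n_named)
    rng_detect = np.random.default_rng(children[0])
    rng_noise = np.random.default_rng(children[1])
    rng_cont = np.random.default_rng(children[2])

    candidates: list[dict] = []
    n_hydrolysis = 0
    sites_true: dict[str, int] = {"N": 0, "Q": 0, "R": 0}
    for rec, child in zip(proteome, children[n_named:]):
        rng_p = np.random.default_rng(child)
        fragments = simulate_damage(rec, params, rng_p)
        n_hydrolysis += len(fragments) - 1
        for frag in fragments:
            for _site, name, res in frag.mods:
                if name == DEAMIDATION:
                    sites_true[res] += 1
            for cand in _stochastic_digest(
                frag,
                rec.sequence,
                profile.missed_cleavage_rate,
                rng_p,
                min_len,
                max_len,
                proline_rule,
            ):
                cand["accession"] = rec.accession
                cand["contaminant"] = False
                candidates.append(cand)

    # Contaminant candidates: modern proteins, tryptic, prep-induced damage.
    cont_abund: dict[str, float] = {}
    if profile.contaminant_load > 0:
        contaminants = (
            sorted(contaminants, key=lambda r: r.accession)
            if contaminants
            else make_contaminant_proteome(seed=0)
        )
        cont_abund = {
            rec.accession: float(
                np.exp(
                    rng_cont.normal(
                        abundance_model.log_mean - 1.0, abundance_model.log_sd
                    )
                )
            )
            for rec in contaminants
        }
        for rec in contaminants:
            fragments = simulate_damage(
                rec,
                params,
                rng_cont,
                damage_scale=params.contaminant_damage_scale,
                hydrolysis=False,
            )
            for frag in fragments:
                for cand in _stochastic_digest(
                    frag,
                    rec.sequence,
                    profile.missed_cleavage_rate,
                    rng_cont,
                    min_len,
                    max_len,
                    proline_rule,
                ):
                    cand["accession"] = rec.accession
                    cand["contaminant"] = True
                    candidates.append(cand)

    if not candidates:
        raise ValueError("simulation produced no candidate peptides")

    # Recovery: softmax tilting by abundance and physicochemistry. Detection
    # probabilities are proportional to the softmax weights, clipped at 1
    # with the clipped mass redistributed (water-filling) so the expected
    # number of detections equals the requested depth.
    def _detect(pool: list[dict], expected: float) -> list[dict]:
        if not pool or expected <= 0:
            return []
        scores = np.array(
            [
                np.log(
                    abundances.get(c["accession"])
                    or cont_abund.get(c["accession"], 1.0)
                )
                + profile.bias_gravy * gravy(c["sequence"])
                + profile.bias_pi * isoelectric_point(c["sequence"])
                for c in pool
            ]
        )
        w = np.exp(scores - scores.max())
        target = min(float(expected), float(len(pool)))
        lam = target / w.sum()
        hi = lam
        for _ in range(200):
            if np.minimum(1.0, hi * w).sum() >= target - 1e-9:
                break
            hi *= 2.0
        lo = 0.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.minimum(1.0, mid * w).sum() < target:
                lo = mid
            else:
                hi = mid
        p = np.minimum(1.0, hi * w)
        keep = rng_detect.random(len(pool)) < p
        return [c for c, k in zip(pool, keep) if k]

    total_depth = profile.depth * profile.faims_gain
    endo = [c for c in candidates if not c["contaminant"]]
    cont = [c for c in candidates if c["contaminant"]]
    detected = _detect(endo, total_depth * (1 - profile.contaminant_load))
    detected += _detect(cont, total_depth * profile.contaminant_load)

    sites_detected: dict[str, int] = {"N": 0, "Q": 0, "R": 0}
    rows = []
    for cand in detected:
        acc = cand["accession"]
        abund = abundances.get(acc) or cont_abund.get(acc, 1.0)
        efficiency = float(np.exp(rng_noise.normal(-0.125, 0.5)))
        noise = float(np.exp(rng_noise.normal(0.0, 0.3)))
        intensity = abund * efficiency * noise
        u = rng_noise.random()
        q = (
            rng_noise.uniform(0.0, 0.01)
            if u < confident_fraction
            else rng_noise.uniform(0.01, 0.2)
        )
        pep_score = min(1.0, q * float(np.exp(rng_noise.normal(0.0, 0.5))))
        charge = 2 if rng_noise.random() < 0.7 else 3
        ms1 = intensity
        ms2 = intensity / (
            profile.ms1_ms2_ratio * float(np.exp(rng_noise.normal(0.0, 0.1)))
        )
        if not cand["contaminant"]:
            for _site, name, res in cand["mods"]:
                if name == DEAMIDATION:
                    sites_detected[res] += 1
        rows.append(
            {
                "run": profile.name,
                "protein_group": acc,
                "stripped_sequence": cand["sequence"],
                "modified_sequence": modified_sequence_diann(
                    cand["sequence"], cand["mods"]
                ),
                "charge": charge,
                "intensity": intensity,
                "precursor_q": q,
                "protein_group_q": np.nan,  # filled per group below
                "pep": pep_score,
                "reverse": False,
                "contaminant": cand["contaminant"],
                "ms1": ms1,
                "ms2": ms2,
                "missed_cleavages": cand["missed"],
            }
        )

    table = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)

    # Protein-group q-values: one mixture draw per group.
    pg_q = {}
    for acc in sorted(table["protein_group"].unique()):
        u = rng_noise.random()
        pg_q[acc] = (
            rng_noise.uniform(0.0, 0.01)
            if u < 0.97
            else rng_noise.uniform(0.01, 0.2)
        )
    table["protein_group_q"] = table["protein_group"].map(pg_q)

    # Decoy (reverse) rows.
    n_decoys = int(rng_noise.binomial(len(table), decoy_fraction)) if len(table) else 0
    if n_decoys:
        idx = rng_noise.choice(len(table), size=n_decoys, replace=False)
        decoys = table.iloc[sorted(idx)].copy()
        decoys["stripped_sequence"] = [
            s[::-1] for s in decoys["stripped_sequence"]
        ]
        decoys["modified_sequence"] = decoys["stripped_sequence"]
        decoys["protein_group"] = REVERSE_PREFIX + decoys[
            "protein_group"
        ].str.removeprefix(CONTAMINANT_PREFIX)
        decoys["reverse"] = True
        decoys["contaminant"] = False
        decoys["precursor_q"] = rng_noise.uniform(0.005, 0.2, size=n_decoys)
        decoys["pep"] = np.minimum(
            1.0, decoys["precursor_q"] * rng_noise.uniform(1.0, 3.0, n_decoys)
        )
        table = pd.concat([table, decoys], ignore_index=True)

    # Left-censoring: intensities below the run's lower quantile go missing.
    if len(table) and censor_quantile > 0:
        thr = table["intensity"].quantile(censor_quantile)
        table.loc[table["intensity"] < thr, ["intensity", "ms1", "ms2"]] = np.nan

    # Derived canonical columns (identical to what the readers reconstruct).
    from .report_io import parse_modified_sequence  # deferred: cyclic import

    table["leader"] = [
        g.removeprefix(REVERSE_PREFIX).removeprefix(CONTAMINANT_PREFIX)
        for g in table["protein_group"]
    ]
    parsed = [parse_modified_sequence(m) for m in table["modified_sequence"]]
    table["mods"] = [p[1] for p in parsed]
    table["mods_annotated"] = [p[2] for p in parsed]

    truth = GroundTruth(
        seed=seed,
        profile=dataclasses.asdict(profile),
        params={
            "hydrolysis_intensity": params.hydrolysis_intensity,
            "residue_propensity": dict(params.residue_propensity),
            "deamidation_site_rate": dict(params.deamidation_site_rate),
            "oxidation_rate": dict(params.oxidation_rate),
            "contaminant_damage_scale": params.contaminant_damage_scale,
        },
        abundances=abundances,
        n_hydrolysis_events=n_hydrolysis,
        deamidation_sites_true=sites_true,
        deamidation_sites_detected=sites_detected,
        n_candidates=len(candidates),
        n_detected=len(detected),
    )
    return table, truth


def simulate_experiment(
    profiles: Sequence[ProtocolProfile],
    n_proteins: int = 150,
    length_range: tuple[int, int] = (120, 400),
    params: DiagenesisParams | None = None,
    abundance_model: AbundanceModel | None = None,
    seed: int = 0,
    **run_kwargs,
) -> tuple[pd.DataFrame, dict[str, GroundTruth], list[ProteinRecord]]:
    """Simulate all protocols over one shared proteome and one shared
    abundance draw; returns the concatenated table, per-run ground truth,
    and the proteome."""
    proteome = make_toy_proteome(n_proteins, length_range, seed=seed)
    model = abundance_model or AbundanceModel()
    if model.abundances is None:
        model = dataclasses.replace(
            model, abundances=draw_abundances(proteome, model, seed)
        )
    tables, truths = [], {}
    for i, profile in enumerate(profiles):
        tbl, truth = simulate_run(
            proteome,
            profile,
            params=params,
            abundance_model=model,
            seed=seed + 1000 * (i + 1),
            **run_kwargs,
        )
        tables.append(tbl)
        truths[profile.name] = truth
    return pd.concat(tables, ignore_index=True), truths, proteome


def default_protocol_profiles() -> list[ProtocolProfile]:
    """Ten protocol profiles mirroring a typical extraction-method panel:
    urea / SDS / sodium-laurate / bead-beating lysis crossed with
    in-solution, on-filter, in-gel and on-bead clean-up. Depths are desk
    scale; recovery-bias coefficients encode the urea-extracts-hydrophobic
    and detergent-FASP-loses-hydrophobic pattern."""
    return [
        ProtocolProfile("BeatBox_iST", 2400, 0.05, -0.15, 0.12, 0.06),
        ProtocolProfile("urea_FASP", 2300, 0.25, -0.12, 0.15, 0.02),
        ProtocolProfile("urea_SPE_iST", 2100, 0.35, -0.15, 0.12, 0.05),
        ProtocolProfile("urea_SPE", 2000, 0.30, -0.15, 0.12, 0.02),
        ProtocolProfile("SDS_PAGE", 1700, 0.00, -0.05, 0.12, 0.02),
        ProtocolProfile(
            "SDS_STrap", 1500, -0.05, -0.05, 0.08, 0.02, ms1_ms2_ratio=1.57
        ),
        ProtocolProfile("BeatBox_STrap", 1450, -0.05, -0.05, 0.09, 0.08),
        ProtocolProfile(
            "SDS_FASP", 1100, -0.45, -0.12, 0.16, 0.02, ms1_ms2_ratio=1.15
        ),
        ProtocolProfile("SL_SPE", 700, -0.10, -0.15, 0.12, 0.02),
        ProtocolProfile("SP3", 250, -0.15, -0.05, 0.12, 0.02),
    ]


# ---------------------------------------------------------------------------
# Report-table writers


def _mq_mod_name(name: str, residue: str) -> str:
    if name == DEAMIDATION:
        return "Deamidation (NQ)" if residue in "NQ" else "Deamidation (R)"
    if name == OXIDATION:
        return f"Oxidation ({residue})"
    return name


def _mq_modified_sequence(stripped: str, mods) -> str:
    parts = ["_"]
    by_site = dict()
    for site, name, res in mods:
        by_site[site] = _mq_mod_name(name, res)
    for i, aa in enumerate(stripped, start=1):
        parts.append(aa)
        if i in by_site:
            parts.append(f"({by_site[i]})")
    parts.append("_")
    return "".join(parts)


def _mq_modifications_column(mods) -> str:
    if not mods:
        return "Unmodified"
    counts: dict[str, int] = {}
    for site, name, res in mods:
        label = _mq_mod_name(name, res)
        counts[label] = counts.get(label, 0) + 1
    return ", ".join(
        (f"{n} {label}" if n > 1 else label)
        for label, n in sorted(counts.items())
    )


def _parse_mods_for_mq(modified_sequence: str, stripped: str):
    # Reuse the DIA-NN token grammar to recover (site, name, residue).
    from .report_io import parse_modified_sequence

    _, mods, _ = parse_modified_sequence(modified_sequence)
    return [(m.site, m.name, stripped[m.site - 1]) for m in mods]


def write_report_tables(rows: pd.DataFrame, dialect: str, path) -> list[Path]:
    """Write a canonical precursor table in one of the supported report
    dialects. ``diann`` emits a single ``report.tsv``; ``maxquant`` emits
    ``evidence.txt`` / ``peptides.txt`` / ``proteinGroups.txt``. Shared
    fields round-trip losslessly through :mod:`paleoqc.report_io`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if dialect == "diann":
        out = pd.DataFrame(
            {
                "Run": rows["run"],
                "Protein.Group": rows["protein_group"],
                "Stripped.Sequence": rows["stripped_sequence"],
                "Modified.Sequence": rows["modified_sequence"],
                "Precursor.Charge": rows["charge"],
                "Precursor.Quantity": rows["intensity"],
                "Q.Value": rows["precursor_q"],
                "PG.Q.Value": rows["protein_group_q"],
                "PEP": rows["pep"],
                "Ms1.Area": rows["ms1"],
                "Ms2.Area": rows["ms2"],
            }
        )
        target = path / "report.tsv"
        out.to_csv(target, sep="\t", index=False)
        return [target]
    if dialect == "maxquant":
        mods = [
            _parse_mods_for_mq(m, s)
            for m, s in zip(rows["modified_sequence"], rows["stripped_sequence"])
        ]
        pep = rows["pep"].to_numpy(float)
        evidence = pd.DataFrame(
            {
                "Sequence": rows["stripped_sequence"],
                "Modified sequence": [
                    _mq_modified_sequence(s, m)
                    for s, m in zip(rows["stripped_sequence"], mods)
                ],
                "Modifications": [_mq_modifications_column(m) for m in mods],
                "Proteins": rows["protein_group"],
                "Raw file": rows["run"],
                "Charge": rows["charge"],
                "Intensity": rows["intensity"],
                "PEP": rows["pep"],
                "Score": -10.0 * np.log10(np.clip(pep, 1e-6, None)),
                "Missed cleavages": rows["missed_cleavages"],
                "Reverse": np.where(rows["reverse"], "+", ""),
                "Potential contaminant": np.where(rows["contaminant"], "+", ""),
            }
        )
        peptides = (
            evidence.groupby("Sequence", as_index=False)
            .agg(
                **{
                    "Proteins": ("Proteins", "first"),
                    "PEP": ("PEP", "min"),
                    "Intensity": ("Intensity", "sum"),
                    "Reverse": ("Reverse", "first"),
                    "Potential contaminant": ("Potential contaminant", "first"),
                }
            )
            .sort_values("Sequence")
        )
        pg = (
            rows.groupby("protein_group", as_index=False)
            .agg(
                q=("protein_group_q", "min"),
                reverse=("reverse", "any"),
                contaminant=("contaminant", "any"),
                n_pep=("stripped_sequence", "nunique"),
            )
            .sort_values("protein_group")
        )
        protein_groups = pd.DataFrame(
            {
                "Protein IDs": pg["protein_group"],
                "Majority protein IDs": pg["protein_group"],
                "Q-value": pg["q"],
                "Peptide counts (unique)": pg["n_pep"],
                "Reverse": np.where(pg["reverse"], "+", ""),
                "Potential contaminant": np.where(pg["contaminant"], "+", ""),
            }
        )
        targets = [
            path / "evidence.txt",
            path / "peptides.txt",
            path / "proteinGroups.txt",
        ]
        evidence.to_csv(targets[0], sep="\t", index=False)
        peptides.to_csv(targets[1], sep="\t", index=False)
        protein_groups.to_csv(targets[2], sep="\t", index=False)
        return targets
    raise ValueError(f"unknown report dialect: {dialect!r}")
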