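"""Terminus spectrum, deamidation accounting and protocol summaries."""

import numpy as np
import pandas as pd
import pytest

import paleoqc as pq
from paleoqc.damage_metrics import common_proteome
from paleoqc.proteome_core import ProteinRecord
from paleoqc.report_io import Mod
from paleoqc.synthetic_diagenesis import (
    DiagenesisParams,
    ProtocolProfile,
    make_toy_proteome,
    simulate_run,
)


def _rows(entries, run="r1"):
    out = []
    for e in entries:
        row = {
            "run": run,
            "protein_group": e.get("leader", "P1"),
            "leader": e.get("leader", "P1"),
            "stripped_sequence": e["seq"],
            "modified_sequence": e.get("modseq", e["seq"]),
            "mods": e.get("mods", ()),
            "charge": 2,
            "intensity": e.get("intensity", 100.0),
            "precursor_q": 0.001,
            "protein_group_q": 0.001,
            "pep": 0.001,
            "reverse": False,
            "contaminant": e.get("contaminant", False),
            "ms1": e.get("ms1", np.nan),
            "ms2": e.get("ms2", np.nan),
        }
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Terminus spectrum


def test_digest_products_are_all_tryptic(toy_db):
    peptides = [
        p.sequence for rec in toy_db.values() for p in pq.digest(rec, 2)
    ]
    rows = _rows([{"seq": s, "leader": acc} for acc in toy_db
                  for s in [p.sequence for p in pq.digest(toy_db[acc], 2)]])
    spec = pq.terminus_spectrum(rows, toy_db)
    assert spec.class_fractions["tryptic"] == pytest.approx(1.0)
    assert spec.n_unmapped == 0


def test_terminus_fixture_three_classes():
    db = {"P1": ProteinRecord("P1", "", "GGKAAARLLLFDDD")}
    # AAAR: preceded by K, ends R -> tryptic
    # LLLF: preceded by R, ends F followed by D -> semi
    # LLFD: preceded by L, ends D -> non-tryptic
    rows = _rows(
        [{"seq": "AAAR", "leader": "P1"},
         {"seq": "LLLF", "leader": "P1"},
         {"seq": "LFDD", "leader": "P1"}]
    )
    spec = pq.terminus_spectrum(rows, db)
    assert spec.class_counts == {
        "tryptic": 1,
        "semi_tryptic": 1,
        "non_tryptic": 1,
    }
    for v in spec.class_fractions.values():
        assert v == pytest.approx(1 / 3)
    # C-terminal residue spectrum over non-chain-end termini
    assert spec.cterm_residue_counts == {"R": 1, "F": 1, "D": 1}
    frame = spec.to_frame()
    assert (frame["total"] == 3).all()


def test_unmapped_peptides_counted_and_excluded(toy_db):
    rows = _rows([{"seq": "WWWWW", "leader": "P1"}])
    spec = pq.terminus_spectrum(rows, toy_db)
    assert spec.n_unmapped == 1 and spec.n_classified == 0


def test_nontryptic_fraction_monotone_in_hydrolysis():
    proteome = make_toy_proteome(60, (150, 300), seed=3)
    db = pq.as_database(proteome)
    prof = ProtocolProfile("A", depth=600, contaminant_load=0.0)
    fractions = []
    for intensity in (0.0, 1.5, 4.0):
        params = DiagenesisParams(hydrolysis_intensity=intensity)
        rows, _ = simulate_run(
            proteome, prof, params=params, seed=8, decoy_fraction=0.0
        )
        spec = pq.terminus_spectrum(rows, db)
        frac = spec.class_fractions
        fractions.append(frac["semi_tryptic"] + frac["non_tryptic"])
    assert fractions[0] == pytest.approx(0.0)
    assert fractions[0] < fractions[1] < fractions[2]


# ---------------------------------------------------------------------------
# Deamidation


def test_deamidation_percent_and_site_mix():
    entries = [{"seq": f"AAA{i}NK".replace(str(i), "G" * i)} for i in range(8)]
    entries += [
        {"seq": "CCNGK", "modseq": "CCN(UniMod:7)GK",
         "mods": (Mod(3, "Deamidation"),)},
        {"seq": "DDNGK", "modseq": "DDN(UniMod:7)GK",
         "mods": (Mod(3, "Deamidation"),)},
    ]
    summary = pq.deamidation_accounting(_rows(entries))
    endo = summary.endogenous
    assert endo.n_peptides == 10 and endo.n_deamidated == 2
    assert endo.pct_deamidated == pytest.approx(20.0)
    assert endo.site_mix == {"N": 1.0}


def test_deamidation_peptide_vs_site_units():
    rows = _rows(
        [{"seq": "ANQGK", "modseq": "AN(UniMod:7)Q(UniMod:7)GK",
          "mods": (Mod(2, "Deamidation"), Mod(3, "Deamidation"))}]
    )
    endo = pq.deamidation_accounting(rows).endogenous
    assert endo.n_deamidated == 1
    assert sum(endo.site_counts.values()) == 2


def test_deamidation_on_invalid_residue_errors():
    rows = _rows([{"seq": "AAAGK", "mods": (Mod(1, "Deamidation"),)}])
    with pytest.raises(ValueError, match="only N/Q/R"):
        pq.deamidation_accounting(rows)


def test_deamidation_separates_contaminants():
    rows = _rows(
        [
            {"seq": "ANGGK", "mods": (Mod(2, "Deamidation"),)},
            {"seq": "CCGGK", "contaminant": True},
        ]
    )
    summary = pq.deamidation_accounting(rows)
    assert summary.endogenous.pct_deamidated == pytest.approx(100.0)
    assert summary.contaminant.pct_deamidated == pytest.approx(0.0)


def test_site_mix_recovery_on_equal_opportunity_substrate():
    """With equal numbers of N/Q/R sites, per-site rates proportional to
    (0.514, 0.302, 0.183) must reproduce that mix of observed deamidation
    sites within the binomial 95% interval."""
    seq = ("NAGQAGRAG" * 40)  # equal N/Q/R counts
    rec = ProteinRecord("P1", "", seq)
    params = DiagenesisParams(
        hydrolysis_intensity=0.0,
        deamidation_site_rate={"N": 0.514, "Q": 0.302, "R": 0.183},
        oxidation_rate={"M": 0.0, "P": 0.0},
    )
    from paleoqc.synthetic_diagenesis import simulate_damage

    rng = np.random.default_rng(77)
    counts = {"N": 0, "Q": 0, "R": 0}
    for _ in range(60):
        (frag,) = simulate_damage(rec, params, rng)
        for _s, name, res in frag.mods:
            if name == "Deamidation":
                counts[res] += 1
    total = sum(counts.values())
    expected = {k: v / 0.999 for k, v in
                {"N": 0.514, "Q": 0.302, "R": 0.183}.items()}
    for res, p in expected.items():
        se = np.sqrt(p * (1 - p) / total)
        assert abs(counts[res] / total - p) < 1.96 * se + 1e-9


# ---------------------------------------------------------------------------
# Signal ratio and physicochemistry


def test_ms_signal_ratio_examples():
    rows = _rows([{"seq": "AAAK", "ms1": 100.0, "ms2": 50.0}])
    assert pq.ms_signal_ratio(rows).iloc[0] == pytest.approx(2.0)
    rows = _rows([{"seq": "AAAK", "ms1": 70.0, "ms2": 70.0}])
    assert pq.ms_signal_ratio(rows).iloc[0] == pytest.approx(1.0)
    scaled = rows.assign(ms1=rows["ms1"] * 7, ms2=rows["ms2"] * 7)
    assert pq.ms_signal_ratio(scaled).iloc[0] == pytest.approx(1.0)


def test_ms_signal_ratio_unavailable_and_zero():
    rows = _rows([{"seq": "AAAK"}])
    assert pq.ms_signal_ratio(rows) is None
    rows = _rows([{"seq": "AAAK", "ms1": 5.0, "ms2": 0.0}])
    with pytest.raises(ValueError, match="MS2"):
        pq.ms_signal_ratio(rows)


def test_physchem_percent_hydrophobic():
    rows = _rows([{"seq": "AA"}, {"seq": "KK"}])
    (summary,) = pq.physchem_profile(rows, level="peptide").values()
    assert summary.pct_hydrophobic == pytest.approx(50.0)
    assert summary.n == 2


def test_common_proteome_full_overlap_and_error():
    rows = pd.concat(
        [_rows([{"seq": "AAAK", "leader": "P1"}], run="r1"),
         _rows([{"seq": "AAAK", "leader": "P1"}], run="r2")]
    )
    assert common_proteome(rows) == {"P1"}
    disjoint = pd.concat(
        [_rows([{"seq": "AAAK", "leader": "P1"}], run="r1"),
         _rows([{"seq": "CCCK", "leader": "P2"}], run="r2")]
    )
    with pytest.raises(ValueError, match="presence|counts|empty"):
        common_proteome(disjoint)


def test_simulated_gravy_bias_ordering(sim_experiment):
    summaries = pq.physchem_profile(sim_experiment["filtered"], "peptide")
    means = {k: v.gravy_mean for k, v in summaries.items()}
    assert means["bias_neg"] < means["bias_zero"] < means["bias_pos"]


# ---------------------------------------------------------------------------
# Aggregate summary


def test_summary_consistent_with_individual_ops(toy_db):
    rows = _rows(
        [
            {"seq": "AK", "leader": "P1", "ms1": 100.0, "ms2": 50.0},
            {"seq": "RPGK", "leader": "P1", "ms1": 60.0, "ms2": 30.0},
        ]
    )
    summary = pq.summarize_protocol(rows, toy_db)
    assert summary.n_precursors == 2 and summary.n_proteins == 1
    assert summary.ms1_ms2_ratio == pytest.approx(2.0)
    assert summary.terminus.class_fractions["tryptic"] == pytest.approx(1.0)
    expected_mc = np.mean(
        [pq.count_missed_cleavages(s) for s in rows["stripped_sequence"]]
    )
    assert summary.mean_missed_cleavages == pytest.approx(expected_mc)
    # coverage: AK (1-2) + RPGK (3-6) on a 6-residue protein = 100%
    assert summary.coverage_mean == pytest.approx(100.0)


def test_summary_empty_input(toy_db):
    summary = pq.summarize_protocol(_rows([]).iloc[:0], toy_db)
    assert summary.empty and summary.n_precursors == 0


def test_summaries_partition_by_label(toy_db):
    r1 = _rows([{"seq": "AK", "leader": "P1"}], run="r1")
    r2 = _rows([{"seq": "RPGK", "leader": "P1"}], run="r2")
    both = pq.summarize_experiment(pd.concat([r1, r2]), toy_db)
    solo1 = pq.summarize_protocol(r1, toy_db).to_row()
    solo2 = pq.summarize_protocol(r2, toy_db).to_row()
    assert len(both) == 2
    by_label = {row["protocol"]: row for row in both.to_dict("records")}
    for key in ("n_precursors", "n_peptides", "mean_missed_cleavages"):
        assert by_label["r1"][key] == solo1[key]
        assert by_label["r2"][key] == solo2[key]
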