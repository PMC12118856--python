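"""End-to-end orchestration: simulate (optional) -> read & filter -> QC ->
quantify -> compare -> contamination, each stage writing TSV artifacts and
an entry in a machine-readable run log.

Every percentage written to an artifact carries its numerator and
denominator columns, so downstream checks are plain arithmetic on the
artifact. Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare_stats, damage_metrics, quant_profile, report_io
from . import synthetic_diagenesis as synth
from .config import PipelineConfig, dump_effective_config
from .proteome_core import as_database, read_fasta
from .util import file_sha256, percentage

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log_stage(log: list, stage: str, params: dict, inputs: list, **counts):
    # basenames keep the log identical across relocated output directories
    log.append(
        {
            "stage": stage,
            "params": params,
            "inputs": {Path(p).name: file_sha256(p) for p in inputs},
            **counts,
        }
    )


def _stage(log, name):
    """Decorator-free stage wrapper: run `fn` and convert failures."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _serialize_rows(rows: pd.DataFrame, path: Path) -> None:
    out = rows.drop(columns=["mods", "mods_annotated"], errors="ignore")
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_effective_config(config, out / "effective_config.yaml")
    log: list[dict] = []

    fasta_path = config.fasta
    report_path = config.report

    # -- simulate -----------------------------------------------------------
    if config.simulate is not None:
        with _stage(log, "simulate"):
            sim = config.simulate
            profiles = (
                [
                    synth.ProtocolProfile(**p.model_dump())
                    for p in sim.protocols
                ]
                if sim.protocols
                else synth.default_protocol_profiles()
            )
            params = synth.DiagenesisParams(
                hydrolysis_intensity=sim.diagenesis.hydrolysis_intensity,
                deamidation_site_rate=sim.diagenesis.deamidation_site_rate,
                oxidation_rate=sim.diagenesis.oxidation_rate,
                contaminant_damage_scale=sim.diagenesis.contaminant_damage_scale,
            )
            model = synth.AbundanceModel(
                sim.abundance_log_mean, sim.abundance_log_sd
            )
            table, truths, proteome = synth.simulate_experiment(
                profiles,
                n_proteins=sim.n_proteins,
                length_range=(sim.length_min, sim.length_max),
                params=params,
                abundance_model=model,
                seed=config.seed,
                min_len=config.digestion.min_len,
                max_len=config.digestion.max_len,
                proline_rule=config.digestion.proline_rule,
                censor_quantile=sim.censor_quantile,
            )
            fasta_path = out / "proteome.fasta"
            synth.write_fasta(
                proteome + synth.make_contaminant_proteome(seed=0), fasta_path
            )
            written = synth.write_report_tables(table, config.dialect, out)
            report_path = written[0]
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(
                    {k: dataclasses.asdict(v) for k, v in truths.items()},
                    fh,
                    indent=1,
                    sort_keys=True,
                )
            _log_stage(
                log,
                "simulate",
                {"seed": config.seed, "n_proteins": sim.n_proteins},
                [fasta_path, *written],
                n_rows=len(table),
            )

    if fasta_path is None or report_path is None:
        raise StageError(
            "read", ValueError("config must provide fasta+report or simulate")
        )

    # -- read & filter ------------------------------------------------------
    with _stage(log, "read_filter"):
        database = as_database(read_fasta(fasta_path))
        if config.dialect == "diann":
            rows = report_io.read_diann_report(report_path)
        else:
            parent = Path(report_path).parent
            rows, _ = report_io.read_maxquant_tables(
                report_path,
                proteingroups_path=(
                    parent / "proteinGroups.txt"
                    if (parent / "proteinGroups.txt").exists()
                    else None
                ),
            )
        policy = report_io.FilterPolicy(
            precursor_q=config.filters.precursor_q,
            protein_group_q=config.filters.protein_group_q,
            pep=config.filters.pep,
            min_unique_peptides=config.filters.min_unique_peptides,
            remove_reverse=config.filters.remove_reverse,
            remove_contaminants=config.filters.remove_contaminants,
            per_protocol=config.filters.per_protocol,
        )
        filtered, freport = report_io.apply_identification_filters(rows, policy)
        # Contaminant rows pass the confidence thresholds separately so the
        # deamidation and risk stages can still see them.
        keep_cont = report_io.FilterPolicy(
            precursor_q=config.filters.precursor_q,
            protein_group_q=config.filters.protein_group_q,
            pep=config.filters.pep,
            min_unique_peptides=1,
            remove_reverse=True,
            remove_contaminants=False,
            per_protocol=config.filters.per_protocol,
        )
        with_contaminants, _ = report_io.apply_identification_filters(
            rows, keep_cont
        )
        _serialize_rows(filtered, out / "filtered.tsv")
        freport.to_frame().to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
        _log_stage(
            log,
            "read_filter",
            {"policy": dataclasses.asdict(policy)},
            [report_path],
            n_rows_in=len(rows),
            n_rows_out=len(filtered),
        )

    # -- qc (damage metrics) ------------------------------------------------
    with _stage(log, "qc"):
        metrics = damage_metrics.summarize_experiment(
            filtered, database, config.digestion.proline_rule
        )
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        spectrum = damage_metrics.terminus_spectrum(
            filtered, database, config.digestion.proline_rule
        )
        spectrum.to_frame().to_csv(out / "terminus.tsv", sep="\t", index=False)
        term_classes = pd.DataFrame(
            [
                {
                    "class": cls,
                    "count": n,
                    "total": spectrum.n_classified,
                    "pct": percentage(n, spectrum.n_classified)
                    if spectrum.n_classified
                    else None,
                }
                for cls, n in sorted(spectrum.class_counts.items())
            ]
        )
        term_classes.to_csv(
            out / "terminus_classes.tsv", sep="\t", index=False
        )
        deam = damage_metrics.deamidation_accounting(with_contaminants)
        deam.to_frame().to_csv(out / "deamidation.tsv", sep="\t", index=False)
        _log_stage(
            log,
            "qc",
            {"proline_rule": config.digestion.proline_rule},
            [out / "filtered.tsv"],
            n_protocols=len(metrics),
        )

    # -- quant --------------------------------------------------------------
    with _stage(log, "quant"):
        ibaq = quant_profile.compute_ibaq(
            filtered,
            database,
            bounds=(config.digestion.min_len, config.digestion.max_len),
            proline_rule=config.digestion.proline_rule,
        )
        ibaq.data.to_csv(out / "ibaq_raw.tsv", sep="\t")
        z = quant_profile.zscore_columns(
            quant_profile.impute_qrilc(
                quant_profile.log2_transform(ibaq),
                quantile=config.imputation.quantile,
                seed=config.seed,
            )
        )
        z.data.to_csv(out / "matrix_z.tsv", sep="\t")
        share = pd.DataFrame(
            [
                {
                    "protocol": col,
                    "n_z_gt0": int((z.data[col] > 0).sum()),
                    "n_total": len(z.data),
                    "pct_z_gt0": percentage((z.data[col] > 0).sum(), len(z.data)),
                }
                for col in z.data.columns
            ]
        )
        share.to_csv(out / "z_share.tsv", sep="\t", index=False)
        quant_profile.correlation_matrix(z).to_csv(
            out / "correlation.tsv", sep="\t"
        )
        quant_profile.intersection_counts(
            quant_profile.presence_sets(filtered)
        ).to_csv(out / "intersections.tsv", sep="\t", index=False)
        coords, stress = quant_profile.metric_mds(z, metric="manhattan")
        coords.assign(stress=stress).to_csv(out / "mds.tsv", sep="\t")
        if z.data.shape[1] >= 2:
            cols = quant_profile.hierarchical_cluster(
                z, axis="columns", metric="euclidean", linkage="complete"
            )
            pd.DataFrame(
                cols.linkage, columns=["left", "right", "height", "size"]
            ).to_csv(out / "column_linkage.tsv", sep="\t", index=False)
        _log_stage(
            log,
            "quant",
            {
                "bounds": [config.digestion.min_len, config.digestion.max_len],
                "imputation_quantile": config.imputation.quantile,
                "seed": config.seed,
            },
            [out / "filtered.tsv"],
            n_proteins=len(z.data),
            n_protocols=z.data.shape[1],
        )

    # -- compare ------------------------------------------------------------
    with _stage(log, "compare"):
        table = compare_stats.peptide_response_table(
            filtered, database, response=config.lmm.response
        )
        checks = compare_stats.distribution_checks(
            table[config.lmm.response], table["protocol"]
        )
        pd.DataFrame([dataclasses.asdict(c) for c in checks]).to_csv(
            out / "distribution_checks.tsv", sep="\t", index=False
        )
        lmm = compare_stats.fit_protocol_lmm(table, config.lmm.response)
        lmm.contrasts_frame().to_csv(
            out / "contrasts.tsv", sep="\t", index=False
        )
        pd.Series(lmm.effects, name="effect").rename_axis("protocol").to_csv(
            out / "effects.tsv", sep="\t"
        )
        _log_stage(
            log,
            "compare",
            {"response": config.lmm.response, "family": lmm.contrasts[0].family_size},
            [out / "filtered.tsv"],
            n_obs=lmm.n_obs,
            singular=lmm.singular,
        )

    # -- contamination ------------------------------------------------------
    with _stage(log, "contamination"):
        cont_rows = with_contaminants[with_contaminants["contaminant"]]
        if cont_rows.empty:
            logger.info("no contaminant rows; contamination stage skipped")
            (out / "risk.tsv").write_text("contaminant\n")
        else:
            abundance = (
                cont_rows.dropna(subset=["intensity"])
                .groupby(["leader", "run"])["intensity"]
                .sum()
                .unstack("run")
                .fillna(0.0)
            )
            total = (
                with_contaminants.dropna(subset=["intensity"])
                .groupby("run")["intensity"]
                .sum()
            )
            abundance.to_csv(out / "contaminant_abundance.tsv", sep="\t")
            risk = compare_stats.contamination_risk(
                abundance,
                thresholds=config.risk.thresholds,
                total_signal=total,
            )
            risk.levels.to_csv(out / "risk.tsv", sep="\t")
            risk.global_level.rename("global_risk").rename_axis("protocol").to_csv(
                out / "risk_global.tsv", sep="\t"
            )
        _log_stage(
            log,
            "contamination",
            {"thresholds": list(config.risk.thresholds)},
            [],
            n_contaminant_rows=len(cont_rows),
        )

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Report rendering


REPORT_ARTIFACTS = {
    "intersections": "intersections.tsv",
    "heatmap": "matrix_z.tsv",
    "correlation": "correlation.tsv",
    "mds": "mds.tsv",
    "metrics": "metrics.tsv",
    "deamidation": "deamidation.tsv",
    "physchem": "metrics.tsv",
    "contamination": "risk.tsv",
}


def render_report(out_dir) -> dict[str, list[str]]:
    """Render basic figures + a summary document from pipeline artifacts.

    Missing artifacts are listed by name in the returned dict and noted in
    the summary; available panels are still produced.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = out / "report"
    fig_dir.mkdir(exist_ok=True)
    produced: list[str] = []
    missing: list[str] = []

    def _have(name: str) -> Path | None:
        path = out / REPORT_ARTIFACTS[name]
        if not path.exists():
            missing.append(REPORT_ARTIFACTS[name])
            return None
        return path

    def _save(fig, name: str) -> None:
        fig.savefig(fig_dir / name, dpi=110)
        plt.close(fig)
        produced.append(name)

    if (p := _have("intersections")) is not None:
        tab = pd.read_csv(p, sep="\t").nlargest(15, "count")
        fig, ax = plt.subplots(figsize=(8, 4))
        if len(tab):
            ax.bar(range(len(tab)), tab["count"])
            ax.set_xticks(range(len(tab)))
            ax.set_xticklabels(tab["protocols"], rotation=90, fontsize=6)
        else:
            ax.text(0.5, 0.5, "no data", ha="center")
        ax.set_ylabel("proteins (exclusive)")
        fig.tight_layout()
        _save(fig, "intersections.png")

    if (p := _have("heatmap")) is not None:
        z = pd.read_csv(p, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 6))
        if z.size:
            im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r")
            fig.colorbar(im, ax=ax, label="z-score")
            ax.set_xticks(range(z.shape[1]))
            ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
        else:
            ax.text(0.5, 0.5, "no data", ha="center")
        ax.set_ylabel("protein")
        fig.tight_layout()
        _save(fig, "heatmap.png")

    if (p := _have("correlation")) is not None:
        corr = pd.read_csv(p, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="viridis")
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_xticks(range(corr.shape[1]))
        ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(corr.shape[0]))
        ax.set_yticklabels(corr.index, fontsize=6)
        fig.tight_layout()
        _save(fig, "correlation.png")

    if (p := _have("mds")) is not None:
        coords = pd.read_csv(p, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 5))
        if {"dim1", "dim2"} <= set(coords.columns):
            ax.scatter(coords["dim1"], coords["dim2"])
            for name, row in coords.iterrows():
                ax.annotate(str(name), (row["dim1"], row["dim2"]), fontsize=6)
        ax.set_xlabel("dim1")
        ax.set_ylabel("dim2")
        fig.tight_layout()
        _save(fig, "mds.png")

    if (p := _have("metrics")) is not None:
        m = pd.read_csv(p, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        if len(m):
            axes[0].bar(m["protocol"], m["mean_missed_cleavages"])
            axes[0].set_ylabel("mean missed cleavages")
            axes[1].bar(m["protocol"], m["ms1_ms2_ratio"])
            axes[1].set_ylabel("MS1/MS2 ratio")
            for ax in axes:
                ax.tick_params(axis="x", rotation=90, labelsize=6)
        else:
            axes[0].text(0.5, 0.5, "no data", ha="center")
        fig.tight_layout()
        _save(fig, "efficiency.png")

        fig, ax = plt.subplots(figsize=(6, 3.5))
        if len(m) and "gravy_mean" in m:
            ax.errorbar(
                m["protocol"], m["gravy_mean"], yerr=m["gravy_sd"], fmt="o"
            )
            ax.set_ylabel("mean peptide GRAVY")
            ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        _save(fig, "gravy.png")

    if (p := _have("deamidation")) is not None:
        d = pd.read_csv(p, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        if len(d):
            ax.bar(d["origin"], d["pct_deamidated"].fillna(0.0))
            ax.set_ylabel("% deamidated peptides")
        fig.tight_layout()
        _save(fig, "deamidation.png")

    if (p := _have("contamination")) is not None:
        r = pd.read_csv(p, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 4))
        if r.size:
            im = ax.imshow(r.to_numpy(), vmin=1, vmax=5, cmap="YlOrRd")
            fig.colorbar(im, ax=ax, label="risk level")
            ax.set_xticks(range(r.shape[1]))
            ax.set_xticklabels(r.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(r.shape[0]))
            ax.set_yticklabels(r.index, fontsize=6)
        else:
            ax.text(0.5, 0.5, "no data", ha="center")
        fig.tight_layout()
        _save(fig, "contamination.png")

    lines = ["# Protocol comparison report", ""]
    lines += [f"- produced: {name}" for name in produced]
    if missing:
        lines.append("")
        lines += [f"- missing artifact: {name}" for name in sorted(set(missing))]
    (fig_dir / "summary.md").write_text("\n".join(lines) + "\n")
    return {"produced": produced, "missing": sorted(set(missing))}
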