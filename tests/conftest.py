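import pandas as pd
import pytest

import paleoqc as pq
from paleoqc.synthetic_diagenesis import (
    ProtocolProfile,
    simulate_experiment,
    write_report_tables,
)


@pytest.fixture(scope="session")
def toy_db():
    records = [
        pq.ProteinRecord("P1", "P1 toy", "AKRPGK"),
        pq.ProteinRecord("P2", "P2 toy", "MLEKGGRAADDKLF"),
        pq.ProteinRecord("P3", "P3 toy", "AAAA"),
    ]
    return pq.as_database(records)


@pytest.fixture(scope="session")
def sim_experiment(tmp_path_factory):
    """One shared small simulated experiment: 4 protocols with distinct
    hydropathy-recovery biases, round-tripped through the DIA-NN dialect."""
    profiles = [
        ProtocolProfile("bias_neg", depth=500, bias_gravy=-0.4, contaminant_load=0.03),
        ProtocolProfile("bias_zero", depth=500, bias_gravy=0.0, contaminant_load=0.03),
        ProtocolProfile("bias_pos", depth=500, bias_gravy=0.4, contaminant_load=0.03),
        ProtocolProfile("shallow", depth=150, bias_gravy=0.0, contaminant_load=0.08),
    ]
    table, truths, proteome = simulate_experiment(profiles, n_proteins=80, seed=11)
    out = tmp_path_factory.mktemp("sim")
    (path,) = write_report_tables(table, "diann", out)
    rows = pq.read_diann_report(path)
    database = pq.as_database(proteome)
    filtered, report = pq.apply_identification_filters(rows)
    return {
        "table": table,
        "truths": truths,
        "proteome": proteome,
        "database": database,
        "rows": rows,
        "filtered": filtered,
        "filter_report": report,
        "report_path": path,
    }
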