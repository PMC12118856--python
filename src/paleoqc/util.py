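"""Small shared helpers: packaged data tables, percentages, file hashing."""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage of ``numerator`` in ``denominator``, rounded for printing.

    Every percentage the pipeline writes is accompanied by its numerator and
    denominator so the reported value is always re-derivable as
    ``percentage(n, d)``. Rounds half-to-even at ``ndigits`` decimals (the
    convention of Python's :func:`round`).
    """
    if denominator == 0:
        raise ValueError("percentage undefined for zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def load_data_table(name: str) -> pd.DataFrame:
    """Load one of the TSV tables shipped under ``paleoqc/data``."""
    ref = resources.files("paleoqc.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
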