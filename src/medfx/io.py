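"""Tabular result writers: lossless round-tripping CSV/TSV with NA sentinels."""

from __future__ import annotations

import pandas as pd

__all__ = ["write_results", "read_results", "NA_TOKEN"]

#: Sentinel used for undefined metric values in all delimited outputs.
NA_TOKEN = "NA"

_SEPS = {"csv": ",", "tsv": "\t"}


def write_results(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a results table as CSV or TSV.

    Floats are written with ``repr`` precision so a read-back reproduces them
    bit for bit; undefined values are serialized as ``"NA"``.  Writing an
    empty table is an error (it always indicates an upstream bug).
    """
    if format not in _SEPS:
        raise ValueError("format must be 'csv' or 'tsv'")
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(path, sep=_SEPS[format], index=False, na_rep=NA_TOKEN)


def read_results(path, format: str = "csv") -> pd.DataFrame:
    """Read a table written by :func:`write_results`; "NA" becomes NaN."""
    if format not in _SEPS:
        raise ValueError("format must be 'csv' or 'tsv'")
    return pd.read_csv(
        path, sep=_SEPS[format], na_values=[NA_TOKEN], keep_default_na=False
    )
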