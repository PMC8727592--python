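"""Reading and writing the plain tabular formats used by the pipeline.

All matrices travel as delimited text with probes as rows and a sample-id
header; comma is the default delimiter and tab is accepted via ``sep``.
Missing values are accepted as empty cells or ``NA`` on read and written as
``NA``.
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    SCALE_FRACTION,
    SCALE_PERCENT,
    BetaMatrix,
    DetectionPMatrix,
    ParseError,
    ProbeAnnotation,
    ProportionTable,
    SampleSheet,
    ValidationError,
)

_NA_VALUES = ("", "NA")


def _read_numeric_matrix(path: os.PathLike | str, sep: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    masked = raw.replace(dict.fromkeys(_NA_VALUES, np.nan))
    numeric = masked.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & masked.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {raw.iat[i, j]!r} at probe {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    return numeric


def read_beta_matrix(path: os.PathLike | str, sep: str = ",") -> BetaMatrix:
    """Read a probes x samples beta-value matrix; values validated to [0, 1]."""
    return BetaMatrix(_read_numeric_matrix(path, sep))


def write_beta_matrix(beta: BetaMatrix, path: os.PathLike | str, sep: str = ",") -> None:
    beta.data.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def read_detection_p_matrix(path: os.PathLike | str, sep: str = ",") -> DetectionPMatrix:
    return DetectionPMatrix(_read_numeric_matrix(path, sep))


def write_detection_p_matrix(
    detp: DetectionPMatrix, path: os.PathLike | str, sep: str = ","
) -> None:
    detp.data.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def read_sample_sheet(path: os.PathLike | str, sep: str = ",") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "batch": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: os.PathLike | str, sep: str = ",") -> None:
    sheet.data.to_csv(path, sep=sep, index=False, na_rep="")


def read_probe_annotation(path: os.PathLike | str, sep: str = ",") -> ProbeAnnotation:
    df = pd.read_csv(path, sep=sep)
    if "probe_id" not in df.columns:
        raise ParseError(f"probe annotation {path} lacks a probe_id column")
    for flag in ProbeAnnotation.FLAGS:
        if flag in df.columns:
            df[flag] = (
                df[flag]
                .astype(str)
                .str.strip()
                .str.lower()
                .isin({"1", "true", "t", "yes"})
            )
    return ProbeAnnotation(df)


def write_probe_annotation(
    ann: ProbeAnnotation, path: os.PathLike | str, sep: str = ","
) -> None:
    ann.data.to_csv(path, sep=sep, index_label="probe_id", na_rep="")


def read_probe_list(path: os.PathLike | str) -> set[str]:
    """Read a plain-text probe list: one id per line, ``#`` comments ignored."""
    probes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                probes.add(line)
    return probes


def write_probe_list(probes: Iterable[str], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for p in sorted(set(probes)):
            fh.write(f"{p}\n")


def read_proportions(
    path: os.PathLike | str, scale: str = SCALE_FRACTION, sep: str = ","
) -> ProportionTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ProportionTable(df, scale=scale)


def write_proportions(
    table: ProportionTable,
    path: os.PathLike | str,
    scale: str = SCALE_FRACTION,
    sep: str = ",",
) -> None:
    """Write samples x cell types proportions on the requested scale."""
    if scale == SCALE_FRACTION:
        out = table.as_fraction()
    elif scale == SCALE_PERCENT:
        out = table.as_percent()
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    out.data.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")
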