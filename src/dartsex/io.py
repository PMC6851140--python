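"""Readers and writers for the pipeline's on-disk dialect.

The canonical dialect is plain UTF-8 CSV with a single header row and the
metadata columns first, replacing DArT's proprietary multi-header exports:

* SNP table:  ``locus_id,ref_seq,alt_seq,call_rate,reproducibility,<sample...>``
* PA table:   ``locus_id,sequence,call_rate,reproducibility,<sample...>``
* Sex registry: ``sample_id,sex[,site]`` with sex in {M, F, U}, any case.

Cell tokens are exact strings ("0"/"1"/"2"/"-" for SNP calls, "1"/"0"/"-"
for presence/absence); surrounding whitespace is trimmed, nothing is
coerced numerically.  Row and column order are preserved, so
``read . write`` and ``write . read`` are identities.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import (
    PA_CALL_TO_TOKEN,
    PA_TOKEN_TO_CALL,
    SEX_CODES,
    SNP_CALL_TO_TOKEN,
    SNP_TOKEN_TO_CALL,
)
from .matrices import PresenceMatrix, SexRegistry, SnpMatrix

__all__ = [
    "read_snp_table",
    "read_pa_table",
    "read_sex_registry",
    "write_snp_table",
    "write_pa_table",
    "write_sex_registry",
]

SNP_META_COLUMNS = ["locus_id", "ref_seq", "alt_seq", "call_rate", "reproducibility"]
PA_META_COLUMNS = ["locus_id", "sequence", "call_rate", "reproducibility"]


class TableFormatError(ValueError):
    """Raised when an input table violates the dialect."""


def _read_table(path, meta_columns: list[str]) -> tuple[pd.DataFrame, list[str]]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise TableFormatError(f"{path}: empty table")
    stripped = [c.strip() for c in header]
    dupes = {c for c in stripped if stripped.count(c) > 1}
    if dupes:  # pandas would silently rename these
        raise TableFormatError(f"{path}: duplicate column id(s): {sorted(dupes)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in meta_columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in meta_columns]
    if not sample_cols:
        raise TableFormatError(f"{path}: no sample columns found")
    return df, sample_cols


def _parse_calls(df, sample_cols, token_map, locus_ids, path) -> np.ndarray:
    calls = np.empty((len(df), len(sample_cols)), dtype=np.int8)
    codes = {tok: int(call) for tok, call in token_map.items()}
    for j, col in enumerate(sample_cols):
        tokens = df[col].astype(str).str.strip()
        mapped = tokens.map(codes)
        if mapped.isna().any():
            i = int(np.nonzero(mapped.isna().to_numpy())[0][0])
            raise TableFormatError(
                f"{path}: unknown call token {tokens.iloc[i]!r} at locus "
                f"{locus_ids[i]!r}, sample {col!r}"
            )
        calls[:, j] = mapped.to_numpy(dtype=np.int8)
    return calls


def _parse_fraction(df, column, path) -> np.ndarray:
    try:
        values = df[column].astype(float).to_numpy()
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric {column}: {exc}") from None
    return values


def read_snp_table(path) -> SnpMatrix:
    """Read a SNP genotype table in the canonical dialect.

    Raises :class:`TableFormatError` on an unknown cell token (naming the
    locus, sample and token), a duplicate locus/sample id, or a missing
    metadata column.
    """
    df, sample_cols = _read_table(path, SNP_META_COLUMNS)
    locus_ids = [str(x).strip() for x in df["locus_id"]]
    calls = _parse_calls(df, sample_cols, SNP_TOKEN_TO_CALL, locus_ids, path)
    return SnpMatrix(
        locus_ids,
        sample_cols,
        calls,
        ref_seq=[str(x).strip() for x in df["ref_seq"]],
        alt_seq=[str(x).strip() for x in df["alt_seq"]],
        call_rate=_parse_fraction(df, "call_rate", path),
        reproducibility=_parse_fraction(df, "reproducibility", path),
    )


def read_pa_table(path) -> PresenceMatrix:
    """Read a SilicoDArT presence/absence table in the canonical dialect."""
    df, sample_cols = _read_table(path, PA_META_COLUMNS)
    locus_ids = [str(x).strip() for x in df["locus_id"]]
    calls = _parse_calls(df, sample_cols, PA_TOKEN_TO_CALL, locus_ids, path)
    return PresenceMatrix(
        locus_ids,
        sample_cols,
        calls,
        sequence=[str(x).strip() for x in df["sequence"]],
        call_rate=_parse_fraction(df, "call_rate", path),
        reproducibility=_parse_fraction(df, "reproducibility", path),
    )


def read_sex_registry(path) -> SexRegistry:
    """Read a ``sample_id,sex[,site]`` file; sex codes are case-insensitive."""
    path = Path(path)
    sexes: dict[str, str] = {}
    sites: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise TableFormatError(f"{path}: empty sex registry")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["sample_id", "sex"]:
            raise TableFormatError(
                f"{path}: header must start with 'sample_id,sex', got {header}"
            )
        has_site = len(header) > 2 and header[2] == "site"
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            sample = row[0].strip()
            sex = row[1].strip().upper() if len(row) > 1 else ""
            if sex not in SEX_CODES:
                raise TableFormatError(
                    f"{path}: line {lineno}: invalid sex token {row[1]!r} "
                    f"for sample {sample!r} (expected M, F or U)"
                )
            if sample in sexes:
                raise TableFormatError(
                    f"{path}: line {lineno}: duplicate sample id {sample!r}"
                )
            sexes[sample] = sex
            if has_site and len(row) > 2 and row[2].strip():
                sites[sample] = row[2].strip()
    return SexRegistry(sexes, sites)


def _format_fraction(x: float) -> str:
    return repr(float(x))


def write_snp_table(matrix: SnpMatrix, path) -> None:
    """Write a SNP table re-readable to an equal matrix (bit-exact tokens)."""
    _write_call_table(
        matrix,
        path,
        SNP_META_COLUMNS,
        {"ref_seq": matrix.ref_seq, "alt_seq": matrix.alt_seq},
        SNP_CALL_TO_TOKEN,
    )


def write_pa_table(matrix: PresenceMatrix, path) -> None:
    """Write a presence/absence table (inverse of :func:`read_pa_table`)."""
    _write_call_table(
        matrix, path, PA_META_COLUMNS, {"sequence": matrix.sequence}, PA_CALL_TO_TOKEN
    )


def _write_call_table(matrix, path, meta_columns, seq_meta, token_map) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(meta_columns + list(matrix.sample_ids))
        for i, locus in enumerate(matrix.locus_ids):
            meta = [locus]
            meta += [str(seq_meta[c][i]) for c in meta_columns[1:-2]]
            meta += [
                _format_fraction(matrix.call_rate[i]),
                _format_fraction(matrix.reproducibility[i]),
            ]
            tokens = [token_map[int(c)] for c in matrix.calls[i]]
            writer.writerow(meta + tokens)


def write_sex_registry(registry: SexRegistry, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "sex", "site"])
        for sample, sex in registry.items():
            writer.writerow([sample, sex, registry.site_of(sample) or ""])
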