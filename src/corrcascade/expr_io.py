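"""Expression-matrix I/O and probe/gene bookkeeping.

The expression matrix is a plain :class:`pandas.DataFrame` with probe (or
gene-symbol) row index and sample-id columns, log2-scale values assumed.
Sample group labels are a :class:`pandas.Series` mapping sample id -> group
(``tumor`` / ``normal`` by default, any binary labelling accepted).  Probe
annotations map probe id -> gene symbol (many-to-one; unannotated probes map
to missing).

The on-disk formats are GEO Series Matrix text (metadata lines prefixed
``!``, a tab-separated table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``) and two-column TSVs for sample sheets and probe
annotations.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_series_matrix",
    "write_series_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "map_probes",
    "subset_samples",
    "validate_expression",
]

#: default regexes used to turn sample characteristics into group labels
DEFAULT_LABEL_PATTERNS: dict[str, str] = {
    "normal": r"\bnon[- _]?tumor\b|\bnormal\b",
    "tumor": r"\btumor\b|\bcancer\b|\bcarcinoma\b",
}


def _unquote(tok: str) -> str:
    return tok.strip().strip('"')


def validate_expression(expr: pd.DataFrame, *, drop_missing: bool = True) -> pd.DataFrame:
    """Enforce the expression-matrix invariants.

    Row and column ids must be unique; rows containing missing values are
    dropped (with a logged count) rather than imputed.
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids: {dups[:10]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:10]}")
    expr = expr.astype(float)
    if drop_missing:
        mask = expr.isna().any(axis=1)
        n_bad = int(mask.sum())
        if n_bad:
            logger.warning("dropping %d rows containing missing values", n_bad)
            expr = expr.loc[~mask]
    return expr


def read_series_matrix(
    path: str | Path,
    *,
    label_patterns: Mapping[str, str] | None = None,
    characteristics_prefix: str = "!Sample_characteristics",
) -> tuple[pd.DataFrame, pd.Series]:
    """Parse a GEO Series Matrix file.

    Returns ``(expression, sample_sheet)``.  Group labels are extracted from
    the first sample-characteristics metadata line whose values match the
    ``label_patterns`` regexes (case-insensitive); if none matches, an empty
    sheet is returned with a warning and a sidecar TSV
    (:func:`read_sample_sheet`) should be supplied instead.
    """
    path = Path(path)
    patterns = dict(label_patterns or DEFAULT_LABEL_PATTERNS)
    meta_char_lines: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith(characteristics_prefix):
                meta_char_lines.append([_unquote(t) for t in line.split("\t")])
    if not (saw_begin and saw_end):
        raise ValueError(
            f"{path}: missing !series_matrix_table_begin/end delimiters"
        )
    if not table_lines:
        raise ValueError(f"{path}: empty series matrix table")

    rows = [line.split("\t") for line in table_lines]
    header = [_unquote(t) for t in rows[0]]
    sample_ids = header[1:]
    probe_ids = [_unquote(r[0]) for r in rows[1:]]
    values = np.array(
        [[float(v) if v.strip() not in ("", "null", "NULL", "NA") else np.nan
          for v in r[1:]] for r in rows[1:]],
        dtype=float,
    )
    expr = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe ids: {dups[:10]}")
    expr = validate_expression(expr)

    sheet = _labels_from_characteristics(sample_ids, meta_char_lines, patterns)
    if sheet.empty:
        logger.warning(
            "%s: no characteristics line matched the label patterns; "
            "supply a sample-sheet TSV", path,
        )
    return expr, sheet


def _labels_from_characteristics(
    sample_ids: list[str],
    char_lines: list[list[str]],
    patterns: Mapping[str, str],
) -> pd.Series:
    compiled = {g: re.compile(p, re.IGNORECASE) for g, p in patterns.items()}
    for tokens in char_lines:
        values = tokens[1:]
        if len(values) != len(sample_ids):
            continue
        labels = []
        for v in values:
            # later patterns take precedence only if earlier ones miss
            hit = next((g for g, rx in compiled.items() if rx.search(v)), None)
            labels.append(hit)
        if all(lab is not None for lab in labels):
            return pd.Series(labels, index=sample_ids, name="group")
    return pd.Series(dtype=object, name="group")


def write_series_matrix(
    expr: pd.DataFrame,
    path: str | Path,
    sheet: pd.Series | None = None,
    *,
    characteristics_prefix: str = "!Sample_characteristics_ch1",
) -> None:
    """Write an expression matrix in Series Matrix layout (round-trip safe)."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        if sheet is not None and not sheet.empty:
            labels = "\t".join(f'"{sheet.get(s, "")}"' for s in expr.columns)
            fh.write(f"{characteristics_prefix}\t{labels}\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{c}"' for c in expr.columns]) + "\n")
        for probe, row in zip(expr.index, expr.to_numpy()):
            fh.write('"%s"\t%s\n' % (probe, "\t".join(repr(float(v)) for v in row)))
        fh.write("!series_matrix_table_end\n")


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, group) into a label Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: sample sheet needs two columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("sample_id", "sample", "id"):
        df = df.iloc[1:]
    sheet = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if sheet.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in sheet")
    return sheet


def write_sample_sheet(sheet: pd.Series, path: str | Path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, grp in sheet.items():
            w.writerow([sid, grp])


def read_probe_annotation(path: str | Path) -> pd.Series:
    """Read a two-column TSV (probe_id, gene symbol); blank symbols -> NaN."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("probe_id", "probe", "id"):
        df = df.iloc[1:]
    sym = df.iloc[:, 1].replace("", np.nan)
    ann = pd.Series(sym.values, index=df.iloc[:, 0].values, name="symbol")
    return ann


def map_probes(
    expr: pd.DataFrame,
    annotation: pd.Series | Mapping[str, str],
    rule: str = "max_mean",
) -> pd.DataFrame:
    """Collapse probe-level rows to gene symbols.

    ``max_mean`` (default) keeps, for each symbol, the probe with the highest
    mean expression across all samples — the usual convention for 3'-array
    data.  ``none`` keeps probe-level rows and attaches symbols as an index
    level without touching values.
    """
    if rule not in ("max_mean", "none"):
        raise ValueError(f"unknown collapse rule: {rule!r}")
    ann = pd.Series(annotation).reindex(expr.index)
    annotated = ann.dropna()
    if annotated.empty:
        raise ValueError("annotation shares no probes with the matrix")
    if rule == "none":
        out = expr.copy()
        out.index = pd.MultiIndex.from_arrays(
            [expr.index, ann.reindex(expr.index)], names=["probe_id", "symbol"]
        )
        return out
    means = expr.loc[annotated.index].mean(axis=1)
    best = (
        pd.DataFrame({"symbol": annotated, "mean": means})
        .sort_values(["symbol", "mean"], kind="mergesort")
        .groupby("symbol", sort=True)
        .tail(1)
    )
    out = expr.loc[best.index].copy()
    out.index = pd.Index(best["symbol"].values, name="symbol")
    return out.sort_index()


def subset_samples(expr: pd.DataFrame, sheet: pd.Series, group: str) -> pd.DataFrame:
    """Restrict columns to one sample group, preserving column order."""
    if group not in set(sheet.values):
        raise ValueError(f"group {group!r} not present in sample sheet")
    keep = [s for s in expr.columns if sheet.get(s) == group]
    if not keep:
        raise ValueError(f"no matrix columns labelled {group!r}")
    return expr.loc[:, keep]
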