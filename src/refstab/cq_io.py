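"""Plain-text I/O for Cq panels and pipeline reports.

Two interchange layouts are supported:

* **long CSV** — one row per reaction with columns
  ``sample,group,gene,replicate,cq``;
* **wide CSV** — one row per gene, one column per ``<sample>.<replicate>``
  pair, plus a separate two-column metadata CSV mapping sample to group.

Reactions that did not amplify are encoded with a sentinel: on input the
empty field, ``NA``, ``NaN`` and the instrument convention ``Undetermined``
are accepted case-insensitively; on output ``NA`` is always written.
Replicate indices are 1-based and contiguous in files.

:func:`write_report` serialises any pipeline result: flat tables go to TSV,
nested results to JSON, floats at 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .panel import CqPanel, ExpressionMatrix, PanelError

__all__ = [
    "MISSING_SENTINELS",
    "read_cq_long",
    "read_cq_wide",
    "write_cq_long",
    "write_cq_wide",
    "write_report",
    "CqFormatError",
]

#: Accepted spellings of "no amplification" on input (case-insensitive).
MISSING_SENTINELS = ("", "na", "nan", "undetermined")

LONG_COLUMNS = ["sample", "group", "gene", "replicate", "cq"]


class CqFormatError(ValueError):
    """Raised on malformed panel files."""


def _parse_cq_column(raw: pd.Series) -> pd.Series:
    """Parse the text cq column; NaN for sentinels, error (with the file
    line number, header = line 1) for anything else non-numeric."""
    stripped = raw.astype(str).str.strip()
    is_missing = stripped.str.lower().isin(MISSING_SENTINELS)
    parsed = pd.to_numeric(stripped.where(~is_missing), errors="coerce")
    bad = ~is_missing & parsed.isna()
    if bad.any():
        pos = int(np.flatnonzero(bad.to_numpy())[0])
        raise CqFormatError(
            f"non-numeric cq value {stripped.iloc[pos]!r} at line {pos + 2}"
        )
    return parsed


def read_cq_long(path: str | Path, *, extra_sentinels: Iterable[str] = ()) -> CqPanel:
    """Read a long-format reaction-level CSV into a :class:`CqPanel`.

    Absent (gene, sample, replicate) combinations are filled as missing;
    the replicate count is the maximum 1-based replicate index observed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CqFormatError(f"missing required columns: {missing_cols}")
    if df.empty:
        raise CqFormatError("file contains no reactions")

    sentinels = [s.lower() for s in extra_sentinels]
    raw = df["cq"].astype(str).str.strip()
    if sentinels:
        raw = raw.where(~raw.str.lower().isin(sentinels), "")
    cq = _parse_cq_column(raw)

    try:
        rep = df["replicate"].astype(int)
    except ValueError as exc:
        raise CqFormatError(f"non-integer replicate index: {exc}") from None
    if (rep < 1).any():
        raise CqFormatError("replicate indices must be 1-based positive integers")

    dup = df.duplicated(subset=["gene", "sample", "replicate"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise CqFormatError(
            "duplicate reaction for (gene, sample, replicate) = "
            f"({row['gene']!r}, {row['sample']!r}, {row['replicate']!r})"
        )

    conflicts = df.groupby("sample")["group"].nunique()
    if (conflicts > 1).any():
        bad = conflicts[conflicts > 1].index.tolist()
        raise CqFormatError(f"conflicting group labels for samples: {bad}")

    genes = sorted(df["gene"].unique())
    samples = sorted(df["sample"].unique())
    n_rep = int(rep.max())
    groups = dict(zip(df["sample"], df["group"]))

    gi = pd.Categorical(df["gene"], categories=genes).codes
    si = pd.Categorical(df["sample"], categories=samples).codes
    values = np.full((len(genes), len(samples), n_rep), np.nan)
    values[gi, si, rep.to_numpy() - 1] = cq.to_numpy()
    return CqPanel(genes=genes, samples=samples, groups=groups, values=values)


def write_cq_long(panel: CqPanel, path: str | Path, *, precision: int = 6) -> None:
    """Write a panel as long CSV; missing reactions are written as ``NA``."""
    rows = []
    for gi, gene in enumerate(panel.genes):
        for si, sample in enumerate(panel.samples):
            for r in range(panel.n_replicates):
                v = panel.values[gi, si, r]
                rows.append(
                    (
                        sample,
                        panel.groups[sample],
                        gene,
                        r + 1,
                        "NA" if math.isnan(v) else f"{v:.{precision}g}",
                    )
                )
    out = pd.DataFrame(rows, columns=LONG_COLUMNS)
    out.to_csv(path, index=False)


def read_cq_wide(path: str | Path, metadata_path: str | Path) -> CqPanel:
    """Read a wide gene x (sample.replicate) CSV plus a sample metadata CSV.

    The first column must be ``gene``; every other header must parse as
    ``<sample>.<replicate>`` with a 1-based integer replicate.  The
    metadata CSV needs columns ``sample`` and ``group`` covering every
    sample in the matrix.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "gene":
        raise CqFormatError("first column of a wide panel must be 'gene'")
    meta = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    for col in ("sample", "group"):
        if col not in meta.columns:
            raise CqFormatError(f"metadata file lacks column {col!r}")
    groups = dict(zip(meta["sample"], meta["group"]))

    parsed_cols: list[tuple[str, int]] = []
    for header in df.columns[1:]:
        sample, sep, rep = header.rpartition(".")
        if not sep or not rep.isdigit() or int(rep) < 1:
            raise CqFormatError(
                f"header {header!r} not parseable as <sample>.<replicate>"
            )
        parsed_cols.append((sample, int(rep)))

    absent = sorted({s for s, _ in parsed_cols} - set(groups))
    if absent:
        raise CqFormatError(f"samples absent from metadata: {absent}")

    long_rows = df.melt(id_vars="gene", var_name="header", value_name="cq")
    sample_rep = long_rows["header"].str.rpartition(".")
    long_rows = long_rows.assign(
        sample=sample_rep[0],
        replicate=sample_rep[2].astype(int),
        group=lambda t: t["sample"].map(groups),
    )[["sample", "group", "gene", "replicate", "cq"]]

    dup = long_rows.duplicated(subset=["gene", "sample", "replicate"])
    if dup.any():
        row = long_rows.loc[dup.idxmax()]
        raise CqFormatError(
            "duplicate reaction for (gene, sample, replicate) = "
            f"({row['gene']!r}, {row['sample']!r}, {int(row['replicate'])})"
        )

    cq = _parse_cq_column(long_rows["cq"])
    genes = sorted(long_rows["gene"].unique())
    samples = sorted(long_rows["sample"].unique())
    n_rep = int(long_rows["replicate"].max())
    gi = pd.Categorical(long_rows["gene"], categories=genes).codes
    si = pd.Categorical(long_rows["sample"], categories=samples).codes
    values = np.full((len(genes), len(samples), n_rep), np.nan)
    values[gi, si, long_rows["replicate"].to_numpy() - 1] = cq.to_numpy()
    return CqPanel(genes=genes, samples=samples, groups=groups, values=values)


def write_cq_wide(
    panel: CqPanel, path: str | Path, metadata_path: str | Path, *, precision: int = 6
) -> None:
    """Write a panel as wide CSV plus a sample/group metadata CSV."""
    headers = [
        f"{s}.{r + 1}" for s in panel.samples for r in range(panel.n_replicates)
    ]
    flat = panel.values.reshape(panel.n_genes, -1)
    cells = [
        ["NA" if math.isnan(v) else f"{v:.{precision}g}" for v in row] for row in flat
    ]
    out = pd.DataFrame(cells, columns=headers)
    out.insert(0, "gene", panel.genes)
    out.to_csv(path, index=False)
    meta = pd.DataFrame(
        {"sample": panel.samples, "group": [panel.groups[s] for s in panel.samples]}
    )
    meta.to_csv(metadata_path, index=False)


# ----------------------------------------------------------------------
# report writing


def _sig6(x: Any) -> Any:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return None
        return float(f"{x:.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _jsonable(obj: Any) -> Any:
    """Recursively convert a result object to JSON-serialisable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(map(str, obj.columns)),
            "index": list(map(str, obj.index)),
            "rows": [[_jsonable(v) for v in row] for row in obj.to_numpy().tolist()],
        }
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return _sig6(obj)


def write_report(obj: Any, path: str | Path) -> None:
    """Serialise a pipeline result to ``path``.

    Objects exposing ``to_frame()`` (stability tables, comprehensive
    rankings) and plain DataFrames are written as TSV with stable column
    order; everything else (QC reports, geNorm traces, NormFinder
    diagnostics, NRQ reports) as JSON.  Floats are written at 6 significant
    digits.
    """
    path = Path(path)
    frame = None
    if isinstance(obj, pd.DataFrame):
        frame = obj
    elif hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
        frame = obj.to_frame()
    if frame is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")
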