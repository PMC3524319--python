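"""Readers and writers for the package's text formats.

Expression matrices travel as TSV with a '#'-prefixed metadata header
block mapping each sample column to its condition and replicate pool;
detection calls ride in a companion TSV of the same shape.  A minimal
reader for GEO SOFT-style dataset files (the GDS family) is provided as
a convenience for working with real accessions.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import CONDITIONS, ExpressionMatrix


def write_expression_tsv(
    mat: ExpressionMatrix, path: str | Path, calls_path: str | Path | None = None
) -> None:
    """Write a matrix (and optionally its calls) in the package TSV dialect.

    Layout: '# condition: <tab-joined labels>' and '# replicate: ...'
    metadata lines, then a header row ('probe', optional 'symbol',
    sample names) and one row per probe.
    """
    path = Path(path)
    cond_line = "\t".join(mat.conditions[c] for c in mat.values.columns)
    rep_line = "\t".join(str(mat.replicates.get(c, 1)) for c in mat.values.columns)
    with open(path, "w") as fh:
        fh.write(f"# condition:\t{cond_line}\n")
        fh.write(f"# replicate:\t{rep_line}\n")
        out = mat.values.copy()
        if mat.symbols is not None:
            out.insert(0, "symbol", mat.symbols)
        out.index.name = "probe"
        out.to_csv(fh, sep="\t")
    if calls_path is not None and mat.calls is not None:
        calls = mat.calls.copy()
        calls.index.name = "probe"
        calls.to_csv(calls_path, sep="\t")


def read_expression_tsv(
    path: str | Path, calls_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read the package TSV dialect back into an :class:`ExpressionMatrix`.

    Raises with the offending row/column on duplicate probes, unknown
    condition labels, or non-numeric cells; a matrix lacking some
    conditions loads fine (operations that need them raise later).
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, rest = line[1:].partition(":")
            meta[key.strip()] = rest.strip().split("\t")
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "condition" not in meta:
        raise ValueError(f"{path}: missing '# condition:' metadata line")
    symbols = None
    if "symbol" in df.columns:
        symbols = df.pop("symbol")
    samples = list(df.columns)
    cond_list = meta["condition"]
    if len(cond_list) != len(samples):
        raise ValueError(
            f"{path}: {len(cond_list)} condition labels for {len(samples)} samples"
        )
    for lab in cond_list:
        if lab not in CONDITIONS:
            raise ValueError(f"{path}: unknown condition label {lab!r}")
    reps = meta.get("replicate", ["1"] * len(samples))
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.isna().stack()
        probe, col = bad.index[bad.argmax()]
        raise ValueError(f"{path}: non-numeric cell at probe {probe!r}, column {col!r}")
    calls = None
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        calls = calls[samples]
    return ExpressionMatrix(
        values,
        conditions=dict(zip(samples, cond_list)),
        replicates={s: int(r) for s, r in zip(samples, reps)},
        calls=calls,
        symbols=symbols,
    )


def read_soft_gds(
    path: str | Path, condition_map: dict[str, str]
) -> ExpressionMatrix:
    """Minimal reader for GEO SOFT dataset (GDS) files.

    Parses the ``^DATASET`` table between ``!dataset_table_begin`` and
    ``!dataset_table_end`` plus the ``#<sample> = ... <description>``
    column annotations; ``condition_map`` maps a substring of each
    sample's description (or the sample name itself) to one of the six
    condition labels.  Detection calls are not part of GDS tables.
    Convenience only — the screening pipeline is format-agnostic.
    """
    path = Path(path)
    descriptions: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!dataset_table_begin"):
                in_table = True
                continue
            if line.startswith("!dataset_table_end"):
                break
            if not in_table and line.startswith("#GSM"):
                name, _, desc = line[1:].partition(" = ")
                descriptions[name] = desc
            elif in_table:
                if header is None:
                    header = line.split("\t")
                else:
                    rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no dataset table found")
    df = pd.DataFrame(rows, columns=header)
    sample_cols = [c for c in df.columns if c.startswith("GSM")]
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(df[header[0]], name="probe")
    symbols = (
        pd.Series(df[header[1]].to_numpy(), index=values.index)
        if len(header) > 1 and not header[1].startswith("GSM")
        else None
    )
    conditions = {}
    for s in sample_cols:
        desc = descriptions.get(s, s)
        for key, label in condition_map.items():
            if key in desc or key == s:
                conditions[s] = label
                break
        else:
            raise ValueError(f"{path}: no condition mapping for sample {s} ({desc})")
    reps: dict[str, int] = {}
    seen: dict[str, int] = {}
    for s in sample_cols:
        seen[conditions[s]] = seen.get(conditions[s], 0) + 1
        reps[s] = seen[conditions[s]]
    keep = values.dropna(how="any")
    return ExpressionMatrix(keep, conditions, reps, symbols=(
        symbols.loc[keep.index] if symbols is not None else None
    ))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Index):
        return list(o)
    raise TypeError(f"cannot serialize {type(o)}")
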