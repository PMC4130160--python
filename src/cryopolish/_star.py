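"""Minimal STAR file reader/writer (single data block, single loop)."""

from __future__ import annotations

import pandas as pd

from .errors import FormatError


def read_star(path: str) -> pd.DataFrame:
    """Read the first loop of the first data block into a DataFrame.

    Column labels keep their leading underscore stripped (``_rlnCoordinateX``
    becomes ``rlnCoordinateX``); numeric columns are converted automatically.
    Row order is preserved exactly.
    """
    columns: list[str] = []
    rows: list[list[str]] = []
    in_block = in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if in_loop and rows:
                    break  # blank line ends the loop body
                continue
            if line.startswith("data_"):
                if in_loop and rows:
                    break
                in_block = True
                continue
            if not in_block:
                continue
            if line == "loop_":
                in_loop = True
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                values = line.split()
                if len(values) != len(columns):
                    raise FormatError(
                        f"{path}: row has {len(values)} fields, "
                        f"expected {len(columns)}"
                    )
                rows.append(values)
    if not columns:
        raise FormatError(f"{path}: no STAR loop found")
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def write_star(df: pd.DataFrame, path: str, block_name: str = "particles") -> None:
    """Write a DataFrame as a single STAR data block with one loop."""
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block_name}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            fields = []
            for value in row:
                if isinstance(value, float):
                    fields.append(f"{value:.6f}")
                else:
                    fields.append(str(value))
            fh.write(" ".join(fields) + "\n")
        fh.write("\n")
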