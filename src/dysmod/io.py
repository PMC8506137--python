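"""Reading and writing of the plain-text formats used across the pipeline.

All tables are tab-separated with a header row.  Floats are written with a
fixed ``%.10g`` format so that repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a DataFrame as deterministic TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(values: pd.DataFrame, path: str | Path) -> Path:
    """Expression matrix: rows are genes, columns samples, index column 'gene'."""
    out = values.copy()
    out.index.name = "gene"
    return write_table(out, path, index=True)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> Path:
    """Sample sheet: index column 'sample', a 'group' column, trait columns."""
    out = samples.copy()
    out.index.name = "sample"
    return write_table(out, path, index=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise ValueError(f"sample sheet {path} lacks a 'group' column")
    return df


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> Path:
    """Write gene sets in GMT format: name TAB description TAB member..."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = sorted(sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file; every line needs name, description and >= 1 member."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            sets[name] = members
    return sets


def write_edges(edges: pd.DataFrame, path: str | Path) -> Path:
    """Regulator network edges: regulator, target, score, class."""
    cols = ["regulator", "target", "score", "class"]
    return write_table(edges[cols], path)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str, "class": str})
    missing = {"regulator", "target", "score", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table {path} lacks columns: {sorted(missing)}")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def gene_list(genes: Sequence[str], path: str | Path) -> Path:
    return write_table(pd.DataFrame({"gene": sorted(genes)}), path)
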