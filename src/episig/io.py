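"""Plain-text readers/writers for the pipeline's tabular artifacts.

All tables are TSV/CSV with a probe or sample id in the first column.
Writers can prepend a ``#``-prefixed provenance line; readers skip any
``#`` comment lines, so files round-trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    index_label: str,
    sep: str = "\t",
    provenance: dict | None = None,
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, sep=sep, index_label=index_label)
    return path


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Probes x samples numeric matrix (beta or detection-p)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    for col in ("is_allosomal", "is_snp", "is_crossreactive"):
        man[col] = man[col].astype(bool)
    man["position"] = man["position"].astype(int)
    return man


def read_sample_sheet_csv(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col=0, comment="#", keep_default_na=False)
    sheet["age"] = sheet["age"].astype(float)
    return sheet


def read_reference_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_json(obj: dict, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    if provenance is not None:
        obj = {"provenance": provenance, **obj}
    path.write_text(json.dumps(obj, indent=1, default=str))
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
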