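"""Tab-separated readers/writers for clinical tables and expression matrices.

All files are plain TSV with a one-line header and subject ids in the first
column.  A YAML sidecar records generator parameters and seeds so a dataset
is self-describing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .normalize import ExpressionMatrix

FLOAT_FMT = "%.10g"


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path, tissue: str, state: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, tissue=tissue, state=state)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_dataset(outdir, clinical, carcinoma, normal, specs: dict) -> dict:
    """Write clinical + expression TSVs and a YAML metadata sidecar.

    Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "carcinoma": outdir / "carcinoma.tsv",
        "normal": outdir / "normal.tsv",
        "metadata": outdir / "metadata.yaml",
    }
    write_clinical(clinical, paths["clinical"])
    write_expression(carcinoma, paths["carcinoma"])
    write_expression(normal, paths["normal"])
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump({k: _to_plain(v) for k, v in specs.items()}, fh, sort_keys=True)
    return paths


def read_mirna_list(path) -> list:
    """One miRNA id per line; '#' comments and blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"miRNA list not found: {path}")
    out = []
    for line in path.read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
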