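"""Reading and writing the long-format tables and tensorized cohorts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import TensorizedCohort

__all__ = ["write_tables", "read_tables", "save_tensorized", "load_tensorized"]

_TABLES = ("records", "cohort", "normal_ranges")


def write_tables(outdir, records: pd.DataFrame, cohort: pd.DataFrame,
                 normal_ranges: pd.DataFrame, fmt: str = "csv") -> dict[str, str]:
    """Write the three cohort tables; ``fmt`` is ``csv`` or ``parquet``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in zip(_TABLES, (records, cohort, normal_ranges)):
        path = outdir / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths[name] = str(path)
    return paths


def read_tables(indir, fmt: str = "csv"):
    indir = Path(indir)
    out = []
    for name in _TABLES:
        path = indir / f"{name}.{fmt}"
        out.append(pd.read_csv(path) if fmt == "csv" else pd.read_parquet(path))
    return tuple(out)


def save_tensorized(tc: TensorizedCohort, prefix) -> None:
    """Columnar values table plus a JSON sidecar with orderings/edges."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame(
        tc.as_matrix(),
        columns=[f"{v}::b{b}" for v in tc.variables for b in range(tc.n_bins)],
    )
    wide.insert(0, "patient_id", tc.patients)
    wide.to_parquet(f"{prefix}.parquet", index=False)
    sidecar = {
        "patients": list(tc.patients),
        "variables": list(tc.variables),
        "bin_edges": tc.bin_edges.tolist(),
        "labels": tc.labels.tolist(),
        "var_means": None if tc.var_means is None else tc.var_means.tolist(),
        "var_sds": None if tc.var_sds is None else tc.var_sds.tolist(),
        "n_dropped": tc.n_dropped,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar))


def load_tensorized(prefix) -> TensorizedCohort:
    side = json.loads(Path(f"{prefix}.json").read_text())
    wide = pd.read_parquet(f"{prefix}.parquet")
    values = wide.drop(columns=["patient_id"]).to_numpy(dtype=float)
    n_bins = len(side["bin_edges"]) - 1
    return TensorizedCohort(
        patients=side["patients"],
        variables=side["variables"],
        values=values.reshape(len(side["patients"]), len(side["variables"]), n_bins),
        bin_edges=np.asarray(side["bin_edges"], dtype=float),
        labels=np.asarray(side["labels"], dtype=int),
        var_means=None if side["var_means"] is None else np.asarray(side["var_means"]),
        var_sds=None if side["var_sds"] is None else np.asarray(side["var_sds"]),
        n_dropped=int(side["n_dropped"]),
    )
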