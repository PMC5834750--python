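"""Reading and writing the pipeline's delimited-text formats.

All on-disk formats are plain text: per-subject time series as
tab-separated tables (T rows x N region columns, header = region
names), connectivity matrices as square CSVs, and tabular results as
CSVs.  Files whose rows or columns refer to regions carry a leading
``#`` comment declaring the 1-based region numbering convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, ROITimeSeries
from .synthetic import GroundTruth

REGION_COMMENT = "# region indices are 1-based (atlas numbering)\n"

_FLOAT_FMT = "%.17g"


def write_timeseries(ts: ROITimeSeries, path: Path) -> None:
    frame = pd.DataFrame(ts.values, columns=ts.region_names)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: Path, sampling_interval: float = 2.0) -> ROITimeSeries:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ROITimeSeries(frame.to_numpy(dtype=float), list(frame.columns), sampling_interval)


def write_cohort(
    outdir: Path,
    series: Sequence[np.ndarray],
    meta: pd.DataFrame,
    truth: GroundTruth | None,
    region_names: Sequence[str],
    sampling_interval: float = 2.0,
) -> None:
    """Write a cohort: one time-series file per subject, a metadata CSV
    and (when available) the generator's ground truth as JSON."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for values, sid in zip(series, meta["subject_id"]):
        write_timeseries(
            ROITimeSeries(values, list(region_names), sampling_interval),
            ts_dir / f"{sid}.tsv",
        )
    meta.to_csv(outdir / "metadata.csv", index=False, float_format=_FLOAT_FMT)
    if truth is not None:
        payload = {
            "planted_edges": [list(e) for e in truth.planted_edges],
            "degradation_factor": truth.degradation_factor,
            "group_covariance": {
                g: np.round(c, 6).tolist() for g, c in truth.group_covariance.items()
            },
        }
        (outdir / "ground_truth.json").write_text(json.dumps(payload))


def read_timeseries_dir(
    data_dir: Path,
    meta: pd.DataFrame,
    region_names: Sequence[str],
    sampling_interval: float = 2.0,
) -> list[ROITimeSeries]:
    """Load per-subject time series aligned to the metadata row order.

    Every file must exist, share the region-table header, and be
    rectangular; failures name the offending file.
    """
    ts_dir = Path(data_dir)
    out = []
    expected = list(region_names)
    for sid in meta["subject_id"]:
        path = ts_dir / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file for subject {sid}: {path}")
        try:
            ts = read_timeseries(path, sampling_interval)
        except ValueError as err:
            raise ValueError(f"malformed time-series file {path}: {err}") from err
        if ts.region_names != expected:
            raise ValueError(
                f"time-series file {path} has {len(ts.region_names)} columns "
                f"that do not match the {len(expected)}-region table"
            )
        out.append(ts)
    return out


def write_connectivity(m: ConnectivityMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(REGION_COMMENT)
        pd.DataFrame(m.z, columns=m.region_names).to_csv(
            fh, index=False, float_format=_FLOAT_FMT
        )


def read_connectivity(path: Path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return ConnectivityMatrix(frame.to_numpy(dtype=float), list(frame.columns))


def write_edge_list(
    m: ConnectivityMatrix, path: Path, region_names: Sequence[str] | None = None
) -> None:
    names = list(region_names or m.region_names)
    iu, ju = np.triu_indices(m.n_regions, k=1)
    frame = pd.DataFrame(
        {
            "i": iu + 1,
            "j": ju + 1,
            "region_i": [names[a] for a in iu],
            "region_j": [names[b] for b in ju],
            "weight": m.z[iu, ju],
        }
    )
    with open(path, "w") as fh:
        fh.write(REGION_COMMENT)
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_table(frame: pd.DataFrame, path: Path, region_indexed: bool = False) -> None:
    with open(path, "w") as fh:
        if region_indexed:
            fh.write(REGION_COMMENT)
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
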