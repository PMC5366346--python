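"""CSV readers/writers tying the pipeline together.

All files are UTF-8 CSV with a mandatory header row, "." decimal separator
and ISO-8601 dates; internal time is thermal time in degree-days with day 0
at simulation start.  Run provenance (seed, config name) is written to a
``meta.json`` next to the tables so the CSVs themselves stay plain.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import DataValidationError
from .estimate import ObservationDataset, PcaResult

_DATASET_FILES = {"census": "census.csv", "lengths": "lengths.csv",
                  "scans": "leaf_scans.csv", "branching": "branching.csv"}


def write_dataset(dataset: ObservationDataset, out_dir, truth: dict | None = None,
                  meta: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _DATASET_FILES.items():
        getattr(dataset, attr).to_csv(out / fname, index=False)
    if truth is not None:
        pd.DataFrame([truth]).to_csv(out / "truth.csv", index=False)
    if meta is not None:
        (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_dataset(in_dir) -> ObservationDataset:
    src = Path(in_dir)
    frames = {}
    for attr, fname in _DATASET_FILES.items():
        path = src / fname
        if not path.exists():
            raise DataValidationError(f"missing observation table {fname} in {src}")
        # round_trip parsing keeps write -> read -> write byte-identical
        frames[attr] = pd.read_csv(path, float_precision="round_trip")
    return ObservationDataset(**frames).validate()


def read_truth(in_dir) -> dict:
    frame = pd.read_csv(Path(in_dir) / "truth.csv")
    return frame.iloc[0].to_dict()


def write_architecture(arch, tt_grid, out_dir, meta: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arch.to_long_frame(tt_grid).to_csv(out / "architecture.csv", index=False)
    arch.snapshots(tt_grid).to_csv(out / "summaries.csv", index=False)
    if meta is not None:
        (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def write_traits(traits: pd.DataFrame, diagnostics: pd.DataFrame, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits.to_csv(out / "traits.csv")
    diagnostics.to_csv(out / "diagnostics.csv", index=False)
    return out


def write_pca(result: PcaResult, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.loadings.to_csv(out / "pca_loadings.csv")
    result.scores.to_csv(out / "pca_scores.csv")
    pd.DataFrame({"component": result.loadings.columns,
                  "variance_fraction": result.variance_fraction}).to_csv(
        out / "pca_variance.csv", index=False)
    return out


def write_thermal_time(series, tt, out_path) -> Path:
    frame = series.to_frame()
    frame["tt_cd"] = tt
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    return out
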