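"""Readers and writers for every file the pipeline touches.

All formats are plain UTF-8 CSV with ISO-8601 timestamps and empty fields
for missing values, chosen for diff-ability: identical inputs, config and
seed must reproduce every output byte-for-byte (manifests therefore carry
no wall-clock timestamps).

Panel CSV columns (the panel dialect):
person_id, day_index, date, is_weekend, wear_min, sb_min, pa_min,
valid_day, pain, fatigue, wellbeing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import EFFECTS, EpochSeries, PanelDataset, PosteriorDraws

PANEL_COLUMNS = [
    "person_id",
    "day_index",
    "date",
    "is_weekend",
    "wear_min",
    "sb_min",
    "pa_min",
    "valid_day",
    "pain",
    "fatigue",
    "wellbeing",
]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# epoch streams


def read_epochs(path: str | Path, skip_rows: int = 0) -> list[EpochSeries]:
    """Read an epoch CSV (person_id, timestamp, counts) into series.

    ``skip_rows`` skips header banners of ActiGraph-style exports. Epoch
    length is inferred from the timestamp spacing; timestamps must be
    strictly increasing within person.
    """
    frame = pd.read_csv(path, skiprows=skip_rows)
    expected = {"person_id", "timestamp", "counts"}
    if not expected <= set(frame.columns):
        raise ValueError(f"epoch CSV needs columns {sorted(expected)}")
    try:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"malformed timestamp in {path}: {err}") from err
    series = []
    for pid, grp in frame.groupby("person_id", sort=False):
        ts = grp["timestamp"].to_numpy()
        deltas = np.diff(ts).astype("timedelta64[s]").astype(int)
        if (deltas <= 0).any():
            bad = int(np.argwhere(deltas <= 0)[0][0])
            row = grp.index[bad + 1] + 2 + skip_rows  # 1-based incl. header
            raise ValueError(
                f"non-monotone timestamps for {pid} at row {row} of {path}"
            )
        if deltas.size and len(set(deltas)) > 1:
            raise ValueError(f"unequal epoch spacing for {pid} in {path}")
        epoch_s = int(deltas[0]) if deltas.size else 60
        series.append(
            EpochSeries(
                person_id=str(pid),
                epoch_length_s=epoch_s,
                start_time=pd.Timestamp(ts[0]),
                counts=grp["counts"].to_numpy(np.int64),
            )
        )
    return series


def write_epochs(series_list: list[EpochSeries], path: str | Path) -> None:
    """Write epoch series as a single long CSV."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "person_id": s.person_id,
                    "timestamp": s.times().strftime("%Y-%m-%dT%H:%M:%S"),
                    "counts": s.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panels


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    data = panel.data.copy()
    for col in PANEL_COLUMNS:
        if col not in data.columns:
            data[col] = np.nan
    data = data[PANEL_COLUMNS]
    data["date"] = pd.to_datetime(data["date"]).dt.strftime("%Y-%m-%d")
    data["is_weekend"] = data["is_weekend"].astype(bool)
    data["valid_day"] = data["valid_day"].astype(bool)
    data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_panel(
    path: str | Path, predictor: str = "pain", max_days: int = 7
) -> PanelDataset:
    """Read a panel CSV, validating the dialect.

    Raises on missing columns, duplicate (person_id, day_index) pairs and
    day indices outside 1..``max_days``.
    """
    data = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    data["person_id"] = data["person_id"].astype(str)
    data["date"] = pd.to_datetime(data["date"])
    bad = data[(data["day_index"] < 1) | (data["day_index"] > max_days)]
    if len(bad):
        raise ValueError(
            f"day_index {int(bad.iloc[0]['day_index'])} outside 1..{max_days}"
        )
    return PanelDataset(data=data, predictor=predictor)


# ---------------------------------------------------------------------------
# draws, summaries, manifests


def write_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Write thinned draws as long CSV (chain, draw, parameter, value)."""
    records = []
    c, d = draws.n_chains, draws.n_draws
    chain_idx = np.repeat(np.arange(c), d)
    draw_idx = np.tile(np.arange(d), c)

    def emit(name: str, mat: np.ndarray):
        records.append(
            pd.DataFrame(
                {
                    "chain": chain_idx,
                    "draw": draw_idx,
                    "parameter": name,
                    "value": mat.reshape(-1),
                }
            )
        )

    for j, e in enumerate(EFFECTS):
        emit(e, draws.gamma0[:, :, j])
        emit(f"{e}_on_p", draws.gamma1[:, :, j])
        emit(f"tau_{e}", draws.tau[:, :, j])
    emit("sigma_mu", draws.sigma_mu)
    emit("deviance", draws.deviance)
    pids = list(draws.person_ids) or [str(i) for i in range(draws.person.shape[2])]
    for i, pid in enumerate(pids):
        for j, e in enumerate(EFFECTS):
            emit(f"{e}[{pid}]", draws.person[:, :, i, j])
    long = pd.concat(records, ignore_index=True)
    long.to_csv(path, index=False, float_format="%.12g")


def write_summary(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def write_manifest(manifest: dict, path: str | Path) -> None:
    manifest = dict(manifest)
    manifest.setdefault("actdsem_version", __version__)
    manifest.setdefault("numpy_version", np.__version__)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


__all__ = [
    "PANEL_COLUMNS",
    "read_epochs",
    "write_epochs",
    "read_panel",
    "write_panel",
    "write_draws",
    "write_summary",
    "write_manifest",
]
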