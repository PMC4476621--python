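"""File formats: accelerometer TSV, gradiometer HDF5, trigger TSV, JSON
sidecars, and column-mapped ingestion of third-party accelerometer exports.

The native accelerometer dialect is a plain TSV with ``#key=value`` header
lines (site, subject, fs_hz, start_time_s) followed by columns
``time_s  acc_x  acc_y  acc_z``.  External exports whose internal layout is
not known a priori are ingested through an explicit column-mapping config
(YAML/JSON/dict) — the mapping is declared, never guessed silently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import AccelRecording, EventSeries, MatchedEvents
from .coherence import CoherenceMatrix, GradiometerRecording, TopoVector
from .streamsync import ClockMap, TriggerTrace
from .synthgen import GroundTruth

__all__ = [
    "write_accel_tsv",
    "read_accel_tsv",
    "read_accel_mapped",
    "write_events_tsv",
    "write_pairs_tsv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_grad_h5",
    "read_grad_h5",
    "write_trigger_tsv",
    "read_trigger_tsv",
    "write_clock_map_json",
    "read_clock_map_json",
    "write_topo_tsv",
    "write_coherence_matrix",
]


# ---------------------------------------------------------------------------
# accelerometer TSV


def write_accel_tsv(rec: AccelRecording, path: str | Path) -> None:
    path = Path(path)
    t = rec.times_s
    with open(path, "w") as fh:
        fh.write(f"#site={rec.site}\n#subject={rec.subject}\n")
        fh.write(f"#fs_hz={rec.fs_hz!r}\n#start_time_s={rec.start_time_s!r}\n")
        fh.write("time_s\tacc_x\tacc_y\tacc_z\n")
        np.savetxt(
            fh,
            np.column_stack([t, rec.samples.T]),
            fmt="%.6f\t%.9g\t%.9g\t%.9g",
        )


def _read_hash_headers(path: Path) -> tuple[dict, int]:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            skip += 1
    return meta, skip


def read_accel_tsv(path: str | Path) -> AccelRecording:
    path = Path(path)
    meta, skip = _read_hash_headers(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return AccelRecording(
        site=meta.get("site", ""),
        subject=meta.get("subject", ""),
        fs_hz=float(meta["fs_hz"]),
        samples=df[["acc_x", "acc_y", "acc_z"]].to_numpy().T,
        start_time_s=float(meta.get("start_time_s", 0.0)),
    )


def read_accel_mapped(path: str | Path, mapping: dict | str | Path) -> AccelRecording:
    """Ingest an arbitrary delimited accelerometer export via a column map.

    ``mapping`` (dict, or path to a YAML/JSON file) must declare::

        columns: {x: <name-or-index>, y: ..., z: ...}
        fs_hz: <rate>            # or  time_column: <name-or-index>
        site: <label>
        subject: <label>

    and may declare ``delimiter`` (default tab), ``scale`` (unit factor,
    default 1), ``header`` (row count to skip / "none") and
    ``start_time_s``.  Nothing about axis order, units or polarity is ever
    inferred from the data itself.
    """
    if not isinstance(mapping, dict):
        mpath = Path(mapping)
        text = mpath.read_text()
        if mpath.suffix in {".yaml", ".yml"}:
            import yaml

            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
    cols = mapping["columns"]
    delim = mapping.get("delimiter", "\t")
    header = mapping.get("header", "infer")
    df = pd.read_csv(Path(path), sep=delim,
                     header=None if header in (None, "none") else 0)
    scale = float(mapping.get("scale", 1.0))

    def _col(key):
        c = cols[key]
        series = df.iloc[:, c] if isinstance(c, int) else df[c]
        return series.to_numpy(dtype=float)

    samples = np.vstack([_col("x"), _col("y"), _col("z")]) * scale
    if "fs_hz" in mapping:
        fs = float(mapping["fs_hz"])
    elif "time_column" in mapping:
        tc = mapping["time_column"]
        t = (df.iloc[:, tc] if isinstance(tc, int) else df[tc]).to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise ValueError("mapping must declare fs_hz or time_column")
    return AccelRecording(
        site=str(mapping.get("site", "")),
        subject=str(mapping.get("subject", "")),
        fs_hz=fs,
        samples=samples,
        start_time_s=float(mapping.get("start_time_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# events / pairs / stats


def write_events_tsv(events: EventSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\ttime_s\n")
        for t in events.times_s:
            fh.write(f"{events.site}\t{t:.6f}\n")


def write_pairs_tsv(m: MatchedEvents, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# signed lag convention: {m.site_b} minus {m.site_a}, ms\n")
        fh.write("t_a_s\tt_b_s\tsigned_lag_ms\tvalid\n")
        for ta, tb, lag, v in zip(m.t_a_s, m.t_b_s, m.signed_lags_ms, m.valid):
            fh.write(f"{ta:.6f}\t{tb:.6f}\t{lag:.6f}\t{int(v)}\n")


# ---------------------------------------------------------------------------
# ground truth JSON


def write_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "events_a": gt.events_a.tolist(),
        "events_b": gt.events_b.tolist(),
        "true_lags_ms": gt.true_lags_ms.tolist(),
        "planted_channels": {k: list(map(int, v))
                             for k, v in gt.planted_channels.items()},
        "clock_offset_s": dict(gt.clock_offset_s),
        "clock_drift_ppm": dict(gt.clock_drift_ppm),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        events_a=np.asarray(d["events_a"]),
        events_b=np.asarray(d["events_b"]),
        true_lags_ms=np.asarray(d["true_lags_ms"]),
        planted_channels=d.get("planted_channels", {}),
        clock_offset_s=d.get("clock_offset_s", {}),
        clock_drift_ppm=d.get("clock_drift_ppm", {}),
    )


# ---------------------------------------------------------------------------
# gradiometer HDF5 container


def write_grad_h5(rec: GradiometerRecording, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.create_dataset("module_map", data=rec.module_map)
        f.create_dataset("layout_2d", data=rec.layout_2d)
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["site"] = rec.site
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["sss_applied"] = rec.sss_applied


def read_grad_h5(path: str | Path) -> GradiometerRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return GradiometerRecording(
            site=str(f.attrs["site"]),
            fs_hz=float(f.attrs["fs_hz"]),
            data=f["data"][()],
            channel_names=[s.decode() for s in f["channel_names"][()]],
            module_map=f["module_map"][()],
            layout_2d=f["layout_2d"][()],
            sss_applied=bool(f.attrs["sss_applied"]),
        )


# ---------------------------------------------------------------------------
# trigger / clock


def write_trigger_tsv(tt: TriggerTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#site={tt.site}\n#fs_hz={tt.fs_hz!r}\n")
        fh.write("level\n")
        np.savetxt(fh, tt.samples, fmt="%d")


def read_trigger_tsv(path: str | Path) -> TriggerTrace:
    meta, skip = _read_hash_headers(Path(path))
    levels = np.loadtxt(path, skiprows=skip + 1, dtype=np.int64)
    return TriggerTrace(fs_hz=float(meta["fs_hz"]), samples=levels,
                        site=meta.get("site", ""))


def write_clock_map_json(cm: ClockMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cm), indent=1))


def read_clock_map_json(path: str | Path) -> ClockMap:
    return ClockMap(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# coherence outputs


def write_topo_tsv(tv: TopoVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#site={tv.site}\n")
        fh.write("module\tper_module\n")
        for m, v in enumerate(tv.per_module):
            fh.write(f"{m}\t{v:.9g}\n")


def write_coherence_matrix(cm: CoherenceMatrix, path: str | Path) -> None:
    """Matrix as whitespace text plus a JSON sidecar with the estimation
    parameters (band, window, overlap, taper, site roles)."""
    path = Path(path)
    np.savetxt(path, cm.values, fmt="%.8g")
    sidecar = {
        "band_hz": list(cm.band_hz),
        "window_len": cm.window_len,
        "overlap": cm.overlap,
        "taper": cm.taper,
        "rows_site": cm.rows_site,
        "cols_site": cm.cols_site,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
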