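"""File formats: TSV matrices and tables, design timelines, movie containers,
run manifests, and an optional NIfTI input adapter.

Canonical interchange is flat TSV with JSON sidecars; every writer emits a
deterministic column order and fixed float formatting (10 significant
digits for matrices and tables, full precision for design timelines), so
identical inputs export byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from gazefield.stimulus import BarEvent, DesignSpec, Epoch, StimulusMovie

FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# --------------------------------------------------------------------------
# BOLD matrices
# --------------------------------------------------------------------------

def write_bold(path, data: np.ndarray, voxel_ids=None, tr_s: float = 2.0) -> None:
    """Voxel x TR matrix as TSV: first column voxel_id, header TR indices."""
    data = np.asarray(data)
    ids = voxel_ids if voxel_ids is not None else np.arange(len(data))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("voxel_id\t" + "\t".join(str(t) for t in
                                          range(data.shape[1])) + "\n")
        for vid, row in zip(ids, data):
            fh.write(str(vid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"tr_s": tr_s,
                                   "n_voxels": int(data.shape[0]),
                                   "n_trs": int(data.shape[1])}, indent=1)
                       + "\n")


def read_bold(path, mask=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a voxel x TR matrix.

    TSV input: returns (data, voxel_ids, tr_s from the sidecar).  NIfTI-1
    input (suffix .nii/.nii.gz) is flattened over ``mask`` in C scan order;
    voxel ids are the flat indices of the mask voxels.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asarray(img.dataobj)
        if vol.ndim != 4:
            raise ValueError("NIfTI input must be a 4D volume")
        if mask is None:
            raise ValueError("a mask is required for NIfTI input")
        m = np.asarray(mask, dtype=bool)
        data = vol[m]                      # C scan order over mask voxels
        ids = np.flatnonzero(m.ravel())
        tr = float(img.header.get_zooms()[3]) if len(
            img.header.get_zooms()) > 3 else np.nan
        return data.astype(float), ids, tr
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    data = df.drop(columns="voxel_id").to_numpy(float)
    if np.isnan(data).any():
        raise ValueError(f"NaN cells in {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"missing TR sidecar {sidecar}")
    tr = float(json.loads(sidecar.read_text())["tr_s"])
    return data, df["voxel_id"].to_numpy(), tr


# --------------------------------------------------------------------------
# parameter / fit tables
# --------------------------------------------------------------------------

def write_table(path, table: pd.DataFrame) -> None:
    """Generic TSV table writer with stable float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# --------------------------------------------------------------------------
# designs
# --------------------------------------------------------------------------

_DESIGN_COLS = ("onset_s", "duration_s", "kind", "target_x_deg",
                "target_y_deg", "bar_orientation", "bar_center_x_deg",
                "bar_center_y_deg", "bar_width_deg")


def write_design(path, design: DesignSpec) -> None:
    rows = []
    for ep in design.epochs:
        rows.append(dict(onset_s=ep.onset_s, duration_s=ep.duration_s,
                         kind="fixation",
                         target_x_deg=ep.target_x, target_y_deg=ep.target_y,
                         bar_orientation="", bar_center_x_deg="",
                         bar_center_y_deg="", bar_width_deg=""))
    for onset, dur in design.baselines:
        rows.append(dict(onset_s=onset, duration_s=dur, kind="baseline",
                         target_x_deg="", target_y_deg="",
                         bar_orientation="", bar_center_x_deg="",
                         bar_center_y_deg="", bar_width_deg=""))
    for ev in design.bar_events:
        rows.append(dict(onset_s=ev.onset_s,
                         duration_s=ev.offset_s - ev.onset_s, kind="bar",
                         target_x_deg="", target_y_deg="",
                         bar_orientation=ev.orientation,
                         bar_center_x_deg=ev.center_x,
                         bar_center_y_deg=ev.center_y,
                         bar_width_deg=ev.width))
    with open(path, "w") as fh:
        fh.write("\t".join(_DESIGN_COLS) + "\n")
        for r in rows:
            # full precision: the timeline must round-trip losslessly
            fh.write("\t".join("%.17g" % r[c] if isinstance(r[c], float)
                               else str(r[c]) for c in _DESIGN_COLS) + "\n")
    meta = dict(tr_s=design.tr_s, run_duration_s=design.run_duration_s,
                frame_rate_hz=design.frame_rate_hz)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_design(path) -> DesignSpec:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".json").read_text())
    epochs, baselines, bars = [], [], []
    for _, r in df.iterrows():
        if r["kind"] == "bar":
            bars.append(BarEvent(float(r["onset_s"]),
                                 float(r["onset_s"]) + float(r["duration_s"]),
                                 r["bar_orientation"],
                                 float(r["bar_center_x_deg"]),
                                 float(r["bar_center_y_deg"]),
                                 float(r["bar_width_deg"])))
        elif r["kind"] == "baseline":
            baselines.append((float(r["onset_s"]), float(r["duration_s"])))
        else:
            epochs.append(Epoch(float(r["onset_s"]), float(r["duration_s"]),
                                float(r["target_x_deg"]),
                                float(r["target_y_deg"])))
    epochs.sort(key=lambda e: e.onset_s)
    return DesignSpec(tuple(epochs), tuple(sorted(bars,
                                                  key=lambda b: b.onset_s)),
                      tuple(baselines), meta["tr_s"], meta["run_duration_s"],
                      meta["frame_rate_hz"])


# --------------------------------------------------------------------------
# movie container
# --------------------------------------------------------------------------

def write_movie(path_prefix, movie: StimulusMovie) -> None:
    """Flat binary frame stack (dense, float32) plus a JSON sidecar."""
    prefix = Path(path_prefix)
    dense = movie.dense()
    dense.astype(np.float32).tofile(str(prefix) + ".bin")
    meta = dict(ppd=movie.ppd, frame_rate_hz=movie.frame_rate_hz,
                fov_deg=list(movie.fov), n_frames=int(movie.n_frames),
                height_px=int(movie.height), width_px=int(movie.width),
                dtype="float32")
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_movie(path_prefix) -> StimulusMovie:
    prefix = Path(path_prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    flat = np.fromfile(str(prefix) + ".bin", dtype=meta["dtype"])
    frames = flat.reshape(meta["n_frames"], meta["height_px"],
                          meta["width_px"])
    return StimulusMovie.from_frames(frames, meta["ppd"],
                                     meta["frame_rate_hz"],
                                     tuple(meta["fov_deg"]))


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, seeds: dict, inputs=(), outputs=(),
                   include_timestamp: bool = True) -> dict:
    """Record config hash, per-stage seeds and file digests for a run."""
    from gazefield import __version__

    manifest = {
        "package_version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    if include_timestamp:
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True)
                          + "\n")
    return manifest
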