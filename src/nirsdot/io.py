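"""File formats: SNIRF-style HDF5 recordings, TSV fallbacks, cohort fixture.

The HDF5 layout is a simplified SNIRF-style schema:

    /format            "nirsdot-snirf-like 1.0"
    /data/intensity    (channels, wavelengths, time) float64
    /data/fs           scalar Hz
    /probe/source      channel source names (bytes)
    /probe/detector    channel detector names
    /probe/wavelengths (n_wl,) nm
    /events/onset_s, /events/label
    /artifacts/onset_s, /artifacts/duration_s

A plain-TSV fallback (one wide table plus sidecar event/artifact TSVs)
round-trips to the identical in-memory objects.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventSet
from .preprocess import RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_recording_tsv",
    "read_recording_tsv",
    "write_hemo_images",
    "load_cohort_table",
    "cohort_field",
]

_FORMAT = "nirsdot-snirf-like 1.0"


def write_recording(rec: RawRecording, path, events: EventSet | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        d = f.create_group("data")
        d.create_dataset("intensity", data=rec.intensity)
        d.create_dataset("fs", data=float(rec.fs))
        p = f.create_group("probe")
        p.create_dataset("source", data=np.array([s for s, _ in rec.channel_ids], dtype="S"))
        p.create_dataset("detector", data=np.array([d_ for _, d_ in rec.channel_ids], dtype="S"))
        p.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        a = f.create_group("artifacts")
        segs = np.asarray(rec.artifact_segments, float).reshape(-1, 2)
        a.create_dataset("onset_s", data=segs[:, 0])
        a.create_dataset("duration_s", data=segs[:, 1] - segs[:, 0])
        if events is not None:
            e = f.create_group("events")
            e.create_dataset("onset_s", data=np.asarray(events.times, float))
            e.create_dataset("label", data=np.array(list(events.labels), dtype="S"))
            e.attrs["run_id"] = events.run_id


def read_recording(path) -> tuple[RawRecording, EventSet | None]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} file")
        if "probe" not in f:
            raise ValueError(f"{path}: missing /probe group")
        srcs = [s.decode() for s in f["probe/source"][()]]
        dets = [s.decode() for s in f["probe/detector"][()]]
        wls = tuple(int(w) for w in f["probe/wavelengths"][()])
        on = f["artifacts/onset_s"][()]
        du = f["artifacts/duration_s"][()]
        rec = RawRecording(
            channel_ids=list(zip(srcs, dets)),
            intensity=f["data/intensity"][()],
            fs=float(f["data/fs"][()]),
            wavelengths=wls,
            artifact_segments=[(float(a), float(a + b)) for a, b in zip(on, du)],
        )
        ev = None
        if "events" in f:
            ev = EventSet(
                times=f["events/onset_s"][()],
                labels=np.array([s.decode() for s in f["events/label"][()]], object),
                run_id=str(f["events"].attrs.get("run_id", "run-1")),
            )
    return rec, ev


def write_recording_tsv(rec: RawRecording, path, events: EventSet | None = None) -> None:
    """Wide TSV: time_s column plus one column per channel x wavelength."""
    path = Path(path)
    nt = rec.intensity.shape[-1]
    cols = {"time_s": np.arange(nt) / rec.fs}
    for ci, (s, d) in enumerate(rec.channel_ids):
        for wi, wl in enumerate(rec.wavelengths):
            cols[f"{s}-{d}@{wl}"] = rec.intensity[ci, wi]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    segs = np.asarray(rec.artifact_segments, float).reshape(-1, 2)
    pd.DataFrame({"onset_s": segs[:, 0], "duration_s": segs[:, 1] - segs[:, 0]}).to_csv(
        path.with_suffix(".artifacts.tsv"), sep="\t", index=False
    )
    if events is not None:
        events.to_tsv(path.with_suffix(".events.tsv"))


def read_recording_tsv(path) -> tuple[RawRecording, EventSet | None]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    dt = np.diff(df["time_s"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    chan_wl: dict[tuple[str, str], dict[int, np.ndarray]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        pair, wl = col.rsplit("@", 1)
        s, d = pair.split("-", 1)
        chan_wl.setdefault((s, d), {})[int(wl)] = df[col].to_numpy(float)
    channels = sorted(chan_wl)
    wls = tuple(sorted(next(iter(chan_wl.values()))))
    intensity = np.stack(
        [np.stack([chan_wl[ch][wl] for wl in wls], axis=0) for ch in channels], axis=0
    )
    art = pd.read_csv(path.with_suffix(".artifacts.tsv"), sep="\t")
    segs = [(float(a), float(a + b)) for a, b in zip(art["onset_s"], art["duration_s"])]
    rec = RawRecording(
        channel_ids=channels, intensity=intensity, fs=round(fs, 6), wavelengths=wls,
        artifact_segments=segs,
    )
    ev_path = path.with_suffix(".events.tsv")
    ev = EventSet.from_tsv(ev_path) if ev_path.exists() else None
    return rec, ev


def write_hemo_images(images, grid_shape, voxel_size_mm, out_dir) -> None:
    """Export per-event reconstructions: one 4-D NIfTI per chromophore per
    event (zero outside the FOV), an HDF5 bundle, and the FOV voxel TSV."""
    import nibabel as nib

    from .reconstruction import CHROMOPHORES

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    fov = np.asarray(images[0].fov_voxels, int)
    pd.DataFrame(fov, columns=["i", "j", "k"]).to_csv(out / "fov_voxels.tsv", sep="\t", index=False)
    with h5py.File(out / "hemo_images.h5", "w") as f:
        f.attrs["fs"] = images[0].fs
        f.create_dataset("fov_voxels", data=fov)
        for im in images:
            f.create_dataset(f"events/{im.event_id}", data=im.values)
    for im in images:
        for ci, chrom in enumerate(CHROMOPHORES):
            dense = np.zeros(tuple(grid_shape) + (im.values.shape[-1],), dtype=np.float32)
            dense[fov[:, 0], fov[:, 1], fov[:, 2], :] = im.values[:, ci, :]
            nib.save(
                nib.Nifti1Image(dense, affine),
                str(out / f"{im.event_id}_{chrom}.nii.gz"),
            )


def load_cohort_table() -> pd.DataFrame:
    """Bundled per-patient response summary table (both hemispheres)."""
    with resources.files("nirsdot.data").joinpath("cohort_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_field(side: str, column: str) -> np.ndarray:
    """One summary column for one side, patients without a response dropped."""
    df = load_cohort_table()
    sel = df[(df["side"] == side) & (df["hr_detected"] == 1)]
    return sel[column].to_numpy(float)
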