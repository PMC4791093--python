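"""Standard-format I/O: scheme files, signal tables, NIfTI volumes, config.

The plain-text scheme file carries the full protocol (pulse onsets/lengths,
amplitude, echo time, b = 0 count) plus one row per measurement mapping it
to an arrangement and gradient direction; a conventional bval/bvec pair can
be emitted for third-party tools.  Image data are 4-D NIfTI-1 volumes with
a binary mask; parameter maps are written one scalar volume per summary
with NaN background, radius in micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .protocol import (
    Protocol,
    PulseArrangement,
    infer_polarities,
)


@dataclass
class VoxelDataset:
    """One voxel's measurements, ordered to match the protocol index."""

    signals: np.ndarray
    voxel: tuple[int, int, int] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


def save_scheme(protocol: Protocol, path) -> None:
    doc = {
        "echo_time_ms": protocol.arrangements[0].echo_time,
        "n_b0": protocol.n_b0,
        "gyromagnetic_ratio": protocol.gyromagnetic_ratio,
        "arrangements": [
            {
                "onsets_ms": list(a.onsets),
                "lengths_ms": list(a.lengths),
                "amplitude_T_per_m": a.amplitude,
                "polarities": list(a.polarities) if a.polarities else None,
            }
            for a in protocol.arrangements
        ],
        "measurements": [
            {"arrangement": int(i), "direction": None if d is None else [float(v) for v in d]}
            for i, d in protocol.measurement_table()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scheme(path) -> Protocol:
    doc = yaml.safe_load(Path(path).read_text())
    arrs = []
    for a in doc["arrangements"]:
        arr = PulseArrangement(
            onsets=tuple(a["onsets_ms"]),
            lengths=tuple(a["lengths_ms"]),
            amplitude=a["amplitude_T_per_m"],
            echo_time=doc["echo_time_ms"],
            polarities=tuple(a["polarities"]) if a.get("polarities") else None,
        )
        if arr.n_pulses and arr.polarities is None:
            arr = infer_polarities(arr)
        arrs.append(arr)
    dirs: list[list] = [[] for _ in arrs]
    for m in doc["measurements"]:
        if m["direction"] is not None:
            dirs[m["arrangement"]].append(m["direction"])
    directions = tuple(
        np.asarray(d) if d else np.empty((0, 3)) for d in dirs
    )
    return Protocol(
        arrangements=tuple(arrs),
        directions=directions,
        n_b0=doc["n_b0"],
        gyromagnetic_ratio=doc.get("gyromagnetic_ratio", 2.6752e8),
    )


def write_bval_bvec(protocol: Protocol, prefix) -> None:
    """Conventional FSL-style bval/bvec pair for interoperability."""
    b = protocol.measurement_bvalues()
    vecs = np.zeros((3, len(b)))
    for k, (i, d) in enumerate(protocol.measurement_table()):
        if d is not None:
            vecs[:, k] = d
    prefix = str(prefix)
    np.savetxt(prefix + ".bval", b[None, :], fmt="%.1f")
    np.savetxt(prefix + ".bvec", vecs, fmt="%.6f")


def save_signal_table(datasets: list[VoxelDataset], path) -> None:
    """Tab-separated table: one column per dataset, one row per measurement."""
    cols = {}
    for j, ds in enumerate(datasets):
        name = f"voxel{j}" if ds.voxel is None else "_".join(map(str, ds.voxel))
        cols[name] = ds.signals
    pd.DataFrame(cols).to_csv(path, sep="\t", index_label="measurement")


def load_signal_table(path) -> list[VoxelDataset]:
    df = pd.read_csv(path, sep="\t", index_col="measurement")
    return [
        VoxelDataset(signals=df[c].to_numpy(), provenance={"source": str(path), "column": c})
        for c in df.columns
    ]


def load_image_dataset(
    image_path, mask_path, protocol: Protocol, n_dummy: int = 1
) -> list[VoxelDataset]:
    """Per-voxel signal vectors from a 4-D NIfTI volume inside a mask.

    The first ``n_dummy`` leading volumes are discarded (dummy b = 0
    acquisitions); the remaining count must match the protocol.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    mask = np.asanyarray(msk.dataobj) > 0
    if data.ndim != 4:
        raise ValueError("image must be 4-D")
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match mask grid {mask.shape}"
        )
    usable = data.shape[3] - n_dummy
    if usable != protocol.n_measurements:
        raise ValueError(
            f"{usable} usable volumes but protocol defines "
            f"{protocol.n_measurements} measurements"
        )
    out = []
    for x, y, z in zip(*np.nonzero(mask)):
        out.append(
            VoxelDataset(
                signals=data[x, y, z, n_dummy:].astype(float),
                voxel=(int(x), int(y), int(z)),
                provenance={"source": str(image_path), "n_dummy": n_dummy},
            )
        )
    if not out:
        import warnings

        warnings.warn("mask selects no voxels", stacklevel=2)
    return out


# map name -> (summary key, scaling applied before writing)
_MAP_SPECS = {
    "radius_index_um": ("radius_index", 1e6),
    "f_r": ("f_r_median", 1.0),
    "f_i": ("f_i_median", 1.0),
    "D_par": ("D_par_median", 1.0),
    "D_perp": ("D_perp_median", 1.0),
}


def write_maps(results: dict, reference_image, out_dir, extra: dict | None = None):
    """Write one scalar NIfTI volume per parameter summary.

    ``results`` maps voxel coordinates to summary dicts (from
    :func:`dsemicro.inference.summarize`); ``extra`` maps additional map
    names to {voxel: value} dicts (e.g. FA, R2, CoV).  Background is NaN;
    the radius map is stored in micrometers (noted in the header
    description).
    """
    ref = (
        nib.load(str(reference_image))
        if not isinstance(reference_image, nib.Nifti1Image)
        else reference_image
    )
    shape = ref.shape[:3]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    layers = {
        name: {vox: summ[key] * scale for vox, summ in results.items()}
        for name, (key, scale) in _MAP_SPECS.items()
    }
    for name, vals in (extra or {}).items():
        layers[name] = vals
    for name, vals in layers.items():
        vol = np.full(shape, np.nan, dtype=np.float32)
        for vox, v in vals.items():
            if not all(0 <= c < s for c, s in zip(vox, shape)):
                raise ValueError(f"voxel {vox} outside image grid {shape}")
            vol[vox] = v
        img = nib.Nifti1Image(vol, ref.affine, ref.header)
        img.header["descrip"] = (
            b"radius index, micrometres" if name == "radius_index_um" else name.encode()[:79]
        )
        path = out_dir / f"{name}.nii.gz"
        nib.save(img, str(path))
        written[name] = path
    return written


@dataclass
class RunConfig:
    """Serializable description of a fitting run."""

    scheme: str | None = None
    burn_in: int = 50_000
    n_samples: int = 50
    thin: int = 100
    seed: int = 0
    fix_f_i: bool = False
    disabled_priors: list = field(default_factory=list)
    snr: float | None = None
    notes: str = ""

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
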