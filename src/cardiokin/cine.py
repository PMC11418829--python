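"""Reading and preprocessing of short-axis cine-MRI slice sequences.

The unit of analysis is one short-axis slice observed through the cardiac
cycle: a 2D+t grayscale stack.  Volumes arrive as 4D NIfTI files (X, Y,
slice, time) in the ACDC per-patient layout, with the diagnostic class
recorded in an ``Info.cfg`` (``Group: DCM``) or a ``labels.yaml`` side file.

Preprocessing fixes the temporal and spatial geometry the downstream
network expects: the cycle is resampled to a fixed number of frames
(default 13, always retaining the end-diastolic first frame and the final
frame so both extremes of the cycle are covered), frames are center-cropped
to square and resized to 128x128, and intensities are min-max normalized
per sequence to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from skimage.transform import resize

CLASS_LABELS = ("DCM", "HCM", "MINF", "N", "RV")

__all__ = [
    "CLASS_LABELS",
    "CineSequence",
    "read_cine_volume",
    "read_labels",
    "resample_cycle",
    "preprocess_frames",
    "save_sequence",
    "load_sequence",
]


@dataclass
class CineSequence:
    """One slice-level 2D+t image stack with identity and label.

    Attributes
    ----------
    frames : ndarray, shape (L, H, W)
        Grayscale frames in temporal order; arbitrary intensity units
        before preprocessing, [0, 1] after.
    patient_id : str
    slice_index : int
    label : str
        One of :data:`CLASS_LABELS` or ``"unknown"``.
    pixel_spacing : tuple of float or None
        In-plane spacing (mm, mm) when known; informational only.
    frame_indices : ndarray of int
        Original frame indices retained after resampling.  Strictly
        relative to the *original* recording: first element 0, last
        element original ``L - 1``.
    """

    frames: np.ndarray
    patient_id: str = "unknown"
    slice_index: int = 0
    label: str = "unknown"
    pixel_spacing: tuple[float, float] | None = None
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (L, H, W) stack, got ndim={self.frames.ndim}"
            )
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.frames.shape[0])
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


def _patient_id_from_path(path: Path) -> str:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    # ACDC convention: patientXXX/patientXXX_4d.nii.gz
    if stem.endswith("_4d"):
        stem = stem[:-3]
    return stem


def _parse_info_cfg(path: Path) -> str | None:
    for line in path.read_text().splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            if key.strip() == "Group":
                return value.strip()
    return None


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a patient_id -> class-label mapping.

    Accepts either a YAML mapping file or an ACDC ``Info.cfg`` dialect
    (``Group: DCM`` lines; then the mapping has a single entry keyed by the
    parent directory name).
    """
    path = Path(path)
    if path.name == "Info.cfg":
        group = _parse_info_cfg(path)
        return {path.parent.name: group} if group else {}
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"label file {path} does not contain a mapping")
    return {str(k): str(v) for k, v in data.items()}


def _lookup_label(path: Path, patient_id: str) -> str:
    info = path.parent / "Info.cfg"
    if info.exists():
        group = _parse_info_cfg(info)
        if group:
            return group
    for candidate in (path.parent / "labels.yaml", path.parent.parent / "labels.yaml"):
        if candidate.exists():
            mapping = read_labels(candidate)
            if patient_id in mapping:
                return mapping[patient_id]
    return "unknown"


def read_cine_volume(path: str | Path, slice_index: int) -> CineSequence:
    """Extract one short-axis slice from a 4D NIfTI cine volume.

    Parameters
    ----------
    path : path to a 4D NIfTI file, axis order (X, Y, slice, time).
    slice_index : which short-axis slice to extract.

    Returns
    -------
    CineSequence with ``L`` = number of temporal frames, raw intensities,
    and the label resolved from an ``Info.cfg`` or ``labels.yaml`` side
    file when one is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cine volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4D cine volume, got {data.ndim}D data in {path}"
        )
    n_slices = data.shape[2]
    if not 0 <= slice_index < n_slices:
        raise IndexError(
            f"slice_index {slice_index} out of range for volume with "
            f"{n_slices} slices"
        )
    frames = np.moveaxis(data[:, :, slice_index, :], -1, 0).astype(np.float64)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    patient_id = _patient_id_from_path(path)
    return CineSequence(
        frames=frames,
        patient_id=patient_id,
        slice_index=int(slice_index),
        label=_lookup_label(path, patient_id),
        pixel_spacing=spacing,
    )


def resample_cycle(seq: CineSequence, target_len: int = 13) -> CineSequence:
    """Resample the cardiac cycle to a fixed number of frames.

    Frames are selected at uniformly spaced original indices (rounded
    half-up), always including the first and last frame so end-diastole
    and end-systole are covered.  Longer cycles are sub-sampled; shorter
    cycles are extended by nearest-index repetition.  Idempotent when the
    sequence already has ``target_len`` frames.
    """
    if target_len < 2:
        raise ValueError(f"target_len must be >= 2, got {target_len}")
    L = seq.n_frames
    if L < 2:
        raise ValueError(f"sequence must have at least 2 frames, got {L}")
    # round-half-up of linspace keeps selection deterministic across platforms
    positions = np.linspace(0.0, L - 1, target_len)
    indices = np.floor(positions + 0.5).astype(int)
    return replace(
        seq,
        frames=seq.frames[indices],
        frame_indices=seq.frame_indices[indices],
    )


def _center_crop_square(frame: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    return frame[top : top + side, left : left + side]


def preprocess_frames(seq: CineSequence, size: int = 128) -> CineSequence:
    """Spatially normalize frames to ``size`` x ``size`` and scale to [0, 1].

    Each frame is center-cropped to its short side, resized with bilinear
    interpolation, and the whole sequence min-max normalized.  A
    constant-intensity sequence maps to all zeros.
    """
    cropped = np.stack([_center_crop_square(f) for f in seq.frames])
    if cropped.shape[1] != size:
        out = np.stack(
            [
                resize(f, (size, size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
                for f in cropped
            ]
        )
    else:
        out = cropped.astype(np.float64)
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return replace(seq, frames=out)


def save_sequence(seq: CineSequence, path: str | Path) -> Path:
    """Persist a sequence as a compressed array archive + JSON sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, frames=seq.frames, frame_indices=seq.frame_indices)
    sidecar = {
        "patient_id": seq.patient_id,
        "slice_index": seq.slice_index,
        "label": seq.label,
        "pixel_spacing": list(seq.pixel_spacing) if seq.pixel_spacing else None,
        "frame_indices": [int(i) for i in seq.frame_indices],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_sequence(path: str | Path) -> CineSequence:
    path = Path(path).with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spacing = tuple(meta["pixel_spacing"]) if meta.get("pixel_spacing") else None
    return CineSequence(
        frames=arrays["frames"],
        patient_id=meta["patient_id"],
        slice_index=meta["slice_index"],
        label=meta["label"],
        pixel_spacing=spacing,
        frame_indices=np.asarray(meta["frame_indices"], dtype=int),
    )
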