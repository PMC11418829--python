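"""Beating-annulus cine phantoms with class-specific kinematic signatures.

Real short-axis cine-MRI shows the left-ventricular myocardium as a bright
ring contracting and twisting through the cardiac cycle.  The phantom
reduces that to its kinematic essentials: a textured annulus whose inner
radius follows a single-harmonic cycle

    r(t) = r_es + (r_ed - r_es) * (1 + cos(2*pi*t/(n-1))) / 2

so end-diastole sits at t = 0 (and returns at t = n-1) and end-systole at
mid-cycle, with cumulative in-plane twist.  Five presets mimic the
kinematic signatures of the standard diagnostic classes:

* ``N``    - strong contraction, moderate twist (healthy control);
* ``MINF`` - normal geometry with one akinetic sector frozen at its
  end-diastolic shape (regional infarct);
* ``DCM``  - dilated cavity, contraction amplitude under 25% of normal;
* ``HCM``  - wall at least twice the normal thickness, normal contraction;
* ``RV``   - a dilated, hypokinetic second cavity beside the first.

The angular intensity texture makes rotation observable to optical flow
(a homogeneous ring would be rotation-blind due to the aperture problem).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from pathlib import Path

from .cine import CineSequence

__all__ = ["PhantomParams", "CLASS_PRESETS", "generate_phantom", "generate_cohort",
           "write_cohort"]


@dataclass
class PhantomParams:
    """Geometry and dynamics of one beating-annulus phantom.

    Radii and thickness are in pixels at ``image_size``; twist is the
    in-plane rotation per frame in degrees; ``akinetic_sector`` is a
    (start, end) angle pair in degrees or ``None``; ``noise_sd`` is the
    additive Gaussian noise level in intensity units.
    """

    image_size: int = 64
    n_frames: int = 13
    inner_radius_ed: float = 16.0
    inner_radius_es: float = 9.0
    wall_thickness: float = 6.0
    twist_deg_per_frame: float = 2.0
    akinetic_sector: tuple[float, float] | None = None
    second_cavity: bool = False
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.inner_radius_es > self.inner_radius_ed:
            raise ValueError("inner_radius_es must be <= inner_radius_ed")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")


# Presets at image_size 64; radii scale linearly with image_size.
CLASS_PRESETS: dict[str, PhantomParams] = {
    "N": PhantomParams(inner_radius_ed=16.0, inner_radius_es=9.0,
                       wall_thickness=6.0, twist_deg_per_frame=2.0),
    "MINF": PhantomParams(inner_radius_ed=16.0, inner_radius_es=9.0,
                          wall_thickness=6.0, twist_deg_per_frame=2.0,
                          akinetic_sector=(-20.0, 110.0)),
    # amplitude 1.5 px < 25% of N's 7 px
    "DCM": PhantomParams(inner_radius_ed=22.0, inner_radius_es=20.5,
                         wall_thickness=4.0, twist_deg_per_frame=1.0),
    "HCM": PhantomParams(inner_radius_ed=14.0, inner_radius_es=8.0,
                         wall_thickness=12.0, twist_deg_per_frame=2.0),
    "RV": PhantomParams(inner_radius_ed=12.0, inner_radius_es=10.8,
                        wall_thickness=4.0, twist_deg_per_frame=0.5,
                        second_cavity=True),
}

_EDGE = 0.8          # sigmoid edge softness, px
_TEX_HARMONIC = 8    # angular texture period count
_TEX_AMPLITUDE = 0.35


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x / _EDGE, -60, 60)))


def _radius_at(t: int, n: int, r_ed: float, r_es: float) -> float:
    return r_es + (r_ed - r_es) * (1.0 + np.cos(2.0 * np.pi * t / (n - 1))) / 2.0


def _render_ring(r: np.ndarray, theta: np.ndarray, r_in: np.ndarray,
                 wall: float, twist_rad: np.ndarray) -> np.ndarray:
    ring = _sigmoid(r - r_in) * _sigmoid(r_in + wall - r)
    texture = 1.0 + _TEX_AMPLITUDE * np.cos(_TEX_HARMONIC * (theta - twist_rad))
    cavity = 0.2 * _sigmoid(r_in - r)
    return cavity + 0.9 * ring * texture


def _sector_weight(theta: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    """Smooth membership of angle theta (rad) in [start, end] degrees."""
    start, end = np.deg2rad(sector[0]), np.deg2rad(sector[1])
    mid = (start + end) / 2.0
    half = (end - start) / 2.0
    # wrapped angular distance to sector midline
    d = np.abs(np.angle(np.exp(1j * (theta - mid))))
    ramp = np.deg2rad(10.0)
    return np.clip((half + ramp / 2.0 - d) / ramp, 0.0, 1.0)


def generate_phantom(label: str, params: PhantomParams | None = None) -> CineSequence:
    """Render one beating-annulus phantom for the given diagnostic class.

    Deterministic given ``params.seed``.  Uses the class preset when
    ``params`` is omitted.
    """
    if label not in CLASS_PRESETS:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {sorted(CLASS_PRESETS)}"
        )
    if params is None:
        params = CLASS_PRESETS[label]
    params.validate()

    n = params.image_size
    scale = n / 64.0
    half = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    # main cavity shifted left when a second cavity must fit beside it
    cx_off = -0.14 * n if params.second_cavity else 0.0
    x = cols - half - cx_off
    y = rows - half
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    rng = np.random.default_rng(params.seed)
    frames = np.empty((params.n_frames, n, n))
    for t in range(params.n_frames):
        r_t = scale * _radius_at(t, params.n_frames,
                                 params.inner_radius_ed, params.inner_radius_es)
        r_ed = scale * params.inner_radius_ed
        twist = np.deg2rad(params.twist_deg_per_frame) * t
        if params.akinetic_sector is not None:
            w = _sector_weight(theta, params.akinetic_sector)
            r_in = (1.0 - w) * r_t + w * r_ed
            twist_map = (1.0 - w) * twist
        else:
            r_in = np.full_like(r, r_t)
            twist_map = np.full_like(r, twist)
        img = 0.05 + _render_ring(r, theta, r_in, scale * params.wall_thickness,
                                  twist_map)
        if params.second_cavity:
            # smaller hypokinetic crescent-side cavity (right-ventricle-like)
            r2_ed, r2_es, wall2 = 9.0 * scale, 8.2 * scale, 3.0 * scale
            x2 = cols - half - 0.27 * n
            y2 = y
            rr2 = np.hypot(x2, y2)
            th2 = np.arctan2(y2, x2)
            r2_t = r2_es + (r2_ed - r2_es) * (1 + np.cos(2 * np.pi * t /
                                                         (params.n_frames - 1))) / 2
            img = img + _render_ring(rr2, th2, np.full_like(rr2, r2_t), wall2,
                                     np.zeros_like(rr2))
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        frames[t] = img

    return CineSequence(frames=frames, patient_id=f"{label}-phantom",
                        slice_index=0, label=label)


def generate_cohort(n_per_class: int, base_params: PhantomParams | None = None,
                    seed: int = 0) -> list[CineSequence]:
    """Generate a balanced labelled cohort of phantoms.

    Returns ``5 * n_per_class`` sequences with unique patient ids.  Each
    sequence takes its class preset with radii, wall thickness, and twist
    jittered uniformly by +/-10%, from per-sequence substreams of a single
    master seed, so cohorts are reproducible and distinct across seeds.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.SeedSequence(seed)
    labels = sorted(CLASS_PRESETS)
    children = master.spawn(len(labels) * n_per_class)
    cohort: list[CineSequence] = []
    k = 0
    for label in labels:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            preset = CLASS_PRESETS[label]
            if base_params is not None:
                preset = replace(
                    preset,
                    image_size=base_params.image_size,
                    n_frames=base_params.n_frames,
                    noise_sd=base_params.noise_sd,
                )
            amp = preset.inner_radius_ed - preset.inner_radius_es

            def jitter(v: float) -> float:
                return v * rng.uniform(0.9, 1.1)

            r_ed = jitter(preset.inner_radius_ed)
            params = replace(
                preset,
                inner_radius_ed=r_ed,
                inner_radius_es=r_ed - jitter(amp),
                wall_thickness=jitter(preset.wall_thickness),
                twist_deg_per_frame=jitter(preset.twist_deg_per_frame),
                seed=int(children[k].generate_state(1)[0] % (2**31)),
            )
            seq = generate_phantom(label, params)
            seq.patient_id = f"{label}{i:03d}"
            cohort.append(seq)
            k += 1
    return cohort


def write_cohort(cohort: list[CineSequence], outdir: str | Path) -> Path:
    """Write a cohort as per-patient 4D NIfTI files plus a labels.yaml.

    The layout is exactly what :func:`cardiokin.cine.read_cine_volume`
    reads back: ``<outdir>/<patient_id>_4d.nii.gz`` with axis order
    (X, Y, slice, time), and a ``labels.yaml`` patient->label mapping.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels: dict[str, str] = {}
    for seq in cohort:
        data = np.moveaxis(seq.frames, 0, -1)[:, :, np.newaxis, :]
        img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
        nib.save(img, str(outdir / f"{seq.patient_id}_4d.nii.gz"))
        labels[seq.patient_id] = seq.label
    (outdir / "labels.yaml").write_text(yaml.safe_dump(labels))
    return outdir
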