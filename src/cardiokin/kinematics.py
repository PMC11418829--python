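"""Kinematic maps derived from dense velocity fields.

Treating the inter-frame displacement field ``v = (u, v)`` as a planar
velocity in pixels/frame, four standard differential descriptors of
cardiac motion are computed:

* divergence  ``div = du/dx + dv/dy``  (1/frame) - local contraction is
  negative, expansion positive;
* vorticity   ``vor = dv/dx - du/dy``  (1/frame) - local rotational
  motion (myocardial twist);
* tangential acceleration ``a_T = (v . a) / |v|`` (px/frame^2) - rate of
  speed change along the motion direction;
* normal acceleration ``a_N = |u_x a_y - u_y a_x| / |v|`` (px/frame^2) -
  rate of direction change, i.e. the component of ``a`` perpendicular to
  ``v``; non-negative by construction.

Here ``a = dv/dt`` is the forward temporal difference of consecutive flow
fields.  Spatial derivatives use centered finite differences in the
interior and one-sided differences at the borders, on a unit pixel grid
(x = column index increasing rightward, y = row index increasing
downward).  Where the speed falls below ``eps`` both acceleration
components are defined as 0.  Wherever ``|v| >= eps`` the decomposition
is complete: ``a_T**2 + a_N**2 == |a|**2``.

Maps are assembled into the network input tensor: a (T, H, W, C) stack of
named channels, each standardized per sequence to zero mean and unit
variance (a constant channel maps to zeros).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .flow import FlowField, FlowSequence

SUPPORTED_CHANNELS = ("u", "v", "div", "vor", "a_N", "a_T", "intensity")
#: canonical ordering used when fusing descriptors
CANONICAL_ORDER = ("a_N", "div", "vor", "a_T", "intensity", "u", "v")

__all__ = ["SUPPORTED_CHANNELS", "KinematicStack", "divergence_map",
           "vorticity_map", "acceleration_maps", "build_kinematic_stack",
           "save_stack", "load_stack"]


@dataclass
class KinematicStack:
    """Named multi-channel 2D+t kinematic tensor, the network input.

    ``data`` has shape (T, H, W, C) with C == len(channel_names).
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    label: str = "unknown"
    patient_id: str = "unknown"
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError("data must be (T, H, W, C)")
        if self.data.shape[-1] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def divergence_map(flow: FlowField) -> np.ndarray:
    """Planar divergence of the velocity field, in 1/frame."""
    du_dx = np.gradient(flow.u, axis=1)
    dv_dy = np.gradient(flow.v, axis=0)
    return du_dx + dv_dy


def vorticity_map(flow: FlowField) -> np.ndarray:
    """Out-of-plane vorticity (scalar curl) of the velocity field, 1/frame."""
    dv_dx = np.gradient(flow.v, axis=1)
    du_dy = np.gradient(flow.u, axis=0)
    return dv_dx - du_dy


def acceleration_maps(flow_t: FlowField, flow_t1: FlowField,
                      eps: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Tangential and normal acceleration from two consecutive flow fields.

    Returns ``(a_T, a_N)``.  The temporal derivative is the forward
    difference ``flow_t1 - flow_t``; projection uses the velocity at time
    t.  Below the speed floor ``eps`` both components are 0.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if flow_t.shape != flow_t1.shape:
        raise ValueError(
            f"flow shapes differ: {flow_t.shape} vs {flow_t1.shape}"
        )
    ax = flow_t1.u - flow_t.u
    ay = flow_t1.v - flow_t.v
    speed = np.hypot(flow_t.u, flow_t.v)
    moving = speed >= eps
    safe = np.where(moving, speed, 1.0)
    a_t = np.where(moving, (flow_t.u * ax + flow_t.v * ay) / safe, 0.0)
    a_n = np.where(moving, np.abs(flow_t.u * ay - flow_t.v * ax) / safe, 0.0)
    return a_t, a_n


def _standardize(channel: np.ndarray) -> np.ndarray:
    sd = channel.std()
    if sd == 0:
        return np.zeros_like(channel)
    return (channel - channel.mean()) / sd


def build_kinematic_stack(flow_seq: FlowSequence,
                          channels: list[str] | tuple[str, ...],
                          eps: float = 1e-3,
                          frames: np.ndarray | None = None,
                          standardize: bool = True) -> KinematicStack:
    """Assemble the (T, H, W, C) network input from a flow sequence.

    ``T == len(flow_seq)`` (12 for a 13-frame cycle).  Acceleration
    channels at time t use the flow pair (t, t+1); the final time index
    reuses the last available pair so the temporal depth matches the
    other channels.  The ``intensity`` channel requires the source frames
    (the first T are used).  Each channel is z-scored per sequence unless
    ``standardize`` is disabled.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("channels must be non-empty")
    unknown = [c for c in channels if c not in SUPPORTED_CHANNELS]
    if unknown:
        raise ValueError(
            f"unknown channel(s) {unknown}; supported: {SUPPORTED_CHANNELS}"
        )
    T = len(flow_seq)
    if T < 1:
        raise ValueError("flow sequence is empty")
    if "intensity" in channels and frames is None:
        raise ValueError("'intensity' channel requires the source frames")

    need_accel = any(c in ("a_N", "a_T") for c in channels)
    accel: list[tuple[np.ndarray, np.ndarray]] = []
    if need_accel:
        for t in range(T):
            t0 = min(t, T - 2) if T >= 2 else 0
            if T == 1:
                z = np.zeros(flow_seq[0].shape)
                accel.append((z, z.copy()))
            else:
                accel.append(acceleration_maps(flow_seq[t0], flow_seq[t0 + 1], eps))

    planes = {
        "u": lambda t: flow_seq[t].u,
        "v": lambda t: flow_seq[t].v,
        "div": lambda t: divergence_map(flow_seq[t]),
        "vor": lambda t: vorticity_map(flow_seq[t]),
        "a_T": lambda t: accel[t][0],
        "a_N": lambda t: accel[t][1],
        "intensity": lambda t: np.asarray(frames)[t],
    }
    data = np.stack(
        [np.stack([planes[c](t) for c in channels], axis=-1) for t in range(T)]
    )
    if standardize:
        for ci in range(data.shape[-1]):
            data[..., ci] = _standardize(data[..., ci])
    return KinematicStack(data=data, channel_names=channels,
                          label=flow_seq.label, patient_id=flow_seq.patient_id,
                          slice_index=flow_seq.slice_index)


def save_stack(stack: KinematicStack, path: str | Path, eps: float = 1e-3) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, data=stack.data)
    sidecar = {
        "channel_names": list(stack.channel_names),
        "label": stack.label,
        "patient_id": stack.patient_id,
        "slice_index": stack.slice_index,
        "eps": eps,
        "standardization": "per-sequence z-score",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_stack(path: str | Path) -> KinematicStack:
    path = Path(path).with_suffix(".npz")
    data = np.load(path)["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return KinematicStack(data=data, channel_names=tuple(meta["channel_names"]),
                          label=meta["label"], patient_id=meta["patient_id"],
                          slice_index=meta["slice_index"])
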