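"""Per-frame geometric observables of the troponin domain motion.

The principal motion of the Ca2+-saturated troponin core is a hinge motion
between the regulatory N-terminal domain of troponin C (NcTnC) and the
quasi-rigid ITC arm.  This module computes, per trajectory frame:

* the interdomain hinge angle — the angle at the centroid of the TnC
  C-lobe (the "fulcrum") between the vector to the NcTnC centroid and the
  vector to the end of the IT arm;
* the A/B interhelical angle — the supplement of the angle between the
  axes of TnC helix A and helix B, the classic open/closed metric of the
  NcTnC hydrophobic patch (>110 deg is conventionally "open");
* centroid-to-centroid distances (e.g. NcTnC to CcTnC).

Helix axes follow the endpoint-average convention: each axis endpoint is
the mean of a window of alpha-carbon coordinates taken from each end of
the helix, and the axis is oriented N-terminus -> C-terminus.

All quantities are internal to the structure and therefore invariant under
global rigid-body motion; no superposition is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .structure_io import (
    SelectionExpr,
    Topology,
    Trajectory,
    parse_selection,
    resolve_selection_union,
)

__all__ = [
    "GeometryError",
    "HingeDefinition",
    "HelixDefinition",
    "AngleSeries",
    "DEFAULT_MANIFEST",
    "centroid",
    "hinge_angle",
    "helix_axis",
    "interhelical_angle",
    "pair_distance",
    "hinge_series",
    "interhelical_series",
    "distance_series",
    "metric_series",
]


class GeometryError(ValueError):
    """Raised on degenerate geometry (coincident centroids, zero axes)."""


def _as_exprs(sels) -> tuple[SelectionExpr, ...]:
    if isinstance(sels, (str, SelectionExpr)):
        sels = [sels]
    return tuple(parse_selection(s) if isinstance(s, str) else s for s in sels)


@dataclass(frozen=True)
class HingeDefinition:
    """Three centroid anchors of the hinge angle.

    ``arm_end`` may union multiple subunit ranges; the pooled atoms are
    averaged into a single joint centroid.
    """

    head: tuple[SelectionExpr, ...]
    hinge: tuple[SelectionExpr, ...]
    arm_end: tuple[SelectionExpr, ...]

    @classmethod
    def create(cls, head, hinge, arm_end) -> "HingeDefinition":
        return cls(_as_exprs(head), _as_exprs(hinge), _as_exprs(arm_end))


@dataclass(frozen=True)
class HelixDefinition:
    """A helix selection plus the alpha-carbon endpoint-window size."""

    subunit: str
    lo: int
    hi: int
    endpoint_window: int = 10

    def __post_init__(self):
        if self.hi - self.lo + 1 < 4:
            raise GeometryError("helix must span at least 4 residues")
        if self.endpoint_window < 1:
            raise GeometryError("endpoint window must be >= 1")

    @property
    def selection(self) -> SelectionExpr:
        return SelectionExpr(self.subunit, self.lo, self.hi, "CA")


@dataclass
class AngleSeries:
    """Per-frame scalar metric values (degrees or Angstrom)."""

    values: np.ndarray
    metric_name: str
    run_ids: np.ndarray
    frame_indices: np.ndarray
    n_failed: int = 0


#: The default troponin metric manifest: NcTnC head TnC 3-85, C-lobe fulcrum
#: TnC 94-157, IT-arm end pooled over TnT 241-251 and TnI 69-76; helix A
#: TnC 14-25 and helix B TnC 38-47 with 10-CA endpoint windows; NcTnC/CcTnC
#: centers TnC 3-85 and TnC 94-157.  All config-overridable.
DEFAULT_MANIFEST: dict = {
    "hinge": {
        "head": ["TnC:3-85:CA"],
        "hinge": ["TnC:94-157:CA"],
        "arm_end": ["TnT:241-251:CA", "TnI:69-76:CA"],
    },
    "helix_a": {"subunit": "TnC", "lo": 14, "hi": 25, "endpoint_window": 10},
    "helix_b": {"subunit": "TnC", "lo": 38, "hi": 47, "endpoint_window": 10},
    "distance": {"a": ["TnC:3-85:CA"], "b": ["TnC:94-157:CA"]},
    "open_threshold_deg": 110.0,
}


def hinge_from_manifest(manifest: dict | None = None) -> HingeDefinition:
    m = (manifest or DEFAULT_MANIFEST)["hinge"]
    return HingeDefinition.create(m["head"], m["hinge"], m["arm_end"])


def helices_from_manifest(manifest: dict | None = None) -> tuple[HelixDefinition, HelixDefinition]:
    m = manifest or DEFAULT_MANIFEST
    return (HelixDefinition(**m["helix_a"]), HelixDefinition(**m["helix_b"]))


# ---------------------------------------------------------------------------
# Single-frame primitives
# ---------------------------------------------------------------------------

def centroid(coordinates: np.ndarray, atom_indices: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of the selected coordinates."""
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise GeometryError("centroid of empty selection")
    return np.asarray(coordinates, dtype=float)[atom_indices].mean(axis=0)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def hinge_angle(coordinates: np.ndarray, topology: Topology, hinge_def: HingeDefinition) -> float:
    """Angle (deg) at the fulcrum centroid between head and arm-end vectors."""
    h = centroid(coordinates, resolve_selection_union(topology, hinge_def.hinge))
    head = centroid(coordinates, resolve_selection_union(topology, hinge_def.head))
    arm = centroid(coordinates, resolve_selection_union(topology, hinge_def.arm_end))
    return _angle_deg(head - h, arm - h)


def _endpoint_windows(n_ca: int, window: int) -> tuple[slice, slice]:
    w = min(window, n_ca - 1)
    if w < window:
        warnings.warn(
            f"endpoint window {window} clamped to {w} for a {n_ca}-residue helix",
            stacklevel=3,
        )
    return slice(0, w), slice(n_ca - w, n_ca)


def helix_axis(coordinates: np.ndarray, topology: Topology, helix: HelixDefinition) -> np.ndarray:
    """Unit axis vector of a helix, oriented N -> C.

    Endpoints are centroids of the first and last ``endpoint_window`` alpha
    carbons; for short helices the window is clamped to length-1 so the two
    endpoint centroids remain distinct.
    """
    idx = resolve_selection_union(topology, [helix.selection])
    ca = np.asarray(coordinates, dtype=float)[idx]
    n_sl, c_sl = _endpoint_windows(len(ca), helix.endpoint_window)
    v = ca[c_sl].mean(axis=0) - ca[n_sl].mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise GeometryError(f"degenerate helix axis for {helix.selection}")
    return v / norm


def interhelical_angle(
    coordinates: np.ndarray,
    topology: Topology,
    helix_a: HelixDefinition,
    helix_b: HelixDefinition,
) -> float:
    """Supplement (180 deg minus) of the angle between two N->C helix axes."""
    a = helix_axis(coordinates, topology, helix_a)
    b = helix_axis(coordinates, topology, helix_b)
    return 180.0 - _angle_deg(a, b)


def pair_distance(coordinates: np.ndarray, topology: Topology, sel_a, sel_b) -> float:
    """Euclidean distance (Angstrom) between two selection centroids."""
    ca = centroid(coordinates, resolve_selection_union(topology, _as_exprs(sel_a)))
    cb = centroid(coordinates, resolve_selection_union(topology, _as_exprs(sel_b)))
    return float(np.linalg.norm(ca - cb))


# ---------------------------------------------------------------------------
# Vectorised per-trajectory series
# ---------------------------------------------------------------------------

def _centroid_series(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return traj.coordinates[:, idx, :].mean(axis=1)


def _angles_deg_vec(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = (n1 < 1e-9) | (n2 < 1e-9)
    n1 = np.where(bad, 1.0, n1)
    n2 = np.where(bad, 1.0, n2)
    cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    out[bad] = np.nan
    return out


def _finish_series(values: np.ndarray, traj: Trajectory, name: str) -> AngleSeries:
    failed = np.isnan(values)
    n_failed = int(failed.sum())
    if n_failed > 0.10 * len(values):
        raise GeometryError(
            f"{name}: {n_failed}/{len(values)} frames failed (>10%)"
        )
    labels = np.array(traj.frame_labels())
    keep = ~failed
    return AngleSeries(
        values=values[keep],
        metric_name=name,
        run_ids=labels[keep, 0],
        frame_indices=labels[keep, 1],
        n_failed=n_failed,
    )


def hinge_series(traj: Trajectory, hinge_def: HingeDefinition | None = None) -> AngleSeries:
    """Per-frame interdomain hinge angle series."""
    hinge_def = hinge_def or hinge_from_manifest()
    top = traj.topology
    h = _centroid_series(traj, resolve_selection_union(top, hinge_def.hinge))
    head = _centroid_series(traj, resolve_selection_union(top, hinge_def.head))
    arm = _centroid_series(traj, resolve_selection_union(top, hinge_def.arm_end))
    values = _angles_deg_vec(head - h, arm - h)
    return _finish_series(values, traj, "hinge_angle")


def _axis_series(traj: Trajectory, helix: HelixDefinition) -> np.ndarray:
    idx = resolve_selection_union(traj.topology, [helix.selection])
    ca = traj.coordinates[:, idx, :]
    n_sl, c_sl = _endpoint_windows(ca.shape[1], helix.endpoint_window)
    v = ca[:, c_sl, :].mean(axis=1) - ca[:, n_sl, :].mean(axis=1)
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm < 1e-9] = np.nan
    return v / norm


def interhelical_series(
    traj: Trajectory,
    helix_a: HelixDefinition | None = None,
    helix_b: HelixDefinition | None = None,
) -> AngleSeries:
    """Per-frame A/B interhelical angle series."""
    if helix_a is None or helix_b is None:
        ha, hb = helices_from_manifest()
        helix_a = helix_a or ha
        helix_b = helix_b or hb
    a = _axis_series(traj, helix_a)
    b = _axis_series(traj, helix_b)
    values = 180.0 - _angles_deg_vec(a, b)
    return _finish_series(values, traj, "ab_helix_angle")


def distance_series(traj: Trajectory, sel_a=None, sel_b=None) -> AngleSeries:
    """Per-frame centroid-pair distance series (Angstrom)."""
    m = DEFAULT_MANIFEST["distance"]
    sel_a = _as_exprs(sel_a if sel_a is not None else m["a"])
    sel_b = _as_exprs(sel_b if sel_b is not None else m["b"])
    top = traj.topology
    ca = _centroid_series(traj, resolve_selection_union(top, sel_a))
    cb = _centroid_series(traj, resolve_selection_union(top, sel_b))
    values = np.linalg.norm(ca - cb, axis=1)
    return _finish_series(values, traj, "centroid_distance")


def metric_series(traj: Trajectory, metric: str, manifest: dict | None = None) -> AngleSeries:
    """Dispatch by metric name: ``hinge`` / ``ab_helix`` / ``distance``."""
    manifest = manifest or DEFAULT_MANIFEST
    if metric == "hinge":
        return hinge_series(traj, hinge_from_manifest(manifest))
    if metric == "ab_helix":
        ha, hb = helices_from_manifest(manifest)
        return interhelical_series(traj, ha, hb)
    if metric == "distance":
        d = manifest["distance"]
        return distance_series(traj, d["a"], d["b"])
    raise GeometryError(f"unknown metric {metric!r}")
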