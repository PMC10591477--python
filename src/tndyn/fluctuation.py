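"""Fluctuation analysis: superposition, RMSF, pairwise RMSD, medoid selection.

RMSF is reported per residue over alpha carbons, measured about an iterated
mean structure (align -> average -> re-align, two passes).  The pairwise RMSD
matrix ("RMSD2d") uses optimal rigid-body superposition over all heavy atoms
for every frame pair; the frame with the lowest summed distance to all other
frames (the medoid) is the representative structure of a system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import SelectionExpr, Topology, Trajectory, resolve_selection

__all__ = [
    "FluctuationError",
    "RmsfProfile",
    "RmsdMatrix",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsf",
    "pairwise_rmsd_matrix",
    "representative_structure",
]


class FluctuationError(ValueError):
    pass


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Angstrom)."""

    residue_keys: list[tuple[str, int]]
    values: np.ndarray
    selection: str

    def as_dict(self) -> dict[tuple[str, int], float]:
        return dict(zip(self.residue_keys, self.values.tolist()))


@dataclass
class RmsdMatrix:
    """Symmetric pairwise-RMSD matrix with (run_id, frame_index) labels."""

    matrix: np.ndarray
    frame_labels: list[tuple[int, int]]
    selection: str


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` optimally superposed.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise FluctuationError("selection atom counts differ")
    if len(mobile) < 3:
        raise FluctuationError("need at least 3 atoms for superposition")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    e0 = (P * P).sum() + (Q * Q).sum()
    msd = max(0.0, (e0 - 2.0 * (S[0] + S[1] + d * S[2])) / len(P))
    t = cr - R @ cm
    return R, t, float(np.sqrt(msd))


def superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_indices: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Superpose a full frame onto a reference over a fit selection.

    The transform is computed on ``fit_indices`` and applied to every atom.
    Returns the transformed frame and the post-fit RMSD over the selection.
    """
    fit_indices = np.asarray(fit_indices, dtype=int)
    R, t, fit_rmsd = kabsch(mobile_coords[fit_indices], reference_coords[fit_indices])
    return mobile_coords @ R.T + t, fit_rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum (superposed) RMSD between two coordinate sets."""
    return kabsch(a, b)[2]


def _default_ca_selection(top: Topology) -> list[SelectionExpr]:
    return [
        SelectionExpr(su, lo, hi, "CA") for su, (lo, hi) in top.subunit_ranges.items()
    ]


def rmsf(
    traj: Trajectory,
    selection: SelectionExpr | str | list | None = None,
    n_iterations: int = 2,
) -> RmsfProfile:
    """Per-residue alpha-carbon RMSF about the iterated mean structure.

    Frames are superposed onto the current mean over the selection, the mean
    is recomputed, and the cycle repeats ``n_iterations`` times; RMSF is the
    root-mean-square displacement of each residue's CA from its mean position.
    """
    if traj.n_frames < 2:
        raise FluctuationError("RMSF requires at least 2 frames")
    top = traj.topology
    if selection is None:
        sels = _default_ca_selection(top)
    elif isinstance(selection, (str, SelectionExpr)):
        sels = [selection]
    else:
        sels = list(selection)
    idx = np.unique(np.concatenate([resolve_selection(top, s) for s in sels]))
    X = traj.coordinates[:, idx, :].copy()
    mean = X[0]
    for _ in range(n_iterations):
        aligned = np.empty_like(X)
        for i in range(len(X)):
            R, t, _ = kabsch(X[i], mean)
            aligned[i] = X[i] @ R.T + t
        mean = aligned.mean(axis=0)
        X = aligned
    disp2 = ((X - mean) ** 2).sum(axis=2)  # (n_frames, n_sel)
    per_atom = np.sqrt(disp2.mean(axis=0))
    keys = [(top.subunits[i], int(top.resids[i])) for i in idx]
    # aggregate atoms of the same residue (CA-only selections: one atom each)
    agg: dict[tuple[str, int], list[float]] = {}
    for k, v in zip(keys, per_atom):
        agg.setdefault(k, []).append(float(v))
    res_keys = list(agg)
    values = np.array([float(np.sqrt(np.mean(np.square(agg[k])))) for k in res_keys])
    sel_str = ",".join(str(s) for s in sels)
    return RmsfProfile(res_keys, values, sel_str)


def pairwise_rmsd_matrix(
    traj: Trajectory,
    selection: str = "heavy",
    stride: int = 1,
    max_frames: int = 20000,
    force: bool = False,
) -> RmsdMatrix:
    """All-against-all superposed RMSD over heavy atoms (or CA).

    ``stride`` subsamples frames; more than ``max_frames`` strided frames is
    refused unless ``force`` (the matrix is quadratic in frame count).
    """
    top = traj.topology
    if selection == "heavy":
        idx = np.flatnonzero(top.heavy_mask())
    elif selection == "CA":
        idx = np.flatnonzero(top.names == "CA")
    else:
        idx = resolve_selection(top, selection)
    labels = traj.frame_labels()[::stride]
    X = traj.coordinates[::stride][:, idx, :]
    n = len(X)
    if n < 2:
        raise FluctuationError("need at least 2 frames after striding")
    if n > max_frames and not force:
        raise FluctuationError(
            f"{n} strided frames exceeds the {max_frames}-frame guard; "
            "increase stride or pass force=True"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.einsum("fij,fij->f", Xc, Xc)
    natoms = X.shape[1]
    M = np.zeros((n, n))
    for i in range(n):
        Pi = Xc[i]
        for j in range(i + 1, n):
            H = Pi.T @ Xc[j]
            S = np.linalg.svd(H, compute_uv=False)
            d = np.sign(np.linalg.det(H)) if np.linalg.det(H) != 0 else 1.0
            msd = max(0.0, (norms[i] + norms[j] - 2.0 * (S[0] + S[1] + d * S[2])) / natoms)
            M[i, j] = M[j, i] = np.sqrt(msd)
    return RmsdMatrix(M, labels, selection)


def representative_structure(matrix: RmsdMatrix) -> tuple[int, int]:
    """Medoid frame label: lowest summed RMSD to all other frames.

    Ties (within 1e-9 of the minimum row sum) break to the lowest
    ``(run_id, frame_index)`` label.
    """
    row_sums = matrix.matrix.sum(axis=1)
    lo = row_sums.min()
    tied = np.flatnonzero(row_sums <= lo + 1e-9)
    best = min(tied, key=lambda i: matrix.frame_labels[i])
    return matrix.frame_labels[best]
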