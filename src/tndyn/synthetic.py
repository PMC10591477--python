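"""Synthetic two-domain trajectories with planted, recorded ground truth.

The generator emulates the statistical structure of the troponin-core
simulations at desk scale: a rigid "regulatory head" (toy NcTnC carrying two
ideal alpha-helices and a disordered NcTnI tail) articulated against a rigid
"IT arm" (toy CcTnC + TnI/TnT segments) about a hinge.  Per frame it

* draws a hinge angle from a stated Gaussian (or bimodal mixture)
  distribution and rotates the head rigidly about an axis through the hinge
  centroid to realise that angle *exactly*;
* adds i.i.d. Gaussian positional jitter of stated amplitude to the flagged
  flexible residues (the NcTnI-tail stand-in);
* places designated side-chain pseudo-atoms of planted residue-pair contacts
  within their interaction-type cutoff in a Bernoulli(f) subset of frames and
  beyond 1.5x the cutoff otherwise.

Toy residue numbering reuses the troponin anchor ranges (TnC 1-161,
TnI 1-80, TnT 230-260) so the default metric manifest runs unmodified.
Every random draw is recorded in :class:`GroundTruth`; a single seeded PRNG
stream makes output bit-reproducible.  No force field, solvent or
thermodynamics is emulated — statistical structure only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    HelixDefinition,
    helices_from_manifest,
    interhelical_angle,
)
from .structure_io import AtomRecord, Topology, Trajectory, write_frames

__all__ = [
    "GaussianAngles",
    "MixtureAngles",
    "PlantedContact",
    "SyntheticSpec",
    "GroundTruth",
    "build_toy_topology",
    "generate_trajectory",
    "plant_bimodal",
    "write_system",
    "DEFAULT_CONTACTS",
]

# ideal alpha-helix geometry (CA trace)
HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # deg per residue
HELIX_RADIUS = 2.3     # A


@dataclass(frozen=True)
class GaussianAngles:
    mu: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        return rng.normal(self.mu, self.sigma, n), np.zeros(n, dtype=int)


@dataclass(frozen=True)
class MixtureAngles:
    """Weighted Gaussian mixture; weights must sum to 1."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mu, sigma)

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if not np.isclose(w, 1.0):
            raise ValueError(f"mixture weights sum to {w}, expected 1")
        if any(c[0] < 0 for c in self.components):
            raise ValueError("negative mixture weight")

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        weights = np.array([c[0] for c in self.components])
        labels = rng.choice(len(weights), size=n, p=weights)
        mus = np.array([c[1] for c in self.components])[labels]
        sigmas = np.array([c[2] for c in self.components])[labels]
        return rng.normal(mus, sigmas), labels


@dataclass(frozen=True)
class PlantedContact:
    """A residue-pair contact present in a Bernoulli(f) fraction of frames."""

    res_a: tuple[str, int]
    res_b: tuple[str, int]
    interaction_type: str  # hbond / ionic / aromatic / vdw
    occupancy: float
    resname_a: str | None = None  # default chosen by type
    resname_b: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.interaction_type not in ("hbond", "ionic", "aromatic", "vdw"):
            raise ValueError(f"unknown interaction type {self.interaction_type}")

    @property
    def key(self) -> str:
        a, b = sorted([self.res_a, self.res_b])
        return f"{a[0]}:{a[1]}-{b[0]}:{b[1]}:{self.interaction_type}"


_DEFAULT_RESNAMES = {
    "ionic": ("ARG", "GLU"),
    "hbond": ("SER", "GLN"),
    "aromatic": ("PHE", "PHE"),
    "vdw": ("ALA", "ALA"),
}

#: Default planted contacts, chosen on the rigid arm plus one phosphoserine
#: pair, with occupancies on the scale of the strong (~80%), medium and weak
#: contact frequencies seen in troponin contact maps.
DEFAULT_CONTACTS: tuple[PlantedContact, ...] = (
    PlantedContact(("TnC", 95), ("TnC", 98), "ionic", 0.8),
    PlantedContact(("TnC", 105), ("TnC", 108), "hbond", 0.6),
    PlantedContact(("TnC", 115), ("TnC", 118), "aromatic", 0.25),
    PlantedContact(("TnI", 23), ("TnC", 39), "ionic", 0.8, "SEP", "LYS"),
)


@dataclass
class SyntheticSpec:
    """Study-condition parameters of a synthetic system.

    Defaults mirror the wild-type unphosphorylated troponin scale: five
    independent runs, hinge angles ~ N(121.6, 7.2) degrees, A/B helix
    crossing near 101.8 degrees, NcTnC-CcTnC separation 30 A, 0.5 A
    flexible-tail jitter.
    """

    n_runs: int = 5
    frames_per_run: int = 1000
    seed: int = 0
    hinge_distribution: GaussianAngles | MixtureAngles = field(
        default_factory=lambda: GaussianAngles(121.6, 7.2)
    )
    helix_crossing_angle: float = 101.8
    jitter_sigma: float = 0.5
    domain_separation: float = 30.0
    planted_contacts: tuple[PlantedContact, ...] = DEFAULT_CONTACTS
    tnc_n_residues: int = 161
    tni_n_residues: int = 80
    tnt_range: tuple[int, int] = (230, 260)
    flexible: tuple[str, int, int] = ("TnI", 1, 30)

    def __post_init__(self):
        if self.frames_per_run < 1 or self.n_runs < 1:
            raise ValueError("need at least one run and one frame")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.tnc_n_residues < 161:
            raise ValueError(
                "toy TnC must span residues 1-161 to host the default "
                "helix/hinge anchors"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, one entry per frame where per-frame."""

    hinge_angles: np.ndarray
    helix_angle: float                 # measured on the noiseless reference
    helix_crossing_nominal: float
    domain_separation: float
    jitter_sigma: float
    contact_states: dict[str, np.ndarray]   # key -> bool per frame
    contact_occupancy: dict[str, float]     # planted f
    component_labels: np.ndarray | None
    run_ids: np.ndarray
    seed: int

    def as_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "hinge_angles": self.hinge_angles.tolist(),
            "helix_angle": self.helix_angle,
            "helix_crossing_nominal": self.helix_crossing_nominal,
            "domain_separation": self.domain_separation,
            "jitter_sigma": self.jitter_sigma,
            "contact_occupancy": self.contact_occupancy,
            "contact_states": {k: v.astype(int).tolist() for k, v in self.contact_states.items()},
            "component_labels": None
            if self.component_labels is None
            else self.component_labels.tolist(),
            "run_ids": self.run_ids.tolist(),
        }


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {"N": (-1.0, 0.6, 0.3), "C": (1.0, 0.6, 0.3), "O": (1.2, 1.7, 0.3)}

# side-chain pseudo-atom offsets from CA; first atom is the contact anchor
_SIDECHAIN = {
    "ARG": [("NE", (0.0, 0.0, 1.4)), ("NH1", (0.0, 0.0, 2.6)), ("NH2", (0.9, 0.0, 2.2))],
    "GLU": [("OE1", (0.0, 0.0, 2.2)), ("OE2", (0.9, 0.0, 2.6))],
    "LYS": [("NZ", (0.0, 0.0, 2.6))],
    "SER": [("OG", (0.0, 0.0, 1.4))],
    "GLN": [("OE1", (0.0, 0.0, 2.2)), ("NE2", (0.9, 0.0, 2.4))],
    # O1P first: the contact anchor must belong to the -2 phosphate group
    "SEP": [
        ("O1P", (0.0, 0.0, 3.4)),
        ("P", (0.0, 0.0, 2.0)),
        ("O2P", (0.9, 0.0, 2.4)),
        ("O3P", (-0.9, 0.0, 2.4)),
        ("OG", (0.0, 0.0, 1.0)),
    ],
    "ALA": [("CB", (0.0, 0.0, 1.5))],
}


def _phe_ring(center: np.ndarray, normal: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Ideal 6-ring (C-C 1.39 A) centred at ``center`` in the plane of ``normal``."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    out = []
    for k, nm in enumerate(names):
        ang = np.radians(60.0 * k)
        out.append((nm, center + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)))
    return out


def _helix_ca(n: int, phase: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix CA trace along +z starting at z=0."""
    i = np.arange(n)
    ang = np.radians(HELIX_TWIST * i + phase)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i]
    )


def _lattice(n: int, origin: np.ndarray, row: int = 10) -> np.ndarray:
    """Compact serpentine CA lattice: 3.8 A along x, 4.8 A rows, 5.0 A layers."""
    k = np.arange(n)
    return origin + np.column_stack(
        [3.8 * (k % row), 4.8 * ((k // row) % 8), 5.0 * (k // (row * 8))]
    )


def _window_axis(ca: np.ndarray, window: int) -> np.ndarray:
    """Endpoint-window axis estimate (same convention as the metric)."""
    w = min(window, len(ca) - 1)
    v = ca[len(ca) - w:].mean(axis=0) - ca[:w].mean(axis=0)
    return v / np.linalg.norm(v)


def _calibrate_crossing(
    ca_a: np.ndarray, ca_b: np.ndarray, window_a: int, window_b: int, target: float
) -> float:
    """Tilt (rad, about y) of helix B making the measured A/B angle == target."""
    from scipy.optimize import minimize_scalar

    e_a = _window_axis(ca_a, window_a)
    e_b = _window_axis(ca_b, window_b)

    def measured(beta: float) -> float:
        b = _rotation(np.array([0.0, 1.0, 0.0]), beta) @ e_b
        cosang = np.clip(np.dot(e_a, b), -1.0, 1.0)
        return 180.0 - np.degrees(np.arccos(cosang))

    res = minimize_scalar(
        lambda beta: (measured(beta) - target) ** 2,
        bounds=(0.0, np.pi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


class _ToyModel:
    """Reference geometry plus the atom bookkeeping needed per frame."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        resname_map: dict[tuple[str, int], str] = {}
        for c in spec.planted_contacts:
            na, nb = _DEFAULT_RESNAMES[c.interaction_type]
            resname_map[c.res_a] = c.resname_a or na
            resname_map[c.res_b] = c.resname_b or nb

        atoms: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        self.head_atoms: list[int] = []     # indices moving with the head
        self.flex_atoms: list[int] = []     # indices receiving jitter
        ca_of: dict[tuple[str, int], int] = {}
        contact_atoms: dict[tuple[str, int], list[int]] = {}

        def add_residue(subunit: str, resnum: int, ca_xyz: np.ndarray, in_head: bool):
            resname = resname_map.get((subunit, resnum), "GLY")
            start = len(atoms)
            records = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
            xyz = [
                ca_xyz + np.array(_BACKBONE_OFFSETS["N"]),
                ca_xyz,
                ca_xyz + np.array(_BACKBONE_OFFSETS["C"]),
                ca_xyz + np.array(_BACKBONE_OFFSETS["O"]),
            ]
            if resname == "PHE":
                for nm, p in _phe_ring(ca_xyz + np.array([0, 0, 2.4]), np.array([0, 0, 1.0])):
                    records.append((nm, "C"))
                    xyz.append(p)
            elif resname in _SIDECHAIN:
                for nm, off in _SIDECHAIN[resname]:
                    records.append((nm, nm[:1] if nm[0] in "NOP" else "C"))
                    xyz.append(ca_xyz + np.array(off))
            for (nm, el), p in zip(records, xyz):
                idx = len(atoms)
                atoms.append(AtomRecord(nm, el, subunit, resnum, resname, idx))
                coords.append(np.asarray(p, dtype=float))
                if in_head:
                    self.head_atoms.append(idx)
                if nm == "CA":
                    ca_of[(subunit, resnum)] = idx
                if nm not in ("N", "CA", "C", "O"):
                    contact_atoms.setdefault((subunit, resnum), []).append(idx)

        # ---- head (local coordinates; centred later) ----
        helix_a, helix_b = helices_from_manifest()
        ca_a = _helix_ca(helix_a.hi - helix_a.lo + 1)
        ca_b0 = _helix_ca(helix_b.hi - helix_b.lo + 1)
        # Endpoint-window axis estimates of short ideal helices deviate from
        # the geometric axis; calibrate helix B's tilt so the *measured*
        # interhelical angle equals the planted crossing angle exactly.
        beta = _calibrate_crossing(ca_a, ca_b0, helix_a.endpoint_window,
                                   helix_b.endpoint_window, spec.helix_crossing_angle)
        Rb = _rotation(np.array([0.0, 1.0, 0.0]), beta)
        ca_b = (Rb @ ca_b0.T).T + np.array([10.0, 0.0, 0.0])
        head_positions: dict[tuple[str, int], np.ndarray] = {}
        for j, r in enumerate(range(helix_a.lo, helix_a.hi + 1)):
            head_positions[("TnC", r)] = ca_a[j]
        for j, r in enumerate(range(helix_b.lo, helix_b.hi + 1)):
            head_positions[("TnC", r)] = ca_b[j]
        rest = [r for r in range(1, 94) if ("TnC", r) not in head_positions]
        rest_xyz = _lattice(len(rest), np.array([-22.0, 8.0, -4.0]))
        for r, p in zip(rest, rest_xyz):
            head_positions[("TnC", r)] = p
        tail = list(range(1, 31))  # flexible NcTnI tail
        tail_xyz = _lattice(len(tail), np.array([-22.0, -18.0, 2.0]))
        for r, p in zip(tail, tail_xyz):
            head_positions[("TnI", r)] = p

        for (su, r), p in sorted(head_positions.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            add_residue(su, r, p, in_head=True)

        # ---- arm (global coordinates, static) ----
        arm_c = list(range(94, spec.tnc_n_residues + 1))
        for r, p in zip(arm_c, _lattice(len(arm_c), np.array([60.0, 0.0, 0.0]))):
            add_residue("TnC", r, p, in_head=False)
        arm_i = list(range(31, spec.tni_n_residues + 1))
        for r, p in zip(arm_i, _lattice(len(arm_i), np.array([95.0, 2.0, 8.0]))):
            add_residue("TnI", r, p, in_head=False)
        tnt = list(range(spec.tnt_range[0], spec.tnt_range[1] + 1))
        for r, p in zip(tnt, _lattice(len(tnt), np.array([95.0, -6.0, -8.0]))):
            add_residue("TnT", r, p, in_head=False)

        self.topology = Topology(atoms)
        self.reference = np.array(coords)
        self.ca_of = ca_of
        self.contact_atoms = contact_atoms
        for (su, lo, hi) in [spec.flexible]:
            for i, a in enumerate(self.topology.atoms):
                if a.subunit == su and lo <= a.residue_number <= hi:
                    self.flex_atoms.append(i)
        self.head_atoms = np.array(self.head_atoms, dtype=int)
        self.flex_atoms = np.array(self.flex_atoms, dtype=int)

        # hinge frame vectors
        from .structure_io import resolve_selection_union
        from .geometry import DEFAULT_MANIFEST

        top = self.topology
        m = DEFAULT_MANIFEST["hinge"]
        self.head_sel = resolve_selection_union(top, m["head"])
        hinge_sel = resolve_selection_union(top, m["hinge"])
        arm_sel = resolve_selection_union(top, m["arm_end"])
        # centre head local coordinates on the head-selection CA centroid
        head_ca = [i for i in self.head_sel if i in set(self.head_atoms.tolist())]
        offset = self.reference[head_ca].mean(axis=0)
        self.reference[self.head_atoms] -= offset

        self.hinge_centroid = self.reference[hinge_sel].mean(axis=0)
        arm_centroid = self.reference[arm_sel].mean(axis=0)
        u = arm_centroid - self.hinge_centroid
        self.u_hat = u / np.linalg.norm(u)
        z = np.array([0.0, 0.0, 1.0])
        m_vec = z - np.dot(z, self.u_hat) * self.u_hat
        if np.linalg.norm(m_vec) < 1e-6:
            m_vec = np.array([1.0, 0.0, 0.0]) - self.u_hat[0] * self.u_hat
        self.m_hat = m_vec / np.linalg.norm(m_vec)
        self.rot_axis = np.cross(self.u_hat, self.m_hat)

    def frame(self, theta_deg: float) -> np.ndarray:
        """Assemble one noiseless frame at hinge angle theta (exact)."""
        theta = np.radians(theta_deg)
        X = self.reference.copy()
        R = _rotation(self.rot_axis, theta - np.pi / 2)
        base = self.hinge_centroid + self.spec.domain_separation * (
            np.cos(np.pi / 2) * self.u_hat + np.sin(np.pi / 2) * self.m_hat
        )
        # head local coords are centred on the head centroid: rotate the
        # whole rigid head about the hinge centroid from the 90-deg pose
        posed = (R @ (X[self.head_atoms] + base - self.hinge_centroid).T).T + self.hinge_centroid
        X[self.head_atoms] = posed
        return X


_ON_DISTANCE = {"hbond": 3.0, "ionic": 3.2, "aromatic": 4.0, "vdw": 3.7}
_OFF_FACTOR = 1.5
_CUTOFF = {"hbond": 3.5, "ionic": 4.0, "aromatic": 5.0, "vdw": 3.9}


def build_toy_topology(spec: SyntheticSpec | None = None) -> Topology:
    """Deterministic toy topology for a spec (no frames)."""
    return _ToyModel(spec or SyntheticSpec()).topology


def _place_contact(
    X: np.ndarray, model: _ToyModel, contact: PlantedContact, on: bool
) -> None:
    """Move res_b's pseudo-atoms to realise (or break) the contact."""
    itype = contact.interaction_type
    a_atoms = model.contact_atoms[contact.res_a]
    b_atoms = model.contact_atoms[contact.res_b]
    if itype == "aromatic":
        anchor = X[a_atoms].mean(axis=0)
    else:
        anchor = X[a_atoms[0]]
    target_ca = X[model.ca_of[contact.res_b]]
    direction = target_ca - anchor
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    dist = _ON_DISTANCE[itype] if on else _OFF_FACTOR * _CUTOFF[itype] + 1.0
    target = anchor + dist * direction
    if itype == "aromatic":
        ring = _phe_ring(target, direction)
        for (nm, p), idx in zip(ring, b_atoms):
            X[idx] = p
    else:
        key = X[b_atoms[0]].copy()
        for idx in b_atoms:
            X[idx] = target + (X[idx] - key)


def generate_trajectory(spec: SyntheticSpec | None = None) -> tuple[Trajectory, GroundTruth]:
    """Generate a multi-run trajectory and its planted ground truth."""
    spec = spec or SyntheticSpec()
    model = _ToyModel(spec)
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_runs * spec.frames_per_run
    angles, labels = spec.hinge_distribution.sample(rng, n_total)
    angles = np.clip(angles, 1.0, 179.0)
    contact_states = {
        c.key: rng.random(n_total) < c.occupancy for c in spec.planted_contacts
    }
    frames = np.empty((n_total, model.topology.n_atoms, 3))
    for i in range(n_total):
        X = model.frame(angles[i])
        if spec.jitter_sigma > 0 and len(model.flex_atoms):
            X[model.flex_atoms] += rng.normal(
                0.0, spec.jitter_sigma, (len(model.flex_atoms), 3)
            )
        for c in spec.planted_contacts:
            _place_contact(X, model, c, bool(contact_states[c.key][i]))
        frames[i] = X
    run_ids = np.repeat(np.arange(spec.n_runs), spec.frames_per_run)
    traj = Trajectory(model.topology, frames, run_ids)
    helix_a, helix_b = helices_from_manifest()
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        measured_helix = interhelical_angle(
            model.frame(90.0), model.topology, helix_a, helix_b
        )
    truth = GroundTruth(
        hinge_angles=angles,
        helix_angle=measured_helix,
        helix_crossing_nominal=spec.helix_crossing_angle,
        domain_separation=spec.domain_separation,
        jitter_sigma=spec.jitter_sigma,
        contact_states=contact_states,
        contact_occupancy={c.key: c.occupancy for c in spec.planted_contacts},
        component_labels=labels if isinstance(spec.hinge_distribution, MixtureAngles) else None,
        run_ids=run_ids,
        seed=spec.seed,
    )
    return traj, truth


def plant_bimodal(
    mus: tuple[float, float],
    sigmas: tuple[float, float],
    weights: tuple[float, float] = (0.5, 0.5),
    **kwargs,
) -> tuple[Trajectory, GroundTruth]:
    """Convenience: generate with a two-component hinge-angle mixture."""
    mixture = MixtureAngles(
        ((weights[0], mus[0], sigmas[0]), (weights[1], mus[1], sigmas[1]))
    )
    spec = SyntheticSpec(hinge_distribution=mixture, **kwargs)
    return generate_trajectory(spec)


def write_system(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write topology PDB, per-run multi-model PDBs and ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj, truth = generate_trajectory(spec)
    top_path = out_dir / "topology.pdb"
    write_frames(traj.topology, traj.coordinates[:1], top_path)
    run_paths = []
    for run in range(spec.n_runs):
        p = out_dir / f"run_{run:02d}.pdb"
        write_frames(traj.topology, traj.coordinates[traj.run_ids == run], p)
        run_paths.append(str(p))
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(truth.as_json_dict()))
    manifest = {
        "topology": str(top_path),
        "runs": run_paths,
        "ground_truth": str(gt_path),
        "seed": spec.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
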