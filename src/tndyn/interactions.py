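"""Per-frame atomistic interaction profiling aggregated to residue pairs.

For every trajectory frame, atom pairs are classified into four interaction
types — hydrogen bond, ionic (salt bridge), aromatic (ring stacking) and
van der Waals contact — from atom typing rules and geometric cutoffs, then
collapsed to a boolean residue-pair presence per type per frame.  Counts over
all frames of a system yield occupancy percentages (100 x count / n_frames),
the quantity shown in contact heat maps; differences between two states
(e.g. unphosphorylated vs Ser22/Ser23-bisphosphorylated) are percentage-point
deltas.

Typing covers the 20 standard amino acids plus phosphoserine (SEP, modelled
with a net -2 phosphate group, the physiological-pH species).  Default
geometric criteria (all configurable):

* hydrogen bond: donor-heavy to acceptor distance <= 3.5 A, and, when the
  topology carries explicit hydrogens, D-H...A angle >= 120 deg;
* ionic: any atom of a positive charge group within 4.0 A of any atom of a
  negative group;
* aromatic: ring-centroid distance <= 5.0 A;
* van der Waals: heavy-atom distance <= r1 + r2 + 0.5 A, counted for a
  residue pair only when that pair has no hydrogen-bond/ionic event in the
  same frame.

Pairs within one residue are never counted; backbone-backbone contacts of
sequence neighbours are excluded from the hydrogen-bond and ionic types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Topology, Trajectory

__all__ = [
    "InteractionCutoffs",
    "AtomTyping",
    "ContactEvent",
    "FrequencyTable",
    "assign_atom_types",
    "detect_interactions",
    "profile_trajectory",
    "aggregate",
    "compare_states",
    "heatmap_matrix",
    "INTERACTION_TYPES",
]

INTERACTION_TYPES = ("hbond", "ionic", "aromatic", "vdw")

ResKey = tuple[str, int]


@dataclass(frozen=True)
class InteractionCutoffs:
    """Geometric criteria (Angstrom / degrees)."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    ionic_dist: float = 4.0
    aromatic_centroid_dist: float = 5.0
    vdw_margin: float = 0.5

    def as_dict(self) -> dict:
        return asdict(self)


# Bondi van der Waals radii (A); fallback 1.70 for unusual elements.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

# --- typing rule tables ----------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}

# donor heavy atoms per residue name (backbone N handled generically)
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "HIP": {"ND1", "NE2"},
    "HID": {"ND1"},
    "HIE": {"NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "SEP": set(),
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "HIS": {"ND1", "NE2"},
    "HID": {"NE2"},
    "HIE": {"ND1"},
    "SEP": {"O1P", "O2P", "O3P", "OG"},
}

# charge groups: residue name -> (atom names, sign)
_CHARGE_GROUPS = {
    "ARG": ({"NE", "NH1", "NH2"}, +1),
    "LYS": ({"NZ"}, +1),
    "HIP": ({"ND1", "NE2"}, +1),
    "ASP": ({"OD1", "OD2"}, -1),
    "GLU": ({"OE1", "OE2"}, -1),
    "SEP": ({"O1P", "O2P", "O3P"}, -1),
}

_RING_ATOMS = {
    "PHE": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "TYR": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}],
    "TRP": [
        {"CG", "CD1", "CD2", "NE1", "CE2"},
        {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    ],
    "HIS": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
    "HIP": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
    "HID": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
    "HIE": [{"CG", "ND1", "CD2", "CE1", "NE2"}],
}

_STANDARD_RESNAMES = set(_SIDECHAIN_DONORS) | set(_SIDECHAIN_ACCEPTORS) | {
    "ALA", "GLY", "VAL", "LEU", "ILE", "PRO", "PHE", "TRP", "ASP", "GLU",
    "ARG", "LYS", "MET", "CYS", "HIS", "HIP", "HID", "HIE",
}


@dataclass
class AtomTyping:
    """Per-atom interaction flags derived from the topology."""

    donor: np.ndarray          # bool
    acceptor: np.ndarray       # bool
    charge_sign: np.ndarray    # int8: -1/0/+1
    charge_group: np.ndarray   # int: group id, -1 if none
    ring_id: np.ndarray        # int: ring id, -1 if none
    vdw_radius: np.ndarray     # float, A
    n_atoms: int


def assign_atom_types(topology: Topology) -> AtomTyping:
    """Build donor/acceptor, charge-group, aromatic-ring and vdW-radius flags.

    Residues with unrecognised names are typed for van der Waals contact only
    (a warning is emitted once per unknown name).  Chain-terminal residues of
    each subunit get the free N-terminal amine (+) and C-terminal carboxylate
    (-) charge groups.
    """
    n = topology.n_atoms
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    charge_sign = np.zeros(n, dtype=np.int8)
    charge_group = np.full(n, -1, dtype=int)
    ring_id = np.full(n, -1, dtype=int)
    vdw_radius = np.array([VDW_RADII.get(e, 1.70) for e in topology.elements])

    warned: set[str] = set()
    next_group = 0
    next_ring = 0
    # group atoms by residue in topology order
    res_atoms: dict[ResKey, list[int]] = {}
    for i, a in enumerate(topology.atoms):
        res_atoms.setdefault((a.subunit, a.residue_number), []).append(i)

    termini: dict[str, tuple[int, int]] = topology.subunit_ranges

    for (su, resnum), indices in res_atoms.items():
        resname = topology.resnames[indices[0]]
        names = {topology.names[i]: i for i in indices}
        if resname not in _STANDARD_RESNAMES:
            if resname not in warned:
                warnings.warn(f"unknown residue {resname}: typed vdW-only")
                warned.add(resname)
            continue
        # backbone donors/acceptors
        if "N" in names and resname != "PRO":
            donor[names["N"]] = True
        for bb_acc in ("O", "OXT"):
            if bb_acc in names:
                acceptor[names[bb_acc]] = True
        for nm in _SIDECHAIN_DONORS.get(resname, ()):
            if nm in names:
                donor[names[nm]] = True
        for nm in _SIDECHAIN_ACCEPTORS.get(resname, ()):
            if nm in names:
                acceptor[names[nm]] = True
        if resname in _CHARGE_GROUPS:
            group_names, sign = _CHARGE_GROUPS[resname]
            hit = [names[nm] for nm in group_names if nm in names]
            if hit:
                for i in hit:
                    charge_sign[i] = sign
                    charge_group[i] = next_group
                next_group += 1
        lo, hi = termini[su]
        if resnum == lo and "N" in names and charge_sign[names["N"]] == 0:
            charge_sign[names["N"]] = +1
            charge_group[names["N"]] = next_group
            next_group += 1
        if resnum == hi:
            hit = [names[nm] for nm in ("OXT", "O") if nm in names]
            if hit:
                for i in hit:
                    charge_sign[i] = -1
                    charge_group[i] = next_group
                next_group += 1
        for ring in _RING_ATOMS.get(resname, ()):
            hit = [names[nm] for nm in ring if nm in names]
            if len(hit) >= 3:
                for i in hit:
                    ring_id[i] = next_ring
                next_ring += 1
    return AtomTyping(donor, acceptor, charge_sign, charge_group, ring_id, vdw_radius, n)


@dataclass(frozen=True)
class ContactEvent:
    """One residue-pair interaction present in one frame."""

    frame_index: int
    res_a: ResKey
    res_b: ResKey
    interaction_type: str


def _canonical_pair(a: ResKey, b: ResKey) -> tuple[ResKey, ResKey]:
    return (a, b) if a <= b else (b, a)


def _residue_arrays(topology: Topology):
    keys = [(su, int(r)) for su, r in zip(topology.subunits, topology.resids)]
    uniq = list(dict.fromkeys(keys))
    key_to_id = {k: i for i, k in enumerate(uniq)}
    res_id = np.array([key_to_id[k] for k in keys], dtype=int)
    return res_id, uniq


def detect_interactions(
    coordinates: np.ndarray,
    topology: Topology,
    typing: AtomTyping,
    cutoffs: InteractionCutoffs | None = None,
    frame_index: int = 0,
) -> list[ContactEvent]:
    """Classify all interacting atom pairs of one frame.

    Emits at most one event per residue pair per interaction type ("present
    or not" per frame).  Deterministic for identical input.
    """
    cutoffs = cutoffs or InteractionCutoffs()
    if typing.n_atoms != topology.n_atoms:
        raise ValueError("typing does not match topology")
    X = np.asarray(coordinates, dtype=float)
    res_id, res_keys = _residue_arrays(topology)
    heavy = topology.heavy_mask()
    is_bb = np.isin(topology.names, list(_BACKBONE))
    same_subunit = topology.subunits

    max_r = float(typing.vdw_radius[heavy].max()) if heavy.any() else 1.8
    search = max(
        cutoffs.hbond_dist, cutoffs.ionic_dist, 2 * max_r + cutoffs.vdw_margin
    )
    hidx = np.flatnonzero(heavy)
    tree = cKDTree(X[hidx])
    pairs = tree.query_pairs(search, output_type="ndarray")
    events: set[tuple[ResKey, ResKey, str]] = set()
    if len(pairs):
        ai = hidx[pairs[:, 0]]
        bi = hidx[pairs[:, 1]]
        dist = np.linalg.norm(X[ai] - X[bi], axis=1)
        ra, rb = res_id[ai], res_id[bi]
        inter = ra != rb
        # sequence-adjacent backbone-backbone (same subunit, |dres| == 1)
        adj_bb = (
            (same_subunit[ai] == same_subunit[bi])
            & (np.abs(topology.resids[ai] - topology.resids[bi]) == 1)
            & is_bb[ai]
            & is_bb[bi]
        )
        polar_ok = inter & ~adj_bb

        # hydrogen bonds (either direction donor->acceptor)
        hb = polar_ok & (dist <= cutoffs.hbond_dist) & (
            (typing.donor[ai] & typing.acceptor[bi])
            | (typing.donor[bi] & typing.acceptor[ai])
        )
        for k in np.flatnonzero(hb):
            ok = False
            for d_at, a_at in ((ai[k], bi[k]), (bi[k], ai[k])):
                if typing.donor[d_at] and typing.acceptor[a_at]:
                    if _hbond_geometry_ok(X, topology, typing, d_at, a_at, cutoffs):
                        ok = True
                        break
            if ok:
                events.add((*_canonical_pair(res_keys[ra[k]], res_keys[rb[k]]), "hbond"))

        # ionic: opposite charge signs, different groups
        ion = (
            polar_ok
            & (dist <= cutoffs.ionic_dist)
            & (typing.charge_sign[ai] * typing.charge_sign[bi] == -1)
        )
        for k in np.flatnonzero(ion):
            events.add((*_canonical_pair(res_keys[ra[k]], res_keys[rb[k]]), "ionic"))

        # van der Waals
        vdw = inter & (
            dist <= typing.vdw_radius[ai] + typing.vdw_radius[bi] + cutoffs.vdw_margin
        )
        vdw_pairs = {
            _canonical_pair(res_keys[ra[k]], res_keys[rb[k]])
            for k in np.flatnonzero(vdw)
        }
    else:
        vdw_pairs = set()

    # aromatic ring stacking (centroid criterion)
    n_rings = typing.ring_id.max() + 1
    if n_rings > 0:
        cents = np.empty((n_rings, 3))
        ring_res: list[int] = []
        for r in range(n_rings):
            members = np.flatnonzero(typing.ring_id == r)
            cents[r] = X[members].mean(axis=0)
            ring_res.append(int(res_id[members[0]]))
        for r1 in range(n_rings):
            for r2 in range(r1 + 1, n_rings):
                if ring_res[r1] == ring_res[r2]:
                    continue
                if np.linalg.norm(cents[r1] - cents[r2]) <= cutoffs.aromatic_centroid_dist:
                    events.add(
                        (*_canonical_pair(res_keys[ring_res[r1]], res_keys[ring_res[r2]]),
                         "aromatic")
                    )

    # vdW only where the pair has no hbond/ionic this frame
    claimed = {(a, b) for a, b, t in events if t in ("hbond", "ionic")}
    for pair in vdw_pairs:
        if pair not in claimed:
            events.add((*pair, "vdw"))

    return [
        ContactEvent(frame_index, a, b, t)
        for a, b, t in sorted(events)
    ]


def _hbond_geometry_ok(X, topology, typing, d_at, a_at, cutoffs) -> bool:
    """Angle criterion D-H...A >= threshold, applied only with explicit H."""
    if not topology.has_hydrogens:
        return True
    # hydrogens bonded to the donor: same residue, within 1.25 A
    res = (topology.subunits[d_at], topology.resids[d_at])
    cand = np.flatnonzero(
        (topology.elements == "H")
        & (topology.subunits == res[0])
        & (topology.resids == res[1])
    )
    if cand.size == 0:
        return True
    dh = np.linalg.norm(X[cand] - X[d_at], axis=1)
    bonded = cand[dh <= 1.25]
    if bonded.size == 0:
        return True
    for h in bonded:
        v1 = X[d_at] - X[h]
        v2 = X[a_at] - X[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if ang >= cutoffs.hbond_angle:
            return True
    return False


@dataclass
class FrequencyTable:
    """Residue-pair x type interaction counts over all frames of a system."""

    table: pd.DataFrame  # columns: subunit_a,res_a,subunit_b,res_b,type,count,percentage
    n_frames: int

    def lookup(self, res_a: ResKey, res_b: ResKey, itype: str) -> float:
        """Occupancy percentage for a residue pair and type (0 if absent)."""
        a, b = _canonical_pair(res_a, res_b)
        t = self.table
        hit = t[
            (t.subunit_a == a[0]) & (t.res_a == a[1])
            & (t.subunit_b == b[0]) & (t.res_b == b[1])
            & (t.type == itype)
        ]
        return float(hit.percentage.iloc[0]) if len(hit) else 0.0


def aggregate(events: list[ContactEvent], n_frames: int) -> FrequencyTable:
    """Count residue-pair/type presences over frames 0..n_frames-1."""
    counts: dict[tuple[ResKey, ResKey, str], int] = {}
    for ev in events:
        if ev.frame_index >= n_frames or ev.frame_index < 0:
            raise ValueError(f"event frame_index {ev.frame_index} outside 0..{n_frames - 1}")
        key = (*_canonical_pair(ev.res_a, ev.res_b), ev.interaction_type)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "subunit_a": a[0], "res_a": a[1],
            "subunit_b": b[0], "res_b": b[1],
            "type": t, "count": c,
            "percentage": 100.0 * c / n_frames,
        }
        for (a, b, t), c in sorted(counts.items())
    ]
    cols = ["subunit_a", "res_a", "subunit_b", "res_b", "type", "count", "percentage"]
    df = pd.DataFrame(rows, columns=cols).astype(
        {"res_a": int, "res_b": int, "count": int, "percentage": float}
    )
    return FrequencyTable(df, n_frames)


def profile_trajectory(
    traj: Trajectory,
    cutoffs: InteractionCutoffs | None = None,
    typing: AtomTyping | None = None,
) -> FrequencyTable:
    """Detect and aggregate interactions over every frame of a trajectory."""
    cutoffs = cutoffs or InteractionCutoffs()
    typing = typing or assign_atom_types(traj.topology)
    events: list[ContactEvent] = []
    for i in range(traj.n_frames):
        events.extend(
            detect_interactions(traj.coordinates[i], traj.topology, typing, cutoffs, i)
        )
    return aggregate(events, traj.n_frames)


def compare_states(table_a: FrequencyTable, table_b: FrequencyTable) -> pd.DataFrame:
    """Percentage-point occupancy difference (state B minus state A).

    Pairs absent from one state contribute 0% there.
    """
    keys = ["subunit_a", "res_a", "subunit_b", "res_b", "type"]
    a = table_a.table[keys + ["percentage"]].rename(columns={"percentage": "pct_a"})
    b = table_b.table[keys + ["percentage"]].rename(columns={"percentage": "pct_b"})
    merged = a.merge(b, on=keys, how="outer")
    merged[["pct_a", "pct_b"]] = merged[["pct_a", "pct_b"]].fillna(0.0)
    merged["delta"] = merged.pct_b - merged.pct_a
    return merged.sort_values(keys).reset_index(drop=True)


def heatmap_matrix(
    table: FrequencyTable,
    row_range: tuple[str, int, int],
    col_range: tuple[str, int, int],
    itype: str,
) -> pd.DataFrame:
    """Dense occupancy matrix for one type over two residue ranges.

    Rows/columns are labelled ``subunit:resnum``; cells are percentages.
    """
    rsu, rlo, rhi = row_range
    csu, clo, chi = col_range
    if rlo > rhi or clo > chi:
        raise ValueError("empty residue range for heat map")
    rows = [(rsu, r) for r in range(rlo, rhi + 1)]
    cols = [(csu, c) for c in range(clo, chi + 1)]
    M = np.zeros((len(rows), len(cols)))
    t = table.table[table.table.type == itype]
    for _, rec in t.iterrows():
        a = (rec.subunit_a, int(rec.res_a))
        b = (rec.subunit_b, int(rec.res_b))
        for x, y in ((a, b), (b, a)):
            if x in rows and y in cols:
                M[rows.index(x), cols.index(y)] = rec.percentage
    return pd.DataFrame(
        M,
        index=[f"{s}:{r}" for s, r in rows],
        columns=[f"{s}:{r}" for s, r in cols],
    )
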