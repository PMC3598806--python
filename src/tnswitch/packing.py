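"""Hydrophobic packing: residue contacts and solvent exposure.

Contacts are minimum heavy-atom distances with a 4.5 A persistence cutoff
(a standard hydrophobic-contact convention; it is configuration, and every
output states the cutoff used).  Exposure uses Shrake-Rupley solvent-
accessible surface area with deterministic golden-section spiral sphere
points, probe radius 1.4 A.

The default contact panel follows the repacking narrative of the N-lobe
closure: the PHE25/74/77 scaffold, PHE28 expulsion, VAL44 insertion, the
MET45/80/81 triad, MET27-MET47 sealing, and the ILE60/MET80, MET81/LEU48
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .metrics import MetricSeries
from .structure_io import Structure, Trajectory

__all__ = [
    "ContactDef",
    "default_contact_panel",
    "min_heavy_distance_series",
    "contact_persistence",
    "sasa_shrake_rupley",
    "residue_exposure_series",
    "VDW_RADII",
]

VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "Ca": 2.31,
    "H": 1.20,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "HN", "H", "OXT"}


@dataclass(frozen=True)
class ContactDef:
    """A residue pair watched for contact."""

    res_a: tuple[str, int]  # (chain, residue_number)
    res_b: tuple[str, int]
    scope: str = "heavy"  # "heavy" | "side-chain-heavy"
    cutoff: float = 4.5   # Angstrom
    label: str = ""

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.res_a == self.res_b:
            raise ValueError("contact residues must be distinct")
        if self.scope not in ("heavy", "side-chain-heavy"):
            raise ValueError(f"unknown atom scope {self.scope!r}")


# (label, residue pair) sets of the closure repacking narrative
_PANEL = [
    ("scaffold PHE25-PHE74", 25, 74),
    ("scaffold PHE25-PHE77", 25, 77),
    ("scaffold PHE74-PHE77", 74, 77),
    ("PHE28-PHE77", 28, 77),
    ("PHE28-LEU41", 28, 41),
    ("PHE28-VAL44", 28, 44),
    ("VAL44-PHE77", 44, 77),
    ("VAL44-PHE25", 44, 25),
    ("VAL44-ALA24", 44, 24),
    ("MET45-MET80", 45, 80),
    ("MET45-MET81", 45, 81),
    ("MET80-MET81", 80, 81),
    ("MET27-MET47", 27, 47),
    ("ILE60-MET80", 60, 80),
    ("MET81-LEU48", 81, 48),
]


def default_contact_panel(chain: str, cutoff: float = 4.5) -> list[ContactDef]:
    return [
        ContactDef((chain, ra), (chain, rb), "side-chain-heavy", cutoff, label)
        for label, ra, rb in _PANEL
    ]


def _residue_scope_indices(struct: Structure, chain: str, resnum: int, scope: str):
    idx = []
    for i, a in enumerate(struct.atoms):
        if a.chain_id != chain or a.residue_number != resnum or a.element == "H":
            continue
        if scope == "side-chain-heavy" and a.atom_name in _BACKBONE_NAMES:
            continue
        idx.append(i)
    return np.asarray(idx, dtype=int)


def min_heavy_distance_series(traj: Trajectory, pair: ContactDef) -> MetricSeries:
    """Per-frame minimum pairwise distance between the in-scope atoms of
    the two residues.  Symmetric in the pair."""
    ia = _residue_scope_indices(traj.topology, *pair.res_a, pair.scope)
    ib = _residue_scope_indices(traj.topology, *pair.res_b, pair.scope)
    if len(ia) == 0 or len(ib) == 0:
        empty = pair.res_a if len(ia) == 0 else pair.res_b
        raise ValueError(
            f"residue {empty} has no atoms in scope {pair.scope!r} "
            "(glycine has no side-chain heavy atoms)"
        )
    diffs = traj.frames[:, ia, None, :] - traj.frames[:, None, ib, :]
    d = np.sqrt(np.sum(diffs**2, axis=3)).min(axis=(1, 2))
    return MetricSeries(
        name=f"contact_{pair.label or f'{pair.res_a}-{pair.res_b}'}",
        values=d,
        anchors=(pair.res_a, pair.res_b),
    )


def contact_persistence(traj: Trajectory, pairs) -> dict[str, float]:
    """Fraction of frames each pair spends within its cutoff."""
    out: dict[str, float] = {}
    for pair in pairs:
        series = min_heavy_distance_series(traj, pair)
        key = pair.label or f"{pair.res_a}-{pair.res_b}"
        out[key] = float(np.mean(series.values <= pair.cutoff))
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere
    (golden-section spiral; no randomness, bit-for-bit reproducible)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_shrake_rupley(
    struct: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict | None = None,
    indices=None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2 (Shrake-Rupley).

    Each atom is probed with ``n_points`` quasi-uniform sphere points at
    radius r_vdw + probe; its area is 4*pi*(r+probe)^2 times the fraction
    of points not buried inside any neighbour's expanded sphere.  The
    neighbour search is restricted to atoms within r_i + r_j + 2*probe.

    ``indices`` limits which atoms get an area (occlusion still considers
    every atom); omitted entries are 0 in the returned array.
    """
    radii = VDW_RADII if radii is None else radii
    rs = np.empty(len(struct))
    for i, a in enumerate(struct.atoms):
        try:
            rs[i] = radii[a.element]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius configured for element "
                f"{a.element!r} (atom {a.key})"
            ) from None
    coords = struct.coords
    expanded = rs + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(struct))
    targets = range(len(struct)) if indices is None else indices
    for i in targets:
        pts = coords[i] + expanded[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            if np.linalg.norm(coords[j] - coords[i]) > expanded[i] + expanded[j]:
                continue
            buried = np.linalg.norm(pts - coords[j], axis=1) < expanded[j]
            accessible &= ~buried
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def residue_exposure_series(
    traj: Trajectory,
    residue: tuple[str, int],
    probe: float = 1.4,
    n_points: int = 240,
) -> MetricSeries:
    """Per-frame relative side-chain exposure of one residue.

    Side-chain SASA in the full structure divided by the same side chain's
    SASA with every other residue deleted (same conformation): near 0 when
    buried, near 1 when fully exposed.  Glycine has no side chain and is
    rejected.
    """
    topo = traj.topology
    chain, resnum = residue
    sc_idx = _residue_scope_indices(topo, chain, resnum, "side-chain-heavy")
    if len(sc_idx) == 0:
        raise ValueError(
            f"residue {residue} has no side-chain heavy atoms (glycine?)"
        )
    res_idx = np.asarray(topo.residue_atoms(chain, resnum), dtype=int)
    iso_topo = topo.subset(res_idx)
    # positions of the side-chain atoms within the isolated residue
    sc_in_iso = np.array([list(res_idx).index(i) for i in sc_idx], dtype=int)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        full = topo.with_coords(traj.frames[f])
        a_full = sasa_shrake_rupley(full, probe, n_points, indices=sc_idx)
        iso = iso_topo.with_coords(traj.frames[f, res_idx])
        a_iso = sasa_shrake_rupley(iso, probe, n_points, indices=sc_in_iso)
        denom = a_iso.sum()
        vals[f] = a_full[sc_idx].sum() / denom if denom > 0 else 0.0
    return MetricSeries(
        name=f"exposure_{chain}{resnum}",
        values=vals,
        unit="relative",
        anchors=(residue,),
    )
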