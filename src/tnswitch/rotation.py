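"""Inter-lobe rotation via virtual dihedral angles.

A virtual dihedral is a torsion over four chosen Ca atoms spanning the two
lobes; its central bond runs along the helix connecting them, so a rigid
rotation of one lobe about that axis shifts the dihedral by exactly the
rotation angle.  The two standard definitions share anchors Ca131 (C-lobe),
Ca104 and Ca73 (connecting segment) and differ in the fourth anchor:
Ca15 (start of the A helix, VD1) or Ca54 (start of the C helix, VD2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, dihedral
from .metrics import MetricSeries
from .structure_io import Structure, Trajectory

__all__ = [
    "VirtualDihedralDef",
    "VD1",
    "VD2",
    "virtual_dihedral_series",
    "rotation_between_states",
]


@dataclass(frozen=True)
class VirtualDihedralDef:
    """Four Ca anchors (chain, residue_number); label is free text."""

    residues: tuple[int, int, int, int]
    chain: str = "A"
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.residues)) != 4:
            raise ValueError("the four anchors must be distinct residues")

    def anchors(self):
        return tuple((self.chain, r, "CA") for r in self.residues)


def VD1(chain: str = "A") -> VirtualDihedralDef:
    return VirtualDihedralDef((131, 104, 73, 15), chain, "VD1")


def VD2(chain: str = "A") -> VirtualDihedralDef:
    return VirtualDihedralDef((131, 104, 73, 54), chain, "VD2")


def _anchor_indices(struct: Structure, vd: VirtualDihedralDef):
    return [struct.index_of(*key) for key in vd.anchors()]


def virtual_dihedral_series(
    traj: Trajectory,
    vd: VirtualDihedralDef,
    unwrap: bool = False,
) -> MetricSeries:
    """Per-frame virtual dihedral, degrees in (-180, 180].

    With ``unwrap`` the series is shifted by multiples of 360 so successive
    values never jump by more than 180 (continuous rotations tracked past
    the branch cut); raw wrapped angles are the default.
    """
    idx = _anchor_indices(traj.topology, vd)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            vals[f] = dihedral(*(traj.frames[f, i] for i in idx))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {f}: {exc}") from None
    if unwrap:
        vals = np.degrees(np.unwrap(np.radians(vals)))
    return MetricSeries(
        name=f"virtual_dihedral_{vd.label}",
        values=vals,
        unit="degree",
        anchors=vd.anchors(),
    )


def rotation_between_states(
    a: Structure,
    b: Structure,
    vd: VirtualDihedralDef,
) -> float:
    """Minimal signed dihedral difference dihedral(b) - dihedral(a),
    wrapped into (-180, 180]."""
    da = dihedral(*(a.atoms[i].position for i in _anchor_indices(a, vd)))
    db = dihedral(*(b.atoms[i].position for i in _anchor_indices(b, vd)))
    delta = (db - da) % 360.0
    if delta > 180.0:
        delta -= 360.0
    return float(delta)
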