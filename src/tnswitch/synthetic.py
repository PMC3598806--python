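"""Synthetic structures and trajectories with prescribed ground truth.

The troponin MD trajectories this package's metrics were designed around
are not publicly deposited, so every analysis stage is exercised instead on
generated data whose geometry and statistics are known by construction:

* an idealized two-state TnC N-lobe (open / semi-closed / closed) whose
  pocket distance, EF-site spans, prong contacts and inter-lobe anchors are
  placed at prescribed values,
* linear morphs, isotropic-noise ensembles, scheduled rigid rotations,
  scheduled displacement events, and an Ornstein-Uhlenbeck distance probe
  with an analytic stationary law.

Every generator is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import rotate_about_axis
from .structure_io import AtomRecord, Structure, Trajectory

__all__ = [
    "ToyLobeSpec",
    "SyntheticParams",
    "ConstructionError",
    "build_toy_two_state_lobe",
    "build_beta_hairpin",
    "morph_trajectory",
    "noisy_static_trajectory",
    "rigid_rotation_trajectory",
    "displacement_event_trajectory",
    "ou_two_probe_trajectory",
]


class ConstructionError(ValueError):
    """Synthetic geometry violates its own sanity constraints (e.g. clash)."""


# ---------------------------------------------------------------------------
# Toy two-state N-lobe
# ---------------------------------------------------------------------------

# Pocket-distance construction targets for the three states, Angstrom.
# They reproduce the printed state geometry of the system this emulates:
# fully open ~23.9, semi-closed ~15.7, closed ~13.4.
_STATE_TARGET_D = {"open": 23.9, "semi-closed": 15.7, "closed": 13.4}

# EF-site loop span (Ca of loop position 1 to position 12): the binding
# site expands subtly when the ion is released.
_STATE_SITE_SPAN = {"open": 10.2, "semi-closed": 10.6, "closed": 11.6}

# Inter-lobe rotation of the N-lobe about the connecting-helix axis
# (through Ca73 toward Ca104), degrees; ion release rotates the N-lobe
# relative to the rest of the molecule.
_STATE_TWIST = {"open": 0.0, "semi-closed": 14.0, "closed": 30.0}


@dataclass(frozen=True)
class ToyLobeSpec:
    """Parameters of the idealized N-lobe (plus a C-lobe stub for the
    inter-lobe rotation anchors).

    The conformer controls the B/C-unit closing angle (solved so the
    Ca16-Ca48 pocket distance hits ``target_pocket_distance``), the EF-loop
    spans, and whether the position-12 glutamate "prong" side chains point
    into the sites (open/semi-closed) or are released outward (closed).
    """

    conformer: str = "open"
    chain_id: str = "A"
    target_pocket_distance: float | None = None  # Angstrom; None -> state default
    site_span: float | None = None               # Angstrom; None -> state default
    interlobe_twist: float | None = None         # degrees; None -> state default
    helix_rise: float = 1.5                      # Angstrom per residue
    helix_twist: float = 100.0                   # degrees per residue
    helix_radius: float = 2.3                    # Angstrom (tapered at segment ends)

    def __post_init__(self) -> None:
        if self.conformer not in _STATE_TARGET_D:
            raise ValueError(f"unknown conformer {self.conformer!r}")

    @property
    def pocket_target(self) -> float:
        if self.target_pocket_distance is not None:
            return self.target_pocket_distance
        return _STATE_TARGET_D[self.conformer]

    @property
    def span(self) -> float:
        if self.site_span is not None:
            return self.site_span
        return _STATE_SITE_SPAN[self.conformer]

    @property
    def twist(self) -> float:
        if self.interlobe_twist is not None:
            return self.interlobe_twist
        return _STATE_TWIST[self.conformer]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Segment table: (name, first_res, last_res, kind, direction, start_offset).
# Directions give each segment's open-layout course; start_offset is the
# junction vector from the previous segment's last Ca (helix axes end up
# packed side by side instead of threading through one another).  The
# closing motion is a solved rigid rotation of the B..loopII unit about a
# hinge at Ca40.
_SEGMENTS = [
    ("N",      3,  15, "helix", (0.05, 0.10, 1.0),   (0.0, 0.0, 0.0)),
    ("A",     16,  28, "helix", (0.25, 0.12, -1.0),  (6.5, 1.0, 0.0)),
    ("loopI", 29,  40, "loop",  (0.38, 0.90, 0.22),  (2.8, 2.8, -1.2)),
    ("B",     41,  48, "helix", (0.00, -0.10, 1.0),  (1.0, 2.5, 3.0)),
    ("BC",    49,  53, "ext",   (0.05, -0.95, 0.20), (0.5, -5.5, 0.5)),
    ("C",     54,  64, "helix", (0.05, 0.30, -1.0), (-0.3, -6.0, 0.0)),
    ("loopII", 65, 76, "loop",  (-0.78, -0.60, -0.20), (-3.2, -3.0, -1.5)),
    ("D",     77, 112, "helix", (-0.15, -0.25, -1.0), (-2.8, -3.5, -3.0)),
    ("CLOBE", 125, 135, "helix", (0.80, 0.40, -0.30), (3.0, 1.0, -1.0)),
]

_CLOSING_RESIDUES = (41, 48)   # the B helix is the pocket gate
_HINGE_RESIDUE = 40

# Residue names; everything else defaults to ALA.  The names at metric
# anchor positions match the chicken fast-skeletal TnC residues the
# metrics address; side-chain chemistry is pseudo-atoms only.
_RESIDUE_NAMES = {
    15: "GLU", 16: "GLU", 17: "MET", 21: "PHE", 24: "ALA", 25: "PHE",
    27: "MET", 28: "PHE",
    29: "ASP", 30: "ALA", 31: "ASP", 32: "GLY", 33: "GLY", 34: "GLY",
    35: "ASP", 36: "ILE", 37: "SER", 38: "THR", 39: "LYS", 40: "GLU",
    41: "LEU", 43: "THR", 44: "VAL", 45: "MET", 47: "MET", 48: "LEU",
    49: "GLY", 50: "GLY", 51: "GLY", 52: "GLY", 53: "GLY",
    54: "GLU", 60: "ILE", 61: "ILE", 64: "VAL",
    65: "ASP", 66: "GLU", 67: "ASP", 68: "GLY", 69: "SER", 70: "GLY",
    71: "THR", 72: "ILE", 73: "ASP", 74: "PHE", 75: "GLU", 76: "GLU",
    77: "PHE", 80: "MET", 81: "MET", 104: "PHE", 131: "GLU",
}

# Residues that carry a CG pseudo-atom (hydrophobic-panel side chains).
_CG_RESIDUES = {17, 21, 25, 27, 28, 36, 41, 44, 45, 47, 48, 60, 61, 64,
                72, 74, 77, 80, 81}

_PRONG_SITES = {  # loop_start: (pos2, pos9, pos12)
    29: (30, 37, 40),
    65: (66, 73, 76),
}


def _segment_ca_path(kind, start, direction, n_res, span, spec: ToyLobeSpec):
    """Ca positions of one segment beginning at ``start``.

    Returns (positions, outward) where ``outward`` holds per-residue unit
    vectors pointing radially away from the segment's local axis; CB
    pseudo-atoms are placed along them so side chains of a tight curl
    never point into each other."""
    u = _unit(direction)
    ref = np.array([0.36, 0.48, 0.80])
    if abs(np.dot(ref, u)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    n = _unit(ref - np.dot(ref, u) * u)
    b = np.cross(u, n)
    ks = np.arange(n_res)
    if kind == "helix":
        taper = np.sin(np.pi * ks / max(n_res - 1, 1))
        phase = np.radians(spec.helix_twist) * ks
        axis = start + np.outer(ks * spec.helix_rise, u)
        radial = np.outer(np.cos(phase), n) + np.outer(np.sin(phase), b)
        return axis + spec.helix_radius * taper[:, None] * radial, radial
    if kind == "ext":
        sign = np.where(ks % 2 == 0, 1.0, -1.0)
        zig = 0.8 * sign * np.sin(np.pi * ks / max(n_res - 1, 1))
        return start + np.outer(ks * 3.0, u) + np.outer(zig, n), np.outer(sign, n)
    if kind == "loop":
        # solenoidal curl from start to start + span*u: constant-radius
        # helix with a linear drift correction pinning both endpoints, so
        # the loop position 1 <-> 12 span is exact while consecutive Ca
        # spacing stays near 3.5 A
        frac = ks / (n_res - 1)
        phase = np.radians(100.0) * ks
        radial = np.outer(np.cos(phase), n) + np.outer(np.sin(phase), b)
        offset = 2.2 * radial
        drift = np.outer(1.0 - frac, offset[0]) + np.outer(frac, offset[-1])
        return start + np.outer(frac * span, u) + offset - drift, radial
    raise ValueError(kind)


def _build_ca_path(spec: ToyLobeSpec):
    """(Ca positions, outward unit vectors) keyed by residue number,
    before the closing rotation."""
    ca: dict[int, np.ndarray] = {}
    outward: dict[int, np.ndarray] = {}
    cursor = np.zeros(3)
    first = True
    for name, lo, hi, kind, direction, offset in _SEGMENTS:
        start = cursor if first else cursor + np.asarray(offset, dtype=float)
        first = False
        path, rad = _segment_ca_path(kind, start, direction, hi - lo + 1, spec.span, spec)
        for res, pos, r in zip(range(lo, hi + 1), path, rad):
            ca[res] = pos
            outward[res] = r
        if kind == "loop":
            # advance the chain by the reference (open-state) span so a
            # conformer's loop expansion does not shift every downstream
            # segment: conformers then differ only by the B-helix closing
            # angle, the loop geometry itself and the inter-lobe twist
            cursor = start + _STATE_SITE_SPAN["open"] * _unit(direction)
        else:
            cursor = path[-1]
    return ca, outward


def _apply_closing(ca, outward, spec: ToyLobeSpec):
    """Rotate the B helix about a hinge at Ca40 so the Ca16-Ca48 pocket
    distance equals the conformer target (solved deterministically).
    Outward side-chain directions of the moving residues co-rotate."""
    hinge = ca[_HINGE_RESIDUE]
    toward = ca[16] - hinge
    u_b = _unit(ca[48] - ca[41])
    axis = _unit(np.cross(u_b, toward))
    moving = [r for r in ca if _CLOSING_RESIDUES[0] <= r <= _CLOSING_RESIDUES[1]]
    pts = np.array([ca[r] for r in moving])
    i48 = moving.index(48)

    def d_of(phi_deg: float) -> float:
        rot = rotate_about_axis(pts, hinge, axis, phi_deg)
        return float(np.linalg.norm(rot[i48] - ca[16]))

    target = spec.pocket_target
    grid = np.linspace(-150.0, 150.0, 301)
    vals = np.array([d_of(g) for g in grid])
    bracket = None
    for i in range(len(grid) - 1):
        if (vals[i] - target) * (vals[i + 1] - target) <= 0:
            cand = (grid[i], grid[i + 1])
            if bracket is None or abs(0.5 * (cand[0] + cand[1])) < abs(
                0.5 * (bracket[0] + bracket[1])
            ):
                bracket = cand
    if bracket is None:
        raise ConstructionError(
            f"cannot reach pocket distance {target:.2f} A "
            f"(achievable {vals.min():.2f}..{vals.max():.2f})"
        )
    phi = float(brentq(lambda p: d_of(p) - target, bracket[0], bracket[1], xtol=1e-10))
    rot = rotate_about_axis(pts, hinge, axis, phi)
    ca_out = dict(ca)
    dir_out = dict(outward)
    for r, p in zip(moving, rot):
        ca_out[r] = p
        dir_out[r] = rotate_about_axis(outward[r], np.zeros(3), axis, phi)
    return ca_out, dir_out


def _apply_interlobe_twist(ca, outward, spec: ToyLobeSpec):
    """Rotate the whole N-lobe (residues 3-76) about the connecting-helix
    axis (through Ca73 toward Ca104) by the conformer's twist angle.

    Both pocket anchors co-rotate, so the pocket distance is untouched;
    virtual dihedrals anchored on Ca131/104/73 shift by exactly the twist.
    """
    angle = spec.twist
    if angle == 0.0:
        return ca, outward
    axis_point = ca[73]
    axis_dir = _unit(ca[104] - ca[73])
    ca_out = dict(ca)
    dir_out = dict(outward)
    for r in ca:
        if r <= 76:
            ca_out[r] = rotate_about_axis(ca[r], axis_point, axis_dir, angle)
            dir_out[r] = rotate_about_axis(outward[r], np.zeros(3), axis_dir, angle)
    return ca_out, dir_out


def _segment_of(res: int) -> tuple[int, int]:
    for _, lo, hi, *_rest in _SEGMENTS:
        if lo <= res <= hi:
            return lo, hi
    raise KeyError(res)


def _local_frames(ca: dict[int, np.ndarray]) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-residue (tangent, normal, binormal), computed within segments."""
    frames = {}
    ref = np.array([0.36, 0.48, 0.80])
    for res, pos in ca.items():
        lo, hi = _segment_of(res)
        prev = ca[res - 1] if res - 1 >= lo else pos
        nxt = ca[res + 1] if res + 1 <= hi else pos
        t = nxt - prev
        if np.linalg.norm(t) < 1e-9:
            t = np.array([0.0, 0.0, 1.0])
        t = _unit(t)
        r = ref if abs(np.dot(ref, t)) < 0.95 else np.array([1.0, 0.0, 0.0])
        n = _unit(r - np.dot(r, t) * t)
        b = np.cross(t, n)
        frames[res] = (t, n, b)
    return frames


def _prong_atoms(ca, backbone_n, loop_start, formed: bool, context_points=None) -> dict[int, dict[str, np.ndarray]]:
    """Side-chain CD/OE1/OE2 of the position-12 glutamate.

    ``formed``: OE oxygens held in toward the site, 2.85/2.90 A from the
    backbone N of loop positions 2 and 9 (a pseudo-ion sits at the loop
    centre).  Released: the side chain swings away from the lobe, all
    prong distances > 4.5 A.
    """
    pos2, pos9, pos12 = _PRONG_SITES[loop_start]
    loop_center = np.mean([ca[r] for r in range(loop_start, loop_start + 12)], axis=0)
    n2, n9 = backbone_n[pos2], backbone_n[pos9]
    mid = 0.5 * (n2 + n9)
    out = _unit(mid - loop_center)
    if formed:
        # pseudo ion near the loop mouth: try a small deterministic grid of
        # candidate sites above/below the loop plane and keep the one whose
        # prong atoms clear the loop backbone best
        pn = _unit(np.cross(n9 - n2, out))
        if context_points is None:
            context = np.array(
                [ca[r] for r in range(loop_start, loop_start + 12)]
                + [backbone_n[r] for r in range(loop_start, loop_start + 12)]
            )
        else:
            context = np.asarray(context_points)

        def prong_for(site):
            oe1 = n2 + 2.85 * _unit(site - n2)
            oe2 = n9 + 2.90 * _unit(site - n9)
            cd = 0.5 * (oe1 + oe2) + 0.9 * _unit(0.5 * (oe1 + oe2) - site)
            return oe1, oe2, cd

        def clearance(site):
            pts = np.array(prong_for(site))
            dmat = np.linalg.norm(pts[:, None, :] - context[None, :, :], axis=2)
            return float(dmat.min())

        candidates = [
            loop_center + f_out * out + f_pn * pn
            for f_out in (0.8, 1.6, 2.4, 3.2, 4.0)
            for f_pn in (2.0, 2.8, 3.6, -2.0, -2.8, -3.6)
        ]
        site = max(candidates, key=clearance)
        oe1, oe2, cd = prong_for(site)
    else:
        # swing away from the molecule as a whole, not just the loop,
        # so the released side chain cannot land inside another helix
        centroid = np.mean([p for p in ca.values()], axis=0)
        away = _unit(_unit(mid - centroid) + 0.5 * out)
        cd = mid + 5.0 * away
        perp = _unit(np.cross(away, n9 - n2))
        oe1 = cd + 1.25 * _unit(away + 0.4 * perp)
        oe2 = cd + 1.25 * _unit(away - 0.4 * perp)
    return {pos12: {"CD": cd, "OE1": oe1, "OE2": oe2}}


def _check_clashes(atoms: list[AtomRecord], min_dist: float = 1.5) -> None:
    """Raise if heavy atoms of non-adjacent residues come closer than
    ``min_dist``; bonded neighbours are exempt."""
    coords = np.array([a.position for a in atoms])
    resnum = np.array([a.residue_number for a in atoms])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_dist):
        if abs(int(resnum[i]) - int(resnum[j])) > 1:
            raise ConstructionError(
                f"construction clash: atoms {atoms[i].key} and {atoms[j].key} "
                f"are {np.linalg.norm(coords[i] - coords[j]):.2f} A apart"
            )


def build_toy_two_state_lobe(spec: ToyLobeSpec = ToyLobeSpec()) -> Structure:
    """Deterministic idealized N-lobe (residues 3-112 plus a C-lobe stub
    125-135) with backbone N/CA/C/O, CB on non-glycine residues, CG
    pseudo-atoms on the hydrophobic-panel residues, and a full glutamate
    prong (CB/CG/CD/OE1/OE2) at EF-loop position 12 of sites I and II.

    Open, semi-closed and closed conformers share identical topology; only
    coordinates differ.
    """
    ca_raw, outward_raw = _build_ca_path(spec)
    ca, outward = _apply_closing(ca_raw, outward_raw, spec)
    ca, outward = _apply_interlobe_twist(ca, outward, spec)
    frames = _local_frames(ca)

    backbone_n: dict[int, np.ndarray] = {}
    records: list[tuple] = []  # (res, atom_name, pos)
    for res in sorted(ca):
        t, _, _ = frames[res]
        out_dir = outward[res]
        pos = ca[res]
        n_at = pos - 1.25 * t + 0.70 * out_dir
        c_at = pos + 1.35 * t + 0.70 * out_dir
        o_at = c_at + 1.23 * out_dir
        backbone_n[res] = n_at
        resname = _RESIDUE_NAMES.get(res, "ALA")
        records.append((res, "N", n_at))
        records.append((res, "CA", pos))
        records.append((res, "C", c_at))
        records.append((res, "O", o_at))
        if resname != "GLY":
            cb = pos + 1.53 * outward[res]
            records.append((res, "CB", cb))
            if res in _CG_RESIDUES:
                records.append((res, "CG", cb + 1.52 * outward[res]))

    formed = spec.conformer in ("open", "semi-closed")
    side: dict[int, dict[str, np.ndarray]] = {}
    for loop_start in _PRONG_SITES:
        context = np.array(
            [p for res, _, p in records if loop_start <= res < loop_start + 12]
        )
        side.update(_prong_atoms(ca, backbone_n, loop_start, formed, context))
    # attach prong atoms (and a CG bridging CB->CD) to the GLU12 residues
    out_records: list[tuple] = []
    for res, name, pos in records:
        if res in side and name == "CG":
            cb = next(p for r, nm, p in records if r == res and nm == "CB")
            out_records.append((res, "CG", 0.5 * (cb + side[res]["CD"])))
        else:
            out_records.append((res, name, pos))
    for res, extra in side.items():
        for name in ("CD", "OE1", "OE2"):
            out_records.append((res, name, extra[name]))

    atoms = []
    serial = 1
    order = {nm: i for i, nm in enumerate(["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"])}
    for res, name, pos in sorted(out_records, key=lambda r: (r[0], order[r[1]])):
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                residue_name=_RESIDUE_NAMES.get(res, "ALA"),
                chain_id=spec.chain_id,
                residue_number=res,
                element="O" if name.startswith("O") else ("N" if name == "N" else "C"),
                position=pos,
            )
        )
        serial += 1
    _check_clashes(atoms)
    return Structure(atoms, source_id=f"toy-lobe-{spec.conformer}")


# ---------------------------------------------------------------------------
# Toy beta-hairpin (the site I / site II scaffold sheet in isolation)
# ---------------------------------------------------------------------------


def build_beta_hairpin(splay: float = 0.0, chain_id: str = "A") -> Structure:
    """Two antiparallel strands (residues 33-39 and 69-75) whose four
    scaffold H-bonds (36O-72HN, 72O-36HN, 34O-74HN, 38HN-70O) are formed by
    construction (HN...O = 1.9 A).

    ``splay`` > 0 bends the strand ends apart in proportion to the distance
    from the strand centres (residues 36 and 72), breaking the flanking
    bonds while the central pair stays formed.
    """
    strands = {  # residues, y level, x direction
        1: (list(range(33, 40)), 0.0, +1.0),
        2: (list(range(69, 76)), 4.8, -1.0),
    }
    names = {34: "GLY", 36: "ILE", 38: "THR", 70: "GLY", 72: "ILE", 74: "PHE"}
    pos: dict[tuple[int, str], np.ndarray] = {}
    for sid, (residues, y, dirx) in strands.items():
        inward = +1.0 if sid == 1 else -1.0  # toward the partner strand
        for k, res in enumerate(residues):
            x = dirx * 3.4 * (k - 3)
            ca = np.array([x, y, 0.15 * ((-1) ** k)])
            n_at = ca + np.array([-dirx * 1.30, -inward * 0.55, 0.0])
            c_at = ca + np.array([dirx * 1.40, -inward * 0.45, 0.2])
            pos[(res, "N")] = n_at
            pos[(res, "CA")] = ca
            pos[(res, "C")] = c_at
            # provisional carbonyl O, replaced for H-bonded pairs below
            pos[(res, "O")] = c_at + np.array([0.0, 0.0, 1.23])

    def placed_hn(res: int) -> np.ndarray:
        # same rule as hbond add_amide_hydrogens: bisector of C_prev-N, CA-N
        n_at = pos[(res, "N")]
        c_prev = pos[(res - 1, "C")]
        ca = pos[(res, "CA")]
        d = _unit(_unit(c_prev - n_at) + _unit(ca - n_at))
        return n_at - 1.01 * d

    # acceptor O placed 1.9 A beyond the donor HN, along the N->H direction
    for acceptor, donor in ((36, 72), (72, 36), (34, 74), (70, 38)):
        h = placed_hn(donor)
        n_at = pos[(donor, "N")]
        pos[(acceptor, "O")] = h + 1.9 * _unit(h - n_at)

    if splay != 0.0:
        # bend only the residues two or more positions from the strand
        # centre, so the central 36<->72 pair (and the backbone its amide
        # hydrogens are computed from) stays exactly in place
        for sid, (residues, _, _) in strands.items():
            centre = residues[3]
            sign = -1.0 if sid == 1 else +1.0
            for res in residues:
                reach = max(0, abs(res - centre) - 1)
                off = np.array([0.0, sign * splay * reach / 2.0, 0.0])
                for nm in ("N", "CA", "C", "O"):
                    pos[(res, nm)] = pos[(res, nm)] + off

    atoms = []
    serial = 1
    for res in sorted({r for r, _ in pos}):
        for nm in ("N", "CA", "C", "O"):
            atoms.append(
                AtomRecord(
                    serial,
                    nm,
                    names.get(res, "ALA"),
                    chain_id,
                    res,
                    "O" if nm == "O" else ("N" if nm == "N" else "C"),
                    pos[(res, nm)],
                )
            )
            serial += 1
    return Structure(atoms, source_id="toy-beta-hairpin")


# ---------------------------------------------------------------------------
# Trajectory generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs for the stochastic generators; the seed is mandatory."""

    seed: int
    n_frames: int = 100
    noise_sd: float = 0.0
    event_frame: int | None = None
    ou: dict = field(
        default_factory=lambda: {"theta": 1.0, "mu": 4.0, "sigma": 1.4, "dt": 0.01}
    )

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _check_same_topology(a: Structure, b: Structure) -> None:
    if len(a) != len(b) or any(x.key != y.key for x, y in zip(a.atoms, b.atoms)):
        raise ValueError("structures do not share an identical topology")


def morph_trajectory(
    open_struct: Structure,
    closed_struct: Structure,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Linear interpolation between two same-topology conformers plus
    i.i.d. Gaussian coordinate noise of SD ``noise_sd`` (Angstrom)."""
    _check_same_topology(open_struct, closed_struct)
    if n_frames < 2:
        raise ValueError("a morph needs at least 2 frames")
    a = open_struct.coords
    b = closed_struct.coords
    ts = np.linspace(0.0, 1.0, n_frames)
    frames = a[None, :, :] * (1.0 - ts)[:, None, None] + b[None, :, :] * ts[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(open_struct, frames)


def noisy_static_trajectory(
    struct: Structure,
    per_atom_sd,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Frames = structure + per-atom isotropic Gaussian noise.

    ``per_atom_sd`` is one SD (Angstrom, per coordinate) per atom, so each
    atom's expected RMSF about its mean is sd*sqrt(3)."""
    sd = np.asarray(per_atom_sd, dtype=float)
    if np.isscalar(per_atom_sd) or sd.ndim == 0:
        sd = np.full(len(struct), float(per_atom_sd))
    if sd.shape != (len(struct),):
        raise ValueError("per_atom_sd length must equal atom count")
    if np.any(sd < 0):
        raise ValueError("per_atom_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base = struct.coords
    frames = base[None, :, :] + rng.normal(size=(n_frames, len(struct), 3)) * sd[None, :, None]
    return Trajectory(struct, frames)


def rigid_rotation_trajectory(
    struct: Structure,
    rotate_indices,
    axis_atoms: tuple[tuple[str, int, str], tuple[str, int, str]],
    angle_schedule_deg,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trajectory:
    """Per-frame rotation of selected atoms about the axis through two
    anchor atoms; all other atoms stay fixed.

    ``axis_atoms`` are (chain, residue, atom_name) keys.  An anchor atom
    inside the rotating selection is flagged with a warning: the axis is
    defined by its position, so metrics that treat it as part of the moving
    body would be inconsistent with the fixed axis."""
    import warnings

    rotate_indices = np.asarray(rotate_indices, dtype=int)
    i1 = struct.index_of(*axis_atoms[0])
    i2 = struct.index_of(*axis_atoms[1])
    p1 = struct.atoms[i1].position
    p2 = struct.atoms[i2].position
    if np.linalg.norm(p2 - p1) < 1e-9:
        raise ValueError("axis anchors coincide")
    axis_dir = _unit(p2 - p1)
    selected = set(rotate_indices.tolist())
    if i1 in selected or i2 in selected:
        warnings.warn(
            "rotation axis anchor lies inside the rotating selection; "
            "rotation metrics anchored on it may be inconsistent",
            stacklevel=2,
        )
    schedule = np.asarray(angle_schedule_deg, dtype=float)
    base = struct.coords
    frames = np.repeat(base[None, :, :], len(schedule), axis=0)
    for fi, ang in enumerate(schedule):
        frames[fi, rotate_indices] = rotate_about_axis(
            base[rotate_indices], p1, axis_dir, float(ang)
        )
    if noise_sd > 0:
        if seed is None:
            raise ValueError("noise requires a seed")
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(struct, frames)


def displacement_event_trajectory(
    struct: Structure,
    move_indices,
    displacement,
    event_frame: int,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """A step event: selected atoms sit at their input position before
    ``event_frame`` and at position + ``displacement`` from it onward.

    Emulates scheduled H-bond breakage/reformation, side-chain expulsion
    and insertion events with an exactly known event frame."""
    move_indices = np.asarray(move_indices, dtype=int)
    displacement = np.asarray(displacement, dtype=float).reshape(3)
    if not (0 < event_frame < n_frames):
        raise ValueError("event_frame must fall strictly inside the trajectory")
    base = struct.coords
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    frames[event_frame:, move_indices] += displacement
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(struct, frames)


def ou_two_probe_trajectory(params: SyntheticParams) -> tuple[Trajectory, float, float]:
    """Euler-Maruyama Ornstein-Uhlenbeck distance series carried by two
    probe atoms at (0,0,0) and (0,0,x_t).

    Returns (trajectory, stationary mean, stationary SD) with the analytic
    stationary law sd = sigma / sqrt(2*theta).  Raises for an unstable
    discretization (theta*dt >= 2)."""
    theta = float(params.ou["theta"])
    mu = float(params.ou["mu"])
    sigma = float(params.ou["sigma"])
    dt = float(params.ou["dt"])
    if theta <= 0 or dt <= 0:
        raise ValueError("theta and dt must be positive")
    if theta * dt >= 2.0:
        raise ValueError("unstable Euler-Maruyama discretization: theta*dt >= 2")
    rng = np.random.default_rng(params.seed)
    x = np.empty(params.n_frames)
    x[0] = mu
    noise = rng.normal(size=params.n_frames - 1) if params.n_frames > 1 else np.empty(0)
    for t in range(params.n_frames - 1):
        x[t + 1] = x[t] + theta * (mu - x[t]) * dt + sigma * np.sqrt(dt) * noise[t]
    atoms = [
        AtomRecord(1, "CA", "GLY", "A", 1, "C", np.zeros(3)),
        AtomRecord(2, "CA", "GLY", "A", 2, "C", np.array([0.0, 0.0, mu])),
    ]
    topo = Structure(atoms, source_id="ou-two-probe")
    frames = np.zeros((params.n_frames, 2, 3))
    frames[:, 1, 2] = x
    traj = Trajectory(topo, frames)
    return traj, mu, sigma / np.sqrt(2.0 * theta)
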