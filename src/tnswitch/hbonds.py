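"""Hydrogen-bond distance monitoring and transition detection.

Crystal structures carry no hydrogens, so amide hydrogens are placed
geometrically (1.01 A from N along the bisector of the C_prev-N and CA-N
directions) and recomputed per frame so they follow backbone motion.
H-bonds are judged on distance only: HN...O <= 2.5 A (hydrogen mode) or
N...O <= 3.5 A (heavy mode) counts as formed.  Breakage/reformation events
are detected by thresholding with a dwell filter.

The beta-scaffold report covers the four-stranded H-bond ladder joining
EF sites I and II (ILE36/ILE72 central pair, GLY34-PHE74 and THR38-GLY70
flanking pairs), whose consolidation accompanies ion release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import MetricSeries
from .structure_io import AtomRecord, Structure, Trajectory

__all__ = [
    "HBondPair",
    "TransitionEvent",
    "add_amide_hydrogens",
    "hbond_distance_series",
    "detect_transitions",
    "beta_scaffold_report",
    "BETA_SCAFFOLD_PAIRS",
]

_H_BOND_LENGTH = 1.01  # N-H, Angstrom

# (donor residue, acceptor residue) of the scaffold sheet, TnC numbering;
# the donor contributes HN, the acceptor its carbonyl O.
BETA_SCAFFOLD_PAIRS = (
    ("ILE72HN-ILE36O", 72, 36),
    ("ILE36HN-ILE72O", 36, 72),
    ("PHE74HN-GLY34O", 74, 34),
    ("THR38HN-GLY70O", 38, 70),
)


@dataclass(frozen=True)
class HBondPair:
    """Donor/acceptor atom keys (chain, residue_number, atom_name)."""

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


@dataclass(frozen=True)
class TransitionEvent:
    kind: str  # "breakage" | "reformation"
    frame: int
    dwell_before: int
    dwell_after: int


def _amide_h_position(n, ca, c_prev) -> np.ndarray:
    u = lambda v: v / np.linalg.norm(v)
    return n - _H_BOND_LENGTH * u(u(c_prev - n) + u(ca - n))


def add_amide_hydrogens(struct: Structure) -> Structure:
    """Return a copy with an HN placed on every eligible residue.

    Skipped: prolines, chain N-termini, residues already holding an HN,
    and residues missing a geometric anchor (counted with a warning).
    Heavy atoms are never moved; the operation is idempotent.
    """
    by_res: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    res_meta: dict[tuple[str, int], str] = {}
    for a in struct.atoms:
        by_res.setdefault((a.chain_id, a.residue_number), {})[a.atom_name] = a.position
        res_meta[(a.chain_id, a.residue_number)] = a.residue_name

    chain_first: dict[str, int] = {}
    for ch, rn in by_res:
        chain_first[ch] = min(chain_first.get(ch, rn), rn)

    new_atoms = list(struct.atoms)
    serial = max((a.serial for a in struct.atoms), default=0)
    skipped = 0
    for (ch, rn), atoms in by_res.items():
        if res_meta[(ch, rn)] == "PRO" or rn == chain_first[ch]:
            continue
        if "HN" in atoms or "H" in atoms:
            continue
        prev = by_res.get((ch, rn - 1), {})
        if "N" not in atoms or "CA" not in atoms or "C" not in prev:
            skipped += 1
            continue
        serial += 1
        new_atoms.append(
            AtomRecord(
                serial=serial,
                atom_name="HN",
                residue_name=res_meta[(ch, rn)],
                chain_id=ch,
                residue_number=rn,
                element="H",
                position=_amide_h_position(atoms["N"], atoms["CA"], prev["C"]),
            )
        )
    if skipped:
        warnings.warn(
            f"amide hydrogen placement skipped {skipped} residue(s) with "
            "missing geometric anchors",
            stacklevel=2,
        )
    out = Structure(new_atoms, struct.source_id, struct.model_number)
    out.hydrogens_skipped = skipped
    return out


def hbond_distance_series(
    traj: Trajectory,
    pair: HBondPair,
    mode: str = "heavy",
) -> MetricSeries:
    """Per-frame donor-acceptor distance.

    ``heavy``: N...O using the named donor atom.  ``hydrogen``: HN...O with
    the amide hydrogen recomputed each frame from that frame's backbone
    (the donor key names the residue whose HN is used)."""
    topo = traj.topology
    ch_d, rn_d, _ = pair.donor
    i_acc = topo.index_of(*pair.acceptor)
    if mode == "heavy":
        i_don = topo.index_of(*pair.donor)
        d = np.linalg.norm(traj.frames[:, i_don] - traj.frames[:, i_acc], axis=1)
    elif mode == "hydrogen":
        i_n = topo.index_of(ch_d, rn_d, "N")
        i_ca = topo.index_of(ch_d, rn_d, "CA")
        i_cprev = topo.index_of(ch_d, rn_d - 1, "C")
        n = traj.frames[:, i_n]
        ca = traj.frames[:, i_ca]
        cp = traj.frames[:, i_cprev]
        u = lambda v: v / np.linalg.norm(v, axis=1, keepdims=True)
        h = n - _H_BOND_LENGTH * u(u(cp - n) + u(ca - n))
        d = np.linalg.norm(h - traj.frames[:, i_acc], axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    label = pair.label or f"{pair.donor}-{pair.acceptor}"
    return MetricSeries(
        name=f"hbond_{label}_{mode}", values=d, anchors=(pair.donor, pair.acceptor)
    )


def detect_transitions(
    series: MetricSeries,
    threshold: float,
    min_dwell: int = 1,
) -> list[TransitionEvent]:
    """Breakage/reformation events of a distance series.

    A bond is formed while the distance is <= ``threshold``.  A crossing
    counts only if the new state persists for at least ``min_dwell``
    frames; shorter excursions are ignored.  Events alternate in kind; the
    initial state is the first frame's side of the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    formed = series.values <= threshold
    events: list[TransitionEvent] = []
    state = bool(formed[0])
    run_start = 0
    i = 1
    while i < len(formed):
        if bool(formed[i]) != state:
            # candidate crossing: require the new state to persist
            j = i
            while j < len(formed) and bool(formed[j]) != state:
                j += 1
            dwell_after = j - i
            if dwell_after >= min_dwell:
                events.append(
                    TransitionEvent(
                        kind="breakage" if state else "reformation",
                        frame=int(series.frame_indices[i]),
                        dwell_before=i - run_start,
                        dwell_after=dwell_after,
                    )
                )
                state = not state
                run_start = i
                i += 1
            else:
                i = j  # blip too short: stay in the old state
        else:
            i += 1
    return events


def beta_scaffold_report(
    traj: Trajectory,
    chain: str,
    formed_threshold: float = 2.5,
) -> dict[str, dict]:
    """The four scaffold H-bonds in hydrogen mode, with formed fractions.

    Returns ``{label: {"series": MetricSeries, "formed_fraction": float}}``
    where formed means HN...O <= ``formed_threshold`` (default 2.5 A).
    """
    topo = traj.topology
    needed = {34, 36, 38, 70, 72, 74}
    present = set(topo.residue_numbers(chain))
    if not needed <= present:
        raise KeyError(
            f"beta-scaffold residues missing from chain {chain!r}: "
            f"{sorted(needed - present)}"
        )
    out: dict[str, dict] = {}
    for label, donor_res, acceptor_res in BETA_SCAFFOLD_PAIRS:
        pair = HBondPair(
            donor=(chain, donor_res, "HN"),
            acceptor=(chain, acceptor_res, "O"),
            label=label,
        )
        series = hbond_distance_series(traj, pair, mode="hydrogen")
        out[label] = {
            "series": series,
            "formed_fraction": float(np.mean(series.values <= formed_threshold)),
        }
    return out
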