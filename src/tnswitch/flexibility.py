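"""Per-residue Ca root-mean-square fluctuation and cross-condition ratios.

Frames are least-squares superposed (Kabsch) on a fit selection before the
fluctuation of each analyzed Ca about its post-fit mean position is taken;
RMSF_i = sqrt(<|r_i - <r_i>|^2>).  The default fit selection is the
analyzed N-lobe itself (Ca of residues 5-80); the superposition protocol
is explicit configuration because different choices redistribute apparent
flexibility between regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structure_io import Selection, Trajectory, resolve_selection

__all__ = ["FlexibilityProfile", "rmsf_profile", "rmsf_fold_change"]


@dataclass(frozen=True)
class FlexibilityProfile:
    residue_numbers: np.ndarray
    rmsf: np.ndarray  # Angstrom, one value per analyzed residue
    fit_selection: Selection | None
    reference: str  # "mean-structure" | "frame-0"

    def __post_init__(self) -> None:
        rn = np.asarray(self.residue_numbers, dtype=int)
        rf = np.asarray(self.rmsf, dtype=float)
        if rn.shape != rf.shape:
            raise ValueError("one RMSF value per residue required")
        if np.any(rf < 0):
            raise ValueError("RMSF cannot be negative")
        object.__setattr__(self, "residue_numbers", rn)
        object.__setattr__(self, "rmsf", rf)


def _superpose_frames(frames: np.ndarray, fit_idx: np.ndarray, reference: str) -> np.ndarray:
    """Superpose every frame onto the reference using the fit atoms.

    ``mean-structure`` iterates once: fit to frame 0, take the mean, refit
    to that mean (the standard RMSF protocol)."""
    def fit_all(target_fit: np.ndarray, frames_in: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames_in)
        for f in range(frames_in.shape[0]):
            tr, _ = kabsch_superpose(frames_in[f, fit_idx], target_fit)
            out[f] = tr.apply(frames_in[f])
        return out

    if reference == "frame-0":
        return fit_all(frames[0, fit_idx], frames)
    if reference == "mean-structure":
        pass1 = fit_all(frames[0, fit_idx], frames)
        mean_fit = pass1[:, fit_idx].mean(axis=0)
        return fit_all(mean_fit, frames)
    raise ValueError(f"unknown reference {reference!r}")


def rmsf_profile(
    traj: Trajectory,
    analyze: Selection | None = None,
    fit: Selection | None = None,
    reference: str = "mean-structure",
    chain: str = "A",
) -> FlexibilityProfile:
    """Per-residue Ca RMSF after superposition.

    ``analyze`` defaults to Ca of residues 5-80; ``fit`` defaults to the
    same selection.  ``fit=Selection()`` with zero matches is rejected;
    pass ``fit="identity"`` to skip superposition entirely (useful when
    frames are already aligned or noise is applied to a static frame).
    """
    if analyze is None:
        analyze = Selection(chain=chain, residue_range=(5, 80), atom_names=frozenset({"CA"}))
    analyze_idx = resolve_selection(traj.topology, analyze, require_nonempty=True)

    if isinstance(fit, str) and fit == "identity":
        aligned = traj.frames
        fit_sel = None
    else:
        fit_sel = fit if fit is not None else analyze
        fit_idx = resolve_selection(traj.topology, fit_sel, require_nonempty=True)
        if len(fit_idx) < 3:
            raise ValueError("fit selection must resolve at least 3 atoms")
        aligned = _superpose_frames(traj.frames, fit_idx, reference)

    sub = aligned[:, analyze_idx]
    mean_pos = sub.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sub - mean_pos) ** 2, axis=2), axis=0))
    residues = np.array(
        [traj.topology.atoms[i].residue_number for i in analyze_idx], dtype=int
    )
    return FlexibilityProfile(residues, rmsf, fit_sel, reference)


def rmsf_fold_change(
    a: FlexibilityProfile,
    b: FlexibilityProfile,
    floor: float = 0.05,
    peak_ratio_cutoff: float = 2.0,
) -> tuple[np.ndarray, list[dict]]:
    """Per-residue RMSF ratio a/b with a floor, plus ratio peaks.

    ``ratio_i = max(a_i, floor) / max(b_i, floor)`` guards against division
    by near-zero fluctuations.  Peaks are local maxima of the ratio above
    ``peak_ratio_cutoff``, reported as dicts with the centre residue and
    the peak ratio.
    """
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        sa, sb = set(a.residue_numbers.tolist()), set(b.residue_numbers.tolist())
        raise ValueError(
            f"profiles cover different residues; symmetric difference: "
            f"{sorted(sa ^ sb)}"
        )
    ra = np.maximum(a.rmsf, floor)
    rb = np.maximum(b.rmsf, floor)
    ratio = ra / rb
    peaks: list[dict] = []
    for i in range(len(ratio)):
        if ratio[i] < peak_ratio_cutoff:
            continue
        left = ratio[i - 1] if i > 0 else -np.inf
        right = ratio[i + 1] if i < len(ratio) - 1 else -np.inf
        if ratio[i] >= left and ratio[i] > right:
            peaks.append(
                {"residue": int(a.residue_numbers[i]), "ratio": float(ratio[i])}
            )
    return ratio, peaks
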