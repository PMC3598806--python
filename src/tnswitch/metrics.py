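"""Headline metrics of the TnC N-lobe calcium switch.

The openness of the A/B-helix hydrophobic pocket is measured as the
distance *d* between the Ca atoms of the first A-helix residue (GLU16) and
the last B-helix residue (LEU48).  Trajectory means of *d* classify the
lobe as closed, semi-closed, or open.  EF-hand binding-site geometry is
tracked as the loop position 1 <-> 12 Ca span (site expansion) and as the
"prong" contacts from the position-12 glutamate side-chain oxygens to the
backbone nitrogens of loop positions 2 and 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import ChainMap, Structure, Trajectory

__all__ = [
    "MetricSeries",
    "EFSiteDefinition",
    "PocketStateThresholds",
    "site_I",
    "site_II",
    "pocket_openness_series",
    "window_stats",
    "classify_pocket_state",
    "site_expansion_series",
    "prong_distance_series",
]


@dataclass(frozen=True)
class MetricSeries:
    """Per-frame scalar values with units and provenance."""

    name: str
    values: np.ndarray
    unit: str = "angstrom"
    anchors: tuple = ()
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        fi = self.frame_indices
        fi = np.arange(len(v)) if fi is None else np.asarray(fi, dtype=int)
        if fi.shape != v.shape:
            raise ValueError("frame_indices length must match values")
        object.__setattr__(self, "frame_indices", fi)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EFSiteDefinition:
    """A 12-residue EF-hand Ca-binding loop.

    The ion is coordinated by the residues at loop positions 1, 3, (5 in
    site II), 7 and 12; position 12 is an invariant bidentate glutamate.
    Site I spans residues 29-40 and site II residues 65-76 in the fast
    skeletal isoform numbering used throughout.
    """

    site_id: str
    loop_start: int
    chain: str
    ligand_positions: tuple = (1, 3, 5, 7, 12)

    def __post_init__(self) -> None:
        if not set(self.ligand_positions) <= {1, 3, 5, 7, 12}:
            raise ValueError("ligand positions must be a subset of {1,3,5,7,12}")

    @property
    def loop_residues(self) -> range:
        return range(self.loop_start, self.loop_start + 12)

    @property
    def position1_residue(self) -> int:
        return self.loop_start

    @property
    def position2_residue(self) -> int:
        return self.loop_start + 1

    @property
    def position9_residue(self) -> int:
        return self.loop_start + 8

    @property
    def position12_residue(self) -> int:
        return self.loop_start + 11


def site_I(chain: str) -> EFSiteDefinition:
    return EFSiteDefinition("I", 29, chain)


def site_II(chain: str) -> EFSiteDefinition:
    return EFSiteDefinition("II", 65, chain, ligand_positions=(1, 3, 5, 7, 12))


@dataclass(frozen=True)
class PocketStateThresholds:
    """State boundaries on the mean pocket distance d (Angstrom).

    Defaults separate the closed cluster (~13.2-13.7), the semi-closed
    cluster (~15.2-16.5) and the open cluster (~23.8-23.9)."""

    closed_max: float = 14.5
    semi_closed_max: float = 18.0

    def __post_init__(self) -> None:
        if not self.closed_max < self.semi_closed_max:
            raise ValueError("closed_max must be below semi_closed_max")


def _ca_index(traj: Trajectory, chain: str, residue: int) -> int:
    topo = traj.topology
    try:
        return topo.index_of(chain, residue, "CA")
    except KeyError:
        raise KeyError(
            f"Ca atom of residue {residue} (chain {chain!r}) required by the "
            "metric is missing from the topology"
        ) from None


def pocket_openness_series(
    traj: Trajectory,
    res_a: int = 16,
    res_b: int = 48,
    chain: str = "A",
) -> MetricSeries:
    """Per-frame pocket openness d = |Ca(res_a) - Ca(res_b)| in Angstrom."""
    ia = _ca_index(traj, chain, res_a)
    ib = _ca_index(traj, chain, res_b)
    d = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    return MetricSeries(
        name="pocket_openness_d",
        values=d,
        anchors=((chain, res_a, "CA"), (chain, res_b, "CA")),
    )


def window_stats(series: MetricSeries, window="all") -> tuple[float, float]:
    """(mean, sample SD) of a series over a window.

    ``window``: "all", ("last_n_frames", n), or ("frame_range", lo, hi)
    with an inclusive frame range clipped to the series."""
    v = series.values
    if window == "all":
        w = v
    elif isinstance(window, tuple) and window[0] == "last_n_frames":
        n = int(window[1])
        if n < 1:
            raise ValueError("last_n_frames window must be >= 1")
        w = v[-n:]
    elif isinstance(window, tuple) and window[0] == "frame_range":
        lo, hi = int(window[1]), int(window[2])
        mask = (series.frame_indices >= lo) & (series.frame_indices <= hi)
        w = v[mask]
    else:
        raise ValueError(f"unknown window spec {window!r}")
    if len(w) == 0:
        raise ValueError("window is empty after clipping")
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1)) if len(w) > 1 else 0.0
    return mean, sd


def classify_pocket_state(
    mean_d: float,
    thresholds: PocketStateThresholds = PocketStateThresholds(),
) -> str:
    """closed / semi-closed / open label for a mean pocket distance."""
    if mean_d < 0:
        raise ValueError("mean pocket distance cannot be negative")
    if mean_d <= thresholds.closed_max:
        return "closed"
    if mean_d <= thresholds.semi_closed_max:
        return "semi-closed"
    return "open"


def site_expansion_series(traj: Trajectory, site: EFSiteDefinition) -> MetricSeries:
    """Per-frame Ca(position 1) - Ca(position 12) distance of an EF loop;
    the binding pocket expands when the ion is released."""
    i1 = _ca_index(traj, site.chain, site.position1_residue)
    i12 = _ca_index(traj, site.chain, site.position12_residue)
    d = np.linalg.norm(traj.frames[:, i1] - traj.frames[:, i12], axis=1)
    return MetricSeries(
        name=f"site_{site.site_id}_expansion",
        values=d,
        anchors=(
            (site.chain, site.position1_residue, "CA"),
            (site.chain, site.position12_residue, "CA"),
        ),
    )


def prong_distance_series(
    traj: Trajectory,
    site: EFSiteDefinition,
) -> dict[str, MetricSeries]:
    """The four prong distances of one EF site, per frame.

    For each of the backbone nitrogens at loop positions 2 and 9:
    (a) the minimum distance to the position-12 glutamate side-chain
    oxygens {OE1, OE2} and (b) the distance to its CD carbon.  Keys:
    ``N2-OE``, ``N2-CD``, ``N9-OE``, ``N9-CD``.
    """
    topo = traj.topology
    p12 = site.position12_residue
    missing = [
        nm for nm in ("CD", "OE1", "OE2") if not topo.has_atom(site.chain, p12, nm)
    ]
    if missing:
        res_name = next(
            (a.residue_name for a in topo.atoms
             if a.chain_id == site.chain and a.residue_number == p12),
            "?",
        )
        raise KeyError(
            f"site {site.site_id} position 12 residue {p12} ({res_name}) lacks "
            f"side-chain atoms {missing}; a glutamate-like side chain is required"
        )
    i_cd = topo.index_of(site.chain, p12, "CD")
    i_oe = [topo.index_of(site.chain, p12, nm) for nm in ("OE1", "OE2")]
    out: dict[str, MetricSeries] = {}
    for label, res in (("N2", site.position2_residue), ("N9", site.position9_residue)):
        try:
            i_n = topo.index_of(site.chain, res, "N")
        except KeyError:
            raise KeyError(
                f"site {site.site_id} position {label[1]} residue {res} lacks a "
                "backbone N atom"
            ) from None
        d_oe = np.min(
            np.stack(
                [np.linalg.norm(traj.frames[:, i_n] - traj.frames[:, j], axis=1)
                 for j in i_oe]
            ),
            axis=0,
        )
        d_cd = np.linalg.norm(traj.frames[:, i_n] - traj.frames[:, i_cd], axis=1)
        out[f"{label}-OE"] = MetricSeries(
            name=f"site_{site.site_id}_{label}-OE12",
            values=d_oe,
            anchors=((site.chain, res, "N"), (site.chain, p12, "OE1/OE2")),
        )
        out[f"{label}-CD"] = MetricSeries(
            name=f"site_{site.site_id}_{label}-CD12",
            values=d_cd,
            anchors=((site.chain, res, "N"), (site.chain, p12, "CD")),
        )
    return out
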