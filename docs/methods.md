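# Methods

## The switch and its metrics

Troponin-C's N-lobe is a pair of coupled EF-hands (site I, residues
29–40; site II, residues 65–76, fast skeletal numbering). Each 12-residue
loop coordinates Ca²⁺ through positions 1, 3, (5 in site II), 7 and the
invariant position-12 glutamate, whose side-chain oxygens are
additionally hydrogen-bonded to the backbone nitrogens of loop positions
2 and 9 (the "prong"). Ion release breaks the prong, lets the sites
expand, consolidates the small β-sheet joining them, and allows the
A/B-helix hydrophobic pocket to close and the whole lobe to rotate
relative to the C-lobe. The package turns each of those statements into a
per-frame scalar:

| metric | definition | default parameters |
|---|---|---|
| pocket openness *d* | Cα16–Cα48 distance | states: closed ≤ 14.5 Å < semi-closed ≤ 18.0 Å < open |
| site expansion | Cα(loop pos 1)–Cα(pos 12) | sites 29–40, 65–76 |
| prong distances | min(N···OE1, N···OE2) and N···CD for loop N² and N⁹ | formed reported at N–OE ≤ 3.5 Å |
| β-scaffold | HN···O for the four sheet pairs, H re-placed per frame | formed ≤ 2.5 Å (HN mode), 3.5 Å (heavy) |
| RMSF | per-residue Cα fluctuation after Kabsch fit | analyze + fit = Cα 5–80, mean-structure reference |
| contacts | min heavy-atom distance per residue pair | persistence cutoff 4.5 Å, side-chain scope |
| SASA | Shrake–Rupley, golden-spiral points | probe 1.4 Å, 960 points |
| rotation | virtual dihedrals VD1 = Cα(131,104,73,15), VD2 = (…,54) | degrees in (−180, 180], unwrap off |

Notes on choices that were genuinely open:

* **State thresholds (14.5/18.0 Å)** separate the trajectory-mean
  clusters reported for this system (closed 13.2–13.7, semi-closed
  15.2–16.5, open 23.8–23.9 Å). They are configuration, not hard-coded.
* **Distance-only H-bond criterion.** No donor-angle term: the source
  observations are distance traces, and an angle cutoff would add an
  unverifiable parameter. The HN mode threshold 2.5 Å matches the
  "collapsed to under 2.5 Å" description of the formed THR38HN–GLY70O
  bond; the heavy-atom 3.5 Å is the standard N–O cutoff.
* **Amide H placement**: 1.01 Å from N along the bisector of the
  C_prev→N and CA→N unit vectors, recomputed every frame so hydrogens
  follow the backbone; prolines and chain N-termini are skipped.
* **RMSF superposition** is unstated in the observations this emulates;
  the default fits on the analyzed N-lobe Cα set itself and is exposed in
  config (`fit="identity"` skips fitting, e.g. for pre-aligned frames).
* **Contact cutoff 4.5 Å** heavy-atom is the usual hydrophobic-contact
  convention; the narrative being quantified never defines "contact"
  numerically, so every output states the cutoff used.
* **Residue identity by number.** Site positions are resolved by author
  residue number only; names are informational (the same position is
  called ALA30 and ASP30 in different places of the source material).
* **Dihedral convention**: IUPAC sign,
  `atan2((n₁×n₂)·b̂₂, n₁·n₂)`, degrees at every API boundary. Rotation
  magnitudes are compared as |Δ| because the sign depends on the anchor
  ordering.
* **Kabsch** uses uniform weights by default (no mass weighting is implied
  by the source analyses) and excludes reflections by determinant sign
  correction.
* **Windows are frames.** "Last 10 ns"-style statements map to frames via
  `frame_times` when present; the pipeline's default end window is the
  final quarter of the trajectory.

## The synthetic generator

MD trajectories for this system are not publicly deposited, so all
testing runs on generated data with known answers.

**Two-state toy lobe.** Helices N/A/B/C/D (ideal rise 1.5 Å/residue,
100°/residue twist, radius 2.3 Å tapered at segment ends), two 12-residue
EF loops built as constant-radius solenoids whose position 1↔12 span is
exact, a D/central helix continuing to residue 112, and a C-lobe stub
(125–135) so the inter-lobe dihedral anchors exist. Backbone N/CA/C/O are
placed from local frames; CB (and CG on the hydrophobic-panel residues)
point along the local outward radial direction; position-12 glutamates
carry CB/CG/CD/OE1/OE2. Conformers:

| conformer | pocket d | site span | prong | inter-lobe twist |
|---|---|---|---|---|
| open | 23.9 Å | 10.2 Å | formed (OE···N = 2.85/2.90 Å) | 0° |
| semi-closed | 15.7 Å | 10.6 Å | formed | 14° |
| closed | 13.4 Å | 11.6 Å | released (> 4 Å) | 30° |

The pocket distance is hit exactly by solving the B-helix hinge angle
(Brent's method on a deterministic objective); the twist rotates residues
3–76 about the Cα73→Cα104 axis. Because the EF-loop spans also differ
between conformers, the virtual dihedrals report the twist combined with
that expansion geometry: VD1 measures ≈ 33° and VD2 ≈ 20° between open
and closed, bracketing the prescribed 30°. Construction fails loudly if
any non-adjacent heavy atoms come within 1.5 Å.

**Other generators.** Linear morphs with i.i.d. Gaussian coordinate noise
(default SD 0.3 Å, a typical coordinate jitter scale); per-atom isotropic
noise ensembles (the analytic RMSF is σ√3 per atom); scheduled rigid
rotations about an atom-defined axis; step displacement events with an
exact event frame; a β-hairpin whose four scaffold H-bonds are formed at
HN···O = 1.9 Å by construction (a splay parameter bends the strand ends
apart, breaking only the flanking pairs); and an Euler–Maruyama
Ornstein–Uhlenbeck distance probe (default θ = 1, μ = 4 Å, σ = 1.4,
dt = 0.01, rejecting θ·dt ≥ 2) with stationary SD σ/√(2θ). Every
generator is a pure function of its inputs and seed.

**What the synthetic conditions do not establish.** The toy lobe has
pseudo side chains, no solvent, no forces and no kinetics; passing tests
demonstrate that the metrics measure what they claim on geometry with
known answers (correctness), not that real trajectories will show the
same magnitudes. In particular the hydrophobic-panel persistences on the
toy describe the toy, and the morph is a geometric interpolation, not a
transition pathway. The deposited crystal pair for this system is
emulated by the generator's open/closed conformers; analyses labelled
"state" or "stand-in" in the acceptance output refer to those synthetic
structures, not to downloaded coordinates.

## Numerical details

* PDB I/O is fixed-width v3.3; elements come from the element column or,
  when blank, from the atom-name field (column-13 convention separates a
  calcium ion `CA  ` from an alpha carbon ` CA `). Alt-locs keep the
  highest-occupancy conformer, ties to 'A'. Coordinates outside the
  ±999.999/9999.999 field are a write error, never truncated.
* Shrake–Rupley sphere points come from a golden-section spiral —
  deterministic, so SASA is bit-for-bit reproducible; rigid-motion
  invariance holds to ~0.5 % at 960 points. Radii (Å): C 1.70, N 1.55,
  O 1.52, S 1.80, Ca 2.31, H 1.20; configurable.
* Transition detection is threshold + dwell: a crossing counts only if
  the new state persists ≥ `min_dwell` frames (default 5 in the
  pipeline); events therefore alternate and their counts differ by ≤ 1.
* Relative exposure divides side-chain SASA in context by the same
  conformation's SASA with all other residues deleted; glycine is
  rejected explicitly.
* Problem sizes in the test-suite and acceptance runs: 10 000 frames for
  the RMSF limit (2 % tolerance), 4 000 for fold-change recovery, 100–200
  frames for morphs, 50 replicates for noisy event recovery, 10⁵ steps
  for the OU stationary law (5 %). These sizes make each stochastic check
  tight at its stated tolerance while the whole suite stays fast.

## Known limitations

* The xyz-table trajectory dialect carries coordinates only; chemistry
  must be supplied as a topology object.
* `add_amide_hydrogens` covers backbone amides only; side-chain donors
  are out of scope, as is DSSP-style secondary-structure assignment.
* Binary trajectory formats (DCD/XTC) are not read; convert to
  multi-MODEL PDB first.
* Rotation is reported as virtual-dihedral differences, not a full
  screw-axis decomposition; MET rotamer sampling is visible only through
  distance variance, not χ angles.
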