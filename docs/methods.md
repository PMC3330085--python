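# Methods

This note records the models, conventions and numerical choices behind
`gpcrtraj`, in the package's own terms. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Containers and residue addressing

A trajectory is an immutable atom table (name, residue, chain, element) plus a
`(frames, atoms, 3)` coordinate array in Å and strictly increasing times in
ns; frame times default to `index × stride` with a 0.1 ns stride, matching a
100 ps sampling interval. Ballesteros–Weinstein (BW) codes `H.NN` resolve
through per-helix anchors: `res_seq(H.NN) = res_seq(H.50) + (NN − 50)`.
Explicit per-code entries override the arithmetic and are validated for
consecutiveness within each TM span, so maps for constructs with insertions
must be supplied code-by-code. The TM span windows used for membrane analysis
are 1.29–1.59, 2.38–2.67, 3.24–3.53, 4.39–4.63, 5.38–5.63, 6.33–6.59,
7.30–7.56. Alternate locations other than blank/'A' are dropped with a
warning; insertion codes are rejected.

## Helix axes, bend and face-shift

Segment axes are fitted to the track of *local helical origins*: weighted
centroids of 4 consecutive Cα with weights `[1, a, a, 1]`,
`a = 1.3472963553…`, chosen so that the 100°/residue radial wobble of an
ideal α-helix cancels exactly (`Σ w_k e^{i·100°k} = 0`). A total-least-squares
line through these origins is exact on ideal helical geometry and, unlike an
equal-weight 4-residue window (which leaves a ~0.35 Å residual wobble and a
~19° bias on 6-residue segments), remains unbiased for the short pre/post
segments used in kink analysis. With exactly 4 Cα a plain TLS line through
the raw coordinates is used. The axis point is the centre of the circle
fitted to the Cα cloud in the plane normal to the axis; the sign points from
the first to the last fitted residue.

For a proline at `H.50` with flank f (default 6), the pre-segment is residues
`H.(50−1−f)…H.48` and the post-segment `H.52…H.(51+f)`; the distorted turn
P±1 and the proline are excluded. **Bend** = arccos of the dot product of the
two axis directions, in [0°, 180°]. **Face-shift** compares the observed
radial phase of Cα(P+4) about the pre-axis with the phase predicted by a
linear fit of the pre-segment's unwrapped helical phase versus residue
number, signed by the right-hand rule about the pre-axis. This
phase-extrapolation reference was chosen over a Cβ-based reference because it
is defined for glycine, exact on ideal geometry (a straight helix gives
face-shift ≡ 0), and recovers a scripted rigid spin of the post-segment
exactly when the bend is zero. A pure bend with no spin still produces a
non-zero face-shift (the post-segment presents a different face); this is a
property of any face-shift convention, and the synthetic ground-truth tests
therefore validate face-shift differentially (spin on vs. spin off). Bends
below 0.1° set a `degenerate` flag. Helix tilt is
`arccos |axis·normal|` ∈ [0°, 90°], invariant to axis sign.

Per-frame bend estimates on noisy data (σ = 0.2 Å per atom) have ≈2.7° r.m.s.
scatter and negligible bias; recovery tests therefore compare plateau means,
and event detection relies on sustained threshold crossings (below).

## SM/FM observables and event rules

Dihedrals use the standard IUPAC torsion (cis = 0, right-handed positive);
the implementation is cross-checked against MDAnalysis on random quadruples.
χ1 rotamer bins: g− = [−120°, 0°), g+ = [0°, 120°), trans elsewhere. The
ionic-lock threshold is 9 Å on the R3.50–E6.30 Cα distance with ties labelled
closed; a 5-frame dwell filter suppresses single-frame flicker. The running
average is a trailing mean over the previous 10 samples aligned to the last
sample of each window (the block-vs-sliding ambiguity is resolved in favour
of the trailing rule and fixed). Ring tilt is the angle between the
least-squares plane normal of the six-membered indole ring atoms and the
membrane normal, folded to [0°, 90°] (0° = ring parallel to the membrane).

Activation events are sustained threshold crossings: the onset is the start
of the first run of ≥ dwell (5) frames satisfying the rule condition that
follows a run of ≥ dwell frames violating it; an initially satisfied
condition is baseline state, not an event. The six default rules (TM6 bend
< 20°; D3.32–F6.52 < 8.2 Å; TM6 bend > 20°; W6.48 χ1 trans; D3.32–V6.40
> 21.2 Å; R3.50–E6.30 > 9 Å) use the 9 Å lock threshold from the literature
and otherwise absolute thresholds placed between the baseline and displaced
plateaus of the synthetic bundle — they are generator-calibrated detection
config, not claims about any real receptor, and are replaceable per rule. A
lock-closing rule (distance < 9 Å) covers inverse-agonist-like runs.

## Correlation analysis

Coupling between slow variables is the squared Spearman rank correlation:
Pearson's r on average ranks, which reduces to `1 − 6Σd²/(N(N²−1))` without
ties, then squared; constant series return NaN. Plain Pearson is available
as a comparison mode. The canonical variable sets are m = 8 (TM6/TM7 bend and
face-shift + cholesterol minimum distances to I6.53, M6.57, I6.60, C6.61) and
m = 12 (same kink variables + distances to K6.35, I6.39, F6.42, V6.46, L7.44,
V7.48, V7.52, L7.55). Cholesterol identity is tracked by residue id;
occupancy of a labelled region is the fraction of frames with ≥1 cholesterol
heavy atom within the contact cutoff (default 5.5 Å, a typical heavy-atom
lipid-contact convention) of any region atom. No periodic-boundary treatment
is applied (the synthetic systems are non-periodic; periodic wrapping of real
trajectories must be resolved upstream).

## Essential dynamics

The covariance of atomic fluctuations is mass-unweighted and computed over
Cα coordinates of frames superposed on a common reference by Kabsch fit
(proper rotation enforced, det R = +1). Eigenpairs are sorted descending;
each eigenvector's sign is fixed so its largest-magnitude component is
positive, making projections reproducible. For combined essential dynamics
the last K frames of each source are concatenated; the default reference is
the average structure of the concatenation, obtained by fitting to the first
frame and refitting once to the resulting mean (a fixed two-pass rule rather
than iteration to convergence — deterministic and sufficient for the
conserved invariants: eigenvalue sum = trace, orthonormal basis, exact
reconstruction of centered coordinates). Per-source projection clouds and
their centers quantify how the sources' sampled conformational spaces differ;
extreme projections displace the mean structure to the minimum and maximum
observed projection along one eigenvector, and the per-atom |Δ| between the
extremes is the displacement-magnitude colouring quantity. A rigid shift of
one helix (n of N atoms) by s, after common-fit translation removal, projects
onto the first eigenvector with center separation `s·√(n(N−n)/N)` — the
closed-form oracle used in tests.

## Membrane thickness and residual mismatch

Leaflets are assigned per frame by z about the median C2 coordinate; inputs
whose two groups are separated by < 5 Å are rejected as single-layer. The
thickness map bins the membrane plane into squares (default 2 Å); each bin's
per-frame sample is (mean upper-leaflet C2 z) − (mean lower-leaflet C2 z),
well-defined for sparse bins and equal to the pairwise C2–C2 distance for
flat bilayers; bins with either leaflet absent contribute nothing and bins
containing protein heavy atoms are masked. Values are averaged over the
analysis window (a `--window` last-K-frames generalization of a fixed-length
tail window).

The hydrophobic length of a TM is the extent along the membrane normal of
the Cα of its hydrophobic residues (binary hydropathy classes:
ACFGILMVWY hydrophobic, DEKNQRSTHP polar; config-overridable). The local
membrane thickness d_memb of a TM is the mean of unmasked map bins in an
annulus 5–12 Å from the helix axis restricted to the 90° wedge facing away
from the bundle center — the sector geometry is not prescribed anywhere
authoritative, so it is declared config with these defaults. Residual
exposure per TM sums the lipid-facing SASA of residues whose hydropathy
class mismatches their position relative to the hydrophobic slab
`[mid − d_memb/2, mid + d_memb/2]` (hydrophobic outside, polar inside);
lipid-facing means within 6 Å of a lipid heavy atom, or, for lipid-free
validation structures, on the side of the helix axis facing away from the
bundle. TMs whose sector has no lipid are flagged NaN. Ranking TMs by
residual area (NaN last) gives the candidate oligomerization interface
ordering, plus the summed total. Residual exposure is monotone in d_memb at
fixed structure and contact shell for an all-hydrophobic TM; globally
rescaling the slab also moves the contact shell, so whole-system
monotonicity is not asserted.

SASA is Shrake–Rupley with a deterministic golden-spiral point set (960
points/atom), probe 1.4 Å, and radii C 1.70, N 1.55, O 1.52, S 1.80 Å.
Accuracy against closed-form one- and two-sphere areas is ≤1% at 960 points;
rotation invariance holds to the same quadrature error (translation
invariance is exact).

## Synthetic generator

The generator is kinematic scripting, not dynamics. A 7-TM bundle of ideal
α-helices (rise 1.5 Å, twist 100°, Cα radius 2.3 Å) occupies fixed xy
positions with per-helix spans covering the TM windows plus the juxtamembrane
residues the observables need (e.g. 6.30, 7.60); functionally special BW
positions carry the appropriate residue identities (D3.32, D3.49, R3.50,
E6.30, W6.48, P6.50, P7.50, Y7.53/Y7.60, the cholesterol-contact sets), all
other positions are leucine. Side-chain atoms are placed by internal
coordinates so scripted χ1/χ2 values are recovered exactly by the dihedral
code; tryptophan carries a planar six-membered ring. TM6 leans its
intracellular end toward TM3 so the ionic-lock Cα distance sits in the
closed range (~6.8 Å) at baseline, and helix phases are set so the lock
partners face each other — geometry chosen once so that the literature 9 Å
lock threshold is meaningful in the synthetic system.

Scripted events ramp linearly over 4 frames by default: proline-kink bend
changes (an exact rotation of the post-pivot segment about a horizontal axis
through the pivot Cα; spin is applied first, about the helix-axis line, so a
scripted spin is exactly a helical-phase change), rotamer flips
(instantaneous), rigid segment shifts (the lock-opening/closing sugar moves
the IC segment of TM6 relative to TM3), cholesterol approach/departure along
a tether whose minimum heavy-atom distance is servoed to the scripted value,
and static thickness profiles realized by displacing leaflet C2 planes to
±t(x,y)/2 over a 4 Å lattice with two tail beads per site. Gaussian noise
(default σ = 0.2 Å) is added after all event geometry, so scripted ground
truth is exact underneath the noise; output is bit-reproducible for a fixed
seed. Pseudo-lipids carry only the atoms the analyses read.

What the generator does **not** emulate: real backbone bond geometry beyond
the Cα spiral, side-chain packing and sterics, lipid chemistry and disorder,
periodic boundaries, correlated (physical) fluctuations, and any energetics.
Passing the recovery suite therefore demonstrates that the analysis chain is
correct and self-consistent on known geometry — not that the defaults are
tuned for any particular force field or lipid composition.

## Problem sizes and scripted magnitudes

The recovery suite uses a 500-frame agonist scenario (~1200 protein atoms,
events at frames 50–300, noise σ = 0.2 Å); membrane fixtures use 3–10 frames
of a static bundle in a ~2600-atom slab. `scripts/acceptance.py` additionally
builds two-state stand-ins whose scripted magnitudes are the published
inactive/active values for the β2-adrenergic receptor — TM6 bend 33.2°/25.9°
and NPxxY Cα 7.53–7.60 distance 6.3/9.6 Å (the latter realized by solving the
post-7.56 kink angle whose noiseless distance matches, then measuring the
noisy trajectory through the pipeline). These are synthetic stand-ins for the
crystal-structure worked examples, which require the public PDB entries 2RH1
and 3SN6 (not redistributed; see `tests/data/`).

## Known limitations

- The face-shift convention is this package's declared construction; absolute
  values are not comparable across tools that use a Cβ- or ideal-template
  reference, though differences (e.g. along a trajectory) are.
- Event-onset rules are absolute-threshold config; applying them to a real
  receptor requires re-baselining the thresholds.
- No periodic-boundary handling anywhere; wrap real trajectories first.
- BW maps with insertions inside TM spans must be given explicitly per code.
- SASA rotation invariance and two-sphere accuracy are limited by the fixed
  960-point quadrature (≈1%).
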