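# Methods

This note records the models, parameter choices and numerical conventions
behind `tandemnmr`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and bond vectors

PDB files are read through gemmi. Alternate locations are resolved at read
time by keeping the highest-occupancy conformer (ties go to altloc `A`), so
every downstream selection sees one atom per name. Author residue numbering
is preserved end to end; residues absent from the coordinates inside a
chain's numbering range are recorded as gaps and treated as first-class
information — run-based classifications and selections never bridge them.

Backbone amide protons, when absent (crystal structures), are placed with
the standard sp² idealisation: in the C(i−1)–N(i)–CA(i) plane, along the
external bisector of the C–N–CA angle, 1.02 Å from N. Prolines, chain
starts and residues with incomplete backbone geometry are skipped (the
latter with a warning). This construction commutes with rigid motions of
the input, which the test suite asserts. Side-chain protons are out of
scope; only N–H unit vectors feed the RDC analysis.

Superposition is the closed-form least-squares (Kabsch) fit, computed via
`scipy.spatial.transform.Rotation.align_vectors` on centred coordinates,
which cannot return a reflection. Atoms are paired by the intersection of
(chain, residue number, atom name); hydrogens are excluded by default, and
the pairing rule is a parameter because published RMSD figures rarely state
their exact atom selection. Fewer than three pairs, or a (near-)collinear
set, is a hard error.

## Chemical shifts

The NMR-STAR reader extracts the v3 `_Atom_chem_shift` loop (Seq_ID /
Comp_ID / Atom_ID / Val); a 4-column TSV is accepted interchangeably. No
installed library parses NMR-STAR, so this small reader is part of the
package.

Completeness denominators follow chemistry: prolines are excluded from the
amide (HN/N) classes, glycine from Cβ/Hβ and counted with two Hα. The
N-terminal residue is *included* in the amide denominator by default (its
exclusion is an option, `exclude_n_terminal`), matching the usual
"non-proline residues" accounting of deposition statistics. Percentages are
rounded to one decimal, the precision at which such statistics are
conventionally reported.

Secondary shifts are Δδ(Cα) and Δδ(Cβ) against a bundled random-coil table
(values follow the widely used neutral-pH random-coil compilations for
proteins in water); ΔCα−ΔCβ is the classifier input, with glycine assigned
ΔCβ = 0 so its Cα information is retained. The run-based classifier calls a
residue helix above +0.7 ppm and strand below −0.7 ppm and demotes runs
shorter than 4 (helix; one turn) or 3 (strand) residues to coil. These cuts
are this package's own operating point — dedicated shift-based predictors
(TALOS-style) use far richer inputs and are deliberately not reimplemented.
Assignment gaps break runs.

CSP combines the amide changes as `sqrt(ΔδH² + (w·ΔδN)²)` with `w = 0.15`,
the conventional scaling for the wider ¹⁵N dispersion; `w` is exposed
because published titration analyses vary in their combination rule.
"Significantly shifted" means combined CSP strictly above the threshold
(default 0.1 ppm).

## Dynamics

The hetNOE is `I_sat / I_ref`. Its uncertainty is the standard deviation of
that ratio over `n_mc = 500` Monte-Carlo resamples with independent
Gaussian noise (the spectrum baseline noise) added to both intensities —
both spectra carry baseline noise, so perturbing only one would
underestimate the error. For small relative noise this converges to the
first-order propagation value `ratio·sqrt((σ/I_sat)² + (σ/I_ref)²)`, which
the tests assert to 5% at n_mc = 10⁴. Flexibility is flagged strictly below
a 0.7 ratio cutoff, the conventional boundary for sub-nanosecond motion.

H/D-exchange protection is classed from peak detectability at each
timepoint, with detection meaning intensity above `detect_k·σ` (default
3σ — published analyses state observability qualitatively, so an explicit
operational threshold is used here). Detection is required to be cumulative
from the first timepoint: with the canonical 15 min / 24 h / 48 h schedule
the classes are unprotected (gone by 15 min), short, medium, and persistent
(still present at 48 h). Exchange extent is `1 − I(t)/I_ref`, clamped to
[0, 1]. Rate constants and protection factors are not fitted.

## RDC analysis

Units: the Saupe matrix carries Hz — the dipolar prefactor is folded in —
because couplings are measured and reported in Hz. Canonical eigenvalue
ordering is |Azz| ≥ |Ayy| ≥ |Axx|, giving `Da = Azz/2` and
`R = (2/3)(Axx−Ayy)/Azz`, which the ordering makes non-negative (R ∈ [0,
2/3]). Orientations are intrinsic z-y-z Euler angles in degrees, stated in
every report. The angular form and the `vᵀSv` contraction are both
implemented and agree to 1e-10 on randomized inputs (a dual-formula test).

Single-tensor fitting is exact weighted linear least squares over the five
independent Saupe components (records weighted 1/σ), solved by SVD; a
design condition number above 1e10 is reported as a degeneracy error rather
than a silently unstable fit. χ² = Σ((Dexp − Dcalc)/σ)². When per-record
uncertainties are absent the reader applies a 0.5 Hz floor — splitting
measurements are typically averaged over a few repeats and sub-half-Hertz
confidence is rarely defensible.

Residues with hetNOE below 0.7 are excluded from tensor fitting: an RDC on
a mobile amide is motion-averaged and would bias a rigid-body fit.
Residues lacking an NOE value are retained with a warning.

The two-domain model shares `Da` and `R` (both domains sit in the same
alignment medium) and frees the per-domain orientation: 8 parameters. For
fixed orientations the coupling is linear in `(Da, Da·R)`, so those two are
profiled out by an inner weighted least-squares solve (variable
projection), leaving a 6-dimensional angular optimisation run with
Levenberg–Marquardt from the per-domain SVD orientations. Sign-flip images
of a tensor frame leave the Saupe matrix — and hence the residual surface —
identical, so they are useless as extra starting points; instead a few
deterministic angular perturbations of the SVD start guard against local
minima. Tolerances are 1e-12 (ftol/xtol/gtol) with a 10⁴ evaluation cap.

Model comparison uses
`F = ((χ²_red − χ²_full)/(p_full − p_red)) / (χ²_full/(N − p_full))` with
the F-distribution CDF as the significance probability. Under a true common
tensor the reported probabilities are uniform (checked by KS test over 500
simulations), i.e. the test is correctly calibrated rather than
anti-conservative. The interdomain angle is the angle between the two
principal (z) eigenvectors, folded into [0°, 90°] because an eigenvector's
sign is arbitrary.

Q uses `rms(Dexp)` in the denominator by default; the tensor-magnitude
normalisation `sqrt(2Da²(4+3R²)/5)` is available as an option, since the
literature citation chains behind published Q values do not always pin down
which was used.

## Synthetic data: what it emulates, and what it does not

The generators stand in for raw spectra, which cannot be bundled. They are
deterministic per seed and always return their ground truth.

- Coordinates: ideal poly-alanine α-helices (φ = −57°, ψ = −47°, standard
  bond geometry, ~1.5 Å rise), two domains separated in space with a
  one-residue numbering gap; domain B can be rigidly rotated about the
  tensor's y principal axis so its principal-axis tilt equals the requested
  angle exactly. Straight helices put all N–H vectors on a ~15° cone about
  the helix axis, which conditions the tensor fit worse than a mixed-α/β
  protein; the recovery benchmarks therefore use isotropically distributed
  bond vectors, while the helical construct exercises the structural
  plumbing (H placement, gaps, superposition, end-to-end CLI runs).
- RDCs: one tensor (default Da = 15 Hz, R = 0.3 — magnitudes typical of the
  strong alignment of an elongated domain in a dilute liquid-crystalline
  medium), homoscedastic Gaussian noise (default 1 Hz).
- Shift tables: random coil plus per-state offsets (+3.0/−0.5 ppm helix,
  −1.5/+2.0 strand on Cα/Cβ — round literature-scale values), Gaussian
  noise 0.2 ppm.
- Titrations: one-site fast-exchange isotherm `[L]/(Kd+[L])` with a fixed
  per-residue partition of the combined CSP into H and N components.
- hetNOE: fixed reference intensity 1e6, class ratios 0.82 (rigid) and 0.35
  (flexible).
- HDX: two-state exponential decay with class rates 1.0 / 0.02 / 2e-3 /
  1e-4 min⁻¹ (≥10× apart; each sits well inside its detectability band at
  the 3σ threshold). A noise-free simulation keeps the default recorded
  noise level so detection thresholds remain defined.

None of this models peak overlap, spectral artifacts, heteroscedastic or
correlated noise, partial occupancy, intermediate-exchange line broadening,
or motional averaging of RDCs. Passing the synthetic benchmarks therefore
demonstrates correctness of the estimators and calibration of the F-test
under the stated noise model — not robustness to every pathology of real
spectra.

## Problem sizes and determinism

The shipped benchmarks use 50 bond vectors per tensor fit, 100 seeds for
parameter recovery, 50 simulations for interdomain detection, 500 for null
calibration and 20 for the classifier recovery rates — sizes chosen so the
whole suite and the acceptance script each run in well under a minute on one
core while leaving the medians statistically stable. All stochastic stages
take explicit seeds; identical configuration and seed reproduce every
output byte for byte.

## Known limitations

- The NMR-STAR reader handles the assigned-chemical-shift loop only, not
  full entry metadata, stereo-assignment flags or ambiguity codes.
- The two-domain model assumes rigid domains and exactly two of them;
  flexible linkers (partial alignment averaging between conformers) and
  three-domain systems are out of scope.
- Amide-proton placement uses a single idealised geometry; refinement-grade
  placement would differ at the hundredth-Ångström level.
- The secondary-structure classifier is a two-threshold run-length rule; it
  is calibrated for clarity and testability, not to compete with
  database-driven predictors.
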