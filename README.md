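# tandemnmr

Solution-NMR analysis for tandem-domain proteins, built around the question a
crystal structure cannot answer on its own: **do the two domains keep their
crystallographic relative orientation in solution?**

The package grew out of the characterisation of a tandem BRCT domain — the
phosphopeptide-binding module of the kinetoplastid kinetochore protein KKT4
from *Trypanosoma brucei* — and implements the complete solution-state
analysis for such a system:

- **Chemical-shift perturbation (CSP) mapping** of ligand titrations
  (e.g. phosphate binding in a BRCT phospho-binding pocket), with the
  combined amide perturbation
  `Δδ = sqrt(ΔδH² + (0.15·ΔδN)²)`;
- **Assignment completeness** statistics from NMR-STAR (BMRB) depositions,
  with chemically correct denominators (prolines carry no amide, glycine no
  Cβ);
- **Secondary-shift secondary structure**: ΔCα−ΔCβ relative to random-coil
  values, positive in α-helices and negative in β-strands, segmented into
  helix/strand/coil runs;
- **{¹H}-¹⁵N heteronuclear NOE** ratios with Monte-Carlo uncertainties from
  baseline noise, flagging sub-nanosecond backbone flexibility (ratio < 0.7);
- **H/D-exchange protection classes** from peak detectability across timed
  spectra after transfer into D₂O (canonically 15 min / 24 h / 48 h);
- **Residual dipolar coupling (RDC) analysis** — the core. For an N–H bond
  with polar angles (θ, φ) in the alignment-tensor principal frame,

  ```
  D(θ, φ) = Da · [ (3cos²θ − 1) + (3/2)·R·sin²θ·cos2φ ]
  ```

  equivalently `D = vᵀ S v` with `S` the symmetric traceless Saupe matrix.
  A single tensor is fitted by weighted linear least squares (SVD over the
  five Saupe components). The interdomain question is posed as a nested
  model pair: one tensor for everything (5 parameters) versus shared
  magnitude `Da` and rhombicity `R` but free per-domain orientation
  (8 parameters), compared by an F-test on the χ² drop. The angle between
  the two fitted principal axes is the reorientation the data support.
  Fit quality is reported as the Q factor, `Q = rms(Dexp − Dcalc) / rms(Dexp)`.

A synthetic-data module generates ground-truth-labelled inputs for every
stage (ideal two-domain helical coordinates, RDCs from a known tensor with a
controlled interdomain rotation, shift tables with secondary-structure
offsets, saturation/reference intensity pairs, timed exchange series,
fast-exchange titrations), so the whole pipeline is testable offline.

## Worked example

Generate a synthetic two-domain construct whose domain B is reoriented by 7°
relative to the reference coordinates, then run the full analysis:

```
$ tandemnmr pipeline --seed 11 --out demo --stages synth,completeness,csp,sse,noe,hdx,rdc
7 stages completed; manifest at demo/manifest.json
```

`demo/rdc_fit.json` then contains (abridged):

```json
{
  "interdomain_angle_deg": 6.83,
  "pooled":  {"chi2": 107.69, "q_overall": 0.051},
  "shared":  {"chi2": 40.06,  "q_overall": 0.031,
              "f_test": {"f_value": 31.51, "dof": [3, 56],
                         "probability": 0.9999999999954}}
}
```

Reading: forcing both domains onto one tensor orientation leaves χ² = 107.7;
letting the orientations differ (same Da, R) drops it to 40.1. The F-test
says that improvement is overwhelmingly significant, and the fitted
principal axes differ by 6.8° — recovering the 7° rotation the generator
embedded. The other stages write per-residue TSVs: CSP values with the
seeded binding-site residues above the 0.1 ppm threshold
(`csp_shifted.json`), helix/strand segments (`secondary_structure.tsv`),
hetNOE ratios with flexible residues flagged (`hetnoe_flexible.json`), and
H/D protection classes (`hdx_classes.tsv`).

Every stage is also available as a standalone subcommand
(`completeness`, `csp`, `sse`, `noe`, `hdx`, `rdc-fit`, `superpose`,
`synth`) operating on plain TSV / NMR-STAR / PDB files.

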