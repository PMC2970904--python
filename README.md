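# ildnfit

A toolkit for re-parameterizing protein side-chain torsion potentials in the
Amber force-field convention, in the style of the ff99SB-ILDN correction of
the Ile, Leu, Asp and Asn χ₁ (and Asp/Asn χ₂) torsions. It is aimed at
force-field developers and simulators who want to refit a torsion term
against quantum-mechanical reference scans and validate the result against
rotamer statistics and side-chain NMR observables.

## What it does

A force-field torsion term is a cosine series

    V(θ) = Σₘ kₘ [1 + cos(m·θ − θ₀)],    θ₀ = 0° (Amber convention)

Given a dihedral scan — conformations with a reference QM energy `E_qm` and
the base force-field energy `E_mm_base` (the force field with the old
torsion removed) — the replacement force constants kₘ and an offset k₀ are
obtained by weighted linear least squares on

    J = Σᵢ wᵢ (E_mm_base,i + V(θᵢ) + k₀ − E_qm,i)²,   wᵢ ∝ exp(−β·E_qm,i)

with inverse temperature β = 1.0 mol kcal⁻¹ (≈500 K) by default: minima are
weighted strongly without making barrier regions invisible. Because the
phase is pinned at 0°, the fit is repeated over candidate dihedral
definitions (e.g. N–Cα–Cβ–Cγ vs C′–Cα–Cβ–Cγ) and the best-fitting one kept.

Around that core the package provides:

* the canonical scan grids (χ₁ in 15° steps × three χ₂ values = 72 points;
  full 30° χ₁/χ₂ grids = 144 points, halved to 72 under two-fold χ₂
  symmetry) and delimited-text scan-table I/O (`scan_grid`);
* the published ILDN parameter set and restraint/torsion evaluation
  (`torsion_model`);
* Amber frcmod DIHE export/import with exact sign-to-phase handling
  (`frcmod_io`);
* χ₁ extraction from PDB models, three-state (p/m/t) rotamer
  classification and distribution RMSD (`rotamer_geometry`);
* Karplus ³J back-calculation and alignment-tensor RDC fitting/prediction
  (`nmr_backcalc`);
* synthetic generators with known ground truth for every input
  (`synthetic_data`) and an end-to-end identify → refit → validate recipe
  (`recipe`, CLI `ildnfit recipe`).

## Worked example

```python
from ildnfit import (ildn_parameters, torsion_amplitude, make_chi1_grid,
                     fit_torsion, FitSpec)
from ildnfit.synthetic_data import SyntheticScanSpec, synth_scan

for res in ("ILE", "LEU", "ASP", "ASN"):
    amp = torsion_amplitude(ildn_parameters(res, "chi1")[0])
    print(f"{res} chi1 peak-to-peak: {amp:.2f} kcal/mol")

series, definition = ildn_parameters("ILE", "chi1")
grid = make_chi1_grid(step=15.0, residue="ILE")
scan = synth_scan(grid, SyntheticScanSpec(generators={"chi1": series},
                                          noise_sigma=0.2, seed=42))
result = fit_torsion(scan, FitSpec({"chi1": (1, 2)}, beta=1.0))
print(f"fitted on {definition}: k1={result.chi1.force_constants[0]:+.3f}, "
      f"k2={result.chi1.force_constants[1]:+.3f} (generating: +0.195, -0.846)")
```

prints

```
ILE chi1 peak-to-peak: 1.89 kcal/mol
LEU chi1 peak-to-peak: 1.43 kcal/mol
ASP chi1 peak-to-peak: 5.28 kcal/mol
ASN chi1 peak-to-peak: 2.58 kcal/mol
fitted on N-CA-CB-CG2: k1=+0.199, k2=-0.877 (generating: +0.195, -0.846)
```

The amplitudes are the peak-to-peak ranges of the packaged replacement
potentials — the corrections span roughly 1 (Leu) to 5 (Asp) kcal/mol. The
fit recovers the generating Ile constants from a noisy (σ = 0.2 kcal/mol)
synthetic 72-point scan to within a few hundredths of a kcal/mol; at σ = 0
recovery is exact to 1e−8.

The same workflow is available from the shell:

```sh
ildnfit simulate scan --seed 42 -o scan.csv
ildnfit fit --scan scan.csv --multiplicities 1,2 -o params.txt
ildnfit frcmod --params params.txt --types "N -CX-2C-3C" -o new.frcmod
ildnfit recipe --seed 2010 -o summary.yaml
```

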