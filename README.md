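# dockquant

Quantification of vesicle docking sites in cryo-electron tomograms of
reconstituted SNARE-mediated membrane fusion.

In such reconstitutions, small unilamellar vesicles (SUVs) carrying the
v-SNARE VAMP2 and Synaptotagmin-1 dock onto giant unilamellar vesicles
(GUVs) carrying preassembled t-SNARE — a minimal mimic of a synaptic
vesicle held at the plasma membrane in the primed, pre-fusion state.
Cryo-ET resolves, at each docking site, the separation between the two
membranes and the arrangement of the protein densities that bridge them.
`dockquant` turns those maps into numbers:

* **detection** of docked vesicles (spherical-shell matched filter) and of
  the target-membrane surface, with the docking rule *outer-leaflet gap ≤
  50 nm and visible inter-membrane protein density*;
* **oriented subtomograms**: 150 nm boxes, docking axis rotated onto +z;
* **morphometrics** per junction: membrane separation *d* (SUV outer
  leaflet → GUV outer leaflet at closest approach), protein-density
  landmarks with compartment tags, contact-facet diameter, GUV-protrusion
  flag;
* **morphology class** on the 0 / 0.5 / 1 scale — *clustered* (all
  densities within an exclusion cylinder of radius r_ex = 10 nm about the
  docking axis), *intermediate* (mixed), *ring-like* (all displaced
  radially outward) — plus ring completeness;
* **statistics**: Pearson correlation matrix over (class, d, protrusion,
  density count), r-to-p via t = r·√((n−2)/(1−r²)), strength labels
  (|r| ≥ 0.5 strong, ≥ 0.3 moderate, ≥ 0.1 small);
* **landmark-based class averaging** with density-point overlays and
  radial profiles;
* **biophysical calculators**: reconstitution copy numbers
  (lipids = π·D²/a_lipid, copies = lipids × c_protein/c_lipid), the
  bridging span of a partially zippered SNAREpin (0.365 nm per unfolded
  residue), and the steric-exclusion predicate (a complex of diameter w is
  excluded where d < w);
* a **synthetic scene generator** that renders ground-truth docking scenes
  into noisy, missing-wedge-filtered volumes, used throughout the test
  suite to validate the pipeline end to end.

## Worked example

```python
from dockquant import pipeline
from dockquant.biophysics_models import ReconstitutionSpec, copy_number

total, outward = copy_number(ReconstitutionSpec(140e-9, 50e-6,
                                                vesicle_diameter=80.0))
print(f"VAMP2: {total:.1f} copies per 80 nm SUV, {outward} facing outward")

df, _ = pipeline.simulate_and_analyze_population(12, seed=7)
rec = df[df.recovered]
print(f"{len(rec)}/12 junctions recovered")
print(rec[["gt_class_code", "class_code",
           "gt_separation_nm", "separation_nm"]].round(2).to_string())
```

prints

```
VAMP2: 86.6 copies per 80 nm SUV, 43 facing outward
12/12 junctions recovered
    gt_class_code  class_code  gt_separation_nm  separation_nm
0             0.0         0.0             21.14          21.22
1             0.5         1.0              3.20           3.78
2             0.5         0.0              7.53           6.25
3             1.0         0.5              0.00           2.00
...
```

— the copy-number model (0.65 nm² per lipid, single-surface counting, half
of the reconstituted copies facing outward) applied to a 140 nM protein /
50 µM lipid mix, and a simulated docking population pushed blindly through
detection, orientation, measurement and classification, with ground truth
side by side. Separations come back within about a voxel; the morphology
class matches the generated arrangement for roughly three sites in four at
these conditions — junctions whose densities merge into unresolvable
clusters at separations of a few nm are the ones that flip, a resolution
limit discussed in `docs/methods.md`.

A command-line interface wraps the same library:

```
dockquant simulate --config scene.yaml --seed 1 --out sim/
dockquant detect   --in sim/volume.mrc --out sites/
dockquant stats    --in sites/sites.csv --out report/
dockquant biophys copy-number --protein 140e-9 --lipid 50e-6
```

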