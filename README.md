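# helixpack

Packing-mode, crossing-angle and stability analysis for transmembrane (TM)
helix dimer ensembles.

Many membrane receptors signal through the association of two single-span
TM helices — the integrin alphaIIb/beta3 pair is the canonical example —
and ensembles of self-assembly simulations (or multi-model NMR
depositions) of such systems need the same battery of analyses every time:
how are the helices packed, how many packing modes exist and how populated
are they, is a given model conformationally stable, and which residues
form the helix/helix interface?  `helixpack` implements that battery as a
library plus a thin CLI, together with a synthetic-data module that
generates every input class with known ground truth so the analyses are
testable as parameter recovery.

## What it computes

* **Signed crossing angle** Omega in (-90, +90]: magnitude = acute angle
  between the fitted helix axes (principal direction of the Calpha
  coordinates), sign = chirality triple product `(d_a x d_b) . u` with `u`
  the closest-approach offset between the finite axis segments.  Negative
  Omega is right-handed (RH) packing, positive is left-handed (LH); a
  GxxxG-packed dimer like alphaIIb/beta3 sits near -30 degrees.
* **Angle distributions** over ensembles with RH/LH fractions (sign
  classes over determinate frames) and per-handedness mode means.
* **Spatial density maps**: probability of finding the mobile helix's
  backbone at a point of the bilayer plane around the reference-fitted
  partner helix, with watershed maxima = packing modes, ranked by basin
  mass, plus per-mode representative structures.
* **Stability classification** of RMSD time series (plateau below 3 A and
  flat Theil-Sen drift = stable; steady rise past the threshold =
  unstable), crossing-angle spreads, dimerization-event detection in
  diffusion/association runs, and pairwise cross-trajectory RMSD.
* **Interface characterization**: inter-chain contact maps (heavy-atom or
  residue-centre distances, auto-selected), interface residue sets,
  toward/away residue orientation relative to the partner axis, and
  Jaccard overlap between two interfaces.
* **Synthetic inputs**: ideal helices, dimers at prescribed crossing angle
  and interface azimuth, 70/30 RH/LH mode-mixture ensembles,
  60-A-separation diffusion/association trajectories, plateau/ramp RMSD
  trajectories, and 15-degree rotation scans — all seeded, with
  construction truth recorded in provenance.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from helixpack import synthetic as syn
from helixpack.core import HelixSelector
from helixpack.ensemble import angle_distribution, spatial_density_map

ens = syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=1000, seed=1))
sa = HelixSelector("A", (963, 986))   # alphaIIb-like TM helix
sb = HelixSelector("B", (692, 714))   # beta3-like TM helix

dist = angle_distribution(ens, sa, sb)
print(f"RH fraction: {dist.fraction_rh:.3f}")
print(f"RH mode mean: {dist.mode_means['RH']:.1f} deg")

dmap = spatial_density_map(ens, sb, sa)   # beta3-like helix as reference
for m in dmap.maxima:
    print(f"{m.label}: position ({m.position[0]:.1f}, {m.position[1]:.1f}) A, "
          f"basin mass {m.basin_mass:.2f}")
```

prints

```
RH fraction: 0.687
RH mode mean: -29.6 deg
mode1: position (9.5, 3.5) A, basin mass 0.69
mode2: position (-8.5, -0.5) A, basin mass 0.31
```

i.e. the sign-classified right-handed fraction recovers the generator's
70% weight within sampling error, the RH mode mean recovers the -30 degree
centre, and the density map resolves the two packing modes on opposite
faces of the reference helix with basin masses matching the mixture
weights.

The same analyses are available from the shell:

```sh
helixpack simulate --kind ensemble --n 200 --seed 1 --out ens.pdb
helixpack angles  --config config.yaml ens.pdb
helixpack density --config config.yaml --out density.txt ens.pdb
helixpack run     --config config.yaml --out rundir     # full pipeline
```

where `config.yaml` names the chains, TM residue ranges and parameters:

```yaml
helix_a: {chain: A, residues: [963, 986]}
helix_b: {chain: B, residues: [692, 714]}
backbone_atoms: [CA]
inputs: [ens.pdb]
seed: 0
```

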