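# oligotopo

Topological and biophysical analysis of oligomeric protein assemblies, built
around four questions about a homotrimeric globular domain and its monomers:

- **Surface roughness** — fractal dimension from the scaling of
  solvent-accessible surface area (SASA) with probe radius
  (`FD = 2 − d log SASA / d log PR`, probe ladder 1.0–2.0 Å).
- **Overall shape** — least-squares fit of the general 9-coefficient quadric
  ellipsoid (`Ax² + By² + Cz² + Dxy + Exz + Fyz + Gx + Hy + Iz = 1`) to atomic
  coordinates, reduced to a polar/equatorial spheroid summary (the two most
  similar radii are averaged into the equatorial radius).
- **Internal organisation** — residue contact networks (Cα pairs with
  4 Å < d < 8 Å), Fiedler-vector spectral clustering (k = 2, 3), raw
  betweenness centrality with high (>5000) / medium (4000–5000) tiers, and
  inter-chain pairing statistics (which two chains of a trimer pair up 2:1).
- **Dissociation equilibrium** — trimer ⇌ 3 monomer (Kd = [M]³/[T], M²) and
  the extended trimer ⇌ dimer + monomer ⇌ 3 monomer scheme; titration-curve
  fitting with bootstrap CIs; Perrin/Stokes–Einstein diffusion predictions
  from fitted spheroids as a hydrodynamic cross-check.

All stages are also exercised end-to-end on synthetic fixtures
(`oligotopo.synthetic`): ellipsoid point clouds, Cα bead trimers with planted
contact structure, titration curves, and bimodal size distributions — each
with seeded determinism and machine-readable ground truth.

## CLI

```sh
oligotopo fd INPUT.pdb --per-chain --probes 1.0:2.0:0.2   # fractal dimension
oligotopo ellipsoid INPUT.pdb [--atoms CA|all]            # quadric shape fit
oligotopo pcn INPUT.pdb --k 3 --bc -o pcn_out             # contact network
oligotopo equilibrium fit DATA.csv --scheme t3m           # Kd fit
oligotopo equilibrium predict --kd 5.2e-16 --conc 4e-8    # species fractions
oligotopo hydro --polar 24 --equatorial 17.6              # Perrin diffusion
oligotopo dls DATA.csv --fit-bimodal                      # size distribution
oligotopo simulate trimer --seed 7 -o out                 # synthetic fixtures
oligotopo run CONFIG.yaml                                 # full pipeline
```

Titration CSVs use the header `c_tot_M,f_monomer,technique,weight`
(concentrations molar; the titration span of interest is roughly 2 nM–20 µM).
Size distributions use `diameter_nm,weight_percent`. A pipeline config is a
YAML mapping with `structure`, `output_dir` and a `stages` section
(`fd`, `ellipsoid`, `pcn`, `equilibrium`, `dls`); unknown keys are rejected
before anything runs, and every run writes a `manifest.json` with the
resolved configuration, seeds and radii-table name.

## Conventions

- van der Waals radii default to a united heavy-atom table
  (C 1.87, N 1.65, O 1.40, S 1.85 Å); hydrogens are dropped at load. The
  table is configurable and its name is recorded in run manifests.
- SASA is Shrake–Rupley with a deterministic golden-spiral sphere lattice
  (default 960 points/atom): results are bit-stable across runs.
- Contact-network cutoffs are strict inequalities; betweenness is raw
  unordered-pair counts (no normalization), endpoints not counted.
- Concentrations are molar throughout; Kd is M², the dimer constants M.
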