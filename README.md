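# pntkit

Reduced-scale steered molecular dynamics for the self-assembly of
diphenylalanine (FF) dipeptide chains into helical nanotubes, together with
two triple-product chirality indices, geometry statistics, and many-run
handedness statistics.

The package is a desk-scale research tool, not a production force field:

* **Structures** (`pntkit.structures`): an idealized 43-atom FF unit
  (40-atom zwitterionic dipeptide + one structural water), linear chains
  (`Poly(FF)_n` along +z, configurable gap), parametric helices, exact
  mirroring (L/D enantiomers), and fixed-width PDB I/O (one chain per
  assembly, PHE/PHE/HOH residue triples per unit, optional charges in the
  B-factor column, TSV charge tables).
* **Chirality** (`pntkit.chirality`): the Calpha support-vector index
  (sum of scalar triple products of consecutive Calpha-Calpha vectors;
  positive = right-handed = D, negative = left-handed = L), its
  per-term-normalized variant (`k` configurable, default 5), and the
  dipole-moment index over per-unit dipoles computed about each unit's
  center of mass (any number of units), plus sliding-window profiles for
  detecting mixed-handedness structures.
* **Manipulator** (`pntkit.manipulator`): velocity-Verlet dynamics with a
  four-kind Hooke-spring scaffold (NH3-CO2 contacts, inner/outer diameter
  extensions with even/odd unit groups, helix-pitch springs), a staged
  stiffness schedule (default 0.001/0.01/0.1/1.1 pN/A for 5/15/30/30 ps),
  a collisional thermostat (Poisson collisions with Maxwell-distributed
  virtual particles, lambda default 5/ps, m0 = 1 a.m.u., 300 K), and a
  scaffold-free relaxation phase.  The intramolecular model is *reduced*:
  harmonic 1-2/1-3 distance restraints to the template geometry plus a
  soft inter-unit repulsion — no full biomolecular force field.
* **Geometry** (`pntkit.geometry`): principal-component axis fitting,
  atom-to-axis radial statistics, reflection-free pairwise superposition
  (Kabsch with det = +1 enforced), and unwrapped cylindrical surface maps.
* **Run statistics** (`pntkit.run_stats`): sign-rule and fractional-score
  aggregation of per-run outcomes, including a packaged 2 x 32-run fixture
  table with a frozen checksum.

All force terms and the thermostat are parity-equivariant: mirroring the
initial structure and the collision impulse stream produces the exactly
mirrored trajectory, so chirality outcomes flip sign run by run.

## CLI

```sh
pntkit build chain --chirality L --units 24 --gap 10 -o chain.pdb
pntkit build helix --handedness right --units 24 --per-turn 6 -o helix.pdb
pntkit chirality calpha helix.pdb --k 5 --window 24 --json
pntkit chirality dipole helix.pdb --charges charges.tsv
pntkit geometry radius helix.pdb
pntkit geometry map helix.pdb --bins 30 15 -o map.txt
pntkit stats table            # packaged fixture summary
pntkit assemble run chain.pdb --config cfg.yml --seed 3 -o out.pdb
pntkit assemble batch --runs 32 --base-seed 0 -o batch_out
pntkit pipeline --runs 8 --base-seed 7 --stage-ps 10 -o pipeline_out
```

`pipeline` executes build -> batch assembly -> per-run chirality -> totals
and writes a run-table-shaped `summary.tsv`, per-run PDBs, the resolved
`config.yml`, and aggregated `totals.tsv`.  Every run is deterministic from
its seed; `--mirror` mirrors both the chain and the collision impulses and
negates the chirality column exactly.

## Units

Angstrom / a.m.u. / ps / pN / elementary charge throughout; dipoles in e*A
(1 e*A = 4.8032 debye).  Conversion constants live in `pntkit.constants`.
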