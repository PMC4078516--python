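# acvconf

Conformational analysis toolkit for acyclovir-like acyclic nucleoside
analogues.

The molecule's flexible chain is described by five exocyclic torsions
(phi1..phi5), a pseudo-bond distance R (N9···O5') and two placement angles
beta (C4–N9···O5') and Phi (C1'–N9···O5').  On top of that geometric layer
the package provides:

- **Table analytics** — A/B (anti/syn) classification from the sign of
  phi1, circular torsion-range binning, energy-band statistics, and
  Boltzmann populations `p_i ∝ exp(−E_i/RT)` from tabulated relative
  energies (quantum-chemical energies are *inputs*, never computed here).
- **Structure analytics** — chain-placement descriptors, purine-ring
  nonplanarity dihedrals (nu0..nu4) with threshold flagging, and
  hydrogen-bond detection/typing within monomers and across multimer
  assemblies (the two intramolecular motifs are H5'···N3 = type i and
  H5'···O2' = type ii).
- **Torsion-grid search** — exhaustive 60°-step enumeration over the five
  chain torsions of a template, torsion-space relaxation under a pluggable
  energy model, circular-distance deduplication and A#/B# ranking.
- **Synthetic data** — an idealized 20-atom template whose torsions can be
  set exactly, posed monomers/dimers for H-bond testing, toy energy models,
  circular-mixture conformer ensembles, and packaged transcriptions of the
  reference tautomer/conformer energy tables (`src/acvconf/data/*.tsv`,
  sha256-pinned).

All angles are degrees reported in (−180°, 180°], distances Ångström,
energies kcal/mol, temperatures kelvin.

## CLI

```sh
acvconf descriptors mol.xyz --label-map labels.tsv   # phi1..phi5, R, beta, Phi
acvconf classify table.tsv --level "B3LYP/6-31G(d,p)"
acvconf populations table.tsv -T 298.15 -T 273.15 --energy-column dE
acvconf hbonds assembly.xyz --label-map labels.tsv --max-distance 2.6
acvconf search --step 60 --torsions phi1,phi2,phi3,phi4,phi5 --model toy
acvconf simulate --n 1000 --seed 7
acvconf report --tautomer-table t1.tsv --conformer-table t2.tsv \
    --level "B3LYP/6-31G(d,p)" -o report/
```

Coordinate input is XYZ (count / comment / `element x y z`); multimers are
split by a `molecules=n1,n2,...` comment marker or by covalent-distance
connected components.  A minimal PDB v3 reader (ATOM/HETATM, read-only) is
included; `O5*`-style primes are normalized to `O5'`.  Conformer tables are
UTF-8 comma- or tab-delimited with the canonical header
`name,R,beta,Phi,phi1,phi2,phi3,phi4,phi5,mu,dE,dG` (optional `level`
column; Unicode minus accepted).

## Notes

- Population weighting defaults to the `dE` (electronic + ZPE) column,
  which is the column that reproduces the reference headline populations;
  `dG` is selectable via `PopulationConfig`/`--energy-column`.
- Torsion-bin edges transcribed from printed range summaries are rounded
  extremes, so bin membership is tested after rounding observed values to
  the edges' precision (integer degrees); pass `edge_decimals=None` for raw
  comparisons.
- The template's bond lengths/angles are idealized standard values
  (`acvconf.synthetic.GEOMETRY`); torsion-level quantities are exact but no
  coordinate-level agreement with any published optimized geometry is
  claimed.
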