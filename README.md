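# ssipsolv

Rule-based **surface site interaction point (SSIP)** model for solvation:
predict solvation free energies, solvent–solvent transfer free energies and
partition coefficients, and 1:1 hydrogen-bond complexation free energies of
small neutral organic molecules directly from their SMILES, for water,
non-polar organic solvents and polar organic solvents (ethers, nitriles,
ketones, alcohols).

The package is aimed at physical-organic and medicinal chemists who want
quantitative, interpretable partition estimates (e.g. log *P* between any
two of ~35 parameterised solvents) without quantum chemistry or molecular
dynamics: everything is a small sum of pairwise terms.

## The model

A molecule is represented as a discrete multiset of interaction points, each
carrying a dimensionless hydrogen-bond polarity: donors (α) sit on hydrogen
atoms, acceptors (β) on lone pairs and π systems. Assignment is by
functional-group rules — e.g. every aliphatic C–H contributes one α = 1.20
and one β = 0.60; an aromatic C–H contributes α = 1.40 and two β = 0.70; a
six-membered aromatic ring adds two π-face acceptors (β = 2.00 for a
benzene-like ring, rising with alkyl substitution); water is two α = 2.80
plus two β = 4.50. The total number of SSIPs is anchored so the SSIP
concentration of a pure liquid is ≈ 220 M (water: 4 × 55 M).

A simple solvent S is described by site polarities (α_S, β_S), constants
(C_α, C_β, in kJ mol⁻¹) for the solvent–solvent interactions disrupted on
solvation, and a whole-molecule offset C₀ relative to *n*-hexadecane.
Transferring one solute SSIP into S costs

    Δg_S(α) = −α·β_S − C_β        Δg_S(β) = −α_S·β − C_α

and the molecular solvation free energy is ΔG\*(S) = Σ Δg_S − C₀, so the
solvent-to-solvent transfer free energy is ΔG°(S1→S2) = ΔG\*(S2) − ΔG\*(S1)
and log P = −ΔG°/(RT ln 10). Polar solvents are *two-domain*: a non-polar
site pair (alkane-like, subscript 1) and a polar site pair (subscript 2);
a solute SSIP equilibrates between the domains with effective equilibrium
constants K_i = exp((α·β_Si + C_βi)/RT), combined as
Δg = −RT ln(f₁K₁ + f₂K₂) with site fractions f taken from the SSIP counts
of the solvent molecule itself. For a single site pair this reduces exactly
to the simple-solvent formula.

The 1:1 complexation free energy of a donor α with an acceptor β in a
non-polar solvent is

    ΔG° = −αβ + αβ_S + α_Sβ + C_α + C_β,

equivalent to the solvent-competition form −(α − α_S)(β − β_S) + 6 whenever
C_α + C_β = −α_S β_S + RT ln[S·S] with RT ln[S·S] = 6 kJ mol⁻¹.

All empirical parameters ship in human-readable CSVs under
`src/ssipsolv/data/`, each value tagged with its provenance
(`experimental_1to1`, `optimised`, `assumed`, `fixed`). The `fitting`
module reproduces the calibration machinery: rmsd objective, bounded
derivative-free minimisation over selected registry parameters, and a
seeded synthetic partition-data generator for parameter-recovery tests.

## Worked example

```bash
$ ssip partition "CCCCCCC" --from hexadecane --to water
solute,solvent_from,solvent_to,dG_kJmol,logP
CCCCCCC,hexadecane,water,28.74,-5.03
```

*n*-Heptane has 16 C–H bonds, hence 16 α and 16 β SSIPs. Each C–H group
costs ≈ 1.80 kJ mol⁻¹ on moving from hexadecane into water
((−3.40 − 1.52) − (−3.36 − 3.36)), so the transfer is unfavourable by
16 × 1.80 ≈ 28.8 kJ mol⁻¹ (log P = −5.03 in favour of hexadecane) — the
hydrophobic effect as a pure site count, with no cavitation term. The same
value is predicted for every 16-hydrogen alkane; the experimental values
cluster at 29 ± 2 kJ mol⁻¹.

```python
>>> from ssipsolv import assign, complexation_dg
>>> assign("c1ccccc1").n_total          # benzene: 6 alpha + 12 pi + 2 pi-face
20
>>> round(complexation_dg(2.80, 4.50, "carbon tetrachloride").dg, 2)
0.54
```

The library surface mirrors the CLI: `assign` (SMILES → SSIP profile),
`solvation_free_energy`, `transfer_free_energy`, `complexation_dg`,
`fit_parameters` / `simulate_partition_dataset`. See `docs/methods.md` for
the model's assumptions, conventions and limitations.

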