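# Methods

## Model

The package implements an empirical, additive solvation model. A molecule
is a multiset of surface site interaction points (SSIPs); each SSIP makes
exactly one pairwise contact with a solvent site, all sites in a liquid are
assumed fully paired, and van der Waals contributions are assumed to cancel
between phases, so every free energy is a sum of polar pairwise terms. The
key consequences:

- **Assignment is integer and structural.** One α per hydrogen (on C, O),
  one β per sp3 C–H, two β per sp2 carbon π face, four β per sp carbon,
  one β per heteroatom lone pair, two π-face β per six-membered aromatic
  ring. No geometry, conformers or surface calculations are involved. The
  ~220 M liquid SSIP concentration benchmark (water: 4 sites × 55 M) is an
  advisory consistency check (`ssip_count_from_liquid`), never an override
  of the templates.
- **Solvation is local.** A simple solvent is four numbers (α_S, β_S,
  C_α, C_β) plus the offset C₀; there is no dielectric, cavity or
  entropy-of-mixing term. The same machinery describes water (strongly
  interacting, C_α = C_β < 0) and perfluoroalkanes (weakly interacting)
  with no special cases.
- **Polar solvents are two independent domains.** Ethers, nitriles,
  ketones and alcohols expose an alkane-like domain (1) and a polar domain
  (2). A solute SSIP distributes over the two acceptor (or donor) site
  types according to effective equilibrium constants
  K_i = exp((α·β_Si + C_βi)/RT) weighted by the fraction of solvent sites
  of each type: Δg = −RT ln(f₁K₁ + f₂K₂). The combination is made inside
  the logarithm (a population average of bound states); with degenerate
  sites or f₂ ∈ {0, 1} it collapses exactly to the single-site formula,
  which the property tests enforce at 1e-9 kJ/mol.

## Conventions fixed by this implementation

- **Sign of C₀.** ΔG\*(S) = Σ Δg_S − C₀. A positive C₀ makes solvation in
  S more favourable relative to *n*-hexadecane by C₀, consistent with the
  observed constant gas-to-liquid offset between hexane and hexadecane
  (+1.38/+1.39 kJ mol⁻¹ in hexane's favour). The sign is isolated in one
  place (`solvation_free_energy`).
- **log P.** ΔG°(S1→S2) = ΔG\*(S2) − ΔG\*(S1) and
  log P = −ΔG°/(RT ln 10) = log10([solute]_S2/[solute]_S1): positive log P
  means the solute prefers the destination solvent S2.
- **Site fractions of two-domain solvents.** Per member solvent, the
  fractions are SSIP-count fractions of the member molecule itself,
  stored as integer counts in `polar_members.csv` and cross-checked
  against the assignment rules in the test suite. Polar-domain donors are
  the hydroxyl O–H (alcohols) and the activated C–H on carbons bonded to
  a carbonyl or nitrile carbon (ketones, nitriles, whose solvent α_S2 of
  1.5 reflects exactly those weak donors); polar-domain acceptors are the
  lone-pair/π SSIPs of the functional group. Ethers have no polar donor
  site (f_α2 = 0 for every member).
- **Temperature.** T = 298.15 K, R = 8.3145 J mol⁻¹ K⁻¹ (RT = 2.479
  kJ mol⁻¹), which reproduces the −0.47 kJ mol⁻¹ water constant from
  [S·S] = 110 M. Temperature is overridable through `ModelConstants`, but
  every shipped parameter is a room-temperature quantity; extrapolation is
  out of scope.
- **Complexation in polar solvents is refused**, not approximated: the
  explicit-constant expression is validated against 1:1 complexation data
  in non-polar solvents only.
- **Printed precision.** Free energies are carried at full double
  precision; comparisons against two-decimal reference values round at the
  comparison, and the 16-H-alkane worked example follows the reference
  arithmetic (per-C–H value quoted at two decimals, then scaled by the C–H
  count).

## Parameters and provenance

All numbers live in four CSVs under `ssipsolv/data/`; code contains no
embedded parameter values. Tags: `experimental_1to1` (from 1:1
complexation measurements), `optimised` (calibrated on partition data),
`fixed` (definitional zeros of the reference solvents), and `assumed`.
The `assumed` tag marks secondary-site values chosen by package
convention where no measured or published-fit value is available:

- ether oxygen second lone pair β = 3.98 (the alcohol reduced-second-site
  value; the polar acceptor site of ethers and alcohols is the same
  5.30-class oxygen);
- nitrile nitrogen lone pair β = 5.15 (the nitrile solvent-site value);
- nitrile sp-carbon π β = 0.60 and ketone carbonyl-carbon π-face β = 0.88
  (non-polar π defaults taken from the alkane/aromatic values).

Functional groups with no printed value at all (amines, amides,
thioethers, fluorides, phenols, esters, aryl halides, alkenes, fused
aromatics) are deliberately absent: assignment raises an explicit
`UnassignedAtomError`/`UnsupportedRingError` rather than guessing.
Supported chemistry in this version: alkanes and cycloalkanes, alkyl
chlorides (with the α = 1.6 polarised C–H adjacent to Cl), benzene-like
aromatics with 0–3 or 6 alkyl substituents, water, alcohols, dialkyl
ethers, dialkyl ketones, alkyl nitriles. Neutral molecules only.

## Calibration machinery

`fit_parameters` minimises the rmsd between calculated and experimental
transfer free energies over a named set of registry parameters with box
bounds. The optimiser is deterministic and derivative-free: cyclic
coordinate descent with a halving step (initial 0.25 kJ/mol-scale step,
at most 500 sweeps, rmsd tolerance 1e-4 kJ/mol), then a bounded
Nelder–Mead polish. The best-so-far trace is recorded per sweep and is
non-increasing by construction. Parameters to which the dataset is
insensitive (finite-difference change below 1e-12) are frozen with a
warning instead of drifting. SSIP counts are structural integers and are
never free parameters. The stepwise curriculum used to build the shipped
registry (hydrocarbons → water descriptors → remaining solvents) is a
documented recipe, not code.

## Synthetic data

`simulate_partition_dataset` emulates a solvent–solvent partition table:
for each solute × destination solvent it records the model's transfer
free energy from a common origin solvent (default water, matching the
field's water→organic measurement convention) plus i.i.d. Gaussian noise
(`noise_sd`, default 0; 0.5 kJ/mol is used in the recovery tests, roughly
a third of the 1.4–1.7 kJ/mol scatter of real partition compilations),
seeded and reproducible. It inherits the model's own linearity: it does
not emulate experimental artefacts such as solute association, mutual
solvent saturation ("wet" vs dry octanol), ionisation, or
temperature drift. Passing parameter-recovery tests therefore shows that
the calibration machinery is correct and well-conditioned for the chosen
designs, not that the shipped parameters are optimal for real data.
Recovery tests use 8–12 solutes with deliberately varied donor/acceptor
count ratios (alkanes, benzene, water, alcohols, chloroalkanes) over
8–18 solvents — about 100–220 records for 3 free parameters, which keeps
the linear design full-rank and the suite fast.

## Numerical notes and degenerate inputs

- `ssip_count_from_liquid` rounds half to even (Python's `round`).
- An empty SSIP profile solvates to −C₀ exactly; zero-polarity SSIPs cost
  only the solvent constants.
- Transfer between a solvent and itself is exactly 0; antisymmetry holds
  to 1e-12 across the fixture set.
- Registry round-trips (save → load) are bit-exact: floats are serialised
  with `repr`.
- Two-domain equilibrium factors use exponentials of
  (polarity·site + constant)/RT ≤ exp(~17) for the parameter ranges
  involved — far from overflow.

## Known limitations

- Perfluorocarbon *solutes* in perfluorocarbon solvents are known to be
  poorly described by this class of model (the fluorous effect); the
  solvent side (perfluoroalkane descriptors) is fine for ordinary solutes.
- Gas–liquid and solid–liquid equilibria are out of scope: the reference
  state is liquid-like, and phase changes carry additional contributions
  (vapour-pressure and melting effects) that the model does not capture.
- Single-functional-group solutes were the calibration domain;
  polyfunctional molecules with through-bond electronic coupling or
  intramolecular hydrogen bonds will be less accurate even where all
  groups are parameterised.
- π-face SSIPs are assigned per six-membered ring; fused polycyclic
  aromatics are rejected in this version because their fusion carbons
  have no registered value.
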