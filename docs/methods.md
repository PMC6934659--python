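# Methods

## Two-state denaturation model

A protein unfolding in a chemical denaturant is treated as a two-state
equilibrium observed through a spectroscopic signal with linear pre- and
post-transition baselines:

    S(D) = (α_N + β_N D)(1 − f_U) + (α_U + β_U D) f_U,
    f_U  = 1 / (1 + exp(−x)),   x = m (D − D₅₀) / (R T).

`D` is the denaturant concentration (M), `m` (kcal mol⁻¹ M⁻¹) the
denaturant dependence of the folding free energy, `D₅₀` (M) the midpoint,
and `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹` the molar gas constant (energies here
are per mole, so the molar constant is the appropriate one). The default
temperature is 303.15 K (a 30 °C incubation), overridable per curve. The
logistic form is evaluated with a saturating sigmoid, so the model is
numerically stable for arbitrarily large |x|.

**Fitting.** All six parameters are fitted by Levenberg–Marquardt least
squares. Initialization is data-driven: baselines from linear fits to the
outer 25% of points, `D₅₀` from the half-unfolded crossing of the
baseline-normalized signal, `m` from the slope of logit(f_U) in the
transition region. The model is invariant under swapping the two baselines
together with `m → −m`; fits are canonicalized to `m > 0`, so
`ΔG = m·D₅₀ > 0` always denotes a stable folded state. Featureless data are
rejected with an explicit "no transition" error when the fitted transition
amplitude does not exceed three times the residual standard deviation. A
midpoint outside the observed denaturant range, or fewer than three points
on either side of it, raises a warning rather than an error.

**Uncertainties.** The parameter covariance comes from the Jacobian at the
optimum scaled by the residual variance; `σ(ΔG)` follows by the delta
method, `σ² = D₅₀² var(m) + m² var(D₅₀) + 2 m D₅₀ cov(m, D₅₀)`. Because the
error model behind published ± values is generally unstated, a seeded
residual-resampling bootstrap is provided as an alternative
(`bootstrap_folding_energy`); neither is claimed to reproduce any
particular published error bar.

## Mutant-cycle algebra

The double-mutant cycle isolates the pairwise interaction of side chains
x and y from four folding free energies,
`ΔΔG_xy = ΔG_xy − ΔG_x′y − ΔG_xy′ + ΔG_x′y′`; two cycles measured in
backgrounds differing only in a third residue z give the three-body
cooperativity `ΔΔΔG_coop = ΔΔG_xy(z) − ΔΔG_xy(z′)`. Negative values are
favorable (cycles) or cooperative (boxes). The eight-record box expansion
and the two-cycle difference are algebraically identical and both exposed;
the box value is independent of which residue pair is tracked (path
independence), which the tests verify exactly.

Errors propagate in quadrature assuming independent variant measurements —
the common situation when each variant's ΔG comes from its own melt. When
variants share measurements (e.g. a common wild-type reference), a full
covariance matrix over the input free energies can be supplied instead.

Box classification defaults to sign alone (`cooperative` iff ΔΔΔG < 0),
matching how experimental boxes are usually reported; an opt-in `1sigma`
mode additionally requires |ΔΔΔG| to exceed its propagated σ.

Mutation labels are order-free sets ("L5V-T18A" ≡ "T18A-L5V"); the wild
type is the empty set.

## XH···π geometry

A contact is parameterized by `d`, the distance from the donor heavy atom
(methyl carbon or amide nitrogen) to the unweighted centroid of the six
aromatic ring carbons, and `ω`, the angle (heavy atom)−H−centroid at the
hydrogen; for multi-hydrogen donors the largest such angle is taken and the
winning hydrogen recorded. Design choices:

* `d` is measured from the **heavy atom** because that choice is
  independent of hydrogen placement; a donor-group center-of-mass mode
  (`d_from="group_com"`) is available since either convention appears in
  the literature.
* The tyrosine hydroxyl oxygen (and any other exocyclic atom) is excluded
  from the centroid; only the six ring carbons count. Mass weighting is
  offered but identical to the unweighted mean for all-carbon rings.
* The amide rule mirrors the methyl rule: both N−H hydrogens are evaluated
  and the larger angle taken.
* Donors are side-chain methyls (Ala Cβ, Val Cγ1/Cγ2, Leu Cδ1/Cδ2,
  Ile Cγ2/Cδ1, Thr Cγ2, Met Cε) and side-chain amides (Asn Nδ2, Gln Nε2);
  rings are Phe/Tyr six-rings. Trp and His rings are not enumerated by
  default (extensible through `RingDefinition`).
* Missing hydrogens — the norm in crystal structures — are constructed
  ideally (tetrahedral methyl on the parent-atom axis, C−H 0.109 nm;
  planar sp² amide, N−H 0.101 nm) and flagged in the output. The rotor
  phase of a rebuilt methyl is arbitrary, which leaves `d` exact and
  perturbs `ω` by at most the spread across the three cone positions.

Detection enumerates all donor/ring pairs (excluding same-residue pairs)
and keeps those with ensemble-mean `d ≤ 0.6 nm` and `ω ≥ 120°`, the region
where XH···π contacts cluster in folded proteins; both thresholds are
tunable, and shrinking `d_max` or raising `ω_min` can only remove
candidates. Internally all measured quantities are nm/degrees; coordinate
containers keep the PDB-native angstrom and are converted at the
measurement boundary.

`Δd` — the change in mean contact distance when a neighboring residue is
mutated — is reported under two labeled sign conventions: `eq-literal`
(d_WT − d_MUT) and `weakening-positive` (its negation, positive when the
contact lengthens in the mutant). Both are kept because published usage is
ambiguous between them.

## Pair energetics

The interaction energy between two disjoint atom selections is the sum
over cross pairs of screened Coulomb and Lennard-Jones terms,

    E = Σ_ij k_e q_i q_j / (ε r_ij) + Σ_ij 4 ε_ij [(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶],

with `k_e = 332.0636 kcal Å mol⁻¹ e⁻²`, an effective dielectric constant
`ε = 4.0` by default (a standard protein-interior screening value,
overridable), Lorentz–Berthelot combination (arithmetic σ, geometric ε)
unless a per-pair override is supplied, and **no distance cutoff** within
the pair — cutoffs belong to trajectory propagation, which is out of scope.
Energies are averaged over ensemble snapshots; the standard error over
snapshots is reported.

The cycle/box algebra on energies (ΔΔE, ΔE_xyz = E_xy + E_yz + E_xz, ΔΔΔE)
mirrors the thermodynamic one. Mutated-away side chains contribute zero by
simply emptying the selection (alanine-truncation logic). The
percentagewise cooperativity is ΔΔΔE divided by the **absolute value** of
the mean of the two pair interactions it couples: with attractive
(negative) pair energies this keeps negative fractions cooperative and
positive ones anticooperative, matching the signed-percentage usage this
quantity is reported with.

The packaged parameter table (`toy_params.tsv`) holds generic
protein-force-field magnitudes for the synthetic donor/ring residues only;
it is a test fixture, not a validated force field. Real force-field tables
are supplied by the user in the same TSV format (residue, atom, charge_e,
sigma_nm, epsilon_kcal).

## Synthetic data generators

The generators define the conditions under which the pipeline is validated:

* **Melts** — exact denaturant concentrations with i.i.d. Gaussian noise on
  the signal only, matching fluorescence-readout noise and keeping the fit
  well-posed. Defaults: m = 2.0 kcal mol⁻¹ M⁻¹, D₅₀ = 2.5 M, 25 points over
  0–6 M, baselines spanning ≈ 0.8 signal units, noise 1% of that span —
  a realistic stable-small-protein titration.
* **Mutant families** — per-variant truth free energies are strictly
  additive: a base ΔG plus planted pair terms (removed when either residue
  is mutated) plus planted triple terms (removed when any member is
  mutated). This makes the cycle and box algebra exact on noiseless truth
  values, so end-to-end tests isolate fitting error from algebra. Each
  variant's melt midpoint is D₅₀ = ΔG/m. Note that the planted terms enter
  the truth ΔG with the sign the cycle algebra reports (favorable =
  negative), so a favorable planted term lowers the synthetic variant's
  midpoint — a bookkeeping convention, not a physical claim.
* **Ensembles** — one donor group (tetrahedral methyl, C–H 0.109 nm, or
  planar amide, N–H 0.101 nm) facing an ideal regular hexagon (C–C
  0.139 nm; TYR-like adds an exocyclic oxygen that the centroid excludes).
  The donor hydrogen that realizes the target ω is placed by solving the
  tilt equation with a bracketing root finder; the methyl rotor axis is
  oriented so that this hydrogen is guaranteed to carry the maximal angle,
  and the construction raises an error when the target (d, ω) cannot be
  realized (d below the H reach, or ω that no hydrogen of that donor kind
  could maximize). Isotropic per-atom Gaussian jitter emulates thermal
  scatter. Coordinates are kept in float64 so the zero-jitter
  construct-then-measure round trip holds to 1e-6.

All randomness flows through explicit integer seeds (numpy `default_rng` /
`SeedSequence.spawn`; per-variant streams are spawned so adding a variant
does not perturb the others). What the generators deliberately do **not**
emulate: correlated conformational noise, solvent, force-field dynamics,
secondary interactions of real mutations. Passing recovery tests therefore
demonstrate the correctness of the fitting and algebra under the stated
noise model, not the accuracy of any force field or the absence of
secondary-interaction contamination in real cycles.

## Problem sizes and validation design

The stochastic suites use 100 replicate melts for parameter recovery,
50 eight-variant families (400 fits) for planted-cooperativity recovery,
1,000 random donors for the geometric oracle-equivalence check, and
10⁵-draw Monte-Carlo resampling to validate quadrature propagation — sizes
chosen so each estimate's Monte-Carlo error is well below the tolerance it
is tested against.

## Known limitations

* Only two-state, linear-baseline chemical denaturation; no three-state or
  thermal-melt models.
* Detection covers side-chain methyl/amide donors versus Phe/Tyr six-rings;
  O−H/S−H donors, backbone amides and five-membered rings are out of scope.
* The energy decomposition consumes coordinate ensembles; it does not
  generate them (no MD), and no entropic term is computed, so computed ΔΔE
  magnitudes generally exceed measured ΔΔG ones.
* Cycle energies from non-alanine mutations carry residual secondary
  interactions; the package reports, but cannot correct, this
  contamination.
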