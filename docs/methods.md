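# Methods

## The two-state model

A crystal soaked with a ligand at occupancy `q` is treated as a physical
mixture: a fraction `q` of unit cells holds the *bound* state, the remaining
`1 − q` the *ground* state — the composition of the crystal with everything
identical except the change of interest (the ground state may contain a
substrate mimetic, ordered solvent, or alternate side-chain rotamers; it is
not "empty"). Scattering mixes linearly in `q`:

    F_obs(h) = (1 − q) F_ground(h) + q F_bound(h).

All ensemble machinery follows from taking this superposition seriously:

- **Merging.** Atoms identical in both states (matched by chain, residue,
  name, altloc, and displaced less than `identity_tol` = 0.05 Å — refinement
  jitter must not split atoms) stay single with a blank altloc. Ground-only
  atoms get one conformer ID at occupancy `1 − q`, bound-only atoms a second
  at `q`. The IDs are the first letters of the alphabet used as altloc
  *nowhere* in either input, so causally unrelated conformers elsewhere
  (labelled A/B, say) can never be confused with the binding states (then
  C/D). Labels are applied only inside the *binding region*: residues with
  bound-only atoms, residues with any atom within `proximity_radius` = 5 Å
  of one (first contact shell, including displaced solvent), and residues
  whose matched atoms move more than `move_tol` = 0.5 Å (reordered side
  chains). All three defaults are configurable; the region definition is a
  design choice of this package.
- **Occupancy constraints.** The two conformer groups are written as
  refinement constraint files (REFMAC occupancy keywords; Phenix
  `constrained_group` parameter block) encoding occupancies that sum to
  unity. Refinement itself is out of scope — this package prepares and
  validates models and constraint files, and performs toy-scale estimation.
- **Single conformer per state.** Merging a state that itself has multiple
  conformers at one site raises a branching error rather than inventing
  semantics: the altloc formalism does not support branched conformations,
  and duplicating residues silently would add unconstrained parameters.
- **Extraction.** Selecting a conformer recovers a state; an atom whose site
  has no remaining siblings gets its altloc cleared. The *bound-only* model
  (the conventional single-state model) sets the formerly bound atoms to
  occupancy 0.95, the value that triggers automated occupancy refinement in
  common refinement programs; the *ground-only* model uses 1.0.

## Toy density engine

Atoms are single isotropic Gaussians normalized to integrate to
`occupancy × Z` electrons, with real-space width from `B + B_MIN`
(`B_MIN` = 10 Å² keeps zero-B atoms representable on practical grids). In
reciprocal space the same atom is `occ · Z · exp(−(B + B_MIN) s²/4)` — the
ordinary Debye–Waller factor — so the direct Gaussian summation and the
analytic structure-factor route are exact transforms of each other; the test
suite uses each as the independent oracle for the other. No 4/5-Gaussian
form factors, no anisotropic ADPs, no bulk solvent, P1 only: none of these
add behaviour to the occupancy physics the package exists to exercise, and
each would slow the sub-second FFT loop the tests depend on.

Simulated observations are `|F|` of the two-state mixture with
multiplicative Gaussian noise (`|F| ← |F|(1 + ε)`, `ε ~ N(0, noise_frac)`,
clipped at zero), phases discarded, `F(000)` removed (it is not measurable),
and 5% of reflections flagged as a free set. Map surrogates are unweighted:
`(|Fo| − k|Fc|) e^{iφc}` and `(2|Fo| − k|Fc|) e^{iφc}` after one overall
least-squares scale `k` — the σA-weighted `m`/`D` coefficients of refinement
programs are estimation machinery external to the physics tested here, so
absolute contour levels differ from refinement-program maps while every
stated property (self-consistency, scale invariance, sign of omitted-state
density) holds.

Occupancy is estimated by scanning `q`, scaling `|(1−q)F_g + qF_b|` to the
observations, and refining the residual minimum by parabolic interpolation;
the residual profile is returned for diagnostics. A ground and bound pair
that scatter identically makes the problem ill-posed: the estimate is NaN
with a warning, not a silent number.

The event map `(ρ_obs − bdc·ρ_ground)/(1 − bdc)` cancels the ground
contribution algebraically when `bdc = 1 − q`; on noisy data it still
correlates better with the true bound density than the observed map does
over the ligand — this gain, not any constant, is what the tests assert.

### Toy refinement surrogates

Two single-residue fits emulate what full refinement does to a mis-modelled
ligand, at toy scale: a one-parameter B-factor shift fitted to the
amplitudes (a ligand modelled at 0.95 occupancy when the crystal holds 0.4
fits best with strongly inflated B — the classic B/occupancy trade-off), and
a rigid translation fitted the same way (cheap because a translation only
multiplies the residue's structure factors by a phase factor). They feed the
B-ratio and RMSD axes of the model comparison; they are deliberately not a
refinement program.

## Validation metrics

For one residue, against maps on a common grid:

| metric | definition here | preferred |
| --- | --- | --- |
| RSCC | Pearson correlation of total (2Fo−Fc surrogate) and model density over the residue mask | > 0.7 |
| RSZD | normal-equivalent of the χ² of signed difference-map Z scores over the mask (worse sign taken), floored at 0 | < 3 |
| RSZO | mean total density over the mask / whole-cell map RMS; RSZO/OCC divides by occupancy | RSZO/OCC > 2 |
| B ratio | occupancy-weighted mean B of the residue ÷ same over side-chain atoms of protein residues within 4 Å (waters and backbone excluded) | ~1 |
| RMSD | per-matched-atom RMS deviation to a reference model, **no superposition** — it measures drift in refinement, which superposition would hide | < 1 Å |

Numerical choices that matter:

- The residue mask is all grid points within 1.5 Å of a non-H atom,
  periodic images included. Neighbouring voxels are not independent; the
  χ² degrees of freedom use `n_eff = n · voxel_volume / (resolution/2.4)³`
  as an independent-points correction. These constants reproduce the
  qualitative score contracts (perfect model → 0, omitted state ≫ 3); exact
  numerical compatibility with any external validation program is a
  non-goal.
- The RSZD null: synthesizing amplitude errors with *fixed model phases*
  makes difference-map noise coherent at density peaks — its variance there
  reaches exactly twice the cell average, and residue masks sit on peaks.
  The default Z normalization is therefore `√2 ×` the whole-cell RMS;
  callers may pass their own σ. The normal-equivalent conversion inverts
  the χ² log-tail asymptotically when the survival function underflows, so
  the score stays smooth and monotone instead of saturating. Even so, RSZD
  near its floor is a tail statistic: across seeds an occasional draw of a
  perfectly modelled residue fluctuates above 1, which is why the
  model-comparison contracts are asserted as seed averages and pass rates.
- Because the map noise divides the scores, *worse* phases make RSZD
  *smaller* at fixed model error — the degraded-phase control reproduces
  this deceptive improvement, and it is asserted as a property, not fixed.
- Radar plots use axis order (RSCC, RSZD, RSZO/OCC, B-ratio, RMSD) with a
  monotone "badness" per axis (1−RSCC; RSZD; 1/(RSZO/OCC); |log B-ratio| so
  ratios of ½ and 2 are equally bad; RMSD). Relative mode maps the best
  observed value to the centre and the worst to the rim (≥2 models
  required); absolute mode puts the preferred-value thresholds on the
  marked mid-radius ring, with the B-ratio ring at ratio 2 (or ½).

## Phase tools

Mean absolute phase difference is computed over the common reflection list
with Δφ wrapped to [0°, 180°], in unweighted and amplitude-weighted
variants (phase-matching programs do not always document which convention
they report, so both are available), plus ≥4 equal-count resolution shells.
The degradation control displaces all atoms *outside* a protected region by
a fixed seeded Gaussian direction field scaled by σ_d, with σ_d found by
bisection (≤8 steps, σ_d ≤ 2 Å) until the mean calculated-phase difference
to the original lands in the 20–30° target window; protected atoms are
bit-identical and the whole procedure is deterministic in the seed. B
factors are untouched — the distortion is purely geometric, which satisfies
the published contract (the achieved phase-difference window) without
claiming to reproduce any particular distortion protocol.

## Census

Ligand = hetero residue not on the exclusion list (waters, standard amino
acids and nucleotides; configurable). Rules, in order: first instance of
each ligand code per structure (file order — reproducible); codes with
fewer than 5 non-H atoms excluded; codes kept in more than 50 structures
excluded as too common. Total occupancy is the sum over the ligand's
conformers (each conformer contributing its atoms' mean occupancy once);
sums above 1 + 1e-6 are classified `over_unitary` and counted, never
clamped, because deposited models really contain them. Classes partition
the kept records by construction.

## Synthetic fixtures

The toy protein is a zig-zag chain of eight 4-atom pseudo-residues
(backbone-like N/CA/C + side-chain-like CB) in a 22 Å P1 cube — big enough
for a 4 Å B-ratio neighbourhood and a pocket above the chain, small enough
that a full simulate→map→score pipeline runs in ~0.1 s, which sets the
problem sizes used throughout the tests and the acceptance script
(6.6 × 10³ reflections at 1.5 Å, 44³ grids, 10-seed repeats). Default study
conditions: 1.5 Å resolution, 3% amplitude noise, q = 0.4 (with 0.85 for
the high-occupancy archetype); the occupancy-recovery checks scan
q ∈ {0.1, 0.26, 0.5, 0.7, 0.84, 0.9}. Four archetypes cover the recurring
situations: a substrate mimetic superposed with a perpendicular ligand plus
one reordered side chain; ordered waters displaced by the ligand; a ligand
superposed on a ground-state side-chain rotamer; and high-occupancy binding
where only traces of the ground state remain. Generation is a pure function
of the spec including its seed, and every generated model round-trips
through the PDB/mmCIF writers.

What the fixtures do **not** emulate — and hence what passing tests do not
show about real data: chemically realistic geometry or restraints,
space-group symmetry, bulk solvent, anisotropic displacement, σA weighting,
measurement errors beyond i.i.d. multiplicative amplitude noise, and real
refinement dynamics. Conclusions about score *contracts* (orderings, signs,
invariances) transfer; absolute score values do not.

## Known limitations

- The unweighted map surrogates make absolute contour levels and R values
  incomparable with refinement-program output.
- RSZD magnitudes depend on the `n_eff` heuristic; only orderings and
  threshold contracts are calibrated.
- The empirical R-factor null for an uninformative model on these toy data
  (amplitudes permuted within resolution shells) is ≈0.8, higher than the
  ≈0.59 of Wilson-statistics intuition, because a toy cell with ~40 atoms
  is far from the many-atom Gaussian regime.
- The census is exercised on synthetic collections; absolute counts from
  any real archive snapshot depend on that snapshot and are out of scope.
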