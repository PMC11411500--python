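# Methods

This note records the model, its parameters, the numerical choices, and
the limits of what the test suite demonstrates.

## Site model

A molecule parsed from SMILES or a MOL block (RDKit, hydrogens made
explicit) is reduced to spectroscopic sites: one ¹³C site per carbon, one
¹H site per proton, except that the protons of a rotor group (CH₃, NH₂,
NH₃⁺) are magnetically equivalent and collapse to one site.  Aromatic
protons never collapse: chemical equivalence by symmetry is a property of
the crystal, not of the 2D graph, and treating them separately matches
how peak lists are picked.  Exchangeable O–H/N–H protons are ordinary
sites carrying a flag, since they are observed and assignable.  All
structural reasoning uses the minimum covalent bond distance between
sites (minimum over member atoms); no 3D coordinates are consumed
anywhere in the pipeline.

## Inputs and tolerances

Peak lists are taken as picked positions; no lineshape information is
used.  Matching tolerances default to half a typical ultra-fast-MAS
linewidth: 0.25 ppm (¹H) and 0.5 ppm (¹³C); the DQ coordinate of a
¹H–¹H DQ/SQ entry is a sum of two uncertain shifts, so its tolerance is
doubled.  DQ/SQ entries are resolved into proton-pair contacts; when
several partners fall within tolerance all of them are emitted, and
disambiguation is left to the assignment engine.

Predicted shieldings σ are converted to shifts via δ = offset − σ with
per-nucleus referencing offsets (30.78 ppm ¹H, 170.04 ppm ¹³C).  The
subtraction is done in decimal arithmetic so the identity
δ + σ = offset holds exactly at the printed precision of the inputs;
binary floating point alone cannot guarantee that.

## Priors and candidate gating

Each site gets a Gaussian shift prior.  By default the standard
deviation is the shift predictor's published per-nucleus model error,
4.53 ppm (¹³C) and 0.47 ppm (¹H); a column in the prediction table can
override it per site.  Gaussians replace the empirical fragment-based
shift distributions of database-driven assignment methods deliberately:
they preserve the inference structure while accepting input from any
predictor that reports a value and an uncertainty.

A peak is a candidate for a site when it lies within `z_max` = 4 prior
standard deviations of the mean — conservative enough that the true peak
is essentially never gated out under the Gaussian model — and candidate
weights are the prior densities, floored at 10⁻³⁰ so that no feasible
global assignment underflows to probability zero.

## Constraint and evidence model

The posterior over global assignments (injective site→peak per nucleus;
a strict bijection by default, with an option admitting surplus peaks)
is a product of the per-site prior weights and the following terms:

* **One-bond HETCOR** entries are hard: the two peaks must be assigned
  to a directly bonded C–H pair.
* **Long-range HETCOR** entries are hard outside the bond-distance
  window 2..`w` (default `w` = 3; every narrated long-range correlation
  of the packaged example is consistent with 2–3 bonds) and graded
  inside it.  Grading implements a Bernoulli detection model: an
  in-window pair at distance d produces its cross peak with probability
  p(d) (defaults p(2) = 0.7, p(3) = 0.2, reflecting the steep fall of
  cross-polarisation transfer with distance, chosen on physical grounds
  rather than fitted).  Over all in-window pairs the product of p/(1−p)
  presence terms and (1−p) absence terms factorises into a constant
  times, per *observed* entry, the odds p(d)/(1−p(d)) of the assigned
  pair — so one multiplicative weight per entry carries the full
  presence-and-absence evidence, including the "this carbon should have
  shown more correlations" argument, per identity rather than per
  count.  A coarser count-level alternative (expected in-window partner
  counts vs observed counts per peak, Poisson-matched) is implemented
  and can be enabled instead; both are soft — a missing cross peak never
  eliminates a candidate, since peaks can vanish for dynamics or
  transfer-efficiency reasons.
* **¹H–¹H contacts** are soft with an intermolecular escape: an
  assignment placing the two peaks within `hh_window` = 3 bonds is
  multiplied by a reward (default 2.0); any other assignment is left
  unpenalised, because DQ/SQ contacts are frequently intermolecular.
  Autocorrelation contacts impose nothing.

## Inference

Arc-consistency propagation interleaves two rules to a fixed point:
support pruning on every hard constraint, and all-different propagation
(a site reduced to one candidate removes that peak elsewhere).  Every
elimination is logged with the triggering constraint, so a run's
deduction chain can be replayed; an emptied candidate set raises an
error naming the site and constraint.

The surviving ambiguity decomposes into independent components (sites
linked by shared candidate peaks or by constraints whose both peaks are
still contested).  Components with at most `max_enum` = 9 sites — or all
components, when exact marginalization is requested — are enumerated by
depth-first search over peaks with most-constrained-variable ordering,
bitmask domains, forward checking, and incremental constraint
evaluation; leaf weights are accumulated in log space with running
rescaling.  Larger components fall back to a seeded Metropolis sampler
over feasible assignments whose proposals are same-nucleus peak swaps
extended, deterministically and therefore symmetrically, with the
induced swaps of constraint-partner owners (one-bond constraints tie
each proton peak to its carbon partner, so bare transpositions are
almost always infeasible; block moves restore mixing).  The sampler
assumes the feasible set is connected under these block transpositions —
true for every tested component, but not guaranteed in general, which is
why exact enumeration is preferred wherever affordable.  Marginal rows
are normalised to sum to one within 10⁻⁹.

A site enters the unambiguous map when its top marginal reaches 0.95;
the map is kept injective per nucleus, ties and sub-threshold sites stay
ambiguous, and no tie-breaking is applied.  The threshold cleanly
separates forced assignments (≈1.0) from genuine coin-flips (≈0.5) such
as near-equivalent methyl pairs.

## Validation

For each mapped site, Δδ = δ_exp − δ_pred; ambiguous sites are either
excluded or included under the best-case pairing (the injective pairing
minimising total squared deviation, solved as a linear assignment) and
flagged.  The per-nucleus RMSD is compared with the predictor's expected
errors, and sites with |Δδ| > 3 expected errors are outliers (a
conventional 3σ reading of "no significant outliers").  The verdict is
`validated` iff both RMSDs are within the expected errors and there are
no outliers; worsening any deviation can only flip the verdict one way.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
true shifts drawn uniformly from nucleus-typical ranges (¹H 0–16 ppm,
¹³C 10–180 ppm) with a minimum separation (0.15 / 1.0 ppm) emulating
resolved spectra; priors equal to true shifts plus Gaussian bias;
observed peaks merged when closer than an overlap resolution; one-bond
entries for every bonded C–H pair and long-range entries for every
2..w-bond pair, each dropped independently with a missing rate; DQ/SQ
entries for proton pairs within the contact window.  Instances
serialise through the same delimited formats the readers consume.  A
random-molecule generator (heavy-atom tree growth with ring insertion
respecting valence, hydrogens filling remaining valences) supplies
graphs for property tests; small real templates (quinoline, naphthalene,
verinurad, ...) drive the recovery studies because ring topology, not
size, sets the difficulty.

What passing synthetic tests does *not* show: real spectra have
intensity information, t1 noise, spinning sidebands, temperature drifts
and second-order lineshape effects that the generator omits; the
missing-peak process is distance-independent in the generator but
distance-graded in the inference model (a deliberate robustness check,
not a match); and real predictor errors are correlated across similar
sites, while the generator draws them independently.

## Problem sizes used in the tests

The verinurad example (32 sites; one 25-site ambiguity component) runs
exactly enumerated in a few seconds.  Oracle-equivalence tests compare
exact enumeration with a naive all-permutations oracle, and the Gibbs
sampler with exact marginals, on 100 seeded synthetic instances capped
at 6 sites per nucleus; Gibbs agreement is asserted at three
Monte-Carlo standard errors in aggregate (≥99 % of entries, mean z² < 2,
max |z| ≤ 5) because with thousands of compared marginals occasional
chance exceedances of a per-entry 3σ bound are expected for a correct
sampler.  Recovery studies use the 16-site quinoline template: 50 seeds
at prior sd = 0.3 × the median inter-peak spacing and a 0.3 missing
rate, plus a 3×3 degradation grid of 12 seeds per cell.

## Known limitations

* Site equivalence is graph-based; crystallographic splitting of
  graph-equivalent sites (more peaks than sites) is out of scope.
* Strict-bijection mode requires complete, impurity-free peak lists;
  the non-strict option tolerates surplus peaks but not missing ones
  (merged/overlapping peaks break injectivity).
* The Gibbs fallback can in principle face a transposition-disconnected
  feasible set; diagnostics (batch-means standard errors) are reported
  so such failures are visible.
* Intensities, temperature series and relaxation data are not modelled.
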