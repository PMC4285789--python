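# Methods

## The geometric model

An ideal α-helix places successive Cα atoms on a cylinder of radius
≈ 2.3 Å, advancing ≈ 1.5 Å and rotating ≈ 100° per residue. A *kink* is a
localized departure from this: the axes of the helix segments on either
side of some residue diverge by a measurable angle. The method estimates
the local axis by least-squares cylinder fitting to six-residue backbone
windows (N, Cα, C, O → 24 points), sliding one residue at a time, and
defines the kink angle at residue *i* as the angle between the axes of the
two *disjoint* windows `i−6 … i−1` and `i … i+5`, both oriented N→C. This
convention makes 12 residues the shortest helix with any defined angle and
leaves angles defined at 0-based indices 6 … L−6 of an L-residue helix.

### Cylinder fitting

The fit minimizes Σ(dᵢ − r)², dᵢ being point-to-axis distance. Given an
axis, the optimal radius is the mean distance, so the optimization runs
over four parameters only — two direction components in a tangent
parameterization around the first principal component of the points, and
two axis-offset coordinates in the normal plane — with
`scipy.optimize.least_squares` (LM, xtol 1e-8, effectively exact on clean
data). The axis direction of a cylinder is sign-ambiguous; orientation is
fixed afterwards by requiring a positive projection on the window's
Cα(first)→Cα(last) span, so no antipodal restart is needed. Collinear
point sets (second singular value < 1e-6) raise a degenerate-geometry
error.

Backbone atom types do not share one radius: on an ideal helix N, Cα, C
and O sit at ≈ 1.5, 2.3, 1.7 and 2.0 Å from the axis. For backbone windows
the fit therefore uses *coaxial cylinders* — one shared axis, one
closed-form radius per atom type. This removes an ~0.35 Å systematic
residual of the single-radius model and, empirically on the synthetic
fixtures, raises planted-kink recovery (±5°, ±1 residue at noise
σ = 0.15 Å) from roughly 88% to 97%. The single-radius objective remains
available (`fit_cylinder` without `groups`, and the `ca_only` atom
selection) and is the form checked against the brute-force oracle. The
reported `radius` is always the overall mean point-to-axis distance.

`fit_cylinder_grid` is an independent reference implementation: a
Fibonacci hemisphere scan over axis directions (4000 coarse directions,
two 21×21 local refinements at ±4° and ±0.5°) with a closed-form Kåsa
circle fit per direction and a geometric polish of the final circle
center. It shares no code path with the optimizer and is used only for
cross-checking.

### Wobble angle and kink-residue selection

At a residue with a defined, nonzero kink angle, let d_N and d_C be the
flanking axes. v₁ is d_C projected onto the plane perpendicular to d_N;
v₂ is the perpendicular from the d_N axis line to the residue's Cα. The
wobble angle is the signed angle from v₂ to v₁ about d_N (positive =
counterclockwise viewed from the C-terminal side; only |wobble| matters
downstream). |wobble| ≈ 0 means the helix bends *toward* that Cα — the
residue is on the inside of the kink. The kink residue of a detected peak
is the candidate among {peak−1, peak, peak+1, peak+2} (with defined
wobble) minimizing |wobble|, ties to the lower index. Wobble is treated
as undefined when the kink angle is below 1°: the fit's angular noise
floor on noiseless fixtures is ≈ 0.2°, so "no bend direction" is the only
honest answer there.

### Kink calling and classification

The first kink is the largest angle in the helix if strictly over the
threshold (default 20°, sensible within 15–25°). Further kinks are taken
in descending angle order and must be ≥ 20°, at least 4 residues from
*every* accepted kink, and separated from each by at least one residue
with angle ≤ 10°. Helices classify as kinked (max ≥ 20°), straight
(max ≤ 14°) or intermediate (between; excluded from both comparison
sets).

## Helix extraction

Per-residue H states come either from an internal Kabsch–Sander
implementation — amide H placed 1 Å from N opposite the preceding
carbonyl, electrostatic energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol, bond when E < −0.5, helix when two consecutive
(i, i+4) bonds exist — or from a standard DSSP output file. H runs
separated by one or two non-H residues are merged (transitively, left to
right, gap residues included); candidates with a local angle > 60° are
split recursively at the max-angle residue, which starts the C-terminal
fragment (no residues are lost, and trimming cleans the boundary);
ends are trimmed until the first/last five residues form a *helical
seed*; helices of ≤ 12 residues are dropped.

A seed requires (1) the first residue's (φ, ψ) inside a rectangular α
region (φ ∈ [−140°, −30°], ψ ∈ [−90°, 45°]); (2) the angles between
Cα(1)→Cα(2) and Cα(1)→Cα(1+x) inside 35–50° (x=2), 60–80° (x=3), 45–65°
(x=4); (3) |Cα(1)−Cα(1+x)| within 0.5 Å of the ideal parametrization's
values (5.43, 5.05, 6.20 Å). On the generated ideal helix these evaluate
to ≈ 44.8°, 73.8°, 54.4° and 5.40, 5.05, 6.20 Å — comfortably inside
every band. The C-terminal test applies the same three criteria to the
last five residues read N→C. Membrane trimming (when an annotation is
ingested) removes terminal residues until at most five consecutive ones
are outside the membrane, treats `unknown` as outside, and rejects
helices with no tail-region residue.

## Residue annotation

Backbone hydrogen bonds at offsets 3, 4, 5 use the Kabsch–Sander energy
above; Proline never donates. A residue's i+4→i bond is *broken* when the
pair is assessable (atoms present, donor not Proline) but no bond is
found. Sidechain→backbone bonds use a geometric rule: donor heavy atom
within 3.5 Å of a backbone O/N and an antecedent–donor–acceptor angle
≥ 90°. Solvent accessibility is Shrake–Rupley with 256 deterministic
golden-spiral sphere points per atom (probe 1.4 Å), divided by extended
Gly-X-Gly reference maxima and clipped to [0, 1]; "accessible" defaults
to > 7%. Sequence profiles weight each MSA row by 1 − (mean fractional
identity to the other rows), floored at 1e-3 and normalized — dissimilar
sequences weigh more; gap columns are excluded with renormalization.
Hydrophobicity is the profile-weighted mean of the experimentally derived
interface-to-octanol transfer free energies, shipped as a packaged
constant.

## Statistics

Positions around a kink are numbered −6 … +6 with the kink residue as 0;
offsets −4, −3, 0, +3, +4 lie on the inside of the bend, −5, −2, +2, +5
on the outside. The propensity of amino acid *a* at offset *i* is
log₂[(Nᵃᵢ/Nᵢ)/(Nᵃ/N)] with background totals from the helix set the kinks
came from; zero cells receive a 0.5 pseudocount (flagged) so the log
stays finite, and the raw ratio is emitted alongside the log — both
readings of the propensity equation are exposed. Counts are integer by
default and profile-weighted fractional with `use_profiles`. Motif
enrichment matches expressions (literals, `x`, `[...]` classes, plus the
positional "G_0 or G_+1" special case) against the 13 residues around
each kink, versus one uniformly random 13-mer per straight (max angle
≤ 14°) helix per resample, 50 resamples, reporting % of kink segments, %
of straight segments (mean ± sd) and their ratio. Length matching draws,
for every helix length, exactly the target's count from the pool without
replacement within a sample; angle distributions are compared with the
two-sample Kolmogorov–Smirnov test, pooled or stratified by length.
Wheel summaries average any per-residue scalar by offset (wheel angle =
100°·offset) with a 2 s.d. band.

## The synthetic generator

Backbones are built by sequential atom placement (NeRF) from standard
bond lengths and angles with ω trans. For a target rise/twist the solver
finds (φ, ψ, τ): rise and twist are not independently reachable with a
fully rigid backbone, so the N-Cα-C angle τ is allowed to flex with a
soft penalty toward its standard 111.2° — at the default rise 1.5 Å /
twist 100° it settles at 109.7°, within the range observed in real
helices, and the Cα radius emerges at ≈ 2.28 Å (the `ca_radius` field is
the nominal reference, not an independent dial). Construction φ/ψ are
stored on all residues, including chain termini, so seed tests are
defined from residue 0; recomputing dihedrals from (noisy) coordinates
overwrites them.

Kinks are inserted by rigidly rotating everything C-terminal of a chosen
Cα about an axis through that Cα perpendicular to the helix axis; the
azimuth picks the bend direction (0 = toward that residue's own Cα,
giving wobble ≈ 0 there; 180 = directly away). The true inter-segment
angle equals the requested angle exactly. Because the rotation is sharp
where real kinks have a transition region, windows adjacent to the kink
mix residues from both sides: recovered angles and positions carry a
±5° / ±1 residue contract rather than exactness, and this — not
measurement noise — dominates the residual failure rate (~3%) of the
recovery criterion. Gaussian coordinate noise (seeded) is applied after
kink insertion. Sequence corpora are i.i.d. draws from a supplied
composition (uniform by default); a planted motif occupies its
kink-relative offset in exactly a Bernoulli(fraction) subset and is
guaranteed absent at that offset otherwise, so the realized positional
frequency equals the nominal fraction.

What the generator does *not* emulate: physically relaxed kink
geometries, sidechains, crystallographic artifacts (altlocs, missing
atoms appear only in hand-written parser fixtures), real amino-acid
composition, and homolog divergence structure in MSAs. Passing tests
therefore demonstrate the correctness of the geometry, rules and
bookkeeping under known ground truth — not the biological conclusions
one would draw from a curated structure set, which additionally depend
on dataset assembly steps (culling services, membrane databases, homolog
searches) that are inputs to this package, not parts of it.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| window | 6 residues | cylinder-fit window |
| kink threshold | 20° | kinked if max angle ≥; first call needs > |
| straight threshold | 14° | straight if max angle ≤ |
| split threshold | 60° | helix split during extraction |
| valley | 10° | required dip between accepted kinks |
| min separation | 4 residues | between accepted kinks |
| min helix length | 13 | after all trimming |
| max outside | 5 residues | membrane trimming rule |
| seed distance tol | 0.5 Å | Cα distance band for helical seeds |
| SASA accessible | 7% | relative-accessibility threshold |
| resamples | 50 | straight-background and length-matched sampling |
| H-bond cutoff | −0.5 kcal/mol | Kabsch–Sander bond threshold |

Validation problem sizes (chosen to exercise the statistics at
comfortable resolution): 500 + 500 straight helices (lengths 13–45),
500 kinked helices (100 per angle in {20, 25, 30, 40, 60}°, lengths
26–40, noise σ = 0.15 Å), 200 fixtures per wobble-alignment direction,
100 oracle windows, 10⁴ planted / 10⁵ null propensity windows, 10⁴ + 2×10⁴
enrichment segments.

## Known limitations

- Absolute hydrogen-bond and SASA counts come from this package's own
  Kabsch–Sander and Shrake–Rupley implementations and will not exactly
  reproduce annotations from other structure-annotation programs.
- The sequence-weighting scheme realizes the qualitative property
  "dissimilar sequences weigh more" rather than any specific published
  weighting formula.
- The kink angle saturates near the splitting threshold: helices with
  true angles > 60° are split during extraction, so such bends surface
  as two helices, not one call.
- NMR ensembles contribute only their first conformer; no
  biological-assembly expansion or structure repair is attempted.
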