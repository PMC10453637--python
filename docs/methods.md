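# Methods

## Scope and model

`metastab` analyses a conformational ensemble of a single protein — an
ordered atom topology shared by `n_frames` coordinate sets in Å — around one
or more focal residue positions. Positions are 1-based author numbers from
the PDB; residues are identified by (chain, position), and hetero groups
(cofactors, waters) never count as neighborhood members. Producing the
ensemble (force fields, sampling) is outside the package's scope; it only
consumes multi-model PDB files.

The statistical model behind the state analysis is a finite mixture: frames
are exchangeable draws from K metastable conformations with fixed
occupancies, observed through the focal-to-neighbor minimum heavy-atom
distance features plus noise. The pipeline estimates K, the occupancies,
a representative frame per state, and a per-state local energy.

## Featurization

For focal residue *i* with neighborhood N(i), frame *f* yields
`d[f, j] = min over heavy-atom pairs (a in i, b in j) of ||a − b||`,
j ∈ N(i) \ {i}, neighbors ascending. By default N(i) is computed from one
stated reference frame (frame 0) with a 5 Å heavy-atom contact cutoff;
because a single frame of a multi-state ensemble may not exhibit every
contact, an explicit neighbor list can be supplied and is used verbatim
(curated contact sets are the norm in practice, and the synthetic recovery
analyses use the generator's planted selection). Features are standardized
per trajectory, column-wise, with population (ddof = 0) statistics; the
statistics are retained so the transform inverts exactly. A zero-variance
column aborts with an error naming the frozen neighbor rather than silently
producing NaNs. Focal positions are analyzed as separate featurizations;
an all-pairs within-neighborhood mode exists behind a flag for sensitivity
analysis but is not the default.

## State discovery

PCA (scikit-learn, full SVD) projects the standardized matrix onto
`n_components = 2` leading components; component signs are fixed so each
component's largest-magnitude loading is positive, making results
deterministic. K-means (k-means++ initialization, 10 restarts, tolerance
1e-6, squared Euclidean distance) runs in the retained 2-D space — the same
space as the free-energy landscape — with all randomness flowing from one
user-visible seed.

"The inertia decrease becomes linear" is not algorithmic, so the elbow is
operationalized as the K ∈ [2, k_max − 1] maximizing the discrete second
difference (I(K−1) − I(K)) − (I(K) − I(K+1)), ties toward smaller K; the
full inertia curve is always reported so a user can override the choice.
The representative frame of a state is the member minimizing Euclidean
distance to the centroid in the projected space (ties to the lowest frame
index). The landscape is a 60 × 60 2-D histogram with
G = −ln(count/total), shifted so the fullest bin is 0 kT; empty bins are
masked, not zero.

## Local stability

From the most populated state, up to 200 frames are extracted by an evenly
strided deterministic subsample (a seeded random policy exists; stride is
the default because it is reproducible without a seed and thins
autocorrelation in time-ordered ensembles — frames are otherwise treated as
exchangeable). The local energy of a frame is the sum of per-residue scores
over the full neighborhood (focal included). Its mean carries a percentile
bootstrap CI (2.5/97.5 percentiles of 1000 resample means at the default
95% level), resampling the per-frame sums — not per-residue scores —
because the uncertainty of interest is over the sampled conformations.
Variant comparison reports the difference of means with a bootstrap CI from
independent resampling of each variant, plus whether the individual CIs
overlap. Score tables carry an opaque units label; summaries with different
units cannot be compared.

Per-residue scores come either from an imported TSV (header
`frame<TAB>pos1<TAB>pos2...`, e.g. exported Rosetta residue energies) or
from the built-in surrogate scorer. The surrogate captures the two
qualitative drivers of local stability the analysis cares about — packing
and backbone hydrogen bonding — with deliberately simple terms:
`score(r) = packing(r) + hbond(r)`, where packing sums over heavy-atom
pairs (a ∈ r, b ∉ r, d ≤ 6 Å) the 12-6 term ε[(σ/d)¹² − 2(σ/d)⁶] with
ε = 0.05, σ = R(a) + R(b) (R: C 1.70, N 1.55, O 1.52, S 1.80 Å), each pair
term capped at +10 so a single clash saturates rather than diverges; and
hbond adds −0.5 to both partners of every backbone N···O=C pair within
3.5 Å at sequence separation ≥ 2. Lower is more favorable. The surrogate's
absolute values on the schematic toy chains are large (the idealized
extended geometry is not energy-minimized and adjacent backbone atoms sit
inside their contact radii); only contrasts between variants are
meaningful, and no claim about absolute thermostability follows from them.

## Conservation

Hits are filtered with query coverage strictly greater than 70% (reading
"over" literally) and identity inclusively within [40, 97]; both bounds are
parameters, not constants. A 12-column BLAST-style tabular file needs the
query length to derive coverage (per-subject union of HSP query intervals
by default; per-HSP available and flagged); a 13th column is taken as
coverage directly. Alignment columns map to 1-based ungapped query
positions; at each position, frequencies of the 20 canonical amino acids
are computed over the non-query sequences, normalized by the non-gap
canonical count, with gap and non-canonical fractions reported separately
over all non-query sequences. The query is excluded from the counts by
default so the profile describes the homologs, not the template.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure each stage assumes,
with planted truth for recovery tests:

- **Trajectories.** A toy extended chain (N, CA, C, O, CB per residue,
  3.8 Å CA spacing) whose frames draw a state by occupancy; the residues
  flanking the focal position are rigidly offset by the state's
  displacement vector, and isotropic Gaussian noise (σ = 0.3 Å default) is
  added to all coordinates. Default study conditions: 2000 frames, three
  states at occupancies 0.6/0.3/0.1, displacements 10σ apart. The default
  displacement geometry is deliberately non-collinear — (0,0,0), (0,10σ,0),
  (20σ/3, −40σ/3, 0) — because three states placed equally spaced on a line
  with unequal weights are a degenerate case for *any* inertia-curve elbow
  (merging the two minor states is nearly free, so the curvature peaks at
  K = 2); a triangle arrangement makes the three states genuinely distinct
  in the distance features. A warning fires if any state pair is closer
  than 3σ. What this does not emulate: force-field physics, barrier
  crossing kinetics, autocorrelated frames, or solvent.
- **Score tables.** Per-frame neighborhood sums drawn Normal(μ, σ²) with
  the planted per-variant μ (defaults mirror a realistic favorable/
  unfavorable contrast of 0.32 vs 1.35 with σ = 0.1), spread across
  residues with zero-sum jitter so sums keep the planted distribution
  exactly.
- **MSAs.** Columns drawn i.i.d. from planted profiles (residues + gap),
  uniform over the 20 canonical amino acids elsewhere; the query is
  included ungapped. No phylogenetic correlation between sequences.
- **Hit tables.** 13-column tabular rows with coverage/identity drawn from
  stated distributions and the exact filter pass fraction recorded.

Passing recovery tests on these inputs shows the pipeline's estimators are
correct under the assumed model; it does not validate the model against
real MD ensembles or real homolog sets.

## Numerical choices and degenerate inputs

- PDB parsing keeps altloc ' '/'A' only; insertion codes are rejected with
  an explicit error (simulation ensembles carry neither). Blank element
  columns fall back to the first alphabetic character of the atom name.
  Inconsistent atom order between models is an error naming the model.
- Coordinates serialize at the PDB fixed-format 3-decimal precision, so
  write/read round-trips agree to 0.001 Å and are a fixed point after one
  write.
- Bootstrap CIs are clamped to contain the sample mean (the percentile
  interval can exclude it only by resampling noise at tiny n).
- Problem sizes in the recovery analyses (2000-frame trajectories, 20
  seeds, 1000 bootstrap replicates, 998-sequence MSAs, 5000-row hit
  tables) were chosen to make the binomial/CLT error bands comfortably
  tighter than the assertions while keeping a full run to seconds.
- The elbow scan requires k_max ≥ 3 and more frames than k_max; K-means
  requires k ≤ n_frames; empty clusters cannot occur with k-means++.

## Known limitations

- The 5 Å contact neighborhood from a single reference frame can differ
  from a neighborhood defined on another frame of a multi-state ensemble;
  explicit lists are the robust path and the default in the analyses.
- The surrogate scorer is not an all-atom energy function; imported score
  tables should be used for any quantitative claim about real proteins.
- Frames are treated as independent in the bootstrap; heavily
  autocorrelated trajectories should be thinned (the stride policy helps
  but does not estimate correlation time).
- Conservation frequencies are unweighted; redundant homolog sets bias the
  profile toward over-represented clades.
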