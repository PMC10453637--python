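# metastab

Metastable-state discovery and local-stability scoring for protein
conformational ensembles, with homolog residue-conservation profiling.

When a point mutation changes a protein's thermostability, one structural
explanation is that it reshapes the conformational ensemble around the
mutated position: the local packing and hydrogen bonding sampled by the
dominant conformational states become more (or less) favorable. `metastab`
implements that analysis for anyone with an ensemble of conformations of one
protein (e.g. snapshots from a molecular-dynamics run, stored as a
multi-model PDB):

1. **Featurization.** Around a focal residue *i*, the contact neighborhood
   N(i) is every protein residue with a heavy atom within 5 Å of residue
   *i* (or an explicit curated list). Each frame *f* becomes a vector of
   minimum heavy-atom distances
   d_fj = min {‖a − b‖ : a ∈ atoms(i), b ∈ atoms(j)}, j ∈ N(i),
   standardized column-wise to zero mean and unit variance.
2. **State discovery.** PCA reduces the standardized distances to two
   components; K-means (k-means++ seeding, 10 restarts) discretizes the
   projected frames into metastable states. K is chosen by the elbow
   heuristic over K = 1..9: the K maximizing the second difference of the
   within-cluster sum of squares, i.e. where the decrease turns linear.
   Each state reports its occupancy and a representative frame (the member
   closest to its centroid); the 2-D density gives a relative free-energy
   landscape G = −ln(p/p_max) in units of kT.
3. **Local stability.** 200 frames are extracted from the most populated
   state and the local energy E_f = Σ_{j ∈ N(i)} e_fj is summed over
   per-residue energy scores e_fj — imported from an external scorer's
   table (e.g. Rosetta residue energies) or from the built-in surrogate
   (12-6 heavy-atom packing plus backbone hydrogen-bond terms). The mean of
   E_f carries a percentile-bootstrap 95% confidence interval (1000
   resamples), and two variants are compared by the bootstrap CI of their
   mean difference.
4. **Conservation.** Homology-search hits are filtered on query coverage
   (> 70%) and identity (40–97% inclusive); an alignment of the survivors
   is profiled per ungapped query position as frequencies of the 20
   canonical amino acids (gaps and non-canonical letters tracked
   separately).

A small `library_stats` module handles selection-experiment bookkeeping
(plated-library capability: CFU / plated µL × 1000 µL/mL × culture mL).

Every input the pipeline consumes can be generated synthetically with
planted ground truth (`metastab.synthetic_data`), so the whole analysis is
testable end to end without any external data.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(each accepts `--seed`):

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_discover_states.py --seed 1
```

`02_discover_states.py` featurizes a 600-frame ensemble planted with three
metastable states at occupancies 0.6/0.3/0.1 and prints:

```
explained variance fractions: [0.507, 0.493]
inertia curve: [1200.0, 674.6, 222.3, 158.2, 132.6, 114.1, 99.8, 89.2, 79.3]
elbow-selected K = 3
recovered occupancies: [0.608, 0.293, 0.098]
planted occupancies:   [0.6, 0.3, 0.1]
max |occupancy error|: 0.0083
```

The elbow lands on the planted K = 3 (the inertia drop turns linear after
three clusters) and the recovered occupancies match the planted fractions
to better than 0.01. `analysis/03_stability_contrast.py` then scores both
variant ensembles and recovers a planted local-energy contrast
(neighborhood-sum means 0.32 vs 1.35):

```
gv: mean 0.313 [0.299, 0.326]
wt: mean 1.350 [1.336, 1.364]
difference: 1.038 (planted 1.03), CIs overlap: False
```

i.e. the favorable variant scores ≈ 1.03 units lower with non-overlapping
95% CIs. `analysis/04_conservation_profile.py` recovers a planted
conservation profile (pooled A+G frequency 0.966 against a planted 0.97),
and `analysis/05_library_capability.py` prints the plating arithmetic
(50 CFU / 2 µL × 1000 µL/mL × 20 mL = 5×10⁵, order of magnitude 10⁶).

The same stages are available as a command-line tool:

```bash
metastab simulate trajectory --n-frames 600 --seed 1 --out traj.pdb
metastab analyze --input sim=traj.pdb --focal 6 --seed 1 --out results/
metastab conserve --msa msa.fasta --positions 6 --residue-set AG
metastab library-stats --cfu 50 --plated-ul 2 --culture-ml 20
```

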