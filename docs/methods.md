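# Methods

This note documents the models and numerical choices behind the
package, in the spirit of a methods section: what is computed, under
which assumptions, and where the genuinely open design decisions were
made.

## Coarse-site model

All analyses operate on one site per protein residue (the Cα atom) and
one per nucleotide (the backbone phosphorus). For the DNA polymerase β /
gapped-DNA complex this gives 354 sites: 326 Cα (residues 10–335) and
28 P. Domains follow the enzyme's architecture — lyase 10–87,
DNA-binding (D) 90–150, catalytic (C) 151–260, nascent-pair-binding (N)
261–335; residues 88–89 fall in no named domain and are treated as
linker. Internal indexing is 0-based and stable across every matrix the
package produces; user-facing labels are the 1-based residue numbers of
the source structure (bare labels refer to the protein chain; DNA sites
are addressed with an explicit chain). Coordinates are ångström
throughout; trajectory formats that store nm are converted on read.

## Structural descriptors

RMSD uses Kabsch least-squares superposition (SVD with reflection
correction, so the rotation determinant is +1); the fit selection equals
the measure selection unless configured otherwise. RMSF superposes every
frame onto the ensemble mean with two mean-refinement passes before
measuring per-site fluctuations, so rigid tumbling contributes nothing.
Radius of gyration is mass-weighted with equal masses by default — a
pure geometric Rg, matching the information content of a coarse model.

Hydrogen bonds use the geometric criterion: donor–acceptor distance
≤ 3.5 Å **and** hydrogen–donor–acceptor angular deviation ≤ 30°. Both
thresholds are configurable; the angle convention (deviation, not the
raw D–H–A angle) is the one used by the standard trajectory tools.
Salt bridges are scored by the distance between the charged-group proxy
sites; a pair is reported when it sits below 4.0 Å in at least half the
frames, and the full distance series is always retained because
physically meaningful bridge distances straddle any single cutoff.
Moving averages use a centered window that shrinks at the edges, so the
output length equals the input length (default bin 500 for distance
traces).

## Essential dynamics

The covariance estimator is maximum-likelihood (divisor n). When
alignment is requested, frames are superposed onto the iteratively
refined mean (two passes) — standard essential-dynamics practice; for
ensembles sampled directly in the fluctuation space (no rigid-body
component by construction) the pipeline skips alignment. PCA is the
eigendecomposition of the 3N×3N covariance, not mass-weighted
(equal-mass coarse sites). Cosine content is evaluated by discrete
quadrature of c_k = (2/T)(∫cos(kπt/T)p dt)²/∫p² dt; it is reported,
never used to filter silently.

Free-energy surfaces are F = −kT ln(count/max count) on a 2-D histogram
(default 50×50; an explicit bin range is accepted, which matters when two
surfaces or two peaks must share bin alignment). Empty bins are masked
and written as `NA` sentinels. Basin detection seeds basins at strict
8-connected local minima below a depth threshold and assigns the
remaining bins by steepest descent; basins are labelled in order of
increasing minimum free energy, ties broken by x-then-y bin index. A
flat surface yields one basin flagged degenerate. Because a histogram of
a finite sample has spurious shallow minima, the pipeline counts only
basins within 1 kT of the global minimum by default (configurable).

## Elastic network and PRS

The anisotropic network model connects sites within 12 Å with springs of
uniform constant γ = 1; the off-diagonal Hessian block of a contact is
−(γ/d²) d⊗d and diagonal blocks close the row sums to zero, so
translation invariance is exact. Zero modes are eigenvalues below
1e-8 × the largest; a connected, properly braced structure has exactly
six. The builder rejects both disconnected contact graphs (listing
components) and connected-but-floppy ones (mechanism regions), which at
coarse resolution arise from nearly collinear or coplanar spring
arrangements.

PRS applies the three Cartesian unit forces at each site through the
mode-restricted pseudo-inverse H⁺ (default: the 20 slowest nonzero
modes): S_ij is the squared Frobenius norm of the (j,i) 3×3 block of H⁺,
which equals the summed squared response of site j to the unit forces at
site i and is proportional to the expectation over uniformly random
force directions — hence deterministic by construction. Rows are
normalized by the self-response S_ii by default so profiles compare
across systems. Effector and sensor profiles are the row and column
means. The ANM is built from the ensemble-average structure by default
(any single frame can be selected instead), keeping the model
well-defined while using the trajectory.

## LMI networks and betweenness

Linear mutual information uses the 3×3 marginal and 6×6 joint
fluctuation covariance blocks, I = ½[ln det C_ii + ln det C_jj −
ln det C_(ij)], mapped to the generalized correlation
r = (1 − e^(−2I/3))^½. Unlike the Pearson-based DCCM, r captures
orthogonal-but-coupled motions; in the isotropic single-ρ construction
r = |ρ| exactly, which the tests exploit as a closed form.

Network edges are restricted to contact pairs and weighted −ln r, so
stronger coupling means shorter paths. For trajectory input the default
edge rule is contacts within 10 Å of the mean structure persisting in
≥ 75 % of frames; the synthetic pipeline instead uses each system's
elastic-network contact set (with the perturbation edit applied), so the
graph topology reflects the couplings that actually generate the
dynamics. A fully dense network is available for sensitivity analysis.
Betweenness centrality uses weighted shortest paths with fractional
counting of degenerate paths (Brandes) and the (n−1)(n−2)/2
normalization; the ΔBC comparison (perturbed − reference) flags sites
with |ΔBC| > 0.1.

## The synthetic-data generator

The generator replaces the undeposited microsecond trajectories with
ensembles whose statistical structure is known exactly, so every
analysis stage can be tested for parameter recovery:

* **Reference architecture.** A self-avoiding pseudo-chain (3.8 Å Cα
  bonds, 2 Å self-avoidance, bounded retries with backtracking) confined
  to four domain blobs and threaded through pinned anchors. The
  catalytic domain is central with D and N on opposite sides; the lyase
  blob hangs clear of the others (surface gaps beyond the 12 Å cutoff)
  so its only mechanical attachments are the chain linker near residues
  85–90 and a single bridge contact 44–335 placed 11 Å apart — the
  synthetic analogue of the S44–E335 hydrogen bond that locks the closed
  state. Bridge-flanking residues are pinned so no other lyase/N pair
  falls inside the cutoff, and the bridge bond points along the lyase
  pendulum's swing direction, making it the one spring that braces that
  motion. DNA is a 28-site double pseudo-helix (6.5 Å P–P spacing,
  60° twist, 154° strand phase) adjacent to the D/C interface; the
  tight twist keeps the strand network elastically rigid at P-only
  resolution. Grown geometries are validated to have exactly six zero
  modes with and without the bridge, and regrown (bounded) otherwise.
* **Ensembles.** ANM-Gaussian ensembles are sampled exactly in the
  nonzero-mode basis (covariance kT·H⁺, no rigid-body component);
  two-state ensembles are i.i.d. mixtures of two references with
  isotropic jitter and recorded basin labels — i.i.d. rather than
  Markov-switching because every analysis here is time-order-free except
  moving averages, which are exercised on deterministic traces. The
  open-state reference is a rigid rotation of the lyase domain toward
  the catalytic-domain centroid about a hinge at the lyase/D junction.
* **Perturbation.** The phosphorylation mimic edits the contact set:
  remove 44–335, add 44–149 (the new salt bridge to R149 at the D/C
  junction). Applied to the elastic network this reproduces, by
  construction, the study's qualitative findings: increased lyase-domain
  RMSF, a cross-correlation difference concentrated in the couplings the
  edit touches (the lyase×N block), and betweenness flags on the
  rerouted path (the bridge endpoints lose traffic; the D/C junction
  gains it).
* **Scripted H-bond traces** place exactly round(occupancy·n_frames)
  frames in a bonded geometry, order permuted by seed, with the bonded
  and unbonded geometries validated against the criterion at
  construction.

What the generator does **not** emulate: real force-field energetics,
anharmonicity, solvent and ion effects, time correlation, and the actual
2FMS coordinates. Passing tests therefore demonstrate that the analysis
machinery recovers planted signals under the stated statistical
assumptions — not that the biological conclusions transfer to any
particular real trajectory.

## Pipeline conventions

The comparison pipeline treats the generator's default architecture as
the fixed study system — the role a crystal structure plays — while the
run seed drives the stochastic ensembles (wild type uses `seed`,
perturbed `seed + 1`). Summaries follow the `mean (sd)` convention with
population (divisor n) standard deviation. Default problem sizes are
3000 frames per system for the pipeline and 50 000 frames / 100 sites
for the sampling-convergence measurements, chosen so sampling error sits
well inside the documented tolerances. Every run writes labelled TSV
artifacts, a manifest recording all parameters, and a log of every
cutoff used; reruns with the same configuration are byte-identical.

## Known limitations

* The elastic-network linear response is harmonic; PRS and ΔBC results
  describe the near-native regime only.
* LMI assumes Gaussian fluctuations; on strongly multimodal ensembles
  the generalized correlation underestimates dependence.
* Basin detection operates on raw histograms (no kernel smoothing);
  counts depend on binning, which is why depth thresholds and bin
  ranges are explicit parameters.
* The coarse H-bond/salt-bridge machinery scores site geometry; it does
  not perceive chemistry (donor/acceptor typing is the caller's
  responsibility).
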