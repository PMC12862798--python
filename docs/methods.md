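# Methods

## Contact definition

A residue pair (i, j) is a contact if the shortest distance between their
heavy atoms (element ≠ H, inferred from PDB-style atom names) is below
`heavy_atom_cutoff` (default 0.45 nm) in at least `population_threshold`
(default 10%) of frames, pooled over all trajectories of the ensemble.
Sequence neighbors with |i−j| ≤ `neighbor_exclusion` (default 2) are
excluded within a chain; pairs spanning the protein and a ligand chain are
never sequence-excluded, and the same |i−j| rule applies inside the ligand
chain. Ligand residues are numbered downward from 0 so protein (≥ 1) and
ligand (≤ 0) indices never collide.

The 10% population criterion is not a sensitive tuning knob — it removes
rarely formed pairs that would only add noise downstream — but its pooling
convention matters for ensembles with heterogeneous run lengths: we pool
over all frames of all runs ("total simulation time" semantics). A
per-trajectory evaluation is not offered; pooling plus the deterministic
lexicographic pair ordering makes contact tables reproducible run-to-run.

The cheaper variant monitors the single Cα–Cα distance against
`c_alpha_cutoff` (default 0.8 nm). Since the Cα pair is one of the heavy
atom pairs, the heavy-atom minimum never exceeds the Cα distance, which the
test suite exploits as an invariant. Distances can be reported as r (nm)
or 1/r (1/nm); inverse distances emphasize short-range changes but leave
the rest of the pipeline unchanged.

Distances are computed on coordinates as given. Trajectories from periodic
simulations are expected to be whole-molecule/PBC-corrected; an
orthorhombic minimum-image option (`minimum_image=True`) exists for inputs
that are not.

## Correlation matrix and contact clusters

Contact-distance series are subsampled (every fifth frame by default —
the clustering is robust to sparse data), centered per trajectory (so
between-run offsets do not masquerade as correlation), and concatenated.
The default similarity is |Pearson r|: anticorrelated contacts are just as
dynamically coupled as correlated ones, so the magnitude is the right
connectivity measure; the signed matrix is retained for reporting. For
strongly nonlinear coupling a normalized-mutual-information estimator is
provided: ⌈√N⌉ equal-width bins per variable, MI from the joint histogram,
normalized by the arithmetic mean of the marginal entropies (diagonal 1 by
construction). Zero-variance features get zero off-diagonal similarity and
a logged warning rather than an error.

Clustering maximizes the constant Potts model (CPM) objective

    Σ_c [ W_c − γ · n_c (n_c − 1) / 2 ],

with W_c the summed intra-cluster similarity (each unordered pair once,
diagonal excluded). γ ∈ (0,1] sets the resolution: it is the similarity
level below which merging two features stops paying. Leiden optimization
(igraph/leidenalg) is stochastic, so we run 10 seeded restarts and keep the
best objective, breaking ties toward fewer clusters and then
lexicographically smallest membership; the CPM score is recomputed
in-package from the matrix, independently of the optimizer's internal
bookkeeping. Communities smaller than `min_cluster_size` (default 2) are
reported as noise. Default γ = 0.5, with `gamma_scan` reporting cluster
counts and mean intra-cluster correlation over a γ list as the standard
selection diagnostic. On planted block models (intra ≥ 0.7, inter ≤ 0.1,
blocks ≥ 5) recovery is exact over γ ∈ [0.3, 0.6]; on ≤ 12 features the
returned objective equals the exhaustive-search optimum.

## Ensemble averaging

The response of a feature is the pointwise mean over trajectories sharing
the perturbation origin t = 0, with the standard error of the mean (SEM)
and the live-trajectory count n(t) recorded per time point. Campaigns
commonly mix short and long runs (e.g. 90 × 1 μs plus 22 × 10 μs); past
the short-run horizon the statistics simply use the surviving runs, and the
recorded n(t) drop lets the fit down-weight the noisier tail.

## Preprocessing for the log-time fit

Four steps, in this order, condition a uniformly sampled response:

1. linear interpolation refining the grid by `interp_factor` = 4
   (n frames → (n−1)·4 + 1);
2. resampling onto a log-spaced time axis at about `frames_per_decade` =
   750 frames per decade, so every decade carries equal weight in the fit;
3. Gaussian low-pass filtering with σ = `filter_sigma` = 6 (log-spaced)
   frames, suppressing fluctuations faster than the sampling of interest;
4. extension of the data by `extend_decades` = 1 order of magnitude with a
   constant equal to the mean over the last half decade of the filtered
   data, stabilizing the fit at the upper boundary.

SEM and n(t) are carried through steps 1–2 by the same interpolation and
held at their final values across the extension; the filter is not applied
to the SEM. Constants are exact fixed points of the whole chain, and the
filter equals direct-summation convolution with a normalized truncated
Gaussian kernel (radius 4σ, edge replication) — both are asserted in the
tests.

## Maximum-entropy multiexponential fit

The model is r(t) = Σ_k a_k exp(−t/τ_k) + c on a fixed τ grid covering the
data window at `per_decade` = 10 points per decade, with the lower bound
defaulting to twice the frame interval (faster components are not
identifiable from the sampling). Signed amplitudes are represented by two
non-negative channels, a_k = a_k⁺ − a_k⁻ — distances both rise and fall, so
a positivity-only spectrum cannot represent the data — each regularized by
the Skilling entropy relative to a flat prior m:

    objective(a, c) = χ(a, c) − λ · S̄(a),
    χ = sqrt( Σ_i w_i (model_i − data_i)² / Σ_i w_i ),
    S̄ = (1/2K) Σ_{k,±} [ a_k± − m − a_k± ln(a_k± / m) ].

Weights are w_i = 1/sem_i² by default (zero SEMs replaced by the smallest
positive one; all-zero SEM falls back to uniform), with a `uniform` mode
for data without error bands. Long-time points, averaged over fewer
trajectories, therefore count less. χ is the RMS (not squared) deviation;
together with the per-channel entropy normalization 1/2K this makes λ
dimensionless with respect to grid size and, in uniform mode, makes the
fit exactly scale-covariant: scaling data and prior by c scales the
amplitudes by c.

The constant offset c is fitted freely outside the entropy, initialized at
the long-time plateau; the model has no such term a priori, but the
boundary extension implies one.

**Optimization.** L-BFGS-B with analytic gradients from two deterministic
starts, keeping the lower objective: (i) the flat prior a± = m, and (ii) a
non-negative least-squares (NNLS) solution of the two-channel system with
both channels lifted by m. The NNLS start matters because neighboring
exponentials are nearly collinear: from the flat start the optimizer stalls
in a shallow valley of smoothly spread spectra, whereas NNLS, being
naturally sparse, anchors concentrated solutions when the data supports
them (a noiseless on-grid exponential is then recovered as an exact delta).
The lift by m places inactive channels at the entropy optimum, where the
gradient is informative. No randomness enters the fit; results are
bit-reproducible given the configuration. The objective decreases
monotonically over iterations (asserted on the recorded trace), and
non-convergence returns the best iterate flagged with a warning.

**Choosing λ.** λ trades residual against spectral smoothness; χ² is
non-decreasing in λ and the λ→0 limit reproduces direct least squares on
the same basis. The appropriate value depends on the objective's
normalization, so values quoted for other max-ent implementations do not
transfer. For this package's scaling, λ = 10 is the default: on the
synthetic forward model (components separated by ≥ 1 decade, SEM ≈ 5% of
amplitude) it recovers every planted component as a correctly signed peak
within half a decade while keeping χ² within ~1.6× the noise floor;
λ ≈ 50 already over-smooths (χ² up to ~5× the floor). `lambda_scan`
produces the (λ, χ², S, peak-count) table used to pick a per-system value —
isolated slow components benefit from stronger smoothing (λ ≈ 50).

**Resolution.** Like any regularized inverse Laplace transform, the
spectrum's intrinsic resolution is about half a decade: at moderate λ a
single exponential appears as a bump ~±0.3 decades wide, because the
entropy is convex in the amplitudes (spreading is always entropically
favorable) and χ barely distinguishes neighboring τ's. Peak positions are
accurate well below that width; all recovery tolerances in the tests are
therefore stated as "within half a decade".

## Dynamical content

D(τ_k) = Σ_j a_kj² sums the squared spectral amplitudes over features.
Restricting j to one cluster's features gives the per-cluster profiles
D_n(τ_k); features outside every cluster form a "noise" profile, and the
total is assembled as Σ_n D_n + D_noise so the decomposition identity holds
exactly (not merely to rounding). Reported peaks are strict local maxima
of the total above 1% of its global maximum — small bumps below that floor
are plotting noise, not processes.

## Power-law tails

Slow conformational relaxation is often diffusive rather than exponential;
the μs tail of a response is then better summarized by r(t) ∝ t^α, with
α ≈ 0.3 indicating subdiffusive and α ≈ 0.5 free-diffusive behavior. The
fit is an ordinary least-squares line on (log t, log r) over a window
spanning at least one decade, either on the raw values (`raw`) or on
|r(t) − r(t_lo)| (`shift`, response relative to the window entry). Exact
power laws are recovered to machine precision; 1% multiplicative noise
leaves the mean estimate within 0.02 of the truth.

## Synthetic data

The generators are the forward models of the analyses, so every stage has
exact ground truth:

- **Clustered series**: x = √ρ_out·g + √(ρ_in−ρ_out)·z_c + √(1−ρ_in)·ε
  with standardized latent components gives expected Pearson correlation
  exactly ρ_in within and ρ_out between clusters.
- **Response ensembles**: deterministic multiexponential mean plus iid
  Gaussian noise per frame (optionally AR(1) for correlated noise); a
  configurable fraction of trajectories extends to t_max, the rest to
  t_max/10, mirroring mixed-length MD campaigns. Defaults follow a
  realistic campaign (112 runs of which 22 long, 10 μs window, 20 ps
  write-out).
- **Toy structures**: residues on a 2 nm lattice with sub-0.1 nm atom
  jitter; designated pairs are placed 0.3 nm apart in a seeded random
  subset of frames, so the expected contact table (including populations)
  is known exactly. Cα atoms sit at the residue centers, so both contact
  modes are exercised.

What the generators do *not* emulate: force-field physics, anharmonic or
non-Markovian dynamics beyond AR(1) noise, genuinely power-law-distributed
relaxation (slow tails are planted as explicit long-τ exponentials), or
realistic protein geometry. Passing tests therefore demonstrate
correctness of the analysis chain on its own model class, not accuracy on
any particular protein.

## Pipeline

`run_pipeline` executes contacts → cluster → fit → content from a TOML
config, persisting every intermediate (contact table, distance tables,
correlation matrix, partition, spectra, content profile) and writing a
manifest with SHA-256 checksums of all outputs. With `--resume`, stages
whose recorded outputs still exist with matching checksums (and an
unchanged config) are skipped; a corrupted intermediate fails the checksum
and the stage re-runs. All randomness is seeded from the config, so two
runs with equal config and inputs are byte-identical apart from manifest
timestamps. CLI exit codes distinguish config validation (2), stage
failure (3) and I/O errors (4).

## Problem sizes in tests and the acceptance script

Chosen so ground truth is unambiguous and the whole suite runs in well
under a minute per module on one CPU:

- contact oracle: 20 random structures, 10–60 residues × 1–4 atoms,
  6 frames;
- partition recovery: 100 runs of 2–5 blocks × 5–12 features, 5000 frames;
  exhaustive CPM cross-check at 10 features (Bell(10) ≈ 1.2·10⁵
  partitions);
- timescale recovery: 30 trajectories (¼ long), 10 μs window at 1 ns
  write-out, per-frame noise √30 × 5% so the ensemble SEM is ~5% of a unit
  amplitude;
- end-to-end: 12 features in 3 clusters, 24 trajectories (6 long), planted
  τ = 10/200/3000 ns, intra-cluster noise correlation 0.85 at σ = 0.6 nm.

## Known limitations

- The contact engine computes a full heavy-atom distance matrix per frame;
  fine for 10²-residue systems and the package's test scale, but a
  neighbor-list implementation would be needed for 10³+ residues over 10⁶
  frames.
- λ must be chosen per system (the scan utility helps); no automatic
  L-curve or Bayesian selection is provided.
- Spectral uncertainties are not quantified beyond the λ scan.
- NMI uses a fixed equal-width binning; heavily skewed marginals may
  deserve adaptive bins.
- The minimum-image option assumes orthorhombic boxes.
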