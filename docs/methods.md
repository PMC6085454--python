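# Methods

## Electron-balance composition of brutto-equations

The balance module treats a growth phase as the sum of three parallel
catabolic half-processes: lactate → acetate (4 e⁻/mol), CO + H₂O → CO₂
(2 e⁻/mol), and on the accepting side Fe³⁺ → Fe²⁺ (1 e⁻/Fe) or
2H⁺ → H₂ (2 e⁻/H₂). Three conventions matter:

* **Lactate catabolized is measured as acetate formed.** Roughly half of
  consumed lactate is assimilated as carbon source and carries no catabolic
  electrons, so the acetate increment — not the lactate decrement — enters
  the ledger. The module reports both the per-phase and the cumulative
  lactate→acetate conversion ratios without arbitrating between them.
* **Fe(II) counts as one electron per atom** regardless of the mineral
  product (magnetite vs siderite).
* **Coefficients are exact rationals** (`fractions.Fraction`) internally and
  only rounded for display; the canonical 30:1 and 270:1 phases are
  integer-exact and `check_balance` returns exactly-zero residuals over
  {C, H, O, Fe, charge}.

If a phase shows `F < 4L` with `L > 0` the ledger would require negative CO
consumption; this is a "donor electron excess" error. When it arises from
noisy time-series deltas, `partition_from_timeseries` falls back to treating
the lactate as assimilated only (L = 0) with a warning.

Phase boundaries: user-supplied breakpoints always take precedence.
`breakpoint_from_eh` (the redox-potential threshold crossing) is the
physiologically meaningful default, since the switch from iron reduction to
hydrogenogenesis is Eh-gated; `detect_breakpoint` (exhaustive two-segment
hinge regression on the Fe(II) curve, knot at a sample time, flagged when
the hinge improves the straight-line SSE by <5%) is a data-driven
convenience when no Eh trace exists.

## Mössbauer simulation and fitting

Thin-absorber approximation, unit-area Lorentzian lines, symmetric doublets
(two half-area lines at δ ± Δ/2). Default velocity grid ±4 mm/s with 512
channels, which covers silicate Fe²⁺/Fe³⁺ and siderite doublets; note a
Lorentzian with Γ ≈ 0.3 mm/s keeps ~2.4% of its area outside that window,
which cancels in relative areas. Counting noise is Poisson per channel and a
seed is mandatory.

Fitting is nonlinear least squares (lmfit/`leastsq`) with a free baseline.
The equal-linewidth constraint shares one Γ across all 2n lines (3n + 2 free
parameters); the unconstrained fit gives every line its own width (5n + 1),
so the constraint removes 2n − 1 parameters. 1σ uncertainties come from the
covariance at the optimum and are flagged unavailable when the covariance is
rank-deficient.

The doublet model is multimodal — overlapping doublets admit rival optima
that pair left/right lines the wrong way round. Initialisation therefore
proceeds in three cooperating stages, and the lowest-SSE solution wins
(ties break toward smaller total Γ):

1. **Free-line assignment:** 2n unconstrained Lorentzian lines are placed
   incrementally (each new line anchored at the channel giving the largest
   closed-form SSE reduction, Γ frozen during placement, freed at the end),
   then paired into doublets by enumerating perfect matchings ranked by the
   equal-area constraint; the best three pairings are refit as doublet
   models.
2. **Incremental doublet build-up:** doublets are added one at a time,
   anchored on a 21×21 (δ, Δ) grid over δ ∈ [0, 1.4], Δ ∈ [0.2, 3.0] mm/s
   scored against the current residual, with a full refit after each
   addition. A greedy 5×5 coarse-grid initialisation is run as a further
   independent start.
3. **Pairing polish:** from the best solution, every alternative re-pairing
   of lines between each pair of fitted doublets is refit; improvements are
   kept, iterated to a fixed point (≤4 rounds).

Phase assignment uses a priority-ordered window library of
literature-typical room-temperature values — siderite δ∈[1.10, 1.35],
Δ∈[1.60, 2.05]; Fe²⁺ octahedral silicate δ∈[1.00, 1.30], Δ∈[2.10, 3.00];
Fe³⁺ octahedral silicate δ∈[0.20, 0.50], Δ∈[0.30, 1.40] (all mm/s) — fully
overridable, since published analyses of this system name the phases without
printing windows. `fe2_share` sums the fractions of Fe²⁺-state windows.

The glauconite presets pin down only the quantities of interest — Fe²⁺ area
share 2.2% (initial), 5.7% (166 h) and a 3.9% siderite doublet among four
doublets (960 h). The individual δ/Δ/Γ values and the split of the remaining
Fe³⁺ area between its two doublets are this package's documented defaults
(δ = 0.35/0.37/1.12/1.22, Δ = 0.45/1.00/2.60/1.80, Γ = 0.32 mm/s), chosen as
literature-typical for glauconite and siderite at room temperature, and
overridable.

Out of scope: magnetic sextets, transmission-integral (thick absorber)
corrections, temperature-dependent recoil-free fractions (equal recoil-free
fractions are assumed throughout, making areas proportional to Fe-atom
fractions).

## Genome screens

* **IUPAC scanning** compiles the degenerate pattern to per-position
  character classes; overlapping windows are reported, minus-strand hits in
  plus-strand coordinates of the window start with the match given as read
  on the minus strand. A subject `N` satisfies only a pattern `N` — an
  ambiguous base never satisfies a constrained position. The CooA consensus
  `TGTCRNNNNNNYGACR` has random-match probability (1/4)⁷(1/2)³ ≈ 1/131,072
  per strand-position (≈1 hit per 131 kb per strand, i.e. a handful of
  chance hits per megabase that downstream upstream-window filtering must
  reject).
* **Operon inference** groups same-contig, same-strand runs with intergenic
  gaps ≤ `max_gap` (default 60 bp — deliberately below the 70–100 bp spacing
  that marks a gene as transcriptionally alone; configurable). A strand flip
  always splits. Output partitions the gene set.
* **Site-to-operon assignment** maps a hit to at most one operon when it
  lies within `upstream_window` (default 300 bp, a typical bacterial
  promoter region) upstream of the operon's 5′ gene on the operon's strand;
  strand-matching candidates win, ties break by distance then coordinate;
  hits inside coding spans stay unmapped.
* **Heme census**: strict policy counts non-overlapping left-to-right
  C-x(2)-C-H; extended additionally admits C-x(3)-C-H and C-x(4)-C-H
  (shortest variant preferred). `X` never matches. This is a motif count,
  not a Pfam-domain count: on real proteomes annotated by domain databases
  the multiheme census may differ by a few genes, so both policies are
  reported side by side rather than asserted.
* **Pairwise alignment** is global affine-gap (BLOSUM62, open −11, extend
  −1, free end gaps) via `Bio.Align.PairwiseAligner`; identity is matches
  over columns between the alignment core (end gaps excluded). Active-site
  conservation maps reference positions through that alignment and flags
  pairs under 30% identity as unreliable. Reciprocal-best-hit comparison
  prescreens candidates by edit distance (edlib) and confirms with the
  affine-gap alignment; default floors 40% identity / 70% coverage, a
  deliberately conservative orthology threshold.
* **ANI** follows the fragment-based definition: 1020-bp fragments,
  seed-and-extend placement (sampled 16-mer index, windowed edlib infix
  alignment, both strands), ≥30% identity keep-filter, mean of both
  directions. Because the infix alignment spans the whole fragment, the
  canonical ≥70%-of-length coverage condition is satisfied by construction.

## Synthetic data

`simulate_culture` integrates a forward-Euler trajectory (dt = 0.05 h,
sampled every 2 h). CO oxidation is first-order in cells with a Monod term
on CO; lactate catabolism is slaved to it through a phase-specific
CO:lactate coupling (30:1 in the iron-reducing phase, 270:1 in the
hydrogenogenic phase); the CO electron flux is split between Fe(III)
(limited by the accessible pool) and protons by the phase partition
(13/30 → 3/270 for ferrihydrite). Cell yield is proportional to catabolic
electron flux — the simplest growth law matching the qualitative two-phase
curves. Eh declines linearly from −90 mV toward a floor (−360 mV
ferrihydrite, −520 mV glauconite) as Fe(II) accumulates, and the partition
switches when Eh crosses the scenario threshold (−320 mV for ferrihydrite,
tuned so the switch falls near 24 h). The ferrihydrite preset is calibrated
so cumulative lactate consumption ≈ 2.3 mM with ≈ 1.1 mM acetate (77%
phase-1 conversion, ~25% phase-2); the glauconite preset produces no acetate
(lactate drawn only as carbon source, ~1 mM), reaches ≈ 1.42 mM Fe(II), and
its iron reduction stops when CO is exhausted. By construction the
noise-free signal satisfies 4·Δacetate + 2·ΔCO = ΔFe²⁺ + 2·ΔH₂ at every
step. Gaussian relative noise (seeded) is applied last. Published endpoint
values constrain these presets; full trajectory shapes are the model's own.

`generate_strain_pair` plants, in both strains: a coo cluster in the order
cooA | cooS-cooC | cooM-K-L-X-U-H-hypA-cooF-cooS-cooC (three transcription
units; within-operon gaps 5–20 bp, between-unit gaps ≥110 bp), with one
consensus instance sampled from the CooA pattern ~50 bp upstream of each of
the two downstream operons; 30 shared multiheme proteins (3–16 planted
CXXCH motifs, C/H-free linkers so strict and extended censuses agree); and
random background CDS reverse-translated at the target GC (49.14%). Strain B
additionally carries one exclusive 17-heme protein. Intergenic DNA inside
the coo neighborhood is rejection-sampled to be consensus-free; elsewhere
random consensus hits are deliberately left in, and the upstream-window
filter is what rejects them. Output is deterministic under the seed.

What the generator does **not** emulate: measurement error structure of real
culture assays (only i.i.d. relative Gaussian noise), codon-usage bias,
mobile elements, paralogy, or sequence divergence between the strains'
shared genes (they are planted identical at the protein level; nucleotide
divergence for ANI calibration is produced separately by `mutate_sequence`).
Passing tests therefore demonstrate correctness of the analysis machinery on
in-model data, not robustness to every artifact of real measurements.

## Problem sizes and numerical choices

Default analyses run at: 512-channel spectra with baseline 10⁶ counts and
≥20 noise seeds for recovery statistics; 120-kb synthetic genomes (~70 genes
per strain) for the end-to-end screens; 2-Mb genomes for ANI calibration;
1,000 random phase summaries for the balance property suite. ANI k-mer
seeding uses k = 16 with a 4-bp index stride and up to 3 candidate offsets
per fragment (±64 bp alignment pad). Fit tolerances are lmfit/`leastsq`
defaults; degenerate inputs (all-zero areas, <6 time points, <8·parameters
channels, genomes shorter than two fragments) raise typed errors rather
than returning garbage.

## Known limitations

* The CO partition recovered from a trajectory is exact only when the phase
  boundary coincides with a sample; mid-interval switches mix phases over
  one sampling interval (≈3% relative on the default ferrihydrite preset).
* Heavily overlapping doublets (ΔSSE between rival pairings comparable to
  noise) can still mislead the fitter; the multi-start machinery makes this
  rare at 10⁶-count baselines but cannot exclude it in principle.
* `reciprocal_unique` is O(|A|·|B|) edit-distance comparisons — fine for
  dozens-to-hundreds of proteins per proteome, not for metagenome-scale
  inputs.
* ANI assumes mostly-collinear genomes (fragment placement takes the best
  of a few seeded offsets); heavy rearrangement with high divergence would
  need a full local aligner.
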