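# Methods

## Translation velocity from footprints

Reads are unique single-end alignments against a CDS "transcriptome"
(or a plain `gene_id / five_prime_pos / length` table), in CDS-local,
0-based coordinates; the SAM/BAM reader converts the 1-based alignment
convention exactly once, at that boundary, and drops secondary,
supplementary, reverse-strand and low-MAPQ (< 10) records.

**Abundant lengths.** Footprint-length distributions are multi-modal;
lengths with at least 50 % of the modal length's count (configurable)
enter calibration, which in practice keeps 2–3 lengths.

**P-site calibration.** For each retained length L the offset is the
`o ∈ [8, 18]` maximizing the number of reads with
`five_prime_pos + o = 0` (the first nucleotide of the start codon),
aggregated over genes; ties break toward the smaller offset. Because
only offsets congruent to the true one modulo 3 score at all, the
decision is effectively between the start codon and its neighbours;
the initiation peak present in real coverage makes the start codon win.
A length whose peak is below 2× the mean over candidates is flagged
low-confidence (reported, never enforced); a length with no start-codon
hits is dropped with a warning.

**Occupancy and scaling.** Each read adds 1 to codon
`floor((five_prime_pos + offset)/3)` if that index lies within the
gene's sense codons; everything else is counted as discarded, so
`used + discarded = input reads` always holds. Scaled footprints divide
counts by the gene mean over the analyzed range — codons
`[exclude_first, L − exclude_last)`, defaults 5 and 5 to clip the
initiation/termination peaks; zeros are included in the mean, values
outside the range are missing, and a zero-total gene yields an
all-missing flagged profile. The exact normalization used by upstream
protocols varies; gene-mean scaling is the simplest form that preserves
the property the analysis needs (within-gene comparability, mean ≈ 1
baseline) and is documented as this package's convention.

**Coverage filter.** A gene is retained iff strictly more than 60 %
(configurable) of analyzed-range codons have at least one footprint —
strict, so an exactly-60 % gene is excluded.

**Periodicity QC.** Fractions of calibrated positions in codon frames
0/1/2 plus mean coverage at −30..+60 nt around the start and −60..+30
around the stop. Codon-resolution data should concentrate in frame 0;
status is "fail" below 0.5, as a report only.

## Structure features

Input models are single-chain PDB/mmCIF with per-residue confidence
(pLDDT, 0–100) in the B-factor column. Element radii: C 1.70, N 1.55,
O 1.52, S 1.80 Å.

**Secondary structure** is assigned from Kabsch–Sander backbone
H-bond energies: the amide H sits 1.0 Å from N along the preceding
residue's O→C direction (no donor at chain starts, chain breaks —
detected by a C(i−1)–N(i) distance over 2.5 Å or a residue-numbering
gap — or proline); `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
kcal/mol and a bond requires `E < −0.5`. Two consecutive i→i+n turns
(n = 4; 3₁₀ and π analogues collapsed in) mark residues i..i+n−1 as H;
parallel/antiparallel bridge patterns mark strands; H beats E; chains
under 5 residues are all coil. The three classes match the downstream
analysis (α-helix, β-sheet, coil); no turn/bend/PPII classes.

**ASA** is Shrake–Rupley: each atom's augmented sphere (vdW + probe,
probe 1.4 Å) is sampled at n deterministic golden-spiral points
(default 960); a point survives if outside every neighbour's augmented
sphere; residue ASA sums its atoms. rASA divides by the residue's
theoretical maximum (Tien et al. 2013 table), clipped to [0,1] —
terminal residues can exceed the maximum. The golden-spiral layout
makes results reproducible bit-for-bit at fixed n; per-residue values
vary by up to ~3 % under rigid rotation at n = 960 (occlusion
boundaries cross discrete points) while the summed area is stable to
0.5 %; raise `sphere_points` for tighter per-residue invariance.

**Disorder** defaults to a centered moving average (window 15,
truncated at termini) of `1 − pLDDT/100`, reflecting the strong
empirical association between low predicted confidence and intrinsic
disorder; a per-residue external predictor table can replace it
unchanged (range-checked to [0,1]).

**Local absolute contact order** for residue i is the mean `|i − j|`
over residues j with `|i − j| ≥ 2` and any heavy-atom pair within 6 Å;
missing (not zero) when no such j exists. "Absolute" means not
normalized by chain length. All three parameters are exposed. A
sliding-window/substructure variant is a conceivable alternative
reading of "local"; the per-residue contact definition is the committed
one.

Backbone-only models (the generator's fixtures) are legal inputs:
contacts and ASA then use N/CA/C/O only, which lowers absolute ASA and
contact counts but leaves every comparison within a run consistent.

## Integration

Codon usage frequency is the input-wide fraction of each sense codon
among all sense codons (stop codons excluded; RSCU is available as a
sensitivity alternative). Codon i (0-based) corresponds to residue
i+1 (1-based); the P-site codon is taken as the residue currently being
synthesized — a configurable `residue_lag` (default 0) can model
ribosome-tunnel exit delay instead. Region terciles split residues into
N/M/C thirds with remainders assigned to earlier segments
(boundaries ⌈L/3⌉, ⌈2L/3⌉). The joint table inner-joins scaled values
and features per gene, drops ramp-excluded rows, and keeps missing
contact order as NaN with pairwise deletion downstream.

## Statistics

Spearman is Pearson on mid-ranks; the partial correlation ranks all
three vectors and applies the first-order closed form
`(r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))`. The covariate is codon
usage frequency — the classical confounder of velocity–structure
associations — and the covariate's own row uses plain Spearman; genes
need ≥ 30 valid positions per feature (configurable), and skips are
ledgered. Cross-gene inference is a one-sample t on the per-gene ρ
(equal gene weights), two-sided, with Bonferroni over the features
tested in the run (configurable `n_tests`) and bands at
0.05 / 2.2e−5 / 2.2e−10 / 2.2e−15 on the corrected p.

The Wilcoxon rank-sum test enumerates all rank assignments exactly for
tie-free pooled samples of at most 12 values
(two-sided p = P(|W − E W| ≥ |w − E W|)); otherwise it uses the normal
approximation with tie and continuity corrections. Metagene profiles
average scaled values at offsets ±window (default 30 codons) around
each occurrence of the residue class (P, or K/R for positive charge)
whose full window has data; since profiles average to 1 within genes,
stalls appear as peaks above 1 at offset 0 without further
normalization.

## Synthetic data

The generator emulates the study conditions every test runs under.
CDSs are ATG + body codons drawn from a codon-usage bias (default: a
seeded log-normal weight profile, σ = 0.5) + one stop; secondary
structure strings come from a run-length Markov chain (mean runs
H 10, E 5, C 6). Velocity is planted as
`λ_i = exp(β₀ + β_coil 1[C] + β_pro 1[P] + β_pos 1[K/R] + β_f f(codon) + β_rasa rASA)`
with defaults β_coil = ln 2, β_pro = 0.4, β_pos = 0.5, β_f = −20 (raw
frequency scale, spanning ≈ e⁻¹ across the usage range), β_rasa = 0.5 —
magnitudes chosen once to make planted directions clearly detectable at
realistic depth without dominating the Poisson noise. Counts are
Poisson with mean `depth · λ/mean(λ)` (negative binomial optional for
robustness work); codon 0 is inflated 3× to emulate the initiation
peak that anchors start-codon calibration in real data. Reads are the
exact expansion of counts: length from the configured weights
(defaults 28 nt 60 %, 29 nt 40 %, matching multi-modal real
distributions), 5′ end `3i − offset(length)` — possibly negative by at
most the offset, exactly like a P-site-calibrated footprint overhanging
the start codon — so decoding with the true offsets is the identity on
counts, a property the tests exploit.

Ideal structures are built by NeRF chain extension from canonical
dihedrals (helix −57/−47, strand −119/113, coil sampled from a broad
extended region, seeded), standard bond lengths/angles, backbone
N/CA/C/O only; pLDDT is 90 in H/E runs and 40 in C runs. The
antiparallel-strand fixture places a second strand by a deterministic
least-squares rigid fit targeting 2.9 Å N···O distances between
registered pairs. For large statistical simulations the per-residue
rASA/IDR/contact-order features are drawn from seeded class-conditional
distributions (coil more exposed: Beta(4,2) vs Beta(2,4)/Beta(1.5,5);
laco log-normal, larger in strands) rather than 3D builds — orders of
magnitude faster and with exactly known feature values to plant on.

What the generator does **not** emulate: UTRs/introns, sequencing
error, library-preparation and nuclease biases, multi-mapping,
replicate structure, and any real covariance between codon usage and
structure beyond what the planted model induces. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
recovers planted relationships at realistic scales — not that any
particular biological association holds in real data.

## Problem sizes and numerical choices

Simulated validations use 20–50 genes of 100–300 codons at 30–50
expected reads per codon (statistical recovery at 50 × 300 × 50; 40
seeded repeats for the metagene peak-location rate; 500 repeats for
null p-value uniformity), sizes at which every planted sign is
recovered with large margins while the whole suite stays fast. Mean
tests use sample sd (ddof 1). Degenerate inputs raise structured
errors rather than NaNs: zero-variance correlation inputs, constant or
perfectly collinear covariates (|r| ≥ 1 − 1e−12 on ranks), sd = 0
across genes, empty Wilcoxon groups. Profile normalization holds to
1e−9; occupancy decoding and contact order are exact integer/rational
computations.

## Known limitations

* Single chain, single model per structure; no PAE, no β-turn classes.
* A-site analyses and replicate-aware pooling are not implemented
  (reads are pooled before occupancy).
* The disorder default is a pLDDT transform, not a dedicated predictor;
  supply external scores where fidelity matters.
* The scaled-footprint convention is gene-mean normalization as
  documented above; other normalizations (e.g. winsorized means) would
  change absolute profile values but not the rank-based statistics.
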