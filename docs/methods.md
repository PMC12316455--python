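# Methods

## Read model and classification

Input is single-end FASTQ (75 bp in the datasets this package targets),
plain or gzipped, Phred+33. Qualities are carried through but never used for
filtering, and no adapter trimming or deduplication is performed: the
counting stages must not silently alter read totals, so inputs are taken as
given and any preprocessing is the caller's responsibility.

A read is G-rich telomeric if it contains at least `min_repeats` (default 4)
exact consecutive copies of TTAGGG, C-rich if the same holds for CCCTAA.
Matching is literal — a single mismatch or an N breaks a run — because the
definition is a k-mer repeat count, not a fuzzy motif; tolerant matching of
variant repeats is the VTR scanner's job. No reverse-complement search is
performed: the sequencing chemistry guarantees the first sequenced base is
the first base of the blunted end, so the sequenced orientation *is* the
strand identity. Reads containing runs of both units are classed AMBIGUOUS
and excluded from strand-ratio denominators; at 75 bp such a read needs
≥ 48 nt of split signal and is overwhelmingly artifactual. RPM normalisation
divides by all reads in the library, not only telomeric ones.

The machinery is unit-generic (any complementary unit pair can be supplied,
e.g. a centromeric consensus for enrichment controls), but no consensus
catalogue is shipped.

## Terminal hexamer and information content

C-rich reads begin at the chromosome's 5′-terminal base, so the terminal
hexamer is the read's **first** six bases, displayed reversed ("-5′"
notation): prefix CTAACC ↔ canonical CCAATC-5′. An alternative reading —
reverse-complementing the read and taking the last six bases — yields the
same category set but must not be mixed with this convention; this package
uses prefix-then-reverse throughout. Categories are the six cyclic rotations
of the repeat plus OTHER (N, errors, terminal variant repeats). OTHER is
retained in reported distributions but excluded (with renormalisation) from
KL comparisons: phase randomisation by resection can only move mass among
the six rotations, while OTHER reflects orthogonal noise processes.

Per-position information content is `bits_i = 2 − H_i`, `H_i` the base-2
Shannon entropy of the observed A/C/G/T frequencies at terminal position `i`
(terminal-most first; N skipped per position). No small-sample correction is
applied — the intended libraries have 10³–10⁶ C-rich reads, where the
plug-in bias (≈ 3/(2·ln2·n) bits) is negligible. The emitted base-frequency
matrix is directly consumable by logo-rendering tools; no graphics are
produced.

## KL divergence and mixture estimation

Divergences are computed in bits over the six rotation categories with a
pseudocount `ε = 1e-9` added to each renormalised cell (then renormalised
again), making D finite when a reference cell is empty while perturbing
well-populated comparisons by < 1e-6 bits. Direction: `P` = observed sample,
`Q` = reference/in-silico control — the conventional sample-vs-model
direction, recorded in output metadata since KL is asymmetric. The log base
matters only for internal consistency with the dot thresholds; bits match
the logo units used alongside.

Dot banding: `< 0.125` ns, `[0.125, 0.25)` ●, `[0.25, 0.375)` ●●, `≥ 0.375`
●●●; boundary values go to the higher band.

The canonical-end fraction is estimated by matching the observed
distribution against mixtures `Q_p` with canonical cell `p + (1−p)/6` and
`(1−p)/6` elsewhere — randomised ends are uniform over the *six rotations*,
not over all 4⁶ hexamers, because resection of a pure repeat can only expose
rotational phases. The grid is `{0, 0.01, …, 1}` with ties to the smallest
`p`; the estimator is exact on noiseless mixtures at every grid point.
`CanonicalMixtureModel.fit(n_boot=...)` adds a multinomial bootstrap SE and
percentile CI for `p̂`. A deliberate modelling note: in S1-treated libraries
most C-rich reads start at internal cuts whose phase is uniform, so the
fitted `p̂` is diluted toward 0 — terminal-end estimation is meaningful on
END-seq (cut-free) libraries.

## ssDNA end counting

Each chromosome end contributes one C-readable end; each internal S1 cut
contributes one C-readable and one G-readable end, assuming equal capture
efficiency of both end types. Hence `f = (n+1)/(2n+1)` and
`n_raw = (1−f)/(2f−1)`. The reported `n_min = ⌈n_raw⌉` is a *minimum*:
losses can only hide G-ends and bias `f` (hence `n`) upward/downward
respectively, and the ceiling (rather than rounding) keeps the bound
conservative while reproducing the model's exact integer solutions. A guard
of 1e-9 is subtracted before the ceiling so float noise on an exactly
model-generated `f` cannot inflate the integer answer. `f ≤ 0.5` has no
finite solution (it violates the one-ended-terminus assumption) and raises
at the function level; the model-level `fit()` reports it as a diagnostic
(`n_min = None`) instead, alongside the Wilson 95% interval for `f`
propagated through the inversion. ALT thresholds default to `f ≤ 0.58`
positive and `f ≥ 0.98` negative (the observed ranges); both are
configurable. Estimating ssDNA tract *lengths* is out of scope — the read
counts carry no length information.

## VTR scanning

Variant telomeric repeats are counted at the repeat-unit level within the
first 30 nt of each telomeric read (5 tiled hexamers). Per read, the tiling
offset in {0..5} maximising exact canonical matches is chosen first (ties to
the smallest offset), so a rotated terminal phase does not flag every unit
of an otherwise canonical read; offsets that misalign the unit frame
essentially never match, making the selection sharp. Units containing N are
excluded from numerator and denominator; partial units at the window edge
are discarded for a determinate denominator. Reads shorter than the window
are skipped and counted. Published per-unit frequencies of ~1.9% (terminal)
and ~3.8% (internal) depend on an unstated denominator and phase convention,
so they serve as order-of-magnitude context, not as reproduction targets.

## Synthetic library generator

The simulator emulates the read-level footprint of both assays on a
parametric telomere: a pure C-strand repeat tract with unit-level variant
substitution, a terminal rotation phase, and internal cut positions. What it
reproduces: one C-strand read per natural terminus starting at the terminal
base; one C-strand plus one G-strand read per internal cut; terminal-phase
mixture law matching the estimator's model; per-unit VTR injection; uniform
per-base substitution error; uniform-random background reads; fragment size
selection (fragments under `min_fragment` yield no read). What it does not
model: subtelomeric sequence (all stages operate within 75 bp of an end),
C-circle rolling-circle structures, R-loops or G-quadruplex geometry (their
read-level footprint is abstracted as internal cuts), ligation/capture bias
(an optional `g_capture_efficiency` thins G-reads but defaults to 1), and
quality-score variation (constant Q40). Passing recovery tests therefore
demonstrates correctness of the analysis pipeline under the stated
generative model, not robustness to every artefact of real libraries.

Defaults are the study conditions: 75 bp reads; telomere lengths uniform on
5–15 kb; `p_canonical = 0.70` (the POT1-proficient estimate);
`vtr_rate = 0.02` (the ~1.9% terminal VTR frequency); `error_rate = 0.001`
(typical Illumina substitution rate); `background_fraction = 0.5`;
`min_fragment = 36`. Cut positions are uniform over the tract interior at
least `min_fragment` from both boundaries. `terminal_randomization='none'`
models the precisely processed terminus (always canonical);
`'uniform_rotation'` applies the mixture law — uniform over all six phases,
matching the behaviour of exonucleolytic randomisation.

Only sequence windows that can be read (terminus and ±read-length around
each cut) are materialised, at hexamer-unit granularity, so simulation cost
scales with read count, not telomere length. All randomness flows from one
seeded generator; an identical configuration gives byte-identical FASTQ
(gzip header mtime pinned to 0). The truth sidecar records every telomere's
length, terminal phase and cut positions plus emitted read counts, and
`describe_truth` converts it to closed-form expectations
(`f = Σ(1+cuts)/Σ(1+2·cuts)`, terminal-label mixture frequencies, the VTR
rate) used by the recovery tests.

## Problem sizes and numerical choices

Recovery tests use 3,000–50,000-telomere libraries: large enough that
binomial error on the recovered quantities sits well inside the asserted
tolerances (e.g. SE(f) ≈ 0.002 at 50,000 telomeric reads against a ±0.01
check), small enough to run in seconds. The acceptance script simulates
20,000 telomeres per condition. Ties in the mixture grid go to the smallest
`p`; the KL pseudocount, grid step and ceiling guard are fixed constants
documented above; degenerate inputs (empty library, zero telomeric reads,
all-N positions, `f ≤ 0.5`) raise typed errors at the function level and
become structured "insufficient data" statuses at the pipeline level.

## Known limitations

Real END-seq libraries contain adapter chimeras, duplicated fragments and
non-uniform coverage that the generator does not emulate. The end-counting
inversion assumes equal C/G end capture; any asymmetry rescales `f` and
hence `n_min`. The classifier's exact-match rule undercounts telomeric reads
in genomes with high variant-repeat density (a read whose every 4-unit
window contains a variant is called non-telomeric); at the ~2% per-unit
rates considered here the effect is negligible but it grows quickly with
the rate. Per-chromosome-arm resolution is impossible without subtelomere
anchoring, which short telomeric reads do not provide.
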