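# teloend

Telomere terminal-sequence and single-stranded-DNA analysis for END-seq and
S1-END-seq sequencing libraries.

## The problem

END-seq ligates biotinylated adaptors to blunted double-strand DNA ends and
sequences them so that the first sequenced base is the first base of the
blunted end. Natural chromosome termini therefore appear as *one-ended*
breaks: telomeric END-seq reads come (almost) exclusively from the C-rich
strand (CCCTAA repeats), starting exactly at the chromosome's 5′-terminal
nucleotide. Two questions follow directly from the read sequences:

1. **What does the chromosome 5′ terminus look like?** The first six bases of
   each C-rich read are the terminal hexamer. Because end-processing of a
   pure telomeric repeat can only leave one of the six rotational phases of
   CCCTAA, the terminus distribution lives on six categories (written
   reversed, "-5′" notation: CCAATC-5′ is the canonical ATC-terminating end);
   depletion of the shelterin protein POT1, or in-vitro 5′→3′ resection by
   T7 exonuclease, randomises the phase.
2. **How much internal single-stranded DNA do telomeres carry?** S1 nuclease
   converts every internal ssDNA region into a *two-ended* break, which adds
   one C-readable and one G-readable end each. The telomeric C-strand read
   fraction `f = c/(c+g)` then carries a count signal: cells using the
   recombination-based ALT telomere-maintenance pathway show `f ≈ 0.4–0.58`,
   telomerase-positive cells `f ≈ 0.98–0.99`.

`teloend` implements the full read-level analysis: strand classification by
consecutive-repeat scanning, terminal-hexamer distributions and per-position
information content, Kullback–Leibler comparison of distributions with
dot-category banding, mixture estimation of the canonical-end fraction,
inversion of `f` into a minimum ssDNA-region count with an ALT call, a
variant-telomeric-repeat (VTR) scanner, and a ground-truthed synthetic
library simulator so every stage is testable without downloading data.

## Models

**Classification.** A read is telomeric when it contains ≥ k exact
consecutive copies of TTAGGG (G-rich) or CCCTAA (C-rich), default k = 4,
anywhere in the sequenced orientation; reads with both runs are ambiguous
and excluded from strand ratios. Telomeric counts are reported as reads per
million of the whole library.

**Canonical-end mixture.** The observed terminal-hexamer distribution `P`
over the six rotational phases is compared against in-silico controls
`Q_p = p·δ(CCAATC) + (1−p)·Uniform(6)` by

    D(P‖Q_p) = Σ_i P_i log2(P_i / Q_p,i)   (bits),

and `p̂ = argmin_p D(P‖Q_p)` over a 0.01 grid. Divergences are banded:
`< 0.125` nonsignificant, `[0.125, 0.25)` ●, `[0.25, 0.375)` ●●, `≥ 0.375`
●●●.

**ssDNA end counting.** With `n` internal ssDNA regions (S1 cuts) per
chromosome end, each end contributes `n + 1` C-readable and `n` G-readable
ends, so `f = (n+1)/(2n+1)`. Inverting,

    n = (1 − f) / (2f − 1),

reported as the ceiling `n_min` — a minimum, since capture losses can only
hide G-ends. `f ≤ 0.58` calls ALT-positive, `f ≥ 0.98` ALT-negative.

## Worked example

```python
from teloend import (
    SimulationConfig, simulate_reads, tally_library, classify_stream,
    StrandClass, end_distribution, CanonicalMixtureModel, SsdnaBreakModel,
)

# END-seq library: one-ended chromosome termini, 70% canonical 5' ends
endseq = SimulationConfig(
    n_telomeres=20000, mode="endseq", p_canonical=0.7,
    terminal_randomization="uniform_rotation",
    error_rate=0.0, background_fraction=0.5, seed=7,
)
reads, _ = simulate_reads(endseq)
c_reads = [r for r, cls in classify_stream(reads) if cls == StrandClass.C_RICH]
print(CanonicalMixtureModel(end_distribution(c_reads)).fit(n_boot=50, seed=7).summary())

# S1-END-seq library from an ALT-like cell: Poisson(5) internal ssDNA cuts
s1 = SimulationConfig(
    n_telomeres=5000, mode="s1", cuts_law="poisson", cuts_per_telomere=5.0,
    p_canonical=0.7, terminal_randomization="uniform_rotation",
    error_rate=0.0, background_fraction=0.5, seed=7,
)
reads, _ = simulate_reads(s1)
print(SsdnaBreakModel.from_counts(tally_library(reads)).fit().summary())
```

prints

```
Canonical terminal-end mixture (KL grid fit)
==============================================
n reads (all categories)                 19987
canonical fraction p_hat                  0.70
KL at minimum (bits)                    0.0001
dot category at minimum                     ns
grid step                                 0.01
divergence direction             D(obs || mix)
bootstrap SE(p)                         0.0043
bootstrap 95% CI                  [0.69, 0.71]

Internal ssDNA end-counting model
==============================================
telomeric reads (C / G)          29415 /  24419
C-strand fraction f                     0.5464
SE(f)                                   0.0021
Wilson 95% CI for f           [0.5422, 0.5506]
model solution n_raw                     4.888
min ssDNA regions per end                    5
95% CI for n_min                        [5, 6]
ALT call                          ALT_positive
```

The mixture fit recovers the generating canonical fraction (0.70) from the
terminal hexamers of ~20,000 C-rich reads. The S1 library, generated with a
mean of five ssDNA cuts per telomere, yields `f = 0.546`; the model inverts
that to a minimum of 5 ssDNA regions per chromosome end and calls the
library ALT-positive. Note that in an S1 library most C-rich reads start at
internal cut sites, whose phase is uninformative — terminal-end mixture
estimation belongs on END-seq (cut-free) libraries.

The same analyses are available from the shell:

```bash
teloend simulate -o lib.fastq.gz --mode s1 --cuts 3 --error-rate 0 --seed 1
teloend classify -i lib.fastq.gz
teloend ssdna -i lib.fastq.gz
teloend report -i lib.fastq.gz -d results/
```

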