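# Methods

## Scope and data model

`ligandkit` operates on post-search peptide identification tables: one row
per peptide observation with sequence, retention time (seconds), FDR tier,
modification annotations, source-protein accession, run identifier and
allele label. Peptide identity for every set operation is the bare
amino-acid sequence; modifications are carried as annotations but never
split identities, because dataset comparisons in this field count unique
peptide sequences. Sequence matching is exact — no I/L equivalence — and
only the 20 canonical residues are accepted (rows with other letters are
rejected and reported, not silently dropped).

FDR status is a two-level tier (`q01`, `q05`) rather than a raw q-value:
upstream validation pipelines report identifications as 1%- or 5%-FDR
classes, and the relaxed additions are meant to stay visibly flagged.
Retention times are seconds internally; dialects may declare minutes,
converted on read, since the nested-culling window is specified in seconds.

## Filter cascade

Four filters run in a fixed order — FDR tier, length window (default
8–14), contaminant cull, nested cull — so that report attribution is
deterministic; the order does not change the final kept set. Contaminant-
and nested-culled records are flagged and retained rather than deleted,
and every analysis works on the non-culled view by default.

Nested culling removes a record iff a strictly longer record *in the same
run* contains its sequence as a contiguous substring and the absolute
retention-time difference is at most the window (default 30 s, two-sided).
Key choices:

- **Single pass against the original set.** If A ⊂ B ⊂ C all co-elute,
  both A and B are culled; survivors are not re-evaluated. A simple
  rejection rule cannot rescue a peptide, and the operation is therefore
  idempotent.
- **Same-run only.** In-source fragmentation is a within-injection
  artifact; peptides in other runs are never culling witnesses.
- **Missing retention times never cull.** Such records are counted as
  unevaluated instead.
- The recorded witness is the longest qualifying parent, ties broken
  lexicographically, making reports reproducible.

## Overlap statistics

Two-set comparisons use `100 · 2A2 / (A1 + 2A2 + A3)` on unique sequences
(a Dice-style coefficient). It is symmetric, bounded in [0, 100], equals
100 iff the sets are identical and 0 iff disjoint, and systematically
skews low when the compared sets differ greatly in size — the property
suite asserts this monotonically on a grid. Recovery
(`100 · |ref ∩ query| / |ref|`) is the asymmetric companion. Pairwise
replicate tables average the unweighted unordered-pair overlaps per length
bin (8…14 and pooled); a run empty in a bin excludes its pairs from that
bin's mean, reported explicitly. Percentages are carried at full precision
internally and rounded only in rendered reports.

## Relative-entropy logos

Peptides are analyzed per exact length with positions P1…PL; no gapped
alignment is performed (class-I peptides of different lengths bulge in the
groove rather than align). Position frequencies use
`(count + pc) / (n + 20·pc)` with pseudocount 0 by default for logos.
Letter heights are `p·log2(p/q)` with the `0·log 0 := 0` limit, the unique
per-letter decomposition whose positional sum is the relative entropy
`KL(p‖q)` in bits; the suite verifies the totals against an independent
brute-force KL oracle at 1e-9. Rendering ranks letters by |height|
(the alternative |p − q| ranking is computed alongside); drawing is a thin
SVG layer that no numeric computation or test depends on.

The default background is a bundled UniProtKB/Swiss-Prot proteome-wide
amino-acid composition table (normalized on load, fully overridable) —
appropriate for human-proteome-derived ligandomes; for other organisms
supply `BackgroundFrequencies.from_sequences` over the relevant proteome.

## KL convergence

For fixed-length sets A and B, per position:
`convergence = 1 − KL(p_A ‖ p_B) / KL(p_A ‖ uniform)`, clipped to [0, 1];
when `KL(p_A ‖ uniform) = 0` the convergence is 1 if `KL(p_A‖p_B) = 0`,
else 0. The raw unclipped ratio is exported alongside. The direction is
A‖B with A the subsampled set, and B is held at full size on every grid
point. Curves subsample A without replacement (default 500 resamples per
grid size); the subset drawn depends only on `(seed, N_A, resample index)`
through a splittable generator, so grids are reproducible and
parallelizable. With 500 resamples, repeat runs under different seeds agree
within 0.05 at every grid point on the bundled synthetic fixtures.

Zeros in `p_B` where `p_A > 0` would make the divergence infinite; at such
positions B's tallies receive a 0.5 count-unit pseudocount per letter and
are renormalized. The pseudocount is *lazy* — applied only where needed —
which keeps self-comparison at full sample size exactly 1.0 at every
position, the defining boundary case, while regularizing cross-set
comparisons. The uniform reference is 1/20 per canonical letter.

## Target mapping

Placements are exact substring occurrences in 1-based inclusive
coordinates (0-based half-open accessors provided); overlapping and
multiple occurrences are all reported and all contribute to coverage
(union semantics). Coverage is the union of covered residues over the full
sequence — including leader peptides, which genuinely contribute observed
peptides — with per-region fractions over annotated features; a mature-
chain-only denominator is a matter of passing restricted features. Sequon
scanning uses N-X-[S/T] with X ≠ P by default (prolines block
glycosylation); a flag disables the proline exclusion, and both counts can
be compared when they differ. The sequon/peptide intersection
distinguishes triplets fully inside a peptide from those whose completing
S/T lies past the peptide's C-terminus. Modification reports translate
peptide-local sites to protein coordinates through every placement and
express counts as fractions of all observations covering the position.

The bundled mesothelin reference is the 622-residue MPF+MSLN proprotein
(AAV87530.1 numbering) with 68 published target peptides. Moiety
boundaries derive from the furin site RPRFRR at 290–295; leader and
GPI-signal extents are approximate display annotations. The whitespace of
the published peptide table was reconstructed by segmenting concatenated
runs into 8–16-mer substrings of the precursor using the table's
alphabetical ordering; the one ambiguous split covers identical protein
positions either way.

## Synthetic ligandome generator

The generator provides ground truth for every stage; its defaults are the
study conditions of the test suite.

- **Motifs.** Each allele preset fixes length weights over 8–14-mers and
  anchor tables at P2 and the C-terminal position. Anchor positions sample
  from `0.8 · anchor + 0.2 · background` (the concentration parameter
  keeps motifs probabilistic so convergence curves are nontrivial);
  non-anchor positions sample the UniProt background. Presets
  (A\*02:01-, A\*03:01-, A\*11:01-, A\*24:02-, B\*07:02-, C\*07:02-like)
  are loosely inspired by published class-I motifs (e.g. A3: P2 L/I,
  P9 K/R; A11: P2 T/S, P9 K, longer lengths; A24: P2 Y, P9 F/L) but are
  synthetic calibrations, never claimed to reproduce real motifs.
  A configurable fraction of 8-mers carries the P2 preference at P1
  (the alternate short-peptide binding mode), and 13/14-mers receive a
  3× glycine boost at central positions (bulged long peptides).
- **Retention times** are `2700 + 45 · (summed Kyte–Doolittle hydropathy)
  + N(0, 30²)` seconds, clamped at 0. No claim of chromatographic realism
  is made: only the relative co-elution of artifacts matters for testing,
  so the simplest monotone model is used.
- **Truncation artifacts**: a chosen fraction of peptides gains an N- or
  C-terminally truncated copy (1–3 residues shorter) offset in retention
  time by a magnitude uniform in [jitter/2, jitter] with random sign, so a
  jitter below the culling window plants artifacts that must all be
  removed, and a jitter more than twice the window plants artifacts that
  must all survive. Collisions with existing sequences are skipped to keep
  ground truth unambiguous.
- **Contaminants** are drawn position-independently from the background
  composition (hence flat logos) and sourced to listed accessions.
- **Replicates.** Experimental replicates detect each peptide
  independently with probability p per run (default 0.8). Under the
  overlap formula this gives expected pairwise overlap `100·p` (the
  exclusive domains are `p(1−p)N` each and the shared domain `p²N`, so
  `2A2/(A1+2A2+A3) = 2p²/2p = p`), reproducing the ~80% experimental
  regime. Biological replicates first resample the underlying ligandome —
  keeping each peptide with probability f = 0.8 and replacing the dropped
  ones with fresh motif draws — then apply detection, giving expected
  overlap near `100·p·f² ≈ 51%`, the reported biological-replicate regime.

What the generator does **not** emulate: spectrum-level effects and FDR
behavior of the search engine, intensity-dependent detection, shared
contaminant structure between runs, correlated peptide abundances, or
ligandome remodeling beyond random resampling. Passing tests therefore
demonstrate correctness of the analysis operations under controlled
conditions, not performance claims on real ligandomes.

## Problem sizes and numerics

Tests and the acceptance script use ligandomes of 1000–2000 peptides,
replicate ensembles of 50–500 pairs, and 5–500 convergence resamples —
sizes at which every planted effect is detectable at comfortable margins
(binomial/multinomial checks use 3–4 standard errors). Stochastic
assertions fix seeds; determinism invariants are asserted byte-for-byte
on written tables. Degenerate inputs (empty sets, all-zero Venn domains,
empty subsample grids, zero-length bins) raise explicit errors rather than
returning NaNs, except where a defined limit exists (`0·log 0 := 0`).

## Known limitations

- Binder classes are consumed as annotations; no affinity prediction.
- The nested cull cannot distinguish a genuine co-eluting shorter ligand
  from an in-source fragment; like the upstream convention it errs
  conservative.
- Multi-allele (pan) deconvolution is out of scope by design — the data
  model assumes single-allele capture or externally assigned alleles.
- Venn rendering is schematic, not area-proportional; graphics are
  conveniences, not results.
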