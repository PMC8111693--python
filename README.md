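# ligandkit

Downstream analysis of HLA class I ligandome peptide lists from
immunopeptidomics experiments.

Single-allele peptide-capture experiments (secreted HLA-I reagents,
immunoprecipitation, or single-allele cell lines) end in long tables of
MS-identified peptides. `ligandkit` covers everything that happens after the
search engine: conservative filtering of the peptide lists, quantitative
comparison of datasets and replicates, characterization of allele binding
motifs, and mapping of identified peptides onto target proteins of interest.
It is written for computational immunologists and proteomics analysts who
receive post-search peptide tables (it does not touch raw MS data, database
searching, or binding prediction — external binder-class calls are consumed
as annotations).

## What it computes

**Filtering** (`ligandkit.filtering`) — keep a chosen FDR tier (1% only, or
5% with the relaxed additions flagged); restrict to the 8–14-mer class-I
window; cull peptides from CRAPome-style contaminant source proteins
(flagged, never deleted); and cull *nested* peptides — shorter peptides
wholly contained in a longer identified sequence — when they co-elute with
the encompassing peptide within a retention-time window (default 30 s), the
signature of in-source fragmentation.

**Overlap analysis** (`ligandkit.overlap`) — Venn domains `(A1, A2, A3)` of
two unique-sequence sets and the overlap percentage

```
overlap % = 100 · 2·A2 / (A1 + 2·A2 + A3)
```

plus asymmetric recovery (share of a reference set found in a query),
three-set Venn domains, run-by-run pairwise overlap matrices binned by
peptide length, and unique-sequence accumulation curves across replicates.

**Motif analysis** (`ligandkit.motif`) — per-length position frequency
matrices and relative-entropy sequence logos: letter heights
`h_i(a) = p_i(a) · log2(p_i(a) / q(a))` against a UniProt proteome
background `q`, so each position's signed heights sum to the
Kullback–Leibler divergence `KL(p_i ‖ q)` in bits. Also length
distributions, binder-class summaries (which can exceed 100% when one
peptide is predicted to bind several alleles), and GO-compartment profiles.

**KL convergence** (`ligandkit.convergence`) — per-position convergence of
peptide set A toward set B, `1 − KL(p_A ‖ p_B) / KL(p_A ‖ uniform)` clipped
to [0, 1], estimated as a function of the A-sample size by repeated
subsampling without replacement (default 500 resamples). Self-convergence
shows how many peptides determine a motif; cross-allele convergence shows
which positions genuinely diverge between related alleles.

**Target mapping** (`ligandkit.mapping`) — exact placements of peptides on
a protein (1-based coordinates), union sequence coverage overall and per
annotated region, N-glycosylation sequon scans (N-X-S/T, X ≠ P by default),
sequon/peptide intersections, and per-protein-position modification
reports. The mesothelin precursor (MPF+MSLN proprotein) with its published
target peptides is bundled as a reference dataset.

**Synthetic ligandomes** (`ligandkit.simulate`) — a ground-truth generator
for all of the above: allele motif presets with probabilistic P2/C-terminal
anchors, length distributions, hydrophobicity-driven retention times,
co-eluting truncation artifacts, contaminant peptides, and
experimental/biological replicate models calibrated to ~80% / ~50%
pairwise overlap.

## Worked example

```python
import ligandkit as lk

# map the bundled published MPF/MSLN target peptides onto the precursor
protein  = lk.load_msln_protein()
peptides = lk.load_msln_target_peptides()
placements, unplaced = lk.place_peptides(peptides, protein)
cov = lk.coverage(placements, protein)
print(f"{100 * cov.coverage_fraction:.1f}% of {protein.length} residues covered")
print([(s.position, s.triplet) for s in lk.find_sequons(protein)])
```

prints

```
57.6% of 622 residues covered
[(57, 'NIS'), (388, 'NVT'), (488, 'NGS'), (515, 'NVS')]
```

— 68 published target peptides cover 57.6% of the proprotein, and the scan
finds its four potential N-glycan sequons, one (NIS at Asn57) in the MPF
moiety. The A\*02:01 peptide GVLANPPNI ends on that asparagine with the
completing serine just past its C-terminus
(`sequon_peptide_intersection` reports the boundary-spanning relation).

The numbered scripts under `analysis/` run the full study on synthetic
data: `01` generates six allele ligandomes with planted artifacts, `02`
audits the filter cascade against ground truth (all 200 planted truncation
artifacts removed, none falsely), `03` simulates replicate structure
(experimental ~80%, biological ~51% mean pairwise overlap), `04` builds
length-specific logos (planted anchors dominate every 9-mer logo), `05`
estimates KL convergence (self-convergence reaches 1.0 exactly; the
divergent planted P2 stays near 0 between allele pairs), and `06` maps the
MSLN targets. Outputs land in `results/`.

A CLI mirrors the modules: `ligandkit simulate | filter | compare |
replicates | motif | converge | map | run`.

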