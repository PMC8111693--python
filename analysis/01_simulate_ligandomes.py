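#!/usr/bin/env python
"""Generate the synthetic study ligandomes.

Draws single-allele ligandomes for the six motif presets, plants truncation
artifacts (co-eluting nested peptides) and contaminant-protein peptides in
the A*03:01 set, and writes peptide tables plus ground truth under
results/synthetic/. Everything downstream (02-05) works from these tables.
"""

import json
from pathlib import Path

import pandas as pd

import ligandkit as lk

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2021

CRAP_ACCESSIONS = [f"CRAP_{i:03d}" for i in range(1, 21)]

summary = []
for allele, spec in lk.presets().items():
    pset, truth = lk.sample_ligandome(spec, lk.SimulationConfig(n_peptides=2000, seed=SEED))
    if allele == "A*03:01":
        pset, t_art = lk.inject_truncations(pset, rate=0.10, jitter_s=20, seed=SEED + 1)
        pset, t_crap = lk.inject_contaminants(pset, 0.05, CRAP_ACCESSIONS, seed=SEED + 2)
        truth = truth.merge(t_art).merge(t_crap)
    safe = allele.replace("*", "").replace(":", "")
    lk.write_peptide_table(pset, OUT / f"{safe}.tsv")
    pd.DataFrame(
        [{"sequence": s, "label": l, "parent": truth.parents.get(s, "")}
         for s, l in sorted(truth.labels.items())]
    ).to_csv(OUT / f"{safe}_truth.tsv", sep="\t", index=False)
    counts, mean_len = lk.length_distribution(pset)
    summary.append({
        "allele": allele, "records": len(pset),
        "unique": len(pset.unique_sequences), "mean_length": round(mean_len, 2),
    })
    print(f"{allele}: {len(pset)} records, {len(pset.unique_sequences)} unique, "
          f"mean length {mean_len:.2f}")

(OUT / "summary.json").write_text(json.dumps({"seed": SEED, "alleles": summary}, indent=1))
(Path(__file__).resolve().parents[1] / "results" / "contaminants.txt").write_text(
    "\n".join(CRAP_ACCESSIONS) + "\n"
)
print(f"\nwrote tables to {OUT}")
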