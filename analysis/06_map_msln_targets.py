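#!/usr/bin/env python
"""Map the published MPF/MSLN target peptides onto the precursor.

Places the 68 published target-protein peptides (A*02:01, A*11:01,
A*24:02) on the 622-residue mesothelin precursor, computes union coverage
overall and per moiety (MPF vs MSLN, split at the furin site), scans for
potential N-glycosylation sequons, and reports the sequon/peptide
intersections — including the boundary case where a peptide ends on a
sequon asparagine whose completing serine lies past its C-terminus.
"""

import json
from pathlib import Path

import pandas as pd

import ligandkit as lk
from ligandkit.mapping import sequon_peptide_intersection

ROOT = Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(exist_ok=True)

protein = lk.load_msln_protein()
peptides = lk.load_msln_target_peptides()
placements, unplaced = lk.place_peptides(peptides, protein)
assert not unplaced
cov = lk.coverage(placements, protein)
sequons = lk.find_sequons(protein)

pd.DataFrame(
    [{"peptide": p.peptide, "start": p.start, "end": p.end, "allele": p.allele}
     for p in placements]
).to_csv(ROOT / "msln_placements.tsv", sep="\t", index=False)

rels = sequon_peptide_intersection(placements, sequons)
print(f"{len(peptides.unique_sequences)} target peptides, "
      f"{len(placements)} placements, coverage "
      f"{100 * cov.coverage_fraction:.1f}% of {protein.length} residues")
print("per-moiety coverage:",
      {k: f"{100 * v:.1f}%" for k, v in cov.per_region_coverage.items()
       if k in ("MPF", "MSLN", "leader")})
print(f"sequons ({len(sequons)}):", [(s.position, s.triplet) for s in sequons])
for p, s, rel in rels:
    print(f"  {p.peptide} [{p.start}..{p.end}] intersects {s.triplet}@{s.position}: {rel}")

(ROOT / "msln_coverage.json").write_text(json.dumps({
    "coverage_pct": round(100 * cov.coverage_fraction, 2),
    "per_region": {k: round(100 * v, 2) for k, v in cov.per_region_coverage.items()},
    "sequons": [{"position": s.position, "triplet": s.triplet} for s in sequons],
    "sequon_peptide_relations": [
        {"peptide": p.peptide, "sequon_position": s.position, "relation": rel}
        for p, s, rel in rels
    ],
}, indent=1))
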