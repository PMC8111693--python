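"""Mapping identified peptides onto target protein sequences.

Placements are exact substring occurrences, 1-based inclusive (the biology
convention for protein positions); converters to 0-based half-open are
provided for interchange. Coverage is the union of covered residues over
the full sequence and per annotated region. Potential N-glycosylation
sequons (N-X-[S/T], X != P by default) are scanned with overlapping windows
allowed, and intersected with placements to flag peptides that carry an
intact sequon or end on a sequon asparagine whose completing residues lie
past the peptide's C-terminus.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .io import PeptideSet, ProteinRecord


@dataclass(frozen=True)
class PeptidePlacement:
    """One exact occurrence of a peptide in a protein (1-based inclusive)."""

    peptide: str
    protein_accession: str
    start: int
    end: int
    allele: str = ""
    occurrences: int = 1  # distinct start positions of this peptide in the protein

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (exclusive)."""
        return self.end


@dataclass
class CoverageResult:
    protein_accession: str
    covered_positions: set[int]  # 1-based
    coverage_fraction: float
    per_region_coverage: dict[str, float]


@dataclass(frozen=True)
class SequonSite:
    """A potential N-glycosylation site; position indexes the asparagine."""

    position: int  # 1-based
    triplet: str


def place_peptides(
    peptides: PeptideSet | list[str], protein: ProteinRecord
) -> tuple[list[PeptidePlacement], list[str]]:
    """Every exact occurrence of each unique peptide in the protein.

    Overlapping occurrences are all reported. Returns (placements, unplaced)
    where ``unplaced`` lists peptides with zero occurrences (possible
    contaminants or sequence variants).
    """
    if isinstance(peptides, PeptideSet):
        allele_by_seq = {}
        for r in peptides.active_records:
            allele_by_seq.setdefault(r.sequence, r.allele)
        seqs = sorted(allele_by_seq)
    else:
        seqs = sorted(set(peptides))
        allele_by_seq = {s: "" for s in seqs}
    placements: list[PeptidePlacement] = []
    unplaced: list[str] = []
    for s in seqs:
        starts = [m.start() + 1 for m in re.finditer(f"(?={re.escape(s)})", protein.sequence)]
        if not starts:
            unplaced.append(s)
            continue
        for st in starts:
            placements.append(
                PeptidePlacement(
                    peptide=s,
                    protein_accession=protein.accession,
                    start=st,
                    end=st + len(s) - 1,
                    allele=allele_by_seq[s],
                    occurrences=len(starts),
                )
            )
    return placements, unplaced


def coverage(
    placements: list[PeptidePlacement], protein: ProteinRecord
) -> CoverageResult:
    """Union residue coverage over the full protein and per annotated region.

    All occurrences of multi-occurrence peptides contribute (union
    semantics); adding a placement can never decrease coverage.
    """
    covered: set[int] = set()
    for p in placements:
        if p.protein_accession != protein.accession:
            raise ValueError(
                f"placement of {p.peptide} refers to {p.protein_accession}, "
                f"not {protein.accession}"
            )
        covered.update(range(p.start, p.end + 1))
    per_region: dict[str, float] = {}
    for kind, start, end, label in protein.features:
        span = set(range(start, end + 1))
        per_region[label] = len(covered & span) / len(span)
    return CoverageResult(
        protein_accession=protein.accession,
        covered_positions=covered,
        coverage_fraction=len(covered) / protein.length,
        per_region_coverage=per_region,
    )


def find_sequons(protein: ProteinRecord, exclude_proline: bool = True) -> list[SequonSite]:
    """Scan for N-X-[S/T] sequons, left to right, overlapping windows allowed.

    By default the central X must not be proline (prolines block
    glycosylation); pass ``exclude_proline=False`` for the permissive
    N-X-S/T rule.
    """
    mid = "[^P]" if exclude_proline else "."
    pat = re.compile(f"(?=N({mid})(S|T))")
    return [
        SequonSite(position=m.start() + 1, triplet=protein.sequence[m.start(): m.start() + 3])
        for m in pat.finditer(protein.sequence)
    ]


N_WITHIN_PEPTIDE = "N_within_peptide"
SEQUON_SPANS_BOUNDARY = "sequon_spans_boundary"


def sequon_peptide_intersection(
    placements: list[PeptidePlacement], sequons: list[SequonSite]
) -> list[tuple[PeptidePlacement, SequonSite, str]]:
    """Placements containing a sequon asparagine, with the containment relation.

    ``N_within_peptide`` means the whole N-X-S/T triplet lies inside the
    peptide; ``sequon_spans_boundary`` means the peptide ends on (or just
    after) the asparagine so the completing residues run past its
    C-terminus.
    """
    out = []
    for p in placements:
        for sq in sequons:
            if p.start <= sq.position <= p.end:
                relation = (
                    N_WITHIN_PEPTIDE if sq.position + 2 <= p.end else SEQUON_SPANS_BOUNDARY
                )
                out.append((p, sq, relation))
    return out


def modification_report(
    peptides: PeptideSet, placements: list[PeptidePlacement]
) -> pd.DataFrame:
    """Per-protein-position modification summary.

    For each protein position touched by modified peptides, reports the
    number of peptide observations (records, not unique sequences) carrying
    each modification type there, and that count as a fraction of all
    observations of peptides covering the position. Peptide-local
    modification positions are translated to protein coordinates through
    every placement of the peptide.
    """
    place_by_seq: dict[str, list[PeptidePlacement]] = defaultdict(list)
    for p in placements:
        place_by_seq[p.peptide].append(p)

    # observations covering each protein position (only peptides with placements)
    obs_at: dict[int, int] = defaultdict(int)
    modcount: dict[tuple[int, str, str], int] = defaultdict(int)
    residue_at: dict[int, str] = {}
    for rec in peptides.active_records:
        for p in place_by_seq.get(rec.sequence, []):
            for pos in range(p.start, p.end + 1):
                obs_at[pos] += 1
            for mod in rec.modifications:
                prot_pos = p.start + mod.position - 1
                modcount[(prot_pos, mod.type, p.protein_accession)] += 1
                residue_at[prot_pos] = rec.sequence[mod.position - 1]
    rows = []
    for (pos, mtype, acc), count in sorted(modcount.items()):
        rows.append(
            {
                "protein_accession": acc,
                "position": pos,
                "residue": residue_at[pos],
                "modification": mtype,
                "n_modified": count,
                "n_observations": obs_at[pos],
                "fraction": count / obs_at[pos],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "position",
            "residue",
            "modification",
            "n_modified",
            "n_observations",
            "fraction",
        ],
    )
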