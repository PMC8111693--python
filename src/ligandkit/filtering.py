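"""Conservative peptide-list filters.

The filter cascade mirrors standard immunopeptidomics practice: keep a chosen
FDR tier, restrict to the 8-14-mer class-I length window, cull peptides from
known affinity-purification contaminant proteins, and cull "nested" peptides
(shorter peptides wholly contained in a longer identified sequence) that
co-elute with their parent within a narrow retention-time window — the
signature of in-source fragmentation rather than genuine presentation.

Culled records are flagged and retained, never deleted; every analysis
downstream works on the non-culled view by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .io import PeptideRecord, PeptideSet

DEFAULT_RT_WINDOW_S = 30.0
DEFAULT_MIN_LEN = 8
DEFAULT_MAX_LEN = 14


@dataclass
class NestGroup:
    """A maximal peptide together with the shorter peptides nested inside it.

    ``members`` hold every record in the set whose sequence is a strict,
    contiguous substring of the parent sequence, sorted by descending length;
    ``delta_rt`` holds |rt(member) - rt(parent)| in seconds (None where either
    retention time is missing).
    """

    parent: PeptideRecord
    members: list[PeptideRecord] = field(default_factory=list)
    delta_rt: list[float | None] = field(default_factory=list)


@dataclass
class FilterReport:
    """Counts for one filter application; counts are conserved."""

    input_count: int = 0
    kept_count: int = 0
    culled_crapome: int = 0
    culled_nested: int = 0
    culled_length: int = 0
    culled_fdr: int = 0
    unevaluated_no_rt: int = 0
    witnesses: list[tuple[str, str, float]] = field(default_factory=list)
    # (culled sequence, parent sequence, delta_rt)

    @property
    def total_culled(self) -> int:
        return self.culled_crapome + self.culled_nested + self.culled_length + self.culled_fdr

    def check_conserved(self) -> None:
        if self.input_count != self.kept_count + self.total_culled:
            raise AssertionError(
                f"filter counts not conserved: {self.input_count} != "
                f"{self.kept_count} + {self.total_culled}"
            )


def filter_fdr(pset: PeptideSet, tier: str = "q01") -> PeptideSet:
    """Keep records at the requested FDR tier.

    ``q01`` keeps only 1%-FDR identifications; ``q05`` keeps both tiers (the
    relaxed additions stay flagged by their own ``fdr_tier`` field).
    """
    if tier not in ("q01", "q05"):
        raise ValueError(f"tier must be q01 or q05, got {tier!r}")
    if tier == "q05":
        return pset.replace_records(list(pset.records))
    return pset.replace_records([r for r in pset.records if r.fdr_tier == "q01"])


def filter_length(
    pset: PeptideSet, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> PeptideSet:
    """Keep records whose length lies in [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return pset.replace_records(
        [r for r in pset.records if min_len <= r.length <= max_len]
    )


def cull_contaminants(
    pset: PeptideSet, contaminant_accessions: set[str]
) -> tuple[PeptideSet, FilterReport]:
    """Flag records whose source protein is on the contaminant list.

    Flagged records are retained in the output set with ``culled="crapome"``
    but excluded from its unique-sequence view.
    """
    report = FilterReport(input_count=len(pset.records))
    out: list[PeptideRecord] = []
    for rec in pset.records:
        if rec.culled is None and rec.source_accession in contaminant_accessions:
            out.append(dataclasses.replace(rec, culled="crapome"))
            report.culled_crapome += 1
        else:
            out.append(rec)
            report.kept_count += 1
    report.check_conserved()
    return pset.replace_records(out), report


def find_nests(pset: PeptideSet) -> list[NestGroup]:
    """Group each maximal peptide with the shorter peptides nested inside it.

    A peptide is maximal when no strictly longer sequence in the set contains
    it. Substring matching is exact and contiguous. A peptide contained in two
    distinct maximal peptides appears in both groups.
    """
    records = pset.active_records
    seqs = sorted({r.sequence for r in records})
    by_seq: dict[str, list[PeptideRecord]] = {}
    for r in records:
        by_seq.setdefault(r.sequence, []).append(r)

    def is_maximal(s: str) -> bool:
        return not any(s != t and s in t for t in seqs)

    groups: list[NestGroup] = []
    for s in seqs:
        if not is_maximal(s):
            continue
        nested = [t for t in seqs if t != s and t in s]
        for parent_rec in by_seq[s]:
            members = [
                rec
                for t in sorted(nested, key=lambda t: (-len(t), t))
                for rec in by_seq[t]
            ]
            deltas = [
                abs(rec.retention_time - parent_rec.retention_time)
                if rec.retention_time is not None and parent_rec.retention_time is not None
                else None
                for rec in members
            ]
            groups.append(NestGroup(parent=parent_rec, members=members, delta_rt=deltas))
    return groups


def cull_nested(
    pset: PeptideSet, window_s: float = DEFAULT_RT_WINDOW_S
) -> tuple[PeptideSet, FilterReport]:
    """Cull nested peptides co-eluting with a longer encompassing peptide.

    A record is culled iff some strictly longer record *in the same run* has
    its sequence as a contiguous substring and |delta rt| <= window_s.
    Culling is decided in a single pass against the original set, never
    iteratively against survivors: if A < B < C all co-elute, both A and B
    are culled. Records without a retention time are never culled (counted as
    unevaluated). The recorded witness is the longest qualifying parent
    sequence, ties broken lexicographically.
    """
    if window_s < 0:
        raise ValueError(f"window_s must be nonnegative, got {window_s}")
    report = FilterReport(input_count=len(pset.records))
    by_run: dict[str, list[PeptideRecord]] = {}
    for rec in pset.records:
        if rec.culled is None:
            by_run.setdefault(rec.run_id, []).append(rec)

    out: list[PeptideRecord] = []
    for rec in pset.records:
        if rec.culled is not None:
            out.append(rec)
            report.kept_count += 1
            continue
        if rec.retention_time is None:
            out.append(rec)
            report.kept_count += 1
            report.unevaluated_no_rt += 1
            continue
        witnesses = [
            other
            for other in by_run[rec.run_id]
            if len(other.sequence) > rec.length
            and rec.sequence in other.sequence
            and other.retention_time is not None
            and abs(other.retention_time - rec.retention_time) <= window_s
        ]
        if witnesses:
            best = max(witnesses, key=lambda w: (len(w.sequence), [-ord(c) for c in w.sequence]))
            # longest parent; lexicographically smallest among equal lengths
            report.witnesses.append(
                (
                    rec.sequence,
                    best.sequence,
                    abs(best.retention_time - rec.retention_time),
                )
            )
            out.append(dataclasses.replace(rec, culled="nested"))
            report.culled_nested += 1
        else:
            out.append(rec)
            report.kept_count += 1
    report.check_conserved()
    return pset.replace_records(out), report


def apply_filters(
    pset: PeptideSet,
    fdr_tier: str = "q05",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    contaminant_accessions: set[str] | None = None,
    rt_window_s: float = DEFAULT_RT_WINDOW_S,
) -> tuple[PeptideSet, FilterReport]:
    """Run the full cascade in fixed order: FDR -> length -> contaminants -> nested.

    The order fixes FilterReport attribution (each record is culled by at
    most one rule); it does not change the final kept set.
    """
    report = FilterReport(input_count=len(pset.records))
    n0 = len(pset.records)
    pset = filter_fdr(pset, fdr_tier)
    report.culled_fdr = n0 - len(pset.records)
    n1 = len(pset.records)
    pset = filter_length(pset, min_len, max_len)
    report.culled_length = n1 - len(pset.records)
    if contaminant_accessions:
        pset, crap = cull_contaminants(pset, contaminant_accessions)
        report.culled_crapome = crap.culled_crapome
    pset, nest = cull_nested(pset, rt_window_s)
    report.culled_nested = nest.culled_nested
    report.unevaluated_no_rt = nest.unevaluated_no_rt
    report.witnesses = nest.witnesses
    report.kept_count = report.input_count - report.total_culled
    report.check_conserved()
    return pset, report
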