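"""Dataset intersection statistics.

Two-set comparisons use the Venn-domain overlap percentage

    overlap = 100 * 2*A2 / (A1 + 2*A2 + A3)

where A1 and A3 are the peptides exclusive to each set and A2 the shared
peptides (a Dice-style coefficient; it skews low when the two sets differ
greatly in size). Recovery is the asymmetric fraction of a reference set
found in a query set. Replicate structure is summarized by run-by-run
pairwise overlap matrices binned by peptide length and by accumulation
curves of unique sequences across progressively larger unions.

All operations act on unique, non-culled peptide sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .io import PeptideSet


@dataclass(frozen=True)
class VennDomains:
    """Counts of the three domains of a two-set comparison."""

    a1: int  # in set 1 only
    a2: int  # in both
    a3: int  # in set 2 only

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0:
            raise ValueError("Venn domain counts must be nonnegative")


@dataclass(frozen=True)
class Venn3Domains:
    """The seven exclusive region counts of a three-set comparison."""

    only_1: int
    only_2: int
    only_3: int
    d12: int
    d13: int
    d23: int
    d123: int

    @property
    def union_size(self) -> int:
        return (
            self.only_1 + self.only_2 + self.only_3
            + self.d12 + self.d13 + self.d23 + self.d123
        )


@dataclass
class OverlapMatrix:
    """Symmetric matrix of pairwise overlap percentages for one length bin."""

    labels: list[str]
    values: np.ndarray
    length_bin: str  # "all" or "8".."14"
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def off_diagonal_mean(self) -> float:
        """Unweighted mean over unordered pairs, excluding empty-run pairs."""
        n = len(self.labels)
        excluded = {frozenset(p) for p in self.excluded_pairs}
        vals = [
            self.values[i, j]
            for i, j in combinations(range(n), 2)
            if frozenset((self.labels[i], self.labels[j])) not in excluded
        ]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class AccumulationCurve:
    """Cumulative unique-sequence counts across progressively larger unions."""

    order: list[str]
    union_sizes: list[int]


def _seqs(s: PeptideSet | Iterable[str]) -> set[str]:
    return s.unique_sequences if isinstance(s, PeptideSet) else set(s)


def venn2(set1: PeptideSet | Iterable[str], set2: PeptideSet | Iterable[str]) -> VennDomains:
    """Two-set Venn domain counts over unique sequences."""
    s1, s2 = _seqs(set1), _seqs(set2)
    inter = s1 & s2
    return VennDomains(a1=len(s1 - s2), a2=len(inter), a3=len(s2 - s1))


def venn3(
    set1: PeptideSet | Iterable[str],
    set2: PeptideSet | Iterable[str],
    set3: PeptideSet | Iterable[str],
) -> Venn3Domains:
    """Three-set Venn domain counts over unique sequences."""
    s1, s2, s3 = _seqs(set1), _seqs(set2), _seqs(set3)
    return Venn3Domains(
        only_1=len(s1 - s2 - s3),
        only_2=len(s2 - s1 - s3),
        only_3=len(s3 - s1 - s2),
        d12=len((s1 & s2) - s3),
        d13=len((s1 & s3) - s2),
        d23=len((s2 & s3) - s1),
        d123=len(s1 & s2 & s3),
    )


def overlap_percentage(v: VennDomains) -> float:
    """Overlap percentage 100 * 2*A2 / (A1 + 2*A2 + A3), in [0, 100]."""
    denom = v.a1 + 2 * v.a2 + v.a3
    if denom == 0:
        raise ValueError("overlap percentage undefined for all-empty domains")
    return 100.0 * (2 * v.a2) / denom


def overlap_of(set1, set2) -> float:
    """Convenience: overlap percentage of two sets."""
    return overlap_percentage(venn2(set1, set2))


def recovery_percentage(reference: PeptideSet | Iterable[str], query: PeptideSet | Iterable[str]) -> float:
    """Percentage of the reference set's unique sequences found in the query.

    Asymmetric, unlike the overlap percentage.
    """
    ref, q = _seqs(reference), _seqs(query)
    if not ref:
        raise ValueError("recovery undefined for an empty reference set")
    return 100.0 * len(ref & q) / len(ref)


def recovery_from_counts(intersection: int, reference_total: int) -> float:
    """Recovery percentage from raw counts (for published-count arithmetic)."""
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    if not 0 <= intersection <= reference_total:
        raise ValueError("intersection must be within [0, reference_total]")
    return 100.0 * intersection / reference_total


DEFAULT_LENGTH_BINS: tuple[object, ...] = (8, 9, 10, 11, 12, 13, 14, "all")


def pairwise_overlap_table(
    runs: Sequence[PeptideSet], length_bins: Sequence[object] = DEFAULT_LENGTH_BINS
) -> dict[str, OverlapMatrix]:
    """Run-by-run pairwise overlap matrices, one per length bin.

    The bin "all" pools 8-14-mers. A run empty in a bin excludes its pairs
    from that bin's mean (reported in ``excluded_pairs``). Diagonal entries
    are 100 for non-empty runs.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    labels = [r.name or f"run{i+1}" for i, r in enumerate(runs)]
    out: dict[str, OverlapMatrix] = {}
    for bin_ in length_bins:
        if bin_ == "all":
            seq_sets = [
                {s for s in r.unique_sequences if 8 <= len(s) <= 14} for r in runs
            ]
        else:
            seq_sets = [set(r.sequences_of_length(int(bin_))) for r in runs]
        n = len(runs)
        mat = np.zeros((n, n))
        excluded: list[tuple[str, str]] = []
        for i in range(n):
            mat[i, i] = 100.0 if seq_sets[i] else float("nan")
        for i, j in combinations(range(n), 2):
            if not seq_sets[i] or not seq_sets[j]:
                mat[i, j] = mat[j, i] = float("nan")
                excluded.append((labels[i], labels[j]))
                continue
            mat[i, j] = mat[j, i] = overlap_of(seq_sets[i], seq_sets[j])
        out[str(bin_)] = OverlapMatrix(
            labels=labels, values=mat, length_bin=str(bin_), excluded_pairs=excluded
        )
    return out


def accumulation_curve(runs: Sequence[PeptideSet]) -> AccumulationCurve:
    """Cumulative union sizes of unique sequences in the given run order."""
    if not runs:
        raise ValueError("need at least one run")
    seen: set[str] = set()
    sizes: list[int] = []
    order: list[str] = []
    for i, r in enumerate(runs):
        seen |= r.unique_sequences
        sizes.append(len(seen))
        order.append(r.name or f"run{i+1}")
    return AccumulationCurve(order=order, union_sizes=sizes)


def mean_accumulation_curve(
    runs: Sequence[PeptideSet], n_orders: int = 100, seed: int = 0
) -> list[float]:
    """Mean accumulation curve over random run orderings (seeded)."""
    rng = np.random.default_rng(seed)
    k = len(runs)
    totals = np.zeros(k)
    for _ in range(n_orders):
        perm = rng.permutation(k)
        totals += accumulation_curve([runs[i] for i in perm]).union_sizes
    return list(totals / n_orders)
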