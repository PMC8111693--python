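"""Position frequency matrices and relative-entropy sequence logos.

Peptides are analyzed per exact length, positions indexed P1..PL with no
gapped alignment (class-I peptides of different lengths bulge rather than
align). Logo letter heights are the per-residue contributions

    height[i][a] = p_{i,a} * log2(p_{i,a} / q_a)

against a background distribution q (UniProt proteome amino-acid
frequencies by default), so the signed heights at one position sum to the
Kullback-Leibler divergence KL(p_i || q) in bits. Positive heights mark
residues enriched over background, negative heights mark depleted residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, BinderAnnotation, COMPARTMENTS, PeptideSet

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


@dataclass
class BackgroundFrequencies:
    """Amino-acid background distribution (strictly positive, sums to 1)."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.freq)
        if missing:
            raise ValueError(f"background missing letters {sorted(missing)}")
        total = sum(self.freq[a] for a in AMINO_ACIDS)
        if total <= 0:
            raise ValueError("background frequencies must be positive")
        self.freq = {a: self.freq[a] / total for a in AMINO_ACIDS}
        if min(self.freq.values()) <= 0:
            raise ValueError("background frequencies must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.freq[a] for a in AMINO_ACIDS])

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls({a: 1.0 / N_AA for a in AMINO_ACIDS})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BackgroundFrequencies":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    @classmethod
    def uniprot(cls) -> "BackgroundFrequencies":
        """The bundled UniProt proteome-wide composition table."""
        ref = resources.files("ligandkit.data") / "uniprot_background.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def from_sequences(cls, seqs, pseudocount: float = 1.0) -> "BackgroundFrequencies":
        counts = {a: pseudocount for a in AMINO_ACIDS}
        for s in seqs:
            for c in s:
                if c in counts:
                    counts[c] += 1
        return cls(counts)


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid counts and frequencies for length-L peptides.

    ``freqs`` applies the pseudocount policy
    (count + pc) / (n + 20 * pc) at every position.
    """

    length: int
    counts: np.ndarray  # (L, 20) ints
    n_peptides: int
    pseudocount: float = 0.0
    freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.length, N_AA):
            raise ValueError(f"counts must be ({self.length}, {N_AA})")
        if not np.all(self.counts.sum(axis=1) == self.n_peptides):
            raise ValueError("counts column sums must equal n_peptides at every position")
        self.freqs = (self.counts + self.pseudocount) / (
            self.n_peptides + N_AA * self.pseudocount
        )


def build_pfm(
    peptides: PeptideSet | list[str], length: int, pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Tally a position frequency matrix from the length-L unique sequences."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if isinstance(peptides, PeptideSet):
        seqs = peptides.sequences_of_length(length)
    else:
        seqs = sorted({s for s in peptides if len(s) == length})
    if not seqs:
        raise ValueError(f"no peptides of length {length}")
    counts = np.zeros((length, N_AA), dtype=int)
    for s in seqs:
        for i, c in enumerate(s):
            counts[i, AA_INDEX[c]] += 1
    return PositionFrequencyMatrix(
        length=length, counts=counts, n_peptides=len(seqs), pseudocount=pseudocount
    )


@dataclass
class LogoMatrix:
    """Signed relative-entropy letter heights, in bits.

    ``per_position_total[i]`` equals KL(p_i || background) >= 0. The stored
    rendering order ranks letters at each position by |height| (letters
    deviating most from the reference plotted tallest and furthest from the
    axis); the alternative ranking by |p - q| is kept alongside.
    """

    length: int
    heights: np.ndarray  # (L, 20) signed bits
    per_position_total: np.ndarray  # (L,)
    rank_by_height: list[list[str]]
    rank_by_deviation: list[list[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.heights, columns=list(AMINO_ACIDS),
                            index=[f"P{i+1}" for i in range(self.length)])


def logo_heights(
    pfm: PositionFrequencyMatrix, background: BackgroundFrequencies
) -> LogoMatrix:
    """Relative-entropy logo heights p * log2(p/q) against a background.

    The 0*log(0) limit is taken as 0, so positions are well defined at
    pseudocount 0; a zero background frequency is an error.
    """
    q = background.as_array()
    p = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        heights = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
    totals = heights.sum(axis=1)
    dev = np.abs(p - q)
    rank_h = [
        [AMINO_ACIDS[j] for j in np.argsort(-np.abs(heights[i]), kind="stable")]
        for i in range(pfm.length)
    ]
    rank_d = [
        [AMINO_ACIDS[j] for j in np.argsort(-dev[i], kind="stable")]
        for i in range(pfm.length)
    ]
    return LogoMatrix(
        length=pfm.length,
        heights=heights,
        per_position_total=totals,
        rank_by_height=rank_h,
        rank_by_deviation=rank_d,
    )


def length_distribution(pset: PeptideSet) -> tuple[dict[int, int], float]:
    """Unique-sequence counts per length and the count-weighted mean length."""
    seqs = pset.unique_sequences
    if not seqs:
        raise ValueError("empty peptide set")
    counts: dict[int, int] = {}
    for s in seqs:
        counts[len(s)] = counts.get(len(s), 0) + 1
    mean = sum(l * c for l, c in counts.items()) / len(seqs)
    return dict(sorted(counts.items())), mean


def binder_class_summary(
    pset: PeptideSet,
    annotations: list[BinderAnnotation],
    alleles: list[str],
) -> pd.DataFrame:
    """Per-length strong/weak/non percentages, summed over alleles.

    Every queried (peptide, allele) pair must be annotated. Because a
    peptide can be predicted to bind several alleles, the summed
    percentages can exceed 100.
    """
    amap = {(a.sequence, a.allele): a.binder_class for a in annotations}
    seqs = sorted(pset.unique_sequences)
    missing = [(s, al) for s in seqs for al in alleles if (s, al) not in amap]
    if missing:
        preview = ", ".join(f"{s}/{al}" for s, al in missing[:5])
        raise ValueError(
            f"{len(missing)} (peptide, allele) pairs lack binder annotations: {preview} ..."
        )
    lengths = sorted({len(s) for s in seqs})
    rows = []
    for L in lengths:
        ls = [s for s in seqs if len(s) == L]
        row = {"length": L, "n": len(ls)}
        for cls in ("strong", "weak", "non"):
            row[cls] = sum(
                100.0 * sum(1 for s in ls if amap[(s, al)] == cls) / len(ls)
                for al in alleles
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("length")


def compartment_profile(
    pset: PeptideSet, accession_to_compartment: dict[str, str]
) -> dict[str, float]:
    """Percentage of unique peptides per GO cellular-compartment label.

    A peptide's compartment is that of its source protein; accessions absent
    from the mapping are binned as "unmapped". When a sequence was observed
    from several source proteins, the lexicographically first accession is
    used (deterministic tie-break).
    """
    acc_by_seq: dict[str, str] = {}
    for rec in pset.active_records:
        prev = acc_by_seq.get(rec.sequence)
        if prev is None or rec.source_accession < prev:
            acc_by_seq[rec.sequence] = rec.source_accession
    n = len(acc_by_seq)
    if n == 0:
        return {c: 0.0 for c in COMPARTMENTS}
    out = {c: 0 for c in COMPARTMENTS}
    for seq, acc in acc_by_seq.items():
        label = accession_to_compartment.get(acc, "unmapped")
        if label not in out:
            label = "unmapped"
        out[label] += 1
    return {c: 100.0 * k / n for c, k in out.items()}
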