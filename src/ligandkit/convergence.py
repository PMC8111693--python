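"""Positional Kullback-Leibler convergence between peptide sets.

For two fixed-length peptide sets A and B, the per-position amino-acid
distributions p_A and p_B are compared by KL divergence, normalized against
the divergence of p_A from a uniform amino-acid distribution:

    convergence(i) = 1 - KL(p_A,i || p_B,i) / KL(p_A,i || uniform)

clipped to [0, 1]. Identical sets give 1.0 at every position by
construction; a point-mass position compared against uniform gives 0.
Convergence as a function of the A-set sample size N_A is estimated by
repeatedly subsampling A without replacement (B held at full size) and
averaging, which shows how many peptides are needed before a motif is
reliably determined, and at which positions two sets genuinely diverge.

The KL direction is A||B (A is the subsampled set). Zeros in p_B where
p_A > 0 would make the divergence infinite; at such positions B's tallies
receive a pseudocount (0.5 count-units per letter by default) and are
renormalized. The pseudocount is applied lazily — only at positions that
need it — so self-comparison at full size stays exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import PeptideSet
from .motif import AA_INDEX, N_AA, PositionFrequencyMatrix, build_pfm

UNIFORM = np.full(N_AA, 1.0 / N_AA)
DEFAULT_PSEUDOCOUNT = 0.5


def kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in bits with the 0*log(0) := 0 convention.

    Infinite when p has mass where q is zero.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def positional_kl(
    p: PositionFrequencyMatrix,
    q: PositionFrequencyMatrix,
    position: int,
    pseudocount: float = 0.0,
) -> float:
    """KL divergence in bits between two PFMs at one position (0-based).

    With pseudocount 0, a zero in q where p has mass is an error (advising a
    pseudocount); a positive pseudocount is applied to q's counts at the
    evaluated position.
    """
    pv = p.freqs[position]
    qc = q.counts[position].astype(float)
    if pseudocount > 0:
        qv = (qc + pseudocount) / (qc.sum() + N_AA * pseudocount)
    else:
        qv = q.freqs[position]
        if np.any((pv > 0) & (qv == 0)):
            raise ValueError(
                "q is zero where p has mass; pass a positive pseudocount to "
                "regularize the comparison"
            )
    return kl_bits(pv, qv)


@dataclass
class PositionalDivergence:
    """Per-position divergence of A from B and its normalized convergence."""

    position: int  # 1-based
    kl_ab: float  # bits
    kl_a_uniform: float  # bits
    convergence: float  # in [0, 1]
    raw_ratio: float  # unclipped 1 - kl_ab / kl_a_uniform


@dataclass
class ConvergenceCurve:
    """Mean per-position convergence as a function of subsample size N_A."""

    length: int
    n_grid: list[int]
    values: np.ndarray  # (len(n_grid), L)
    resamples: int
    seed: int
    positions: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.positions = list(range(1, self.length + 1))


def _position_convergence(
    p_a: np.ndarray, q_b_counts: np.ndarray, n_b: int, pseudocount: float
) -> tuple[float, float, float]:
    """(kl_ab, kl_a_uniform, raw ratio) for one position."""
    q_b = q_b_counts / n_b
    if np.any((p_a > 0) & (q_b == 0)):
        q_b = (q_b_counts + pseudocount) / (n_b + N_AA * pseudocount)
    kl_ab = kl_bits(p_a, q_b)
    kl_au = kl_bits(p_a, UNIFORM)
    if kl_au == 0.0:
        raw = 1.0 if kl_ab == 0.0 else 0.0
    else:
        raw = 1.0 - kl_ab / kl_au
    return kl_ab, kl_au, raw


def convergence(
    a: PeptideSet | list[str],
    b: PeptideSet | list[str],
    length: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PositionalDivergence]:
    """Per-position convergence of set A toward set B at one peptide length."""
    pfm_a = build_pfm(a, length)
    pfm_b = build_pfm(b, length)
    out = []
    for i in range(length):
        kl_ab, kl_au, raw = _position_convergence(
            pfm_a.freqs[i], pfm_b.counts[i].astype(float), pfm_b.n_peptides, pseudocount
        )
        out.append(
            PositionalDivergence(
                position=i + 1,
                kl_ab=kl_ab,
                kl_a_uniform=kl_au,
                convergence=float(np.clip(raw, 0.0, 1.0)),
                raw_ratio=raw,
            )
        )
    return out


def _subsample_rng(seed: int, n_a: int, resample: int) -> np.random.Generator:
    # splittable deterministic stream: the subset depends only on
    # (seed, N_A, resample index), so grids parallelize reproducibly
    return np.random.default_rng([seed, n_a, resample])


def convergence_curve(
    a: PeptideSet | list[str],
    b: PeptideSet | list[str],
    length: int,
    n_grid: Sequence[int] | None = None,
    resamples: int = 500,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ConvergenceCurve:
    """Mean convergence of subsamples of A toward the full B.

    For each N_A in ``n_grid``, A's length-L unique sequences are subsampled
    without replacement ``resamples`` times; B is held at full size.
    Deterministic given ``seed``.
    """
    seqs_a = (
        a.sequences_of_length(length) if isinstance(a, PeptideSet)
        else sorted({s for s in a if len(s) == length})
    )
    if not seqs_a:
        raise ValueError(f"set A has no peptides of length {length}")
    pfm_b = build_pfm(b, length)
    n_total = len(seqs_a)
    if n_grid is None:
        n_grid = default_grid(n_total)
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty subsample grid")
    for n_a in n_grid:
        if not 1 <= n_a <= n_total:
            raise ValueError(f"N_A {n_a} outside [1, {n_total}]")

    encoded = np.array([[AA_INDEX[c] for c in s] for s in seqs_a])  # (n, L)
    b_counts = pfm_b.counts.astype(float)
    n_b = pfm_b.n_peptides
    values = np.zeros((len(n_grid), length))
    for gi, n_a in enumerate(n_grid):
        n_draws = 1 if n_a == n_total else resamples  # full set: single possible draw
        acc = np.zeros(length)
        for r in range(n_draws):
            if n_a == n_total:
                sub = encoded
            else:
                rng = _subsample_rng(seed, n_a, r)
                sub = encoded[rng.choice(n_total, size=n_a, replace=False)]
            for i in range(length):
                p_sub = np.bincount(sub[:, i], minlength=N_AA) / n_a
                _, _, raw = _position_convergence(p_sub, b_counts[i], n_b, pseudocount)
                acc[i] += np.clip(raw, 0.0, 1.0)
        values[gi] = acc / n_draws
    return ConvergenceCurve(
        length=length, n_grid=n_grid, values=values, resamples=resamples, seed=seed
    )


def self_convergence_curve(
    a: PeptideSet | list[str],
    length: int,
    n_grid: Sequence[int] | None = None,
    resamples: int = 500,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ConvergenceCurve:
    """Convergence of subsamples of A toward the full A itself.

    The final grid point (N_A = |A|) is exactly 1.0 at every position; the
    rate of approach shows which positions are most enriched.
    """
    return convergence_curve(a, a, length, n_grid, resamples, seed, pseudocount)


def default_grid(n_total: int, n_points: int = 12, start: int = 5) -> list[int]:
    """A roughly geometric subsample grid from ``start`` to ``n_total``."""
    if n_total < start:
        return [n_total]
    pts = np.unique(
        np.round(np.geomspace(start, n_total, n_points)).astype(int)
    )
    return [int(p) for p in pts]
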