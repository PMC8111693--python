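"""Synthetic ligandome generation with known ground truth.

The generator emulates the features of single-allele class-I ligandome data
that the analysis stages exercise: allele-specific anchor motifs (a P2
anchor and a C-terminal P-omega anchor, mixed with proteome background
frequencies through a concentration parameter so motifs are probabilistic
rather than hard), length distributions over 8-14-mers, retention times
increasing linearly with Kyte-Doolittle hydrophobicity plus Gaussian noise,
nested truncation artifacts co-eluting with their parent peptide,
contaminant-protein peptides drawn from background composition, and
experimental vs biological replicate structure with distinct expected
overlap levels.

Allele presets are loosely inspired by published class-I binding motifs
(A*03:01: P2 L/I, P9 K/R; A*11:01: P2 T/S, P9 K; A*24:02: P2 Y, P9 F/L...)
but are synthetic calibrations, never claimed to reproduce real motifs.

Under the experimental replicate model (each peptide detected independently
with probability p in each run) the expected pairwise overlap percentage of
the Venn formula 100*2A2/(A1+2A2+A3) reduces to 100*p; the default
detection probability 0.8 therefore reproduces the ~80% experimental-
replicate overlap regime, and the biological model's default ligandome
resampling (keep 0.8, replace the rest with fresh motif draws) lands the
expected overlap near 100*p*f^2 ~ 51%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import AMINO_ACIDS, PeptideRecord, PeptideSet
from .motif import AA_INDEX, BackgroundFrequencies, N_AA

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class RtModel:
    """Linear retention-time proxy: rt = intercept + slope * sum(KD) + noise."""

    slope: float = 45.0  # seconds per hydropathy unit
    intercept: float = 2700.0  # seconds (mid-gradient)
    noise_sd: float = 30.0  # seconds
    scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))


@dataclass
class ReplicateModel:
    """Replicate structure: detection per run, and ligandome resampling for
    biological replicates."""

    kind: str = "experimental"  # experimental | biological
    detection_p: float = 0.8
    resample_keep: float = 0.8  # biological: fraction of the ligandome retained

    def __post_init__(self) -> None:
        if self.kind not in ("experimental", "biological"):
            raise ValueError(f"unknown replicate model kind {self.kind!r}")
        for name in ("detection_p", "resample_keep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class AlleleMotifSpec:
    """Synthetic allele motif: length preferences plus anchored positions.

    ``anchors`` maps anchor positions (2 for P2, -1 for the C-terminal
    P-omega) to letter-weight tables; at an anchor the sampling distribution
    is anchor_concentration * anchor_table + (1 - concentration) *
    background. ``p1_shift_fraction`` of 8-mers have their P2 anchor
    preference planted at P1 instead (the alternate short-peptide binding
    mode); ``mid_glycine_boost`` multiplies the glycine weight at the
    central positions of 13/14-mers (bulged long peptides).
    """

    allele: str
    length_weights: dict[int, float]
    anchors: dict[int, dict[str, float]]
    anchor_concentration: float = 0.8
    p1_shift_fraction: float = 0.0
    mid_glycine_boost: float = 1.0
    background: BackgroundFrequencies | None = None

    def __post_init__(self) -> None:
        total = sum(self.length_weights.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"length_weights must sum to 1, got {total}")
        if not 0.0 <= self.anchor_concentration <= 1.0:
            raise ValueError("anchor_concentration must be in [0, 1]")
        if not 0.0 <= self.p1_shift_fraction <= 1.0:
            raise ValueError("p1_shift_fraction must be in [0, 1]")

    def _background_array(self) -> np.ndarray:
        bg = self.background or BackgroundFrequencies.uniprot()
        return bg.as_array()

    def anchor_positions(self, length: int) -> dict[int, dict[str, float]]:
        """Anchors resolved to 1-based positions for a given length."""
        out = {}
        for pos, table in self.anchors.items():
            out[length + 1 + pos if pos < 0 else pos] = table
        return out

    def position_probs(self, length: int, p1_shifted: bool = False) -> np.ndarray:
        """(L, 20) sampling distribution for one peptide length."""
        bg = self._background_array()
        probs = np.tile(bg, (length, 1))
        anchors = self.anchor_positions(length)
        if p1_shifted and 2 in anchors:
            anchors = {**anchors, 1: anchors[2]}
            del anchors[2]
        for pos, table in anchors.items():
            vec = np.zeros(N_AA)
            for letter, w in table.items():
                vec[AA_INDEX[letter]] = w
            vec = vec / vec.sum()
            probs[pos - 1] = self.anchor_concentration * vec + (
                1 - self.anchor_concentration
            ) * bg
        if length >= 13 and self.mid_glycine_boost != 1.0:
            mid = range(length // 3, length - length // 3)
            g = AA_INDEX["G"]
            for i in mid:
                if (i + 1) not in anchors:
                    probs[i, g] *= self.mid_glycine_boost
                    probs[i] /= probs[i].sum()
        return probs


@dataclass
class SimulationConfig:
    n_peptides: int = 1000
    seed: int = 0
    truncation_rate: float = 0.0
    truncation_rt_jitter_s: float = 15.0
    contaminant_fraction: float = 0.0
    replicate_model: ReplicateModel = field(default_factory=ReplicateModel)
    rt_model: RtModel = field(default_factory=RtModel)

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        for name in ("truncation_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: Per-record ground-truth labels.
MOTIF_PEPTIDE = "motif_peptide"
TRUNCATION_ARTIFACT = "truncation_artifact"
CONTAMINANT = "contaminant"


@dataclass
class GroundTruth:
    """Planted structure of a synthetic peptide set."""

    labels: dict[str, str] = field(default_factory=dict)  # sequence -> label
    parents: dict[str, str] = field(default_factory=dict)  # artifact -> parent sequence
    anchor_positions: dict[int, dict[int, set[str]]] = field(default_factory=dict)
    # length -> {1-based position -> planted letters}

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            labels={**self.labels, **other.labels},
            parents={**self.parents, **other.parents},
            anchor_positions={**self.anchor_positions, **other.anchor_positions},
        )


def presets() -> dict[str, AlleleMotifSpec]:
    """Synthetic single-allele motif presets (A and B/C alleles)."""

    def lw(d):  # normalize a length-weight table
        t = sum(d.values())
        return {k: v / t for k, v in d.items()}

    return {
        "A*02:01": AlleleMotifSpec(
            allele="A*02:01",
            length_weights=lw({8: 0.20, 9: 0.50, 10: 0.15, 11: 0.07, 12: 0.04, 13: 0.02, 14: 0.02}),
            anchors={2: {"L": 0.6, "M": 0.4}, -1: {"V": 0.6, "L": 0.4}},
            p1_shift_fraction=0.15,
            mid_glycine_boost=3.0,
        ),
        "A*03:01": AlleleMotifSpec(
            allele="A*03:01",
            length_weights=lw({8: 0.12, 9: 0.48, 10: 0.18, 11: 0.10, 12: 0.06, 13: 0.03, 14: 0.03}),
            anchors={2: {"L": 0.55, "I": 0.45}, -1: {"K": 0.55, "R": 0.45}},
            p1_shift_fraction=0.15,
            mid_glycine_boost=3.0,
        ),
        "A*11:01": AlleleMotifSpec(
            allele="A*11:01",
            length_weights=lw({8: 0.05, 9: 0.35, 10: 0.25, 11: 0.15, 12: 0.10, 13: 0.06, 14: 0.04}),
            anchors={2: {"T": 0.55, "S": 0.45}, -1: {"K": 1.0}},
            p1_shift_fraction=0.10,
            mid_glycine_boost=3.0,
        ),
        "A*24:02": AlleleMotifSpec(
            allele="A*24:02",
            length_weights=lw({8: 0.15, 9: 0.45, 10: 0.20, 11: 0.10, 12: 0.05, 13: 0.03, 14: 0.02}),
            anchors={2: {"Y": 1.0}, -1: {"F": 0.55, "L": 0.45}},
            p1_shift_fraction=0.30,
            mid_glycine_boost=3.0,
        ),
        "B*07:02": AlleleMotifSpec(
            allele="B*07:02",
            length_weights=lw({8: 0.18, 9: 0.50, 10: 0.16, 11: 0.08, 12: 0.04, 13: 0.02, 14: 0.02}),
            anchors={2: {"P": 1.0}, -1: {"L": 0.5, "F": 0.5}},
            p1_shift_fraction=0.10,
            mid_glycine_boost=3.0,
        ),
        "C*07:02": AlleleMotifSpec(
            allele="C*07:02",
            length_weights=lw({8: 0.30, 9: 0.50, 10: 0.12, 11: 0.05, 12: 0.02, 13: 0.005, 14: 0.005}),
            anchors={2: {"Y": 0.6, "F": 0.4}, -1: {"Y": 0.5, "F": 0.5}},
            p1_shift_fraction=0.10,
            mid_glycine_boost=3.0,
        ),
    }


def _retention_time(seq: str, rt_model: RtModel, rng: np.random.Generator) -> float:
    kd = sum(rt_model.scale[c] for c in seq)
    return max(0.0, rt_model.intercept + rt_model.slope * kd + rng.normal(0, rt_model.noise_sd))


def sample_ligandome(
    spec: AlleleMotifSpec, config: SimulationConfig, run_id: str = "run1"
) -> tuple[PeptideSet, GroundTruth]:
    """Draw a synthetic single-allele ligandome. Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    lengths = sorted(spec.length_weights)
    lw = np.array([spec.length_weights[L] for L in lengths])
    tables = {L: spec.position_probs(L) for L in lengths}
    shifted_tables = {
        L: spec.position_probs(L, p1_shifted=True) for L in lengths if L == 8
    }
    aa = np.array(list(AMINO_ACIDS))
    records: list[PeptideRecord] = []
    truth = GroundTruth()
    for L in lengths:
        truth.anchor_positions[L] = {
            pos: set(table) for pos, table in spec.anchor_positions(L).items()
        }
    drawn = rng.choice(len(lengths), size=config.n_peptides, p=lw)
    for k in range(config.n_peptides):
        L = lengths[drawn[k]]
        table = tables[L]
        if L == 8 and spec.p1_shift_fraction > 0 and rng.random() < spec.p1_shift_fraction:
            table = shifted_tables[L]
        idx = [rng.choice(N_AA, p=table[i]) for i in range(L)]
        seq = "".join(aa[idx])
        rt = _retention_time(seq, config.rt_model, rng)
        records.append(
            PeptideRecord(
                sequence=seq,
                retention_time=rt,
                fdr_tier="q01",
                source_accession=f"HOST_{int(rng.integers(1, 51)):03d}",
                run_id=run_id,
                allele=spec.allele,
            )
        )
        truth.labels.setdefault(seq, MOTIF_PEPTIDE)
    pset = PeptideSet(
        name=f"{spec.allele}-{run_id}", allele=spec.allele,
        replicate_kind="experimental", records=records,
    )
    return pset, truth


def inject_truncations(
    pset: PeptideSet, rate: float, jitter_s: float, seed: int = 0
) -> tuple[PeptideSet, GroundTruth]:
    """Append co-eluting truncated copies of a fraction of the peptides.

    Each selected parent gains an N- or C-terminally truncated copy (1-3
    residues shorter) whose retention time is offset from the parent by a
    magnitude drawn uniformly between ``jitter_s / 2`` and ``jitter_s``
    (random sign), i.e. always within ``jitter_s`` seconds of the parent.
    Truncations colliding with sequences already in the set are skipped so
    the planted artifacts stay unambiguous.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if jitter_s < 0:
        raise ValueError("jitter_s must be nonnegative")
    rng = np.random.default_rng(seed)
    existing = {r.sequence for r in pset.records}
    n_parents = int(round(rate * len(pset.records)))
    order = rng.permutation(len(pset.records))
    truth = GroundTruth()
    new_records: list[PeptideRecord] = list(pset.records)
    made = 0
    for i in order:
        if made >= n_parents:
            break
        parent = pset.records[i]
        if parent.retention_time is None or parent.length < 6:
            continue
        produced = None
        for _ in range(6):  # try a few truncation choices before giving up
            k = int(rng.integers(1, min(3, parent.length - 5) + 1))
            n_term = bool(rng.integers(0, 2))
            seq = parent.sequence[k:] if n_term else parent.sequence[:-k]
            if seq not in existing:
                produced = seq
                break
        if produced is None:
            continue
        delta = float(rng.uniform(jitter_s / 2, jitter_s)) * (1 if rng.integers(0, 2) else -1)
        rec = dataclasses.replace(
            parent,
            sequence=produced,
            retention_time=max(0.0, parent.retention_time + delta),
            modifications=(),
        )
        new_records.append(rec)
        existing.add(produced)
        truth.labels[produced] = TRUNCATION_ARTIFACT
        truth.parents[produced] = parent.sequence
        made += 1
    return pset.replace_records(new_records), truth


def inject_contaminants(
    pset: PeptideSet,
    fraction: float,
    contaminant_accessions: list[str],
    seed: int = 0,
) -> tuple[PeptideSet, GroundTruth]:
    """Append motif-non-compliant peptides sourced to contaminant proteins.

    Sequences are drawn position-independently from the UniProt background
    composition, so their relative-entropy logo is flat.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = BackgroundFrequencies.uniprot().as_array()
    aa = np.array(list(AMINO_ACIDS))
    accs = sorted(contaminant_accessions)
    n = int(round(fraction * len(pset.records)))
    existing = {r.sequence for r in pset.records}
    truth = GroundTruth()
    new_records = list(pset.records)
    rts = [r.retention_time for r in pset.records if r.retention_time is not None]
    lo, hi = (min(rts), max(rts)) if rts else (600.0, 5000.0)
    run_id = pset.records[0].run_id if pset.records else "run1"
    made = 0
    while made < n:
        L = int(rng.integers(8, 15))
        seq = "".join(aa[rng.choice(N_AA, p=bg, size=L)])
        if seq in existing:
            continue
        new_records.append(
            PeptideRecord(
                sequence=seq,
                retention_time=float(rng.uniform(lo, hi)),
                fdr_tier="q01",
                source_accession=accs[int(rng.integers(0, len(accs)))],
                run_id=run_id,
                allele=pset.allele,
            )
        )
        existing.add(seq)
        truth.labels[seq] = CONTAMINANT
        made += 1
    return pset.replace_records(new_records), truth


def make_replicates(
    base: PeptideSet,
    model: ReplicateModel,
    k_runs: int,
    seed: int = 0,
    spec: AlleleMotifSpec | None = None,
    rt_model: RtModel | None = None,
) -> list[PeptideSet]:
    """Simulate replicate runs of a base ligandome.

    Experimental replicates: each run independently detects each base
    peptide with probability ``detection_p`` (repeat injections of one
    eluate). Biological replicates: each run first resamples the underlying
    ligandome — keeping each peptide with probability ``resample_keep`` and
    replacing the dropped ones with fresh draws from ``spec`` — and then
    applies detection (independent preparations of a dynamic ligandome).
    """
    if k_runs < 2:
        raise ValueError("k_runs must be >= 2")
    if model.kind == "biological" and spec is None:
        raise ValueError("biological replicates need an AlleleMotifSpec to draw novel peptides")
    rng = np.random.default_rng(seed)
    rt_model = rt_model or RtModel()
    runs: list[PeptideSet] = []
    base_records = [r for r in base.active_records]
    aa = np.array(list(AMINO_ACIDS))
    for k in range(k_runs):
        run_id = f"{base.name or 'base'}-rep{k + 1}"
        if model.kind == "experimental":
            pool = base_records
        else:
            keep = rng.random(len(base_records)) < model.resample_keep
            pool = [r for r, kf in zip(base_records, keep) if kf]
            n_new = len(base_records) - len(pool)
            lengths = sorted(spec.length_weights)
            lw = np.array([spec.length_weights[L] for L in lengths])
            tables = {L: spec.position_probs(L) for L in lengths}
            existing = {r.sequence for r in base_records}
            while n_new > 0:
                L = lengths[int(rng.choice(len(lengths), p=lw))]
                idx = [rng.choice(N_AA, p=tables[L][i]) for i in range(L)]
                seq = "".join(aa[idx])
                if seq in existing:
                    continue
                pool = pool + [
                    PeptideRecord(
                        sequence=seq,
                        retention_time=_retention_time(seq, rt_model, rng),
                        fdr_tier="q01",
                        source_accession="HOST_NEW",
                        run_id=run_id,
                        allele=base.allele,
                    )
                ]
                existing.add(seq)
                n_new -= 1
        detected = rng.random(len(pool)) < model.detection_p
        records = [
            dataclasses.replace(r, run_id=run_id)
            for r, d in zip(pool, detected)
            if d
        ]
        runs.append(
            PeptideSet(
                name=run_id,
                allele=base.allele,
                replicate_kind=model.kind,
                records=records,
            )
        )
    return runs
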