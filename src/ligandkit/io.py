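"""Reading and writing ligandome data.

Peptide identification tables (delimited text), protein sequences (FASTA),
contaminant accession lists, binder-class annotations and GO-compartment maps
are all consumed here and turned into the in-memory types the analysis
modules operate on.

Peptide identity throughout the package is the bare amino-acid sequence:
modifications are carried as annotations on a record but never split set
identities, because all dataset comparisons count unique peptide sequences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

FDR_TIERS = ("q01", "q05")
BINDER_CLASSES = ("strong", "weak", "non")

#: GO cellular-compartment labels used by compartment profiles.
COMPARTMENTS = (
    "Nucleus",
    "Mitochondrion",
    "ER",
    "Golgi",
    "Cytosol",
    "Membrane",
    "Extracellular",
    "unmapped",
)


class TableFormatError(ValueError):
    """Raised when an input table cannot be interpreted."""


@dataclass(frozen=True)
class Modification:
    """A localized modification on a peptide.

    position is 1-based within the peptide; site_probability is the search
    engine's localization probability in [0, 1]; mass_shift is in Daltons.
    """

    position: int
    type: str
    site_probability: float = 1.0
    mass_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.site_probability <= 1.0:
            raise ValueError(
                f"site_probability must be in [0, 1], got {self.site_probability}"
            )


@dataclass
class PeptideRecord:
    """One identified peptide observation."""

    sequence: str
    retention_time: float | None = None  # seconds
    fdr_tier: str = "q01"
    modifications: tuple[Modification, ...] = ()
    source_accession: str = ""
    run_id: str = ""
    allele: str = ""
    culled: str | None = None  # reason ("crapome", "nested", ...) or None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"non-canonical residues {sorted(bad)} in sequence {self.sequence!r}"
            )
        if self.fdr_tier not in FDR_TIERS:
            raise ValueError(f"fdr_tier must be one of {FDR_TIERS}, got {self.fdr_tier!r}")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError("retention_time must be nonnegative")
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.sequence):
                raise ValueError(
                    f"modification position {mod.position} outside peptide "
                    f"{self.sequence!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSet:
    """A named collection of peptide records with replicate/allele metadata.

    ``unique_sequences`` is the deduplicated projection of the non-culled
    records onto their sequences; it is the identity domain for every set
    operation in the package.
    """

    name: str = ""
    allele: str = "pan"
    replicate_kind: str = "experimental"  # experimental | biological | union | external
    records: list[PeptideRecord] = field(default_factory=list)

    @property
    def active_records(self) -> list[PeptideRecord]:
        """Records not flagged as culled (the default analysis view)."""
        return [r for r in self.records if r.culled is None]

    @property
    def unique_sequences(self) -> set[str]:
        return {r.sequence for r in self.active_records}

    def __len__(self) -> int:
        return len(self.records)

    def sequences_of_length(self, length: int) -> list[str]:
        """Sorted unique non-culled sequences of exactly ``length`` residues."""
        return sorted(s for s in self.unique_sequences if len(s) == length)

    def replace_records(self, records: Iterable[PeptideRecord], **meta) -> "PeptideSet":
        out = dataclasses.replace(self, records=list(records))
        for key, val in meta.items():
            setattr(out, key, val)
        return out


@dataclass
class ProteinRecord:
    """A protein sequence with optional region features (1-based inclusive)."""

    accession: str
    sequence: str
    features: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for kind, start, end, label in self.features:
            if not 1 <= start <= end <= len(self.sequence):
                raise ValueError(
                    f"feature {label!r} [{start}..{end}] outside protein "
                    f"{self.accession} (length {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BinderAnnotation:
    """Externally produced binder-class call for a (peptide, allele) pair."""

    sequence: str
    allele: str
    binder_class: str

    def __post_init__(self) -> None:
        if self.binder_class not in BINDER_CLASSES:
            raise ValueError(
                f"binder_class must be one of {BINDER_CLASSES}, got {self.binder_class!r}"
            )


@dataclass
class TableDialect:
    """Column mapping for a peptide table.

    ``rt_unit`` may be "s" or "min"; minutes are converted to seconds on
    read, since the nested-peptide culling window is expressed in seconds.
    """

    sep: str = "\t"
    sequence: str = "sequence"
    retention_time: str | None = "retention_time"
    fdr_tier: str | None = "fdr_tier"
    source_accession: str | None = "source_accession"
    run_id: str | None = "run_id"
    allele: str | None = "allele"
    modifications: str | None = "modifications"
    culled: str | None = "culled"
    rt_unit: str = "s"


@dataclass
class RowRejection:
    line_number: int
    reason: str


def _parse_modifications(text: str) -> tuple[Modification, ...]:
    """Parse ``pos:type:prob:shift`` triplets separated by ';'."""
    mods = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) < 2:
            raise ValueError(f"unparseable modification {chunk!r}")
        pos = int(parts[0])
        mtype = parts[1]
        prob = float(parts[2]) if len(parts) > 2 and parts[2] != "" else 1.0
        shift = float(parts[3]) if len(parts) > 3 and parts[3] != "" else 0.0
        mods.append(Modification(pos, mtype, prob, shift))
    return tuple(mods)


def _format_modifications(mods: Sequence[Modification]) -> str:
    return ";".join(
        f"{m.position}:{m.type}:{m.site_probability:g}:{m.mass_shift:g}" for m in mods
    )


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    name: str = "",
    allele: str = "pan",
    replicate_kind: str = "external",
) -> PeptideSet:
    """Read a delimited peptide table into a :class:`PeptideSet`.

    Rows whose sequence contains non-canonical residues, or whose numeric
    fields cannot be parsed, are rejected rather than fatal; the rejections
    (with 1-based data line numbers) are attached to the returned set as
    ``.rejections``. Missing retention times are allowed — such records are
    simply never evaluated by retention-time-based filters.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.sep, comment="#", dtype=str, keep_default_na=False)
    if dialect.sequence not in df.columns:
        raise TableFormatError(
            f"{path}: no sequence column {dialect.sequence!r} (columns: {list(df.columns)})"
        )

    def col(row, colname):
        if colname is None or colname not in df.columns:
            return None
        val = row[colname]
        return None if val == "" else val

    records: list[PeptideRecord] = []
    rejections: list[RowRejection] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            rt = col(row, dialect.retention_time)
            rt = None if rt is None else float(rt)
            if rt is not None and dialect.rt_unit == "min":
                rt *= 60.0
            mods_text = col(row, dialect.modifications)
            rec = PeptideRecord(
                sequence=row[dialect.sequence],
                retention_time=rt,
                fdr_tier=col(row, dialect.fdr_tier) or "q01",
                modifications=_parse_modifications(mods_text) if mods_text else (),
                source_accession=col(row, dialect.source_accession) or "",
                run_id=col(row, dialect.run_id) or "",
                allele=col(row, dialect.allele) or "",
                culled=col(row, dialect.culled),
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(i, str(exc)))
            continue
        records.append(rec)
    out = PeptideSet(
        name=name or path.stem, allele=allele, replicate_kind=replicate_kind, records=records
    )
    out.rejections = rejections  # type: ignore[attr-defined]
    return out


def write_peptide_table(pset: PeptideSet, path: str | Path, header_comment: str | None = None) -> None:
    """Write a peptide table (TSV) with deterministic row order.

    Rows are sorted by sequence then run id; retention times are written to
    0.1 s. Culled records are retained, with the culling reason in the
    ``culled`` column (mirroring the convention of marking, not deleting,
    contaminant-derived peptides).
    """
    rows = []
    for r in sorted(pset.records, key=lambda r: (r.sequence, r.run_id)):
        rows.append(
            {
                "sequence": r.sequence,
                "retention_time": "" if r.retention_time is None else f"{r.retention_time:.1f}",
                "fdr_tier": r.fdr_tier,
                "modifications": _format_modifications(r.modifications),
                "source_accession": r.source_accession,
                "run_id": r.run_id,
                "allele": r.allele,
                "culled": r.culled or "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "retention_time",
            "fdr_tier",
            "modifications",
            "source_accession",
            "run_id",
            "allele",
            "culled",
        ],
    )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fasta(path: str | Path, features: Mapping[str, list] | None = None) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The accession is the first whitespace-delimited token of the header.
    Duplicate accessions are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        feats = list(features.get(acc, [])) if features else []
        out.append(ProteinRecord(accession=acc, sequence=str(rec.seq), features=feats))
    return out


def read_features_table(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a region-feature table (kind, start, end, label; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (str(r.kind), int(r.start), int(r.end), str(r.label)) for r in df.itertuples(index=False)
    ]


def read_accession_list(path: str | Path) -> set[str]:
    """Read a contaminant accession list: one accession per line, '#' comments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return out


_CLASS_ALIASES = {
    "strong": "strong",
    "sb": "strong",
    "strong binder": "strong",
    "weak": "weak",
    "wb": "weak",
    "weak binder": "weak",
    "non": "non",
    "nb": "non",
    "non-binder": "non",
    "nonbinder": "non",
    "non binder": "non",
}


def read_binder_annotations(path: str | Path) -> list[BinderAnnotation]:
    """Read (sequence, allele, class) binder annotations.

    Class labels are normalized to strong/weak/non. A duplicated
    (sequence, allele) pair with a conflicting class is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: list[BinderAnnotation] = []
    seen: dict[tuple[str, str], str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        seq, allele, cls = str(row[0]).upper(), str(row[1]), str(row[2]).strip().lower()
        if cls not in _CLASS_ALIASES:
            raise ValueError(f"row {i}: unknown binder class {cls!r}")
        cls = _CLASS_ALIASES[cls]
        key = (seq, allele)
        if key in seen:
            if seen[key] != cls:
                raise ValueError(
                    f"row {i}: conflicting class for {seq}/{allele}: {seen[key]} vs {cls}"
                )
            continue
        seen[key] = cls
        out.append(BinderAnnotation(seq, allele, cls))
    return out


def read_compartment_map(path: str | Path) -> dict[str, str]:
    """Read a source-accession -> GO-compartment label mapping (TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}
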