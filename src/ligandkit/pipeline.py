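"""End-to-end pipeline: filter, compare, motif, converge, map.

A declarative configuration drives the stages; every output file carries a
provenance header (tool version, config hash, seed) and all randomness is
funneled through the single recorded seed, so re-running an identical
configuration reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .convergence import convergence_curve, default_grid, self_convergence_curve
from .filtering import apply_filters
from .io import (
    PeptideSet,
    TableDialect,
    read_accession_list,
    read_fasta,
    read_features_table,
    read_peptide_table,
    write_peptide_table,
)
from .mapping import coverage, find_sequons, place_peptides
from .motif import BackgroundFrequencies, build_pfm, length_distribution, logo_heights
from .overlap import overlap_percentage, pairwise_overlap_table, venn2, accumulation_curve
from .svg import convergence_svg, logo_svg, venn2_svg

log = logging.getLogger("ligandkit.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    peptide_tables: list[str] = field(default_factory=list)
    out_dir: str = "ligandkit_out"
    seed: int = 0
    fdr_tier: str = "q05"
    min_len: int = 8
    max_len: int = 14
    rt_window_s: float = 30.0
    contaminant_list: str | None = None
    background_path: str | None = None
    logo_length: int = 9
    converge_resamples: int = 100
    protein_fasta: str | None = None
    protein_features: str | None = None
    run_overlap: bool = False
    run_motif: bool = False
    run_converge: bool = False
    run_map: bool = False
    rt_unit: str = "s"
    table_sep: str = "\t"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for p in self.peptide_tables:
            if not Path(p).exists():
                raise PipelineError("validate", f"peptide table not found: {p}")
        for name in ("contaminant_list", "background_path", "protein_fasta", "protein_features"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{name} not found: {p}")
        if not self.peptide_tables:
            raise PipelineError("validate", "no peptide tables given")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return (
        f"ligandkit {__version__} | config {config.config_hash()} | seed {config.seed}"
    )


def _write_text(path: Path, text: str, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a summary report dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    report: dict = {"provenance": prov, "stages": {}}
    dialect = TableDialect(sep=config.table_sep, rt_unit=config.rt_unit)

    t0 = time.time()
    contaminants = (
        read_accession_list(config.contaminant_list) if config.contaminant_list else None
    )
    filtered: list[PeptideSet] = []
    for path in config.peptide_tables:
        pset = read_peptide_table(path, dialect)
        kept, frep = apply_filters(
            pset,
            fdr_tier=config.fdr_tier,
            min_len=config.min_len,
            max_len=config.max_len,
            contaminant_accessions=contaminants,
            rt_window_s=config.rt_window_s,
        )
        for seq, parent, drt in frep.witnesses:
            log.debug("culled nested %s (parent %s, |dRT| %.1f s)", seq, parent, drt)
        filtered.append(kept)
        write_peptide_table(kept, out_dir / f"filtered_{kept.name}.tsv", header_comment=prov)
        report["stages"].setdefault("filter", {})[kept.name] = dataclasses.asdict(frep)
    log.info("filter stage: %d tables in %.2f s", len(filtered), time.time() - t0)

    if config.run_overlap:
        t0 = time.time()
        if len(filtered) < 2:
            raise PipelineError("overlap", "need at least two peptide tables")
        v = venn2(filtered[0], filtered[1])
        venn = {
            "a1": v.a1, "a2": v.a2, "a3": v.a3,
            "overlap_percentage": overlap_percentage(v),
        }
        _write_text(out_dir / "venn2.json", json.dumps(venn, indent=1), prov)
        _write_text(
            out_dir / "venn2.svg", venn2_svg(v, filtered[0].name, filtered[1].name)
        )
        if len(filtered) >= 2:
            table = pairwise_overlap_table(filtered)
            rows = [
                {"length_bin": bin_, "mean_overlap_pct": mat.off_diagonal_mean}
                for bin_, mat in table.items()
            ]
            pd.DataFrame(rows).to_csv(out_dir / "overlap_means.tsv", sep="\t", index=False)
            acc = accumulation_curve(filtered)
            pd.DataFrame({"run": acc.order, "union_size": acc.union_sizes}).to_csv(
                out_dir / "accumulation.tsv", sep="\t", index=False
            )
        report["stages"]["overlap"] = venn
        log.info("overlap stage in %.2f s", time.time() - t0)

    if config.run_motif:
        t0 = time.time()
        bg = (
            BackgroundFrequencies.from_tsv(config.background_path)
            if config.background_path
            else BackgroundFrequencies.uniprot()
        )
        pset = filtered[0]
        try:
            pfm = build_pfm(pset, config.logo_length)
        except ValueError as exc:
            raise PipelineError("motif", str(exc)) from exc
        logo = logo_heights(pfm, bg)
        logo.to_frame().to_csv(out_dir / f"logo_{config.logo_length}mer.tsv", sep="\t")
        _write_text(out_dir / f"logo_{config.logo_length}mer.svg", logo_svg(logo))
        counts, mean_len = length_distribution(pset)
        pd.DataFrame(
            {"length": list(counts), "count": list(counts.values())}
        ).to_csv(out_dir / "length_distribution.tsv", sep="\t", index=False)
        report["stages"]["motif"] = {
            "n_peptides": pfm.n_peptides,
            "mean_length": mean_len,
            "per_position_bits": [float(x) for x in logo.per_position_total],
        }
        log.info("motif stage in %.2f s", time.time() - t0)

    if config.run_converge:
        t0 = time.time()
        a = filtered[0]
        n = len(a.sequences_of_length(config.logo_length))
        if n < 5:
            raise PipelineError("converge", f"too few {config.logo_length}-mers ({n})")
        grid = default_grid(n)
        if len(filtered) >= 2:
            curve = convergence_curve(
                a, filtered[1], config.logo_length, grid,
                resamples=config.converge_resamples, seed=config.seed,
            )
        else:
            curve = self_convergence_curve(
                a, config.logo_length, grid,
                resamples=config.converge_resamples, seed=config.seed,
            )
        df = pd.DataFrame(
            curve.values, columns=[f"P{i}" for i in curve.positions]
        )
        df.insert(0, "n_a", curve.n_grid)
        df.to_csv(out_dir / "convergence.tsv", sep="\t", index=False)
        _write_text(out_dir / "convergence.svg", convergence_svg(curve))
        report["stages"]["converge"] = {
            "final": [float(x) for x in curve.values[-1]],
        }
        log.info("converge stage in %.2f s", time.time() - t0)

    if config.run_map:
        t0 = time.time()
        if not config.protein_fasta:
            raise PipelineError("map", "protein_fasta required for the map stage")
        protein = read_fasta(config.protein_fasta)[0]
        if config.protein_features:
            protein.features = read_features_table(config.protein_features)
        union = PeptideSet(
            name="union",
            records=[r for ps in filtered for r in ps.active_records],
        )
        placements, unplaced = place_peptides(union, protein)
        cov = coverage(placements, protein)
        sequons = find_sequons(protein)
        pd.DataFrame(
            [
                {
                    "peptide": p.peptide, "start": p.start, "end": p.end,
                    "allele": p.allele, "occurrences": p.occurrences,
                }
                for p in placements
            ]
        ).to_csv(out_dir / "placements.tsv", sep="\t", index=False)
        cov_json = {
            "protein": cov.protein_accession,
            "coverage_fraction": cov.coverage_fraction,
            "per_region": cov.per_region_coverage,
            "n_placed": len({p.peptide for p in placements}),
            "n_unplaced": len(unplaced),
            "sequons": [{"position": s.position, "triplet": s.triplet} for s in sequons],
        }
        _write_text(out_dir / "coverage.json", json.dumps(cov_json, indent=1), prov)
        report["stages"]["map"] = cov_json
        log.info("map stage in %.2f s", time.time() - t0)

    _write_text(out_dir / "report.json", json.dumps(report, indent=1))
    return report
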