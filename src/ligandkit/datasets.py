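"""Accessors for the small reference datasets bundled with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import (
    PeptideRecord,
    PeptideSet,
    ProteinRecord,
    read_fasta,
    read_features_table,
)


def _data_path(name: str):
    return resources.as_file(resources.files("ligandkit.data") / name)


def load_msln_protein(with_features: bool = True) -> ProteinRecord:
    """The MSLN precursor (MPF+MSLN proprotein, AAV87530.1 numbering).

    622 residues; region features cover the leader peptide, the furin
    cleavage site separating the MPF and MSLN moieties, and the GPI signal.
    """
    with _data_path("msln_aav87530_1.fasta") as p:
        protein = read_fasta(p)[0]
    if with_features:
        with _data_path("msln_features.tsv") as p:
            protein.features = read_features_table(p)
    return protein


def load_msln_target_peptides() -> PeptideSet:
    """The published MPF/MSLN target-protein peptides with allele labels.

    68 unique peptides recovered with the A*02:01, A*11:01 and A*24:02
    capture reagents; the ``note`` column distinguishes previously reported
    peptides and peptides from the MPF moiety.
    """
    with _data_path("msln_table2_peptides.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    records = [
        PeptideRecord(
            sequence=row.sequence,
            allele=row.allele,
            source_accession="AAV87530.1",
            run_id="published",
        )
        for row in df.itertuples(index=False)
    ]
    return PeptideSet(
        name="msln_target_peptides",
        allele="pan",
        replicate_kind="external",
        records=records,
    )
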