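"""Tab-separated and FASTA input/output for the screen's tables.

Cohort tables are TSV with the clinical block (sample_id, time_months,
event, stage, histology, her2, treatment) followed by one column per
gene.  Paired expression tables are TSV (pair_id, normal, tumor).
Promoters are plain FASTA, read and written through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifSpec
from .simulate import CLINICAL_COLUMNS

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_paired",
    "write_paired",
    "read_fasta",
    "write_fasta",
    "read_motif_specs",
    "write_table",
]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV and validate the clinical block."""
    cohort = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required columns: {missing}")
    for label in ("stage", "histology", "her2", "treatment"):
        cohort[label] = cohort[label].astype(str)
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    write_table(cohort, path)


def read_paired(path) -> pd.DataFrame:
    paired = pd.read_csv(path, sep="\t")
    missing = [c for c in ("normal", "tumor") if c not in paired.columns]
    if missing:
        raise ValueError(f"paired table {path} lacks required columns: {missing}")
    return paired


def write_paired(paired: pd.DataFrame, path) -> None:
    write_table(paired, path)


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_motif_specs(path) -> list[MotifSpec]:
    """Motif spec TSV: columns name, pattern, and optionally strands
    ('both' or 'forward', default both)."""
    table = pd.read_csv(path, sep="\t")
    for col in ("name", "pattern"):
        if col not in table.columns:
            raise ValueError(f"motif table {path} lacks required column {col!r}")
    specs = []
    for _, row in table.iterrows():
        strands = str(row.get("strands", "both")).lower()
        specs.append(
            MotifSpec(str(row["name"]), str(row["pattern"]), both_strands=strands != "forward")
        )
    return specs


def km_curve_frame(curve, group: str) -> pd.DataFrame:
    """Flatten a KM curve into the TSV layout (time, survival, at_risk,
    events, group)."""
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "group": group,
        }
    )


def cohort_gene_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in CLINICAL_COLUMNS]


def ensure_parent(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
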