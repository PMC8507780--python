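"""Readers and writers for the plain-text formats used throughout the pipeline.

All tabular data are tab-separated with a header row.  Absent intensities
(one-channel detections, identification-only rows) are written as empty
fields and read back as NaN.  Reference proteomes are FASTA; gene sets are
GMT; contaminant and known-interactor lists are one accession per line.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PEPTIDE_COLUMNS = [
    "peptide", "proteins", "n_kr", "replicate",
    "intensity_L", "intensity_H", "id_fdr",
]
PROTEIN_COLUMNS = [
    "protein", "gene", "replicate",
    "intensity_L", "intensity_H", "unique_peptides", "id_fdr",
]
QUANT_COLUMNS = ["ratio_hl", "log2_ratio", "capped", "p_value", "n_reps"]


def read_peptide_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a peptide-level SILAC intensity table (long format)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def write_peptide_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="",
              columns=[c for c in PEPTIDE_COLUMNS if c in df.columns])


def read_protein_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a proteome or interactome intensity table (long format)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "gene": str})
    missing = set(PROTEIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protein table missing columns: {sorted(missing)}")
    return df


def write_protein_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="",
              columns=[c for c in PROTEIN_COLUMNS if c in df.columns])


def write_quant_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_quant_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA proteome into an accession -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteins: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="")
               for acc, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def read_accession_list(path: str | os.PathLike) -> list[str]:
    """One accession per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_accession_list(items: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")


def read_peptide_list(path: str | os.PathLike) -> list[str]:
    """Plain epitope list: one peptide per line."""
    return read_accession_list(path)


def read_gmt(path: str | os.PathLike) -> dict[str, dict]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = [g for g in parts[2:] if g]
            sets[parts[0]] = {"description": parts[1], "genes": genes}
    return sets


def write_gmt(sets: Mapping[str, dict], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, entry in sets.items():
            genes = "\t".join(entry["genes"])
            fh.write(f"{name}\t{entry.get('description', '')}\t{genes}\n")


def read_directions(path: str | os.PathLike) -> pd.DataFrame:
    """Direction annotations: columns set, gene, direction (+1/-1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"set", "gene", "direction"} - set(df.columns)
    if missing:
        raise ValueError(f"direction table missing columns: {sorted(missing)}")
    return df


def write_directions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_pwm(freq: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialize a PWM frequency matrix: residue rows, position columns."""
    freq.to_csv(path, sep="\t", index_label="residue")


def read_pwm(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="residue")
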