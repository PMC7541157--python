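"""Readers and writers for the flat-file interfaces between pipeline stages.

All tabular files are plain TSV; promoter sequences travel as FASTA with
headers ``>gene|chrom|tss|strand``; gene sets use the three-column GMT
convention (set name, description, member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ValidationError

MANIFEST_COLUMNS = ["probe_id", "gene", "chrom", "position", "strand", "tss"]
CLINICAL_COLUMNS = [
    "sample", "age", "site", "stage", "breslow_mm", "ulcer",
    "braf_mut", "nras_mut", "os_days", "os_event",
]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")


def read_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MANIFEST_COLUMNS, f"manifest {path}")
    if df["probe_id"].duplicated().any():
        raise ValidationError(f"manifest {path} contains duplicate probe ids")
    if (df["position"] < 1).any() or (df["tss"] < 1).any():
        raise ValidationError(f"manifest {path} has non-positive coordinates")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"manifest {path} strand must be '+' or '-'")
    return df


def write_manifest(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_promoter_fasta(path: Path) -> Dict[str, str]:
    """Return gene -> promoter sequence (header ``gene|chrom|tss|strand``)."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id.split("|")[0]
        seqs[gene] = str(rec.seq).upper()
    if not seqs:
        raise ValidationError(f"no FASTA records in {path}")
    return seqs


def write_promoter_fasta(records: Mapping[str, dict], path: Path) -> None:
    """``records`` maps gene -> {'seq', 'chrom', 'tss', 'strand'}."""
    out = []
    for gene, rec in records.items():
        header = f"{gene}|{rec['chrom']}|{rec['tss']}|{rec['strand']}"
        out.append(SeqRecord(Seq(rec["seq"]), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_beta_matrix(path: Path) -> pd.DataFrame:
    """Probes x samples beta matrix; first column holds probe ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"beta matrix {path} contains missing values")
    if ((df.values < 0) | (df.values > 1)).any():
        raise ValidationError(f"beta matrix {path} has values outside [0, 1]")
    return df


def write_beta_matrix(df: pd.DataFrame, path: Path) -> None:
    df.round(4).to_csv(path, sep="\t", index_label="probe_id")


def read_calibration(path: Path) -> pd.DataFrame:
    """Long-format calibration table: probe_id, expected_fraction, measured_beta."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["probe_id", "expected_fraction", "measured_beta"], f"calibration {path}"
    )
    return df


def write_calibration(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_clinical(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CLINICAL_COLUMNS, f"clinical table {path}")
    return df


def write_clinical(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_gmt(path: Path) -> Dict[str, set]:
    """Parse a GMT file into {set name: set of gene symbols}."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    if not sets:
        raise ValidationError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_truth(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
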