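"""Plain-text table I/O: TSV readers/writers for the study tables, ground
truth JSON, and exports. All floats are written with a fixed %.10g format
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, StudyTables

__all__ = [
    "read_numeric_table",
    "write_table",
    "write_study_tables",
    "read_study_tables",
    "write_ground_truth",
    "read_ground_truth",
]

# pandas' default float formatting is the shortest exact repr: values
# round-trip bit-for-bit and identical runs write identical bytes
FLOAT_FMT = None


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_numeric_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV/CSV of numbers, reporting the exact cell on failure."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=index_col, dtype=str)
    out = {}
    for col in raw.columns:
        try:
            out[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            for row, cell in raw[col].items():
                if cell is not None and not _is_number(cell):
                    raise ValueError(
                        f"{path}: malformed numeric cell at row {row!r}, column {col!r}: {cell!r}"
                    ) from None
            raise
    return pd.DataFrame(out, index=raw.index)


def _is_number(s: str) -> bool:
    if s == "" or s.lower() in ("nan", "na"):
        return True
    try:
        float(s)
        return True
    except ValueError:
        return False


_FILES = {
    "metadata": "metadata.tsv",
    "physio": "physio.tsv",
    "metabolites": "metabolites.tsv",
    "taxa_relabund": "taxa_relabund.tsv",
    "taxa_counts": "taxa_counts.tsv",
}


def write_study_tables(tables: StudyTables, outdir: str | Path) -> None:
    """Write one cohort as five TSV tables plus the taxonomy map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        write_table(getattr(tables, attr), outdir / fname)
    tables.taxonomy.rename_axis("species").to_csv(outdir / "taxonomy.tsv", sep="\t")


def read_study_tables(indir: str | Path) -> StudyTables:
    """Read a cohort written by :func:`write_study_tables` (or assembled by
    hand in the same layout). Sample alignment is validated on construction."""
    indir = Path(indir)
    frames = {attr: read_numeric_table(indir / fname) for attr, fname in _FILES.items()}
    taxonomy = pd.read_csv(indir / "taxonomy.tsv", sep="\t", index_col=0)["genus"]
    counts = frames["taxa_counts"]
    frames["taxa_counts"] = counts.astype(np.int64)
    frames["metadata"] = frames["metadata"].astype({"aging_year": np.int64})
    return StudyTables(taxonomy=taxonomy, **frames)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
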