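"""Reading and writing the tab-separated tables the scoring pipeline touches.

All tables are UTF-8 tab-separated text with a header row.  Spectral-count
tables come in three dialects, selected explicitly (never sniffed):

``long``
    columns ``protein_id``, ``assay_id``, ``count``; one row per observed
    (protein, assay) cell.  Cells absent from the file are zeros.
``wide``
    column ``protein_id`` plus one column per assay; every cell present,
    zeros retained.
``peptide``
    columns ``peptide_id``, ``protein_id``, ``assay_id``, ``count``; peptide
    rows are summed per (protein, assay) before validation, which is the
    per-protein aggregation step of spectral counting.

Protein and assay identifiers are treated as case-sensitive strings and are
whitespace-trimmed on read (MS exports commonly pad fields).  Counts are
opaque non-negative integers — whether they are unique-peptide counts or
PSMs is upstream of this package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CountTable",
    "DETable",
    "PhaseAnnotation",
    "InteractorCall",
    "PHASES",
    "read_count_table",
    "read_lengths",
    "read_de_table",
    "read_phase_annotation",
    "read_maxquant_protein_groups",
    "write_count_table",
    "write_calls",
]

PHASES = ("G1", "SMC", "NONCYCLICAL")


@dataclass(frozen=True)
class CountTable:
    """Per-protein spectral counts for one or more pulldown assays.

    ``counts`` is a wide integer matrix (rows = proteins, columns = assays);
    every cell is materialised, zeros retained.  ``lengths`` maps protein to
    length in amino acids and may be absent until :meth:`attach_lengths` —
    the normalization stage is where a missing length becomes an error.
    ``bait_id`` names the tagged protein; a pulldown in which the bait was
    not detected is invalid, so the bait count must be >= 1 in every assay.
    """

    counts: pd.DataFrame
    bait_id: str
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = sorted(c.index[c.index.duplicated()].unique())
            raise ValidationError(f"duplicate protein rows: {dups}")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate assay columns")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be whole numbers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative counts are not allowed")
        if self.bait_id not in c.index:
            raise ValidationError(f"bait {self.bait_id!r} not present in table")
        bait_counts = c.loc[self.bait_id]
        if (bait_counts < 1).any():
            missing = list(c.columns[bait_counts < 1])
            raise ValidationError(
                f"bait {self.bait_id!r} has zero counts in assay(s) {missing}; "
                "a pulldown without its bait is invalid"
            )
        if self.lengths is not None:
            lg = self.lengths
            if lg.index.has_duplicates:
                raise ValidationError("duplicate protein IDs in lengths")
            if (lg <= 0).any():
                raise ValidationError("protein lengths must be >= 1")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def assays(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def prey_ids(self) -> list[str]:
        return [p for p in self.counts.index if p != self.bait_id]

    def attach_lengths(self, lengths: Mapping[str, int] | pd.Series) -> "CountTable":
        """Return a copy with a protein-length table attached."""
        lg = pd.Series(dict(lengths) if not isinstance(lengths, pd.Series) else lengths)
        lg.index = lg.index.astype(str)
        return replace(self, lengths=lg.astype(np.int64))

    def total_counts(self) -> pd.Series:
        """Summed raw counts per protein across all assays."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class DETable:
    """Differential-expression results: log2 fold change and adjusted P."""

    frame: pd.DataFrame  # columns: transcript_id, log2_change, adjusted_p

    def __post_init__(self) -> None:
        f = self.frame
        padj = f["adjusted_p"]
        bad = padj.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError("adjusted_p values must lie in [0, 1]")
        if f["transcript_id"].duplicated().any():
            raise ValidationError("duplicate transcript_id in DE table")


@dataclass(frozen=True)
class PhaseAnnotation:
    """Transcript -> cell-cycle peak-phase mapping (G1, SMC, NONCYCLICAL)."""

    phases: pd.Series  # index transcript_id, values in PHASES

    def __post_init__(self) -> None:
        if self.phases.index.has_duplicates:
            raise ValidationError("a transcript may map to only one phase")
        bad = set(self.phases.unique()) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phase label(s): {sorted(bad)}")


@dataclass(frozen=True)
class InteractorCall:
    """Scored verdict for one protein.

    ``is_interactor`` is true iff the posterior exceeds the threshold
    strictly AND the summed raw count meets the count floor; the bait is
    always reported as an interactor with sentinel posterior 1.0 and
    ``is_bait`` set.
    """

    protein_id: str
    total_raw_count: int
    mean_log2_score: float  # NaN for proteins never observed
    posterior: float
    is_interactor: bool
    is_bait: bool = False


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for c in df.columns:
        df[c] = df[c].str.strip()
    return df


def _parse_counts(series: pd.Series, path: str | Path) -> pd.Series:
    """Parse a string column of counts, reporting the offending row on failure."""
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() | (out != np.floor(out)) | (out < 0)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValidationError(
            f"{path}: row {row}: count {series[bad.idxmax()]!r} is not a "
            "non-negative integer"
        )
    return out.astype(np.int64)


def read_count_table(
    path: str | Path, format: str, bait_id: str  # noqa: A002 - dialect selector
) -> CountTable:
    """Read a spectral-count table in the given dialect.

    The dialect is explicit; there is no sniffing.  In the ``peptide``
    dialect, peptide-level counts are summed per (protein, assay) before
    validation.
    """
    if format == "long":
        df = _read_tsv(path, ["protein_id", "assay_id", "count"])
        df["count"] = _parse_counts(df["count"], path)
        dup = df.duplicated(subset=["protein_id", "assay_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["protein_id", "assay_id"]].tolist()
            raise ValidationError(f"{path}: duplicate (protein, assay) pair {pair}")
        wide = (
            df.pivot(index="protein_id", columns="assay_id", values="count")
            .fillna(0)
            .astype(np.int64)
        )
    elif format == "wide":
        df = _read_tsv(path, ["protein_id"])
        assay_cols = [c for c in df.columns if c != "protein_id"]
        if not assay_cols:
            raise FormatError(f"{path}: wide table has no assay columns")
        for c in assay_cols:
            df[c] = _parse_counts(df[c], path)
        wide = df.set_index("protein_id")[assay_cols]
    elif format == "peptide":
        df = _read_tsv(path, ["peptide_id", "protein_id", "assay_id", "count"])
        df["count"] = _parse_counts(df["count"], path)
        wide = (
            df.groupby(["protein_id", "assay_id"])["count"]
            .sum()
            .unstack(fill_value=0)
            .astype(np.int64)
        )
    else:
        raise FormatError(f"unknown dialect {format!r}; expected long, wide or peptide")
    wide.index.name = "protein_id"
    wide.columns.name = "assay_id"
    return CountTable(counts=wide.sort_index(), bait_id=bait_id)


def read_lengths(path: str | Path) -> pd.Series:
    """Read a two-column protein-length table (protein_id, length in aa)."""
    df = _read_tsv(path, ["protein_id", "length"])
    lengths = pd.to_numeric(df["length"], errors="coerce")
    if lengths.isna().any() or (lengths != np.floor(lengths)).any() or (lengths <= 0).any():
        bad = df.loc[lengths.isna() | (lengths != np.floor(lengths)) | (lengths <= 0)]
        raise ValidationError(
            f"{path}: non-positive or non-integer length for "
            f"{bad['protein_id'].tolist()}"
        )
    df = df.assign(length=lengths.astype(np.int64))
    conflicts = df.groupby("protein_id")["length"].nunique()
    if (conflicts > 1).any():
        raise ValidationError(
            f"{path}: conflicting lengths for {list(conflicts.index[conflicts > 1])}"
        )
    out = df.drop_duplicates("protein_id").set_index("protein_id")["length"]
    return out


def read_de_table(path: str | Path) -> DETable:
    """Read a differential-expression table (transcript_id, log2_change, adjusted_p)."""
    df = _read_tsv(path, ["transcript_id", "log2_change"])
    frame = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "log2_change": pd.to_numeric(df["log2_change"], errors="raise"),
            "adjusted_p": pd.to_numeric(df["adjusted_p"], errors="coerce")
            if "adjusted_p" in df.columns
            else np.nan,
        }
    )
    return DETable(frame=frame)


def read_phase_annotation(path: str | Path) -> PhaseAnnotation:
    """Read a transcript -> peak-phase table (transcript_id, peak_phase)."""
    df = _read_tsv(path, ["transcript_id", "peak_phase"])
    return PhaseAnnotation(
        phases=df.set_index("transcript_id")["peak_phase"].str.upper()
    )


def read_maxquant_protein_groups(
    path: str | Path, bait_id: str, count_prefix: str = "Peptides "
) -> CountTable:
    """Read a MaxQuant proteinGroups-style export as a wide count table.

    Columns named ``<count_prefix><experiment>`` (default ``Peptides <exp>``)
    become assay columns; ``Protein IDs`` (first entry of the
    semicolon-separated group) or ``protein_id`` supplies the protein.
    Off the default path — callers opt in explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = "Protein IDs" if "Protein IDs" in df.columns else "protein_id"
    if id_col not in df.columns:
        raise FormatError(f"{path}: need a 'Protein IDs' or 'protein_id' column")
    assay_cols = [c for c in df.columns if c.startswith(count_prefix)]
    if not assay_cols:
        raise FormatError(f"{path}: no columns start with {count_prefix!r}")
    out = pd.DataFrame(
        {c[len(count_prefix):]: _parse_counts(df[c].fillna("0"), path) for c in assay_cols}
    )
    out.index = df[id_col].str.split(";").str[0].str.strip()
    out.index.name = "protein_id"
    out.columns.name = "assay_id"
    return CountTable(counts=out.sort_index(), bait_id=bait_id)


# ---------------------------------------------------------------------------
# writers


def write_count_table(table: CountTable, path: str | Path, format: str = "long") -> None:  # noqa: A002
    """Write a CountTable in the long or wide dialect."""
    path = Path(path)
    if format == "long":
        long = (
            table.counts.stack()
            .rename("count")
            .reset_index()
            .sort_values(["protein_id", "assay_id"], kind="mergesort")
        )
        long.to_csv(path, sep="\t", index=False)
    elif format == "wide":
        table.counts.to_csv(path, sep="\t")
    else:
        raise FormatError(f"cannot write dialect {format!r}")


def write_calls(path: str | Path, calls: list[InteractorCall]) -> None:
    """Write interactor calls as a ranked tab-separated table.

    Rows are ordered by descending posterior, ties broken by descending
    total raw count, then lexicographic protein ID; missing log2 scores
    (proteins never observed) are written as NA.
    """
    if not calls:
        raise ValidationError("refusing to write an empty calls table")
    ordered = sorted(
        calls, key=lambda c: (-c.posterior, -c.total_raw_count, c.protein_id)
    )
    buf = io.StringIO()
    buf.write("protein_id\ttotal_raw_count\tmean_log2_score\tposterior\tis_interactor\n")
    for c in ordered:
        score = "NA" if np.isnan(c.mean_log2_score) else f"{c.mean_log2_score:.6g}"
        buf.write(
            f"{c.protein_id}\t{c.total_raw_count}\t{score}\t"
            f"{c.posterior:.6g}\t{str(c.is_interactor).lower()}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
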