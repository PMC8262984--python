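"""Readers/writers for the external formats and the shared record model.

Coordinates are 1-based inclusive everywhere; the length of a region is
``end - start + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical residues plus the ambiguity letter X.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Canonical domain vocabulary; anything else maps to "other" with a warning.
DOMAIN_NAMES = frozenset({"CZB", "MCP", "GGDEF", "EAL", "CheW", "TM", "other"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class CoordinateError(ValueError):
    """Raised when 1-based inclusive coordinates are inconsistent."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession and optional species label."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue letter(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(
                f"{self.protein_id}/{self.domain_name}: bad interval "
                f"[{self.start}, {self.end}] (1-based inclusive required)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DoseResponseDataset:
    """A titration: ascending doses with >=1 replicate response per dose."""

    dose: np.ndarray
    response: np.ndarray  # shape (n_doses, n_reps)
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.atleast_2d(np.asarray(self.response, dtype=float))
        if self.response.shape[0] != self.dose.shape[0]:
            self.response = self.response.T
        if len(np.unique(self.dose)) < 3:
            raise FormatError(f"dataset {self.label!r}: need >= 3 distinct doses")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise FormatError(f"dataset {self.label!r}: doses must be finite and >= 0")
        if np.any(np.diff(self.dose) < 0):
            order = np.argsort(self.dose, kind="stable")
            self.dose = self.dose[order]
            self.response = self.response[order]

    @property
    def mean_response(self) -> np.ndarray:
        return np.nanmean(self.response, axis=1)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dose, response) with doses repeated per replicate."""
        n_rep = self.response.shape[1]
        d = np.repeat(self.dose, n_rep)
        r = self.response.ravel()
        keep = np.isfinite(r)
        return d[keep], r[keep]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, gapped: bool = False) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The header token before the first whitespace is the id; the remainder,
    if present, is kept as the species field.  With ``gapped=True`` the
    '-' gap character is tolerated (aligned FASTA).

    Raises
    ------
    FormatError
        on an empty file, a duplicate id, or an illegal residue letter.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    cls = _GappedRecord if gapped else ProteinRecord
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        species = rec.description[len(rec.id):].strip()
        out.append(cls(rec.id, str(rec.seq).upper(), species=species))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


class _GappedRecord(ProteinRecord):
    """ProteinRecord that tolerates '-' (aligned FASTA rows)."""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - ALLOWED_RESIDUES - {"-"}
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue letter(s) {sorted(bad)}"
            )
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.species) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------

def read_domain_table(
    path: str | Path,
    records: Sequence[ProteinRecord] | None = None,
) -> list[DomainAnnotation]:
    """Read a TSV of (protein_id, domain_name, start, end).

    Unknown domain names are mapped to "other" with a logged warning.  If
    ``records`` is given, coordinates are validated against sequence length.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_name": str})
    required = {"protein_id", "domain_name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    lengths = {r.id: len(r) for r in records} if records is not None else {}
    out: list[DomainAnnotation] = []
    for row in df.itertuples(index=False):
        name = row.domain_name
        if name not in DOMAIN_NAMES:
            logger.warning("unknown domain name %r mapped to 'other'", name)
            name = "other"
        ann = DomainAnnotation(str(row.protein_id), name, int(row.start), int(row.end))
        plen = lengths.get(ann.protein_id)
        if plen is not None and ann.end > plen:
            raise CoordinateError(
                f"{ann.protein_id}: domain end {ann.end} exceeds length {plen}"
            )
        out.append(ann)
    return out


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.domain_name, a.start, a.end) for a in annotations],
        columns=["protein_id", "domain_name", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dose-response CSV (columns: dose_uM, rep1..repN; '#'-prefixed header
# comments carry metadata such as generator truth parameters)
# ---------------------------------------------------------------------------

def read_dose_response(path: str | Path, label: str = "") -> DoseResponseDataset:
    meta: dict = {}
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                text = line[1:].strip()
                if "=" in text:
                    k, v = text.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            header_lines.append(line)
            header_lines.extend(fh)
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(header_lines)))
    if "dose_uM" not in df.columns:
        raise FormatError(f"{path}: missing dose_uM column")
    reps = [c for c in df.columns if c.startswith("rep")]
    if not reps:
        raise FormatError(f"{path}: no replicate columns (rep1..repN)")
    return DoseResponseDataset(
        dose=df["dose_uM"].to_numpy(float),
        response=df[reps].to_numpy(float),
        label=label or Path(path).stem,
        meta=meta,
    )


def write_dose_response(ds: DoseResponseDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in ds.meta.items():
            fh.write(f"# {k} = {v}\n")
        reps = [f"rep{i + 1}" for i in range(ds.response.shape[1])]
        fh.write("dose_uM," + ",".join(reps) + "\n")
        for d, row in zip(ds.dose, ds.response):
            fh.write(f"{d:g}," + ",".join(f"{x:.10g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy tables
# ---------------------------------------------------------------------------

TAXONOMY_COLUMNS = ["protein_id", "species", "genus", "phylum", "candidate_phylum_flag"]


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {sorted(missing)}")
    df["candidate_phylum_flag"] = df["candidate_phylum_flag"].astype(str).str.lower().isin(
        {"1", "true", "yes"}
    )
    return df


def write_taxonomy(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["candidate_phylum_flag"] = out["candidate_phylum_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Optional XLSX ingestion (schema-mapped, not hard-coded)
# ---------------------------------------------------------------------------

def read_xlsx_table(
    path: str | Path,
    sheet: str | int,
    column_map: Mapping[str, str],
    skiprows: int = 0,
) -> pd.DataFrame:
    """Normalize one workbook sheet to a tabular schema.

    ``column_map`` maps source column headers to normalized names (for
    example the domain-table or taxonomy schemas above); unmapped columns
    are dropped.
    """
    df = pd.read_excel(path, sheet_name=sheet, skiprows=skiprows)
    missing = set(column_map) - set(df.columns)
    if missing:
        raise FormatError(f"{path}[{sheet}]: missing source columns {sorted(missing)}")
    return df[list(column_map)].rename(columns=dict(column_map))
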