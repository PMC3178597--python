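"""Reading and writing the plain-text formats the pipeline touches.

FASTA (via Bio.SeqIO), tab-separated metadata and divergence tables,
Newick trees and square PHYLIP distance matrices.  All coordinates in
this package are 1-based, fully closed intervals.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: IUPAC nucleotide one-letter codes accepted in sequence residues.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
#: gap character, legal only inside alignments
GAP = "-"

METADATA_COLUMNS = ("sequence_id", "specimen_id", "species", "locus")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with its specimen annotations.

    ``residues`` are upper-case IUPAC codes; ``-`` may appear only in
    aligned records.  ``description`` preserves any FASTA header text
    after the first whitespace but is never used as an identifier.
    """

    id: str
    residues: str
    species: str = ""
    locus: str = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r}: residues must be non-empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in IUPAC_CODES and ch != GAP:
                raise FormatError(
                    f"sequence {self.id!r}: non-IUPAC character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_aligned(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.replace(GAP, ""))


@dataclass(frozen=True)
class DivergenceFixtureRow:
    """One row of the packaged per-species COI/ITS divergence survey.

    Each locus contributes a maximum intra-specific and a minimum
    inter-specific K2P divergence (proportions).  ``None`` in an intra
    cell means the row pools sequences from different species (no
    conspecific pair exists); a ``*_capped`` flag marks an inter cell
    printed only as exceeding the 20% measurability cutoff.
    """

    label: str
    n: int
    coi_intra: float | None
    coi_inter: float | None
    its_intra: float | None
    its_inter: float | None
    coi_inter_capped: bool = False
    its_inter_capped: bool = False
    flags: str = ""


def _normalize_residues(raw: str, seq_id: str) -> str:
    s = str(raw).upper().replace("U", "T")
    for pos, ch in enumerate(s, start=1):
        if ch not in IUPAC_CODES and ch != GAP:
            raise FormatError(
                f"sequence {seq_id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    return s


def read_fasta(path: str | Path, locus: str = "other") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; the
    remainder is kept as ``description``.  Residues are upper-cased and
    RNA ``U`` is mapped to ``T``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize_residues(str(rec.seq), rec.id),
                locus=locus,
                description=desc,
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as (possibly gapped) FASTA."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV (sequence_id, specimen_id, species, locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"metadata {path}: missing column {col!r}")
    dupes = df["sequence_id"][df["sequence_id"].duplicated()]
    if len(dupes):
        raise FormatError(
            f"metadata {path}: duplicated sequence_id {dupes.iloc[0]!r}"
        )
    return df[list(METADATA_COLUMNS)]


def species_labels(metadata: pd.DataFrame) -> dict[str, str]:
    """Map sequence_id -> species label from a metadata table."""
    return dict(zip(metadata["sequence_id"], metadata["species"]))


def packaged_data_path(name: str):
    """Path to a data file shipped with the package."""
    return resources.files("mycobarcode.data").joinpath(name)


def _parse_cell(raw: str, *, row: str, col: str, allow_capped: bool):
    raw = raw.strip()
    if raw == "NA":
        return None, False
    if raw == "CAPPED":
        if not allow_capped:
            raise FormatError(
                f"divergence table row {row!r}: CAPPED is illegal in intra cell {col}"
            )
        return None, True
    value = float(raw)
    if not 0.0 <= value <= 1.0:
        raise FormatError(
            f"divergence table row {row!r}: {col}={value} outside [0, 1]"
        )
    return value, False


def load_divergence_fixture(path: str | Path | None = None) -> list[DivergenceFixtureRow]:
    """Load the packaged 38-row COI/ITS divergence survey (or a like-formatted TSV).

    Proportions are kept exactly as printed; ``CAPPED`` marks inter-specific
    cells recorded only as ">20%" and ``NA`` marks intra cells of rows whose
    sequences span different species.
    """
    if path is None:
        path = packaged_data_path("agaricomycotina_divergences.tsv")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        rows: list[DivergenceFixtureRow] = []
        for raw in reader:
            label = raw["label"].strip()
            coi_intra, _ = _parse_cell(raw["coi_intra"], row=label, col="coi_intra", allow_capped=False)
            its_intra, _ = _parse_cell(raw["its_intra"], row=label, col="its_intra", allow_capped=False)
            coi_inter, coi_cap = _parse_cell(raw["coi_inter"], row=label, col="coi_inter", allow_capped=True)
            its_inter, its_cap = _parse_cell(raw["its_inter"], row=label, col="its_inter", allow_capped=True)
            rows.append(
                DivergenceFixtureRow(
                    label=label,
                    n=int(raw["n"]),
                    coi_intra=coi_intra,
                    coi_inter=coi_inter,
                    its_intra=its_intra,
                    its_inter=its_inter,
                    coi_inter_capped=coi_cap,
                    its_inter_capped=its_cap,
                    flags=(raw.get("flags") or "").strip(),
                )
            )
    if not rows:
        raise FormatError(f"empty divergence table: {path}")
    return rows


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (``mycobarcode.distance.Tree``) as Newick with branch lengths."""
    text = tree.to_newick()
    Path(path).write_text(text + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file into a dendropy.Tree (for inspection/round-trips)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def write_phylip(matrix, path: str | Path) -> None:
    """Write a distance matrix in square PHYLIP format (UNDEFINED as -1.0)."""
    ids = matrix.ids
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            vals = []
            for j in range(len(ids)):
                v = matrix.values[i, j]
                vals.append("-1.000000" if math.isnan(v) else f"{v:.6f}")
            fh.write(f"{name}  " + " ".join(vals) + "\n")


def read_phylip(path: str | Path):
    """Read a square PHYLIP distance matrix written by :func:`write_phylip`."""
    import numpy as np

    from .distance import DistanceMatrix

    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    values = np.array(rows, dtype=float)
    values[values < 0] = np.nan
    return DistanceMatrix(ids=ids, values=values)
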