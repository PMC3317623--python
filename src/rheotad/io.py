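"""File I/O: FASTA with pipe-delimited metadata headers, measurement tables.

FASTA headers may carry metadata as ``id|species|region|role|status`` (empty
trailing fields may be omitted); sequences are wrapped at 70 columns on
output and uppercased on input.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .barcode import SequenceRecord
from .morphometrics import ABBREVIATIONS, MeasurementRecord

__all__ = ["read_fasta", "write_fasta", "read_measurements", "write_measurements"]

_QUALITATIVE_COLUMNS = {
    "has_dorsal_gap": bool,
    "has_upper_jaw_sheath": bool,
    "has_medial_convexity": bool,
    "oral_disc_margin": str,
    "lower_sheath_shape": str,
    "lower_sheath_ribbed": bool,
    "lateral_bulge": bool,
    "lateral_emargination": bool,
    "has_dorsolateral_glands": bool,
    "lateral_transparent_area": str,
    "ltrf": str,
}


def _split_header(description: str) -> dict[str, Optional[str]]:
    parts = (description.split("|") + [""] * 5)[:5]
    keys = ("id", "taxon_label", "locality", "role", "reference_status")
    return {k: (v.strip() or None) for k, v in zip(keys, parts)}


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read sequences; duplicate ids and empty files are errors.

    Lowercase sequences are normalised to uppercase with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _split_header(rec.description)
        rec_id = meta["id"] or rec.id
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"sequence {rec_id!r}: lowercase normalised", stacklevel=2)
        records.append(
            SequenceRecord(
                id=rec_id,
                sequence=seq,
                taxon_label=meta["taxon_label"] or "",
                locality=meta["locality"] or "",
                role=meta["role"] or "tadpole_query",
                reference_status=meta["reference_status"],
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], wrap: int = 70
) -> None:
    records = list(records)
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate ids {sorted(dupes)}")
    bio = []
    for r in records:
        header = "|".join(
            [r.id, r.taxon_label, r.locality, r.role, r.reference_status or ""]
        ).rstrip("|")
        bio.append(BioSeqRecord(Seq(r.sequence), id=header, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(bio)


def read_measurements(path: Union[str, Path]) -> list[MeasurementRecord]:
    """Measurement CSV/TSV: one voucher per row, columns named by abbreviation."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        measurements = {
            col: float(row[col])
            for col in df.columns
            if col in ABBREVIATIONS and pd.notna(row[col])
        }
        kwargs = {}
        for col, typ in _QUALITATIVE_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = bool(row[col]) if typ is bool else str(row[col])
        records.append(
            MeasurementRecord(
                voucher_id=str(row.get("voucher_id", "")),
                field_number=str(row.get("field_number", "")),
                species_label=str(row.get("species_label", "")),
                gosner_stage=(
                    int(row["gosner_stage"]) if pd.notna(row.get("gosner_stage")) else None
                ),
                measurements=measurements,
                **kwargs,
            )
        )
    return records


def write_measurements(
    records: Iterable[MeasurementRecord], path: Union[str, Path]
) -> None:
    rows = []
    for r in records:
        row: dict = {
            "voucher_id": r.voucher_id,
            "field_number": r.field_number,
            "species_label": r.species_label,
            "gosner_stage": r.gosner_stage,
        }
        row.update(r.measurements)
        for col in _QUALITATIVE_COLUMNS:
            value = getattr(r, col)
            if value is not None:
                row[col] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
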