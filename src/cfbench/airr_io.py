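"""AIRR Rearrangement I/O and the shared repertoire data model.

Reads and writes annotated BCR heavy-chain repertoires as AIRR Rearrangement
TSV (tab-separated, UTF-8, header row) and exports sequences as FASTA.  The
:class:`Rearrangement` record and :class:`Repertoire` container defined here
are the in-memory currency of every other module.

Column names follow the AIRR Rearrangement schema (``sequence_id``,
``v_call``, ``j_call``, ``junction``, ``junction_aa``, ``clone_id``);
simulated ground truth travels in the non-standard column ``clone_id_true``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd


class AirrFormatError(ValueError):
    """Malformed AIRR TSV: missing mandatory columns or broken structure."""


class AirrValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


#: Columns every input file must carry.
MANDATORY_COLUMNS = ("sequence_id", "v_call", "j_call", "junction_aa")

#: Stable output column order; optional columns appear only when populated.
COLUMN_ORDER = (
    "sequence_id",
    "sample_id",
    "sequence",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "v_mutation_count",
    "v_alignment_length",
    "j_mutation_count",
    "j_alignment_length",
    "lc_v_call",
    "lc_j_call",
    "clone_id_true",
    "clone_id",
)

_INT_COLUMNS = (
    "v_mutation_count",
    "v_alignment_length",
    "j_mutation_count",
    "j_alignment_length",
)


@dataclass
class Rearrangement:
    """One annotated BCR heavy-chain record.

    The junction comprises the CDR3 nucleotide sequence plus its two anchor
    codons (Cys104 and Phe/Trp118).  Mutation counts refer to the V and J
    aligned segments outside the junction; the junction itself carries no
    reliable germline reference, so its mutations are excluded by
    construction.
    """

    sequence_id: str
    v_call: str
    j_call: str
    junction_aa: str
    sample_id: str = ""
    sequence: str = ""
    junction: str = ""
    v_mutation_count: Optional[int] = None
    v_alignment_length: Optional[int] = None
    j_mutation_count: Optional[int] = None
    j_alignment_length: Optional[int] = None
    lc_v_call: Optional[str] = None
    lc_j_call: Optional[str] = None
    clone_id_true: Optional[str] = None
    clone_id: Optional[str] = None

    def validate(self) -> None:
        if self.junction and self.junction_aa:
            if len(self.junction) % 3 == 0 and len(self.junction_aa) != len(self.junction) // 3:
                raise AirrValidationError(
                    f"{self.sequence_id}: junction_aa length {len(self.junction_aa)} "
                    f"inconsistent with junction length {len(self.junction)}"
                )
        for seg in ("v", "j"):
            mut = getattr(self, f"{seg}_mutation_count")
            aln = getattr(self, f"{seg}_alignment_length")
            if mut is not None and aln is not None and mut > aln:
                raise AirrValidationError(
                    f"{self.sequence_id}: {seg}_mutation_count {mut} exceeds "
                    f"alignment length {aln}"
                )
        if (self.lc_v_call is None) != (self.lc_j_call is None):
            raise AirrValidationError(
                f"{self.sequence_id}: lc_v_call and lc_j_call must be both "
                "present or both absent"
            )

    @property
    def junction_in_frame(self) -> bool:
        """Whether the junction length is a multiple of 3 (AA translation defined)."""
        return bool(self.junction_aa) or (bool(self.junction) and len(self.junction) % 3 == 0)


@dataclass
class Repertoire:
    """Ordered collection of rearrangements from one or more samples.

    ``rejected`` collects rows that failed record-level requirements at read
    time as ``(row_dict, reason)`` pairs — rejection is total, never silent:
    len(records) + len(rejected) equals the number of data rows read.
    """

    records: list[Rearrangement] = field(default_factory=list)
    provenance: str = ""
    rejected: list[tuple[dict, str]] = field(default_factory=list)

    @property
    def sample_ids(self) -> set[str]:
        return {r.sample_id for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.sequence_id in seen:
                raise AirrValidationError(f"duplicate sequence_id: {r.sequence_id}")
            seen.add(r.sequence_id)
            r.validate()


def strip_allele(call: str) -> str:
    """Reduce a V/J call to the first-listed gene-level name.

    Multi-assignments are comma-separated; the first listed call is kept and
    any ``*NN`` allele suffix dropped, e.g. ``"IGHV3-23*04,IGHV3-23D*01"`` →
    ``"IGHV3-23"``.  First-listed is a deterministic stand-in for picking the
    most frequent hit, which is undefined on a single record.
    """
    if not call:
        raise ValueError("empty gene call")
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def _parse_optional_int(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return int(value)


def read_rearrangements(path: str | Path, dialect: str = "airr_tsv") -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Rows missing ``junction_aa`` or a V/J call are routed to
    ``Repertoire.rejected`` with a reason, never silently dropped.  Record
    order equals file row order.  Allele suffixes are retained verbatim in the
    stored calls; analysis-side code strips them via :func:`strip_allele`.
    """
    if dialect != "airr_tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    known = {f.name for f in dc_fields(Rearrangement)}
    rep = Repertoire(provenance=str(path))
    for row in df.to_dict(orient="records"):
        reason = None
        for col in ("junction_aa", "v_call", "j_call", "sequence_id"):
            if not row.get(col):
                reason = f"missing {col}"
                break
        if reason is not None:
            rep.rejected.append((row, reason))
            continue
        kwargs = {k: v for k, v in row.items() if k in known and v != ""}
        for col in _INT_COLUMNS:
            if col in kwargs:
                kwargs[col] = _parse_optional_int(kwargs[col])
        rep.records.append(Rearrangement(**kwargs))
    rep.validate()
    return rep


def to_dataframe(rep: Repertoire) -> pd.DataFrame:
    """Repertoire as a DataFrame in the stable column order.

    Optional columns are included only when at least one record carries them.
    """
    rows = []
    for r in rep.records:
        rows.append({f.name: getattr(r, f.name) for f in dc_fields(Rearrangement)})
    df = pd.DataFrame(rows, columns=list(COLUMN_ORDER))
    optional = set(COLUMN_ORDER) - set(MANDATORY_COLUMNS)
    keep = [
        c
        for c in COLUMN_ORDER
        if c not in optional or (len(df) > 0 and df[c].notna().any() and (df[c] != "").any())
    ]
    if len(df) == 0:
        keep = list(MANDATORY_COLUMNS)
    return df[keep]


def write_rearrangements(rep: Repertoire, path: str | Path) -> Path:
    """Write a repertoire as AIRR TSV; returns the path written.

    Round trip with :func:`read_rearrangements` is the identity on valid
    repertoires (field-level equality).
    """
    rep.validate()
    path = Path(path)
    df = to_dataframe(rep)
    out = df.copy()
    for col in _INT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    out = out.fillna("")
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def write_fasta(rep: Repertoire, path: str | Path, field_name: str = "sequence") -> Path:
    """Export a sequence field as FASTA keyed by sequence_id."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    recs = [
        SeqRecord(Seq(getattr(r, field_name)), id=r.sequence_id, description="")
        for r in rep.records
        if getattr(r, field_name)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        seqio_write(recs, fh, "fasta")
    return path
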