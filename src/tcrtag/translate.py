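"""Full-sequence reconstruction, junction extraction and AIRR TSV output.

The junction is the CDR3 plus the conserved bracketing residues: from the
V gene's 2nd-CYS cysteine codon through the J gene's J-PHE phenylalanine
codon, both located by germline annotation rather than motif search.  A
rearrangement is productive when the junction exists, is a whole number
of codons, begins with C, ends with F, and the V-frame translation of the
sequence carries no stop codon up to the end of the junction.

Output rows follow the AIRR Community Rearrangement TSV schema: one row
per unique DNA sequence (distinct rows may encode the same protein), all
required columns present, unfilled ones as empty strings, plus custom
columns for the five-part classifier and the mean cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .collapse import CollapsedTCR
from .decombine import Classifier, reconstruct_sequence
from .germline import GermlineGene, TagSet

AIRR_SCHEMA_VERSION = "1.4"

#: Required fields of the AIRR Rearrangement schema, in output order.
AIRR_REQUIRED_FIELDS = [
    "sequence_id",
    "sequence",
    "rev_comp",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "sequence_alignment",
    "germline_alignment",
    "junction",
    "junction_aa",
    "v_cigar",
    "d_cigar",
    "j_cigar",
]

#: Custom (schema-permitted) extension columns.
AIRR_EXTRA_FIELDS = [
    "duplicate_count",
    "cdr1_aa",
    "cdr2_aa",
    "sequence_aa",
    "decombinator_id",
    "bc_count",
]


def translate_dna(dna: str, frame_offset: int = 0) -> str:
    """Standard-code translation; stop codons render as ``*``; a trailing
    partial codon is dropped."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    s = dna[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())


def junction_span(
    classifier: Classifier, genes: Sequence[GermlineGene]
) -> tuple[int, int] | None:
    """Half-open span of the junction on the reconstructed sequence, or
    ``None`` when either conserved codon was deleted."""
    v = genes[classifier.v_index]
    j = genes[classifier.j_index]
    if classifier.v_deletions > len(v) - (v.conserved_pos + 3):
        return None  # conserved C codon (partly) deleted
    if classifier.j_deletions > j.conserved_pos:
        return None  # conserved F codon (partly) deleted
    v_part = len(v) - classifier.v_deletions
    f_start = v_part + len(classifier.insert) + (j.conserved_pos - classifier.j_deletions)
    return v.conserved_pos, f_start + 3


def extract_junction(
    classifier: Classifier, genes: Sequence[GermlineGene]
) -> tuple[str | None, str]:
    """Return (junction nucleotides or None, junction amino acids).

    The amino-acid junction is empty when the junction is absent or out of
    frame relative to the conserved cysteine.
    """
    span = junction_span(classifier, genes)
    if span is None:
        return None, ""
    seq = reconstruct_sequence(classifier, genes)
    junction = seq[span[0] : span[1]]
    aa = translate_dna(junction) if len(junction) % 3 == 0 else ""
    return junction, aa


def is_productive(
    classifier: Classifier, genes: Sequence[GermlineGene]
) -> bool:
    """True iff the junction exists, is in frame, is C...F bracketed, and
    the V-frame translation is stop-free through the junction."""
    span = junction_span(classifier, genes)
    if span is None:
        return False
    junction, aa = extract_junction(classifier, genes)
    if len(junction) % 3 != 0 or not aa:
        return False
    if not (aa.startswith("C") and aa.endswith("F")):
        return False
    seq = reconstruct_sequence(classifier, genes)
    return "*" not in translate_dna(seq[: span[1]])


@dataclass(slots=True)
class AIRRRecord:
    """One AIRR rearrangement row (required fields + package extensions)."""

    sequence_id: str
    sequence: str
    rev_comp: bool
    productive: bool
    v_call: str
    d_call: str
    j_call: str
    junction: str
    junction_aa: str
    duplicate_count: int
    cdr1_aa: str
    cdr2_aa: str
    sequence_aa: str
    decombinator_id: str
    bc_count: float
    sequence_alignment: str = ""
    germline_alignment: str = ""
    v_cigar: str = ""
    d_cigar: str = ""
    j_cigar: str = ""


def _cdr_aa(gene: GermlineGene, span: tuple[int, int] | None) -> str:
    if span is None:
        return ""
    return translate_dna(gene.sequence[span[0] : span[1]])


def build_airr_records(
    collapsed: Iterable[CollapsedTCR], tagset: TagSet
) -> list[AIRRRecord]:
    """Translate collapsed TCRs into AIRR rows (one per unique DNA sequence)."""
    genes = tagset.genes
    records: list[AIRRRecord] = []
    for i, t in enumerate(collapsed, start=1):
        c = t.classifier
        v, j = genes[c.v_index], genes[c.j_index]
        seq = reconstruct_sequence(c, genes)
        junction, junction_aa = extract_junction(c, genes)
        records.append(
            AIRRRecord(
                sequence_id=f"tcr_{i}",
                sequence=seq,
                rev_comp=False,
                productive=is_productive(c, genes),
                v_call=v.name,
                d_call="",
                j_call=j.name,
                junction=junction or "",
                junction_aa=junction_aa,
                duplicate_count=t.tcr_count,
                cdr1_aa=_cdr_aa(v, v.cdr1_span),
                cdr2_aa=_cdr_aa(v, v.cdr2_span),
                sequence_aa=translate_dna(seq),
                decombinator_id=(
                    f"{c.v_index}, {c.j_index}, {c.v_deletions}, "
                    f"{c.j_deletions}, {c.insert}"
                ),
                bc_count=t.bc_count,
            )
        )
    return records


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "T" if value else "F"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_airr(
    records: Iterable[AIRRRecord],
    out_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write the AIRR Rearrangement TSV (non-productive rows included).

    A ``#`` comment line pins the schema version (and optional provenance)
    ahead of the header row.
    """
    columns = AIRR_REQUIRED_FIELDS + AIRR_EXTRA_FIELDS
    with open(out_path, "w") as fh:
        comment = f"# airr_schema_version={AIRR_SCHEMA_VERSION}"
        if header_comment:
            comment += f" {header_comment}"
        fh.write(comment + "\n")
        fh.write("\t".join(columns) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, col)) for col in columns) + "\n")


def translate_collapsed(
    collapsed: Iterable[CollapsedTCR],
    tagset: TagSet,
    out_path: str | Path,
    drop_nonproductive: bool = False,
) -> list[AIRRRecord]:
    """End-to-end translation stage: collapsed TCRs → AIRR TSV on disk."""
    records = build_airr_records(collapsed, tagset)
    if drop_nonproductive:
        records = [r for r in records if r.productive]
    write_airr(records, out_path, header_comment=f"tag_set={tagset.checksum()}")
    return records
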