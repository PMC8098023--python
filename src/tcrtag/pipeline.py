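"""Demultiplexing and four-stage pipeline orchestration.

Demultiplexing assigns read pairs to samples by dual index barcodes
parsed from the Illumina-style header comment (``...:INDEX1+INDEX2`` as
the final colon-separated field).  A record is assigned to the unique
sample whose both indices are within ``max_mismatch`` substitutions;
records matching zero or several samples fall into the ``undetermined``
bin.  The pipeline then runs annotate → collapse → translate, persisting
each stage's output and a structured per-stage statistics summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .collapse import CollapseConfig, collapse_reads, write_collapsed
from .decombine import iter_fastq, process_fastq, write_decombinator
from .germline import TagSet, load_bundled, load_germline
from .translate import translate_collapsed


class SampleSheetError(ValueError):
    pass


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SampleSheet:
    """sample name -> (index1, index2) dual barcodes."""

    samples: dict[str, tuple[str, str]]

    @classmethod
    def load(cls, path: str | Path, max_mismatch: int = 1) -> "SampleSheet":
        samples: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise SampleSheetError(f"{path}:{ln}: expected 3 columns")
                name, i1, i2 = parts
                if name in samples:
                    raise SampleSheetError(f"duplicate sample {name}")
                samples[name] = (i1.upper(), i2.upper())
        sheet = cls(samples)
        sheet.validate(max_mismatch)
        return sheet

    def validate(self, max_mismatch: int = 1) -> None:
        """Reject index pairs closer than 2 x max_mismatch (unresolvable)."""
        items = sorted(self.samples.items())
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                (na, (a1, a2)), (nb, (b1, b2)) = items[a], items[b]
                if _hamming(a1, b1) + _hamming(a2, b2) <= 2 * max_mismatch:
                    raise SampleSheetError(
                        f"index collision between {na} and {nb}: pairs are "
                        f"within {2 * max_mismatch} total mismatches"
                    )


def _indices_from_header(header: str) -> tuple[str, str] | None:
    # "@id 1:N:0:ACGTACGT+TGCATGCA" -> ("ACGTACGT", "TGCATGCA")
    fields = header.split()
    if len(fields) < 2:
        return None
    tail = fields[-1].rsplit(":", 1)[-1]
    if "+" not in tail:
        return None
    i1, i2 = tail.split("+", 1)
    return i1.upper(), i2.upper()


def demultiplex(
    fastq1: str | Path,
    fastq2: str | Path,
    sheet: SampleSheet,
    out_dir: str | Path,
    max_mismatch: int = 1,
) -> dict[str, int]:
    """Split a read pair into per-sample FASTQ pairs plus an undetermined bin.

    Returns per-sample record counts (conserving the input record count).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(sheet.samples) + ["undetermined"]
    handles = {
        n: (
            open(out_dir / f"{n}_R1.fastq", "w"),
            open(out_dir / f"{n}_R2.fastq", "w"),
        )
        for n in names
    }
    counts = {n: 0 for n in names}
    try:
        for (h1, s1, q1), (h2, s2, q2) in zip(
            iter_fastq(fastq1), iter_fastq(fastq2), strict=True
        ):
            idx = _indices_from_header(h1)
            assigned = "undetermined"
            if idx is not None:
                hits = [
                    name
                    for name, (i1, i2) in sheet.samples.items()
                    if _hamming(idx[0], i1) <= max_mismatch
                    and _hamming(idx[1], i2) <= max_mismatch
                ]
                if len(hits) == 1:
                    assigned = hits[0]
            counts[assigned] += 1
            f1, f2 = handles[assigned]
            f1.write(f"@{h1}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{h2}\n{s2}\n+\n{q2}\n")
    finally:
        for f1, f2 in handles.values():
            f1.close()
            f2.close()
    return counts


@dataclass
class RunConfig:
    """Paths and knobs for a full single-sample run."""

    fastq1: str
    fastq2: str
    out_dir: str
    germline_fasta: str | None = None
    germline_annotations: str | None = None
    bundled_tagset: str = "synthetic_trb"
    umi_spec: str = "N6S4N6"
    th_bc: int = 2
    th_tcr: float = 10.0
    min_umi_qual: float | None = None
    drop_nonproductive: bool = False

    def load_tagset(self) -> TagSet:
        if self.germline_fasta:
            if not self.germline_annotations:
                raise ValueError("germline_annotations required with germline_fasta")
            genes = load_germline(self.germline_fasta, self.germline_annotations)
            from .germline import BUNDLED_TAG_PARAMS

            return TagSet.from_genes(genes, **BUNDLED_TAG_PARAMS)
        return load_bundled(self.bundled_tagset)

    def validate(self) -> None:
        for p in (self.fastq1, self.fastq2):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(cfg: RunConfig) -> dict:
    """annotate → collapse → translate, with persisted intermediates and
    per-stage statistics written to ``summary.json``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tagset = cfg.load_tagset()

    annotated, stats = process_fastq(
        cfg.fastq1, cfg.fastq2, tagset, cfg.umi_spec, cfg.min_umi_qual
    )
    write_decombinator(annotated, out / "annotated.decombinator")

    collapse_cfg = CollapseConfig(
        th_bc=cfg.th_bc, th_tcr=cfg.th_tcr, min_umi_qual=cfg.min_umi_qual
    )
    collapsed = collapse_reads(annotated, collapse_cfg)
    write_collapsed(collapsed, out / "collapsed.csv")

    records = translate_collapsed(
        collapsed, tagset, out / "airr.tsv", cfg.drop_nonproductive
    )

    summary = {
        "decombine": dict(stats),
        "collapse": {
            "reads_in": len(annotated),
            "clusters": sum(t.tcr_count for t in collapsed),
            "unique_tcrs": len(collapsed),
        },
        "translate": {
            "records": len(records),
            "productive": sum(r.productive for r in records),
        },
        "tag_set": tagset.checksum(),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
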