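"""Read classification: V/J tag search, deletion counting, insert extraction.

Every successfully classified read is reduced to the five-part classifier
(V gene, J gene, number of V 3' deletions, number of J 5' deletions,
non-templated insert), a lossless encoding of the rearrangement given the
germline references.  Reads in which exactly one V tag is followed by
exactly one J tag are classified; anything else is a no-call with a
reason code, counted in run statistics but never an error.

Classifier coordinates are 0-based half-open throughout.  A classifier is
stored in *canonical* form: germline attribution is maximized on the V
side first, then on the J side, which is exactly what the annotation walk
computes; :func:`canonical_classifier` puts arbitrary classifiers into
this form so that equality comparisons are well defined.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

from .germline import GermlineGene, TagSet

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class Classifier(NamedTuple):
    """Five-part recombination classifier."""

    v_index: int
    j_index: int
    v_deletions: int
    j_deletions: int
    insert: str


@dataclass(slots=True)
class SequenceRead:
    """One read pair after UMI extraction: the TCR-bearing sequence plus UMI."""

    read_id: str
    tcr_seq: str
    tcr_qual: str | None = None
    umi_seq: str = ""
    sample: str = ""


@dataclass(slots=True)
class AnnotatedRead:
    """A classified read: classifier, barcode (UMI) and the inter-tag window."""

    classifier: Classifier
    barcode: str
    inter_tag_seq: str
    read_id: str
    reverse_complemented: bool = False
    inter_tag_qual: str = ""


@dataclass(slots=True)
class NoCall:
    read_id: str
    reason: str  # no_v | no_j | multiple_v | multiple_j | order_violation | short_umi


def count_deletions(
    read_seq: str,
    tag_pos_in_read: int,
    tag: "object",
    gene: GermlineGene,
    side: str,
    lower_bound: int = 0,
) -> tuple[int, int]:
    """Count germline nucleotides deleted on one side of the junction.

    V side: walk rightward from the tag end in parallel along read and
    germline; the longest contiguous germline-matching extension ends at
    the first mismatch (or read/gene end) and everything from there to the
    gene 3' end counts as deleted.  Returns ``(deletions,
    read_pos_after_last_match)``.

    J side: symmetric leftward walk from the tag start toward the gene 5'
    end, never crossing ``lower_bound`` in the read (this implements the
    V-first tie-break for ambiguous boundary nucleotides).  Returns
    ``(deletions, read_pos_of_first_match)``.
    """
    g_seq = gene.sequence
    if side == "V":
        g = tag.offset + len(tag.keyword)
        r = tag_pos_in_read + len(tag.keyword)
        n = len(read_seq)
        gl = len(g_seq)
        while g < gl and r < n and read_seq[r] == g_seq[g]:
            g += 1
            r += 1
        return gl - g, r
    elif side == "J":
        g = tag.offset - 1
        r = tag_pos_in_read - 1
        while g >= 0 and r >= lower_bound and read_seq[r] == g_seq[g]:
            g -= 1
            r -= 1
        return g + 1, r + 1
    raise ValueError(f"side must be 'V' or 'J', got {side!r}")


def _annotate_oriented(seq: str, tagset: TagSet):
    """Classify one orientation; returns (classifier, span) or a reason string."""
    v_hits: list[tuple[int, int]] = []
    j_hits: list[tuple[int, int]] = []
    genes = tagset.genes
    tags = tagset.tags
    for kw_id, start in tagset.trie.finditer(seq):
        if genes[tags[kw_id].gene_index].segment == "V":
            v_hits.append((kw_id, start))
        else:
            j_hits.append((kw_id, start))
    if not v_hits:
        return "no_v"
    if len(v_hits) > 1:
        return "multiple_v"
    if not j_hits:
        return "no_j"
    if len(j_hits) > 1:
        return "multiple_j"
    (v_id, v_start), (j_id, j_start) = v_hits[0], j_hits[0]
    v_tag, j_tag = tags[v_id], tags[j_id]
    v_end = v_start + len(v_tag.keyword)
    if v_end >= j_start:
        return "order_violation"
    v_gene = genes[v_tag.gene_index]
    j_gene = genes[j_tag.gene_index]
    v_del, v_stop = count_deletions(seq, v_start, v_tag, v_gene, "V")
    j_del, j_first = count_deletions(seq, j_start, j_tag, j_gene, "J", lower_bound=v_stop)
    insert = seq[v_stop:j_first]
    clf = Classifier(v_tag.gene_index, j_tag.gene_index, v_del, j_del, insert)
    return clf, (v_start, j_start + len(j_tag.keyword))


def decombine_read(
    read: SequenceRead, tagset: TagSet, barcode: str = ""
) -> AnnotatedRead | NoCall:
    """Classify one read, trying the reverse complement if the forward
    orientation yields no V+J pair."""
    res = _annotate_oriented(read.tcr_seq, tagset)
    if isinstance(res, str):
        rc_seq = reverse_complement(read.tcr_seq)
        rc_res = _annotate_oriented(rc_seq, tagset)
        if isinstance(rc_res, str):
            # Prefer the more informative failure reason.
            reason = rc_res if (res == "no_v" and rc_res != "no_v") else res
            return NoCall(read.read_id, reason)
        clf, (a, b) = rc_res
        qual = read.tcr_qual[::-1][a:b] if read.tcr_qual else ""
        return AnnotatedRead(clf, barcode or read.umi_seq, rc_seq[a:b],
                             read.read_id, True, qual)
    clf, (a, b) = res
    qual = read.tcr_qual[a:b] if read.tcr_qual else ""
    return AnnotatedRead(clf, barcode or read.umi_seq, read.tcr_seq[a:b],
                         read.read_id, False, qual)


def reconstruct_sequence(classifier: Classifier, genes: Sequence[GermlineGene]) -> str:
    """Inverse of classification: germline V trimmed 3' + insert + germline J
    trimmed 5'."""
    v = genes[classifier.v_index]
    j = genes[classifier.j_index]
    if not 0 <= classifier.v_deletions <= len(v):
        raise ValueError(f"v_deletions {classifier.v_deletions} exceeds {v.name}")
    if not 0 <= classifier.j_deletions <= len(j):
        raise ValueError(f"j_deletions {classifier.j_deletions} exceeds {j.name}")
    return (
        v.sequence[: len(v) - classifier.v_deletions]
        + classifier.insert
        + j.sequence[classifier.j_deletions :]
    )


def canonical_classifier(classifier: Classifier, genes: Sequence[GermlineGene]) -> Classifier:
    """Rewrite a classifier in canonical form (maximal V, then maximal J).

    Boundary nucleotides that could belong either to germline or to the
    insert are attributed to germline, V side first — the same tie-break
    the annotation walk applies — so reconstruct/annotate round-trips are
    exact.
    """
    seq = reconstruct_sequence(classifier, genes)
    v = genes[classifier.v_index].sequence
    j = genes[classifier.j_index].sequence
    p = len(v) - classifier.v_deletions
    n = len(seq)
    while p < len(v) and p < n and seq[p] == v[p]:
        p += 1
    j_start = n - (len(j) - classifier.j_deletions)
    g = classifier.j_deletions - 1
    r = j_start - 1
    while g >= 0 and r >= p and seq[r] == j[g]:
        g -= 1
        r -= 1
    return Classifier(
        classifier.v_index, classifier.j_index,
        len(v) - p, g + 1, seq[p : r + 1],
    )


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------

_UMI_TOKEN = re.compile(r"([NSX])(\d+)")


def parse_umi_spec(spec: str) -> list[tuple[str, int]]:
    """Parse a UMI layout like ``"N6S4N6"``: N = random barcode window,
    S/X = fixed spacer to skip."""
    tokens = _UMI_TOKEN.findall(spec)
    if not tokens or "".join(f"{t}{n}" for t, n in tokens) != spec:
        raise ValueError(f"malformed UMI spec {spec!r}")
    return [(t, int(n)) for t, n in tokens]


def extract_umi(umi_read: str, umi_spec: str = "N6S4N6") -> str | None:
    """Concatenate the random-nucleotide windows of the UMI read.

    Returns ``None`` (a no-call) when the read is shorter than the layout.
    """
    parts = parse_umi_spec(umi_spec)
    need = sum(n for _, n in parts)
    if len(umi_read) < need:
        return None
    out = []
    pos = 0
    for kind, n in parts:
        if kind == "N":
            out.append(umi_read[pos : pos + n])
        pos += n
    return "".join(out)


def _mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


# ---------------------------------------------------------------------------
# FASTQ processing
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (record_id_line, sequence, quality) from a FASTQ file."""
    with _open_maybe_gz(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ValueError(f"{path}: truncated FASTQ record")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record {header!r}")
            yield header[1:].rstrip("\n"), seq, qual


def annotate_records(
    records: Iterable[tuple[str, str, str, str, str]],
    tagset: TagSet,
    umi_spec: str = "N6S4N6",
    min_umi_qual: float | None = None,
    memoize: bool = True,
) -> tuple[list[AnnotatedRead], Counter]:
    """Annotate (read_id, tcr_seq, tcr_qual, umi_read, umi_qual) tuples.

    Returns the list of successful annotations plus a statistics counter
    over input/no-call categories.  ``memoize`` caches the classification
    of identical TCR sequences — annotation is a pure function of the
    sequence, and amplified data is highly redundant.
    """
    stats: Counter = Counter()
    out: list[AnnotatedRead] = []
    cache: dict[str, object] = {}
    for read_id, tcr_seq, tcr_qual, umi_read, umi_qual in records:
        stats["input"] += 1
        barcode = extract_umi(umi_read, umi_spec)
        if barcode is None:
            stats["short_umi"] += 1
            continue
        if min_umi_qual is not None and _mean_quality(umi_qual) < min_umi_qual:
            stats["low_umi_quality"] += 1
            continue
        if memoize:
            hit = cache.get(tcr_seq)
            if hit is None:
                hit = _annotate_oriented(tcr_seq, tagset)
                if isinstance(hit, str):
                    rc = _annotate_oriented(reverse_complement(tcr_seq), tagset)
                    if not isinstance(rc, str):
                        hit = (*rc, True)
                    elif hit == "no_v" and rc != "no_v":
                        hit = rc
                cache[tcr_seq] = hit
            if isinstance(hit, str):
                stats[hit] += 1
                continue
            if len(hit) == 3:
                clf, (a, b), _ = hit
                seq = reverse_complement(tcr_seq)
                ann = AnnotatedRead(clf, barcode, seq[a:b], read_id, True)
            else:
                clf, (a, b) = hit
                ann = AnnotatedRead(clf, barcode, tcr_seq[a:b], read_id, False,
                                    tcr_qual[a:b] if tcr_qual else "")
        else:
            res = decombine_read(
                SequenceRead(read_id, tcr_seq, tcr_qual or None), tagset, barcode
            )
            if isinstance(res, NoCall):
                stats[res.reason] += 1
                continue
            ann = res
        stats["annotated"] += 1
        out.append(ann)
    return out, stats


def process_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    tagset: TagSet,
    umi_spec: str = "N6S4N6",
    min_umi_qual: float | None = None,
) -> tuple[list[AnnotatedRead], Counter]:
    """Annotate a record-synchronized FASTQ pair (read 1 = TCR, read 2 = UMI).

    Desynchronized files (different lengths or mismatched ids) raise with
    the offending record index.
    """

    def paired() -> Iterator[tuple[str, str, str, str, str]]:
        it1, it2 = iter_fastq(fastq1), iter_fastq(fastq2)
        idx = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(
                    f"FASTQ pair desynchronized: one file ended at record {idx}"
                )
            id1, id2 = r1[0].split()[0], r2[0].split()[0]
            if id1 != id2:
                raise ValueError(
                    f"FASTQ pair desynchronized at record {idx}: {id1!r} != {id2!r}"
                )
            yield id1, r1[1], r1[2], r2[1], r2[2]
            idx += 1

    return annotate_records(paired(), tagset, umi_spec, min_umi_qual)


# ---------------------------------------------------------------------------
# Intermediate "Decombinator format" (the collapse stage's input contract)
# ---------------------------------------------------------------------------

def write_decombinator(annotated: Iterable[AnnotatedRead], path: str | Path) -> None:
    """One line per read: v, j, v_del, j_del, insert, read_id, barcode,
    inter_tag_seq, inter_tag_qual (comma-separated)."""
    with open(path, "w") as fh:
        for a in annotated:
            c = a.classifier
            fh.write(
                f"{c.v_index},{c.j_index},{c.v_deletions},{c.j_deletions},"
                f"{c.insert},{a.read_id},{a.barcode},{a.inter_tag_seq},"
                f"{a.inter_tag_qual}\n"
            )


def read_decombinator(path: str | Path) -> list[AnnotatedRead]:
    out: list[AnnotatedRead] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 fields, got {len(fields)}")
            v, j, vd, jd, ins, rid, bc, seq, qual = fields
            out.append(
                AnnotatedRead(
                    Classifier(int(v), int(j), int(vd), int(jd), ins),
                    bc, seq, rid, False, qual,
                )
            )
    return out
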