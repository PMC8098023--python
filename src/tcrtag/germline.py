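"""Germline V/J references, identifying tags, and the tag set.

A tag is a short substring of one germline gene that occurs in no other
gene of the reference set, so that an exact hit identifies the gene.  V
tags are placed as close to the gene 3' end as uniqueness allows and J
tags as close to the 5' end, so that the window between the V tag start
and the J tag end brackets the recombination junction.

Some loci contain subfamilies (e.g. TRBV6-1/6-2/6-3) that are identical
throughout the region a tag may occupy; no tag can tell them apart.  In
``ambiguous="group"`` mode such genes form an ambiguity group sharing a
single tag assigned to the group's first gene in reference order; calls on
any member are reported as that representative.  This is the documented
mechanism behind subfamily-level V mis-assignment.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .trie import AhoCorasick

_DNA = frozenset("ACGT")


class GermlineError(ValueError):
    """Malformed germline reference or annotation."""


class TagBuildError(ValueError):
    """No valid tag placement exists for one or more genes."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline V or J gene (leaderless V-REGION / J-REGION).

    ``conserved_pos`` is the 0-based start of the conserved codon: the
    2nd-CYS cysteine for V genes, the J-PHE phenylalanine for J genes.
    CDR spans are half-open, codon-aligned intervals on V genes.
    """

    name: str
    segment: str  # "V" or "J"
    sequence: str
    conserved_pos: int
    cdr1_span: tuple[int, int] | None = None
    cdr2_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise GermlineError(f"{self.name}: segment must be V or J")
        if not self.sequence:
            raise GermlineError(f"{self.name}: empty sequence")
        if set(self.sequence) - _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise GermlineError(f"{self.name}: non-ACGT characters {bad}")
        if not 0 <= self.conserved_pos <= len(self.sequence) - 3:
            raise GermlineError(
                f"{self.name}: conserved_pos {self.conserved_pos} outside sequence"
            )
        for label, span in (("cdr1", self.cdr1_span), ("cdr2", self.cdr2_span)):
            if span is None:
                continue
            lo, hi = span
            if not (0 <= lo < hi <= len(self.sequence)) or (hi - lo) % 3:
                raise GermlineError(f"{self.name}: bad {label} span {span}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Tag:
    """A gene-identifying keyword.

    ``covers`` lists every gene index the keyword occurs in; for unique
    tags this is just ``(gene_index,)``, for ambiguity-group tags it is
    the whole group with ``gene_index`` the representative.
    """

    keyword: str
    gene_index: int
    offset: int
    covers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.covers:
            object.__setattr__(self, "covers", (self.gene_index,))


def load_germline(fasta_path: str | Path, annotation_path: str | Path) -> list[GermlineGene]:
    """Load germline genes from a FASTA plus a tab-separated annotation table.

    The annotation table has columns ``gene, segment, conserved_pos,
    cdr1_start, cdr1_end, cdr2_start, cdr2_end`` (CDR columns empty for J
    genes).  Genes are returned in FASTA file order; classifier indices
    refer to this order.
    """
    ann: dict[str, dict[str, str]] = {}
    with open(annotation_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["gene"]
            if name in ann:
                raise GermlineError(f"duplicate annotation row for {name}")
            ann[name] = row

    genes: list[GermlineGene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        if name in seen:
            raise GermlineError(f"duplicate gene name {name}")
        seen.add(name)
        if name not in ann:
            raise GermlineError(f"no annotation for gene {name}")
        row = ann[name]
        cdr1 = cdr2 = None
        if row["segment"] == "V":
            if row.get("cdr1_start", "") != "":
                cdr1 = (int(row["cdr1_start"]), int(row["cdr1_end"]))
            if row.get("cdr2_start", "") != "":
                cdr2 = (int(row["cdr2_start"]), int(row["cdr2_end"]))
        genes.append(
            GermlineGene(
                name=name,
                segment=row["segment"],
                sequence=str(rec.seq).upper(),
                conserved_pos=int(row["conserved_pos"]),
                cdr1_span=cdr1,
                cdr2_span=cdr2,
            )
        )
    return genes


def _kmer_index(genes: Sequence[GermlineGene], k: int) -> dict[str, list[int]]:
    """Map every k-mer to the sorted list of gene indices containing it."""
    index: dict[str, set[int]] = {}
    for gi, g in enumerate(genes):
        s = g.sequence
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], set()).add(gi)
    return {kw: sorted(v) for kw, v in index.items()}


def _candidate_starts(gene: GermlineGene, k: int, v_guard: int, v_window: int | None,
                      j_guard: int, j_window: int | None) -> list[int]:
    L = len(gene)
    if gene.segment == "V":
        hi = L - v_guard - k
        lo = 0 if v_window is None else max(0, L - v_window)
        starts = list(range(hi, lo - 1, -1))  # rightmost first
    else:
        lo = j_guard
        hi = (L if j_window is None else min(L, j_window)) - k
        starts = list(range(lo, hi + 1))  # leftmost first
    if not starts:
        raise TagBuildError(
            f"{gene.name}: no room for a {k} nt tag inside the search window"
        )
    return starts


def build_tags(
    genes: Sequence[GermlineGene],
    tag_length: int = 20,
    *,
    v_guard: int = 0,
    v_window: int | None = None,
    j_guard: int = 0,
    j_window: int | None = None,
    ambiguous: str = "error",
) -> list[Tag]:
    """Select one identifying tag per gene (or per ambiguity group).

    V tags are chosen rightmost within their search window, J tags
    leftmost, so the inter-tag region brackets the junction.  ``v_guard``
    / ``j_guard`` keep tags clear of the junction-proximal region that
    recombination may delete; ``v_window`` / ``j_window`` bound how far
    from the junction a tag may sit (reads must still cover it).

    ``ambiguous="error"`` raises :class:`TagBuildError` naming genes with
    no unique placement; ``ambiguous="group"`` lets genes whose entire
    search windows are identical share one tag (see module docstring).
    Deterministic given inputs.
    """
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    if not genes:
        raise ValueError("empty gene list")
    if ambiguous not in ("error", "group"):
        raise ValueError("ambiguous must be 'error' or 'group'")

    index = _kmer_index(genes, tag_length)
    cand = {
        gi: _candidate_starts(g, tag_length, v_guard, v_window, j_guard, j_window)
        for gi, g in enumerate(genes)
    }

    def occurs_once(gi: int, kw: str) -> bool:
        return genes[gi].sequence.count(kw) == 1

    tags: dict[int, Tag] = {}
    unresolved: list[int] = []
    for gi, g in enumerate(genes):
        placed = False
        for start in cand[gi]:
            kw = g.sequence[start : start + tag_length]
            if index[kw] == [gi] and occurs_once(gi, kw):
                tags[gi] = Tag(kw, gi, start)
                placed = True
                break
        if not placed:
            unresolved.append(gi)

    if unresolved and ambiguous == "error":
        names = ", ".join(genes[gi].name for gi in unresolved)
        raise TagBuildError(f"no unique tag placement for: {names}")

    if unresolved:
        # Group genes whose whole candidate window is identical.
        def window(gi: int) -> tuple[str, str]:
            starts = cand[gi]
            lo, hi = min(starts), max(starts)
            return genes[gi].segment, genes[gi].sequence[lo : hi + tag_length]

        groups: dict[tuple[str, str], list[int]] = {}
        for gi in unresolved:
            groups.setdefault(window(gi), []).append(gi)
        for (_, _), members in sorted(groups.items(), key=lambda kv: kv[1][0]):
            members = sorted(members)
            if len(members) < 2:
                raise TagBuildError(
                    f"no unique tag placement for {genes[members[0]].name} "
                    "and its search window matches no other gene exactly"
                )
            rep = members[0]
            placed = False
            for start in cand[rep]:
                kw = genes[rep].sequence[start : start + tag_length]
                if index[kw] == members and all(occurs_once(m, kw) for m in members):
                    tags[rep] = Tag(kw, rep, start, covers=tuple(members))
                    placed = True
                    break
            if not placed:
                names = ", ".join(genes[m].name for m in members)
                raise TagBuildError(f"no shared tag placement for group: {names}")

    out = [tags[gi] for gi in sorted(tags)]
    if len({t.keyword for t in out}) != len(out):  # pragma: no cover - defensive
        raise TagBuildError("internal error: duplicate keywords in tag set")
    return out


def build_trie(tags: Sequence[Tag]) -> AhoCorasick:
    """Build the keyword automaton over a tag set (duplicate keywords raise)."""
    return AhoCorasick([t.keyword for t in tags])


@dataclass
class TagSet:
    """Germline genes + tags + the prebuilt keyword trie.

    ``tags[k]`` corresponds to trie keyword index ``k``.  ``representative``
    maps every covered gene index to the index calls are reported as.
    """

    genes: list[GermlineGene]
    tags: list[Tag]
    trie: AhoCorasick = field(repr=False)
    representative: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.representative:
            self.representative = {
                m: t.gene_index for t in self.tags for m in t.covers
            }

    @classmethod
    def from_genes(cls, genes: Sequence[GermlineGene], **tag_kwargs) -> "TagSet":
        tags = build_tags(genes, **tag_kwargs)
        return cls(genes=list(genes), tags=tags, trie=build_trie(tags))

    # -- convenience lookups -------------------------------------------------
    def segment_of(self, tag_id: int) -> str:
        return self.genes[self.tags[tag_id].gene_index].segment

    def v_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.genes) if g.segment == "V"]

    def j_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.genes) if g.segment == "J"]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for g in self.genes:
            h.update(f"{g.name}:{g.sequence}\n".encode())
        for t in self.tags:
            h.update(f"{t.keyword}@{t.offset}:{t.gene_index}\n".encode())
        return h.hexdigest()[:12]

    # -- serialization -------------------------------------------------------
    def save_tags(self, path: str | Path) -> None:
        """Write the two-column tag file (keyword, gene name)."""
        with open(path, "w") as fh:
            for t in self.tags:
                fh.write(f"{t.keyword}\t{self.genes[t.gene_index].name}\n")

    @classmethod
    def load_tags(cls, path: str | Path, genes: Sequence[GermlineGene]) -> "TagSet":
        """Rebuild a tag set from a two-column tag file and loaded genes.

        Offsets and ambiguity coverage are recomputed against *genes*; a
        keyword that does not occur exactly once in its named gene raises.
        """
        by_name = {g.name: i for i, g in enumerate(genes)}
        tags: list[Tag] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    kw, name = line.split("\t")
                except ValueError as exc:
                    raise GermlineError(f"{path}:{ln}: expected two columns") from exc
                if name not in by_name:
                    raise GermlineError(f"{path}:{ln}: unknown gene {name}")
                gi = by_name[name]
                if genes[gi].sequence.count(kw) != 1:
                    raise GermlineError(
                        f"{path}:{ln}: keyword does not occur exactly once in {name}"
                    )
                covers = tuple(
                    i for i, g in enumerate(genes) if kw in g.sequence
                )
                tags.append(Tag(kw, gi, genes[gi].sequence.index(kw), covers=covers))
        return cls(genes=list(genes), tags=tags, trie=build_trie(tags))


# Tag placement parameters the bundled synthetic human-TRB-like fixture was
# built with: 20 nt tags; V tags within 60 nt of the 3' end but at least
# 20 nt clear of it, J tags at least 16 nt from the 5' end; subfamily
# ambiguity groups enabled.
BUNDLED_TAG_PARAMS = dict(
    tag_length=20, v_guard=20, v_window=60, j_guard=16, ambiguous="group"
)


def load_bundled(name: str = "synthetic_trb") -> TagSet:
    """Load a packaged germline fixture and build its tag set."""
    pkg = resources.files("tcrtag.data")
    fasta = pkg / f"{name}.fasta"
    table = pkg / f"{name}_annotations.tsv"
    with resources.as_file(fasta) as fp, resources.as_file(table) as tp:
        genes = load_germline(fp, tp)
    return TagSet.from_genes(genes, **BUNDLED_TAG_PARAMS)
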