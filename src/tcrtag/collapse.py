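"""UMI-based PCR/sequencing error correction.

Reads are first grouped by exact barcode (UMI).  Groups are then compared
pairwise: if two groups' barcodes are within the barcode threshold
``th_bc`` (Levenshtein distance) and their most frequent TCR sequences are
within the sequence threshold ``th_tcr`` (percentage Levenshtein distance,
edit distance weighted by sequence length), the groups merge into a
cluster — the smaller group is absorbed by the larger, whose barcode
remains the representative, and the dominant TCR sequence is recomputed
after every merge.  Sweeps repeat until a fixed point.  One cluster
estimates one pre-PCR molecule; the output per distinct classifier is the
number of clusters carrying it (TCR count) and the mean cluster size in
reads (BC count).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .decombine import AnnotatedRead, Classifier


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def percent_levenshtein(a: str, b: str) -> float:
    """Edit distance as a percentage of the longer sequence's length."""
    if not a or not b:
        raise ValueError("percent_levenshtein requires non-empty sequences")
    return 100.0 * levenshtein(a, b) / max(len(a), len(b))


@dataclass(slots=True)
class CollapseConfig:
    """User-configurable merge thresholds (and optional input quality gate)."""

    th_bc: int = 2
    th_tcr: float = 10.0
    min_umi_qual: float | None = None
    max_sweeps: int = 10

    def __post_init__(self) -> None:
        if self.th_bc < 0:
            raise ValueError("th_bc must be >= 0")
        if not 0.0 <= self.th_tcr <= 100.0:
            raise ValueError("th_tcr must be in [0, 100]")


def _top_seq(counts: Counter) -> str:
    """Most frequent sequence; ties broken lexicographically smallest."""
    best = max(counts.values())
    return min(s for s, c in counts.items() if c == best)


@dataclass(slots=True)
class BarcodeGroup:
    """All reads sharing one exact barcode."""

    barcode: str
    members: list[AnnotatedRead]
    seq_counts: Counter = field(default_factory=Counter)
    seq_classifier: dict = field(default_factory=dict)
    top_tcr: str = ""

    @classmethod
    def from_reads(cls, barcode: str, reads: list[AnnotatedRead]) -> "BarcodeGroup":
        counts: Counter = Counter()
        clf: dict[str, Classifier] = {}
        for r in reads:
            counts[r.inter_tag_seq] += 1
            clf.setdefault(r.inter_tag_seq, r.classifier)
        return cls(barcode, reads, counts, clf, _top_seq(counts))

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class Cluster:
    """One or more merged barcode groups ≈ one pre-PCR molecule."""

    groups: list[BarcodeGroup]
    barcode: str
    seq_counts: Counter
    seq_classifier: dict
    size: int
    top_tcr: str

    @classmethod
    def from_group(cls, g: BarcodeGroup) -> "Cluster":
        return cls([g], g.barcode, Counter(g.seq_counts),
                   dict(g.seq_classifier), g.size, g.top_tcr)

    def absorb(self, other: "Cluster") -> None:
        self.groups.extend(other.groups)
        self.seq_counts.update(other.seq_counts)
        for s, c in other.seq_classifier.items():
            self.seq_classifier.setdefault(s, c)
        self.size += other.size
        self.top_tcr = _top_seq(self.seq_counts)

    def consensus_classifier(self) -> Classifier:
        return self.seq_classifier[self.top_tcr]


@dataclass(slots=True)
class CollapsedTCR:
    """Error-corrected TCR: molecule count and mean reads per molecule."""

    classifier: Classifier
    tcr_count: int
    bc_count: float


def group_by_barcode(reads: Iterable[AnnotatedRead]) -> list[BarcodeGroup]:
    """One group per exact barcode, returned in barcode order."""
    by_bc: dict[str, list[AnnotatedRead]] = defaultdict(list)
    for r in reads:
        by_bc[r.barcode].append(r)
    return [BarcodeGroup.from_reads(bc, by_bc[bc]) for bc in sorted(by_bc)]


def _order_key(c: Cluster) -> tuple[int, str]:
    return (-c.size, c.barcode)


def merge_groups(groups: Sequence[BarcodeGroup], cfg: CollapseConfig | None = None) -> list[Cluster]:
    """Pairwise-merge barcode groups into clusters under the two thresholds.

    Comparison order is deterministic: descending group size, then barcode
    lexicographic; the earlier (larger) cluster absorbs the later one and
    keeps its barcode.  Sweeps repeat until no merge occurs, capped at
    ``cfg.max_sweeps`` with a warning.

    Performance: when ``th_tcr`` < 25% clusters are only compared within
    buckets sharing the (V, J) call of their dominant sequence.  Dominant
    sequences with different V or J calls differ by at least one whole tag
    (≥ 20 nt), which at such thresholds can never satisfy ``th_tcr``, so
    the restriction does not change the result.
    """
    cfg = cfg or CollapseConfig()
    clusters = [Cluster.from_group(g) for g in groups]

    def bucket_key(c: Cluster):
        clf = c.seq_classifier[c.top_tcr]
        return (clf.v_index, clf.j_index)

    if cfg.th_tcr < 25.0:
        buckets: dict[tuple, list[Cluster]] = defaultdict(list)
        for c in clusters:
            buckets[bucket_key(c)].append(c)
        worklists = list(buckets.values())
    else:
        worklists = [clusters]

    th_bc, th_tcr = cfg.th_bc, cfg.th_tcr
    for sweep in range(cfg.max_sweeps):
        merged_any = False
        for wl in worklists:
            wl.sort(key=_order_key)
            alive = [True] * len(wl)
            for i in range(len(wl)):
                if not alive[i]:
                    continue
                ci = wl[i]
                for j in range(i + 1, len(wl)):
                    if not alive[j]:
                        continue
                    cj = wl[j]
                    if levenshtein(ci.barcode, cj.barcode) > th_bc:
                        continue
                    if percent_levenshtein(ci.top_tcr, cj.top_tcr) > th_tcr:
                        continue
                    ci.absorb(cj)
                    alive[j] = False
                    merged_any = True
            wl[:] = [c for c, a in zip(wl, alive) if a]
        if not merged_any:
            break
    else:
        warnings.warn(
            f"barcode clustering did not reach a fixed point in "
            f"{cfg.max_sweeps} sweeps", RuntimeWarning,
        )
    out = [c for wl in worklists for c in wl]
    out.sort(key=_order_key)
    return out


def collapse(clusters: Sequence[Cluster]) -> list[CollapsedTCR]:
    """Aggregate clusters into error-corrected TCRs.

    Each cluster votes once for the classifier of its dominant sequence
    (recomputed over all member reads after merging).  Per distinct
    classifier: TCR count = number of clusters, BC count = mean cluster
    size.  Sorted by descending TCR count, then classifier.
    """
    agg: dict[Classifier, list[int]] = defaultdict(lambda: [0, 0])
    for c in clusters:
        clf = c.consensus_classifier()
        agg[clf][0] += 1
        agg[clf][1] += c.size
    out = [
        CollapsedTCR(clf, n, total / n)
        for clf, (n, total) in agg.items()
    ]
    out.sort(key=lambda t: (-t.tcr_count, t.classifier))
    return out


def collapse_reads(
    reads: Iterable[AnnotatedRead], cfg: CollapseConfig | None = None
) -> list[CollapsedTCR]:
    """group_by_barcode → merge_groups → collapse in one call."""
    return collapse(merge_groups(group_by_barcode(reads), cfg))


# ---------------------------------------------------------------------------
# Collapsed format I/O
# ---------------------------------------------------------------------------

def write_collapsed(tcrs: Iterable[CollapsedTCR], path: str | Path) -> None:
    """v, j, v_del, j_del, insert, tcr_count, bc_count — one TCR per line."""
    with open(path, "w") as fh:
        for t in tcrs:
            c = t.classifier
            fh.write(
                f"{c.v_index},{c.j_index},{c.v_deletions},{c.j_deletions},"
                f"{c.insert},{t.tcr_count},{t.bc_count:.6g}\n"
            )


def read_collapsed(path: str | Path) -> list[CollapsedTCR]:
    out: list[CollapsedTCR] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 fields")
            v, j, vd, jd, ins, n, bc = fields
            out.append(
                CollapsedTCR(
                    Classifier(int(v), int(j), int(vd), int(jd), ins),
                    int(n), float(bc),
                )
            )
    return out
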