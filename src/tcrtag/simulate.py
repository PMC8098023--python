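"""Synthetic repertoire, PCR and sequencing simulation, and scoring.

The generator is a parameterized surrogate for a learned V(D)J
recombination model: V and J drawn uniformly (or from supplied frequency
tables), junctional deletions geometric, non-templated insert lengths
Poisson with uniform composition.  Each distinct rearranged sequence is a
ground-truth TCR with a pre-PCR molecule count; every molecule receives a
random UMI, is amplified through doubling PCR rounds with per-base
substitution errors that propagate to descendants, and every final copy
is "sequenced" with independent per-base substitution errors on both the
TCR read and the UMI read.

Scoring closes the loop: annotation accuracy against the generator's
classifiers and junctions, and collapse recovery/spurious/abundance
fidelity against the pre-PCR molecule counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .collapse import CollapsedTCR
from .decombine import (
    AnnotatedRead,
    Classifier,
    NoCall,
    _annotate_oriented,
    canonical_classifier,
    reconstruct_sequence,
)
from .germline import TagSet
from .translate import extract_junction

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the simulated evaluation.

    Defaults reproduce the benchmark operating point: 10,000 distinct
    rearrangements, molecule counts of 1 + Poisson(2.7), geometric
    deletions of mean 4 capped at 14 nt, Poisson(6) inserts, 3 PCR
    doubling rounds at 8.5e-5 substitutions/base/duplication, sequencing
    at 1e-3 substitutions/base, and a 12 nt UMI carried on a second read
    as two 6-mers flanking a 4 nt spacer.
    """

    n_tcrs: int = 10_000
    abundance_lambda: float = 2.7
    v_del_mean: float = 4.0
    j_del_mean: float = 4.0
    max_deletions: int = 14
    insert_len_mean: float = 6.0
    pcr_rounds: int = 3
    pcr_error_rate: float = 8.5e-5
    seq_error_rate: float = 1e-3
    umi_length: int = 12
    umi_spacer: str = "GTCA"
    seed: int = 0
    v_freqs: Sequence[float] | None = None
    j_freqs: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "seq_error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_tcrs < 1 or self.pcr_rounds < 0 or self.umi_length < 1:
            raise ValueError("counts must be positive")

    @property
    def umi_spec(self) -> str:
        half = self.umi_length // 2
        rest = self.umi_length - half
        return f"N{half}S{len(self.umi_spacer)}N{rest}"


@dataclass(slots=True)
class GroundTruthTCR:
    truth_id: int
    classifier: Classifier
    sequence: str
    junction: str | None
    junction_aa: str
    abundance: int


@dataclass(slots=True)
class Molecule:
    """One PCR lineage: a pre-PCR molecule's UMI and its final copies,
    aggregated by distinct sequence."""

    origin_id: int
    umi: str
    seq_copies: list[tuple[str, int]]  # (sequence, number of identical copies)

    @property
    def copies(self) -> int:
        return sum(c for _, c in self.seq_copies)


@dataclass(slots=True)
class ReadPair:
    read_id: str
    tcr_seq: str
    tcr_qual: str
    umi_read: str
    umi_qual: str
    origin_id: int


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=n))


def _trunc_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    return min(int(rng.geometric(p)) - 1, cap)


def _mutate(rng: np.random.Generator, seq: str, n_errors: int) -> str:
    """Apply n_errors substitutions at distinct random positions."""
    positions = rng.choice(len(seq), size=min(n_errors, len(seq)), replace=False)
    s = list(seq)
    for pos in positions:
        old = s[pos]
        choices = _BASE_STR.replace(old, "")
        s[pos] = choices[rng.integers(0, 3)]
    return "".join(s)


def _n_errors_positive(rng: np.random.Generator, length: int, rate: float) -> int:
    """Sample from Binomial(length, rate) conditioned on being >= 1."""
    while True:
        k = int(rng.binomial(length, rate))
        if k > 0:
            return k


def simulate_repertoire(cfg: SimConfig, tagset: TagSet,
                        rng: np.random.Generator | None = None) -> list[GroundTruthTCR]:
    """Draw ``cfg.n_tcrs`` distinct ground-truth rearrangements.

    Classifiers are recorded in canonical form (maximal germline
    attribution, V side first) so they compare exactly against annotation
    output; sequences are deduplicated.  Deterministic given the seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genes = tagset.genes
    v_idx = tagset.v_indices()
    j_idx = tagset.j_indices()
    v_p = None if cfg.v_freqs is None else np.asarray(cfg.v_freqs) / np.sum(cfg.v_freqs)
    j_p = None if cfg.j_freqs is None else np.asarray(cfg.j_freqs) / np.sum(cfg.j_freqs)

    out: list[GroundTruthTCR] = []
    seen: set[str] = set()
    while len(out) < cfg.n_tcrs:
        v = v_idx[rng.choice(len(v_idx), p=v_p)]
        j = j_idx[rng.choice(len(j_idx), p=j_p)]
        vd = _trunc_geometric(rng, cfg.v_del_mean, cfg.max_deletions)
        jd = _trunc_geometric(rng, cfg.j_del_mean, cfg.max_deletions)
        ins = _rand_dna(rng, int(rng.poisson(cfg.insert_len_mean)))
        clf = canonical_classifier(Classifier(v, j, vd, jd, ins), genes)
        seq = reconstruct_sequence(clf, genes)
        if seq in seen:
            continue
        seen.add(seq)
        junction, junction_aa = extract_junction(clf, genes)
        abundance = 1 + int(rng.poisson(cfg.abundance_lambda))
        out.append(GroundTruthTCR(len(out), clf, seq, junction, junction_aa, abundance))
    return out


def simulate_pcr(truth: Sequence[GroundTruthTCR], cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> list[Molecule]:
    """Amplify every pre-PCR molecule through ``cfg.pcr_rounds`` doubling
    rounds; each duplication acquires independent per-base substitutions at
    ``cfg.pcr_error_rate``, and errors propagate to descendants."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    molecules: list[Molecule] = []
    e = cfg.pcr_error_rate
    for t in truth:
        L = len(t.sequence)
        p_any = 1.0 - (1.0 - e) ** L
        for _ in range(t.abundance):
            umi = _rand_dna(rng, cfg.umi_length)
            pool: dict[str, int] = {t.sequence: 1}
            for _round in range(cfg.pcr_rounds):
                nxt: dict[str, int] = {}
                for seq, count in pool.items():
                    children = 2 * count
                    k_mut = int(rng.binomial(children, p_any)) if e > 0 else 0
                    if children - k_mut:
                        nxt[seq] = nxt.get(seq, 0) + children - k_mut
                    for _m in range(k_mut):
                        mut = _mutate(rng, seq, _n_errors_positive(rng, L, e))
                        nxt[mut] = nxt.get(mut, 0) + 1
                pool = nxt
            molecules.append(Molecule(t.truth_id, umi, sorted(pool.items())))
    return molecules


def _umi_read(umi: str, spacer: str) -> str:
    half = len(umi) // 2
    return umi[:half] + spacer + umi[half:]


def simulate_sequencing(molecules: Sequence[Molecule], cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> list[ReadPair]:
    """Sequence every final PCR copy: independent per-base substitutions at
    ``cfg.seq_error_rate`` on the TCR read and on the UMI read.  Quality
    strings are flat at the Phred score matching the error rate."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    e = cfg.seq_error_rate
    q = 40 if e <= 0 else min(40, int(round(-10 * np.log10(e))))
    qchar = chr(q + 33)
    reads: list[ReadPair] = []
    ridx = 0
    for mol in molecules:
        umi_read = _umi_read(mol.umi, cfg.umi_spacer)
        lu = len(umi_read)
        pu = 1.0 - (1.0 - e) ** lu
        uqual = qchar * lu
        for seq, count in mol.seq_copies:
            L = len(seq)
            pt = 1.0 - (1.0 - e) ** L
            tqual = qchar * L
            k_t = int(rng.binomial(count, pt)) if e > 0 else 0
            k_u = int(rng.binomial(count, pu)) if e > 0 else 0
            # Which copies carry TCR-read / UMI-read errors: assign randomly,
            # independently (overlap allowed).
            flags_t = np.zeros(count, dtype=bool)
            flags_u = np.zeros(count, dtype=bool)
            if k_t:
                flags_t[rng.choice(count, size=k_t, replace=False)] = True
            if k_u:
                flags_u[rng.choice(count, size=k_u, replace=False)] = True
            for ft, fu in zip(flags_t, flags_u):
                tseq = _mutate(rng, seq, _n_errors_positive(rng, L, e)) if ft else seq
                useq = _mutate(rng, umi_read, _n_errors_positive(rng, lu, e)) if fu else umi_read
                reads.append(ReadPair(f"r{ridx}", tseq, tqual, useq, uqual, mol.origin_id))
                ridx += 1
    return reads


def write_fastq_pair(reads: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write the simulated reads as a paired FASTQ (origin id in the comment)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id} origin={r.origin_id}\n{r.tcr_seq}\n+\n{r.tcr_qual}\n")
            f2.write(f"@{r.read_id} origin={r.origin_id}\n{r.umi_read}\n+\n{r.umi_qual}\n")


def write_truth(truth: Iterable[GroundTruthTCR], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("truth_id\tv\tj\tv_deletions\tj_deletions\tinsert\t"
                 "sequence\tjunction\tjunction_aa\tabundance\n")
        for t in truth:
            c = t.classifier
            fh.write(
                f"{t.truth_id}\t{c.v_index}\t{c.j_index}\t{c.v_deletions}\t"
                f"{c.j_deletions}\t{c.insert}\t{t.sequence}\t"
                f"{t.junction or ''}\t{t.junction_aa}\t{t.abundance}\n"
            )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_annotation(
    results: Sequence[AnnotatedRead | NoCall],
    truth: Sequence[GroundTruthTCR],
    tagset: TagSet,
) -> tuple[float, float]:
    """(classifier accuracy, junction accuracy) of per-read annotation.

    ``results[i]`` is the annotation of a read generated from ``truth[i]``.
    A read is classifier-correct when its five-part classifier equals the
    generator's (no-calls count as incorrect), and junction-correct when
    the junction nucleotide sequence implied by its classifier equals the
    generator's (both absent also counts as correct).
    """
    if len(results) != len(truth):
        raise ValueError("results and truth must align one-to-one")
    genes = tagset.genes
    junction_cache: dict[Classifier, str | None] = {}
    n_clf = n_jct = 0
    for res, t in zip(results, truth):
        if isinstance(res, NoCall):
            continue
        if res.classifier == t.classifier:
            n_clf += 1
        jct = junction_cache.get(res.classifier, "__miss__")
        if jct == "__miss__":
            jct = extract_junction(res.classifier, genes)[0]
            junction_cache[res.classifier] = jct
        if jct == t.junction:
            n_jct += 1
    n = len(truth)
    return n_clf / n, n_jct / n


def annotate_truth(
    truth: Sequence[GroundTruthTCR], tagset: TagSet
) -> dict[Classifier, int]:
    """Annotate the error-free pre-PCR sequences themselves.

    Returns classifier -> total pre-PCR molecule count: the reference the
    collapse stage is scored against — what the annotator would report
    with no PCR or sequencing noise at all.  Truth sequences the tag set
    cannot classify (none, for the bundled references) are skipped.
    """
    out: dict[Classifier, int] = {}
    for t in truth:
        res = _annotate_oriented(t.sequence, tagset)
        if isinstance(res, str):
            continue
        clf = res[0]
        out[clf] = out.get(clf, 0) + t.abundance
    return out


def score_collapse(
    collapsed: Sequence[CollapsedTCR],
    truth_abundance: dict[Classifier, int],
) -> tuple[int, int, float]:
    """(n_recovered, n_spurious, abundance Pearson r).

    ``truth_abundance`` maps each pre-PCR classifier to its molecule
    count (see :func:`annotate_truth`).  Recovered = truth classifiers
    present in the collapsed output; spurious = output classifiers absent
    from truth; r is computed over the recovered classifiers between the
    true molecule count and the reported TCR count.
    """
    by_clf = {t.classifier: t.tcr_count for t in collapsed}
    recovered = [c for c in truth_abundance if c in by_clf]
    n_spurious = sum(1 for c in by_clf if c not in truth_abundance)
    if len(recovered) >= 2:
        x = np.array([truth_abundance[c] for c in recovered], dtype=float)
        y = np.array([by_clf[c] for c in recovered], dtype=float)
        if x.std() == 0 or y.std() == 0:
            r = 1.0 if np.allclose(x / x.mean(), y / y.mean()) else 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = float("nan")
    return len(recovered), n_spurious, r


# ---------------------------------------------------------------------------
# End-to-end evaluation drivers
# ---------------------------------------------------------------------------

def run_annotation_eval(cfg: SimConfig, tagset: TagSet) -> dict:
    """Annotation accuracy on one error-free read per ground-truth TCR."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_repertoire(cfg, tagset, rng)
    results: list[AnnotatedRead | NoCall] = []
    for t in truth:
        res = _annotate_oriented(t.sequence, tagset)
        if isinstance(res, str):
            results.append(NoCall(f"t{t.truth_id}", res))
        else:
            clf, (a, b) = res
            results.append(AnnotatedRead(clf, "", t.sequence[a:b], f"t{t.truth_id}"))
    clf_acc, jct_acc = score_annotation(results, truth, tagset)
    return {
        "n_tcrs": len(truth),
        "classifier_accuracy": clf_acc,
        "junction_accuracy": jct_acc,
    }


def run_collapse_eval(cfg: SimConfig, tagset: TagSet,
                      collapse_cfg=None) -> dict:
    """Full simulate → amplify → sequence → annotate → collapse → score chain."""
    from .collapse import CollapseConfig, collapse_reads
    from .decombine import annotate_records

    rng = np.random.default_rng(cfg.seed)
    truth = simulate_repertoire(cfg, tagset, rng)
    molecules = simulate_pcr(truth, cfg, rng)
    reads = simulate_sequencing(molecules, cfg, rng)
    annotated, stats = annotate_records(
        ((r.read_id, r.tcr_seq, r.tcr_qual, r.umi_read, r.umi_qual) for r in reads),
        tagset,
        umi_spec=cfg.umi_spec,
    )
    collapsed = collapse_reads(annotated, collapse_cfg or CollapseConfig())
    truth_abundance = annotate_truth(truth, tagset)
    n_recovered, n_spurious, r = score_collapse(collapsed, truth_abundance)
    return {
        "n_tcrs": len(truth),
        "n_truth_classifiers": len(truth_abundance),
        "n_molecules": sum(t.abundance for t in truth),
        "n_reads": len(reads),
        "read_stats": dict(stats),
        "n_collapsed": len(collapsed),
        "n_recovered": n_recovered,
        "n_lost": len(truth_abundance) - n_recovered,
        "n_spurious": n_spurious,
        "abundance_r": r,
    }
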