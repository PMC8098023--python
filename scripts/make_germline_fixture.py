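"""Generate the bundled synthetic human-TRB-like germline fixture.

Writes ``src/tcrtag/data/synthetic_trb.fasta`` and
``synthetic_trb_annotations.tsv``: 41 V genes (300 nt, leaderless, in
frame, conserved 2nd-CYS codon at 285, CDR1 at 78-96, CDR2 at 144-162)
and 13 J genes (62 nt, conserved J-PHE codon at 26).  The locus mimics
the property of the real TRB locus that drives subfamily-level V
mis-assignment: TRBV6-1/6-2/6-3 and TRBV12-1/12-2 are identical
throughout the tag search window, so tags cannot tell them apart.
TRBV6-3 additionally differs from TRBV6-1 between the tag window and the
conserved cysteine (position 282), so reads from it are mis-reconstructed
around the junction; TRBV6-2 and TRBV12-2 differ only upstream (CDR1/2
region), so their junctions survive mis-assignment.

The fixture is fully synthetic (no IMGT material); it is deterministic
under the fixed seed below and committed to the repository — rerunning
this script must reproduce the committed files byte for byte.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from tcrtag.germline import BUNDLED_TAG_PARAMS, TagSet, load_germline  # noqa: E402

SEED = 20200827
V_LEN = 300
CYS_POS = 285
CDR1 = (78, 96)
CDR2 = (144, 162)
J_LEN = 62
PHE_POS = 26

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

V_NAMES = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV5-1", "TRBV5-4",
    "TRBV5-5", "TRBV5-6", "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4",
    "TRBV7-2", "TRBV7-3", "TRBV7-6", "TRBV7-8", "TRBV9", "TRBV10-1",
    "TRBV10-3", "TRBV11-1", "TRBV11-2", "TRBV12-1", "TRBV12-2", "TRBV13",
    "TRBV14", "TRBV15", "TRBV16", "TRBV18", "TRBV19", "TRBV20-1",
    "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1", "TRBV30",
    "TRBV5-8", "TRBV7-9", "TRBV10-2", "TRBV11-3", "TRBV23-1",
]
J_NAMES = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]


def rand_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS:
            return c


def make_v(rng: np.random.Generator) -> str:
    codons = [rand_codon(rng) for _ in range(V_LEN // 3)]
    codons[CYS_POS // 3] = "TGT" if rng.integers(0, 2) else "TGC"
    return "".join(codons)


def make_j(rng: np.random.Generator) -> str:
    head = "".join(BASES[i] for i in rng.integers(0, 4, PHE_POS))
    codons = [rand_codon(rng) for _ in range((J_LEN - PHE_POS) // 3)]
    codons[0] = "TTT" if rng.integers(0, 2) else "TTC"
    return head + "".join(codons)


def substitute(rng: np.random.Generator, seq: str, pos: int) -> str:
    """Substitute one base keeping the in-frame codon stop-free."""
    for _ in range(100):
        new = BASES[rng.integers(0, 4)]
        if new == seq[pos]:
            continue
        s = seq[:pos] + new + seq[pos + 1 :]
        cstart = pos - pos % 3
        if s[cstart : cstart + 3] not in STOPS:
            return s
    raise RuntimeError("could not substitute")


def diverge(rng: np.random.Generator, seq: str, region: tuple[int, int], n: int) -> str:
    lo, hi = region
    for pos in sorted(rng.choice(np.arange(lo, hi), size=n, replace=False)):
        seq = substitute(rng, seq, int(pos))
    return seq


def main() -> None:
    rng = np.random.default_rng(SEED)
    v_seqs: dict[str, str] = {}
    for name in V_NAMES:
        if name in ("TRBV6-2", "TRBV6-3", "TRBV12-2"):
            continue
        v_seqs[name] = make_v(rng)
    # Subfamilies: identical downstream of the CDR2 region except where noted.
    v_seqs["TRBV6-2"] = diverge(rng, v_seqs["TRBV6-1"], (CDR1[0], 170), 6)
    v63 = diverge(rng, v_seqs["TRBV6-1"], (CDR1[0], 170), 4)
    v_seqs["TRBV6-3"] = substitute(rng, v63, 282)
    assert v_seqs["TRBV6-3"][282] != v_seqs["TRBV6-1"][282]
    v_seqs["TRBV12-2"] = diverge(rng, v_seqs["TRBV12-1"], (CDR1[0], 170), 5)

    j_seqs = {name: make_j(rng) for name in J_NAMES}

    data = ROOT / "src" / "tcrtag" / "data"
    data.mkdir(parents=True, exist_ok=True)
    fasta = data / "synthetic_trb.fasta"
    table = data / "synthetic_trb_annotations.tsv"
    with open(fasta, "w") as fh:
        for name in V_NAMES:
            fh.write(f">{name}\n{v_seqs[name]}\n")
        for name in J_NAMES:
            fh.write(f">{name}\n{j_seqs[name]}\n")
    with open(table, "w") as fh:
        fh.write("gene\tsegment\tconserved_pos\tcdr1_start\tcdr1_end\t"
                 "cdr2_start\tcdr2_end\n")
        for name in V_NAMES:
            fh.write(f"{name}\tV\t{CYS_POS}\t{CDR1[0]}\t{CDR1[1]}\t"
                     f"{CDR2[0]}\t{CDR2[1]}\n")
        for name in J_NAMES:
            fh.write(f"{name}\tJ\t{PHE_POS}\t\t\t\t\n")

    # Sanity: the tag set must build, with exactly the designed ambiguity
    # groups and unique tags everywhere else.
    genes = load_germline(fasta, table)
    ts = TagSet.from_genes(genes, **BUNDLED_TAG_PARAMS)
    by_name = {g.name: i for i, g in enumerate(genes)}
    groups = {tuple(sorted(t.covers)) for t in ts.tags if len(t.covers) > 1}
    expected = {
        tuple(sorted(by_name[n] for n in ("TRBV6-1", "TRBV6-2", "TRBV6-3"))),
        tuple(sorted(by_name[n] for n in ("TRBV12-1", "TRBV12-2"))),
    }
    assert groups == expected, groups
    assert len(ts.tags) == len(V_NAMES) - 3 + len(J_NAMES)
    print(f"wrote {fasta} ({len(V_NAMES)} V, {len(J_NAMES)} J), "
          f"{len(ts.tags)} tags, checksum {ts.checksum()}")


if __name__ == "__main__":
    main()
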