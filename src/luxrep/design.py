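"""Degenerate-promoter design: IUPAC sequence algebra, consensus
determination, library-space enumeration and degenerate-primer assembly.

The LuxR-repressible promoters share a fixed 20-bp lux box operator
(ACCTGTAGGATCGTACAGGT) in the core, flanked by variable -35 and -10
hexamers.  Because the lux box's first base (A) doubles as the last base of
the -35 hexamer and its last base (T) as the first base of the -10 hexamer,
each promoter is stored as a 5-nt -35 segment, the 20-nt core, a 5-nt -10
segment and a proximal segment.  The library consensus is written in IUPAC
degenerate codes over the two 5-nt variable segments; the shipped consensus
(YTKAY / lux box / AYWRT) spans 8 x 8 = 64 concrete promoter sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

LUX_BOX = "ACCTGTAGGATCGTACAGGT"

#: IUPAC nucleotide codes -> the set of concrete bases each denotes
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
#: base set -> smallest IUPAC code covering exactly that set
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC.items()}


class DesignError(ValueError):
    pass


def _validate(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if not s:
        raise DesignError(f"empty {what}")
    bad = set(s) - set(IUPAC)
    if bad:
        raise DesignError(f"invalid IUPAC residue(s) {sorted(bad)} in {what} {seq!r}")
    return s


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate sequence denotes
    (product of per-position degeneracies)."""
    s = _validate(seq)
    n = 1
    for c in s:
        n *= len(IUPAC[c])
    return n


def expand_degenerate(seq: str) -> list[str]:
    """All concrete A/C/G/T sequences matching a degenerate sequence,
    in lexicographic per-position order."""
    s = _validate(seq)
    return ["".join(p) for p in product(*(sorted(IUPAC[c]) for c in s))]


def matches(seq: str, pattern: str) -> bool:
    """True iff every base of the concrete ``seq`` is allowed by the
    corresponding ``pattern`` residue. Case-insensitive, sense strand only."""
    s = _validate(seq, "seq")
    p = _validate(pattern, "pattern")
    if len(s) != len(p):
        raise DesignError(f"length mismatch: {len(s)} vs {len(p)}")
    return all(b in IUPAC[c] for b, c in zip(s, p))


def minimal_cover(bases: Iterable[str]) -> str:
    """Smallest IUPAC code containing exactly the observed base set."""
    s = frozenset(b.upper() for b in bases)
    if not s <= set("ACGT") or not s:
        raise DesignError(f"invalid base set {sorted(s)}")
    return _SET_TO_CODE[s]


@dataclass(frozen=True)
class PromoterRecord:
    """A library member decomposed into -35 / lux-box core / -10 / proximal.

    The effective -35 hexamer is ``minus35`` plus the first core base; the
    effective -10 hexamer is the last core base plus ``minus10``.
    """

    name: str
    minus35: str
    core: str
    minus10: str
    proximal: str
    #: clone identifier from the screening rounds ("2", "122", ...)
    clone_id: str = ""

    def __post_init__(self) -> None:
        for f, n in (("minus35", 5), ("core", 20), ("minus10", 5)):
            v = _validate(getattr(self, f), f)
            if len(v) != n:
                raise DesignError(f"{self.name}: {f} must be {n} nt, got {len(v)}")
            object.__setattr__(self, f, v)
        object.__setattr__(self, "proximal", _validate(self.proximal, "proximal"))

    @property
    def sequence(self) -> str:
        return self.minus35 + self.core + self.minus10 + self.proximal

    @property
    def minus35_hexamer(self) -> str:
        return self.minus35 + self.core[0]

    @property
    def minus10_hexamer(self) -> str:
        return self.core[-1] + self.minus10


@dataclass(frozen=True)
class ConsensusSpec:
    """Degenerate library consensus: variable 5-nt -35 and -10 segments
    around a fixed lux box, plus the fixed proximal sequence."""

    minus35_consensus: str
    lux_box: str = LUX_BOX
    minus10_consensus: str = ""
    proximal: str = "GCTAGC"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for f in ("minus35_consensus", "minus10_consensus", "lux_box", "proximal"):
            object.__setattr__(self, f, _validate(getattr(self, f), f))
        if len(self.minus35_consensus) != 5 or len(self.minus10_consensus) != 5:
            raise DesignError("consensus segments must be 5 nt")

    @property
    def degenerate_sequence(self) -> str:
        """-35 consensus + lux box + -10 consensus (the degenerate promoter
        region, without the fixed proximal)."""
        return self.minus35_consensus + self.lux_box + self.minus10_consensus

    @property
    def cardinality(self) -> int:
        return degeneracy(self.minus35_consensus) * degeneracy(self.minus10_consensus)

    def enumerate_members(self) -> list[str]:
        """All concrete promoter sequences (variable segments expanded,
        lux box and proximal fixed)."""
        return [
            m35 + self.lux_box + m10 + self.proximal
            for m35 in expand_degenerate(self.minus35_consensus)
            for m10 in expand_degenerate(self.minus10_consensus)
        ]

    def contains(self, record: PromoterRecord) -> bool:
        return (
            matches(record.minus35, self.minus35_consensus)
            and record.core == self.lux_box
            and matches(record.minus10, self.minus10_consensus)
        )


def consensus_from_collection(
    hexamers: Sequence[tuple[str, str]],
    lux_box: str = LUX_BOX,
    proximal: str = "GCTAGC",
) -> ConsensusSpec:
    """Build the library consensus from a collection of constitutive-promoter
    (-35 hexamer, -10 hexamer) pairs.

    Only promoters whose -35 hexamer ends in A and whose -10 hexamer starts
    with T are admissible (those boundary bases coincide with the first and
    last base of the lux box); the rest are excluded and counted.  For each
    of the 5 variable positions of each segment the minimal IUPAC code
    covering the observed bases is taken.
    """
    admissible: list[tuple[str, str]] = []
    n_excluded = 0
    for m35, m10 in hexamers:
        m35, m10 = _validate(m35, "-35 hexamer"), _validate(m10, "-10 hexamer")
        if len(m35) != 6 or len(m10) != 6:
            raise DesignError("hexamers must be 6 nt")
        if m35[-1] == "A" and m10[0] == "T":
            admissible.append((m35[:5], m10[1:]))
        else:
            n_excluded += 1
    if not admissible:
        raise DesignError("empty consensus input: no promoter satisfies the "
                          "boundary constraint (-35 ends in A, -10 starts with T)")
    m35_cons = "".join(
        minimal_cover(p[0][i] for p in admissible) for i in range(5)
    )
    m10_cons = "".join(
        minimal_cover(p[1][i] for p in admissible) for i in range(5)
    )
    return ConsensusSpec(
        minus35_consensus=m35_cons, lux_box=lux_box,
        minus10_consensus=m10_cons, proximal=proximal, n_excluded=n_excluded,
    )


def assemble_degenerate_primer(
    consensus: ConsensusSpec, prefix: str = "", anneal_tail: str = ""
) -> str:
    """Forward library primer: cloning prefix + degenerate promoter region
    (-35 consensus, lux box, -10 consensus, proximal) + annealing tail."""
    if prefix:
        _validate(prefix, "prefix")
    if anneal_tail:
        _validate(anneal_tail, "anneal_tail")
    return (
        prefix.upper()
        + consensus.degenerate_sequence
        + consensus.proximal
        + anneal_tail.upper()
    )


def parse_primer_consensus(primer: str, lux_box: str = LUX_BOX) -> ConsensusSpec:
    """Recover the library consensus from a degenerate forward primer.

    The fixed lux box is located in the primer; the 5 nt on either side of
    it are the -35 and -10 consensus segments (they may mix degenerate and
    concrete residues), and the 6 nt after the -10 consensus are the fixed
    proximal sequence.
    """
    p = _validate(primer, "primer")
    pos = p.find(lux_box)
    if pos < 0:
        raise DesignError(f"primer does not contain the lux box {lux_box!r}")
    if pos < 5 or pos + len(lux_box) + 11 > len(p):
        raise DesignError("primer truncated around the lux box")
    m35 = p[pos - 5:pos]
    m10 = p[pos + len(lux_box):pos + len(lux_box) + 5]
    proximal = p[pos + len(lux_box) + 5:pos + len(lux_box) + 11]
    return ConsensusSpec(
        minus35_consensus=m35, lux_box=lux_box,
        minus10_consensus=m10, proximal=proximal,
    )


def unique_members(
    records: Sequence[PromoterRecord],
) -> tuple[int, list[PromoterRecord]]:
    """Deduplicate on the full concatenated promoter sequence, keeping the
    first occurrence of each; returns (count, deduplicated records)."""
    seen: dict[str, PromoterRecord] = {}
    for r in records:
        seen.setdefault(r.sequence, r)
    dedup = list(seen.values())
    return len(dedup), dedup


# ---------------------------------------------------------------------------
# Shipped fixtures: the 12-member LuxR-repressible library and the primers.

#: -35 and -10 library consensus (5-nt variable segments)
LIBRARY_CONSENSUS = ConsensusSpec(
    minus35_consensus="YTKAY", minus10_consensus="AYWRT"
)

#: BioBrick cloning prefix portion and annealing tail of the forward library
#: primer (prefix includes the XbaI site; the tail anneals downstream of the
#: promoter, at the promoter-RBS junction of the template expression system).
PRIMER_PREFIX = "TCGCGGCCGCTTCTAGAG"
PRIMER_ANNEAL_TAIL = "TACTAGTGAAAGA"

#: the degenerate forward primer used to generate the library
P_LUXH_FWD = assemble_degenerate_primer(
    LIBRARY_CONSENSUS, PRIMER_PREFIX, PRIMER_ANNEAL_TAIL
)

#: the 12 sequenced library members (clone id, BioBrick code, -35, -10);
#: core and proximal are shared (lux box / GCTAGC). Clones 2-79 came from
#: the first degenerate-PCR round, 122 from the second round, and J107100
#: was designed directly from the E. coli consensus hexamers.
_LIBRARY_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("2", "BBa_J107101", "TTGAC", "ACAGT"),
    ("20", "BBa_J107102", "TTGAT", "ATAGT"),
    ("35", "BBa_J107103", "TTGAC", "ATTAT"),
    ("39", "BBa_J107104", "TTGAT", "ACAAT"),
    ("44", "BBa_J107105", "TTGAC", "ACTGT"),
    ("47", "BBa_J107106", "TTGAC", "ACAAT"),
    ("51", "BBa_J107107", "CTTAC", "ACAAT"),
    ("55", "BBa_J107108", "CTGAC", "ACAAT"),
    ("62", "BBa_J107109", "TTGAC", "ATAGT"),
    ("79", "BBa_J107110", "TTGAC", "ATTGT"),
    ("122", "BBa_J107111", "TTGAC", "ACTAT"),
    ("J107100", "BBa_J107100", "TTGAC", "ATAAT"),
)


def library_members(exclude_clones: Sequence[str] = ()) -> list[PromoterRecord]:
    """The 12 sequenced members of the LuxR-repressible promoter library.

    ``exclude_clones`` drops members by clone id (e.g. ``("J107100", "122")``
    restricts to the 10 members found by the first random screening round).
    """
    return [
        PromoterRecord(name=bb, minus35=m35, core=LUX_BOX, minus10=m10,
                       proximal="GCTAGC", clone_id=cid)
        for cid, bb, m35, m10 in _LIBRARY_ROWS
        if cid not in set(exclude_clones)
    ]
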