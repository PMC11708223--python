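"""Nucleotide alphabet helpers shared across the package.

IUPAC ambiguity letters stand for sets of bases; a design sequence mixes
plain bases, ambiguity letters (flanking SNPs) and ``N`` runs (flanking
indels).  All helpers here treat sequences as plain Python strings over
the uppercase alphabet.
"""

from __future__ import annotations

# base set -> IUPAC letter
IUPAC_FOR_SET: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

SET_FOR_IUPAC: dict[str, frozenset[str]] = {v: k for k, v in IUPAC_FOR_SET.items()}

AMBIGUITY_LETTERS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_code(bases) -> str:
    """Return the minimal IUPAC letter covering a set of bases.

    Raises ``ValueError`` for symbols outside A/C/G/T.
    """
    s = frozenset(bases)
    if not s or not s <= frozenset("ACGT"):
        raise ValueError(f"cannot encode base set {sorted(s)!r} as IUPAC")
    return IUPAC_FOR_SET[s]


def iupac_set(letter: str) -> frozenset[str]:
    """Base set represented by an IUPAC letter (N -> all four)."""
    try:
        return SET_FOR_IUPAC[letter]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide letter: {letter!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement, ambiguity-aware (R<->Y, etc.)."""
    return seq.translate(_COMPLEMENT)[::-1]


def bases_compatible(query_letter: str, ref_base: str) -> bool:
    """True when a reference base is among the letter's represented bases."""
    return ref_base in SET_FOR_IUPAC[query_letter]


def gc_weight(letter: str) -> float | None:
    """Fractional G+C contribution of one letter.

    Ambiguity letters contribute the mean GC of their base set; ``N`` is
    uninformative and returns ``None`` (excluded from both numerator and
    denominator of a GC percentage).
    """
    if letter == "N":
        return None
    s = SET_FOR_IUPAC[letter]
    return sum(b in "GC" for b in s) / len(s)


def gc_percent(seq: str) -> float:
    """GC percentage of a (possibly degenerate) sequence, N-exclusive."""
    num = 0.0
    den = 0
    for ch in seq:
        w = gc_weight(ch)
        if w is None:
            continue
        num += w
        den += 1
    if den == 0:
        return 0.0
    return 100.0 * num / den


def translate_cds(seq: str) -> str:
    """Translate a CDS with the standard nuclear code ('*' for stops)."""
    from Bio.Seq import Seq

    return str(Seq(seq).translate())
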