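"""Antiparallel base-pair counting, microhelix fold checking and anticodon decoding.

Sequences here are DNA-alphabet (A/C/G/T; U is mapped to T upstream). Two
equal-length segments are scored antiparallel: position ``i`` of the first is
paired with position ``n+1-i`` of the second, exactly as two strands of a
duplex would meet. Watson-Crick pairs are A:T/T:A/G:C/C:G; the wobble pair is
G:T/T:G (G:U in RNA). No alignment search is performed -- the evolutionary
model aligns fixed-length segments by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "PairingReport",
    "MicrohelixFold",
    "antiparallel_pair_count",
    "fold_microhelix",
    "decode_anticodon",
    "reverse_complement",
    "WC_PAIRS",
    "WOBBLE_PAIRS",
]

WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})

_ACGT = frozenset("ACGT")

# one-letter amino acid -> lower-case common name (standard genetic code)
AMINO_ACID_NAMES = {
    "A": "alanine", "C": "cysteine", "D": "aspartate", "E": "glutamate",
    "F": "phenylalanine", "G": "glycine", "H": "histidine", "I": "isoleucine",
    "K": "lysine", "L": "leucine", "M": "methionine", "N": "asparagine",
    "P": "proline", "Q": "glutamine", "R": "arginine", "S": "serine",
    "T": "threonine", "V": "valine", "W": "tryptophan", "Y": "tyrosine",
    "*": "stop",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement in the DNA alphabet (delegates to Bio.Seq)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PairingReport:
    """Position-wise classification of two antiparallel-aligned segments.

    ``classifications[i]`` scores ``a[i]`` against ``b[n-1-i]`` and is one of
    ``"WC"``, ``"wobble"`` or ``"mismatch"``. ``pairs`` carries the
    corresponding coordinate labels ``(a_pos, b_pos)`` (1-based, offset by the
    ``a_start``/``b_start`` given to :func:`antiparallel_pair_count`, so model
    coordinates can be read straight off the report).
    """

    a: str
    b: str
    classifications: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    allow_wobble: bool = False

    @property
    def wc_count(self) -> int:
        return sum(c == "WC" for c in self.classifications)

    @property
    def wobble_count(self) -> int:
        return sum(c == "wobble" for c in self.classifications)

    @property
    def mismatch_count(self) -> int:
        return sum(c == "mismatch" for c in self.classifications)

    @property
    def strict_count(self) -> int:
        """Watson-Crick pairs only."""
        return self.wc_count

    @property
    def permissive_count(self) -> int:
        """Watson-Crick plus wobble pairs."""
        return self.wc_count + self.wobble_count

    @property
    def match_count(self) -> int:
        """The count under the report's own wobble policy."""
        return self.permissive_count if self.allow_wobble else self.strict_count

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "strict_count": self.strict_count,
            "permissive_count": self.permissive_count,
            "wobble_count": self.wobble_count,
            "mismatch_count": self.mismatch_count,
            "allow_wobble": self.allow_wobble,
            "pairs": [
                {"a_pos": pa, "b_pos": pb, "class": c}
                for (pa, pb), c in zip(self.pairs, self.classifications)
            ],
        }


def _check_alphabet(seq: str, name: str) -> None:
    bad = next((i for i, ch in enumerate(seq) if ch not in _ACGT), None)
    if bad is not None:
        raise ValueError(
            f"non-ACGT symbol {seq[bad]!r} at position {bad + 1} of {name} "
            f"(strict mode accepts A/C/G/T only)"
        )


def antiparallel_pair_count(
    a: str,
    b: str,
    allow_wobble: bool = False,
    *,
    a_start: int = 1,
    b_start: int = 1,
) -> PairingReport:
    """Score two equal-length segments as antiparallel strands.

    Position ``i`` (1-based) of ``a`` is paired with position ``n+1-i`` of
    ``b``.  ``a_start``/``b_start`` label the reported pair coordinates, e.g.
    scoring the D-loop relic (model 25-29) against the V loop (47-51) with
    ``a_start=25, b_start=47`` labels the terminal wobble pair ``(29, 47)``.

    Raises ``ValueError`` on unequal lengths or (always-strict) non-ACGT input.
    """
    a = a.upper()
    b = b.upper()
    if len(a) != len(b):
        raise ValueError(
            f"antiparallel pairing requires equal lengths, got {len(a)} and {len(b)}"
        )
    _check_alphabet(a, "first sequence")
    _check_alphabet(b, "second sequence")
    n = len(a)
    classes = []
    pairs = []
    for i in range(n):
        duo = (a[i], b[n - 1 - i])
        if duo in WC_PAIRS:
            classes.append("WC")
        elif duo in WOBBLE_PAIRS:
            classes.append("wobble")
        else:
            classes.append("mismatch")
        pairs.append((a_start + i, b_start + (n - 1 - i)))
    return PairingReport(a, b, tuple(classes), tuple(pairs), allow_wobble)


@dataclass(frozen=True)
class MicrohelixFold:
    """A 17-nt sequence folded on the fixed 5-nt stem / 7-nt loop / 5-nt stem plan."""

    sequence: str
    stem5: str
    loop_seq: str
    stem3: str
    stem_report: PairingReport = field(repr=False)
    allow_wobble: bool = False

    @property
    def stem_pairs(self) -> int:
        """Paired stem positions (0-5) under the fold's wobble policy."""
        return self.stem_report.match_count

    @property
    def anticodon(self) -> str:
        """Loop positions 3-5 (1-based within the 7-nt loop)."""
        return self.loop_seq[2:5]

    @property
    def decoded_amino_acid(self) -> str:
        return decode_anticodon(self.anticodon)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "stem5": self.stem5,
            "loop": self.loop_seq,
            "stem3": self.stem3,
            "stem_pairs": self.stem_pairs,
            "anticodon": self.anticodon,
            "amino_acid": self.decoded_amino_acid,
        }


def fold_microhelix(seq: str, allow_wobble: bool = False) -> MicrohelixFold:
    """Fold a 17-nt microhelix as 5-7-5 and count antiparallel stem pairs.

    The partition is fixed by the model (it is not searched): the first and
    last 5 nt are the stem strands, the central 7 nt the loop, and the
    anticodon occupies loop positions 3-5.
    """
    seq = seq.upper()
    if len(seq) != 17:
        raise ValueError(f"a microhelix is exactly 17 nt, got {len(seq)}")
    stem5, loop, stem3 = seq[:5], seq[5:12], seq[12:]
    report = antiparallel_pair_count(stem5, stem3, allow_wobble)
    return MicrohelixFold(seq, stem5, loop, stem3, report, allow_wobble)


def decode_anticodon(anticodon: str) -> str:
    """Decode a 3-nt anticodon to an amino acid name via the standard code.

    The codon is the reverse complement of the anticodon read 5'->3'; T is
    read as U. Ambiguous letters yield ``"unknown"``.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3:
        raise ValueError(f"anticodon must be 3 nt, got {len(anticodon)}")
    if any(ch not in _ACGT for ch in anticodon):
        return "unknown"
    codon = reverse_complement(anticodon)
    aa = str(Seq(codon).translate(table=1))
    return AMINO_ACID_NAMES[aa]
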