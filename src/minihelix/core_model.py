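"""The 75-nt tRNA core coordinate system: normalization, segmentation, classification.

The conserved archaeal tRNA core is modeled as 75 nt produced by ligating
three 31-nt minihelices and deleting 9 nt inside each of the two internal
acceptor-stem junctions (93 - 18 = 75). On that coordinate system the core
partitions into seven segments (1-based, inclusive):

======  =======  ==================================================
name    range    meaning
======  =======  ==================================================
AS5     1-7      5' acceptor stem
DMH     8-24     D-arm 17-nt microhelix (refolded in the cloverleaf)
DREM    25-29    5-nt acceptor-stem relic at the 3' end of the D region
ACMH    30-46    anticodon 17-nt microhelix
VLOOP   47-51    5-nt V loop, an acceptor-stem relic
TMH     52-68    T-arm 17-nt microhelix
AS3     69-75    3' acceptor stem
======  =======  ==================================================

Real tRNAs deviate from the 75-nt archetype by deletions in the D region
(DMH) and insertions or 1-nt deletions in the V loop; segmentation anchors
the acceptor stems and T arm positionally, locates the anticodon microhelix
by its hairpin fold, and reads the D- and V-region lengths off the result.
A D region longer than 22 nt violates the model and is an error, never a
silent truncation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .pairing import WC_PAIRS, WOBBLE_PAIRS

__all__ = [
    "SegmentScheme",
    "DEFAULT_SCHEME",
    "SEGMENT_ORDER",
    "NucSequence",
    "SegmentedTRNA",
    "ClassificationSummary",
    "AlphabetError",
    "SegmentationError",
    "normalize_sequence",
    "segment_trna",
    "classify_set",
    "read_sequences",
    "segmentation_table",
    "ANCESTRAL_AS5",
    "ANCESTRAL_AS3",
    "ANCESTRAL_DREM",
    "ANCESTRAL_VLOOP_RELIC",
    "ANCESTRAL_D_MICRO",
    "ANCESTRAL_AC_MICRO",
    "ANCESTRAL_T_MICRO",
    "ANCESTRAL_CORE",
]


class AlphabetError(ValueError):
    """An input symbol outside the normalization table (strict mode)."""


class SegmentationError(ValueError):
    """A sequence that cannot be mapped onto the 75-nt core scheme."""


# ---------------------------------------------------------------------------
# Ancestral reference sequences (DNA alphabet).
#
# The acceptor stems and stem relics are the reconstructed ancestral coding
# sequences; the three microhelices are the reconstructed D-, anticodon- and
# T-arm stem-loops (anticodons GCC, TGT and CAA; the ancestral anticodon of
# the middle unit is unknowable, TGT is a conventional placeholder).
# ---------------------------------------------------------------------------

ANCESTRAL_AS5 = "GCGGCCG"          # positions 1-7
ANCESTRAL_AS3 = "CGGCCGC"          # positions 69-75
ANCESTRAL_DREM = "GACCG"           # positions 25-29 (D-region stem relic)
ANCESTRAL_VLOOP_RELIC = "TGGTC"    # positions 47-51 (V-loop stem relic)
ANCESTRAL_D_MICRO = "TAGTCTAGCCTGGACTA"   # 8-24, anticodon GCC
ANCESTRAL_AC_MICRO = "CCGGGCTTGTAACCCGG"  # 30-46, anticodon TGT (placeholder)
ANCESTRAL_T_MICRO = "CCGGGTTCAAATCCCGG"   # 52-68, anticodon CAA

#: The assembled 75-nt ancestral core. The V loop is the CGGCC remnant left
#: by ligation of identical acceptor stems (the reconstructed relic TGGTC is
#: kept separately as ANCESTRAL_VLOOP_RELIC).
ANCESTRAL_CORE = (
    ANCESTRAL_AS5
    + ANCESTRAL_D_MICRO
    + ANCESTRAL_DREM
    + ANCESTRAL_AC_MICRO
    + "CGGCC"
    + ANCESTRAL_T_MICRO
    + ANCESTRAL_AS3
)

SEGMENT_ORDER = ("AS5", "DMH", "DREM", "ACMH", "VLOOP", "TMH", "AS3")


@dataclass(frozen=True)
class SegmentScheme:
    """The fixed 75-nt coordinate partition (1-based inclusive ranges)."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "AS5": (1, 7),
            "DMH": (8, 24),
            "DREM": (25, 29),
            "ACMH": (30, 46),
            "VLOOP": (47, 51),
            "TMH": (52, 68),
            "AS3": (69, 75),
        }
    )

    # derived constants of the generative model
    acceptor_len: int = 7
    remnant_len: int = 5
    microhelix_len: int = 17
    minihelix_len: int = 31
    junction_len: int = 14       # two joined 7-nt acceptor stems
    deletion_len: int = 9        # removed at each junction
    core_len: int = 75
    precursor_len: int = 93      # three ligated minihelices

    def __post_init__(self) -> None:
        pos = 1
        for name in SEGMENT_ORDER:
            start, end = self.ranges[name]
            if start != pos or end < start:
                raise ValueError(f"segment ranges must tile 1..{self.core_len}")
            pos = end + 1
        if pos - 1 != self.core_len:
            raise ValueError(f"segment ranges must cover 1..{self.core_len}")
        assert 3 * self.minihelix_len - 2 * self.deletion_len == self.core_len
        assert self.junction_len - self.deletion_len == self.remnant_len
        assert 2 * self.remnant_len + self.acceptor_len == self.microhelix_len
        assert self.microhelix_len + self.junction_len == self.minihelix_len

    def length(self, name: str) -> int:
        start, end = self.ranges[name]
        return end - start + 1

    @property
    def intact_d_region_len(self) -> int:
        """Full-length D region: 17-nt microhelix + 5-nt relic = 22 nt."""
        return self.length("DMH") + self.length("DREM")

    @property
    def simple_v_len(self) -> int:
        return self.length("VLOOP")


DEFAULT_SCHEME = SegmentScheme()


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

# tRNAdb-style one-letter codes for modified nucleosides, mapped back to the
# parent base: 5 = 5-methyl-cytosine, P = pseudo-uridine, 1 and Y = adenosine
# derivatives, O = a uracil or guanosine derivative (ambiguous, kept as N).
NORMALIZATION_TABLE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "5": "C", "P": "T", "1": "A", "Y": "A",
    "O": "N", "N": "N",
}

_GAP_CHARS = set("-.~ \t")


@dataclass(frozen=True)
class NucSequence:
    """A normalized nucleotide sequence plus its original reading."""

    residues: str
    raw: str
    gap_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def normalize_sequence(raw: str, strict: bool = True) -> NucSequence:
    """Map a raw sequence onto the internal A/C/G/T alphabet.

    U becomes T and the modified-nucleoside codes are mapped to their parent
    bases (see ``NORMALIZATION_TABLE``). Gap and whitespace characters are
    removed, with their 1-based positions recorded. In strict mode (default)
    any symbol that cannot be resolved to A/C/G/T -- unknown letters and the
    ambiguous codes O/N -- raises :class:`AlphabetError` naming the offending
    character and position; in lenient mode they become ``N``.
    """
    if not raw or not raw.strip():
        raise AlphabetError("empty sequence")
    out = []
    gaps = []
    for i, ch in enumerate(raw):
        if ch in _GAP_CHARS:
            gaps.append(i + 1)
            continue
        mapped = NORMALIZATION_TABLE.get(ch.upper() if ch.isalpha() else ch)
        if mapped is None or mapped == "N":
            if strict:
                raise AlphabetError(
                    f"cannot normalize symbol {ch!r} at position {i + 1} "
                    f"(strict mode)"
                )
            mapped = "N"
        out.append(mapped)
    return NucSequence("".join(out), raw, tuple(gaps))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

MIN_CORE_LEN = 55
MAX_CORE_LEN = 100

#: Minimum weighted hairpin score (WC pair = 1, wobble = 0.5, of max 5) for a
#: 17-nt window to count as a recognizable microhelix stem-loop.
MIN_STEM_SCORE = 2.5


@dataclass
class SegmentedTRNA:
    """One tRNA mapped onto the 75-nt core scheme."""

    source_id: str
    sequence: str                       # normalized, CCA-stripped
    segments: dict[str, str]
    coords: dict[str, tuple[int, int]]  # 1-based inclusive, on `sequence`
    d_region_length: int
    v_region_length: int
    d_status: str                       # intact | deleted
    v_status: str                       # simple | inserted | deleted
    cca_stripped: str                   # "", "A", "CA" or "CCA"
    scheme: SegmentScheme = field(default_factory=lambda: DEFAULT_SCHEME, repr=False)

    def __post_init__(self) -> None:
        joined = "".join(self.segments[name] for name in SEGMENT_ORDER)
        if joined != self.sequence:
            raise ValueError("segments do not concatenate to the input sequence")

    @property
    def is_intact(self) -> bool:
        return self.d_status == "intact"


def _hairpin_score(window17: str, partner: list[int] | None, offset: int) -> float:
    """Weighted stem score of a 17-nt window folded 5-7-5.

    Sequence mode (``partner is None``): WC pair = 1, wobble = 0.5.
    Structure mode: count of annotated stem pairs (i with j = 16 - i),
    each worth 1. ``offset`` is the window's 0-based start in the whole
    sequence, used to index the dot-bracket partner table.
    """
    score = 0.0
    for i in range(5):
        j = 16 - i
        if partner is not None:
            if partner[offset + i] == offset + j:
                score += 1.0
        else:
            duo = (window17[i], window17[j])
            if duo in WC_PAIRS:
                score += 1.0
            elif duo in WOBBLE_PAIRS:
                score += 0.5
    return score


def _relic_pair_score(middle: str, i: int, rem: int = 5) -> float:
    """Antiparallel pairing capacity of the would-be stem relics flanking a
    candidate anticodon-arm window (last <=5 nt of the D region vs first
    <=5 nt of the V region). In the generative model these are the two halves
    of a once-paired acceptor-stem junction, so the true window tends to
    retain more of this complementarity than a shifted false fold."""
    d = middle[max(0, i - rem) : i][-rem:]
    v = middle[i + 17 : i + 17 + rem]
    n = min(len(d), len(v))
    if n == 0:
        return 0.0
    d, v = d[-n:], v[:n]
    score = 0.0
    for k in range(n):
        duo = (d[k], v[n - 1 - k])
        if duo in WC_PAIRS:
            score += 1.0
        elif duo in WOBBLE_PAIRS:
            score += 0.5
    return score


_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}


def _parse_dotbracket(structure: str) -> list[int]:
    """Partner table (0-based; -1 = unpaired) from a dot-bracket string."""
    partner = [-1] * len(structure)
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    closing = {v: k for k, v in _BRACKETS.items()}
    for i, ch in enumerate(structure):
        if ch in _BRACKETS:
            stacks[ch].append(i)
        elif ch in closing:
            stack = stacks[closing[ch]]
            if not stack:
                raise ValueError(f"unbalanced bracket {ch!r} at position {i + 1}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch not in ".:,_-":
            raise ValueError(f"unexpected structure symbol {ch!r} at position {i + 1}")
    for stack in stacks.values():
        if stack:
            raise ValueError("unbalanced brackets in structure line")
    return partner


def _segment_core(
    seq: str,
    partner: list[int] | None,
    scheme: SegmentScheme,
    min_stem_score: float,
) -> tuple[dict[str, str], dict[str, tuple[int, int]], int, int, float, float]:
    """Partition a CCA-stripped sequence; raises SegmentationError on failure."""
    L = len(seq)
    acc = scheme.acceptor_len
    micro = scheme.microhelix_len
    tail = micro + acc  # T arm + 3' acceptor stem

    if L < acc + micro + tail:
        raise SegmentationError(
            f"sequence of {L} nt is too short to hold two microhelices and "
            f"both acceptor stems"
        )

    tmh_off = L - tail
    tmh = seq[tmh_off : tmh_off + micro]
    tmh_score = _hairpin_score(tmh, partner, tmh_off)
    if tmh_score < min_stem_score:
        raise SegmentationError(
            f"cannot locate the T arm as a 17-nt stem-loop adjacent to the 3' "
            f"acceptor stem (stem score {tmh_score:g} < {min_stem_score:g})"
        )

    middle = seq[acc:tmh_off]  # D region + ACMH + V region
    max_d = scheme.intact_d_region_len

    best = None        # (v_in_envelope, penalized score, -i)
    best_i = None
    best_violation = None  # best-scoring candidate with d > 22
    for i in range(len(middle) - micro + 1):
        d_len = i
        v_len = len(middle) - micro - i
        score = _hairpin_score(middle[i : i + micro], partner, acc + i)
        if score < min_stem_score:
            continue
        if d_len > max_d:
            if best_violation is None or score > best_violation[0]:
                best_violation = (score, d_len)
            continue
        # Rank by stem quality, discounted for V regions below the model's
        # 5-nt loop (V deletions beyond 1 nt are off-model, so a candidate
        # implying one is almost always a shifted false fold); candidates
        # implying a long (inserted) V region rank below in-envelope ones.
        # Score ties resolve by the flanking relics' pairing capacity, then
        # by the smaller start.
        penalized = score - 0.75 * max(0, scheme.simple_v_len - v_len)
        key = (1 if v_len <= 9 else 0, penalized, _relic_pair_score(middle, i), -i)
        if best is None or key > best:
            best = key
            best_i = i

    d_len = best_i if best_i is not None else None
    acmh_score = (
        _hairpin_score(middle[best_i : best_i + micro], partner, acc + best_i)
        if best_i is not None
        else -1.0
    )
    # a D region beyond the model's 22-nt envelope is an error, not a silent
    # reinterpretation: flag it whenever the over-length candidate folds
    # strictly better than every admissible one
    if best_violation is not None and best_violation[0] > acmh_score:
        raise SegmentationError(
            f"anticodon arm found only with a D region of "
            f"{best_violation[1]} nt (> {max_d} nt): model violation"
        )
    if best_i is None:
        raise SegmentationError(
            "cannot locate the anticodon arm as a 17-nt stem-loop between the "
            "acceptor stem and the T arm"
        )

    v_len = len(middle) - micro - best_i

    rem = scheme.remnant_len
    d_region = middle[:d_len]
    drem = d_region[-rem:] if d_len >= rem else d_region
    dmh = d_region[: len(d_region) - len(drem)]
    acmh = middle[d_len : d_len + micro]
    vloop = middle[d_len + micro :]

    segments = {
        "AS5": seq[:acc],
        "DMH": dmh,
        "DREM": drem,
        "ACMH": acmh,
        "VLOOP": vloop,
        "TMH": tmh,
        "AS3": seq[tmh_off + micro :],
    }
    coords = {}
    pos = 1
    for name in SEGMENT_ORDER:
        seg = segments[name]
        coords[name] = (pos, pos + len(seg) - 1) if seg else (pos, pos - 1)
        pos += len(seg)
    return segments, coords, d_len, v_len, acmh_score, tmh_score


def segment_trna(
    seq: NucSequence | str,
    structure: str | None = None,
    *,
    source_id: str = "seq",
    scheme: SegmentScheme = DEFAULT_SCHEME,
    strict: bool = True,
    min_stem_score: float = MIN_STEM_SCORE,
) -> SegmentedTRNA:
    """Map one tRNA onto the 75-nt core scheme.

    The 5' and 3' acceptor stems are the outermost 7 nt and the T-arm
    microhelix is the 17 nt adjacent to the 3' stem (the model allows no
    variable region between them). The anticodon microhelix is located within
    the remaining interior as the best-folding 17-nt stem-loop; candidates are
    ranked by (V region within the model's 0-9 nt envelope, hairpin score,
    longer D region, smaller start). A 3'-CCA (or partial CA/A) suffix is
    stripped before segmentation when doing so yields the better-folding
    segmentation, so results are invariant to its presence.

    If a dot-bracket ``structure`` line is supplied (same length as the
    normalized sequence) stem-loops are scored by the annotated pairs instead
    of sequence complementarity.
    """
    if isinstance(seq, str):
        seq = normalize_sequence(seq, strict=strict)
    s = seq.residues

    partner = None
    if structure is not None:
        structure = re.sub(r"\s", "", structure)
        if len(structure) != len(s):
            raise SegmentationError(
                f"structure line length {len(structure)} does not match "
                f"sequence length {len(s)}"
            )
        partner = _parse_dotbracket(structure)

    candidates = [0]
    for suffix in ("A", "CA", "CCA"):
        if s.endswith(suffix):
            candidates.append(len(suffix))

    best = None
    errors = []
    for k in candidates:
        trimmed = s[: len(s) - k] if k else s
        if not MIN_CORE_LEN <= len(trimmed) <= MAX_CORE_LEN:
            errors.append(
                SegmentationError(
                    f"length {len(trimmed)} after stripping {k} 3' nt is outside "
                    f"[{MIN_CORE_LEN}, {MAX_CORE_LEN}]"
                )
            )
            continue
        trimmed_partner = partner[: len(trimmed)] if partner is not None else None
        try:
            result = _segment_core(trimmed, trimmed_partner, scheme, min_stem_score)
        except SegmentationError as exc:
            errors.append(exc)
            continue
        segments, coords, d_len, v_len, acmh_score, tmh_score = result
        key = (acmh_score + tmh_score, k)
        if best is None or key > best[0]:
            best = (key, k, trimmed, segments, coords, d_len, v_len)

    if best is None:
        raise errors[-1] if errors else SegmentationError("segmentation failed")

    _, k, trimmed, segments, coords, d_len, v_len = best
    d_status = "intact" if d_len == scheme.intact_d_region_len else "deleted"
    if v_len == scheme.simple_v_len:
        v_status = "simple"
    elif v_len > scheme.simple_v_len:
        v_status = "inserted"
    else:
        v_status = "deleted"
    return SegmentedTRNA(
        source_id=source_id,
        sequence=trimmed,
        segments=segments,
        coords=coords,
        d_region_length=d_len,
        v_region_length=v_len,
        d_status=d_status,
        v_status=v_status,
        cca_stripped=s[len(s) - k :] if k else "",
        scheme=scheme,
    )


def segment_set(
    records: list[tuple[str, str] | tuple[str, str, str | None]],
    *,
    strict: bool = True,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    on_error: str = "collect",
) -> tuple[list[SegmentedTRNA], list[tuple[str, str]]]:
    """Segment many ``(id, sequence[, structure])`` records.

    Returns ``(segmented, failures)`` where failures are ``(id, message)``
    pairs -- sequences whose arms cannot be recognized (e.g. heavily
    substituted stems) are reported, never silently dropped. With
    ``on_error="raise"`` the first failure raises instead.
    """
    if on_error not in ("collect", "raise"):
        raise ValueError("on_error must be 'collect' or 'raise'")
    segmented: list[SegmentedTRNA] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        struct = rec[2] if len(rec) > 2 else None
        try:
            segmented.append(
                segment_trna(
                    seq, struct, source_id=rid, scheme=scheme, strict=strict
                )
            )
        except (AlphabetError, SegmentationError) as exc:
            if on_error == "raise":
                raise
            failures.append((rid, str(exc)))
    return segmented, failures


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationSummary:
    """D-loop x V-loop status counts over a set of segmented tRNAs."""

    n: int
    d_counts: Counter
    v_counts: Counter
    joint_counts: Counter

    @property
    def intact_count(self) -> int:
        return self.d_counts.get("intact", 0)

    @property
    def intact_fraction(self) -> float:
        return self.intact_count / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "d_status": dict(self.d_counts),
            "v_status": dict(self.v_counts),
            "joint": {f"{d}/{v}": c for (d, v), c in sorted(self.joint_counts.items())},
            "intact_fraction": self.intact_fraction,
        }


def classify_set(trnas: list[SegmentedTRNA]) -> ClassificationSummary:
    """Summarize D-loop/V-loop status counts; counts partition the input."""
    if not trnas:
        raise ValueError("classify_set requires a non-empty list")
    d = Counter(t.d_status for t in trnas)
    v = Counter(t.v_status for t in trnas)
    joint = Counter((t.d_status, t.v_status) for t in trnas)
    return ClassificationSummary(len(trnas), d, v, joint)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_STRUCT_CHARS = set("().<>[]{}:,_")


def read_sequences(
    path: str | Path, structure_path: str | Path | None = None
) -> list[tuple[str, str, str | None]]:
    """Read FASTA records, optionally with dot-bracket structure lines.

    Supports plain multi-FASTA (via Biopython) and the Vienna/tRNAscan-SE
    dialect in which each record's sequence line is followed by a structure
    line. A separate ``structure_path`` (same dialect, matching ids, sequence
    line optional) overrides interleaved structures.

    Returns ``(id, raw_sequence, structure_or_None)`` triples.
    """
    path = Path(path)
    text = path.read_text()
    records = _parse_fasta_like(text) if _looks_vienna(text) else [
        (rec.id, str(rec.seq), None) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if structure_path is not None:
        structs = {}
        for rid, _seq, struct in _parse_fasta_like(Path(structure_path).read_text()):
            structs[rid] = struct if struct is not None else _seq
        records = [(rid, seq, structs.get(rid, st)) for rid, seq, st in records]
    return records


def _looks_vienna(text: str) -> bool:
    return any(
        line and not line.startswith(">") and set(line.strip()) <= _STRUCT_CHARS
        for line in text.splitlines()
    )


def _parse_fasta_like(text: str) -> list[tuple[str, str, str | None]]:
    records = []
    rid = None
    seq_parts: list[str] = []
    struct_parts: list[str] = []

    def flush():
        if rid is not None:
            records.append(
                (rid, "".join(seq_parts), "".join(struct_parts) or None)
            )

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rid = line[1:].split()[0]
            seq_parts, struct_parts = [], []
        elif set(line) <= _STRUCT_CHARS:
            struct_parts.append(line)
        else:
            seq_parts.append(line)
    flush()
    return records


def segmentation_table(trnas: list[SegmentedTRNA]) -> pd.DataFrame:
    """Long-form per-segment table (one row per tRNA x segment) for TSV output."""
    rows = []
    for t in trnas:
        for name in SEGMENT_ORDER:
            start, end = t.coords[name]
            rows.append(
                {
                    "id": t.source_id,
                    "segment": name,
                    "start": start,
                    "end": end,
                    "subsequence": t.segments[name],
                    "d_status": t.d_status,
                    "v_status": t.v_status,
                    "cca_stripped": t.cca_stripped,
                }
            )
    return pd.DataFrame(rows)
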