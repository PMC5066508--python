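"""Generative model of the cloverleaf core: ligation, deletion, replication.

Three 31-nt minihelices (7-nt acceptor stem + 17-nt microhelix + 7-nt
acceptor stem) are ligated into a 93-nt precursor; a 9-nt deletion inside
each of the two 14-nt acceptor-stem junctions yields the 75-nt core, leaving
a 5-nt stem remnant at each junction (14 - 9 = 5). The default deletion
windows are fixed by the model's alignments: the junction-1 remnant is
positions 3-7 of the downstream unit's 5' stem (core 25-29, aligned with
1-7's positions 3-7) and the junction-2 remnant is positions 1-5 of the
upstream unit's 3' stem (core 47-51, aligned with 69-73).

Also provided: the snapback replication mechanism (a complementary minihelix
ligates to the 3' end and primes templated copying, doubling the unit count
per round) and excision of 31-nt units from concatemers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import SEGMENT_ORDER, DEFAULT_SCHEME, SegmentScheme
from .pairing import reverse_complement

__all__ = [
    "Microhelix",
    "Minihelix",
    "LigationPlan",
    "LigationError",
    "DEFAULT_PLAN",
    "build_minihelix",
    "attach_cca",
    "ligate_and_delete",
    "snapback_replicate",
    "excise_minihelices",
    "ANCESTRAL_MINIHELICES",
]


class LigationError(ValueError):
    """Invalid component lengths or deletion windows."""


_ACGT = frozenset("ACGT")


def _check_component(seq: str, name: str, length: int) -> str:
    seq = seq.upper().replace("U", "T")
    if len(seq) != length:
        raise LigationError(f"{name} must be {length} nt, got {len(seq)}")
    bad = set(seq) - _ACGT
    if bad:
        raise LigationError(f"{name} contains non-ACGT symbols {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Microhelix:
    """17-nt stem-loop: 5-nt stem, 7-nt loop, 5-nt stem; anticodon = loop 3-5."""

    stem5: str
    loop: str
    stem3: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "stem5", _check_component(self.stem5, "stem5", 5))
        object.__setattr__(self, "loop", _check_component(self.loop, "loop", 7))
        object.__setattr__(self, "stem3", _check_component(self.stem3, "stem3", 5))

    @classmethod
    def from_sequence(cls, seq: str) -> "Microhelix":
        seq = _check_component(seq, "microhelix", 17)
        return cls(seq[:5], seq[5:12], seq[12:])

    @property
    def anticodon(self) -> str:
        return self.loop[2:5]

    @property
    def sequence(self) -> str:
        return self.stem5 + self.loop + self.stem3

    def __len__(self) -> int:
        return 17


@dataclass(frozen=True)
class Minihelix:
    """31-nt unit: 7-nt acceptor strand + 17-nt microhelix + 7-nt acceptor strand."""

    acc5: str
    micro: Microhelix
    acc3: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "acc5", _check_component(self.acc5, "acc5", 7))
        object.__setattr__(self, "acc3", _check_component(self.acc3, "acc3", 7))

    @classmethod
    def from_sequence(cls, seq: str) -> "Minihelix":
        seq = _check_component(seq, "minihelix", 31)
        return cls(seq[:7], Microhelix.from_sequence(seq[7:24]), seq[24:])

    @property
    def sequence(self) -> str:
        return self.acc5 + self.micro.sequence + self.acc3

    def __len__(self) -> int:
        return 31


def build_minihelix(micro: Microhelix | str, acc5: str, acc3: str) -> Minihelix:
    """Assemble a 31-nt minihelix from a 17-nt microhelix and two 7-nt stems."""
    if isinstance(micro, str):
        micro = Microhelix.from_sequence(micro)
    return Minihelix(acc5, micro, acc3)


def attach_cca(unit: Microhelix | Minihelix | str) -> str:
    """Attach the 3'-CCA amino-acid attachment site.

    A 17-nt microhelix becomes a 20-nt translation adaptor (no acceptor
    stem); a 31-nt minihelix becomes 34 nt. Other lengths are rejected.
    """
    seq = unit if isinstance(unit, str) else unit.sequence
    seq = seq.upper().replace("U", "T")
    if len(seq) not in (17, 31):
        raise LigationError(
            f"CCA attaches to a 17-nt microhelix or 31-nt minihelix, got {len(seq)} nt"
        )
    return seq + "CCA"


@dataclass(frozen=True)
class LigationPlan:
    """Which 9 of each 14-nt junction's nucleotides are deleted.

    ``junction1_del_start``/``junction2_del_start`` are 1-based offsets of the
    9-nt deletion window within each junction (the junction is the upstream
    unit's 7-nt 3' stem followed by the downstream unit's 7-nt 5' stem).
    Valid starts are 1..6 so the window stays inside the junction. The default
    (1, 6) encodes the model's alignments: junction 1 keeps the last 5 nt
    (downstream acc5 positions 3-7), junction 2 keeps the first 5 nt
    (upstream acc3 positions 1-5).
    """

    junction1_del_start: int = 1
    junction2_del_start: int = 6
    scheme: SegmentScheme = field(default_factory=lambda: DEFAULT_SCHEME, repr=False)

    def __post_init__(self) -> None:
        win = self.scheme.junction_len - self.scheme.deletion_len + 1  # = 6
        for label, start in (
            ("junction1_del_start", self.junction1_del_start),
            ("junction2_del_start", self.junction2_del_start),
        ):
            if not 1 <= start <= win:
                raise LigationError(
                    f"{label} must be in 1..{win} so the {self.scheme.deletion_len}-nt "
                    f"deletion window stays inside the {self.scheme.junction_len}-nt junction"
                )


DEFAULT_PLAN = LigationPlan()


def _delete_window(junction: str, start: int, length: int) -> str:
    return junction[: start - 1] + junction[start - 1 + length :]


def ligate_and_delete(
    mh1: Minihelix, mh2: Minihelix, mh3: Minihelix, plan: LigationPlan = DEFAULT_PLAN
) -> tuple[str, str, dict[str, str]]:
    """Ligate three minihelices and apply the two symmetric 9-nt deletions.

    Returns ``(precursor, core, segment_map)``: the 93-nt ligation product,
    the 75-nt core, and the seven core segments keyed by scheme name
    (lengths 7, 17, 5, 17, 5, 17, 7).
    """
    scheme = plan.scheme
    precursor = mh1.sequence + mh2.sequence + mh3.sequence
    assert len(precursor) == scheme.precursor_len

    del_len = scheme.deletion_len
    junction1 = mh1.acc3 + mh2.acc5
    junction2 = mh2.acc3 + mh3.acc5
    remnant1 = _delete_window(junction1, plan.junction1_del_start, del_len)
    remnant2 = _delete_window(junction2, plan.junction2_del_start, del_len)

    segment_map = {
        "AS5": mh1.acc5,
        "DMH": mh1.micro.sequence,
        "DREM": remnant1,
        "ACMH": mh2.micro.sequence,
        "VLOOP": remnant2,
        "TMH": mh3.micro.sequence,
        "AS3": mh3.acc3,
    }
    core = "".join(segment_map[name] for name in SEGMENT_ORDER)
    assert len(core) == scheme.core_len
    return precursor, core, segment_map


def snapback_replicate(
    mh: Minihelix | str,
    rounds: int = 1,
    seed: int | None = None,
    substitution_rate: float = 0.0,
) -> list[str]:
    """Replicate a minihelix by snapback priming and templated extension.

    Each round, a unit complementary to the 3'-terminal 31-nt unit ligates to
    the 3' end (the snapback primer) and extension copies that template, so
    the product of round ``r`` is a concatemer of ``r + 1`` 31-nt units in
    which every newly added unit is the exact reverse complement of the unit
    it copied. Copying is deterministic by default; an optional per-base
    substitution rate (with a seeded generator) models replication error.

    Returns the product of every round, lengths ``31 * (r + 1)``.
    """
    seq = mh if isinstance(mh, str) else mh.sequence
    seq = Minihelix.from_sequence(seq).sequence  # validates length/alphabet
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    letters = "ACGT"
    products = []
    current = seq
    for _ in range(rounds):
        template = current[-31:]
        copy = reverse_complement(template)
        if substitution_rate > 0.0:
            bases = list(copy)
            hits = np.flatnonzero(rng.random(len(bases)) < substitution_rate)
            for i in hits:
                bases[i] = letters[
                    (letters.index(bases[i]) + rng.integers(1, 4)) % 4
                ]
            copy = "".join(bases)
        current = current + copy
        products.append(current)
    return products


def excise_minihelices(concatemer: str) -> list[str]:
    """Cut a concatemer of ligated 31-nt units back into minihelices.

    Concatenating the returned units restores the input. A sequence whose
    length is not a multiple of 31 (e.g. the 75-nt deleted core) is not
    decomposable and raises :class:`LigationError`.
    """
    concatemer = concatemer.upper().replace("U", "T")
    if not concatemer or len(concatemer) % 31 != 0:
        raise LigationError(
            f"length {len(concatemer)} is not a positive multiple of 31: "
            f"not decomposable into minihelices"
        )
    return [concatemer[i : i + 31] for i in range(0, len(concatemer), 31)]


def _ancestral_minihelices() -> tuple[Minihelix, Minihelix, Minihelix]:
    from . import core_model as cm

    return (
        build_minihelix(cm.ANCESTRAL_D_MICRO, cm.ANCESTRAL_AS5, cm.ANCESTRAL_AS3),
        build_minihelix(cm.ANCESTRAL_AC_MICRO, cm.ANCESTRAL_AS5, cm.ANCESTRAL_AS3),
        build_minihelix(cm.ANCESTRAL_T_MICRO, cm.ANCESTRAL_AS5, cm.ANCESTRAL_AS3),
    )


#: The three reconstructed ancestral minihelices (identical acceptor stems;
#: anticodons GCC, TGT and CAA).
ANCESTRAL_MINIHELICES = _ancestral_minihelices()
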