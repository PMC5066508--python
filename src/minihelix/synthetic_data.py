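"""Seeded generators for archaeal-like tRNA sets and idealized hairpin fixtures.

The sequence generator draws i.i.d. descendants of the 75-nt ancestral core:
per-position substitutions at a configurable rate (anticodon positions are
spared by default, since each anticodon marks its own lineage), a D-region
deletion with configurable probability and length drawn from a distribution
over 1..14 (confined to the D-arm microhelix, 8-24), and a V-loop insertion
confined to the V region. Defaults mirror the archaeal survey conditions the
model is tested against: 500 sequences, D-deletion probability 0.8 (so ~20%
of records keep an intact 22-nt D region), substitution rate 0.05. Ground
truth (deletion/insertion lengths, substituted positions) is emitted per
record, and a fixed seed reproduces the output byte for byte.

The coordinate generator writes an idealized A-form-like stem-loop backbone
(6 atoms per residue) as PDB text, with optional per-atom Gaussian noise,
for exercising the structural-overlay stage without downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import ANCESTRAL_CORE, DEFAULT_SCHEME, SegmentScheme

__all__ = [
    "SyntheticConfig",
    "SyntheticTRNASet",
    "generate_trna_set",
    "generate_hairpin_coords",
]

_LETTERS = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the archaeal-like sequence generator (seed-deterministic)."""

    ancestral_core: str = ANCESTRAL_CORE
    n_sequences: int = 500
    substitution_rate: float = 0.05
    d_deletion_probability: float = 0.8
    d_deletion_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    v_insertion_probability: float = 0.1
    v_insertion_lengths: tuple[int, ...] = (1, 2, 3, 4)
    seed: int = 0
    mutate_anticodon: bool = False
    scheme: SegmentScheme = field(default_factory=lambda: DEFAULT_SCHEME, repr=False)

    def __post_init__(self) -> None:
        if len(self.ancestral_core) != self.scheme.core_len:
            raise ValueError(
                f"ancestral core must be {self.scheme.core_len} nt, "
                f"got {len(self.ancestral_core)}"
            )
        for p, name in (
            (self.substitution_rate, "substitution_rate"),
            (self.d_deletion_probability, "d_deletion_probability"),
            (self.v_insertion_probability, "v_insertion_probability"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        max_del = self.scheme.junction_len  # 14, the model's deletion envelope
        if not all(1 <= d <= max_del for d in self.d_deletion_lengths):
            raise ValueError(f"d_deletion_lengths must lie in 1..{max_del}")
        if not all(v >= 1 for v in self.v_insertion_lengths):
            raise ValueError("v_insertion_lengths must be >= 1")


@dataclass(frozen=True)
class SyntheticTRNASet:
    """Generated records plus per-record ground truth."""

    records: tuple[tuple[str, str], ...]  # (id, sequence)
    truth: pd.DataFrame = field(repr=False)
    config: SyntheticConfig = field(repr=False)

    def to_fasta(self, path=None) -> str:
        buf = io.StringIO()
        for rid, seq in self.records:
            buf.write(f">{rid}\n{seq}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def truth_tsv(self, path=None) -> str:
        text = self.truth.to_csv(sep="\t", index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def generate_trna_set(cfg: SyntheticConfig) -> SyntheticTRNASet:
    """Draw an archaeal-like tRNA set with known ground truth.

    Per record: substitutions first (uniform over the other three bases, by
    default sparing the three anticodon positions), then at most one
    contiguous D-region deletion inside the D-arm microhelix and one V-loop
    insertion of random ACGT letters. The expected intact fraction is
    ``1 - d_deletion_probability``.
    """
    rng = np.random.default_rng(cfg.seed)
    scheme = cfg.scheme
    core = cfg.ancestral_core.upper()
    dmh_start, dmh_end = scheme.ranges["DMH"]
    v_start, v_end = scheme.ranges["VLOOP"]
    acmh_start, _ = scheme.ranges["ACMH"]
    # anticodon = loop positions 3-5 of the anticodon microhelix (core 37-39)
    anticodon_cols = {acmh_start + 7 + k for k in range(3)}

    records = []
    rows = []
    width = len(str(cfg.n_sequences))
    for idx in range(cfg.n_sequences):
        bases = list(core)
        substituted = []
        hits = np.flatnonzero(rng.random(len(bases)) < cfg.substitution_rate)
        for col0 in hits:
            pos = int(col0) + 1
            if not cfg.mutate_anticodon and pos in anticodon_cols:
                continue
            bases[col0] = _LETTERS[
                (_LETTERS.index(bases[col0]) + int(rng.integers(1, 4))) % 4
            ]
            substituted.append(pos)

        del_len = 0
        if rng.random() < cfg.d_deletion_probability:
            del_len = int(rng.choice(cfg.d_deletion_lengths))
            del_start = int(rng.integers(dmh_start, dmh_end - del_len + 2))
            del bases[del_start - 1 : del_start - 1 + del_len]

        ins_len = 0
        if rng.random() < cfg.v_insertion_probability:
            ins_len = int(rng.choice(cfg.v_insertion_lengths))
            # insert within the (possibly shifted) V region
            offset = int(rng.integers(1, v_end - v_start + 2))
            at = v_start - del_len - 1 + offset
            insert = [_LETTERS[int(i)] for i in rng.integers(0, 4, ins_len)]
            bases[at:at] = insert

        seq = "".join(bases)
        rid = f"synth_{idx + 1:0{width}d}"
        records.append((rid, seq))
        rows.append(
            {
                "id": rid,
                "intact": del_len == 0,
                "d_deletion_length": del_len,
                "v_insertion_length": ins_len,
                "n_substitutions": len(substituted),
                "substituted_positions": ",".join(map(str, substituted)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "id", "intact", "d_deletion_length", "v_insertion_length",
            "n_substitutions", "substituted_positions",
        ],
    )
    return SyntheticTRNASet(tuple(records), truth, cfg)


# ---------------------------------------------------------------------------
# Idealized hairpin coordinates
# ---------------------------------------------------------------------------

# fixed local offsets (Angstrom) of the six backbone atoms around a residue
# center; an arbitrary but non-planar arrangement so selections are never
# degenerate
_ATOM_OFFSETS = {
    "P": (0.0, 0.0, 0.0),
    "O5'": (1.4, 0.3, 0.8),
    "C5'": (2.3, 1.1, 1.3),
    "C4'": (3.1, 1.9, 0.6),
    "C3'": (3.4, 2.7, -0.4),
    "O3'": (3.0, 3.5, -1.2),
}


def generate_hairpin_coords(
    n_residues: int = 17,
    rise: float = 2.8,
    twist: float = 32.7,
    noise: float = 0.0,
    seed: int | None = None,
    chain: str = "A",
) -> str:
    """PDB text for an idealized stem-loop backbone trace.

    Residues follow a helical ascending strand (given rise/twist, A-form-like
    defaults), an arc closing the loop, and a descending strand; each residue
    carries the six default backbone atoms at fixed local offsets, with
    optional per-atom Gaussian noise (seeded). Output parses with any PDB
    reader; residues are numbered from 1.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues for a hairpin")
    rng = np.random.default_rng(seed)
    stem = max(1, (n_residues - 7) // 2)
    loop = n_residues - 2 * stem
    radius = 9.0
    tw = np.deg2rad(twist)

    centers = []
    for i in range(stem):  # ascending strand
        centers.append(
            (radius * np.cos(i * tw), radius * np.sin(i * tw), i * rise)
        )
    top = (stem - 1) * rise
    phase0 = (stem - 1) * tw
    for j in range(loop):  # loop arc above the stem
        ang = phase0 + (j + 1) * np.pi / (loop + 1)
        centers.append(
            (
                radius * np.cos(ang),
                radius * np.sin(ang),
                top + 4.0 * np.sin((j + 1) * np.pi / (loop + 1)),
            )
        )
    for i in range(stem):  # descending strand, offset in phase
        k = stem - 1 - i
        centers.append(
            (
                radius * np.cos(k * tw + np.pi * 0.85),
                radius * np.sin(k * tw + np.pi * 0.85),
                k * rise,
            )
        )

    lines = []
    serial = 1
    for resseq, center in enumerate(centers, start=1):
        for name, off in _ATOM_OFFSETS.items():
            xyz = np.asarray(center) + np.asarray(off)
            if noise > 0.0:
                xyz = xyz + rng.normal(0.0, noise, 3)
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name} {'A':>3s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
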