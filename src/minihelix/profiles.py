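"""Per-position composition and information content over segmented tRNA sets.

Segmented tRNAs are stacked onto the 75 core coordinates: every segment is
placed at its scheme position, D-region deletions appear as gap characters
inside the D-arm microhelix columns (8-24), and V-loop insertions are
excluded from core columns (only the 5'-most 5 nt of an expanded V region
occupy columns 47-51). Frequencies at each column are taken over the non-gap
observations, with the gap fraction carried separately; information content
is the standard logo quantity, 2 - H bits with H the Shannon entropy of the
column's base frequencies, optionally with the small-sample correction
e(n) = 3 / (2 ln2 n) subtracted and floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import DEFAULT_SCHEME, SEGMENT_ORDER, SegmentScheme, SegmentedTRNA

__all__ = [
    "FrequencyProfile",
    "InformationProfile",
    "SimilarityResult",
    "build_profile",
    "information_content",
    "consensus",
    "segment_similarity",
    "sequence_identity",
    "plot_logo",
    "LETTERS",
]

LETTERS = ("A", "C", "G", "T")
GAP = "-"


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-column letter counts over the 75-nt core coordinates."""

    counts: np.ndarray = field(repr=False)  # shape (width, 4), order LETTERS
    gap_counts: np.ndarray = field(repr=False)  # shape (width,)
    n_sequences: int
    scheme: SegmentScheme = field(default_factory=lambda: DEFAULT_SCHEME, repr=False)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        """Per-column base frequencies over non-gap observations (NaN if all-gap)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    def gap_fraction(self) -> np.ndarray:
        return self.gap_counts / self.n_sequences

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(LETTERS))
        df.insert(0, "position", np.arange(1, self.width + 1))
        df["gap"] = self.gap_counts
        return df


def build_profile(
    trnas: list[SegmentedTRNA], scheme: SegmentScheme = DEFAULT_SCHEME
) -> FrequencyProfile:
    """Stack segmented tRNAs onto core coordinates and count letters per column.

    Within a segment shorter than its scheme range (D deletions, short V
    loops) residues are left-aligned and the remaining columns counted as
    gaps; residues beyond a range (V-loop insertions) are excluded. Lenient
    ``N`` residues are counted as gaps so frequencies stay over resolved
    bases. Every column's non-gap + gap counts sum to the number of
    sequences.
    """
    if not trnas:
        raise ValueError("build_profile requires a non-empty list")
    if any(t.scheme.ranges != scheme.ranges for t in trnas):
        raise ValueError("all tRNAs must be segmented on the profile's scheme")
    width = scheme.core_len
    counts = np.zeros((width, len(LETTERS)), dtype=np.int64)
    gaps = np.zeros(width, dtype=np.int64)
    index = {ch: i for i, ch in enumerate(LETTERS)}
    for t in trnas:
        for name in SEGMENT_ORDER:
            start, end = scheme.ranges[name]
            slot = end - start + 1
            seg = t.segments[name][:slot]  # insertions beyond the range excluded
            for offset in range(slot):
                col = start - 1 + offset
                if offset < len(seg) and seg[offset] in index:
                    counts[col, index[seg[offset]]] += 1
                else:
                    gaps[col] += 1
    return FrequencyProfile(counts, gaps, len(trnas), scheme)


@dataclass(frozen=True)
class InformationProfile:
    """Per-column bits and letter heights (frequency x bits), logo-style."""

    bits: np.ndarray = field(repr=False)  # shape (width,), NaN where all-gap
    heights: np.ndarray = field(repr=False)  # shape (width, 4)
    corrected: bool = False

    @property
    def width(self) -> int:
        return self.bits.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=[f"height_{c}" for c in LETTERS])
        df.insert(0, "position", np.arange(1, self.width + 1))
        df.insert(1, "bits", self.bits)
        return df


def information_content(
    profile: FrequencyProfile, correction: bool = False
) -> InformationProfile:
    """Shannon information per column: bits = 2 - H over non-gap frequencies.

    With ``correction=True`` the small-sample term e(n) = 3 / (2 ln2 n) is
    subtracted (n = non-gap observations at that column) and the result
    floored at 0. All-gap columns are reported as NaN.
    """
    freqs = profile.frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -np.nansum(plogp, axis=1)
    bits = 2.0 - entropy
    all_gap = profile.counts.sum(axis=1) == 0
    if correction:
        n_obs = profile.counts.sum(axis=1).astype(float)
        with np.errstate(divide="ignore"):
            e = np.where(n_obs > 0, 3.0 / (2.0 * np.log(2.0) * n_obs), 0.0)
        bits = np.maximum(bits - e, 0.0)
    bits = np.where(all_gap, np.nan, bits)
    heights = np.where(all_gap[:, None], np.nan, freqs * bits[:, None])
    return InformationProfile(bits, heights, corrected=correction)


def consensus(profile: FrequencyProfile, threshold: float = 0.5) -> str:
    """Majority-letter consensus: per column the top letter if its (non-gap)
    frequency reaches ``threshold``, else ``N``; all-gap columns give ``-``.

    Ties on the top frequency resolve alphabetically. ``threshold`` must
    exceed 0.25 (below that 'majority' is meaningless over four letters).
    """
    if not 0.25 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.25, 1]")
    freqs = profile.frequencies()
    out = []
    for col in range(profile.width):
        if np.isnan(freqs[col]).all():
            out.append(GAP)
            continue
        best = int(np.argmax(freqs[col]))  # argmax takes the first = alphabetical
        out.append(LETTERS[best] if freqs[col, best] >= threshold else "N")
    return "".join(out)


@dataclass(frozen=True)
class SimilarityResult:
    """Consensus identity between two aligned segments."""

    matches: int
    denominator: int
    excluded: int  # positions dropped for ambiguity (N/X/-) in either letter

    @property
    def fraction(self) -> float:
        return self.matches / self.denominator if self.denominator else float("nan")


_AMBIGUOUS = frozenset("NX-")


def sequence_identity(a: str, b: str) -> SimilarityResult:
    """Parallel letter-wise identity, ambiguity codes (N/X/-) excluded from
    the denominator."""
    if len(a) != len(b):
        raise ValueError(f"sequences must have equal length, got {len(a)} and {len(b)}")
    a = a.upper()
    b = b.upper()
    matches = defined = 0
    for x, y in zip(a, b):
        if x in _AMBIGUOUS or y in _AMBIGUOUS:
            continue
        defined += 1
        matches += x == y
    return SimilarityResult(matches, defined, len(a) - defined)


def segment_similarity(
    profile: FrequencyProfile,
    seg_a: tuple[int, int] | str,
    seg_b: tuple[int, int] | str,
    threshold: float = 0.5,
) -> SimilarityResult:
    """Consensus identity between two equal-length core ranges.

    Ranges are 1-based inclusive core coordinates or scheme segment names.
    The comparison is parallel (position k of A against position k of B), as
    the model aligns the stem relics under the acceptor stems.
    """
    cons = consensus(profile, threshold)

    def resolve(seg):
        if isinstance(seg, str):
            return profile.scheme.ranges[seg]
        return seg

    (a1, a2), (b1, b2) = resolve(seg_a), resolve(seg_b)
    if a2 - a1 != b2 - b1:
        raise ValueError("segment ranges must have equal length")
    return sequence_identity(cons[a1 - 1 : a2], cons[b1 - 1 : b2])


def plot_logo(
    info: InformationProfile, path: str, scheme: SegmentScheme = DEFAULT_SCHEME
) -> None:
    """Draw a stacked-letter-height logo (SVG/PNG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}
    fig, ax = plt.subplots(figsize=(max(8, info.width / 5), 3))
    x = np.arange(1, info.width + 1)
    for col in range(info.width):
        if np.isnan(info.bits[col]):
            continue
        order = np.argsort(info.heights[col])
        bottom = 0.0
        for li in order:
            h = info.heights[col, li]
            if h <= 0 or np.isnan(h):
                continue
            ax.bar(
                x[col], h, bottom=bottom, width=0.9,
                color=colors[LETTERS[li]], edgecolor="none",
            )
            bottom += h
    for name in SEGMENT_ORDER:
        start, end = scheme.ranges[name]
        if end <= info.width:
            ax.axvline(end + 0.5, color="grey", lw=0.5, ls=":")
            ax.text((start + end) / 2, 2.05, name, ha="center", fontsize=7)
    ax.set_xlim(0.5, info.width + 0.5)
    ax.set_ylim(0, 2.2)
    ax.set_xlabel("core position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
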