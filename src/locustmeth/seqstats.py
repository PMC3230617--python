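"""Dinucleotide observed/expected statistics with an N correction.

The CpG O/E ratio compares how often the CpG dinucleotide occurs in a
sequence with how often it would occur if C and G were placed independently
at the sequence's own mononucleotide frequencies.  Because 5-methylcytosine
deaminates to thymine, genes that were methylated in the germline lose CpG
sites over evolutionary time; a CpG O/E well below 1 is therefore a footprint
of historic germline methylation, readable from sequence alone.

EST-derived unigene sets contain Ns, so both sides of the ratio are computed
on N-free material only:

    O/E(xy) = (d_xy / W) / ((m_x / L_eff) * (m_y / L_eff))

where ``d_xy`` counts adjacent windows equal to xy among the ``W`` windows
whose two bases are both in {A, C, G, T}, and ``m_x`` counts base x among the
``L_eff`` non-N positions.  With no Ns this reduces to the textbook estimator
d_xy * L^2 / (m_x * m_y * (L - 1)) up to the L/(L-1) window factor, which is
deliberately not applied (no small-sample length correction).

The ratio is *undefined* — a value, not an exception — when a denominator
term is zero or the sequence has fewer than ``min_length`` non-N bases; a
reason code records why.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "DinucleotideCounts",
    "OERecord",
    "CloneCensus",
    "ALL_DINUCLEOTIDES",
    "count_dinucleotides",
    "dinucleotide_oe",
    "oe_profile",
    "all_dinucleotide_profiles",
    "pairwise_identity",
    "clone_census_percentages",
]

BASES = "ACGT"
ALL_DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_LUT = np.full(128, 4, dtype=np.int8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c


@dataclass(frozen=True)
class DinucleotideCounts:
    """Mono- and dinucleotide counts of one sequence, Ns excluded.

    ``L_eff`` is the number of non-N bases; ``W`` the number of adjacent
    windows with both bases in {A,C,G,T}.  The 16 ``di`` counts sum to W.
    """

    gene_id: str
    length: int
    mono: Mapping[str, int]
    L_eff: int
    di: Mapping[str, int]
    W: int


@dataclass(frozen=True)
class OERecord:
    """Per-gene observed/expected ratio for one dinucleotide.

    ``oe`` is NaN when undefined; ``reason`` is None for a defined value,
    otherwise one of ``too_short``, ``no_windows``, ``zero_mono_x``,
    ``zero_mono_y``.  Denominator ingredients are carried for audit.
    """

    gene_id: str
    dinucleotide: str
    oe: float
    reason: str | None
    L_eff: int
    W: int
    mono_x: int
    mono_y: int

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class CloneCensus:
    """Clone counts per sequence category (e.g. repetitive / EST / unknown)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("clone counts must be non-negative")
        if self.total < 1:
            raise ValueError("clone census requires total >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _LUT[arr]


def count_dinucleotides(seq: SequenceRecord) -> DinucleotideCounts:
    """Count mononucleotides and all 16 dinucleotides, excluding Ns.

    Windows spanning an N contribute to neither the window total W nor any
    dinucleotide count; degenerate sequences (all N, or length 1) simply
    yield zero counts.
    """
    codes = _encode(seq.residues)
    valid = codes < 4
    mono_counts = np.bincount(codes[valid], minlength=4)
    L_eff = int(valid.sum())
    if len(codes) >= 2:
        left, right = codes[:-1], codes[1:]
        ok = (left < 4) & (right < 4)
        pair_idx = left[ok].astype(np.int64) * 4 + right[ok]
        di_counts = np.bincount(pair_idx, minlength=16)
    else:
        di_counts = np.zeros(16, dtype=np.int64)
    di = {ALL_DINUCLEOTIDES[i]: int(di_counts[i]) for i in range(16)}
    return DinucleotideCounts(
        gene_id=seq.id,
        length=seq.length,
        mono={b: int(mono_counts[_CODE[b]]) for b in BASES},
        L_eff=L_eff,
        di=di,
        W=int(di_counts.sum()),
    )


def dinucleotide_oe(
    counts: DinucleotideCounts, xy: str, min_length: int = 0
) -> OERecord:
    """Observed/expected ratio for dinucleotide ``xy`` from precomputed counts.

    Undefined (NaN with a reason code) when L_eff < min_length, W == 0, or
    either mononucleotide count is zero.  A zero numerator with valid
    denominators gives oe = 0.0.
    """
    xy = xy.upper()
    if len(xy) != 2 or any(b not in BASES for b in xy):
        raise ValueError(f"invalid dinucleotide {xy!r}")
    x, y = xy[0], xy[1]
    mx, my = counts.mono[x], counts.mono[y]
    reason = None
    if counts.L_eff < min_length:
        reason = "too_short"
    elif counts.W == 0:
        reason = "no_windows"
    elif mx == 0:
        reason = "zero_mono_x"
    elif my == 0:
        reason = "zero_mono_y"
    if reason is not None:
        oe = math.nan
    else:
        observed = counts.di[xy] / counts.W
        expected = (mx / counts.L_eff) * (my / counts.L_eff)
        oe = observed / expected
    return OERecord(
        gene_id=counts.gene_id,
        dinucleotide=xy,
        oe=oe,
        reason=reason,
        L_eff=counts.L_eff,
        W=counts.W,
        mono_x=mx,
        mono_y=my,
    )


DEFAULT_MIN_LENGTH = 100  # non-N bases; unigene sets of interest start at ~100 bp


def oe_profile(
    records: Sequence[SequenceRecord],
    xy: str = "CG",
    min_length: int = DEFAULT_MIN_LENGTH,
    subset: Sequence[str] | None = None,
) -> list[OERecord]:
    """Per-gene O/E ratios for one dinucleotide across a record set.

    One OERecord per input gene, input order preserved; excluded genes are
    flagged with a reason rather than dropped.  ``subset`` restricts the
    profile to the listed gene ids (e.g. a differentially-expressed subset),
    preserving subset order; unknown subset ids raise KeyError.
    """
    if not records:
        raise ValueError("oe_profile requires a non-empty record list")
    if subset is not None:
        by_id = {r.id: r for r in records}
        missing = [g for g in subset if g not in by_id]
        if missing:
            raise KeyError(f"subset ids not in record set: {missing[:5]}")
        records = [by_id[g] for g in subset]
    return [
        dinucleotide_oe(count_dinucleotides(rec), xy, min_length=min_length)
        for rec in records
    ]


def all_dinucleotide_profiles(
    records: Sequence[SequenceRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> dict[str, list[OERecord]]:
    """O/E profiles for all 16 dinucleotides, sharing one counting pass.

    The CpG distribution is the signal of interest; the other 15 serve as
    controls that should remain unimodal when only CpG is hypermutable.
    """
    if not records:
        raise ValueError("all_dinucleotide_profiles requires a non-empty record list")
    all_counts = [count_dinucleotides(rec) for rec in records]
    return {
        xy: [dinucleotide_oe(c, xy, min_length=min_length) for c in all_counts]
        for xy in ALL_DINUCLEOTIDES
    }


def defined_values(profile: Iterable[OERecord]) -> np.ndarray:
    """Extract the defined O/E values of a profile as a float array."""
    return np.array([r.oe for r in profile if r.defined], dtype=float)


_GAPS = frozenset("-.")


def _round_half_away(x: float, ndigits: int = 0) -> float:
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def pairwise_identity(aligned_a: str, aligned_b: str) -> tuple[int, int, float]:
    """Percent identity of two pre-aligned (gapped) sequences.

    Columns gapped in both sequences are dropped; columns with at least one
    residue are compared; identical means equal non-gap residues.  Returns
    (identical_sites, compared_sites, percent) with percent rounded to one
    decimal, half away from zero.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    identical = 0
    compared = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        a_gap, b_gap = ca in _GAPS, cb in _GAPS
        if a_gap and b_gap:
            continue
        compared += 1
        if not a_gap and not b_gap and ca == cb:
            identical += 1
    if compared == 0:
        raise ValueError("alignment has no compared columns")
    percent = _round_half_away(100.0 * identical / compared, 1)
    return identical, compared, percent


def clone_census_percentages(census: CloneCensus) -> dict[str, int]:
    """Integer percentages per clone category (half rounds away from zero)."""
    total = census.total
    return {
        cat: int(_round_half_away(100.0 * n / total))
        for cat, n in census.counts.items()
    }
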