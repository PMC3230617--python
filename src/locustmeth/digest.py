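"""In-silico HpaII/MspI methylation-sensitive restriction digestion.

HpaII and MspI are isoschizomers that both recognize 5'-CCGG-3' and cut
after the first C (C^CGG), but HpaII is blocked when the internal cytosine
of the site is 5-methylated while MspI cuts regardless.  Digesting the same
DNA with both and comparing fragment-length distributions therefore reads
out CpG methylation: methylated sites survive HpaII only, leaving a
high-molecular-weight fraction that disappears in the MspI digest.

Molecules are linear; coordinates are 0-based; cut positions are inter-base
indices.  CCGG is its own reverse complement, so one forward-strand scan
finds every site.  Ns abolish a match (exact matching only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .io import SequenceRecord

__all__ = [
    "MethylationMask",
    "DigestResult",
    "FragmentSummary",
    "find_sites",
    "digest",
    "fragment_summary",
    "compare_digests",
]

MOTIF = "CCGG"


@dataclass(frozen=True)
class MethylationMask:
    """0-based positions of 5-methylcytosine, per strand.

    ``forward`` positions must index a C on the forward strand; ``reverse``
    positions must index a C on the reverse strand, i.e. a G on the forward
    strand.  Validation happens against the sequence at digest time.
    """

    forward: frozenset[int] = frozenset()
    reverse: frozenset[int] = frozenset()

    @classmethod
    def from_cpg_sites(cls, positions: Iterable[int]) -> "MethylationMask":
        """Symmetric-CpG constructor: each position p is the C of a CpG
        methylated on both strands (forward C at p, reverse C at p+1)."""
        pos = frozenset(int(p) for p in positions)
        return cls(forward=pos, reverse=frozenset(p + 1 for p in pos))

    def validate(self, seq: SequenceRecord) -> None:
        for p in self.forward:
            if not (0 <= p < seq.length) or seq.residues[p] != "C":
                raise ValueError(f"forward mask position {p} is not a C")
        for p in self.reverse:
            if not (0 <= p < seq.length) or seq.residues[p] != "G":
                raise ValueError(
                    f"reverse mask position {p} is not a C on the reverse strand"
                )


@dataclass(frozen=True)
class DigestResult:
    """Cut positions and fragment lengths of one linear digest."""

    enzyme: str
    sequence_id: str
    sequence_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]


@dataclass(frozen=True)
class FragmentSummary:
    count: int
    mean_length: float
    median_length: float
    max_length: int
    hmw_fraction: float
    hmw_threshold: int


def find_sites(seq: SequenceRecord, motif: str = MOTIF) -> list[int]:
    """All exact forward-strand start positions of the motif, every offset
    scanned so overlapping occurrences are reported."""
    motif = motif.upper()
    res = seq.residues
    sites = []
    start = 0
    while True:
        i = res.find(motif, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


def digest(
    seq: SequenceRecord,
    enzyme: str,
    mask: MethylationMask | None = None,
) -> DigestResult:
    """Digest a linear molecule with HpaII or MspI under a methylation mask.

    Every CCGG site cuts at inter-base index start+1 (C^CGG) unless blocked.
    HpaII is blocked when the site's internal C is methylated on either
    strand (forward position start+1 or its reverse-strand partner at
    start+2).  MspI ignores internal-C methylation.
    """
    enzyme = enzyme.strip()
    if enzyme not in ("HpaII", "MspI"):
        raise ValueError(f"unknown enzyme {enzyme!r}; use HpaII or MspI")
    if mask is None:
        mask = MethylationMask()
    mask.validate(seq)
    cuts = []
    for site in find_sites(seq):
        if enzyme == "HpaII":
            blocked = (site + 1) in mask.forward or (site + 2) in mask.reverse
            if blocked:
                continue
        cuts.append(site + 1)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [seq.length]
    fragments = tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]) if b > a)
    return DigestResult(
        enzyme=enzyme,
        sequence_id=seq.id,
        sequence_length=seq.length,
        cut_positions=tuple(cuts),
        fragment_lengths=fragments,
    )


def fragment_summary(result: DigestResult, hmw_threshold: int) -> FragmentSummary:
    """Fragment-length statistics and the high-molecular-weight mass fraction.

    The HMW fraction is mass-weighted — the share of total base pairs that
    sit in fragments of length >= threshold — mirroring what ethidium
    staining intensity reports on a gel.
    """
    frags = result.fragment_lengths
    if not frags:
        raise ValueError("empty digest result")
    total = sum(frags)
    hmw = sum(f for f in frags if f >= hmw_threshold)
    return FragmentSummary(
        count=len(frags),
        mean_length=total / len(frags),
        median_length=float(median(frags)),
        max_length=max(frags),
        hmw_fraction=hmw / total,
        hmw_threshold=hmw_threshold,
    )


def compare_digests(
    hpaii: DigestResult, mspi: DigestResult, hmw_threshold: int
) -> float:
    """Methylation signal: HMW fraction of the HpaII digest minus that of the
    MspI digest of the same molecule.

    Zero for unmethylated DNA (identical digests); positive and increasing
    with the fraction of methylation-blocked sites under the blocking model
    implemented here (blocking only removes HpaII cuts).
    """
    if hpaii.sequence_length != mspi.sequence_length:
        raise ValueError("digests are not of the same molecule")
    return (
        fragment_summary(hpaii, hmw_threshold).hmw_fraction
        - fragment_summary(mspi, hmw_threshold).hmw_fraction
    )
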