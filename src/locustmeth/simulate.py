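"""Synthetic unigene sets, annotations and genomes with known ground truth.

The central generator emulates the evolutionary mechanism behind CpG
depletion: 5-methylcytosine deaminates to thymine, so CpG dinucleotides in
germline-methylated sequences are lost at an elevated rate.  Evolution is a
discrete-round approximation — each round every site mutates to a uniformly
chosen different base with probability ``base_rate``, and the C of every CpG
(and its reverse-strand partner G) undergoes an *additional* targeted
transition (C→T / G→A) with probability ``base_rate * (cpg_multiplier - 1)``.
A multiplier of 1 is therefore an exact null (no CpG-specific channel), and
the total CpG transition pressure scales as ``base_rate * cpg_multiplier``.
CpG context is re-evaluated every round, so newly created CpGs become
hypermutable, as in the biological mechanism.  When both channels fire at a
site in the same round the deamination outcome wins.  No indels are modelled
(O/E statistics are alignment-free).

A two-population unigene set — one class evolved under strong CpG
hypermutability, one under a weak regime — reproduces the bimodal CpG O/E
structure seen in historically methylated transcriptomes, with lengths drawn
from a log-normal law emulating EST unigene sets (mean ≈ 598 bp, clipped to
[101, 4278]).  Companion generators plant a known enriched GO term into the
methylated class and build genomes whose repeat copies carry methylated CCGG
sites for the digest module.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import MethylationMask
from .io import SequenceRecord

__all__ = [
    "EvolutionParams",
    "UnigeneSetSpec",
    "generate_ancestral_sequence",
    "evolve_sequence",
    "generate_unigene_set",
    "plant_annotations",
    "generate_genome_with_repeats",
]

_BASES = "ACGT"
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# Calibrated evolution regimes (see docs/methods.md): the strong regime
# drives the methylated class's CpG O/E toward ~0.4, the weak regime leaves
# the unmethylated class near ~0.9.
METHYLATED_REGIME = dict(base_rate=0.01, cpg_multiplier=7.3, rounds=10)
UNMETHYLATED_REGIME = dict(base_rate=0.01, cpg_multiplier=1.8, rounds=10)


@dataclass(frozen=True)
class EvolutionParams:
    """Mutation regime for one evolutionary run."""

    base_rate: float
    cpg_multiplier: float
    rounds: int
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 0.5:
            raise ValueError("base_rate must lie in [0, 0.5]")
        if self.cpg_multiplier < 1.0:
            raise ValueError("cpg_multiplier must be >= 1")
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")

    @property
    def extra_cpg_rate(self) -> float:
        """Per-round targeted C→T / G→A probability at CpG sites."""
        return min(1.0, self.base_rate * (self.cpg_multiplier - 1.0))


@dataclass(frozen=True)
class UnigeneSetSpec:
    """Recipe for a two-population synthetic unigene set.

    Lengths follow a log-normal law (median ≈ 450, mean ≈ 598) clipped to
    [101, 4278] bp, emulating EST unigene sets; GC content 0.45 as typical
    of insect transcriptomes.
    """

    n_genes: int = 2000
    prop_methylated: float = 0.5
    length_log_mu: float = math.log(450.0)
    length_log_sigma: float = 0.7546
    min_length: int = 101
    max_length: int = 4278
    gc_content: float = 0.45
    params_methylated: EvolutionParams = field(
        default_factory=lambda: EvolutionParams(**METHYLATED_REGIME)
    )
    params_unmethylated: EvolutionParams = field(
        default_factory=lambda: EvolutionParams(**UNMETHYLATED_REGIME)
    )
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.prop_methylated <= 1.0:
            raise ValueError("prop_methylated must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("invalid length bounds")


# ---------------------------------------------------------------------------
# core generators (integer-coded, batched across sequences)
# ---------------------------------------------------------------------------


def _random_codes(
    lengths: Sequence[int], gc: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, max_len) int8 matrix of i.i.d. bases, padded with 4 beyond each
    row's length.  P(C) = P(G) = gc/2, P(A) = P(T) = (1-gc)/2."""
    lengths = np.asarray(lengths, dtype=int)
    n, lmax = len(lengths), int(lengths.max())
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=(n, lmax), p=p).astype(np.int8)
    pad = np.arange(lmax)[None, :] >= lengths[:, None]
    codes[pad] = 4
    return codes


def _evolve_codes(
    codes: np.ndarray, params: EvolutionParams, rng: np.random.Generator
) -> np.ndarray:
    """Apply the discrete-round mutation model to an int8 code matrix.

    Padding/N positions (code 4) are inert.  Context for the CpG channel is
    the state at the start of each round.
    """
    codes = codes.copy()
    q = params.extra_cpg_rate
    for _ in range(params.rounds):
        valid = codes < 4
        u = rng.random(codes.shape)
        shift = rng.integers(1, 4, size=codes.shape, dtype=np.int8)
        mutated = (codes + shift) % 4
        out = np.where(valid & (u < params.base_rate), mutated, codes)
        if q > 0.0:
            is_cpg_c = np.zeros_like(valid)
            is_cpg_c[:, :-1] = (codes[:, :-1] == 1) & (codes[:, 1:] == 2)
            is_cpg_g = np.zeros_like(valid)
            is_cpg_g[:, 1:] = is_cpg_c[:, :-1]
            fire = rng.random(codes.shape) < q
            out = np.where(is_cpg_c & fire, np.int8(3), out)  # C -> T
            out = np.where(is_cpg_g & fire, np.int8(0), out)  # G -> A
        codes = out
    return codes


def _decode_row(row: np.ndarray, length: int) -> str:
    return _DECODE[row[:length].astype(np.intp)].tobytes().decode("ascii")


def generate_ancestral_sequence(
    length: int, gc_content: float, seed: int, seq_id: str = "anc"
) -> SequenceRecord:
    """An i.i.d. random sequence with the given GC content (deterministic
    per seed).  The expected O/E of every dinucleotide is 1 by construction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    codes = _random_codes([length], gc_content, rng)
    return SequenceRecord(id=seq_id, residues=_decode_row(codes[0], length))


def evolve_sequence(seq: SequenceRecord, params: EvolutionParams) -> SequenceRecord:
    """Evolve one sequence under the CpG-hypermutability model (deterministic
    per ``params.seed``); Ns are left untouched."""
    lut = np.full(128, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)][None, :]
    rng = np.random.default_rng(params.seed)
    out = _evolve_codes(codes, params, rng)
    return SequenceRecord(id=seq.id, residues=_decode_row(out[0], seq.length))


def generate_unigene_set(
    spec: UnigeneSetSpec,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate a two-population unigene set with per-gene truth labels.

    Returns the records and a gene_id → {"methylated", "unmethylated"}
    truth table covering every gene exactly once.  Class sizes are the
    rounded expectation (not binomial), so the planted mixture weight is
    exact; class membership is randomly permuted across genes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    lengths = np.clip(
        np.round(rng.lognormal(spec.length_log_mu, spec.length_log_sigma, n)),
        spec.min_length,
        spec.max_length,
    ).astype(int)
    n_meth = int(round(n * spec.prop_methylated))
    is_meth = np.zeros(n, dtype=bool)
    is_meth[rng.permutation(n)[:n_meth]] = True

    codes = _random_codes(lengths, spec.gc_content, rng)
    for flag, params in ((True, spec.params_methylated), (False, spec.params_unmethylated)):
        idx = np.where(is_meth == flag)[0]
        if idx.size:
            sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            codes[idx] = _evolve_codes(codes[idx], params, sub_rng)

    width = len(str(n))
    records = []
    truth = {}
    for i in range(n):
        gid = f"g{i + 1:0{width}d}"
        records.append(SequenceRecord(id=gid, residues=_decode_row(codes[i], lengths[i])))
        truth[gid] = "methylated" if is_meth[i] else "unmethylated"
    return records, truth


def plant_annotations(
    truth: Mapping[str, str],
    terms: Sequence[str],
    enriched_term: str,
    enrichment_factor: float,
    seed: int,
    baseline: float = 0.05,
) -> dict[str, set[str]]:
    """Annotation table with one term planted into the methylated class.

    Every gene receives each background term independently with probability
    ``baseline``; the enriched term is assigned to methylated-class genes
    with probability min(1, factor * baseline) and to others at baseline.
    Genes that end up with no terms are omitted (no empty sets stored).
    """
    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    if not 0.0 < baseline <= 1.0:
        raise ValueError("baseline must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    background = [t for t in terms if t != enriched_term]
    p_meth = min(1.0, enrichment_factor * baseline)
    table: dict[str, set[str]] = {}
    for gene in sorted(truth):
        assigned = {t for t in background if rng.random() < baseline}
        p = p_meth if truth[gene] == "methylated" else baseline
        if rng.random() < p:
            assigned.add(enriched_term)
        if assigned:
            table[gene] = assigned
    return table


def generate_genome_with_repeats(
    n_repeats: int,
    repeat_length: int,
    spacer_length: int,
    methylate_repeats: bool,
    seed: int,
    gc_content: float = 0.5,
) -> tuple[SequenceRecord, MethylationMask]:
    """A linear genome of random spacers alternating with copies of one
    CCGG-bearing repeat unit, plus the matching methylation mask.

    The repeat unit is random sequence with a CCGG planted at its centre
    (additional CCGGs may arise by chance anywhere).  When
    ``methylate_repeats`` is true the mask covers, symmetrically on both
    strands, the internal C of every CCGG that lies inside a repeat copy.
    """
    if n_repeats < 1 or repeat_length < 4 or spacer_length < 0:
        raise ValueError("invalid genome sizes")
    rng = np.random.default_rng(seed)

    def rand_seq(length: int) -> str:
        if length == 0:
            return ""
        codes = _random_codes([length], gc_content, rng)
        return _decode_row(codes[0], length)

    unit = rand_seq(repeat_length)
    mid = (repeat_length - 4) // 2
    unit = unit[:mid] + "CCGG" + unit[mid + 4 :]

    parts = [rand_seq(spacer_length)]
    repeat_spans = []
    pos = spacer_length
    for _ in range(n_repeats):
        repeat_spans.append((pos, pos + repeat_length))
        parts.append(unit)
        pos += repeat_length
        parts.append(rand_seq(spacer_length))
        pos += spacer_length
    genome = SequenceRecord(id="synthetic_genome", residues="".join(parts))

    masked: set[int] = set()
    if methylate_repeats:
        res = genome.residues
        for start, end in repeat_spans:
            i = res.find("CCGG", start)
            while 0 <= i <= end - 4:
                masked.add(i + 1)  # internal C of C^CGG
                i = res.find("CCGG", i + 1)
    mask = MethylationMask.from_cpg_sites(masked)
    return genome, mask
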