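"""Synthetic inputs for the phage-propagation deep mutational scan.

Everything the pipeline consumes can be generated here with known ground
truth: NNS saturation libraries, input/output count tables under a
multiplicative log10 selection model, amplicon reads with optional
substitution error, correlated residue trajectories, and the Poisson
arithmetic of low-multiplicity phage infection.

The generative model of selection is deliberately simple. The input
library is a wild-type spike (the mutagenic PCR also produces perfect-match
product, so the wild-type gene dominates the pool) plus a symmetric
Dirichlet over the variants, which reproduces the observed long low-count
tail. One round of selection multiplies each variant's frequency by
10**F_true; both populations are then multinomially sequenced at the
requested depths. Compounding over multiple infection waves is available
(``waves``) but defaults to a single round.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .mdnet import TrajectoryEnsemble
from .readproc import AmpliconRead, CodonCountTable

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "NNSLibrary",
    "Variant",
    "SelectionScenario",
    "InfectionStats",
    "ReadLayout",
    "translate_codon",
    "nns_codon_set",
    "build_library",
    "poisson_infection",
    "simulate_counts",
    "simulate_reads",
    "simulate_trajectory",
    "collapse_reference_variants",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
_BASES = "ACGT"

#: standard genetic code, codon -> one-letter amino acid ('*' for stop)
CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(_BASES, repeat=3)
}


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon.upper()]


def nns_codon_set() -> frozenset[str]:
    """The 32 NNS codons: any first two bases, third base C or G.

    Together they encode all 20 amino acids (with redundancy) and exactly
    one stop codon, TAG.
    """
    return frozenset(
        a + b + s for a in _BASES for b in _BASES for s in "CG"
    )


@dataclass(frozen=True)
class Variant:
    """One member of a saturation library: a single codon replacement."""

    position: int
    codon: str
    aa: str
    is_reference: bool  # codon identical to the wild-type codon


@dataclass(frozen=True)
class NNSLibrary:
    """A single-codon NNS saturation library over a residue interval.

    ``region`` is a 1-based inclusive interval in protein numbering; every
    position carries all 32 NNS codons (a codon equal to the wild-type
    codon is retained and flagged as the reference).
    """

    wt_dna: str
    region: tuple[int, int]
    variants: tuple[Variant, ...]

    @property
    def positions(self) -> range:
        return range(self.region[0], self.region[1] + 1)

    @property
    def n_positions(self) -> int:
        return self.region[1] - self.region[0] + 1

    def wt_codon(self, position: int) -> str:
        return self.wt_dna[(position - 1) * 3 : position * 3]

    def wt_aa(self, position: int) -> str:
        return translate_codon(self.wt_codon(position))

    def wt_codons(self) -> dict[int, str]:
        return {pos: self.wt_codon(pos) for pos in self.positions}

    def wt_protein(self) -> str:
        return "".join(
            translate_codon(self.wt_dna[i : i + 3]) for i in range(0, len(self.wt_dna), 3)
        )


def build_library(wt_dna: str, region: tuple[int, int]) -> NNSLibrary:
    """Enumerate the 32-codons-per-position NNS library over ``region``."""
    wt_dna = wt_dna.upper()
    if len(wt_dna) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if set(wt_dna) - set(_BASES):
        raise ValueError("reference must be unambiguous A/C/G/T")
    n_codons = len(wt_dna) // 3
    start, end = region
    if not (1 <= start <= end <= n_codons):
        raise ValueError(f"region {region} outside 1..{n_codons}")
    codons = sorted(nns_codon_set())
    variants = []
    for pos in range(start, end + 1):
        wt_codon = wt_dna[(pos - 1) * 3 : pos * 3]
        for codon in codons:
            variants.append(
                Variant(pos, codon, translate_codon(codon), codon == wt_codon)
            )
    return NNSLibrary(wt_dna, (start, end), tuple(variants))


@dataclass(frozen=True)
class InfectionStats:
    """Poisson bookkeeping for infection at a given multiplicity (MOI)."""

    moi: float
    n_cells: float
    p0: float
    p1: float
    p_ge2: float
    expected_infected: float
    expected_multiply_infected: float


def poisson_infection(moi: float, n_cells: float) -> InfectionStats:
    """Poisson infection statistics at multiplicity ``moi`` over ``n_cells``.

    The number of phage hitting one cell is Poisson(moi):
    p_k = exp(-moi) moi^k / k!.
    """
    if moi < 0:
        raise ValueError("moi must be non-negative")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    p0 = math.exp(-moi)
    p1 = moi * math.exp(-moi)
    p_ge2 = max(0.0, 1.0 - p0 - p1)
    return InfectionStats(
        moi=moi,
        n_cells=n_cells,
        p0=p0,
        p1=p1,
        p_ge2=p_ge2,
        expected_infected=n_cells * (1.0 - p0),
        expected_multiply_infected=n_cells * p_ge2,
    )


@dataclass
class SelectionScenario:
    """A complete simulated selection experiment with known ground truth.

    ``true_fitness`` maps (position, amino acid) to the true log10 relative
    fitness; unlisted substitutions default to 0, stop codons to
    ``stop_fitness`` (truncation of an essential ATPase is taken as
    near-lethal), and the wild-type identity is 0 by definition.
    """

    library: NNSLibrary
    true_fitness: Mapping[tuple[int, str], float]
    wt_input_fraction: float = 0.38
    input_depth: int = 1_000_000
    output_depth: int = 1_000_000
    dirichlet_concentration: float = 1.0
    replicates: int = 3
    error_rate: float = 0.0
    seed: int = 0
    stop_fitness: float = -3.0
    waves: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.wt_input_fraction < 1.0:
            raise ValueError("wt_input_fraction must be in [0, 1)")
        if self.input_depth <= 0 or self.output_depth <= 0:
            raise ValueError("depths must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        if self.waves < 1:
            raise ValueError("waves must be >= 1")
        for (pos, aa), f in self.true_fitness.items():
            if aa == self.library.wt_aa(pos) and f != 0.0:
                raise ValueError(
                    f"wild-type identity at position {pos} must have fitness 0"
                )

    def variant_fitness(self, v: Variant) -> float:
        if v.is_reference:
            return 0.0
        if (v.position, v.aa) in self.true_fitness:
            return float(self.true_fitness[(v.position, v.aa)])
        if v.aa == STOP:
            return self.stop_fitness
        if v.aa == self.library.wt_aa(v.position):
            return 0.0
        return 0.0


def simulate_counts(
    scenario: SelectionScenario,
) -> list[tuple[CodonCountTable, CodonCountTable]]:
    """Simulate per-replicate (input, output) codon count tables.

    The library composition (wild-type spike + Dirichlet over variants) is
    drawn once per scenario; each replicate independently resamples both
    populations multinomially at the stated depths, so replicates share the
    same true fitness and the same underlying pool.
    """
    rng = np.random.default_rng(scenario.seed)
    lib = scenario.library
    variants = lib.variants
    n = len(variants)
    base = rng.dirichlet(np.full(n, scenario.dirichlet_concentration))
    input_freq = np.concatenate(
        [[scenario.wt_input_fraction], (1.0 - scenario.wt_input_fraction) * base]
    )
    fitness = np.array([scenario.variant_fitness(v) for v in variants])
    weights = input_freq * np.concatenate([[1.0], 10.0 ** (fitness * scenario.waves)])
    output_freq = weights / weights.sum()
    out = []
    for r in range(scenario.replicates):
        rep = f"rep{r + 1}"
        ic = rng.multinomial(scenario.input_depth, input_freq)
        oc = rng.multinomial(scenario.output_depth, output_freq)
        pair = tuple(
            CodonCountTable(
                sample=sample,
                replicate=rep,
                region=lib.region,
                wt_count=int(counts[0]),
                counts={
                    (v.position, v.codon): int(c)
                    for v, c in zip(variants, counts[1:])
                },
            )
            for sample, counts in (("input", ic), ("output", oc))
        )
        out.append(pair)
    return out


def collapse_reference_variants(
    table: CodonCountTable, library: NNSLibrary
) -> CodonCountTable:
    """Fold reference-codon variant counts into the wild-type count.

    A library member whose NNS codon equals the wild-type codon yields
    reads indistinguishable from wild type, so sequence-level counting can
    only observe the merged class. Apply this before comparing a simulated
    table against counts called back from reads.
    """
    wt = table.wt_count
    counts = {}
    for (pos, codon), c in table.counts.items():
        if codon == library.wt_codon(pos):
            wt += c
        else:
            counts[(pos, codon)] = c
    return CodonCountTable(
        sample=table.sample,
        replicate=table.replicate,
        region=table.region,
        wt_count=wt,
        counts=counts,
        rejects=dict(table.rejects),
        background=table.background,
    )


@dataclass(frozen=True)
class ReadLayout:
    """Where the sequenced amplicon sits on the reference, in nucleotides.

    ``amplicon_start``/``amplicon_end`` are a 0-based half-open interval on
    the coding sequence. With ``paired`` set, a forward and a
    reverse-complement read of ``read_length`` are emitted from the two
    amplicon ends; they must overlap so that a merger can reconstruct the
    amplicon.
    """

    amplicon_start: int
    amplicon_end: int
    paired: bool = False
    read_length: int | None = None


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        options = [b for b in _BASES if b != current]
        arr[i] = rng.choice(options).encode()
    return arr.tobytes().decode()


def simulate_reads(
    count_table: CodonCountTable,
    wt_dna: str,
    read_layout: ReadLayout,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[AmpliconRead] | list[tuple[AmpliconRead, AmpliconRead]]:
    """Emit one read (or read pair) per count, with i.i.d. substitution errors.

    Simulated base qualities are a constant Q40. The layout must cover the
    table's mutagenized region.
    """
    start_nt = (count_table.region[0] - 1) * 3
    end_nt = count_table.region[1] * 3
    lo, hi = read_layout.amplicon_start, read_layout.amplicon_end
    if not (0 <= lo < hi <= len(wt_dna)):
        raise ValueError("amplicon outside the reference")
    if lo > start_nt or hi < end_nt:
        raise ValueError("read layout does not cover the mutagenized region")
    if read_layout.paired:
        L = read_layout.read_length
        if L is None:
            raise ValueError("paired layout requires read_length")
        if L > hi - lo or 2 * L <= hi - lo:
            raise ValueError("paired reads must each fit in and jointly overlap the amplicon")
    rng = np.random.default_rng(seed)
    items: list[tuple[str, int, str]] = [("WT", count_table.wt_count, wt_dna)]
    for (pos, codon), c in sorted(count_table.counts.items()):
        mutant = (
            wt_dna[: (pos - 1) * 3] + codon + wt_dna[pos * 3 :]
        )
        items.append((f"{pos}_{codon}", c, mutant))
    reads: list = []
    for name, count, seq in items:
        amplicon = seq[lo:hi]
        for k in range(count):
            rid = f"{count_table.sample}:{count_table.replicate}:{name}:{k}"
            if read_layout.paired:
                L = read_layout.read_length
                fwd_seq = _apply_errors(amplicon[:L], error_rate, rng)
                rev_seq = _apply_errors(
                    str(Seq(amplicon[-L:]).reverse_complement()), error_rate, rng
                )
                reads.append(
                    (
                        AmpliconRead(rid + "/1", fwd_seq, (40,) * L),
                        AmpliconRead(rid + "/2", rev_seq, (40,) * L),
                    )
                )
            else:
                read_seq = _apply_errors(amplicon, error_rate, rng)
                reads.append(AmpliconRead(rid, read_seq, (40,) * len(read_seq)))
    return reads


def simulate_trajectory(
    n_residues: int,
    n_frames: int,
    block_correlations: Sequence[tuple[Sequence[int], float]] = (),
    noise_scale: float = 1.0,
    seed: int = 0,
    mean_positions: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Gaussian residue fluctuations with block-wise per-axis correlation.

    Each group in ``block_correlations`` is a list of 0-based residue
    indices plus a correlation rho applied to every pair in the group, on
    each coordinate axis independently (isotropic coupling). Displacements
    are added to fixed mean positions spaced along the x axis.
    """
    if n_residues < 1 or n_frames < 1:
        raise ValueError("need at least one residue and one frame")
    cov = np.eye(n_residues)
    for members, rho in block_correlations:
        if abs(rho) > 1.0:
            raise ValueError("|rho| must be <= 1")
        members = list(members)
        if len(set(members)) != len(members):
            raise ValueError("duplicate residue in correlation block")
        for a in members:
            for b in members:
                if a != b:
                    cov[a, b] = rho
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # rho = 1 (or block overlap) makes the covariance singular but can
        # still be valid; factor through the eigendecomposition instead.
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-10:
            raise ValueError("requested correlation structure is not positive semidefinite")
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    if mean_positions is None:
        mean_positions = np.zeros((n_residues, 3))
        mean_positions[:, 0] = 10.0 * np.arange(n_residues)
    coords = np.empty((n_frames, n_residues, 3))
    for axis in range(3):
        z = rng.standard_normal((n_frames, n_residues))
        coords[:, :, axis] = mean_positions[:, axis] + noise_scale * (z @ chol.T)
    labels = tuple(("A", i + 1) for i in range(n_residues))
    return TrajectoryEnsemble(coords, labels)


def write_fasta(name: str, sequence: str, path) -> None:
    """Write a single named sequence as FASTA."""
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")
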