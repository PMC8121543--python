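"""Amplicon reads to codon-variant counts.

The phage-propagation assay amplifies a fixed, mutagenized locus, so reads
are located by exact anchor sequences flanking the region rather than by
gapped alignment. Variant calling is a codon-by-codon comparison against
the wild-type reference: zero differing codons is wild type, exactly one is
a single-codon variant, anything else is rejected with a reason. A
double-mutant mode supports suppressor screens performed in a fixed
mutant background.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconRead",
    "VariantCall",
    "CodonCountTable",
    "REJECT_REASONS",
    "merge_pair",
    "call_variant",
    "tabulate",
    "read_fastq",
    "write_fastq",
]

REJECT_MULTI_CODON = "multi_codon"
REJECT_INDEL = "indel_or_length"
REJECT_AMBIGUOUS = "ambiguous_base"
REJECT_NO_ANCHOR = "no_anchor"
REJECT_NO_BACKGROUND = "background_absent"
REJECT_REASONS = (
    REJECT_MULTI_CODON,
    REJECT_INDEL,
    REJECT_AMBIGUOUS,
    REJECT_NO_ANCHOR,
    REJECT_NO_BACKGROUND,
)

_VALID_BASES = frozenset("ACGTN")


@dataclass
class AmpliconRead:
    """A single (possibly merged) amplicon read."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read")
        if set(self.sequence) - _VALID_BASES:
            raise ValueError("read alphabet must be A/C/G/T/N")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length mismatch")


@dataclass(frozen=True)
class VariantCall:
    """Outcome of calling one read: wildtype, a single-codon variant, or a reject."""

    status: str  # "wildtype" | "variant" | "reject"
    position: int | None = None
    codon: str | None = None
    reject_reason: str | None = None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def merge_pair(
    fwd: AmpliconRead,
    rev: AmpliconRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> AmpliconRead | None:
    """Merge a forward/reverse read pair by their best-scoring exact overlap.

    The reverse read is reverse-complemented and every overlap length of at
    least ``min_overlap`` is scored as matches minus mismatches (positions
    where either base is N are ignored). The best overlap whose mismatch
    fraction is within ``max_mismatch_frac`` wins; disagreeing overlap bases
    are resolved in favor of the higher-quality base, ties become N.
    Returns None when no acceptable overlap exists.
    """
    rc = _revcomp(rev.sequence)
    rcq = tuple(reversed(rev.quality)) if rev.quality is not None else None
    f, fq = fwd.sequence, fwd.quality
    best = None  # (score, overlap)
    for ov in range(min_overlap, min(len(f), len(rc)) + 1):
        a = f[len(f) - ov :]
        b = rc[:ov]
        matches = mismatches = 0
        for x, y in zip(a, b):
            if x == "N" or y == "N":
                continue
            if x == y:
                matches += 1
            else:
                mismatches += 1
        compared = matches + mismatches
        if compared == 0 or mismatches / compared > max_mismatch_frac:
            continue
        score = matches - mismatches
        if best is None or (score, ov) > best[:2]:
            best = (score, ov)
    if best is None:
        return None
    ov = best[1]
    head = f[: len(f) - ov]
    tail = rc[ov:]
    merged = list(head)
    merged_q: list[int] = [fq[i] if fq is not None else 40 for i in range(len(head))]
    for i in range(ov):
        x = f[len(f) - ov + i]
        y = rc[i]
        qx = fq[len(f) - ov + i] if fq is not None else 40
        qy = rcq[i] if rcq is not None else 40
        if x == y:
            merged.append(x)
            merged_q.append(max(qx, qy))
        elif x == "N":
            merged.append(y)
            merged_q.append(qy)
        elif y == "N":
            merged.append(x)
            merged_q.append(qx)
        elif qx > qy:
            merged.append(x)
            merged_q.append(qx)
        elif qy > qx:
            merged.append(y)
            merged_q.append(qy)
        else:
            merged.append("N")
            merged_q.append(2)
    merged += list(tail)
    if rcq is not None:
        merged_q += list(rcq[ov:])
    else:
        merged_q += [40] * len(tail)
    return AmpliconRead(fwd.id, "".join(merged), tuple(merged_q))


def default_anchors(
    wt_dna: str, region: tuple[int, int], anchor_len: int = 15
) -> tuple[str, str]:
    """Flanking anchor sequences immediately outside the mutagenized region."""
    start_nt = (region[0] - 1) * 3
    end_nt = region[1] * 3
    left = wt_dna[max(0, start_nt - anchor_len) : start_nt]
    right = wt_dna[end_nt : end_nt + anchor_len]
    if not left or not right:
        raise ValueError("region abuts the reference end; supply explicit anchors")
    return left, right


def _codon_differs(read_codon: str, wt_codon: str) -> tuple[bool, bool]:
    """(differs, has_ambiguous): non-N mismatches define a difference."""
    differs = any(
        r != w for r, w in zip(read_codon, wt_codon) if r != "N"
    )
    return differs, "N" in read_codon


def call_variant(
    read: AmpliconRead,
    wt_dna: str,
    region: tuple[int, int],
    anchors: tuple[str, str] | None = None,
    background: tuple[int, str] | None = None,
) -> VariantCall:
    """Call one read against the wild-type reference over ``region``.

    Anchors (exact flanking sequences) locate the mutagenized segment in
    the read; no gapped alignment is attempted. In double-mutant mode
    (``background`` = (position, codon)) the background codon must be
    present; the call then concerns the remaining positions, and a read
    carrying only the background mutation is reported as "wildtype", i.e.
    the reference class of the screen.
    """
    if anchors is None:
        anchors = default_anchors(wt_dna, region)
    left, right = anchors
    i = read.sequence.find(left)
    if i < 0:
        return VariantCall("reject", reject_reason=REJECT_NO_ANCHOR)
    seg_start = i + len(left)
    j = read.sequence.find(right, seg_start)
    if j < 0:
        return VariantCall("reject", reject_reason=REJECT_NO_ANCHOR)
    segment = read.sequence[seg_start:j]
    start, end = region
    n_pos = end - start + 1
    if len(segment) != 3 * n_pos:
        return VariantCall("reject", reject_reason=REJECT_INDEL)
    diffs: list[tuple[int, str, bool]] = []
    for k in range(n_pos):
        pos = start + k
        read_codon = segment[3 * k : 3 * k + 3]
        wt_codon = wt_dna[(pos - 1) * 3 : pos * 3]
        differs, has_n = _codon_differs(read_codon, wt_codon)
        if differs:
            diffs.append((pos, read_codon, has_n))
    if background is not None:
        bg_pos, bg_codon = background
        if not (start <= bg_pos <= end):
            raise ValueError("background position outside region")
        found = [d for d in diffs if d[0] == bg_pos]
        if not found or found[0][1] != bg_codon:
            return VariantCall("reject", reject_reason=REJECT_NO_BACKGROUND)
        diffs = [d for d in diffs if d[0] != bg_pos]
    if not diffs:
        return VariantCall("wildtype")
    if len(diffs) > 1:
        return VariantCall("reject", reject_reason=REJECT_MULTI_CODON)
    pos, codon, has_n = diffs[0]
    if has_n:
        return VariantCall("reject", reject_reason=REJECT_AMBIGUOUS)
    return VariantCall("variant", position=pos, codon=codon)


@dataclass
class CodonCountTable:
    """Per-sample counts of single-codon variants plus wild type.

    Positions use 1-based residue numbering of the target protein;
    ``region`` is the inclusive mutagenized interval. Rejected-read counts
    are kept as a side tally by reason.
    """

    sample: str
    replicate: str
    region: tuple[int, int]
    wt_count: int
    counts: dict[tuple[int, str], int]
    rejects: dict[str, int] = field(default_factory=dict)
    background: tuple[int, str] | None = None

    def __post_init__(self) -> None:
        if self.wt_count < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        start, end = self.region
        for pos, codon in self.counts:
            if not (start <= pos <= end):
                raise ValueError(f"position {pos} outside region {self.region}")
            if len(codon) != 3:
                raise ValueError(f"bad codon {codon!r}")

    @property
    def accepted_total(self) -> int:
        return self.wt_count + sum(self.counts.values())

    @property
    def rejected_total(self) -> int:
        return sum(self.rejects.values())

    def wt_fraction(self) -> float:
        total = self.accepted_total
        if total == 0:
            raise ValueError("empty table")
        return self.wt_count / total

    def low_coverage_fraction(self, min_count: int, universe_size: int | None = None) -> float:
        """Fraction of the variant pool observed fewer than ``min_count`` times.

        ``universe_size`` sets the pool denominator when the table does not
        enumerate every possible variant (absent variants count as zero).
        """
        n_low = sum(1 for c in self.counts.values() if c < min_count)
        n_seen = len(self.counts)
        n_universe = n_seen if universe_size is None else universe_size
        if n_universe < n_seen:
            raise ValueError("universe smaller than observed variant set")
        n_low += n_universe - n_seen
        if n_universe == 0:
            raise ValueError("empty variant universe")
        return n_low / n_universe

    def to_frame(self) -> pd.DataFrame:
        from .synthetic import translate_codon  # local import avoids a cycle

        rows = [
            {
                "sample": self.sample,
                "replicate": self.replicate,
                "position": pos,
                "codon": codon,
                "amino_acid": translate_codon(codon),
                "count": count,
            }
            for (pos, codon), count in sorted(self.counts.items())
        ]
        rows.append(
            {
                "sample": self.sample,
                "replicate": self.replicate,
                "position": 0,
                "codon": "WT",
                "amino_acid": "WT",
                "count": self.wt_count,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, region: tuple[int, int]) -> "CodonCountTable":
        df = pd.read_csv(path, sep="\t")
        wt = df[df["codon"] == "WT"]
        body = df[df["codon"] != "WT"]
        return cls(
            sample=str(df["sample"].iloc[0]),
            replicate=str(df["replicate"].iloc[0]),
            region=region,
            wt_count=int(wt["count"].sum()),
            counts={
                (int(r["position"]), str(r["codon"])): int(r["count"])
                for _, r in body.iterrows()
            },
        )

    def reject_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.rejects.items()), columns=["reason", "count"]
        )


def tabulate(
    calls: Iterable[VariantCall],
    sample: str,
    replicate: str,
    region: tuple[int, int],
    background: tuple[int, str] | None = None,
) -> CodonCountTable:
    """Partition accepted calls into a count table; tally rejects by reason."""
    wt = 0
    counts: Counter = Counter()
    rejects: Counter = Counter()
    for call in calls:
        if call.status == "wildtype":
            wt += 1
        elif call.status == "variant":
            counts[(call.position, call.codon)] += 1
        else:
            rejects[call.reject_reason] += 1
    return CodonCountTable(
        sample=sample,
        replicate=replicate,
        region=region,
        wt_count=wt,
        counts=dict(counts),
        rejects=dict(rejects),
        background=background,
    )


def read_fastq(path) -> Iterator[AmpliconRead]:
    """Yield reads from a plain or gzipped FASTQ file (Phred+33)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield AmpliconRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[AmpliconRead], path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            qual = read.quality if read.quality is not None else (40,) * len(read.sequence)
            rec.letter_annotations["phred_quality"] = list(qual)
            SeqIO.write(rec, handle, "fastq")
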