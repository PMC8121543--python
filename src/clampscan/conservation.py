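"""Sequence conservation, logos, and the conservation-vs-sensitivity ROC.

Per-column conservation is measured as information content in bits,
log2(20) minus the Shannon entropy of the gap-excluded amino-acid
frequency vector; logo stack heights are frequency times information
content. The "methods" ROC asks how well a *fixed* binarized-conservation
predictor recovers mutational sensitivity as the ground-truth fitness
cutoff is swept: the true positive rate is the fraction of sensitive
positions (mean effect at or below the cutoff) that are conserved, the
false positive rate is the fraction of insensitive positions that are
conserved. A conventional ROC (sweep the conservation threshold against a
fixed sensitivity labeling) is provided as a clearly labeled alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .fitness import AAFitnessMatrix
from .synthetic import AMINO_ACIDS

__all__ = [
    "ConservationProfile",
    "ROCResult",
    "MAX_BITS",
    "column_stats",
    "logo_heights",
    "consensus_substitution_fitness",
    "conservation_roc",
]

MAX_BITS = float(np.log2(len(AMINO_ACIDS)))  # log2(20), the zero-entropy ceiling
_GAPS = frozenset("-.")


@dataclass
class ConservationProfile:
    """Per-reference-position conservation summary from an MSA.

    Frequencies are over the 20 standard amino acids, gap-excluded and
    renormalized; ``bits`` = log2(20) - H. Columns with more than half
    gaps are flagged low-confidence.
    """

    frequencies: pd.DataFrame  # index: position, columns: 20 amino acids
    bits: pd.Series
    consensus: pd.Series
    runner_up: pd.Series
    n_effective: pd.Series
    gap_fraction: pd.Series
    low_confidence: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out["bits"] = self.bits
        out["consensus"] = self.consensus
        out["runner_up"] = self.runner_up
        out["n_effective"] = self.n_effective
        out["gap_fraction"] = self.gap_fraction
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _load_msa(msa) -> MultipleSeqAlignment:
    if isinstance(msa, MultipleSeqAlignment):
        return msa
    return AlignIO.read(str(msa), "fasta")


def column_stats(
    msa,
    reference_id: str,
    start: int = 1,
    small_sample_correction: bool = False,
    max_gap_fraction: float = 0.5,
) -> ConservationProfile:
    """Per-position conservation profile mapped to reference numbering.

    ``msa`` is an aligned FASTA path or a Biopython alignment; alignment
    columns where the reference row is gapped are dropped, and the
    surviving columns are numbered from ``start``. The optional
    small-sample correction subtracts the standard (s-1)/(2 ln2 n) bias
    term from the information content; with ~1000 sequences it is
    negligible and off by default.
    """
    aln = _load_msa(msa)
    ref_rows = [rec for rec in aln if rec.id == reference_id]
    if not ref_rows:
        raise ValueError(f"reference row {reference_id!r} not in alignment")
    ref = str(ref_rows[0].seq).upper()
    columns = [i for i, c in enumerate(ref) if c not in _GAPS]
    positions = [start + k for k in range(len(columns))]
    aas = list(AMINO_ACIDS)
    n_seq = len(aln)
    freq_rows, bits_l, cons_l, runner_l, neff_l, gapf_l = [], [], [], [], [], []
    for col in columns:
        letters = [str(rec.seq[col]).upper() for rec in aln]
        residues = [c for c in letters if c in AMINO_ACIDS]
        n_gap = sum(1 for c in letters if c in _GAPS)
        if not residues:
            raise ValueError(f"alignment column {col} has no residues")
        counts = pd.Series(0.0, index=aas)
        for c in residues:
            counts[c] += 1
        freq = counts / counts.sum()
        nonzero = freq[freq > 0]
        entropy = float(-(nonzero * np.log2(nonzero)).sum())
        bits = MAX_BITS - entropy
        if small_sample_correction:
            bits -= (len(aas) - 1) / (2.0 * np.log(2) * len(residues))
            bits = max(bits, 0.0)
        ranked = freq.sort_values(ascending=False, kind="stable")
        # ties broken alphabetically for determinism
        ranked = freq.iloc[np.lexsort((freq.index, -freq.to_numpy()))]
        freq_rows.append(freq)
        bits_l.append(bits)
        cons_l.append(ranked.index[0])
        runner_l.append(ranked.index[1] if len(ranked) > 1 else ranked.index[0])
        neff_l.append(len(residues))
        gapf_l.append(n_gap / n_seq)
    idx = pd.Index(positions, name="position")
    gap_fraction = pd.Series(gapf_l, index=idx)
    return ConservationProfile(
        frequencies=pd.DataFrame(freq_rows, index=idx),
        bits=pd.Series(bits_l, index=idx),
        consensus=pd.Series(cons_l, index=idx),
        runner_up=pd.Series(runner_l, index=idx),
        n_effective=pd.Series(neff_l, index=idx),
        gap_fraction=gap_fraction,
        low_confidence=gap_fraction > max_gap_fraction,
    )


def logo_heights(profile: ConservationProfile) -> pd.DataFrame:
    """Sequence-logo stack heights: height(a) = freq(a) x bits.

    The stack total at each position equals the information content.
    """
    return profile.frequencies.mul(profile.bits, axis=0)


def consensus_substitution_fitness(
    profile: ConservationProfile,
    wt_seq: Mapping[int, str] | str,
    m: AAFitnessMatrix,
    exclude_conservation_quantile: float = 0.9,
) -> pd.DataFrame:
    """Fitness of the evolutionarily most likely substitution per position.

    Where the wild-type residue equals the alignment consensus, the
    second-most frequent residue is looked up in the fitness matrix;
    elsewhere the consensus itself is. Positions whose conservation
    exceeds the given quantile of the profile are excluded, because the
    runner-up residue is poorly determined at near-invariant columns.
    """
    if isinstance(wt_seq, str):
        wt_map = {i + 1: aa for i, aa in enumerate(wt_seq)}
    else:
        wt_map = dict(wt_seq)
    shared = [p for p in profile.bits.index if p in m.values.index and p in wt_map]
    if not shared:
        raise ValueError("profile and fitness matrix share no positions")
    cutoff = float(profile.bits.loc[shared].quantile(exclude_conservation_quantile))
    rows = []
    for pos in shared:
        if profile.bits[pos] > cutoff:
            continue
        wt = wt_map[pos]
        chosen = (
            profile.runner_up[pos] if wt == profile.consensus[pos] else profile.consensus[pos]
        )
        rows.append(
            {
                "position": pos,
                "wt_aa": wt,
                "chosen_residue": chosen,
                "fitness": float(m.values.loc[pos, chosen]),
            }
        )
    return pd.DataFrame(rows, columns=["position", "wt_aa", "chosen_residue", "fitness"])


@dataclass
class ROCResult:
    """ROC sweep points plus trapezoid AUC."""

    points: pd.DataFrame  # columns: cutoff, tpr, fpr
    auc: float
    t_bits: float
    mode: str


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def conservation_roc(
    mean_effects: pd.Series,
    bits: pd.Series,
    t_bits: float,
    mode: str = "methods",
    theta: float | None = None,
) -> ROCResult:
    """ROC for predicting mutational sensitivity from conservation.

    In "methods" mode the predictor is fixed (conserved = bits >= t_bits)
    and the ground-truth fitness cutoff is swept over all observed mean
    effects; a position is sensitive when its mean effect is <= the
    cutoff. Cutoffs at which either class is empty are skipped. In
    "conventional" mode the conservation score is swept against a fixed
    sensitivity labeling at ``theta``.
    """
    common = mean_effects.index.intersection(bits.index)
    if len(common) == 0:
        raise ValueError("no shared positions")
    me = mean_effects.loc[common].to_numpy(dtype=float)
    conserved = (bits.loc[common].to_numpy(dtype=float) >= t_bits)
    ok = np.isfinite(me)
    me, conserved = me[ok], conserved[ok]
    n = len(me)
    if n == 0:
        raise ValueError("no finite mean effects")
    if mode == "conventional":
        if theta is None:
            raise ValueError("conventional mode requires theta")
        from sklearn.metrics import auc as sk_auc, roc_curve

        labels = me <= theta
        if labels.all() or (~labels).all():
            raise ValueError("all positions in one class")
        score = bits.loc[common].to_numpy(dtype=float)[ok]
        fpr, tpr, thr = roc_curve(labels, score)
        points = pd.DataFrame({"cutoff": thr, "tpr": tpr, "fpr": fpr})
        return ROCResult(points, float(sk_auc(fpr, tpr)), t_bits, mode)
    if mode != "methods":
        raise ValueError(f"unknown mode {mode!r}")
    order = np.argsort(me, kind="stable")
    me_sorted = me[order]
    csum = np.cumsum(conserved[order])
    total_c = int(conserved.sum())
    cutoffs, tprs, fprs = [], [], []
    # sensitive set at cutoff c = positions with mean effect <= c: a prefix
    # of the sorted order; k = prefix length at each distinct cutoff
    for k in range(1, n):
        if me_sorted[k] == me_sorted[k - 1]:
            continue  # not a class boundary: same cutoff value continues
        cutoffs.append(me_sorted[k - 1])
        tprs.append(csum[k - 1] / k)
        fprs.append((total_c - csum[k - 1]) / (n - k))
    if not cutoffs:
        raise ValueError("all positions in one class at every cutoff")
    points = pd.DataFrame({"cutoff": cutoffs, "tpr": tprs, "fpr": fprs})
    return ROCResult(points, _trapezoid_auc(np.array(fprs), np.array(tprs)), t_bits, mode)
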