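"""Relative fitness from input/output variant counts.

The fitness of variant i is the log10 enrichment of its frequency from the
input (plasmid) to the output (recombinant phage) population, relative to
the wild-type sequence:

    F_i = log10(f_out_i / f_in_i) - log10(f_out_WT / f_in_WT)

F = 0 is wild-type-like; +1 and -1 correspond to 10-fold faster and slower
propagation. Because both terms are frequency ratios from the same pair of
samples, the total-depth normalizers cancel and F is invariant to scaling
either sample's counts. A pseudocount (default 0.5) keeps F finite for
dropout variants while shifting well-covered variants by < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import AMINO_ACIDS, STOP, translate_codon

__all__ = [
    "FitnessTable",
    "AAFitnessMatrix",
    "SensitivityProfile",
    "codon_fitness",
    "aa_fitness",
    "combine_replicates",
    "position_sensitivity",
    "classify_effect",
    "fold_change",
    "suppressor_intersection",
    "plot_heatmap",
    "AA_ORDER",
]

AA_ORDER = list(AMINO_ACIDS) + [STOP]

SEVERE = "severe"
MODERATE_NEUTRAL = "moderate/neutral"
GAIN = "gain"

LOW_INPUT = "low_input"
ABSENT_OUTPUT = "absent_output"


@dataclass
class FitnessTable:
    """Per-codon relative fitness (log10) with QC flags and provenance."""

    entries: dict[tuple[int, str], float]
    pseudocount: float
    sample: str = ""
    replicate: str = ""
    background: tuple[int, str] | None = None
    flags: dict[tuple[int, str], tuple[str, ...]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "codon": codon,
                "amino_acid": translate_codon(codon),
                "fitness": f,
                "flags": ",".join(self.flags.get((pos, codon), ())),
            }
            for (pos, codon), f in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def codon_fitness(
    input_table,
    output_table,
    pseudocount: float = 0.5,
    low_input_threshold: int = 50,
) -> FitnessTable:
    """Relative fitness of every variant from one input/output table pair.

    The pseudocount is added to the variant and wild-type counts in both
    samples. With pseudocount 0 a zero wild-type count is undefined and
    raises; a zero variant count then yields -inf (dropout) or NaN
    (absent from both samples).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if input_table.region != output_table.region:
        raise ValueError("input and output tables cover different regions")
    p = pseudocount
    n_in = input_table.accepted_total
    n_out = output_table.accepted_total
    if n_in == 0 or n_out == 0:
        raise ValueError("empty sample")
    wt_in = input_table.wt_count + p
    wt_out = output_table.wt_count + p
    if wt_in == 0 or wt_out == 0:
        raise ValueError("wild-type count is zero and pseudocount is 0; F undefined")
    wt_term = math.log10(wt_out / n_out) - math.log10(wt_in / n_in)
    universe = sorted(set(input_table.counts) | set(output_table.counts))
    entries: dict[tuple[int, str], float] = {}
    flags: dict[tuple[int, str], tuple[str, ...]] = {}
    for key in universe:
        c_in = input_table.counts.get(key, 0)
        c_out = output_table.counts.get(key, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = float(
                np.log10((c_out + p) / n_out) - np.log10((c_in + p) / n_in) - wt_term
            )
        entries[key] = f
        key_flags = []
        if c_in < low_input_threshold:
            key_flags.append(LOW_INPUT)
        if c_out == 0:
            key_flags.append(ABSENT_OUTPUT)
        if key_flags:
            flags[key] = tuple(key_flags)
    return FitnessTable(
        entries=entries,
        pseudocount=p,
        sample=output_table.sample,
        replicate=output_table.replicate,
        background=output_table.background,
        flags=flags,
    )


@dataclass
class AAFitnessMatrix:
    """Positions x (20 amino acids + stop) mean fitness over synonymous codons.

    The cell for the wild-type residue at each position is the mean over
    WT-synonymous codons other than the reference codon itself (0 when no
    such codon exists); per-cell codon multiplicities are recorded and sum
    to 32 per fully-covered NNS position.
    """

    values: pd.DataFrame
    multiplicity: pd.DataFrame
    wt_aa: pd.Series

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def to_long_frame(self) -> pd.DataFrame:
        long = self.values.stack().rename("fitness").reset_index()
        long.columns = ["position", "amino_acid", "fitness"]
        long["wt_aa"] = long["position"].map(self.wt_aa)
        return long


def aa_fitness(
    ft: FitnessTable,
    wt_codons: Mapping[int, str],
) -> AAFitnessMatrix:
    """Aggregate codon-level fitness to amino-acid level by unweighted mean.

    ``wt_codons`` maps each region position to its wild-type codon, which
    identifies the reference codon (excluded from the wild-type cell's
    mean) and the wild-type residue.
    """
    positions = sorted({pos for pos, _ in ft.entries})
    missing = [p for p in positions if p not in wt_codons]
    if missing:
        raise ValueError(f"no wild-type codon for positions {missing}")
    values = pd.DataFrame(np.nan, index=positions, columns=AA_ORDER)
    mult = pd.DataFrame(0, index=positions, columns=AA_ORDER, dtype=int)
    wt_aa = pd.Series({p: translate_codon(wt_codons[p]) for p in positions})
    acc: dict[tuple[int, str], list[float]] = {}
    for (pos, codon), f in ft.entries.items():
        aa = translate_codon(codon)
        mult.loc[pos, aa] += 1
        if aa == wt_aa[pos] and codon == wt_codons[pos]:
            continue  # reference codon: excluded from the wild-type cell mean
        acc.setdefault((pos, aa), []).append(f)
    for (pos, aa), vals in acc.items():
        finite = [v for v in vals if np.isfinite(v)]
        values.loc[pos, aa] = float(np.mean(finite)) if finite else np.nan
    for pos in positions:
        if pd.isna(values.loc[pos, wt_aa[pos]]) and mult.loc[pos, wt_aa[pos]] > 0:
            values.loc[pos, wt_aa[pos]] = 0.0  # only the reference codon exists
    return AAFitnessMatrix(values=values, multiplicity=mult, wt_aa=wt_aa)


def combine_replicates(
    tables: Sequence[FitnessTable],
) -> tuple[FitnessTable, pd.DataFrame]:
    """Per-variant mean across replicates plus all pairwise Pearson r.

    All tables must share the same variant universe. Correlations are
    computed over variants finite in both members of each pair.
    """
    if not tables:
        raise ValueError("no tables")
    universe = set(tables[0].entries)
    for t in tables[1:]:
        if set(t.entries) != universe:
            raise ValueError("replicate tables have mismatched variant universes")
    keys = sorted(universe)
    stack = np.array([[t.entries[k] for k in keys] for t in tables])
    mean_entries = {
        k: float(np.nanmean(stack[:, i])) for i, k in enumerate(keys)
    }
    flags: dict[tuple[int, str], tuple[str, ...]] = {}
    for t in tables:
        for k, fl in t.flags.items():
            flags[k] = tuple(sorted(set(flags.get(k, ())) | set(fl)))
    rows = []
    for a in range(len(tables)):
        for b in range(a + 1, len(tables)):
            x, y = stack[a], stack[b]
            ok = np.isfinite(x) & np.isfinite(y)
            r = float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() >= 2 else np.nan
            rows.append(
                {
                    "replicate_a": tables[a].replicate or str(a),
                    "replicate_b": tables[b].replicate or str(b),
                    "pearson_r": r,
                }
            )
    mean_table = FitnessTable(
        entries=mean_entries,
        pseudocount=tables[0].pseudocount,
        sample=tables[0].sample,
        replicate="mean",
        background=tables[0].background,
        flags=flags,
    )
    return mean_table, pd.DataFrame(rows, columns=["replicate_a", "replicate_b", "pearson_r"])


@dataclass
class SensitivityProfile:
    """Per-position mean mutational effect and a binary sensitive flag.

    The mean is taken over substitutions to the 19 non-wild-type amino
    acids (stop excluded unless requested); a position is sensitive when
    its mean effect is <= theta. Positions with no usable substitution are
    marked missing.
    """

    table: pd.DataFrame  # index: position; columns: mean_effect, sensitive, missing, n_severe, n_moderate, n_gain
    theta: float
    include_stop: bool

    @property
    def mean_effects(self) -> pd.Series:
        return self.table["mean_effect"]

    @property
    def sensitive_positions(self) -> list[int]:
        return list(self.table.index[self.table["sensitive"]])


def position_sensitivity(
    m: AAFitnessMatrix,
    theta: float = -1.6,
    include_stop: bool = False,
) -> SensitivityProfile:
    """Flag positions whose mean substitution effect is at or below theta."""
    rows = []
    for pos in m.values.index:
        cols = [a for a in AA_ORDER if a != m.wt_aa[pos]]
        if not include_stop:
            cols = [a for a in cols if a != STOP]
        vals = m.values.loc[pos, cols].astype(float)
        finite = vals[np.isfinite(vals)]
        missing = finite.empty
        mean = float(finite.mean()) if not missing else np.nan
        cats = [classify_effect(v) for v in finite]
        rows.append(
            {
                "position": pos,
                "mean_effect": mean,
                "sensitive": (not missing) and mean <= theta,
                "missing": missing,
                "n_severe": sum(c == SEVERE for c in cats),
                "n_moderate": sum(c == MODERATE_NEUTRAL for c in cats),
                "n_gain": sum(c == GAIN for c in cats),
            }
        )
    table = pd.DataFrame(rows).set_index("position")
    return SensitivityProfile(table=table, theta=theta, include_stop=include_stop)


def classify_effect(F: float) -> str:
    """Severe (F < -1), moderate/neutral (-1 <= F <= +1), or gain (F > +1)."""
    if not np.isfinite(F):
        raise ValueError("fitness must be finite")
    if F < -1.0:
        return SEVERE
    if F > 1.0:
        return GAIN
    return MODERATE_NEUTRAL


def fold_change(F: float) -> tuple[float, str]:
    """Propagation fold change 10**|F| and its direction."""
    if not np.isfinite(F):
        raise ValueError("fitness must be finite")
    fold = 10.0 ** abs(F)
    direction = "faster" if F > 0 else ("slower" if F < 0 else "neutral")
    return fold, direction


def suppressor_intersection(
    trial1: FitnessTable,
    trial2: FitnessTable,
    gain_threshold: float,
) -> pd.DataFrame:
    """Variants that confer gain of function in both independent trials.

    Requiring F >= gain_threshold in both trials removes hits caused by
    random mutations arising during either selection. Results are ranked
    by the weaker of the two scores.
    """
    if trial1.background != trial2.background:
        raise ValueError("trials have different backgrounds")
    shared = set(trial1.entries) & set(trial2.entries)
    rows = []
    for key in shared:
        f1, f2 = trial1.entries[key], trial2.entries[key]
        if np.isfinite(f1) and np.isfinite(f2) and f1 >= gain_threshold and f2 >= gain_threshold:
            rows.append(
                {
                    "position": key[0],
                    "codon": key[1],
                    "amino_acid": translate_codon(key[1]),
                    "fitness_trial1": f1,
                    "fitness_trial2": f2,
                    "min_fitness": min(f1, f2),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "position",
            "codon",
            "amino_acid",
            "fitness_trial1",
            "fitness_trial2",
            "min_fitness",
        ],
    )
    return df.sort_values("min_fitness", ascending=False).reset_index(drop=True)


def plot_heatmap(m: AAFitnessMatrix, path=None, vmax: float = 1.0):
    """Positions x amino-acids heatmap with wild-type cells outlined.

    Loss of function is blue, wild-type-like white, gain red, mirroring the
    conventional deep-mutational-scanning rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = m.values.T  # amino acids as rows
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(m.values)), 6))
    im = ax.imshow(
        data.to_numpy(dtype=float),
        cmap="RdBu_r",
        vmin=-2.5 * vmax,
        vmax=2.5 * vmax,
        aspect="auto",
    )
    ax.set_yticks(range(len(AA_ORDER)), AA_ORDER)
    ax.set_xticks(range(len(m.values.index)), m.values.index, rotation=90, fontsize=6)
    for x, pos in enumerate(m.values.index):
        y = AA_ORDER.index(m.wt_aa[pos])
        ax.add_patch(
            plt.Rectangle((x - 0.5, y - 0.5), 1, 1, fill=False, edgecolor="black", lw=1.2)
        )
    fig.colorbar(im, ax=ax, label="relative fitness (log10)")
    ax.set_xlabel("position")
    ax.set_ylabel("substitution")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
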