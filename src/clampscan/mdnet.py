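"""Correlation networks from residue-coordinate trajectories.

Post-processing of molecular-dynamics output into residue–residue
communication networks: rigid superposition of frames, per-residue
center-of-mass series, dynamic cross-correlation (normalized covariance of
3-D positional fluctuations), generalized correlation (a mutual-information
based dependence measure mapped to [0, 1]), contact-frequency gating, and
assembly of the final edge list.

The generalized correlation is r_MI = sqrt(1 - exp(-2 I / 3)), where I is
the mutual information between the two 3-D displacement vectors. For
isotropic Gaussian fluctuations with per-axis correlation rho this equals
|rho|, which makes it directly comparable to the linear coefficient while
also capturing non-linear and orthogonal coupling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import digamma

__all__ = [
    "TrajectoryEnsemble",
    "CorrelationMatrix",
    "NetworkParams",
    "SuperpositionResult",
    "kabsch_superpose",
    "align_frames",
    "com_series",
    "linear_correlation",
    "generalized_correlation",
    "contact_frequency",
    "assemble_network",
    "average_correlations",
    "stitch_correlations",
    "read_xyz_table",
    "write_xyz_table",
]

ResidueLabel = tuple[str, int]


@dataclass
class TrajectoryEnsemble:
    """Frames x residues x 3 coordinate ensemble, in Angstrom.

    ``coords`` holds one reference point per residue per frame (typically
    the residue center of mass). An optional atom layer carries per-atom
    coordinates, masses and a residue index so that centers of mass and
    heavy-atom contacts can be recomputed.
    """

    coords: np.ndarray
    labels: tuple[ResidueLabel, ...]
    atom_coords: np.ndarray | None = None
    atom_masses: np.ndarray | None = None
    atom_residue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels do not match the residue axis")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.atom_coords is not None:
            self.atom_coords = np.asarray(self.atom_coords, dtype=float)
            self.atom_masses = np.asarray(self.atom_masses, dtype=float)
            self.atom_residue = np.asarray(self.atom_residue, dtype=int)
            if self.atom_coords.shape[0] != self.n_frames:
                raise ValueError("atom layer frame count mismatch")
            if not (
                self.atom_coords.shape[1]
                == self.atom_masses.shape[0]
                == self.atom_residue.shape[0]
            ):
                raise ValueError("atom layer size mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric residues x residues correlation matrix.

    ``kind`` is "linear" (values in [-1, 1], diagonal exactly 1) or
    "generalized" (values in [0, 1], diagonal 1 by convention since the
    self mutual information diverges).
    """

    values: np.ndarray
    kind: str
    labels: tuple[ResidueLabel, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("linear", "generalized"):
            raise ValueError(f"unknown kind {self.kind!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.labels, names=["chain", "residue"])
        return pd.DataFrame(self.values, index=idx, columns=idx)


@dataclass(frozen=True)
class NetworkParams:
    """Edge-gating thresholds for the correlation network.

    A pair of residues is connected when it is in contact in at least
    ``contact_freq_min`` of the frames and its correlation exceeds the
    kind-appropriate threshold; sequence-adjacent pairs are excluded by
    default because their correlation is dominated by the covalent link.
    """

    contact_freq_min: float = 0.35
    corr_min_linear: float = 0.35
    corr_min_generalized: float = 0.5
    exclude_adjacent: bool = True

    def __post_init__(self) -> None:
        for name in ("contact_freq_min", "corr_min_linear", "corr_min_generalized"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    transformed: np.ndarray


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal rotation is obtained from the SVD of the cross-covariance
    of the selected points (with a determinant correction to exclude
    reflections); the RMSD is reported over the selection. The transform is
    applied to every point of ``mobile``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 points to superpose")
    a = mobile[sel]
    b = reference[sel]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(b0, tol=1e-9) < 2 or np.linalg.matrix_rank(a0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    transformed = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((transformed[sel] - b) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd, transformed)


def align_frames(
    coords: np.ndarray,
    selection: Sequence[int] | None = None,
    reference_frame: int = 0,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto a reference over ``selection``.

    The reference defaults to one of the trajectory's own frames; pass an
    explicit ``reference`` coordinate set to align several trajectories
    into one common frame.
    """
    coords = np.asarray(coords, dtype=float)
    ref = coords[reference_frame] if reference is None else np.asarray(reference, dtype=float)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        out[f] = kabsch_superpose(coords[f], ref, selection).transformed
    return out


def com_series(traj: TrajectoryEnsemble) -> np.ndarray:
    """Mass-weighted center of mass per residue per frame, (F, R, 3)."""
    if traj.atom_coords is None:
        raise ValueError("trajectory has no atom layer")
    out = np.empty((traj.n_frames, traj.n_residues, 3))
    for r in range(traj.n_residues):
        mask = traj.atom_residue == r
        w = traj.atom_masses[mask]
        if w.size == 0:
            raise ValueError(f"residue {traj.labels[r]} has no atoms")
        out[:, r] = (traj.atom_coords[:, mask] * w[None, :, None]).sum(axis=1) / w.sum()
    return out


def _coords_of(series: TrajectoryEnsemble | np.ndarray) -> tuple[np.ndarray, tuple]:
    if isinstance(series, TrajectoryEnsemble):
        return series.coords, series.labels
    arr = np.asarray(series, dtype=float)
    labels = tuple(("A", i + 1) for i in range(arr.shape[1]))
    return arr, labels


def linear_correlation(
    series: TrajectoryEnsemble | np.ndarray,
    align_selection: Sequence[int] | None = None,
) -> CorrelationMatrix:
    """Dynamic cross-correlation c_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>).

    ``dr`` is the deviation of each residue's 3-D position from its time
    mean. If ``align_selection`` is given the frames are first superposed
    onto frame 0 over those residues, removing rigid-body motion.
    """
    coords, labels = _coords_of(series)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if align_selection is not None:
        coords = align_frames(coords, align_selection)
    d = coords - coords.mean(axis=0)
    cov = np.einsum("fia,fja->ij", d, d) / coords.shape[0]
    var = np.diag(cov)
    if np.any(var <= 0):
        bad = labels[int(np.argmin(var))]
        raise ValueError(f"zero-variance residue {bad}")
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, "linear", labels)


def _ksg_mutual_information(x: np.ndarray, y: np.ndarray, k: int) -> float:
    # Kraskov-Stoegbauer-Grassberger estimator (algorithm 1), max-norm.
    n = x.shape[0]
    z = np.hstack([x, y])
    dist, _ = cKDTree(z).query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # Count strictly within eps in each marginal space; shrink radius to
    # exclude boundary points (ties are measure-zero for continuous data).
    r = eps * (1.0 - 1e-10)
    nx = cKDTree(x).query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny = cKDTree(y).query_ball_point(y, r, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(max(mi, 0.0))


def generalized_correlation(
    series: TrajectoryEnsemble | np.ndarray,
    k_neighbors: int = 6,
    align_selection: Sequence[int] | None = None,
    null_shuffles: int = 3,
    seed: int = 0,
) -> CorrelationMatrix:
    """Generalized correlation r_MI from k-NN mutual information.

    For each residue pair the mutual information I between the two 3-D
    displacement vectors is estimated with the Kraskov k-nearest-neighbor
    estimator and mapped to r_MI = sqrt(1 - exp(-2 I / 3)), clamped to
    [0, 1]. The diagonal is set to 1 by convention.

    The finite-sample null of the estimator is not exactly zero and the
    sqrt map amplifies small positive fluctuations, so by default the mean
    MI of ``null_shuffles`` frame-permuted surrogates (which destroy any
    cross-residue dependence) is subtracted before mapping; set
    ``null_shuffles=0`` for the raw estimate.
    """
    coords, labels = _coords_of(series)
    n_frames, n_res = coords.shape[0], coords.shape[1]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n_frames:
        raise ValueError("k_neighbors must be smaller than the number of frames")
    if align_selection is not None:
        coords = align_frames(coords, align_selection)
    d = coords - coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_frames) for _ in range(null_shuffles)]
    out = np.eye(n_res)
    for i in range(n_res):
        for j in range(i + 1, n_res):
            mi = _ksg_mutual_information(d[:, i], d[:, j], k_neighbors)
            if perms:
                null = np.mean(
                    [_ksg_mutual_information(d[:, i], d[perm, j], k_neighbors) for perm in perms]
                )
                mi = max(0.0, mi - null)
            r = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * mi / 3.0)))
            out[i, j] = out[j, i] = min(r, 1.0)
    return CorrelationMatrix(out, "generalized", labels)


def contact_frequency(
    traj: TrajectoryEnsemble,
    cutoff: float | None = None,
    scheme: str = "residue",
) -> np.ndarray:
    """Fraction of frames in which each residue pair is in contact.

    ``scheme`` "residue" uses the residue reference-point distance
    (default cutoff 6.5 A); "atom" uses the minimum heavy-atom distance
    from the atom layer (default cutoff 4.5 A).
    """
    if scheme == "residue":
        cut = 6.5 if cutoff is None else cutoff
        diff = traj.coords[:, :, None, :] - traj.coords[:, None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        freq = (dist <= cut).mean(axis=0)
    elif scheme == "atom":
        if traj.atom_coords is None:
            raise ValueError("atom scheme requires an atom layer")
        cut = 4.5 if cutoff is None else cutoff
        n = traj.n_residues
        hits = np.zeros((n, n))
        for f in range(traj.n_frames):
            d = cdist(traj.atom_coords[f], traj.atom_coords[f])
            close = d <= cut
            frame_contact = np.zeros((n, n), dtype=bool)
            for r in range(n):
                mask = traj.atom_residue == r
                sub = close[mask]
                for s in range(n):
                    frame_contact[r, s] = bool(sub[:, traj.atom_residue == s].any())
            hits += frame_contact
        freq = hits / traj.n_frames
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    np.fill_diagonal(freq, 1.0)
    return freq


def assemble_network(
    corr: CorrelationMatrix,
    freq: np.ndarray,
    params: NetworkParams = NetworkParams(),
) -> pd.DataFrame:
    """Gate correlations by contact frequency into the final edge list.

    An edge (i, j) is emitted when freq[i, j] >= contact_freq_min and the
    correlation strictly exceeds the threshold for the matrix kind
    (|c| > 0.35 for linear, r_MI > 0.5 for generalized by default), and the
    residues are not sequence-adjacent (same chain, residue numbers
    differing by 1) when exclude_adjacent is set.
    """
    freq = np.asarray(freq, dtype=float)
    n = len(corr.labels)
    if freq.shape != (n, n):
        raise ValueError("frequency matrix does not match correlation roster")
    thr = params.corr_min_linear if corr.kind == "linear" else params.corr_min_generalized
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = corr.labels[i], corr.labels[j]
            if params.exclude_adjacent and ci[0] == cj[0] and abs(ci[1] - cj[1]) == 1:
                continue
            strength = abs(corr.values[i, j]) if corr.kind == "linear" else corr.values[i, j]
            if freq[i, j] >= params.contact_freq_min and strength > thr:
                rows.append(
                    {
                        "chain_i": ci[0],
                        "residue_i": ci[1],
                        "chain_j": cj[0],
                        "residue_j": cj[1],
                        "correlation": corr.values[i, j],
                        "frequency": freq[i, j],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chain_i", "residue_i", "chain_j", "residue_j", "correlation", "frequency"],
    )


def average_correlations(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean of per-trajectory correlation matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.kind != first.kind or m.labels != first.labels:
            raise ValueError("matrices differ in kind or roster")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(mean, first.kind, first.labels)


def stitch_correlations(
    within: Sequence[CorrelationMatrix],
    between: Sequence[CorrelationMatrix],
) -> CorrelationMatrix:
    """Merge per-block and cross-block matrices into one roster.

    Within-block matrices (computed with each block's own alignment) supply
    the diagonal blocks; cross-block matrices, computed after aligning the
    pair of blocks together, supply only the entries that span two blocks.
    """
    if not within:
        raise ValueError("need at least one within-block matrix")
    kind = within[0].kind
    labels: list[ResidueLabel] = []
    for m in within:
        if m.kind != kind:
            raise ValueError("mixed correlation kinds")
        for lab in m.labels:
            if lab in labels:
                raise ValueError(f"duplicate residue {lab} across blocks")
            labels.append(lab)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.full((n, n), np.nan)
    block_of = {}
    for b, m in enumerate(within):
        for lab in m.labels:
            block_of[lab] = b
    for m in between:
        if m.kind != kind:
            raise ValueError("mixed correlation kinds")
        for i, li in enumerate(m.labels):
            for j, lj in enumerate(m.labels):
                if li in idx and lj in idx and block_of[li] != block_of[lj]:
                    out[idx[li], idx[lj]] = m.values[i, j]
    for m in within:
        sub = [idx[lab] for lab in m.labels]
        out[np.ix_(sub, sub)] = m.values
    np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(out, kind, tuple(labels))


# --- plain-text trajectory interchange -------------------------------------

_XYZ_COLUMNS = ["frame", "chain", "residue", "x", "y", "z"]


def write_xyz_table(traj: TrajectoryEnsemble, path) -> None:
    """Write residue reference coordinates as a TSV (frame, chain, residue, x, y, z)."""
    rows = []
    for f in range(traj.n_frames):
        for r, (chain, num) in enumerate(traj.labels):
            x, y, z = traj.coords[f, r]
            rows.append((f, chain, num, x, y, z))
    pd.DataFrame(rows, columns=_XYZ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_xyz_table(path) -> TrajectoryEnsemble:
    """Read a plain-text trajectory table written by :func:`write_xyz_table`.

    An optional ``atom``/``mass`` pair of columns turns rows into an atom
    layer; residue reference points are then centers of mass.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    missing = set(_XYZ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    labels = tuple(
        sorted(
            {(str(c), int(r)) for c, r in zip(df["chain"], df["residue"])},
            key=lambda t: (t[0], t[1]),
        )
    )
    frames = sorted(df["frame"].unique())
    has_atoms = "atom" in df.columns and "mass" in df.columns
    if not has_atoms:
        coords = np.empty((len(frames), len(labels), 3))
        lab_idx = {lab: i for i, lab in enumerate(labels)}
        for k, f in enumerate(frames):
            sub = df[df["frame"] == f]
            for _, row in sub.iterrows():
                coords[k, lab_idx[(str(row["chain"]), int(row["residue"]))]] = (
                    row["x"],
                    row["y"],
                    row["z"],
                )
        return TrajectoryEnsemble(coords, labels)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    first = df[df["frame"] == frames[0]].reset_index(drop=True)
    atom_residue = np.array(
        [lab_idx[(str(c), int(r))] for c, r in zip(first["chain"], first["residue"])]
    )
    atom_masses = first["mass"].to_numpy(dtype=float)
    atom_coords = np.empty((len(frames), len(first), 3))
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != len(first):
            raise ValueError("atom roster varies across frames")
        atom_coords[k] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    traj = TrajectoryEnsemble(
        np.zeros((len(frames), len(labels), 3)),
        labels,
        atom_coords=atom_coords,
        atom_masses=atom_masses,
        atom_residue=atom_residue,
    )
    traj.coords = com_series(traj)
    return traj
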