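"""Structural-stability metrics: superposition, RMSD, RMSF, PCA, helix bends.

All metrics operate on heavy-atom selections of a :class:`MolecularSystem`.
RMSD series superpose every frame onto a reference (default: the first
analysed frame) with a least-squares Kabsch fit; RMSF profiles superpose onto
the window-average structure (two iterative passes) and measure per-atom
fluctuation about it; PCA eigendecomposes the 3N x 3N coordinate covariance
after the same superposition.  Helix flexibility uses a local-axis bend-angle
profile: the Calpha trace is smoothed with a sliding-window centroid, local
axes are fitted to short stretches of the smoothed trace, and the bend angle
at a position is the angle between the flanking axes.  Angles are binned with
the conventional colour edges 6/12/18/24 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import AnalysisParameters, MolecularSystem

BEND_BIN_LABELS = ("blue", "cyan", "green", "yellow", "red")


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of one point set onto another."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares optimal rotation + translation mapping P onto Q.

    Reflections are corrected so the rotation is always proper.  Degenerate
    input (< 3 points, or all points collinear) raises.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both have shape (n_points, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check on the source cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is degenerate")
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P0 @ R.T
    rmsd = float(np.sqrt((w[:, None] * (moved - Q0) ** 2).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsd_series(
    system: MolecularSystem,
    selection: np.ndarray,
    reference_frame: int = 0,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) on ``selection`` after superposing onto the reference."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    X = system.coords[:, selection, :]
    ref = X[reference_frame]
    out = np.empty(system.n_frames)
    for f in range(system.n_frames):
        if superpose:
            out[f] = kabsch_superpose(X[f], ref).rmsd
        else:
            out[f] = _rmsd(X[f], ref)
    return out


def _superpose_stack(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(X)
    for f in range(X.shape[0]):
        sup = kabsch_superpose(X[f], ref)
        out[f] = sup.apply(X[f])
    return out


def _window_frames(system: MolecularSystem, window) -> np.ndarray:
    if window is None:
        return np.arange(system.n_frames)
    t0, t1 = window
    frames = np.flatnonzero((system.times >= t0) & (system.times <= t1))
    if len(frames) == 0:
        raise ValueError(f"no frames in window [{t0}, {t1}] ns")
    return frames


def rmsf_profile(
    system: MolecularSystem,
    selection: np.ndarray,
    window: tuple | None = None,
    superpose: bool = True,
    passes: int = 2,
) -> np.ndarray:
    """Per-atom RMSF (A) about the window-average structure.

    Frames in the window are superposed onto their average (``passes``
    iterative refinements, default 2) and RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    ``window`` is (t0_ns, t1_ns); fewer than 2 frames raises.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    frames = _window_frames(system, window)
    if len(frames) < 2:
        raise ValueError("RMSF window must contain at least 2 frames")
    X = system.coords[frames][:, selection, :].astype(float)
    if superpose:
        ref = X[0]
        for _ in range(passes):
            X = _superpose_stack(X, ref)
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    return np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))


@dataclass
class PCAResult:
    """Eigendecomposition of the superposed-coordinate covariance."""

    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # (3N, n_modes), columns
    projections: np.ndarray  # (n_frames, n_modes)
    mean: np.ndarray  # (3N,)


def pca_modes(
    system: MolecularSystem,
    selection: np.ndarray,
    window: tuple | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Principal component analysis of the coordinate covariance.

    Frames are superposed onto the window-average structure on ``selection``
    first; the 3N x 3N covariance is then eigendecomposed with eigenvalues in
    descending order.  Requesting more components than frames truncates with a
    warning.
    """
    import warnings as _warnings

    frames = _window_frames(system, window)
    if len(frames) < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = system.coords[frames][:, selection, :].astype(float)
    ref = X[0]
    for _ in range(2):
        X = _superpose_stack(X, ref)
        ref = X.mean(axis=0)
    flat = X.reshape(len(frames), -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (len(frames) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n_components is not None:
        if n_components > len(frames):
            _warnings.warn(
                f"requested {n_components} components with {len(frames)} frames; truncating"
            )
            n_components = len(frames)
        vals, vecs = vals[:n_components], vecs[:, :n_components]
    return PCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        projections=centered @ vecs,
        mean=mean,
    )


# ---------------------------------------------------------------------------
# helix bend profiles


def bend_bin_label(angle: float, edges=(6.0, 12.0, 18.0, 24.0)) -> str:
    """Colour-bin label for a bend angle (degrees): <6 blue ... >24 red."""
    return BEND_BIN_LABELS[int(np.digitize(angle, edges))]


@dataclass
class BendProfile:
    """Per-frame per-position helix bend angles with colour-bin labels.

    ``angles`` holds the instantaneous bend angle (degrees) at each profile
    position; ``delta_from_first`` the change relative to the first frame
    (both are reported because either reading of "angle changes along the
    helix" can be wanted).  ``positions`` are the residue numbers at the
    centre of each axis split.
    """

    angles: np.ndarray  # (n_frames, n_positions), degrees
    positions: np.ndarray  # (n_positions,) residue numbers
    labels: np.ndarray  # (n_frames, n_positions) colour bins of `angles`
    delta_from_first: np.ndarray
    bin_edges: tuple

    def max_angle(self) -> float:
        return float(self.angles.max())


def _local_axes(ca: np.ndarray, smoothing: int, axis_window: int):
    """Smoothed-centroid trace and PCA-fitted local axes of one Calpha trace."""
    n = len(ca)
    nc = n - smoothing + 1
    cumsum = np.cumsum(np.vstack([np.zeros(3), ca]), axis=0)
    centroids = (cumsum[smoothing:] - cumsum[:-smoothing]) / smoothing

    def axis(pts: np.ndarray) -> np.ndarray:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        v = vt[0]
        if v @ (pts[-1] - pts[0]) < 0:
            v = -v
        return v

    return centroids, axis, nc


def helix_bend_angles(
    ca: np.ndarray,
    smoothing: int = 7,
    axis_window: int = 4,
    gap: int = 7,
):
    """Bend angles (degrees) along a single Calpha trace.

    The trace is smoothed with a ``smoothing``-residue sliding centroid (two
    helical turns by default, which cancels the helical wobble of the Calpha
    spiral); a local axis is the principal direction of ``axis_window``
    consecutive centroids; the bend angle at split position p is the angle
    between the axes fitted just before p and just after p + gap.  The ``gap``
    skips centroids whose smoothing window straddles the split, so a sharp
    kink is recovered at its full inter-axis angle.

    Returns ``(split_positions, angles)`` where positions are 0-based Calpha
    indices at the centre of each split.
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    min_n = smoothing - 1 + 2 * axis_window + gap
    if n < min_n:
        raise ValueError(
            f"helix too short for bend profile: {n} residues, need >= {min_n} "
            f"(smoothing {smoothing}, axis window {axis_window}, gap {gap})"
        )
    centroids, axis, nc = _local_axes(ca, smoothing, axis_window)
    angles = []
    positions = []
    for p in range(axis_window - 1, nc - gap - axis_window):
        left = axis(centroids[p - axis_window + 1 : p + 1])
        right = axis(centroids[p + gap + 1 : p + gap + 1 + axis_window])
        cosv = float(np.clip(left @ right, -1.0, 1.0))
        angles.append(np.degrees(np.arccos(cosv)))
        # centre of the split, expressed as a Calpha index
        positions.append(p + (gap + smoothing) / 2.0)
    return np.array(positions), np.array(angles)


def bend_profile(
    system: MolecularSystem,
    helix_resids: tuple,
    smoothing: int = 7,
    axis_window: int = 4,
    gap: int = 7,
    bin_edges: tuple = (6.0, 12.0, 18.0, 24.0),
) -> BendProfile:
    """Bend-angle profile of one helix over every trajectory frame.

    ``helix_resids`` is the (first, last) residue number of the helix; Calpha
    atoms are used.  See :func:`helix_bend_angles` for the geometry.
    """
    from .system import select_atoms

    sel = select_atoms(
        system, resid_range=helix_resids, names=("CA",), molecule_class="protein"
    )
    order = np.argsort(system.resids[sel], kind="stable")
    sel = sel[order]
    resids = system.resids[sel]
    all_angles = []
    positions = None
    for f in range(system.n_frames):
        pos, ang = helix_bend_angles(
            system.coords[f, sel], smoothing=smoothing, axis_window=axis_window, gap=gap
        )
        all_angles.append(ang)
        if positions is None:
            positions = resids[0] + pos
    angles = np.array(all_angles)
    labels = np.vectorize(lambda a: bend_bin_label(a, bin_edges))(angles)
    return BendProfile(
        angles=angles,
        positions=np.asarray(positions),
        labels=labels,
        delta_from_first=angles - angles[0],
        bin_edges=tuple(bin_edges),
    )
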