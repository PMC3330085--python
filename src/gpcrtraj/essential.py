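"""Essential dynamics: Cα covariance analysis of (concatenated) trajectories.

The covariance matrix of atomic fluctuations, C_ij = <(x_i - <x_i>)(x_j - <x_j>)>
over superposed frames, is diagonalized; the leading eigenvectors describe the
directions of correlated positional change and the eigenvalues the mean-square
fluctuation along them.  Combined essential dynamics (Comb-ED) runs the same
analysis on two or more concatenated trajectories fitted to one reference, so the
leading eigenvectors expose the structural differences between the sources rather
than the internal motions of either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import GeometryError, IntegrityError, ParameterError
from .fitting import apply_fit, kabsch
from .model import Frame, Selection, Trajectory, select

__all__ = [
    "EDResult",
    "ProjectionSet",
    "superpose",
    "fit_trajectory",
    "covariance",
    "decompose",
    "comb_ed",
    "project",
    "extreme_projections",
]


@dataclass(frozen=True)
class EDResult:
    """Eigen-decomposition of a Cα covariance matrix.

    ``mean_coords`` is the 3N mean vector (Å), eigenvalues are descending (Å²),
    eigenvectors orthonormal rows of shape (3N, 3N) columns; ``reference`` is the
    frame the inputs were fitted to and ``selection`` the atom subset analysed.
    """

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column k = eigenvector k
    reference: Frame | None = None
    selection: Selection | None = None

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.size // 3


@dataclass(frozen=True)
class ProjectionSet:
    """Per-source projections of concatenated frames on the leading eigenvectors."""

    labels: tuple[str, ...]
    projections: dict  # label -> (n_frames, n_vectors) array, Å
    centers: dict      # label -> (n_vectors,) mean projection


def superpose(frame: Frame, reference: Frame, selection: Selection) -> Frame:
    """Least-squares (Kabsch) fit of ``frame`` onto ``reference`` over a selection.

    The rotation is proper (det = +1); the whole frame is transformed.
    """
    if len(selection) < 3:
        raise GeometryError("superposition selection needs >=3 atoms")
    rot, trans = kabsch(frame.coords[selection.indices], reference.coords[selection.indices])
    return Frame(frame.table, apply_fit(frame.coords, rot, trans), time=frame.time, box=frame.box)


def fit_trajectory(traj: Trajectory, reference: Frame, selection: Selection) -> Trajectory:
    """Superpose every frame of a trajectory onto a reference over a selection."""
    out = np.empty_like(traj.coords)
    ref = reference.coords[selection.indices]
    for k in range(traj.n_frames):
        rot, trans = kabsch(traj.coords[k, selection.indices], ref)
        out[k] = apply_fit(traj.coords[k], rot, trans)
    return Trajectory(traj.table, out, times=traj.times, stride=traj.stride)


def covariance(traj: Trajectory, selection: Selection, reference: Frame | None = None) -> np.ndarray:
    """3N x 3N covariance matrix of atomic fluctuations over a selection.

    Frames must already be superposed on a common reference (use
    :func:`fit_trajectory`); passing ``reference`` performs the fit here.
    Mass-unweighted.
    """
    if traj.n_frames < 2:
        raise ParameterError("covariance needs at least 2 frames")
    if reference is not None:
        traj = fit_trajectory(traj, reference, selection)
    x = traj.coords[:, selection.indices].reshape(traj.n_frames, -1)
    centered = x - x.mean(axis=0)
    return centered.T @ centered / traj.n_frames


def decompose(
    cov: np.ndarray,
    mean_coords: np.ndarray | None = None,
    reference: Frame | None = None,
    selection: Selection | None = None,
) -> EDResult:
    """Eigenpairs of a symmetric covariance matrix, descending, with fixed signs.

    The sign of each eigenvector is chosen so its largest-magnitude component is
    positive, making projections reproducible run-to-run.
    """
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T, atol=1e-8):
        raise ParameterError("covariance matrix must be square and symmetric")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        imax = np.argmax(np.abs(evecs[:, k]))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    if mean_coords is None:
        mean_coords = np.zeros(cov.shape[0])
    return EDResult(
        mean_coords=np.asarray(mean_coords, float),
        eigenvalues=evals,
        eigenvectors=evecs,
        reference=reference,
        selection=selection,
    )


def project(ed: EDResult, coords: np.ndarray, n_vectors: int | None = None) -> np.ndarray:
    """Project frames (n_frames, n_atoms, 3) onto the eigenbasis (centered on the mean)."""
    flat = np.asarray(coords, float).reshape(len(coords), -1)
    centered = flat - ed.mean_coords
    vecs = ed.eigenvectors if n_vectors is None else ed.eigenvectors[:, :n_vectors]
    return centered @ vecs


def comb_ed(
    trajectories: Sequence[Trajectory],
    selection_spec: str = "name CA",
    labels: Sequence[str] | None = None,
    window: int | None = None,
    reference: Frame | None = None,
    n_vectors: int | None = None,
) -> tuple[EDResult, ProjectionSet]:
    """Combined essential dynamics over concatenated trajectories.

    The last ``window`` frames of each source (all frames if None) are
    concatenated, fitted to a common reference (default: the average structure of
    the concatenation, obtained by one fit-to-first-frame / refit-to-mean pass),
    and the covariance of the selected atoms is diagonalized.  Projections on the
    first ``n_vectors`` eigenvectors are reported per source together with each
    source's cloud center.
    """
    if len(trajectories) < 2:
        raise ParameterError("comb_ed needs at least two trajectories")
    if labels is None:
        labels = tuple(f"traj{i + 1}" for i in range(len(trajectories)))
    sels = [select(t, selection_spec) for t in trajectories]
    n_sel = len(sels[0])
    for t, s in zip(trajectories[1:], sels[1:]):
        if len(s) != n_sel:
            raise IntegrityError("selection resolves to different atom counts across trajectories")

    blocks = [t.window(window).coords[:, s.indices] for t, s in zip(trajectories, sels)]
    sizes = [b.shape[0] for b in blocks]
    cat = np.concatenate(blocks, axis=0)

    table = trajectories[0].table.subset(sels[0].indices)
    if reference is None:
        # fit everything to the first frame, then once more to the resulting mean
        ref_coords = cat[0]
        for _ in range(2):
            fitted = np.empty_like(cat)
            for k in range(cat.shape[0]):
                rot, trans = kabsch(cat[k], ref_coords)
                fitted[k] = apply_fit(cat[k], rot, trans)
            ref_coords = fitted.mean(axis=0)
        cat = fitted
        reference = Frame(table, ref_coords)
    else:
        ref_coords = reference.coords
        fitted = np.empty_like(cat)
        for k in range(cat.shape[0]):
            rot, trans = kabsch(cat[k], ref_coords)
            fitted[k] = apply_fit(cat[k], rot, trans)
        cat = fitted

    flat = cat.reshape(cat.shape[0], -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / flat.shape[0]
    sel_all = Selection(spec=selection_spec, indices=np.arange(n_sel))
    ed = decompose(cov, mean_coords=mean, reference=reference, selection=sel_all)

    projections: dict[str, np.ndarray] = {}
    centers: dict[str, np.ndarray] = {}
    start = 0
    for label, size in zip(labels, sizes):
        proj = project(ed, cat[start : start + size], n_vectors=n_vectors)
        projections[str(label)] = proj
        centers[str(label)] = proj.mean(axis=0)
        start += size
    return ed, ProjectionSet(labels=tuple(map(str, labels)), projections=projections, centers=centers)


def extreme_projections(
    ed: EDResult,
    projections: ProjectionSet,
    k: int = 0,
) -> tuple[Frame, Frame, np.ndarray]:
    """Extreme structures along eigenvector ``k`` and per-atom displacement magnitudes.

    Returns the mean structure displaced to the minimum and maximum observed
    projection on eigenvector ``k``, plus |Δ| per selected atom between the two
    extremes (the quantity used to colour structures by conformational change).
    """
    if k >= ed.eigenvectors.shape[1]:
        raise ParameterError(f"eigenvector index {k} out of range")
    all_proj = np.concatenate([p[:, k] for p in projections.projections.values()])
    pmin, pmax = float(all_proj.min()), float(all_proj.max())
    vec = ed.eigenvectors[:, k]
    lo = (ed.mean_coords + pmin * vec).reshape(-1, 3)
    hi = (ed.mean_coords + pmax * vec).reshape(-1, 3)
    table = ed.reference.table if ed.reference is not None else None
    if table is None:
        raise ParameterError("EDResult has no reference frame to build structures from")
    displacement = np.linalg.norm(hi - lo, axis=1)
    return Frame(table, lo), Frame(table, hi), displacement
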