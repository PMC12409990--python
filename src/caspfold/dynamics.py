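"""Essential dynamics: superposition, coordinate PCA, free-energy landscapes.

Frames are least-squares superposed (Kabsch) onto a reference, the covariance
of the mean-centered coordinates is eigendecomposed, and the trajectory is
projected onto the leading principal components.  The 2D free-energy
landscape over (PC1, PC2) is G = -RT ln(P/Pmax) on a histogram grid with
empty bins masked; occupied local minima are the metastable basins and each
basin's representative frame is the one projecting nearest its minimum bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.ma as ma

from .ensemble import ConformationalEnsemble
from .thermo import R_KCAL

DEFAULT_TEMPERATURE = 298.15


def selection_mask(ensemble: ConformationalEnsemble, selection: str = "CA") -> np.ndarray:
    """Boolean atom mask for the selection strings 'CA', 'heavy' or 'all'."""
    atoms = ensemble.atoms
    if selection == "CA":
        return (atoms["atom_name"] == "CA").to_numpy()
    if selection == "heavy":
        return (atoms["element"] != "H").to_numpy()
    if selection == "all":
        return np.ones(len(atoms), dtype=bool)
    raise ValueError(f"unknown selection {selection!r}")


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation of `mobile` onto `reference` (both centered sets).

    Returns (rotation, mobile_centroid, reference_centroid).
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, rc


def superpose(
    ensemble: ConformationalEnsemble,
    reference: int = 0,
    selection: str = "CA",
) -> tuple[ConformationalEnsemble, np.ndarray]:
    """Kabsch-superpose every frame onto the reference frame.

    The optimal rotation is computed over the selection and applied to all
    atoms; returns the superposed ensemble and the per-frame RMSD over the
    selection.
    """
    mask = selection_mask(ensemble, selection)
    if mask.sum() < 3:
        raise ValueError("selection must contain at least 3 atoms")
    ref_sel = ensemble.coords[reference][mask]
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")

    out = np.empty_like(ensemble.coords)
    rmsd = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        rot, mc, rc = _kabsch(ensemble.coords[f][mask], ref_sel)
        out[f] = (ensemble.coords[f] - mc) @ rot.T + rc
        diff = out[f][mask] - ref_sel
        rmsd[f] = np.sqrt((diff**2).sum() / mask.sum())
    return ensemble.with_coords(out), rmsd


@dataclass
class PCAResult:
    """Eigendecomposition of the coordinate covariance matrix.

    ``eigenvectors`` has shape (n_modes, 3*n_selected) with rows orthonormal;
    eigenvalues are in A^2, sorted descending, and sum to the covariance
    trace.  Eigenvector signs are fixed by making each mode's
    largest-magnitude component positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean: np.ndarray
    selection: str

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def pca(
    ensemble: ConformationalEnsemble,
    selection: str = "heavy",
    mass_weighted: bool = False,
) -> PCAResult:
    """PCA of the mean-centered selected coordinates.

    Uses the thin SVD of the centered frame matrix, equivalent to
    eigendecomposing the (3N x 3N) covariance with denominator n_frames - 1.
    With ``mass_weighted=True`` coordinates are scaled by sqrt(atomic mass)
    first (the GROMACS covariance default).
    """
    if ensemble.n_frames < 4:
        raise ValueError("PCA needs more than 3 frames")
    mask = selection_mask(ensemble, selection)
    x = ensemble.coords[:, mask, :].reshape(ensemble.n_frames, -1).copy()
    if mass_weighted:
        masses = ensemble.atoms.loc[mask, "element"].map(_ATOMIC_MASS).fillna(12.0).to_numpy()
        x *= np.sqrt(np.repeat(masses, 3))[None, :]
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (ensemble.n_frames - 1)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    vecs = vt[order]
    # deterministic sign: largest-magnitude component positive
    for i in range(len(vecs)):
        j = np.argmax(np.abs(vecs[i]))
        if vecs[i, j] < 0:
            vecs[i] = -vecs[i]
    return PCAResult(eigvals, vecs, mean, selection)


def project(
    ensemble: ConformationalEnsemble, result: PCAResult, k: int = 2
) -> np.ndarray:
    """Per-frame projections onto the first k principal components."""
    if k > result.n_modes:
        raise ValueError(f"requested {k} components but PCA has {result.n_modes}")
    mask = selection_mask(ensemble, result.selection)
    x = ensemble.coords[:, mask, :].reshape(ensemble.n_frames, -1)
    if x.shape[1] != result.mean.shape[0]:
        raise ValueError("ensemble selection does not match the PCA result")
    return (x - result.mean) @ result.eigenvectors[:k].T


@dataclass
class Basin:
    """A metastable state: an occupied local minimum of the landscape."""

    bin_index: tuple[int, int]
    center: tuple[float, float]
    g_min: float
    representative_frame: int | None = None


@dataclass
class FreeEnergyLandscape:
    """G = -RT ln(P/Pmax) over a 2D histogram of (PC1, PC2) projections."""

    counts: np.ndarray
    g: ma.MaskedArray
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float
    basins: list[Basin] | None = None

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def bin_area(self) -> float:
        return float(np.diff(self.x_edges).mean() * np.diff(self.y_edges).mean())

    def bin_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            float(0.5 * (self.x_edges[i] + self.x_edges[i + 1])),
            float(0.5 * (self.y_edges[j] + self.y_edges[j + 1])),
        )


def build_fel(
    projections: np.ndarray,
    bins: int = 32,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FreeEnergyLandscape:
    """Histogram (PC1, PC2) projections and convert populations to free energy.

    The most populated bin defines G = 0; empty bins are masked rather than
    assigned the maximum energy.
    """
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2 or p.shape[0] < 1:
        raise ValueError("projections must be (n_frames, >=2)")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    counts, x_edges, y_edges = np.histogram2d(p[:, 0], p[:, 1], bins=bins)
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        g = -rt * np.log(counts / counts.max())
    return FreeEnergyLandscape(
        counts=counts,
        g=ma.masked_array(g, mask=counts == 0),
        x_edges=x_edges,
        y_edges=y_edges,
        temperature=temperature,
    )


def find_basins(
    fel: FreeEnergyLandscape,
    min_separation: int = 2,
    min_prominence: float | None = None,
) -> list[Basin]:
    """Metastable basins: persistent local minima of G on the 8-neighborhood grid.

    Empty bins are treated as passable at the energy of the highest occupied
    bin, and minima are merged by topographic persistence:
    sweeping the energy level upward, a minimum whose component joins a
    deeper one at a saddle less than ``min_prominence`` above its own depth
    is absorbed (union-find over bins sorted by G).  This removes the
    spurious minima that sparsely sampled outskirt bins would otherwise
    produce.  Surviving minima closer than ``min_separation`` bins
    (Euclidean) are additionally merged keeping the deeper one; exact ties
    break toward the lowest (row, col) index.  Basins return ordered by
    depth (lowest G first).

    ``min_prominence`` defaults to 2RT (1.19 kcal/mol at 298.15 K): a basin
    must be at least e^2 ~ 7.4-fold more populated than the saddle joining it
    to a deeper basin, which keeps single-bin sampling artifacts (an isolated
    bin of count c has persistence RT ln c) from being reported as states.
    """
    g = fel.g
    if g.mask.all():
        raise ValueError("landscape is fully masked")
    if min_prominence is None:
        min_prominence = 2.0 * fel.rt
    # strictly above the occupied maximum so occupied bins always win ties
    ceiling = float(g.max()) + 1e-9
    filled = g.filled(ceiling)
    nx_, ny_ = filled.shape

    # union-find with component minimum tracked at the root
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    comp_min: dict[tuple[int, int], tuple[float, int, int]] = {}

    def find(cell):
        root = cell
        while parent[root] != root:
            root = parent[root]
        while parent[cell] != root:
            parent[cell], cell = root, parent[cell]
        return root

    # sweep bins by increasing energy (ties by index for determinism)
    order = sorted(
        ((filled[i, j], i, j) for i in range(nx_) for j in range(ny_))
    )
    survivors: set[tuple[int, int]] = set()
    for val, i, j in order:
        cell = (i, j)
        parent[cell] = cell
        comp_min[cell] = (val, i, j)
        neighbor_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = (i + di, j + dj)
                if nb in parent:
                    neighbor_roots.add(find(nb))
        if not neighbor_roots:
            survivors.add(cell)  # a fresh local minimum
            continue
        # attach to the deepest neighboring component; absorb the others
        roots = sorted(neighbor_roots, key=lambda r: comp_min[r])
        deepest = roots[0]
        parent[cell] = deepest
        for r in roots[1:]:
            r_min_val, ri, rj = comp_min[r]
            if (ri, rj) in survivors and val - r_min_val < min_prominence:
                survivors.discard((ri, rj))
            parent[r] = deepest

    minima = sorted(
        (float(g[i, j]), i, j) for (i, j) in survivors if not g.mask[i, j]
    )
    kept: list[tuple[float, int, int]] = []
    for val, i, j in minima:
        if all(np.hypot(i - ki, j - kj) >= min_separation for _, ki, kj in kept):
            kept.append((val, i, j))
    basins = [
        Basin(bin_index=(i, j), center=fel.bin_center(i, j), g_min=abs(val))
        for val, i, j in kept
    ]
    fel.basins = basins
    return basins


def representative_frame(basin: Basin, projections: np.ndarray) -> int:
    """Frame whose (PC1, PC2) projection is nearest the basin's minimum-bin center.

    Ties resolve to the lowest frame index.
    """
    p = np.asarray(projections, dtype=float)[:, :2]
    d2 = ((p - np.asarray(basin.center)) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))
    basin.representative_frame = idx
    return idx


@dataclass
class LandscapeBreadth:
    occupied_bins: int
    occupied_area: float
    pc1_span: float


def landscape_breadth(fel: FreeEnergyLandscape) -> LandscapeBreadth:
    """Occupied area and PC1 span of the landscape.

    Enables breadth comparisons between conditions (e.g. water vs denaturant,
    monomer vs dimer): broader occupation indicates enhanced conformational
    sampling.
    """
    occ = ~fel.g.mask
    n_occ = int(occ.sum())
    occ_rows = np.flatnonzero(occ.any(axis=1))
    span = float(fel.x_edges[occ_rows.max() + 1] - fel.x_edges[occ_rows.min()]) if len(occ_rows) else 0.0
    return LandscapeBreadth(n_occ, n_occ * fel.bin_area, span)


_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}
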