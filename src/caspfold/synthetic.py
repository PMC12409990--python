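"""Synthetic-data generators for end-to-end testing by parameter recovery.

Every input the pipeline consumes can be generated here with known ground
truth: toy structural ensembles whose fluctuations follow a small number of
planted orthonormal modes plus isotropic noise, equilibrium-unfolding curves
drawn from the two- and three-state monomer models with linear baselines and
Gaussian noise, conservation-grade tables, and structural-region annotations.
All generators are pure functions of their seed.

The toy base geometry is a compressed idealized helix trace (100 degrees of
turn per residue) with one pseudo-sidechain atom per residue whose identity
cycles through hydrophobic, acidic and basic residue types, so the
contact-typing rules of the network stage exercise all three edge types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble
from . import thermo
from .thermo import EquilibriumFoldingDataset, ProbeBaselines, ThermoParams

# Cyclic residue palette: apolar / acidic / basic mix.  The pseudo-sidechain
# atom name is chosen so the formal-charge typing rules apply.  Oppositely
# charged residues sit 3 apart (GLU-LYS, ASP-ARG) and so do an apolar pair
# (VAL-PHE): i, i+3 stub atoms are in contact in the toy geometry, so the
# generated networks carry electrostatic, hydrophobic and vdw edges.
_PALETTE = [
    ("GLU", "OE1", "O"),
    ("LEU", "CD1", "C"),
    ("VAL", "CG1", "C"),
    ("LYS", "NZ", "N"),
    ("ASP", "OD1", "O"),
    ("PHE", "CZ", "C"),
    ("SER", "OG", "O"),
    ("ARG", "NH1", "N"),
]

REGION_CLASSES = ["helix", "beta", "top_loop", "bottom_loop", "short_beta"]


# --------------------------------------------------------------------------
# Toy ensembles
# --------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Recipe for a toy ensemble with planted essential modes.

    ``planted_modes`` is a list of ``(vector, sd)`` pairs: a unit displacement
    vector of shape ``(n_atoms, 3)`` (mutually orthonormal across modes) and
    the standard deviation in Angstrom of the Gaussian amplitude along it.
    Standard deviations must be strictly decreasing so mode identity is
    unambiguous in recovery tests.
    """

    n_residues: int
    n_frames: int
    atoms_per_residue: int = 2
    planted_modes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    isotropic_noise_sd: float = 0.0
    rigid_jitter: bool = False
    seed: int = 0

    @property
    def n_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue

    def validate(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.atoms_per_residue not in (1, 2):
            raise ValueError("atoms_per_residue must be 1 (CA) or 2 (CA + stub)")
        if self.isotropic_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        k = len(self.planted_modes)
        if self.n_frames < k + 1:
            raise ValueError(
                f"{self.n_frames} frames cannot support {k} modes "
                "(covariance would be rank deficient)"
            )
        if k and self.n_frames < 10 * k:
            raise ValueError("n_frames must be at least 10x the number of modes")
        sds = [sd for _, sd in self.planted_modes]
        if any(s <= 0 for s in sds):
            raise ValueError("mode standard deviations must be positive")
        if any(a <= b for a, b in zip(sds, sds[1:])):
            raise ValueError("mode standard deviations must be strictly decreasing")
        if k:
            mat = np.stack([np.asarray(v, dtype=float).reshape(-1) for v, _ in self.planted_modes])
            if mat.shape[1] != 3 * self.n_atoms:
                raise ValueError("mode vectors must have shape (n_atoms, 3)")
            gram = mat @ mat.T
            if not np.allclose(gram, np.eye(k), atol=1e-6):
                raise ValueError("planted mode vectors must be mutually orthonormal")


def helix_base_geometry(n_residues: int, atoms_per_residue: int = 2) -> tuple[np.ndarray, pd.DataFrame]:
    """Compressed idealized helix trace with an optional pseudo-sidechain stub.

    CA atoms sit on a helix with a 100 degree turn per residue but a
    deliberately reduced radius (1.8 A) and rise (0.9 A), so that residues
    i +/- 2..4 fall inside a 4 A heavy-atom contact cutoff — mimicking the
    packing density that full sidechains provide in a real helix while using
    only two atoms per residue.  The stub atom points 1.0 A radially outward
    from its CA.
    """
    coords = []
    rows = []
    radius, rise, turn = 1.8, 0.9, np.deg2rad(100.0)
    for i in range(n_residues):
        res_name, stub_name, stub_elem = _PALETTE[i % len(_PALETTE)]
        theta = turn * i
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        coords.append(ca)
        rows.append((i + 1, res_name, "A", "CA", "C"))
        if atoms_per_residue == 2:
            outward = np.array([np.cos(theta), np.sin(theta), 0.0])
            coords.append(ca + 1.0 * outward)
            rows.append((i + 1, res_name, "A", stub_name, stub_elem))
    atoms = pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "chain_id", "atom_name", "element"]
    )
    return np.asarray(coords), atoms


def random_orthonormal_modes(n_atoms: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k mutually orthonormal random displacement vectors, shape (k, n_atoms, 3)."""
    mat = rng.standard_normal((3 * n_atoms, k))
    q, _ = np.linalg.qr(mat)
    return q.T.reshape(k, n_atoms, 3)


def make_toy_ensemble(spec: EnsembleSpec) -> ConformationalEnsemble:
    """Sample an ensemble with Gaussian amplitudes along the planted modes.

    Frame coordinates are ``base + sum_i z_i*sd_i*mode_i + noise`` with
    ``z_i`` standard normal; identical seeds give identical coordinates.
    """
    spec.validate()
    base, atoms = helix_base_geometry(spec.n_residues, spec.atoms_per_residue)
    rng = np.random.default_rng(spec.seed)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for vec, sd in spec.planted_modes:
        z = rng.standard_normal(spec.n_frames)
        # standardize so the planted sample variance is exactly sd^2: the
        # mode amplitude is the ground truth recovery tests compare against
        z = (z - z.mean()) / z.std(ddof=1)
        coords += z[:, None, None] * sd * np.asarray(vec, dtype=float).reshape(1, spec.n_atoms, 3)
    if spec.isotropic_noise_sd > 0:
        coords += rng.normal(0.0, spec.isotropic_noise_sd, size=coords.shape)
    if spec.rigid_jitter:
        from scipy.spatial.transform import Rotation

        shifts = rng.normal(0.0, 5.0, size=(spec.n_frames, 3))
        for f in range(spec.n_frames):
            rot = Rotation.random(rng=rng)
            center = coords[f].mean(axis=0)
            coords[f] = rot.apply(coords[f] - center) + center + shifts[f]
    region = dict(make_region_annotation(spec.n_residues).itertuples(index=False, name=None))
    return ConformationalEnsemble(coords, atoms, region)


def make_hub_ensemble(
    n_residues: int = 30, n_frames: int = 20, hub_residue: int = 15, seed: int = 0
) -> ConformationalEnsemble:
    """Toy ensemble with one residue persistently contacting many others.

    The hub residue's atoms are placed at the centroid of a compact cluster
    of the other residues' stub atoms so that it touches >= 12 partners in
    every frame; used for hub-classification recovery tests.
    """
    spec = EnsembleSpec(n_residues=n_residues, n_frames=n_frames,
                        isotropic_noise_sd=0.05, seed=seed)
    ens = make_toy_ensemble(spec)
    coords = ens.coords.copy()
    atoms = ens.atoms
    hub_mask = (atoms["residue_index"] == hub_residue).to_numpy()
    others = [r for r in range(1, n_residues + 1) if abs(r - hub_residue) > 1]
    # pull 14 non-adjacent partners onto a 3.5 A ring around the hub centroid
    partners = others[:: max(1, len(others) // 14)][:14]
    hub_center = coords[:, hub_mask, :].mean(axis=1, keepdims=True)
    for j, res in enumerate(partners):
        ang = 2 * np.pi * j / len(partners)
        offset = 3.5 * np.array([np.cos(ang), np.sin(ang), ((j % 3) - 1) * 0.4])
        mask = (atoms["residue_index"] == res).to_numpy()
        spread = coords[:, mask, :] - coords[:, mask, :].mean(axis=1, keepdims=True)
        coords[:, mask, :] = hub_center + offset + 0.1 * spread
    return ConformationalEnsemble(coords, atoms, ens.region)


# --------------------------------------------------------------------------
# Unfolding datasets
# --------------------------------------------------------------------------


@dataclass
class FoldingPreset:
    """Named generating condition for synthetic unfolding experiments."""

    name: str
    model: str
    dG_list: list[float]
    m_list: list[float]
    baselines: dict[str, ProbeBaselines]
    probes: list[str]
    concentrations_uM: list[float]
    temperature: float = 298.15

    def to_params(self) -> ThermoParams:
        return ThermoParams(
            self.model, list(self.dG_list), list(self.m_list),
            self.temperature, dict(self.baselines),
        )

    def validate(self, urea_grid: np.ndarray) -> None:
        params = self.to_params()  # raises on model/baseline mismatch
        for cm in params.midpoints:
            if not (urea_grid.min() <= cm <= urea_grid.max()):
                raise ValueError(
                    f"preset {self.name!r}: midpoint {cm:.2f} M outside the urea grid"
                )


def _standard_baselines(three_state: bool) -> dict[str, ProbeBaselines]:
    """Plausible fluorescence (280/295 nm) and far-UV CD baselines.

    The three probes rank the species differently — total-aromatic emission
    (280 nm) is quenched most in the intermediate, tryptophan-only emission
    (295 nm) is enhanced on partial exposure, and CD ellipticity decays
    monotonically — the classic multi-probe signature that makes a partially
    folded intermediate resolvable in a global fit.  Native baselines are
    urea-independent (no pre-transition slope), matching how marginally
    stable native states are treated in practice.
    """
    if three_state:
        return {
            "fluor_280": ProbeBaselines(1.00, 0.0, 0.60, 0.005, 0.35),
            "fluor_295": ProbeBaselines(0.40, 0.0, 0.20, 0.004, 0.95),
            "cd_222": ProbeBaselines(-12.0, 0.0, -2.5, 0.02, -7.0),
        }
    return {
        "fluor_280": ProbeBaselines(1.00, 0.0, 0.45, 0.006, None),
        "fluor_295": ProbeBaselines(0.85, 0.0, 0.25, 0.005, None),
        "cd_222": ProbeBaselines(-12.0, 0.0, -2.5, 0.02, None),
    }


#: Registry of generating conditions.  "21M" uses the reported three-state
#: free energies of the subunit-swap (21-mutation) caspase variants; its
#: m-values and all baselines are this package's documented stand-ins.
#: "hub_mutant" uses the reported two-state free energy of the
#: phenylalanine-quadruple core mutant.
PRESETS: dict[str, FoldingPreset] = {
    "21M": FoldingPreset(
        name="21M",
        model=thermo.THREE_STATE,
        dG_list=[1.0, 2.7],
        m_list=[0.5, 0.7],
        baselines=_standard_baselines(three_state=True),
        probes=["fluor_280", "fluor_295", "cd_222"],
        concentrations_uM=[2.0, 6.0, 8.0],
    ),
    "hub_mutant": FoldingPreset(
        name="hub_mutant",
        model=thermo.TWO_STATE,
        dG_list=[2.3],
        m_list=[0.6],
        baselines=_standard_baselines(three_state=False),
        probes=["fluor_280", "fluor_295", "cd_222"],
        concentrations_uM=[2.0, 6.0, 8.0],
    ),
}

DEFAULT_UREA_GRID = np.linspace(0.0, 9.0, 25)


def make_unfolding_datasets(
    preset: FoldingPreset,
    urea_grid: np.ndarray | None = None,
    noise_sd_fraction: float = 0.02,
    n_replicates: int = 1,
    seed: int = 0,
    cm_shift_per_doubling: float = 0.0,
) -> list[EquilibriumFoldingDataset]:
    """Simulate unfolding curves for every probe x concentration x replicate.

    The noise standard deviation is ``noise_sd_fraction`` times the probe's
    noiseless signal range over the urea grid (homoscedastic per probe).
    The monomer models have no concentration term, so fractions are
    concentration-independent by construction; ``cm_shift_per_doubling``
    (M urea per doubling of concentration) injects an adversarial,
    oligomer-like midpoint shift for testing the concentration-dependence
    check and defaults to off.
    """
    urea = DEFAULT_UREA_GRID if urea_grid is None else np.asarray(urea_grid, dtype=float)
    if urea.size == 0:
        raise ValueError("urea grid is empty")
    if np.any(np.diff(urea) <= 0):
        raise ValueError("urea grid must be strictly increasing")
    if noise_sd_fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    preset.validate(urea)
    rng = np.random.default_rng(seed)

    datasets = []
    base_params = preset.to_params()
    for probe in preset.probes:
        clean_ref = thermo.signal_model(base_params, urea, probe)
        span = clean_ref.max() - clean_ref.min()
        sd = noise_sd_fraction * span
        for conc in preset.concentrations_uM:
            params = base_params
            if cm_shift_per_doubling != 0.0:
                shift = cm_shift_per_doubling * np.log2(conc / min(preset.concentrations_uM))
                params = ThermoParams(
                    preset.model,
                    [dg + m * shift for dg, m in zip(preset.dG_list, preset.m_list)],
                    list(preset.m_list), preset.temperature, dict(preset.baselines),
                )
            clean = thermo.signal_model(params, urea, probe)
            for rep in range(n_replicates):
                noisy = clean + (rng.normal(0.0, sd, size=urea.shape) if sd > 0 else 0.0)
                datasets.append(
                    EquilibriumFoldingDataset(
                        urea.copy(), noisy, probe=probe, conc_uM=conc, replicate=rep
                    )
                )
    return datasets


# --------------------------------------------------------------------------
# Conservation and region tables
# --------------------------------------------------------------------------


def make_conservation_table(
    n_positions: int, hub_positions: list[int] | None = None, seed: int = 0
) -> pd.DataFrame:
    """ConSurf-style grades 1-9 per position; hub positions draw from {8, 9}."""
    hubs = set(hub_positions or [])
    if any(p < 1 or p > n_positions for p in hubs):
        raise ValueError("hub positions must lie in [1, n_positions]")
    rng = np.random.default_rng(seed)
    grades = rng.integers(1, 10, size=n_positions)
    for p in hubs:
        grades[p - 1] = rng.integers(8, 10)
    return pd.DataFrame({"position": np.arange(1, n_positions + 1), "grade": grades})


def make_region_annotation(n_residues: int) -> pd.DataFrame:
    """Deterministic block pattern of structural-region classes.

    Cycles helix / top_loop / beta / bottom_loop / short_beta in blocks so
    every region class appears on fixtures of realistic size.
    """
    pattern = ["helix"] * 8 + ["top_loop"] * 3 + ["beta"] * 6 + ["bottom_loop"] * 3 + ["short_beta"] * 2
    regions = [pattern[i % len(pattern)] for i in range(n_residues)]
    return pd.DataFrame({"position": np.arange(1, n_residues + 1), "region": regions})


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------


def write_unfolding_tsv(datasets: list[EquilibriumFoldingDataset], path: str | Path) -> None:
    thermo.datasets_to_frame(datasets).to_csv(path, sep="\t", index=False)


def read_unfolding_tsv(path: str | Path) -> list[EquilibriumFoldingDataset]:
    return thermo.datasets_from_frame(pd.read_csv(path, sep="\t"))


def write_conservation_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_conservation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_region_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_region_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
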