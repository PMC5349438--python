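"""Toy electron-density and structure-factor engine.

Atoms are modelled as single isotropic Gaussians whose integrated density is
``occupancy x Z`` electrons and whose width comes from ``B + B_MIN``; this
keeps every property that matters for partial-occupancy modelling (linearity
in occupancy, normalization, the B/occupancy trade-off) while avoiding
multi-Gaussian form factors.  In reciprocal space the same atom contributes
``occ * Z * exp(-(B + B_MIN) s^2 / 4)``, the familiar Debye-Waller factor, so
the real-space and reciprocal-space routes are exact transforms of each other
and are cross-checked in the tests.

Conventions: P1 synthesis, F(h) = sum_j f_j exp(+2 pi i h.x_j) with x in
fractional coordinates, rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).  Observed
data are amplitudes only (phases NaN); 5% of reflections carry a free flag
for cross-validation statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .model import StructureModel

__all__ = [
    "B_MIN",
    "DensityMap",
    "ReflectionSet",
    "OccupancyEstimate",
    "calc_density",
    "calc_structure_factors",
    "structure_factors_at",
    "map_to_sf",
    "sf_to_map",
    "model_map",
    "simulate_two_state",
    "difference_map",
    "event_map",
    "estimate_occupancy",
    "refine_residue_b",
    "refine_residue_shift",
    "default_grid",
]

#: extra smearing (A^2) added to every atomic B factor so that even B=0 atoms
#: have finite width on practical grids
B_MIN = 10.0

FREE_FRACTION = 0.05


def orth_matrix(cell) -> np.ndarray:
    """Orthogonalization matrix: columns are the cell vectors a, b, c (A)."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    return np.array(
        [
            [a, b * np.cos(ga), cx],
            [0.0, b * np.sin(ga), cy],
            [0.0, 0.0, cz],
        ]
    )


def cell_volume(cell) -> float:
    return float(abs(np.linalg.det(orth_matrix(cell))))


def d_spacings(cell, hkl: np.ndarray) -> np.ndarray:
    """d (A) for integer index rows of ``hkl``; (0,0,0) maps to inf."""
    s = hkl @ np.linalg.inv(orth_matrix(cell))  # scattering vector rows, |s| = 1/d
    norm = np.linalg.norm(s, axis=-1)
    with np.errstate(divide="ignore"):
        return np.where(norm > 0, 1.0 / np.where(norm > 0, norm, 1.0), np.inf)


# ------------------------------------------------------------------ containers

@dataclass
class DensityMap:
    """Real-space scalar density (e/A^3) on a periodic grid over one cell."""

    values: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    label: str = "calc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density map contains non-finite values")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def volume(self) -> float:
        return cell_volume(self.cell)

    @property
    def voxel_volume(self) -> float:
        return self.volume / self.values.size

    def integral(self) -> float:
        """Total electrons in the cell."""
        return float(self.values.sum() * self.voxel_volume)

    def sigma(self) -> float:
        """RMS about the mean over the whole cell."""
        return float(self.values.std())

    def write_ccp4(self, path: str) -> None:
        g = gemmi.FloatGrid(*self.grid)
        g.set_unit_cell(gemmi.UnitCell(*self.cell))
        g.spacegroup = gemmi.SpaceGroup("P1")
        np.asarray(g.array)[:] = self.values
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def read_ccp4(cls, path: str, label: str = "obs") -> "DensityMap":
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
        c = m.grid.unit_cell
        return cls(
            values=np.array(m.grid.array, dtype=float),
            cell=(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
            label=label,
        )


@dataclass
class ReflectionSet:
    """Unique-hemisphere structure-factor list on one unit cell.

    ``phase`` is in degrees in [-180, 180), NaN when only amplitudes are
    known (observed data).  Friedel mates are implicit: the stored half plus
    F(-h) = conj(F(h)) describes the full sphere of a real density.
    """

    hkl: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    free_flag: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.free_flag is None:
            self.free_flag = np.zeros(n, dtype=bool)
        self.free_flag = np.asarray(self.free_flag, dtype=bool)
        if not (len(self.amplitude) == len(self.phase) == len(self.free_flag) == n):
            raise ValueError("column length mismatch")
        if np.any(self.amplitude < 0):
            raise ValueError("negative amplitude")
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != n:
            raise ValueError("duplicate (h,k,l) entries")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d_spacing(self) -> np.ndarray:
        return d_spacings(self.cell, self.hkl)

    @property
    def d_min(self) -> float:
        return float(np.min(self.d_spacing))

    @property
    def has_phases(self) -> bool:
        return bool(np.all(np.isfinite(self.phase)))

    @property
    def f(self) -> np.ndarray:
        """Complex structure factors (NaN where phases are unknown)."""
        return self.amplitude * np.exp(1j * np.radians(self.phase))

    def index_of(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def common_with(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (into self, other) of the shared (h,k,l) subset."""
        mine = self.index_of()
        ia, ib = [], []
        for j, h in enumerate(other.hkl):
            i = mine.get(tuple(h))
            if i is not None:
                ia.append(i)
                ib.append(j)
        if not ia:
            raise IndexError("reflection sets share no (h,k,l) indices")
        return np.asarray(ia), np.asarray(ib)

    # -- plain-text hkl table: columns h k l F phi free, '#' comments,
    #    phi written as nan for amplitude-only data
    def write_hkl(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# groundstate hkl table\n")
            fh.write("# cell %.6f %.6f %.6f %.4f %.4f %.4f\n" % tuple(self.cell))
            fh.write("#   h   k   l            F          phi  free\n")
            for (h, k, l), amp, phi, fr in zip(
                self.hkl, self.amplitude, self.phase, self.free_flag
            ):
                fh.write(f"{h:5d}{k:5d}{l:5d} {amp:14.6f} {phi:12.5f} {int(fr):d}\n")

    @classmethod
    def read_hkl(cls, path: str) -> "ReflectionSet":
        cell = None
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# cell"):
                    cell = tuple(float(x) for x in line.split()[2:8])
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                rows.append(
                    (int(parts[0]), int(parts[1]), int(parts[2]),
                     float(parts[3]), float(parts[4]), bool(int(parts[5])))
                )
        if cell is None:
            raise ValueError(f"{path}: missing '# cell' header line")
        if not rows:
            return cls(np.zeros((0, 3), int), [], [], cell)
        arr = list(zip(*rows))
        return cls(
            hkl=np.array(arr[:3]).T,
            amplitude=np.array(arr[3]),
            phase=np.array(arr[4]),
            cell=cell,
            free_flag=np.array(arr[5]),
        )

    def write_mtz(self, path: str) -> None:
        mtz = gemmi.Mtz(with_base=True)
        mtz.cell = gemmi.UnitCell(*self.cell)
        mtz.spacegroup = gemmi.SpaceGroup("P1")
        mtz.add_dataset("groundstate")
        mtz.add_column("F", "F")
        mtz.add_column("PHI", "P")
        mtz.add_column("FreeR_flag", "I")
        data = np.column_stack(
            [self.hkl, self.amplitude, self.phase, self.free_flag.astype(int)]
        ).astype(np.float32)
        mtz.set_data(data)
        mtz.write_to_file(str(path))

    @classmethod
    def read_mtz(
        cls,
        path: str,
        amplitude_col: str = "F",
        phase_col: str | None = "PHI",
        free_col: str | None = "FreeR_flag",
    ) -> "ReflectionSet":
        mtz = gemmi.read_mtz_file(str(path))
        labels = mtz.column_labels()
        arr = np.array(mtz, copy=True)
        cols = {lab: arr[:, i] for i, lab in enumerate(labels)}
        hkl = np.column_stack([cols["H"], cols["K"], cols["L"]]).astype(int)
        amp = cols[amplitude_col]
        phase = cols[phase_col] if phase_col in cols else np.full(len(amp), np.nan)
        free = cols[free_col].astype(bool) if free_col in cols else None
        c = mtz.cell
        return cls(hkl, amp, phase, (c.a, c.b, c.c, c.alpha, c.beta, c.gamma), free)


# ------------------------------------------------------------------ synthesis

def hemisphere_hkl(cell, d_min: float) -> np.ndarray:
    """Unique-half (h,k,l) list with d >= d_min, (0,0,0) included first."""
    a, b, c = cell[0], cell[1], cell[2]
    hmax = int(np.floor(a / d_min)) + 1
    kmax = int(np.floor(b / d_min)) + 1
    lmax = int(np.floor(c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    # unique hemisphere: first nonzero index positive
    keep = (hkl[:, 0] > 0) | (
        (hkl[:, 0] == 0) & ((hkl[:, 1] > 0) | ((hkl[:, 1] == 0) & (hkl[:, 2] >= 0)))
    )
    hkl = hkl[keep]
    d = d_spacings(cell, hkl)
    hkl = hkl[d >= d_min - 1e-9]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def structure_factors_at(model: StructureModel, hkl: np.ndarray) -> np.ndarray:
    """Complex F at the given indices for Gaussian atoms (analytic)."""
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    if len(model.atoms) == 0:
        return np.zeros(len(hkl), dtype=complex)
    A = orth_matrix(model.cell)
    Ainv = np.linalg.inv(A)
    xyz = np.array([a.pos for a in model.atoms])
    frac = xyz @ Ainv.T
    occ = np.array([a.occupancy for a in model.atoms])
    z = np.array([a.atomic_number for a in model.atoms], dtype=float)
    bb = np.array([a.b_factor for a in model.atoms]) + B_MIN
    inv_d = np.linalg.norm(hkl @ np.linalg.inv(A), axis=1)  # |s| = 1/d
    # f_j(h) = occ * Z * exp(-B' s^2 / 4)
    fall = np.exp(-np.outer(inv_d**2, bb) / 4.0) * (occ * z)  # (nref, natom)
    phases = np.exp(2j * np.pi * (hkl @ frac.T))
    return np.einsum("ra,ra->r", fall, phases)


def calc_structure_factors(model: StructureModel, d_min: float) -> ReflectionSet:
    """Analytic structure factors of a model to resolution ``d_min``."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl = hemisphere_hkl(model.cell, d_min)
    f = structure_factors_at(model, hkl)
    return ReflectionSet(
        hkl=hkl,
        amplitude=np.abs(f),
        phase=np.degrees(np.angle(f)),
        cell=model.cell,
    )


def default_grid(cell, resolution: float, oversample: float = 3.0) -> tuple[int, int, int]:
    """Even grid dimensions with spacing <= resolution / oversample."""
    dims = []
    for length in cell[:3]:
        n = int(np.ceil(length / (resolution / oversample)))
        dims.append(n + n % 2)
    return tuple(dims)


def calc_density(
    model: StructureModel,
    grid: tuple[int, int, int],
    resolution: float,
) -> DensityMap:
    """Direct real-space Gaussian summation over atoms and periodic images.

    Each atom contributes ``peak * exp(-4 pi^2 |r - r0|^2 / (B + B_MIN))``
    with the peak chosen so the atom integrates to ``occupancy x Z``
    electrons.  Used both as a stand-alone density calculator and as the
    independent real-space cross-check of the Fourier route.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    grid = tuple(int(n) for n in grid)
    spacing = [model.cell[i] / grid[i] for i in range(3)]
    if max(spacing) > resolution / 3 + 1e-9:
        raise ValueError(
            f"grid spacing {max(spacing):.3f} A too coarse for {resolution} A "
            "resolution (need <= resolution/3)"
        )
    A = orth_matrix(model.cell)
    Ainv = np.linalg.inv(A)
    rho = np.zeros(grid)
    nx, ny, nz = grid
    for atom in model.atoms:
        bprime = atom.b_factor + B_MIN
        alpha = 4.0 * np.pi**2 / bprime  # exponent coefficient, A^-2
        peak = atom.occupancy * atom.atomic_number * (alpha / np.pi) ** 1.5
        cutoff = np.sqrt(np.log(1e10) / alpha)  # where the Gaussian is 1e-10 of peak
        fc = Ainv @ atom.pos
        # fractional half-widths of the bounding box along each axis
        ext = [cutoff / model.cell[i] for i in range(3)]
        i0 = int(np.floor((fc[0] - ext[0]) * nx))
        i1 = int(np.ceil((fc[0] + ext[0]) * nx))
        j0 = int(np.floor((fc[1] - ext[1]) * ny))
        j1 = int(np.ceil((fc[1] + ext[1]) * ny))
        k0 = int(np.floor((fc[2] - ext[2]) * nz))
        k1 = int(np.ceil((fc[2] + ext[2]) * nz))
        ii = np.arange(i0, i1 + 1)
        jj = np.arange(j0, j1 + 1)
        kk = np.arange(k0, k1 + 1)
        fi, fj, fk = np.meshgrid(ii / nx, jj / ny, kk / nz, indexing="ij")
        df = np.stack([fi - fc[0], fj - fc[1], fk - fc[2]], axis=-1)
        dxyz = df @ A.T
        r2 = np.sum(dxyz**2, axis=-1)
        contrib = peak * np.exp(-alpha * r2)
        rho[np.ix_(ii % nx, jj % ny, kk % nz)] += contrib
    return DensityMap(values=rho, cell=model.cell, label="calc")


def map_to_sf(density: DensityMap, d_min: float | None = None) -> ReflectionSet:
    """Discrete Fourier analysis of a map; keeps the unique hemisphere.

    With ``d_min=None`` all coefficients up to the grid Nyquist limit are
    returned (the exact inverse of :func:`sf_to_map` on the same grid).
    """
    coeff = np.fft.ifftn(density.values) * density.volume
    nx, ny, nz = density.grid
    if d_min is None:
        hs = np.fft.fftfreq(nx, 1 / nx).astype(int)
        ks = np.fft.fftfreq(ny, 1 / ny).astype(int)
        ls = np.fft.fftfreq(nz, 1 / nz).astype(int)
        h, k, l = np.meshgrid(hs, ks, ls, indexing="ij")
        hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
        keep = (hkl[:, 0] > 0) | (
            (hkl[:, 0] == 0) & ((hkl[:, 1] > 0) | ((hkl[:, 1] == 0) & (hkl[:, 2] >= 0)))
        )
        hkl = hkl[keep]
    else:
        hkl = hemisphere_hkl(density.cell, d_min)
        if (
            np.any(np.abs(hkl[:, 0]) > nx // 2)
            or np.any(np.abs(hkl[:, 1]) > ny // 2)
            or np.any(np.abs(hkl[:, 2]) > nz // 2)
        ):
            raise ValueError(f"grid {density.grid} cannot carry reflections to {d_min} A")
    f = coeff[hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz]
    return ReflectionSet(
        hkl=hkl,
        amplitude=np.abs(f),
        phase=np.degrees(np.angle(f)),
        cell=density.cell,
    )


def sf_to_map(
    refl: ReflectionSet,
    grid: tuple[int, int, int],
    label: str = "calc",
    coefficients: np.ndarray | None = None,
) -> DensityMap:
    """Fourier synthesis of a real map from a hemisphere of reflections.

    ``coefficients`` overrides the set's own complex values (used for
    difference and 2Fo-Fc style syntheses on the same index list).
    """
    f = refl.f if coefficients is None else np.asarray(coefficients, dtype=complex)
    if np.any(~np.isfinite(f)):
        raise ValueError("cannot synthesize a map from amplitude-only data (missing phases)")
    nx, ny, nz = (int(n) for n in grid)
    hkl = refl.hkl
    if (
        np.any(np.abs(hkl[:, 0]) > nx // 2)
        or np.any(np.abs(hkl[:, 1]) > ny // 2)
        or np.any(np.abs(hkl[:, 2]) > nz // 2)
    ):
        raise ValueError(f"grid {grid} too small for the reflection list (aliasing)")
    G = np.zeros((nx, ny, nz), dtype=complex)
    idx = (hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz)
    G[idx] = f
    # Friedel mates of everything except (0,0,0) and self-conjugate indices
    neg = ((-hkl[:, 0]) % nx, (-hkl[:, 1]) % ny, (-hkl[:, 2]) % nz)
    mask = ~((neg[0] == idx[0]) & (neg[1] == idx[1]) & (neg[2] == idx[2]))
    G[neg[0][mask], neg[1][mask], neg[2][mask]] = np.conj(f[mask])
    rho = np.fft.fftn(G) / cell_volume(refl.cell)
    return DensityMap(values=rho.real, cell=refl.cell, label=label)


def model_map(model: StructureModel, grid, d_min: float, label: str = "calc") -> DensityMap:
    """Band-limited model density: Fourier synthesis of the analytic F's."""
    return sf_to_map(calc_structure_factors(model, d_min), grid, label=label)


# ------------------------------------------------------------------ simulation

def simulate_two_state(
    ground: StructureModel,
    bound: StructureModel,
    q: float,
    resolution: float,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ReflectionSet:
    """Observed amplitudes of a crystal mixing ground and bound states.

    The total scattering of a crystal whose cells host the bound state in a
    fraction ``q`` is the occupancy-weighted average
    ``F = (1-q) F_ground + q F_bound``.  Amplitudes then receive
    multiplicative Gaussian noise of relative width ``noise_frac`` (clipped
    at zero); phases are discarded, as in a diffraction experiment, and a
    random 5% of reflections is flagged as the cross-validation (free) set.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"occupancy q={q} outside [0, 1]")
    if ground.cell != bound.cell:
        raise ValueError("ground and bound models must share a unit cell")
    hkl = hemisphere_hkl(ground.cell, resolution)
    hkl = hkl[~np.all(hkl == 0, axis=1)]  # F(000) is not measurable
    f = (1.0 - q) * structure_factors_at(ground, hkl) + q * structure_factors_at(bound, hkl)
    amp = np.abs(f)
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        amp = np.clip(amp * (1.0 + rng.normal(0.0, noise_frac, len(amp))), 0.0, None)
    free = rng.random(len(amp)) < FREE_FRACTION
    return ReflectionSet(
        hkl=hkl,
        amplitude=amp,
        phase=np.full(len(amp), np.nan),
        cell=ground.cell,
        free_flag=free,
    )


def amplitude_scale(f_obs: np.ndarray, f_calc: np.ndarray) -> float:
    """Least-squares k minimizing sum(|Fo| - k |Fc|)^2."""
    denom = float(np.sum(f_calc**2))
    if denom == 0:
        return 1.0
    return float(np.sum(f_obs * f_calc) / denom)


def difference_map(
    obs: ReflectionSet,
    model: StructureModel,
    grid: tuple[int, int, int],
) -> tuple[DensityMap, DensityMap]:
    """Unweighted Fo-Fc and 2Fo-Fc style maps with model phases.

    After an overall least-squares scale k on amplitudes, the difference map
    uses coefficients ``(|Fo| - k|Fc|) exp(i phi_c)`` and the total map
    ``(2|Fo| - k|Fc|) exp(i phi_c)`` — unweighted surrogates of the usual
    sigma-A weighted mFo-DFc / 2mFo-DFc maps.  Returns (diff, total).
    """
    if tuple(np.round(obs.cell, 6)) != tuple(np.round(model.cell, 6)):
        raise ValueError("observed data and model must share a unit cell")
    fc = structure_factors_at(model, obs.hkl)
    fo = obs.amplitude
    k = amplitude_scale(fo, np.abs(fc))
    phic = np.exp(1j * np.angle(fc))
    # F000 has no experimental analogue; exclude it from both syntheses
    zero = np.all(obs.hkl == 0, axis=1)
    diff_coeff = np.where(zero, 0, (fo - k * np.abs(fc)) * phic)
    total_coeff = np.where(zero, 0, (2 * fo - k * np.abs(fc)) * phic)
    diff = sf_to_map(obs, grid, label="diff", coefficients=diff_coeff)
    total = sf_to_map(obs, grid, label="obs", coefficients=total_coeff)
    return diff, total


def event_map(obs_map: DensityMap, ground_map: DensityMap, bdc: float) -> DensityMap:
    """Partial-difference (event) map revealing the bound state.

    Subtracts a fraction ``bdc`` (background density correction) of the
    ground-state density and rescales:
    ``event = (obs - bdc * ground) / (1 - bdc)``.  With ``bdc = 1 - q`` on a
    crystal that is ``(1-q)`` ground + ``q`` bound, the ground contribution
    cancels exactly and the event map equals the bound-state density.
    """
    if obs_map.grid != ground_map.grid:
        raise ValueError(f"grid mismatch: {obs_map.grid} vs {ground_map.grid}")
    if not 0.0 <= bdc < 1.0:
        raise ValueError(f"bdc={bdc} outside [0, 1)")
    values = (obs_map.values - bdc * ground_map.values) / (1.0 - bdc)
    return DensityMap(values=values, cell=obs_map.cell, label="event")


# ------------------------------------------------------------------ occupancy

@dataclass
class OccupancyEstimate:
    """Grid-search occupancy estimate with its residual profile."""

    q_hat: float
    q_grid: np.ndarray
    residuals: np.ndarray

    def __float__(self) -> float:
        return self.q_hat


def estimate_occupancy(
    obs: ReflectionSet,
    ground: StructureModel,
    bound: StructureModel,
    q_grid: np.ndarray | None = None,
) -> OccupancyEstimate:
    """Estimate the bound-state occupancy from amplitudes alone.

    For each trial q the two-state amplitudes ``|(1-q) F_g + q F_b|`` are
    scaled to the observations by least squares and the residual
    ``sum(|Fo| - k |Fc(q)|)^2`` recorded; the grid minimum is refined by
    parabolic interpolation.  Degenerate inputs (ground and bound scattering
    identical) give a flat profile and an undefined estimate (NaN) with a
    warning.
    """
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 41)
    q_grid = np.asarray(q_grid, dtype=float)
    if len(q_grid) < 3:
        raise ValueError("q_grid needs at least 3 points")
    fg = structure_factors_at(ground, obs.hkl)
    fb = structure_factors_at(bound, obs.hkl)
    if np.max(np.abs(fg - fb)) <= 1e-9 * max(np.max(np.abs(fg)), 1e-30):
        warnings.warn("ground and bound states scatter identically; occupancy is ill-posed")
        return OccupancyEstimate(np.nan, q_grid, np.zeros_like(q_grid))
    fo = obs.amplitude
    residuals = np.empty_like(q_grid)
    for i, q in enumerate(q_grid):
        amp = np.abs((1.0 - q) * fg + q * fb)
        k = amplitude_scale(fo, amp)
        residuals[i] = np.sum((fo - k * amp) ** 2)
    imin = int(np.argmin(residuals))
    q_hat = q_grid[imin]
    if 0 < imin < len(q_grid) - 1:
        x0, x1, x2 = q_grid[imin - 1 : imin + 2]
        y0, y1, y2 = residuals[imin - 1 : imin + 2]
        denom = (x0 - x1) * (y1 - y2) - (x1 - x2) * (y0 - y1)
        if abs(denom) > 1e-300:
            q_par = (
                x1
                - 0.5
                * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0))
                / ((x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0))
            )
            if np.isfinite(q_par) and min(x0, x2) <= q_par <= max(x0, x2):
                q_hat = q_par
    return OccupancyEstimate(float(np.clip(q_hat, 0.0, 1.0)), q_grid, residuals)


# ------------------------------------------------------------------ toy refinement

def _split_sf(model: StructureModel, residue: tuple[str, int], hkl: np.ndarray):
    res_atoms = [a for a in model.atoms if (a.chain, a.res_seq) == residue]
    if not res_atoms:
        raise KeyError(f"residue {residue} not in model")
    rest = StructureModel(
        atoms=[a for a in model.atoms if (a.chain, a.res_seq) != residue],
        cell=model.cell, spacegroup=model.spacegroup,
    )
    res_model = StructureModel(atoms=res_atoms, cell=model.cell, spacegroup=model.spacegroup)
    return res_model, structure_factors_at(res_model, hkl), structure_factors_at(rest, hkl)


def refine_residue_b(
    obs: ReflectionSet,
    model: StructureModel,
    residue: tuple[str, int],
    db_grid: np.ndarray | None = None,
) -> tuple[float, StructureModel]:
    """Fit a single B-factor shift of one residue against the amplitudes.

    A one-parameter surrogate of the B/occupancy trade-off in refinement:
    when a residue is modelled at too high an occupancy, the amplitude
    residual is reduced by inflating its B factors, which damp its
    scattering.  Returns the best shift (A^2, floored so no B goes negative)
    and the adjusted model.
    """
    if db_grid is None:
        db_grid = np.arange(-15.0, 120.1, 2.5)
    res_model, f_res, f_rest = _split_sf(model, residue, obs.hkl)
    inv_d2 = 1.0 / d_spacings(obs.cell, obs.hkl) ** 2
    inv_d2 = np.where(np.isfinite(inv_d2), inv_d2, 0.0)
    min_b = min(a.b_factor for a in res_model.atoms)
    fo = obs.amplitude
    best = (np.inf, 0.0)
    for db in db_grid:
        if db < -min_b:
            continue
        amp = np.abs(f_rest + f_res * np.exp(-db * inv_d2 / 4.0))
        k = amplitude_scale(fo, amp)
        resid = float(np.sum((fo - k * amp) ** 2))
        if resid < best[0]:
            best = (resid, float(db))
    db = best[1]
    out = model.copy()
    for a in out.atoms:
        if (a.chain, a.res_seq) == residue:
            a.b_factor = max(a.b_factor + db, 0.0)
    return db, out


def refine_residue_shift(
    obs: ReflectionSet,
    model: StructureModel,
    residue: tuple[str, int],
    max_shift: float = 1.0,
) -> tuple[np.ndarray, StructureModel]:
    """Fit a rigid translation of one residue against the amplitudes.

    Coarse-to-fine grid search over Cartesian shifts; because a rigid
    translation only multiplies the residue's structure factors by a phase
    factor, each candidate costs one vector operation.  Mirrors the
    coordinate drift of a mis-modelled ligand pulled into unexplained
    density during refinement; the drift magnitude feeds the RMSD metric.
    """
    res_model, f_res, f_rest = _split_sf(model, residue, obs.hkl)
    Ainv = np.linalg.inv(orth_matrix(model.cell))
    fo = obs.amplitude
    hkl = obs.hkl

    def residual(shift: np.ndarray) -> float:
        dfrac = Ainv @ shift
        amp = np.abs(f_rest + f_res * np.exp(2j * np.pi * (hkl @ dfrac)))
        k = amplitude_scale(fo, amp)
        return float(np.sum((fo - k * amp) ** 2))

    center = np.zeros(3)
    for step in (max_shift / 2, max_shift / 8, max_shift / 32):
        offsets = np.array(np.meshgrid(*[[-2, -1, 0, 1, 2]] * 3, indexing="ij"))
        cands = center + step * offsets.reshape(3, -1).T
        norms = np.linalg.norm(cands, axis=1)
        cands = cands[norms <= max_shift + 1e-9]
        center = cands[int(np.argmin([residual(c) for c in cands]))]
    out = model.copy()
    for a in out.atoms:
        if (a.chain, a.res_seq) == residue:
            a.pos = a.pos + center
    return center.copy(), out
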