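"""Crystallographic foundation: cells, symmetry, models, reflections, maps.

This module provides the minimal crystallographic machinery the rest of the
package builds on:

* :class:`UnitCell` and :class:`SymmetryOps` — triclinic cells and explicit
  space-group operator lists (fractional convention).
* :class:`AtomicModel` — a flat, numpy-backed atomic model with PDB I/O
  through :mod:`gemmi`.
* :class:`ReflectionSet` — amplitudes/phases on symmetry-unique Miller
  indices, with resolution trimming and phase biasing.
* :class:`DensityMap` — density on a grid covering one unit cell, with
  periodic trilinear interpolation and CCP4/MRC I/O through :mod:`gemmi`.

The benchmark-map simulator lives here too: structure factors are computed
by direct summation with per-element Gaussian form factors, phases are
degraded to a prescribed mean phase error (uniform noise on acentrics,
sign flips on centrics), and maps are synthesized by inverse FFT and
normalized to zero mean / unit standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.fft import fftn, next_fast_len

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "AtomicModel",
    "ReflectionSet",
    "DensityMap",
    "PhaseBiasResult",
    "ELEMENT_Z",
    "compute_structure_factors",
    "apply_uniform_phase_noise",
    "bias_phases",
    "synthesize_map",
    "generate_benchmark_grid",
    "BENCHMARK_RESOLUTIONS",
    "BENCHMARK_PHASE_ERRORS",
]

#: resolutions (Å) of the simulated benchmark grid
BENCHMARK_RESOLUTIONS = (2.5, 3.0, 3.5, 4.0)
#: target mean phase errors (deg); realized FOMs cluster near 0.92/0.75/0.50
BENCHMARK_PHASE_ERRORS = (18.0, 35.0, 54.0)

# effective electron counts for the elements that occur in nucleic acids
ELEMENT_Z = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0}


# ---------------------------------------------------------------------------
# Unit cell and symmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        # metric tensor must be positive definite (triangle-type condition)
        if np.linalg.det(self.frac_to_cart) <= 0:
            raise ValueError("degenerate unit cell")

    @property
    def frac_to_cart(self) -> np.ndarray:
        """3x3 matrix whose columns are the cell vectors in Cartesian Å."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cw = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        v = np.sqrt(max(np.sin(be) ** 2 - cw**2, 1e-12))
        return np.array(
            [
                [self.a, self.b * np.cos(ga), self.c * np.cos(be)],
                [0.0, self.b * np.sin(ga), self.c * cw],
                [0.0, 0.0, self.c * v],
            ]
        )

    @property
    def cart_to_frac(self) -> np.ndarray:
        return np.linalg.inv(self.frac_to_cart)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.frac_to_cart))

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.cart_to_frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.frac_to_cart.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of Miller indices, shape (..., 3)."""
        recip = self.cart_to_frac  # rows are a*, b*, c*
        s = np.asarray(hkl, float) @ recip
        return 1.0 / np.linalg.norm(s, axis=-1)

    def min_image_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Shortest distance between Cartesian points under lattice translations.

        Uses a search over the 27 neighbouring lattice shifts, which is exact
        for all displacements shorter than half the shortest cell height.
        """
        dfrac = self.fractionalize(np.atleast_2d(x)) - self.fractionalize(np.atleast_2d(y))
        dfrac -= np.round(dfrac)
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
        )
        cand = self.orthogonalize(dfrac[:, None, :] + shifts[None, :, :])
        return np.linalg.norm(cand, axis=-1).min(axis=1)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class SymmetryOps:
    """Explicit space-group operators (rotation, translation) in fractional coords.

    The first operator is always the identity.  No symbol parsing is done
    here; use :meth:`from_symbol` (delegating to gemmi) when reading files.
    """

    rotations: tuple = (tuple(map(tuple, np.eye(3, dtype=int))),)
    translations: tuple = ((0.0, 0.0, 0.0),)
    label: str = "P 1"

    def __post_init__(self) -> None:
        R0 = np.array(self.rotations[0])
        if not np.array_equal(R0, np.eye(3, dtype=int)):
            raise ValueError("first operator must be the identity")

    def __len__(self) -> int:
        return len(self.rotations)

    def __iter__(self):
        for R, t in zip(self.rotations, self.translations):
            yield np.array(R, float), np.array(t, float)

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls()

    @classmethod
    def from_symbol(cls, symbol: str) -> "SymmetryOps":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space group: {symbol}")
        rots, trans = [], []
        for op in sg.operations():
            R = np.array(op.rot, float) / op.DEN
            t = np.array(op.tran, float) / op.DEN
            rots.append(tuple(map(tuple, R.astype(int))))
            trans.append(tuple(t))
        # put identity first
        order = sorted(
            range(len(rots)),
            key=lambda i: (not np.array_equal(np.array(rots[i]), np.eye(3)), i),
        )
        return cls(
            rotations=tuple(rots[i] for i in order),
            translations=tuple(trans[i] for i in order),
            label=sg.xhm(),
        )

    def apply_frac(self, frac: np.ndarray) -> np.ndarray:
        """All operator images of fractional points; shape (n_ops, n, 3)."""
        frac = np.atleast_2d(frac)
        out = []
        for R, t in self:
            out.append(frac @ R.T + t)
        return np.stack(out)


def symmetry_images(
    xyz: np.ndarray, cell: UnitCell, ops: SymmetryOps, shells: int = 1
) -> np.ndarray:
    """Cartesian images of points under all ops and neighbouring lattice shifts.

    Returns shape ``(n_ops * n_shifts, n_points, 3)``.
    """
    frac = cell.fractionalize(np.atleast_2d(xyz))
    imgs = ops.apply_frac(frac)  # (n_ops, n, 3)
    rng = range(-shells, shells + 1)
    shifts = np.array([[i, j, k] for i in rng for j in rng for k in rng], float)
    all_frac = (imgs[:, None, :, :] + shifts[None, :, None, :]).reshape(-1, frac.shape[0], 3)
    return cell.orthogonalize(all_frac)


def min_symmetry_distance(
    x: np.ndarray, targets: np.ndarray, cell: UnitCell, ops: SymmetryOps
) -> np.ndarray:
    """For each point in `x`, distance to the nearest symmetry image of `targets`."""
    x = np.atleast_2d(x)
    imgs = symmetry_images(targets, cell, ops).reshape(-1, 3)
    d = np.linalg.norm(x[:, None, :] - imgs[None, :, :], axis=-1)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

@dataclass
class AtomicModel:
    """Flat table of atoms (element, name, residue, chain, position, B, occ)."""

    element: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    name: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    resname: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    resseq: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    chain: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3), float))
    b_iso: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    occ: np.ndarray = field(default_factory=lambda: np.empty(0, float))

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.name)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "AtomicModel":
        """Rows of (element, name, resname, resseq, chain, (x, y, z), b, occ)."""
        rows = list(rows)
        if not rows:
            return cls()
        el, nm, rn, rs, ch, xyz, b, q = zip(*rows)
        return cls(
            element=np.array(el, object),
            name=np.array(nm, object),
            resname=np.array(rn, object),
            resseq=np.array(rs, int),
            chain=np.array(ch, object),
            xyz=np.array(xyz, float),
            b_iso=np.array(b, float),
            occ=np.array(q, float),
        )

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.element[mask], self.name[mask], self.resname[mask],
            self.resseq[mask], self.chain[mask], self.xyz[mask],
            self.b_iso[mask], self.occ[mask],
        )

    def atoms_named(self, atom_name: str) -> np.ndarray:
        """Cartesian positions of all atoms with the given name."""
        return self.xyz[self.name == atom_name]

    def residues(self) -> list[tuple[str, int, np.ndarray]]:
        """List of (chain, resseq, atom index array) in model order."""
        out, seen = [], {}
        for i, (ch, rs) in enumerate(zip(self.chain, self.resseq)):
            key = (ch, int(rs))
            if key not in seen:
                seen[key] = len(out)
                out.append((ch, int(rs), [i]))
            else:
                out[seen[key]][2].append(i)
        return [(ch, rs, np.array(ix, int)) for ch, rs, ix in out]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AtomicModel":
        new = dataclasses.replace(self)
        new.xyz = self.xyz @ np.asarray(R, float).T + np.asarray(t, float)
        return new

    def concat(self, other: "AtomicModel") -> "AtomicModel":
        return AtomicModel(
            *(np.concatenate([getattr(self, f.name), getattr(other, f.name)])
              for f in dataclasses.fields(self))
        )

    # -- PDB I/O (via gemmi) ------------------------------------------------

    def to_gemmi(self, cell: UnitCell | None = None, spacegroup: str = "P 1") -> gemmi.Structure:
        st = gemmi.Structure()
        st.spacegroup_hm = spacegroup
        if cell is not None:
            st.cell = cell.to_gemmi()
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        cur_res = {}
        for i in range(len(self)):
            ch = str(self.chain[i])
            if ch not in chains:
                chains[ch] = gemmi.Chain(ch)
            key = (ch, int(self.resseq[i]))
            if key not in cur_res:
                res = gemmi.Residue()
                res.name = str(self.resname[i])
                res.seqid = gemmi.SeqId(int(self.resseq[i]), " ")
                chains[ch].add_residue(res)
                cur_res[key] = chains[ch][len(chains[ch]) - 1]
            atom = gemmi.Atom()
            atom.name = str(self.name[i])
            atom.element = gemmi.Element(str(self.element[i]))
            atom.pos = gemmi.Position(*self.xyz[i])
            atom.b_iso = float(self.b_iso[i])
            atom.occ = float(self.occ[i])
            cur_res[key].add_atom(atom)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        return st

    def write_pdb(self, path: str, cell: UnitCell | None = None,
                  spacegroup: str = "P 1") -> None:
        self.to_gemmi(cell, spacegroup).write_pdb(str(path))

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure) -> "AtomicModel":
        rows = []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        rows.append(
                            (atom.element.name, atom.name, res.name,
                             res.seqid.num, chain.name,
                             (atom.pos.x, atom.pos.y, atom.pos.z),
                             atom.b_iso, atom.occ)
                        )
            break  # first model only
        return cls.from_rows(rows)

    @classmethod
    def read_pdb(cls, path: str) -> "AtomicModel":
        return cls.from_gemmi(gemmi.read_structure(str(path)))


# ---------------------------------------------------------------------------
# Reflections
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Symmetry-unique reflections with amplitude F and phase φ (degrees)."""

    hkl: np.ndarray
    f: np.ndarray
    phi: np.ndarray
    centric: np.ndarray
    cell: UnitCell
    ops: SymmetryOps = field(default_factory=SymmetryOps.p1)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.f = np.asarray(self.f, float)
        self.phi = np.asarray(self.phi, float)
        self.centric = np.asarray(self.centric, bool)
        if np.any(self.f < 0):
            raise ValueError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.f)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    def trim(self, d_min: float) -> "ReflectionSet":
        """Keep reflections with d >= d_min (resolution truncation)."""
        mask = self.d >= d_min - 1e-9
        return ReflectionSet(self.hkl[mask], self.f[mask], self.phi[mask],
                             self.centric[mask], self.cell, self.ops)

    # -- plain-text and MTZ I/O --------------------------------------------

    def write_text(self, path: str) -> None:
        """Whitespace file: header line with cell, then `h k l F phi` rows."""
        c = self.cell
        with open(path, "w") as fh:
            fh.write(f"# cell {c.a} {c.b} {c.c} {c.alpha} {c.beta} {c.gamma}\n")
            for (h, k, l), F, phi in zip(self.hkl, self.f, self.phi):
                fh.write(f"{h} {k} {l} {F:.6f} {phi:.4f}\n")

    @classmethod
    def read_text(cls, path: str, cell: UnitCell | None = None,
                  ops: SymmetryOps | None = None) -> "ReflectionSet":
        hkl, f, phi = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "cell" in line and cell is None:
                        vals = [float(x) for x in line.split()[2:8]]
                        cell = UnitCell(*vals)
                    continue
                parts = line.split()
                if len(parts) < 5:
                    continue
                hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
                f.append(float(parts[3]))
                phi.append(float(parts[4]))
        if cell is None:
            raise ValueError("no unit cell in file and none supplied")
        ops = ops or SymmetryOps.p1()
        hkl = np.array(hkl, int)
        return cls(hkl, np.array(f), np.array(phi),
                   _centric_flags(hkl, ops), cell, ops)

    def write_mtz(self, path: str, f_col: str = "F", phi_col: str = "PHI") -> None:
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.find_spacegroup_by_name(self.ops.label) or \
            gemmi.find_spacegroup_by_name("P 1")
        mtz.cell = self.cell.to_gemmi()
        mtz.add_dataset("sim")
        mtz.add_column(f_col, "F")
        mtz.add_column(phi_col, "P")
        data = np.column_stack([self.hkl.astype(float), self.f, self.phi])
        mtz.set_data(data)
        mtz.write_to_file(str(path))

    @classmethod
    def read_mtz(cls, path: str, f_col: str = "F", phi_col: str = "PHI") -> "ReflectionSet":
        mtz = gemmi.read_mtz_file(str(path))
        cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                        mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
        ops = SymmetryOps.from_symbol(mtz.spacegroup.xhm()) if mtz.spacegroup \
            else SymmetryOps.p1()
        hkl = np.array(mtz.make_miller_array(), int)
        f = np.array(mtz.column_with_label(f_col), float)
        phi = np.array(mtz.column_with_label(phi_col), float)
        return cls(hkl, f, phi, _centric_flags(hkl, ops), cell, ops)


def _centric_flags(hkl: np.ndarray, ops: SymmetryOps) -> np.ndarray:
    """A reflection is centric iff some rotation maps h to -h."""
    hkl = np.asarray(hkl, int)
    flags = np.zeros(len(hkl), bool)
    for R, _t in ops:
        flags |= np.all(hkl @ R == -hkl, axis=1)
    return flags


def _unique_half_space(hkl: np.ndarray) -> np.ndarray:
    """Mask selecting one reflection per Friedel pair (l>0, or l=0,k>0, ...)."""
    h, k, l = hkl.T
    return (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h > 0))


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def compute_structure_factors(
    model: AtomicModel,
    cell: UnitCell,
    ops: SymmetryOps | None = None,
    d_min: float = 3.0,
    b_overall: float = 20.0,
) -> ReflectionSet:
    """Direct-summation structure factors with Gaussian form factors.

    Atomic scattering is modelled as a single Gaussian per element,
    ``f(s) = Z exp(-B s^2 / 4)`` with ``B = b_overall + B_iso``, which is an
    adequate smooth peaked profile at the 2.5-4 Å resolutions this package
    targets.  The sum runs over all atoms and all symmetry operators; only
    symmetry-unique reflections (one per Friedel pair) are returned.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    ops = ops or SymmetryOps.p1()

    # enumerate Miller indices inside the resolution sphere
    recip = cell.cart_to_frac  # rows = a*, b*, c*
    hmax = [int(np.floor(cell.frac_to_cart[:, i].__abs__().sum() / d_min)) + 1
            for i in range(3)]
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    svec = H @ recip
    s2 = np.einsum("ij,ij->i", svec, svec)
    keep = s2 <= (1.0 / d_min) ** 2 + 1e-12
    H = H[keep]
    s2 = s2[keep]
    mask = _unique_half_space(H)
    H, s2 = H[mask], s2[mask]

    frac = cell.fractionalize(model.xyz)
    F = np.zeros(len(H), complex)
    for R, t in ops:
        xf = frac @ R.T + t
        for elem in np.unique(model.element):
            sel = model.element == elem
            z = ELEMENT_Z.get(str(elem), 6.0)
            damping = z * np.exp(-(b_overall + np.mean(model.b_iso[sel])) * s2 / 4.0)
            phase = np.exp(2j * np.pi * (H @ xf[sel].T))
            F += damping * (phase @ model.occ[sel])
    amp = np.abs(F)
    phi = np.degrees(np.angle(F))
    phi[amp < 1e-12] = 0.0
    return ReflectionSet(H, amp, phi, _centric_flags(H, ops), cell, ops)


# ---------------------------------------------------------------------------
# Phase biasing
# ---------------------------------------------------------------------------

@dataclass
class PhaseBiasResult:
    """Outcome of phase degradation: biased reflections plus realized stats."""

    reflections: ReflectionSet
    mean_phase_error: float  # realized <|dphi|> in degrees
    fom: float               # realized <cos dphi>
    seed: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.fom <= 1.0
        assert 0.0 <= self.mean_phase_error <= 180.0


def apply_uniform_phase_noise(
    refl: ReflectionSet, half_width: float, seed: int = 0
) -> ReflectionSet:
    """Add Uniform(-a, +a) noise (degrees) to every phase; no calibration.

    For acentric data the expected mean |Δφ| is a/2 and the expected figure
    of merit is sin(a)/a (a in radians).
    """
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-half_width, half_width, size=len(refl))
    out = dataclasses.replace(refl)
    out.phi = refl.phi + noise
    return out


def bias_phases(
    refl: ReflectionSet, target_mean_error: float, seed: int = 0
) -> PhaseBiasResult:
    """Degrade phases to a prescribed mean phase difference.

    Acentric phases receive uniform noise whose amplitude is calibrated so
    that the realized mean |Δφ| over acentrics equals the target exactly;
    a fraction of centric phases (target/180, the value that preserves the
    overall mean) is inverted.  Realized statistics are recomputed from the
    biased phases themselves.
    """
    if not 0.0 <= target_mean_error <= 90.0:
        raise ValueError("target mean phase error must be in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    n = len(refl)
    dphi = np.zeros(n)
    acentric = ~refl.centric
    n_ac = int(acentric.sum())
    if target_mean_error > 0:
        if n_ac:
            u = rng.uniform(-1.0, 1.0, size=n_ac)
            mean_abs = np.abs(u).mean()
            a = target_mean_error / mean_abs if mean_abs > 0 else 0.0
            a = min(a, 180.0 / np.abs(u).max()) if np.abs(u).max() > 0 else a
            dphi[acentric] = a * u
        n_ce = n - n_ac
        if n_ce:
            # number of sign flips that keeps the overall mean on target
            realized_ac = np.abs(dphi[acentric]).sum()
            k = int(round((target_mean_error * n - realized_ac) / 180.0))
            k = min(max(k, 0), n_ce)
            flip_idx = rng.choice(np.where(refl.centric)[0], size=k, replace=False)
            dphi[flip_idx] = 180.0
    out = dataclasses.replace(refl)
    out.phi = refl.phi + dphi
    wrapped = np.abs((dphi + 180.0) % 360.0 - 180.0)
    mean_err = float(wrapped.mean()) if n else 0.0
    fom = float(np.cos(np.radians(dphi)).mean()) if n else 1.0
    return PhaseBiasResult(out, mean_err, fom, seed)


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Density values on a grid covering exactly one unit cell.

    ``grid[i, j, k]`` is the density at fractional position
    ``(i/n1, j/n2, k/n3)``.  Maps used by the detection pipeline are
    normalized to zero mean and unit standard deviation.
    """

    grid: np.ndarray
    cell: UnitCell
    ops: SymmetryOps = field(default_factory=SymmetryOps.p1)
    normalized: bool = False
    info: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.grid.size

    def normalize(self) -> "DensityMap":
        sd = float(self.grid.std())
        if sd < 1e-12:
            raise ValueError("cannot normalize a zero-variance map")
        new = dataclasses.replace(self)
        new.grid = (self.grid - self.grid.mean()) / sd
        new.normalized = True
        return new

    def _frac_index(self, xyz: np.ndarray) -> np.ndarray:
        frac = self.cell.fractionalize(np.atleast_2d(xyz)) % 1.0
        return frac * np.array(self.grid.shape)

    def interpolate(self, xyz: np.ndarray) -> np.ndarray:
        """Periodic trilinear interpolation at Cartesian positions (Å)."""
        g = self._frac_index(xyz)
        i0 = np.floor(g).astype(int)
        w = g - i0
        n = np.array(self.grid.shape)
        vals = np.zeros(len(g))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = (i0 + off) % n
            weight = np.prod(np.where(off == 1, w, 1.0 - w), axis=1)
            vals += weight * self.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        return vals if np.ndim(xyz) > 1 else vals

    def interpolate_gradient(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian gradient (per Å) of the trilinear interpolant."""
        g = self._frac_index(xyz)
        i0 = np.floor(g).astype(int)
        w = g - i0
        n = np.array(self.grid.shape)
        dfrac = np.zeros((len(g), 3))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = (i0 + off) % n
            v = self.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
            terms = np.where(off == 1, w, 1.0 - w)
            sign = np.where(off == 1, 1.0, -1.0)
            for axis in range(3):
                others = [a for a in range(3) if a != axis]
                dfrac[:, axis] += v * sign[axis] * terms[:, others[0]] * terms[:, others[1]]
        # d/dx = d/dfrac * dfrac/dgridindex(n) * dfrac/dx
        return (dfrac * n) @ self.cell.cart_to_frac

    # -- CCP4/MRC I/O -------------------------------------------------------

    def write_ccp4(self, path: str) -> None:
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(self.grid, np.float32),
                                 self.cell.to_gemmi(), gemmi.find_spacegroup_by_name("P 1"))
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def read_ccp4(cls, path: str, ops: SymmetryOps | None = None) -> "DensityMap":
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
        g = np.array(m.grid, float)
        c = m.grid.unit_cell
        return cls(g, UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
                   ops or SymmetryOps.p1())


def _grid_shape(cell: UnitCell, d_min: float, grid_factor: float) -> tuple[int, int, int]:
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = int(np.ceil(length * grid_factor / d_min))
        n = next_fast_len(max(n, 4), real=True)
        if n % 2:
            n = next_fast_len(n + 1, real=True)
        dims.append(n)
    return tuple(dims)


def synthesize_map(
    refl: ReflectionSet,
    cell: UnitCell | None = None,
    ops: SymmetryOps | None = None,
    grid_factor: float = 3.0,
    normalize: bool = True,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Fourier synthesis of a density map from (F, φ) by inverse FFT.

    The reflection list is expanded to the full sphere (symmetry operators
    plus Friedel mates) before the transform.  Grid spacing is at most
    d_min / grid_factor along each axis.  The map is normalized to zero
    mean and unit standard deviation unless ``normalize=False``.
    """
    if len(refl) == 0:
        raise ValueError("empty reflection set")
    cell = cell or refl.cell
    ops = ops or refl.ops
    shape = shape or _grid_shape(cell, refl.d_min, grid_factor)
    coeff = np.zeros(shape, complex)
    seen: set[tuple[int, int, int]] = set()

    def put(h: np.ndarray, value: complex) -> None:
        key = (int(h[0]), int(h[1]), int(h[2]))
        if key in seen:
            return
        seen.add(key)
        coeff[key[0] % shape[0], key[1] % shape[1], key[2] % shape[2]] += value

    f_complex = refl.f * np.exp(1j * np.radians(refl.phi))
    for R, t in ops:
        h_img = refl.hkl @ np.asarray(R, int)
        shift = np.exp(-2j * np.pi * (refl.hkl @ np.asarray(t, float)))
        vals = f_complex * shift
        for h, v in zip(h_img, vals):
            put(h, v)
            put(-h, np.conj(v))
    # rho(x) = (1/V) sum_h F exp(i phi) exp(-2 pi i h.x); the forward FFT
    # carries the e^{-2 pi i} kernel
    grid = np.real(fftn(coeff)) / cell.volume
    out = DensityMap(grid, cell, ops, info={"d_min": refl.d_min})
    return out.normalize() if normalize else out


def generate_benchmark_grid(
    model: AtomicModel,
    refl: ReflectionSet,
    seed: int = 0,
    resolutions: Sequence[float] = BENCHMARK_RESOLUTIONS,
    phase_errors: Sequence[float] = BENCHMARK_PHASE_ERRORS,
) -> list[DensityMap]:
    """Simulated benchmark maps: resolutions x phase-error levels (12 by default).

    Amplitudes are trimmed to each resolution, phases are biased to each
    target mean phase error, and each resulting map is tagged with its
    realized figure of merit in ``map.info``.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if refl.d_min > min(resolutions) + 0.05:
        raise ValueError(
            f"reflections extend only to {refl.d_min:.2f} Å; "
            f"need {min(resolutions)} Å"
        )
    maps = []
    idx = 0
    for res in resolutions:
        trimmed = refl.trim(res)
        for err in phase_errors:
            sub_seed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % (2**31))
            biased = bias_phases(trimmed, err, seed=sub_seed)
            dmap = synthesize_map(biased.reflections)
            dmap.info.update(
                resolution=res,
                target_phase_error=err,
                realized_phase_error=biased.mean_phase_error,
                fom=biased.fom,
                seed=sub_seed,
            )
            maps.append(dmap)
            idx += 1
    return maps
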