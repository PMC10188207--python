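"""Reaction-coordinate and free-energy-landscape analysis of trajectories.

Frames (multi-model PDB or plain XYZ) are reduced to two reaction
coordinates — radius of gyration Rg (Å) and α-helical fraction — whose 2D
occupancy histogram gives a potential of mean force

    PMF(bin) = -kB*T * ln(n_bin / n_max)

zero at the most populated bin and +inf where unvisited.  Basins are grown
from grid local minima by steepest-descent assignment and merged across
sub-thermal barriers; representative frames are drawn from a basin within
windows around its mean coordinates, thinned to a minimum time separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import T_LANDSCAPE_K, kt_kcal

# helical Ramachandran window (degrees) and the minimum run length
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-67.0, -7.0)
MIN_HELIX_RUN = 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameCoords:
    """Per-atom coordinates (Å) of one trajectory frame."""

    coords: np.ndarray
    atom_names: list[str]
    res_ids: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape[0] != len(self.atom_names):
            raise ValueError("coords and atom_names length mismatch")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class ReactionCoordSeries:
    """Per-frame (Rg, helicity) series with times and replica temperature."""

    frame: np.ndarray
    time_ns: np.ndarray
    rg_a: np.ndarray
    f_alpha: np.ndarray
    temperature_k: float = T_LANDSCAPE_K
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=int)
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.rg_a = np.asarray(self.rg_a, dtype=float)
        self.f_alpha = np.asarray(self.f_alpha, dtype=float)
        if self.time_ns.size > 1 and np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any((self.f_alpha < 0) | (self.f_alpha > 1)):
            raise ValueError("f_alpha must lie in [0, 1]")

    def __len__(self) -> int:
        return self.frame.size

    def to_tsv(self, path) -> None:
        header = [
            f"# temperature_K\t{self.temperature_k}",
            *(f"# {k}\t{v}" for k, v in self.meta.items()),
        ]
        frame = pd.DataFrame(
            {
                "frame": self.frame,
                "time_ns": self.time_ns,
                "rg_A": self.rg_a,
                "f_alpha": self.f_alpha,
            }
        )
        Path(path).write_text(
            "\n".join(header) + "\n"
            + frame.to_csv(sep="\t", index=False, lineterminator="\n", float_format="%.17g")
        )

    @classmethod
    def from_tsv(cls, path) -> "ReactionCoordSeries":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value
        temperature = float(meta.pop("temperature_K", T_LANDSCAPE_K))
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        return cls(
            frame=frame["frame"].to_numpy(),
            time_ns=frame["time_ns"].to_numpy(),
            rg_a=frame["rg_A"].to_numpy(),
            f_alpha=frame["f_alpha"].to_numpy(),
            temperature_k=temperature,
            meta=meta,
        )


@dataclass
class Basin:
    """A connected set of PMF bins around one local minimum."""

    label: str
    bins: set
    minimum: tuple[int, int]
    min_pmf: float
    mean_rg: float
    mean_f_alpha: float


@dataclass
class PMFSurface:
    """Binned free energy over (Rg, helicity), zero at the global minimum."""

    rg_edges: np.ndarray
    fa_edges: np.ndarray
    pmf: np.ndarray
    counts: np.ndarray
    temperature_k: float
    basins: list[Basin] = field(default_factory=list)

    @property
    def rg_centers(self) -> np.ndarray:
        return 0.5 * (self.rg_edges[:-1] + self.rg_edges[1:])

    @property
    def fa_centers(self) -> np.ndarray:
        return 0.5 * (self.fa_edges[:-1] + self.fa_edges[1:])

    def to_tsv(self, path) -> None:
        rows = []
        for i, rg in enumerate(self.rg_centers):
            for j, fa in enumerate(self.fa_centers):
                rows.append((rg, fa, self.pmf[i, j], self.counts[i, j]))
        frame = pd.DataFrame(
            rows, columns=["rg_A", "f_alpha", "pmf_kcal_mol", "count"]
        )
        Path(path).write_text(
            f"# temperature_K\t{self.temperature_k}\n"
            + frame.to_csv(sep="\t", index=False, lineterminator="\n", float_format="%.17g")
        )


# ---------------------------------------------------------------------------
# structure readers
# ---------------------------------------------------------------------------

def load_pdb(path) -> list[FrameCoords]:
    """Read a (multi-model) PDB into per-frame coordinates in Å."""
    import mdtraj as md

    traj = md.load(str(path))
    atom_names = [a.name for a in traj.topology.atoms]
    res_ids = np.array([a.residue.resSeq for a in traj.topology.atoms])
    masses = np.array([a.element.mass for a in traj.topology.atoms])
    return [
        FrameCoords(
            coords=xyz * 10.0,  # nm -> Å
            atom_names=atom_names,
            res_ids=res_ids,
            masses=masses,
        )
        for xyz in traj.xyz
    ]


def load_xyz(path) -> list[FrameCoords]:
    """Read a plain multi-frame XYZ file (coordinates assumed in Å)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        names, coords = [], []
        for row in block:
            parts = row.split()
            names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(
            FrameCoords(
                coords=np.array(coords),
                atom_names=names,
                res_ids=np.arange(n),
            )
        )
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# reaction coordinates
# ---------------------------------------------------------------------------

def radius_of_gyration(
    frame: FrameCoords,
    selection: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> float:
    """RMS distance of (selected) atoms from their (weighted) centroid, Å."""
    coords = frame.coords
    weights = (
        frame.masses
        if (mass_weighted and frame.masses is not None)
        else np.ones(frame.n_atoms)
    )
    if selection is not None:
        coords = coords[selection]
        weights = np.asarray(weights)[selection]
    if coords.shape[0] < 1:
        raise ValueError("empty atom selection")
    center = np.average(coords, axis=0, weights=weights)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=weights)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(frame: FrameCoords):
    """Per-residue (phi, psi) in degrees; NaN where not computable."""
    residues = sorted(set(frame.res_ids.tolist()))
    atom_of = {}
    for idx, (name, rid) in enumerate(zip(frame.atom_names, frame.res_ids)):
        atom_of[(int(rid), name)] = idx

    def _pos(rid, name):
        idx = atom_of.get((rid, name))
        return None if idx is None else frame.coords[idx]

    phi = np.full(len(residues), np.nan)
    psi = np.full(len(residues), np.nan)
    for k, rid in enumerate(residues):
        n, ca, c = _pos(rid, "N"), _pos(rid, "CA"), _pos(rid, "C")
        c_prev = _pos(rid - 1, "C")
        n_next = _pos(rid + 1, "N")
        if all(p is not None for p in (c_prev, n, ca, c)):
            phi[k] = dihedral_deg(c_prev, n, ca, c)
        if all(p is not None for p in (n, ca, c, n_next)):
            psi[k] = dihedral_deg(n, ca, c, n_next)
    return np.array(residues), phi, psi


def helical_fraction(frame: FrameCoords) -> float:
    """Fraction of assignable residues in α-helical runs of length >= 3.

    A residue is helical when (phi, psi) fall in the helical Ramachandran
    window; isolated helical residues (runs shorter than 3) do not count.
    Residues lacking either dihedral are excluded from the denominator.
    """
    _, phi, psi = backbone_dihedrals(frame)
    assignable = np.isfinite(phi) & np.isfinite(psi)
    if assignable.sum() < MIN_HELIX_RUN:
        raise ValueError("need backbone dihedrals for >= 3 consecutive residues")
    in_window = (
        assignable
        & (phi >= PHI_WINDOW[0]) & (phi <= PHI_WINDOW[1])
        & (psi >= PSI_WINDOW[0]) & (psi <= PSI_WINDOW[1])
    )
    helical = np.zeros_like(in_window)
    run_start = None
    for i, flag in enumerate(np.append(in_window, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= MIN_HELIX_RUN:
                helical[run_start:i] = True
            run_start = None
    return float(helical.sum() / assignable.sum())


def series_from_frames(
    frames: list[FrameCoords],
    frame_dt_ns: float = 0.5,
    temperature_k: float = T_LANDSCAPE_K,
    selection: np.ndarray | None = None,
) -> ReactionCoordSeries:
    """Reduce structural frames to the (Rg, helicity) series."""
    rg = np.array([radius_of_gyration(f, selection) for f in frames])
    fa = np.array([helical_fraction(f) for f in frames])
    idx = np.arange(len(frames))
    return ReactionCoordSeries(
        frame=idx,
        time_ns=(idx + 1) * frame_dt_ns,
        rg_a=rg,
        f_alpha=fa,
        temperature_k=temperature_k,
    )


# ---------------------------------------------------------------------------
# PMF and basins
# ---------------------------------------------------------------------------

def pmf2d(
    series: ReactionCoordSeries,
    bins: int | tuple[int, int] = 50,
    temperature_k: float | None = None,
    ranges=None,
) -> PMFSurface:
    """2D potential of mean force over (Rg, helicity).

    Default grid is ``bins x bins`` over the observed ranges padded by 5%.
    """
    if len(series) < 100:
        raise ValueError("need >= 100 frames for a meaningful PMF")
    temperature = (
        temperature_k if temperature_k is not None else series.temperature_k
    )
    if ranges is None:
        def _pad(values):
            lo, hi = float(values.min()), float(values.max())
            pad = 0.05 * (hi - lo) or 0.5
            return lo - pad, hi + pad

        ranges = (_pad(series.rg_a), _pad(series.f_alpha))
    counts, rg_edges, fa_edges = np.histogram2d(
        series.rg_a, series.f_alpha, bins=bins, range=ranges
    )
    n_max = counts.max()
    if (counts > 0).sum() <= 1:
        warnings.warn("all frames fall in a single bin: degenerate surface")
    with np.errstate(divide="ignore"):
        pmf = np.where(
            counts > 0,
            -kt_kcal(temperature) * np.log(counts / n_max),
            np.inf,
        )
    return PMFSurface(
        rg_edges=rg_edges,
        fa_edges=fa_edges,
        pmf=pmf,
        counts=counts,
        temperature_k=temperature,
    )


def _neighbors(i, j, shape):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                yield ni, nj


def find_basins(
    surface: PMFSurface, depth_threshold: float = 3.0
) -> list[Basin]:
    """Locate free-energy basins on the PMF grid.

    Local minima below ``depth_threshold`` (kcal/mol above the global
    minimum) seed basins; every finite bin is assigned to the minimum it
    reaches by steepest descent, and basins separated by a barrier lower
    than 0.5 kB*T are merged.  Basins are labeled by increasing minimum PMF.
    """
    pmf = surface.pmf
    shape = pmf.shape
    minima = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not np.isfinite(pmf[i, j]) or pmf[i, j] >= depth_threshold:
                continue
            if all(
                pmf[i, j] <= pmf[ni, nj] for ni, nj in _neighbors(i, j, shape)
            ):
                minima.append((i, j))
    if not minima:
        return []

    # steepest-descent assignment of every finite bin
    assignment = {}

    def _descend(start):
        path = []
        cell = start
        while cell not in assignment:
            path.append(cell)
            i, j = cell
            best, best_val = cell, pmf[i, j]
            for ni, nj in _neighbors(i, j, shape):
                if np.isfinite(pmf[ni, nj]) and pmf[ni, nj] < best_val:
                    best, best_val = (ni, nj), pmf[ni, nj]
            if best == cell:
                root = cell if cell in minima else None
                for c in path:
                    assignment[c] = root
                return
            cell = best
        root = assignment[cell]
        for c in path:
            assignment[c] = root

    for i in range(shape[0]):
        for j in range(shape[1]):
            if np.isfinite(pmf[i, j]):
                _descend((i, j))

    groups = {m: set() for m in minima}
    for cell, root in assignment.items():
        if root is not None:
            groups[root].add(cell)

    # merge basins whose mutual barrier is below 0.5 kT; barriers come from
    # a single pass over inter-basin boundary bins
    merge_cut = 0.5 * kt_kcal(surface.temperature_k)
    while len(groups) > 1:
        owner = {}
        for root, cells in groups.items():
            for cell in cells:
                owner[cell] = root
        barriers: dict = {}
        for (i, j), root in owner.items():
            for ni, nj in _neighbors(i, j, shape):
                other = owner.get((ni, nj))
                if other is None or other == root:
                    continue
                key = (root, other) if root < other else (other, root)
                step = max(pmf[i, j], pmf[ni, nj])
                if key not in barriers or step < barriers[key]:
                    barriers[key] = step
        to_merge = None
        for (a, b), barrier in barriers.items():
            base = max(pmf[a], pmf[b])
            if barrier - base < merge_cut:
                to_merge = (a, b)
                break
        if to_merge is None:
            break
        a, b = to_merge
        keep, drop = (a, b) if pmf[a] <= pmf[b] else (b, a)
        groups[keep] |= groups[drop]
        del groups[drop]

    rg_c, fa_c = surface.rg_centers, surface.fa_centers
    basins = []
    for root in sorted(groups, key=lambda m: pmf[m]):
        cells = groups[root]
        weights = np.array([surface.counts[c] for c in cells])
        rg_mean = float(
            np.average([rg_c[c[0]] for c in cells], weights=weights)
        )
        fa_mean = float(
            np.average([fa_c[c[1]] for c in cells], weights=weights)
        )
        basins.append(
            Basin(
                label=f"B{len(basins) + 1}",
                bins=cells,
                minimum=root,
                min_pmf=float(pmf[root]),
                mean_rg=rg_mean,
                mean_f_alpha=fa_mean,
            )
        )
    surface.basins = basins
    return basins


def select_representatives(
    series: ReactionCoordSeries,
    basin: Basin,
    rg_window: float = 5.0,
    fa_window: float = 0.02,
    min_separation_ns: float = 0.5,
    min_history: int = 10_000,
) -> np.ndarray:
    """Representative frame indices for a basin.

    Frames must lie within ``rg_window`` Å of the basin mean Rg and
    ``fa_window`` of its mean helicity; accepted frames are thinned to at
    least ``min_separation_ns`` apart.  The basin must carry at least
    ``min_history`` frames of sampling history to be considered converged.
    """
    if not basin.bins:
        raise ValueError("basin is empty")
    in_window = (
        (np.abs(series.rg_a - basin.mean_rg) <= rg_window)
        & (np.abs(series.f_alpha - basin.mean_f_alpha) <= fa_window)
    )
    if in_window.sum() < min_history:
        warnings.warn(
            f"basin {basin.label}: only {int(in_window.sum())} qualifying "
            f"frames (< {min_history} required history)"
        )
        return np.array([], dtype=int)
    candidates = np.nonzero(in_window)[0]
    selected = []
    last_time = -np.inf
    for idx in candidates:
        if series.time_ns[idx] - last_time >= min_separation_ns:
            selected.append(int(idx))
            last_time = series.time_ns[idx]
    if not selected:
        warnings.warn(f"basin {basin.label}: no qualifying frames")
    return np.array(selected, dtype=int)
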