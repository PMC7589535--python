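"""Coarse-grained dye models: accessible volumes, inter-dye observables and
distance uncertainties.

A fluorophore on a flexible linker is modeled geometrically: the set of all
sterically allowed dye positions (accessible volume, AV) is enumerated on a
regular grid around the attachment atom.  A grid point belongs to the AV if
(a) a sphere of the dye radius centered there does not overlap any protein
heavy atom's van-der-Waals sphere and (b) the shortest obstacle-avoiding
path from the attachment point, computed by a weighted flood fill over the
26-connected grid graph, does not exceed the linker length.  The
accessible-contact-volume (ACV) variant additionally up-weights positions
in a thin layer near the protein surface to model dye sticking.

Observables derived from AV pairs are the distribution-averaged inter-dye
distance (mean_RDA) and the distance between mean dye positions (Rmp).
Distance uncertainties follow from propagating a FRET-efficiency error
through E(R) = 1 / (1 + (R/R0)^6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import EmptyVolumeError
from .structure_io import Conformer

__all__ = [
    "VDW_RADII",
    "LabelingSite",
    "AccessibleVolume",
    "FRETPair",
    "DistanceRecord",
    "MeasurementSet",
    "ACVParams",
    "compute_av",
    "model_distance",
    "distance_error_from_efficiency",
    "simulate_measurements",
    "write_av_xyz",
    "write_av_opendx",
]

#: Van-der-Waals radii (Angstrom) used for the dye clash check.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
_DEFAULT_VDW = 1.7

#: Fixed seed for the stochastic mean_RDA estimator (documented default).
DEFAULT_AV_SEED = 1234567

#: Exhaustive pair averaging is used when n_donor * n_acceptor is below this.
_EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class LabelingSite:
    """Definition of a dye attachment point and its linker/dye geometry.

    Defaults correspond to a typical cyanine-class dye on a long
    maleimide linker: 20 A linker length, 4.5 A linker width and a
    three-radius ellipsoid approximation (3.5 / 4.5 / 1.5 A).
    """

    chain_id: str
    res_id: int
    atom_name: str = "CB"
    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radii: tuple[float, ...] = (3.5, 4.5, 1.5)
    role: str = "donor"

    def __post_init__(self):
        if self.linker_length <= 0 or self.linker_width <= 0:
            raise ValueError("linker length and width must be positive")
        if any(r <= 0 for r in self.dye_radii):
            raise ValueError("dye radii must be positive")
        if self.role not in ("donor", "acceptor"):
            raise ValueError("site role must be 'donor' or 'acceptor'")

    @property
    def site_id(self) -> str:
        return f"{self.chain_id}:{self.res_id}:{self.atom_name}"


@dataclass(frozen=True)
class ACVParams:
    """Contact-layer parameters for the accessible contact volume model."""

    thickness: float = 3.0
    contact_fraction: float = 0.5


@dataclass
class AccessibleVolume:
    """Positional cloud of a tethered dye with per-point weights."""

    points: np.ndarray  # (M, 3) grid positions, Angstrom
    weights: np.ndarray  # (M,) nonnegative, sum to 1 when non-empty
    attachment_position: np.ndarray  # (3,)
    grid_spacing: float
    empty: bool = False

    @property
    def mean_position(self) -> np.ndarray:
        if self.empty:
            raise EmptyVolumeError("mean position of an empty accessible volume")
        return self.weights @ self.points

    @property
    def n_points(self) -> int:
        return 0 if self.empty else self.points.shape[0]


@dataclass(frozen=True)
class FRETPair:
    """A donor/acceptor labeling-site pair with its Forster radius."""

    donor: LabelingSite
    acceptor: LabelingSite
    r0: float = 52.0
    pair_id: str = ""

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("Forster radius must be positive")
        if self.donor.site_id == self.acceptor.site_id:
            raise ValueError("donor and acceptor sites must differ")
        if not self.pair_id:
            object.__setattr__(
                self, "pair_id", f"{self.donor.site_id}--{self.acceptor.site_id}"
            )


@dataclass(frozen=True)
class DistanceRecord:
    """One reference inter-dye distance with its uncertainty."""

    pair_id: str
    r_ref: float
    dr_ref: float
    provenance: str = "simulated"

    def __post_init__(self):
        if self.r_ref <= 0 or self.dr_ref <= 0:
            raise ValueError("distance and uncertainty must be positive")


@dataclass
class MeasurementSet:
    """A set of reference distances, one per FRET pair."""

    records: list[DistanceRecord]
    skipped_sites: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.pair_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("pair ids must be unique")
        if not self.records:
            raise ValueError("a measurement set needs at least one record")

    @property
    def n_measurements(self) -> int:
        return len(self.records)

    @property
    def pair_ids(self) -> list[str]:
        return [r.pair_id for r in self.records]

    def __getitem__(self, pair_id: str) -> DistanceRecord:
        for r in self.records:
            if r.pair_id == pair_id:
                return r
        raise KeyError(pair_id)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "pair_id": [r.pair_id for r in self.records],
                "r_ref": [r.r_ref for r in self.records],
                "dr_ref": [r.dr_ref for r in self.records],
                "provenance": [r.provenance for r in self.records],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSet":
        df = pd.read_csv(path)
        return cls(
            [
                DistanceRecord(
                    str(row.pair_id),
                    float(row.r_ref),
                    float(row.dr_ref),
                    str(getattr(row, "provenance", "experimental")),
                )
                for row in df.itertuples(index=False)
            ]
        )


# ---------------------------------------------------------------------------
# Accessible volume
# ---------------------------------------------------------------------------

# the 13 lexicographically positive offsets of the 26-neighborhood
_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _surface_distance_grid(
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    obstacles: np.ndarray,
    vdw: np.ndarray,
    reach: float,
) -> np.ndarray:
    """Distance from every grid point to the nearest obstacle vdW surface.

    Only distances below ``reach`` are exact; larger values are reported as
    ``reach`` (sufficient, since only thresholds below ``reach`` are used).
    """
    ax, ay, az = grid_axes
    shape = (ax.size, ay.size, az.size)
    dsurf = np.full(shape, reach)
    spacing = ax[1] - ax[0] if ax.size > 1 else 1.0
    for p, v in zip(obstacles, vdw):
        w = v + reach + spacing
        ix = np.searchsorted(ax, [p[0] - w, p[0] + w])
        iy = np.searchsorted(ay, [p[1] - w, p[1] + w])
        iz = np.searchsorted(az, [p[2] - w, p[2] + w])
        sx, sy, sz = slice(*ix), slice(*iy), slice(*iz)
        dx = ax[sx] - p[0]
        dy = ay[sy] - p[1]
        dz = az[sz] - p[2]
        d = (
            np.sqrt(
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            )
            - v
        )
        np.minimum(dsurf[sx, sy, sz], d, out=dsurf[sx, sy, sz])
    return dsurf


def _grid_path_distances(
    traversable: np.ndarray,
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    attachment: np.ndarray,
    spacing: float,
    source_radius: float = 3.0,
) -> np.ndarray:
    """Shortest obstacle-avoiding path length from the attachment point to
    every traversable grid node (Dijkstra over the 26-connected free grid).

    Returns an array shaped like ``traversable`` with +inf on unreachable or
    blocked nodes.
    """
    shape = traversable.shape
    n_nodes = int(traversable.sum())
    out = np.full(shape, np.inf)
    if n_nodes == 0:
        return out
    idx = -np.ones(shape, dtype=np.int64)
    idx[traversable] = np.arange(n_nodes)

    rows, cols, data = [], [], []
    for off in _OFFSETS:
        src = tuple(
            slice(max(0, -o), shape[k] - max(0, o)) for k, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), shape[k] - max(0, -o)) for k, o in enumerate(off)
        )
        mask = traversable[src] & traversable[dst]
        if not np.any(mask):
            continue
        rows.append(idx[src][mask])
        cols.append(idx[dst][mask])
        data.append(
            np.full(int(mask.sum()), spacing * float(np.linalg.norm(off)))
        )

    # virtual source: traversable nodes near the attachment point, weighted
    # by their Euclidean distance to it (the linker emerges from the
    # attachment atom, where the immediate neighborhood may be sterically
    # blocked by the attachment residue itself)
    ax, ay, az = grid_axes
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    euclid = np.sqrt(
        (X - attachment[0]) ** 2 + (Y - attachment[1]) ** 2 + (Z - attachment[2]) ** 2
    )
    source = n_nodes
    near = traversable & (euclid <= source_radius)
    if not np.any(near):
        # no free grid node next to the attachment: the site is buried
        return out
    rows.append(idx[near])
    cols.append(np.full(int(near.sum()), source))
    data.append(euclid[near])

    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_nodes + 1, n_nodes + 1),
    )
    dist = dijkstra(graph, directed=False, indices=source)
    out[traversable] = dist[:n_nodes]
    return out


def compute_av(
    conf: Conformer,
    site: LabelingSite,
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
) -> AccessibleVolume:
    """Simulate the accessible volume of a dye tethered at ``site``.

    With several dye radii, the AV is the union of the per-radius volumes
    with equal (1/3 each for three radii) total weight per radius.  With
    ``acv`` given, accessible points within the contact layer of the protein
    surface are re-weighted so that their total weight equals
    ``acv.contact_fraction``.
    """
    attach_idx = conf.find_atom(site.chain_id, site.res_id, site.atom_name)
    attach = conf.atoms.coord[attach_idx].astype(float)

    elements = conf.atoms.element
    heavy = elements != "H"
    heavy[attach_idx] = False  # the linker replaces the attachment atom
    obstacles = conf.atoms.coord[heavy].astype(float)
    vdw = np.array([VDW_RADII.get(e, _DEFAULT_VDW) for e in elements[heavy]])

    rmax = site.linker_length + max(site.dye_radii)
    n = int(np.ceil(rmax / grid_spacing))
    offsets = np.arange(-n, n + 1) * grid_spacing
    axes = (attach[0] + offsets, attach[1] + offsets, attach[2] + offsets)

    reach = max(max(site.dye_radii), site.linker_width / 2.0)
    if acv is not None:
        reach = max(reach, acv.thickness + min(site.dye_radii))
    reach += grid_spacing
    # restrict obstacles to those that can influence the grid
    if obstacles.shape[0]:
        close = np.linalg.norm(obstacles - attach, axis=1) <= rmax + vdw.max() + reach
        obstacles, vdw = obstacles[close], vdw[close]
    dsurf = _surface_distance_grid(axes, obstacles, vdw, reach)

    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r_euclid = np.sqrt(
        (X - attach[0]) ** 2 + (Y - attach[1]) ** 2 + (Z - attach[2]) ** 2
    )
    in_sphere = r_euclid <= rmax

    traversable = in_sphere & (dsurf >= site.linker_width / 2.0)
    # the linker emerges from the attachment atom, whose immediate shell is
    # sterically crowded by its own residue: seed the flood fill from free
    # nodes within a small radius of the attachment (buried if none)
    source_radius = max(3.0, 2 * grid_spacing, site.linker_width / 2.0 + grid_spacing)
    path = _grid_path_distances(
        traversable, axes, attach, grid_spacing, source_radius
    )

    weight = np.zeros(dsurf.shape)
    share = 1.0 / len(site.dye_radii)
    for r_dye in site.dye_radii:
        acc = traversable & (dsurf >= r_dye) & (path <= site.linker_length)
        n_acc = int(acc.sum())
        if n_acc:
            weight[acc] += share / n_acc

    total = weight.sum()
    if total <= 0:
        return AccessibleVolume(
            points=np.empty((0, 3)),
            weights=np.empty(0),
            attachment_position=attach,
            grid_spacing=grid_spacing,
            empty=True,
        )
    weight /= total  # renormalize in case a radius variant was empty

    mask = weight > 0
    points = np.column_stack([X[mask], Y[mask], Z[mask]])
    weights = weight[mask]

    if acv is not None:
        contact = dsurf[mask] <= acv.thickness + min(site.dye_radii)
        wc = weights[contact].sum()
        if 0 < wc < 1:
            weights = weights.copy()
            weights[contact] *= acv.contact_fraction / wc
            weights[~contact] *= (1.0 - acv.contact_fraction) / (1.0 - wc)

    return AccessibleVolume(
        points=points,
        weights=weights,
        attachment_position=attach,
        grid_spacing=grid_spacing,
    )


def write_av_xyz(av: AccessibleVolume, path: str | Path, element: str = "D") -> None:
    """Export an AV point cloud in XYZ format for visual inspection."""
    with open(path, "w") as fh:
        fh.write(f"{av.n_points}\naccessible volume point cloud\n")
        for p in av.points:
            fh.write(f"{element} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")


def write_av_opendx(av: AccessibleVolume, path: str | Path) -> None:
    """Export an AV as an OpenDX regular-grid density (weights per voxel)."""
    if av.empty:
        raise EmptyVolumeError("cannot export an empty accessible volume")
    h = av.grid_spacing
    origin = av.points.min(axis=0)
    idx = np.round((av.points - origin) / h).astype(int)
    shape = idx.max(axis=0) + 1
    density = np.zeros(shape)
    density[idx[:, 0], idx[:, 1], idx[:, 2]] = av.weights
    nx, ny, nz = shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {origin[0]:.4f} {origin[1]:.4f} {origin[2]:.4f}",
        f"delta {h:.4f} 0 0",
        f"delta 0 {h:.4f} 0",
        f"delta 0 0 {h:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = density.ravel()  # x fastest-varying last, OpenDX convention
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def model_distance(
    av_d: AccessibleVolume,
    av_a: AccessibleVolume,
    kind: str = "mean_RDA",
    n_samples: int = 100_000,
    seed: int = DEFAULT_AV_SEED,
) -> float:
    """Inter-dye distance observable from two accessible volumes.

    ``"Rmp"`` is the distance between the mean dye positions; ``"mean_RDA"``
    is the weighted average over all point-pair distances, evaluated
    exhaustively when the pair count permits and otherwise by seeded
    weighted Monte-Carlo sampling.
    """
    if av_d.empty or av_a.empty:
        raise EmptyVolumeError("cannot compute a distance from an empty AV")
    if kind == "Rmp":
        return float(np.linalg.norm(av_d.mean_position - av_a.mean_position))
    if kind != "mean_RDA":
        raise ValueError(f"unknown distance kind {kind!r}")
    nd, na = av_d.n_points, av_a.n_points
    if nd * na <= _EXHAUSTIVE_LIMIT:
        diff = av_d.points[:, None, :] - av_a.points[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        return float(av_d.weights @ dist @ av_a.weights)
    rng = np.random.default_rng(seed)
    i = rng.choice(nd, size=n_samples, p=av_d.weights)
    j = rng.choice(na, size=n_samples, p=av_a.weights)
    return float(np.mean(np.linalg.norm(av_d.points[i] - av_a.points[j], axis=1)))


def fret_efficiency(r: float, r0: float) -> float:
    """Transfer efficiency E(R) = 1 / (1 + (R/R0)^6)."""
    return 1.0 / (1.0 + (r / r0) ** 6)


def distance_error_from_efficiency(
    r: float,
    r0: float,
    d_efficiency: float = 0.06,
    clamp: tuple[float, float] = (0.5, 30.0),
) -> float:
    """Distance uncertainty from an absolute FRET-efficiency error.

    Propagates dE through the inverse of E(R) = 1/(1 + (R/R0)^6):
    dR = dE * |dR/dE| = dE * (1 + (R/R0)^6)^2 * R0^6 / (6 R^5).
    The result is clamped to ``clamp`` to keep weights finite for pairs far
    outside the sensitive range around the Forster radius.
    """
    if r <= 0 or r0 <= 0:
        raise ValueError("distances must be positive")
    q = (r / r0) ** 6
    dr = d_efficiency * (1.0 + q) ** 2 * r0**6 / (6.0 * r**5)
    return float(np.clip(dr, clamp[0], clamp[1]))


def simulate_measurements(
    target: Conformer,
    pairs: list[FRETPair],
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    d_efficiency: float = 0.06,
    clamp: tuple[float, float] = (0.5, 30.0),
    noise: bool = False,
    seed: int = 0,
) -> MeasurementSet:
    """Simulate a reference measurement set on a target conformer.

    For each pair, R_ref is the AV-averaged inter-dye distance on the
    target and dR_ref follows from efficiency-error propagation with the
    given dE.  With ``noise`` on, Gaussian noise of scale dR_ref is added
    (seeded).  Pairs with a buried (empty-AV) site are skipped and reported
    in ``skipped_sites``.
    """
    rng = np.random.default_rng(seed)
    av_cache: dict[str, AccessibleVolume] = {}
    records: list[DistanceRecord] = []
    skipped: list[str] = []

    def get_av(site: LabelingSite) -> AccessibleVolume:
        if site.site_id not in av_cache:
            av_cache[site.site_id] = compute_av(target, site, grid_spacing, acv)
        return av_cache[site.site_id]

    for pair in pairs:
        av_d, av_a = get_av(pair.donor), get_av(pair.acceptor)
        if av_d.empty or av_a.empty:
            for site, av in ((pair.donor, av_d), (pair.acceptor, av_a)):
                if av.empty and site.site_id not in skipped:
                    skipped.append(site.site_id)
            continue
        r_ref = model_distance(av_d, av_a, "mean_RDA")
        dr = distance_error_from_efficiency(r_ref, pair.r0, d_efficiency, clamp)
        if noise:
            r_ref = max(1e-3, r_ref + rng.normal(0.0, dr))
        records.append(DistanceRecord(pair.pair_id, r_ref, dr, "simulated"))
    return MeasurementSet(records, skipped_sites=skipped)
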