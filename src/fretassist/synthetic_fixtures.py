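"""Synthetic toy systems: hinge-bending two-segment proteins with labeling
sites, candidate pair pools and simulated reference measurements.

The generator emulates the hinge-bending class of interconversion motions:
two internally rigid helical segments joined by a hinge residue.  The
C-alpha trace is an ideal helix (2.3 A radius, 1.5 A rise, 100 deg twist
per residue, ~3.8 A virtual bonds) and every residue carries a pseudo
C-beta stub pointing away from the helix axis, so accessible-volume
simulation, RMSD/lDDT scoring, screening, pair selection, guided sampling
and restraint generation all run on the same fixture.  Conformers are
parameterized by the hinge angle theta: the second segment is rigidly
rotated about the x axis through the hinge C-alpha.

Reduced realism is deliberate and documented: residues are CA+CB only
(all alanine, vdW 1.7 A) and toy dye parameters are shorter than the
typical experimental ones so the AV grids stay small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .structure_io import Conformer, Ensemble
from .dye_model import (
    FRETPair,
    LabelingSite,
    MeasurementSet,
    simulate_measurements,
)
from .pair_selection import CandidatePairPool, build_pool

__all__ = [
    "HingeToySpec",
    "make_hinge_conformer",
    "make_hinge_ensemble",
    "default_sites",
    "default_pairs",
    "make_benchmark_case",
    "hinge_angle",
    "hinge_angle_between",
]

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_CB_LENGTH = 1.5


@dataclass(frozen=True)
class HingeToySpec:
    """Blueprint of a two-segment hinge toy protein.

    Residues 1..n1 form segment 1, residue n1+1 is the hinge, residues
    n1+2..n1+1+n2 form segment 2.  Toy dye parameters (linker 10 A, width
    3 A, single 2 A dye radius) keep AV grids small while exercising every
    clash and path constraint.  The Forster radius default of 30 A sits in
    the middle of the toy's inter-dye distance range, mirroring how an
    experimentalist matches the dye pair to the expected distances so the
    measurements stay in the sensitive regime.
    """

    n_residues: tuple[int, int] = (20, 20)
    chain_id: str = "A"
    linker_length: float = 10.0
    linker_width: float = 3.0
    dye_radii: tuple[float, ...] = (2.0,)
    r0: float = 30.0
    grid_spacing: float = 1.0
    seed: int = 0

    @property
    def hinge_res_id(self) -> int:
        return self.n_residues[0] + 1

    @property
    def total_residues(self) -> int:
        return self.n_residues[0] + 1 + self.n_residues[1]

    @property
    def segment1(self) -> tuple[int, int]:
        return (1, self.n_residues[0])

    @property
    def segment2(self) -> tuple[int, int]:
        return (self.hinge_res_id + 1, self.total_residues)

    def site(self, res_id: int, role: str) -> LabelingSite:
        return LabelingSite(
            self.chain_id,
            res_id,
            "CB",
            linker_length=self.linker_length,
            linker_width=self.linker_width,
            dye_radii=self.dye_radii,
            role=role,
        )


def _base_coordinates(spec: HingeToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Ideal straight-helix CA and CB coordinates (theta = 0)."""
    n = spec.total_residues
    i = np.arange(n)
    ca = np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
            _HELIX_RISE * i,
        ]
    )
    outward = np.column_stack(
        [np.cos(_HELIX_TWIST * i), np.sin(_HELIX_TWIST * i), np.zeros(n)]
    )
    cb = ca + _CB_LENGTH * outward
    return ca, cb


def make_hinge_conformer(spec: HingeToySpec, theta: float) -> Conformer:
    """Deterministic conformer at hinge angle ``theta`` (degrees).

    Segment 2 (residues after the hinge) is rotated rigidly about the x
    axis through the hinge C-alpha; both segments stay internally rigid.
    """
    ca, cb = _base_coordinates(spec)
    pivot = ca[spec.hinge_res_id - 1]
    rot = Rotation.from_rotvec(np.deg2rad(theta) * np.array([1.0, 0.0, 0.0]))
    moving = np.arange(spec.total_residues) >= spec.hinge_res_id  # 0-based
    ca = ca.copy()
    cb = cb.copy()
    ca[moving] = rot.apply(ca[moving] - pivot) + pivot
    cb[moving] = rot.apply(cb[moving] - pivot) + pivot

    n = spec.total_residues
    atoms = struc.AtomArray(2 * n)
    coords = np.empty((2 * n, 3))
    coords[0::2] = ca
    coords[1::2] = cb
    atoms.coord = coords
    atoms.chain_id = np.full(2 * n, spec.chain_id)
    atoms.res_id = np.repeat(np.arange(1, n + 1), 2)
    atoms.res_name = np.full(2 * n, "ALA")
    atoms.atom_name = np.tile(["CA", "CB"], n)
    atoms.element = np.full(2 * n, "C")
    atoms.hetero = np.zeros(2 * n, dtype=bool)
    return Conformer(atoms, label=f"theta={theta:g}")


def make_hinge_ensemble(spec: HingeToySpec, thetas: list[float]) -> Ensemble:
    """One conformer per hinge angle; clashing angles are flagged."""
    conformers = []
    for theta in thetas:
        conf = make_hinge_conformer(spec, theta)
        ca = conf.ca_coords
        # hinge +/- 2 residues are covalently connected; exempt from check
        lo = spec.hinge_res_id - 3  # 1-based residue ids -> 0-based index
        hi = spec.hinge_res_id + 2
        dmin = np.min(
            np.linalg.norm(ca[:lo, None] - ca[None, hi:], axis=-1)
        )
        if dmin < 3.0:
            warnings.warn(
                f"hinge angle {theta} deg places segments within {dmin:.1f} A "
                "(steric clash)",
                stacklevel=2,
            )
        conformers.append(conf)
    return Ensemble(conformers)


def default_sites(spec: HingeToySpec) -> tuple[list[LabelingSite], list[LabelingSite]]:
    """Three donor sites on segment 1 and three acceptor sites on segment 2.

    Donors sit in the lower half of segment 1 and acceptors in the outer
    half of segment 2, which keeps most inter-dye distances inside the
    sensitive range around the Forster radius and maximizes the lever arm
    of the hinge motion on the measured distances."""
    n1, n2 = spec.n_residues
    seg1 = [max(1, round(n1 * f)) for f in (0.12, 0.35, 0.6)]
    start2 = spec.hinge_res_id + 1
    seg2 = [min(spec.total_residues, start2 + round((n2 - 1) * f)) for f in (0.45, 0.7, 0.95)]
    donors = [spec.site(r, "donor") for r in dict.fromkeys(seg1)]
    acceptors = [spec.site(r, "acceptor") for r in dict.fromkeys(seg2)]
    return donors, acceptors


def default_pairs(spec: HingeToySpec, max_pairs: int | None = None) -> list[FRETPair]:
    """All donor x acceptor combinations across the hinge (the informative
    direction for a hinge-bending motion), optionally truncated."""
    donors, acceptors = default_sites(spec)
    pairs = [
        FRETPair(d, a, r0=spec.r0) for d in donors for a in acceptors
    ]
    return pairs[:max_pairs] if max_pairs else pairs


@dataclass
class BenchmarkCase:
    """A complete synthetic study: ensemble, pool, data and ground truth."""

    ensemble: Ensemble
    pool: CandidatePairPool
    pairs: list[FRETPair]
    measurements: MeasurementSet
    truth: dict = field(default_factory=dict)


def make_benchmark_case(
    spec: HingeToySpec,
    target_theta: float,
    seed_thetas: list[float],
    pair_pool_size: int | None = None,
    d_efficiency: float = 0.06,
    seed: int = 0,
    noise: bool = False,
) -> BenchmarkCase:
    """Simulate a benchmark study on the hinge toy.

    Reference distances are AV-averaged inter-dye distances on the target
    conformer with uncertainties from efficiency-error propagation
    (dE = 0.06 by default); the candidate ensemble holds the seed angles
    (the target angle must not be among them).
    """
    if target_theta in set(seed_thetas):
        raise ValueError("target angle must be excluded from the seed angles")
    target = make_hinge_conformer(spec, target_theta)
    pairs = default_pairs(spec, pair_pool_size)
    meas = simulate_measurements(
        target,
        pairs,
        grid_spacing=spec.grid_spacing,
        d_efficiency=d_efficiency,
        noise=noise,
        seed=seed,
    )
    ensemble = make_hinge_ensemble(spec, seed_thetas)
    pool = build_pool(ensemble, pairs, grid_spacing=spec.grid_spacing)
    return BenchmarkCase(
        ensemble=ensemble,
        pool=pool,
        pairs=pairs,
        measurements=meas,
        truth={"target_theta": target_theta, "seed": seed, "noise": noise},
    )


def hinge_angle(conf: Conformer, spec: HingeToySpec) -> float:
    """Scalar hinge (bend) angle of a conformer in degrees.

    The angle between the conformer's hinge-to-segment-2 direction and the
    same direction in the straight (theta = 0) reference, after aligning
    on segment 1.  For conformers generated by :func:`make_hinge_conformer`
    this recovers theta (up to sign); for conformers produced by arbitrary
    hinge moves it is the bend magnitude, which is the quantity inter-dye
    distances constrain (the azimuthal cone direction of a bend is only
    weakly encoded in distances along an elongated molecule).
    """
    return hinge_angle_between(conf, make_hinge_conformer(spec, 0.0), spec)


def hinge_angle_between(conf_a: Conformer, conf_b: Conformer, spec: HingeToySpec) -> float:
    """Bending-angle deviation (degrees) between two conformers.

    After aligning on segment 1, the angle between the hinge-to-segment-2
    directions (hinge C-alpha to segment-2 C-alpha centroid) is compared.
    This is the hinge *bending* component; twist of a segment about its own
    axis barely moves the labeling sites and is invisible to inter-dye
    distances, so it is deliberately not part of the recovery metric.
    """
    res_a = conf_a.atoms.res_id[conf_a.ca_mask]
    seg1 = res_a <= spec.n_residues[0]
    seg2 = res_a > spec.hinge_res_id
    hinge = res_a == spec.hinge_res_id

    a1, b1 = conf_a.ca_coords[seg1], conf_b.ca_coords[seg1]
    ac, bc = a1.mean(axis=0), b1.mean(axis=0)
    H = (a1 - ac).T @ (b1 - bc)
    U, _, Vt = np.linalg.svd(H)
    R1 = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt

    def direction(ca, hinge_pos):
        v = ca[seg2].mean(axis=0) - hinge_pos
        return v / np.linalg.norm(v)

    ca_a = (conf_a.ca_coords - ac) @ R1 + bc  # a aligned onto b
    u_a = direction(ca_a, ca_a[hinge][0])
    u_b = direction(conf_b.ca_coords, conf_b.ca_coords[hinge][0])
    return float(np.rad2deg(np.arccos(np.clip(u_a @ u_b, -1.0, 1.0))))
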