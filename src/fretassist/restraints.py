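"""Restrained-mean-position (RMP) restraints for FRET-restrained MD.

Dyes are represented implicitly: a pseudoatom sits at the mean position of
each labeling site's accessible volume and is anchored by stiff harmonic
pseudobonds to the C-alpha and C-beta atoms of the attachment residue and
of the residues up to two positions toward either terminus (up to ten
anchors).  Measured donor-acceptor distances act between pseudoatoms via
harmonic-linear restraints: harmonic within one standard error of the
target distance, constant force beyond, capped at F_max = 50 pN to prevent
unphysical unfolding.  Per-pseudoatom force constants are scaled down so
that even with all restraints simultaneously at their cap the net restraint
force on any pseudoatom stays within F_max (collinear restraints share the
budget).  The restraint set serializes to an AMBER NMR-restraint ("DISANG")
file plus a JSON sidecar describing the pseudoatoms for topology patching.

MD execution itself is out of scope: restraints are meant to be
regenerated from a fresh snapshot every ~2 ns by the caller's MD wrapper,
because pseudoatom positions and anchor geometry track the local backbone.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyVolumeError
from .structure_io import Conformer
from .dye_model import (
    ACVParams,
    AccessibleVolume,
    FRETPair,
    LabelingSite,
    MeasurementSet,
    compute_av,
    model_distance,
)

__all__ = [
    "F_MAX",
    "ANCHOR_SCALE",
    "PN_PER_KCAL_MOL_A2",
    "Pseudoatom",
    "HarmonicLinearRestraint",
    "RestraintSet",
    "build_pseudoatoms",
    "restraint_force",
    "tune_force_constants",
    "measurement_to_target",
    "generate_restraints",
    "write_restraint_file",
    "read_restraint_file",
]

#: Empirical cap on each FRET-restraint force and on the per-pseudoatom
#: net restraint force (pN).
F_MAX = 50.0
#: Anchor pseudobond force constants are this multiple of the (tuned)
#: FRET-restraint constants.
ANCHOR_SCALE = 10.0
#: Force-gradient conversion: 1 kcal mol^-1 A^-2 corresponds to 69.48 pN/A.
PN_PER_KCAL_MOL_A2 = 69.48


@dataclass
class Pseudoatom:
    """Mean-dye-position pseudoatom with its backbone anchors."""

    site_id: str
    position: np.ndarray  # (3,) A
    residue: int
    chain_id: str
    # each anchor: (chain, res_id, atom_name, equilibrium distance A)
    anchors: list[tuple[str, int, str, float]] = field(default_factory=list)
    anchor_k: float = 0.0  # pN/A, set after tuning

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class HarmonicLinearRestraint:
    """Distance restraint between two pseudoatoms.

    Harmonic with constant ``k`` within one standard error ``dr`` of the
    target ``r_exp``; constant force k*dr (<= f_max) beyond; continuous at
    the crossover.
    """

    donor_site: str
    acceptor_site: str
    r_exp: float
    dr: float
    k: float  # pN/A
    f_max: float = F_MAX

    def __post_init__(self):
        if self.r_exp <= 0 or self.dr <= 0:
            raise ValueError("target distance and standard error must be positive")
        if self.k * self.dr > self.f_max + 1e-9:
            raise ValueError("cap force k*dr must not exceed f_max")

    @property
    def cap_force(self) -> float:
        return self.k * self.dr


def restraint_force(r: float, rest: HarmonicLinearRestraint) -> float:
    """Signed restoring force (pN) of a harmonic-linear restraint.

    Positive values push the pair apart (r below target), negative pull it
    together.  Zero exactly at the target distance; magnitude capped at
    k*dr (F_max for an untuned restraint) beyond one standard error.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    delta = r - rest.r_exp
    if abs(delta) <= rest.dr:
        return -rest.k * delta
    return -np.sign(delta) * rest.k * rest.dr


def build_pseudoatoms(
    conf: Conformer,
    sites: list[LabelingSite],
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    avs: dict[str, AccessibleVolume] | None = None,
) -> list[Pseudoatom]:
    """Place one pseudoatom per labeling site at its AV mean position.

    Anchors are the CA and CB atoms of the attachment residue and of the
    residues up to two positions toward the N- and C-termini (ten anchors
    mid-chain; fewer at chain ends and for glycines, which have no CB).
    Equilibrium distances come from the current geometry.
    """
    out = []
    for site in sites:
        av = (avs or {}).get(site.site_id) or compute_av(conf, site, grid_spacing, acv)
        if av.empty:
            raise EmptyVolumeError(
                f"site {site.site_id} is buried; it cannot be labeled"
            )
        pos = av.mean_position
        anchors = []
        for res in range(site.res_id - 2, site.res_id + 3):
            for name in ("CA", "CB"):
                try:
                    idx = conf.find_atom(site.chain_id, res, name)
                except KeyError:
                    continue  # chain end or glycine
                d = float(np.linalg.norm(conf.atoms.coord[idx] - pos))
                anchors.append((site.chain_id, res, name, d))
        out.append(
            Pseudoatom(
                site_id=site.site_id,
                position=pos,
                residue=site.res_id,
                chain_id=site.chain_id,
                anchors=anchors,
            )
        )
    return out


def tune_force_constants(
    restraints: list[HarmonicLinearRestraint],
    pseudoatoms: list[Pseudoatom],
) -> list[HarmonicLinearRestraint]:
    """Scale restraint force constants so no pseudoatom can feel a net
    restraint force above F_max.

    The worst case puts every restraint simultaneously at its cap, pulling
    along its current direction.  Restraint cap-force vectors are summed
    per pseudoatom; whenever the resultant exceeds F_max, all restraints of
    that pseudoatom are scaled by a common factor (each restraint takes the
    most restrictive factor of its two ends), iterating to a fixed point.
    Collinear restraints therefore share the F_max budget while orthogonal
    ones each keep a 1/sqrt(2) share.  Anchor constants are set to ten
    times the largest tuned restraint constant at each pseudoatom.
    """
    pos = {p.site_id: p.position for p in pseudoatoms}
    scale = np.ones(len(restraints))
    caps = np.array([r.cap_force for r in restraints])

    # unit direction of the cap force exerted on each end (toward partner)
    dirs = []
    for r in restraints:
        v = pos[r.acceptor_site] - pos[r.donor_site]
        n = np.linalg.norm(v)
        dirs.append(v / n if n > 0 else np.zeros(3))
    dirs = np.asarray(dirs)

    touching: dict[str, list[int]] = {p.site_id: [] for p in pseudoatoms}
    for i, r in enumerate(restraints):
        touching[r.donor_site].append(i)
        touching[r.acceptor_site].append(i)

    for _ in range(200):
        worst = 1.0
        factors = {}
        for sid, idxs in touching.items():
            if not idxs:
                continue
            total = np.zeros(3)
            for i in idxs:
                sign = 1.0 if restraints[i].donor_site == sid else -1.0
                total += sign * scale[i] * caps[i] * dirs[i]
            mag = float(np.linalg.norm(total))
            if mag > F_MAX * (1 + 1e-12):
                factors[sid] = F_MAX / mag
                worst = min(worst, factors[sid])
        if not factors:
            break
        for i, r in enumerate(restraints):
            f = min(
                factors.get(r.donor_site, 1.0), factors.get(r.acceptor_site, 1.0)
            )
            scale[i] *= f

    tuned = [
        HarmonicLinearRestraint(
            r.donor_site, r.acceptor_site, r.r_exp, r.dr, r.k * s, r.f_max
        )
        for r, s in zip(restraints, scale)
    ]
    for p in pseudoatoms:
        ks = [tuned[i].k for i in touching[p.site_id]]
        p.anchor_k = ANCHOR_SCALE * max(ks) if ks else 0.0
    return tuned


def measurement_to_target(
    r_ref: float, av_d: AccessibleVolume, av_a: AccessibleVolume
) -> float:
    """Convert an AV-averaged reference distance to a mean-position target.

    Restraints act between mean positions, while measurements report the
    distribution-averaged distance, which is systematically larger
    (Jensen's inequality for the norm).  The model-computed offset
    (mean_RDA - Rmp) on the restraint-generation conformer corrects for
    this: R_exp = R_ref - (mean_RDA - Rmp).
    """
    offset = model_distance(av_d, av_a, "mean_RDA") - model_distance(
        av_d, av_a, "Rmp"
    )
    return r_ref - offset


@dataclass
class RestraintSet:
    """Pseudoatoms plus tuned restraints, ready for serialization."""

    pseudoatoms: list[Pseudoatom]
    restraints: list[HarmonicLinearRestraint]
    conformer_label: str = ""
    notes: list[str] = field(
        default_factory=lambda: [
            "pseudoatoms must not interact with protein or solvent atoms "
            "(exclude them from nonbonded interactions in the MD topology)",
            "regenerate pseudoatoms and restraints from a fresh snapshot "
            "every ~2 ns of simulation to track local backbone changes",
        ]
    )

    def __post_init__(self):
        ids = {p.site_id for p in self.pseudoatoms}
        for r in self.restraints:
            if r.donor_site not in ids or r.acceptor_site not in ids:
                raise ValueError(f"restraint references undefined pseudoatom: {r}")


def generate_restraints(
    conf: Conformer,
    pairs: list[FRETPair],
    meas: MeasurementSet,
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    f_max: float = F_MAX,
) -> RestraintSet:
    """Full RMP restraint generation for one conformer snapshot.

    Computes AVs, places pseudoatoms, converts measured distances to
    mean-position targets, assigns the untuned constants k = F_max / dR and
    tunes them for collinearity.
    """
    sites: dict[str, LabelingSite] = {}
    for pair in pairs:
        sites.setdefault(pair.donor.site_id, pair.donor)
        sites.setdefault(pair.acceptor.site_id, pair.acceptor)
    avs = {
        sid: compute_av(conf, site, grid_spacing, acv)
        for sid, site in sites.items()
    }
    pseudoatoms = build_pseudoatoms(
        conf, list(sites.values()), grid_spacing, acv, avs=avs
    )
    restraints = []
    for pair in pairs:
        try:
            rec = meas[pair.pair_id]
        except KeyError:
            continue
        r_exp = measurement_to_target(
            rec.r_ref, avs[pair.donor.site_id], avs[pair.acceptor.site_id]
        )
        restraints.append(
            HarmonicLinearRestraint(
                pair.donor.site_id,
                pair.acceptor.site_id,
                max(r_exp, 1e-3),
                rec.dr_ref,
                k=f_max / rec.dr_ref,
                f_max=f_max,
            )
        )
    restraints = tune_force_constants(restraints, pseudoatoms)
    return RestraintSet(pseudoatoms, restraints, conformer_label=conf.label)


# ---------------------------------------------------------------------------
# DISANG serialization
# ---------------------------------------------------------------------------
#
# Dialect (documented so files are bit-reproducible):
#   FRET restraints:  r2 = R_exp - dR, r3 = R_exp + dR (flat bottom spanning
#     the harmonic window), r1 = max(0, r2 - 2 dR), r4 = r3 + 2 dR; the
#     parabola between r1..r2 (and r3..r4) reaches the linear-cap force
#     k*dR at its outer edge, so rk2 = rk3 = (k*dR) / (4 dR) in pN/A at the
#     gradient level.
#   Anchors: plain harmonic bonds, r1 = max(0, eq - 10), r2 = r3 = eq,
#     r4 = eq + 10, rk2 = rk3 = anchor_k / 2 in pN/A at the gradient level.
#   AMBER's rk is the k/2 convention (E = rk * (r - r2)^2, force
#   |F| = 2 rk |r - r2|), and rk values are written in kcal mol^-1 A^-2
#   (1 kcal mol^-1 A^-2 = 69.48 pN/A at the gradient level).


def _rk_amber(gradient_pn_per_a: float) -> float:
    """Convert a force gradient (pN/A) to an AMBER rk (kcal/mol/A^2, k/2)."""
    return gradient_pn_per_a / PN_PER_KCAL_MOL_A2 / 2.0


def write_restraint_file(
    rset: RestraintSet,
    path: str | Path,
    serial_map: dict[str, int],
    sidecar: str | Path | None = None,
) -> None:
    """Write an AMBER DISANG (&rst namelist) restraint file.

    ``serial_map`` maps anchor atom keys ("chain:resid:atomname") and
    pseudoatom keys ("pseudo:<site_id>") to AMBER atom serial numbers (the
    separate namespace avoids clashes with the attachment atom itself).  A
    JSON sidecar with pseudoatom definitions for topology patching is
    written when ``sidecar`` is given.
    """

    def serial(key: str) -> int:
        if key not in serial_map:
            raise KeyError(f"no atom serial for {key!r}")
        return serial_map[key]

    lines = ["# fretassist RMP restraints"]
    if rset.conformer_label:
        lines.append(f"# generated from conformer: {rset.conformer_label}")
    for note in rset.notes:
        lines.append(f"# NOTE: {note}")
    for p in rset.pseudoatoms:
        for chain, res, name, eq in p.anchors:
            rk = _rk_amber(p.anchor_k)
            lines.append(
                " &rst iat={},{}, r1={:.3f}, r2={:.3f}, r3={:.3f}, r4={:.3f},"
                " rk2={:.6f}, rk3={:.6f}, /".format(
                    serial(f"pseudo:{p.site_id}"),
                    serial(f"{chain}:{res}:{name}"),
                    max(0.0, eq - 10.0),
                    eq,
                    eq,
                    eq + 10.0,
                    rk,
                    rk,
                )
            )
    for r in rset.restraints:
        r2, r3 = r.r_exp - r.dr, r.r_exp + r.dr
        rk = _rk_amber(r.cap_force / (4.0 * r.dr) * 2.0)
        lines.append(
            " &rst iat={},{}, r1={:.3f}, r2={:.3f}, r3={:.3f}, r4={:.3f},"
            " rk2={:.6f}, rk3={:.6f}, /".format(
                serial(f"pseudo:{r.donor_site}"),
                serial(f"pseudo:{r.acceptor_site}"),
                max(0.0, r2 - 2.0 * r.dr),
                r2,
                r3,
                r3 + 2.0 * r.dr,
                rk,
                rk,
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")

    if sidecar is not None:
        data = {
            "conformer": rset.conformer_label,
            "notes": rset.notes,
            "pseudoatoms": [
                {
                    "site_id": p.site_id,
                    "position": [round(float(x), 4) for x in p.position],
                    "residue": p.residue,
                    "chain": p.chain_id,
                    "anchor_k_pn_per_a": round(p.anchor_k, 6),
                    "anchors": [
                        {
                            "atom": f"{c}:{r_}:{n}",
                            "equilibrium_a": round(d, 4),
                        }
                        for c, r_, n, d in p.anchors
                    ],
                }
                for p in rset.pseudoatoms
            ],
            "restraints": [
                {
                    "donor": r.donor_site,
                    "acceptor": r.acceptor_site,
                    "r_exp_a": round(r.r_exp, 4),
                    "dr_a": round(r.dr, 4),
                    "k_pn_per_a": round(r.k, 6),
                    "f_max_pn": r.f_max,
                }
                for r in rset.restraints
            ],
        }
        Path(sidecar).write_text(json.dumps(data, indent=2) + "\n")


def default_serial_map(conf: Conformer, rset: RestraintSet) -> dict[str, int]:
    """Serial numbers for a topology where pseudoatoms are appended after
    the conformer's atoms (1-based, PDB order)."""
    serial_map: dict[str, int] = {}
    for i in range(conf.atoms.array_length()):
        key = (
            f"{conf.atoms.chain_id[i]}:{conf.atoms.res_id[i]}:"
            f"{conf.atoms.atom_name[i]}"
        )
        serial_map.setdefault(key, i + 1)
    base = conf.atoms.array_length()
    for j, p in enumerate(rset.pseudoatoms):
        serial_map[f"pseudo:{p.site_id}"] = base + 1 + j
    return serial_map


_RST_RE = re.compile(
    r"&rst\s+iat=(\d+),(\d+),\s*r1=([-\d.]+),\s*r2=([-\d.]+),\s*r3=([-\d.]+),"
    r"\s*r4=([-\d.]+),\s*rk2=([-\d.]+),\s*rk3=([-\d.]+)"
)


def read_restraint_file(path: str | Path) -> list[dict]:
    """Parse a DISANG file written by :func:`write_restraint_file`.

    Returns one dict per &rst block with iat pair, r1..r4 and rk2/rk3
    (AMBER units); used for round-trip verification.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        m = _RST_RE.search(line)
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            r1, r2, r3, r4, rk2, rk3 = (float(m.group(g)) for g in range(3, 9))
            out.append(
                {
                    "iat": (i, j),
                    "r1": r1,
                    "r2": r2,
                    "r3": r3,
                    "r4": r4,
                    "rk2": rk2,
                    "rk3": rk3,
                }
            )
    return out
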