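"""Structure and ensemble I/O plus superposition-based and superposition-free
similarity scores.

The unit of work is the :class:`Conformer` (one structural model) and the
:class:`Ensemble` (an ordered pool of conformers sharing one topology).  All
similarity scores operate on C-alpha atoms only: the pairwise RMSD after
optimal least-squares superposition, and the local distance difference test
(lDDT), which is superposition-free and therefore insensitive to domain
motion of well-preserved sub-structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, TopologyError, UndefinedScoreError

__all__ = [
    "Conformer",
    "Ensemble",
    "read_ensemble",
    "write_ensemble",
    "superpose",
    "rmsd_ca",
    "rmsd_matrix",
    "lddt_ca",
    "granularity",
    "granularity_label",
    "write_matrix_csv",
]


class Conformer:
    """One structural model: a thin wrapper around a biotite ``AtomArray``.

    Hydrogens are retained but ignored by every score.  HETATM records are
    excluded from the C-alpha selection.
    """

    def __init__(self, atoms: struc.AtomArray, label: str = ""):
        if not np.all(np.isfinite(atoms.coord)):
            raise FormatError(f"conformer {label!r} contains non-finite coordinates")
        self.atoms = atoms
        self.label = label

    # -- selections ---------------------------------------------------------

    @property
    def ca_mask(self) -> np.ndarray:
        return (self.atoms.atom_name == "CA") & (~self.atoms.hetero)

    @property
    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.ca_mask)

    @property
    def ca_coords(self) -> np.ndarray:
        return self.atoms.coord[self.ca_mask]

    def ca_topology_key(self) -> tuple:
        """Hashable identity of the C-alpha selection (chain, resid, icode)."""
        m = self.ca_mask
        ins = (
            self.atoms.ins_code[m]
            if "ins_code" in self.atoms.get_annotation_categories()
            else np.full(int(m.sum()), "")
        )
        return tuple(
            zip(
                self.atoms.chain_id[m].tolist(),
                self.atoms.res_id[m].tolist(),
                ins.tolist(),
            )
        )

    def n_residues(self) -> int:
        return int(self.ca_mask.sum())

    # -- atom lookup --------------------------------------------------------

    def find_atom(self, chain_id: str, res_id: int, atom_name: str) -> int:
        """Index of a uniquely identified atom; raises ``KeyError`` if absent."""
        hit = np.flatnonzero(
            (self.atoms.chain_id == chain_id)
            & (self.atoms.res_id == res_id)
            & (self.atoms.atom_name == atom_name)
        )
        if hit.size == 0:
            raise KeyError(f"no atom {chain_id}:{res_id}:{atom_name} in {self.label!r}")
        return int(hit[0])

    def with_coords(self, coord: np.ndarray, label: str | None = None) -> "Conformer":
        """A copy of this conformer with replaced coordinates (same topology)."""
        atoms = self.atoms.copy()
        atoms.coord = np.asarray(coord, dtype=float)
        return Conformer(atoms, self.label if label is None else label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Conformer({self.label!r}, {self.atoms.array_length()} atoms)"


@dataclass
class Ensemble:
    """Ordered pool of conformers sharing one C-alpha topology."""

    conformers: list[Conformer] = field(default_factory=list)

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("an ensemble must contain at least one conformer")
        key = self.conformers[0].ca_topology_key()
        for conf in self.conformers[1:]:
            if conf.ca_topology_key() != key:
                raise TopologyError(
                    f"conformer {conf.label!r} does not share the C-alpha "
                    f"topology of {self.conformers[0].label!r}"
                )

    @property
    def n_conf(self) -> int:
        return len(self.conformers)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conformers]

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return Ensemble([self.conformers[j] for j in i])
        return self.conformers[i]

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble([self.conformers[i] for i in indices])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_ensemble(paths: Iterable[str | Path], chain_filter: str | None = None) -> Ensemble:
    """Read one or more PDB files (single- or multi-MODEL) into an Ensemble.

    One conformer is produced per MODEL per file, in input order.  For
    alternate locations the highest-occupancy variant is kept (ties resolve
    to altloc 'A', biotite's convention).
    """
    conformers: list[Conformer] = []
    for path in paths:
        path = Path(path)
        try:
            pdb = PDBFile.read(str(path))
            stack = pdb.get_structure(model=None, altloc="occupancy")
        except Exception as exc:  # biotite raises several parse error types
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        for m in range(stack.stack_depth()):
            atoms = stack[m]
            if chain_filter is not None:
                atoms = atoms[atoms.chain_id == chain_filter]
            label = path.stem if stack.stack_depth() == 1 else f"{path.stem}#{m + 1}"
            conformers.append(Conformer(atoms, label))
    return Ensemble(conformers)


def write_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    stack = struc.stack([c.atoms for c in ens])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_matrix_csv(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write a conformer-by-conformer score matrix as labeled CSV."""
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``fixed``.

    Closed-form SVD solution with a reflection guard; returns the
    transformed mobile coordinates.
    """
    mob_c = mobile.mean(axis=0)
    fix_c = fixed.mean(axis=0)
    P = mobile - mob_c
    Q = fixed - fix_c
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return P @ R + fix_c


def superpose(conf: Conformer, ref: Conformer) -> Conformer:
    """Rigidly superpose ``conf`` onto ``ref`` using the C-alpha atoms.

    The optimal rotation/translation from the C-alpha fit is applied to all
    atoms of ``conf``.
    """
    _check_shared_topology(conf, ref)
    mobile = conf.ca_coords
    fixed = ref.ca_coords
    mob_c = mobile.mean(axis=0)
    fix_c = fixed.mean(axis=0)
    H = (mobile - mob_c).T @ (fixed - fix_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return conf.with_coords((conf.atoms.coord - mob_c) @ R + fix_c)


def _check_shared_topology(conf: Conformer, ref: Conformer) -> None:
    if conf.ca_topology_key() != ref.ca_topology_key():
        raise TopologyError(
            f"conformers {conf.label!r} and {ref.label!r} do not share a "
            "C-alpha topology"
        )


def rmsd_ca(conf: Conformer, ref: Conformer, superpose: bool = True) -> float:
    """C-alpha root-mean-square deviation in Angstrom.

    With ``superpose`` on (default), the least-squares rigid-body
    superposition is applied first, so the value is invariant under rigid
    motions of either argument and symmetric in its arguments.
    """
    _check_shared_topology(conf, ref)
    mobile = conf.ca_coords
    fixed = ref.ca_coords
    if superpose:
        if mobile.shape[0] < 3:
            raise ValueError("superposition requires at least 3 C-alpha atoms")
        mobile = _kabsch(mobile, fixed)
    return float(np.sqrt(np.mean(np.sum((mobile - fixed) ** 2, axis=1))))


def rmsd_matrix(ens: Ensemble, superpose: bool = True) -> np.ndarray:
    """Symmetric N x N matrix of pairwise C-alpha RMSDs."""
    n = ens.n_conf
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rmsd_ca(ens[i], ens[j], superpose=superpose)
    return out


# ---------------------------------------------------------------------------
# lDDT
# ---------------------------------------------------------------------------


def lddt_ca(
    conf: Conformer,
    ref: Conformer,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> tuple[float, np.ndarray]:
    """Superposition-free local distance difference test over C-alpha atoms.

    A pair (i, j) of distinct residues enters the test set if its distance
    in the *reference* is below ``inclusion_radius``.  A pair is conserved
    at tolerance ``t`` if ``|d_conf - d_ref| < t``.  The global score is the
    conserved fraction averaged over the four tolerance thresholds; the
    per-residue score applies the same average restricted to pairs involving
    that residue (a pair contributes to both of its residues).

    Returns ``(global_score, per_residue_scores)``; residues with no pair in
    the inclusion radius get NaN.
    """
    _check_shared_topology(conf, ref)
    ref_xyz = ref.ca_coords
    mod_xyz = conf.ca_coords
    n = ref_xyz.shape[0]
    d_ref = np.linalg.norm(ref_xyz[:, None] - ref_xyz[None, :], axis=-1)
    d_mod = np.linalg.norm(mod_xyz[:, None] - mod_xyz[None, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    include = d_ref[iu] < inclusion_radius
    if not np.any(include):
        raise UndefinedScoreError("no residue pair within the inclusion radius")
    ii, jj = iu[0][include], iu[1][include]
    dev = np.abs(d_mod[ii, jj] - d_ref[ii, jj])
    conserved = dev[None, :] < np.asarray(thresholds)[:, None]  # (T, P)
    global_score = float(conserved.mean(axis=1).mean())

    per_res = np.full(n, np.nan)
    for r in range(n):
        sel = (ii == r) | (jj == r)
        if np.any(sel):
            per_res[r] = float(conserved[:, sel].mean(axis=1).mean())
    return global_score, per_res


# ---------------------------------------------------------------------------
# Granularity
# ---------------------------------------------------------------------------


def granularity(n_residues: int, n_pairs: int) -> float:
    """Residues per informative FRET pair (model granularity).

    The ratio of protein length to the number of FRET pairs (guiding plus
    cross-validation) needed to reach a target model uncertainty.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return n_residues / n_pairs


def granularity_label(n_residues: int, n_pairs: int) -> str:
    """Format the granularity as the conventional '1:x' string, x to 0.1."""
    return f"1:{granularity(n_residues, n_pairs):.1f}"
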