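"""FRET-guided conformational sampling.

A pluggable proposal engine generates candidate conformers; each candidate
is scored by its normalized chi-squared against the guiding measurement
set, and a Metropolis-Hastings criterion
P_accept = exp((chi2n_prev - chi2n_curr) / kT) decides acceptance.  kT is
annealed in triangular cycles between (almost) 0 and 1 in units of chi2n
(two cycles by default) so the walk can escape local minima while ending
in a refined state.

During guidance every guiding pair is effectively a fitted parameter, so
the run scores with zero fit parameters for *relative* ranking only; an
optional held-out validation set yields the statistically meaningful final
chi2n (with N_fit.param equal to the number of guiding pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import TopologyError
from .structure_io import Conformer, Ensemble, write_ensemble
from .dye_model import (
    ACVParams,
    FRETPair,
    LabelingSite,
    MeasurementSet,
    compute_av,
    model_distance,
)
from . import screening

__all__ = [
    "AnnealingSchedule",
    "ProposalEngine",
    "IdentityEngine",
    "ToyHingeEngine",
    "GuidedRun",
    "accept_probability",
    "make_schedule",
    "run_guided",
]


def accept_probability(chi2n_prev: float, chi2n_curr: float, kT: float) -> float:
    """Metropolis acceptance probability exp((prev - curr) / kT), capped at 1.

    kT = 0 is the greedy limit: accept only non-increasing moves.
    """
    if chi2n_curr <= chi2n_prev:
        return 1.0  # downhill or flat: always accept
    if kT <= 0.0:
        return 0.0  # greedy limit
    return float(np.exp((chi2n_prev - chi2n_curr) / kT))


@dataclass
class AnnealingSchedule:
    """Piecewise-linear triangular kT schedule in units of chi2n."""

    kt: np.ndarray
    n_cycles: int
    peak_kt: float
    floor: float

    @property
    def n_iterations(self) -> int:
        return self.kt.size


def make_schedule(
    n_iterations: int,
    peak_kt: float = 1.0,
    n_cycles: int = 2,
    floor: float = 1e-3,
) -> AnnealingSchedule:
    """Triangular annealing: each cycle ramps kT linearly floor -> peak ->
    floor; cycles are concatenated with equal ramp lengths."""
    if n_iterations < 2 * n_cycles:
        raise ValueError("need at least 2 iterations per annealing cycle")
    base = n_iterations // n_cycles
    lengths = [base] * n_cycles
    lengths[-1] += n_iterations - base * n_cycles
    pieces = []
    for L in lengths:
        i = np.arange(L)
        half = L / 2.0
        pieces.append(floor + (peak_kt - floor) * (1.0 - np.abs(i - half) / half))
    return AnnealingSchedule(np.concatenate(pieces), n_cycles, peak_kt, floor)


# ---------------------------------------------------------------------------
# Proposal engines
# ---------------------------------------------------------------------------


class ProposalEngine(Protocol):
    """Contract: propose a topology-preserving candidate conformer."""

    def propose(self, conf: Conformer, rng: np.random.Generator) -> Conformer: ...


class IdentityEngine:
    """Degenerate engine that always proposes the current conformer."""

    def propose(self, conf: Conformer, rng: np.random.Generator) -> Conformer:
        return conf


class ToyHingeEngine:
    """Rigid two-segment hinge mover (stand-in for a full geometric
    simulation engine).

    Proposes a rotation of the second segment about a random axis through
    the hinge C-alpha, with rotation angle ~ Uniform(-max_step, +max_step)
    degrees.  Proposals placing any inter-segment C-alpha pair closer than
    the clash distance are re-drawn up to a bounded retry count; on
    exhaustion the current conformer is returned and ``last_stalled`` set.
    """

    def __init__(
        self,
        segment1: tuple[int, int],
        segment2: tuple[int, int],
        hinge_res_id: int,
        max_angle_step: float = 10.0,
        chain_id: str = "A",
        clash_distance: float = 3.0,
        max_retries: int = 25,
    ):
        if not segment1[1] < hinge_res_id < segment2[0]:
            raise ValueError("hinge residue must sit between the two segments")
        self.segment1 = segment1
        self.segment2 = segment2
        self.hinge_res_id = hinge_res_id
        self.max_angle_step = max_angle_step
        self.chain_id = chain_id
        self.clash_distance = clash_distance
        self.max_retries = max_retries
        self.last_stalled = False

    def _masks(self, conf: Conformer):
        res = conf.atoms.res_id
        seg2 = res >= self.segment2[0]
        # the hinge region itself (hinge +/- 2 residues) is covalently
        # connected and exempt from the inter-segment clash check
        ca1 = conf.ca_mask & (res <= min(self.segment1[1], self.hinge_res_id - 3))
        ca2 = conf.ca_mask & (res >= max(self.segment2[0], self.hinge_res_id + 3))
        return seg2, ca1, ca2

    def propose(self, conf: Conformer, rng: np.random.Generator) -> Conformer:
        self.last_stalled = False
        if self.max_angle_step == 0:
            return conf
        seg2, ca1, ca2 = self._masks(conf)
        pivot = conf.atoms.coord[
            conf.find_atom(self.chain_id, self.hinge_res_id, "CA")
        ]
        coords1 = conf.atoms.coord[ca1]
        for _ in range(self.max_retries):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(-self.max_angle_step, self.max_angle_step))
            rot = Rotation.from_rotvec(axis * angle)
            new = conf.atoms.coord.copy()
            new[seg2] = rot.apply(new[seg2] - pivot) + pivot
            moved_ca2 = new[ca2]
            dmin = np.min(
                np.linalg.norm(coords1[:, None] - moved_ca2[None, :], axis=-1)
            )
            if dmin >= self.clash_distance:
                return conf.with_coords(new)
        self.last_stalled = True
        return conf


# ---------------------------------------------------------------------------
# Guided run
# ---------------------------------------------------------------------------


class _AVCache:
    """Conservative per-site AV cache: an AV is reused only when every atom
    that could influence it (within the grid reach of the attachment) is at
    an identical position.  Purely an optimization; results are exact."""

    def __init__(self, grid_spacing: float, acv: ACVParams | None):
        self.grid_spacing = grid_spacing
        self.acv = acv
        self._store: dict[str, tuple[bytes, object]] = {}

    def get(self, conf: Conformer, site: LabelingSite):
        attach = conf.atoms.coord[
            conf.find_atom(site.chain_id, site.res_id, site.atom_name)
        ]
        reach = (
            site.linker_length
            + max(site.dye_radii)
            + max(site.linker_width, *site.dye_radii)
            + 2.0
        )
        near = (
            np.linalg.norm(conf.atoms.coord - attach, axis=1) <= reach
        )
        key = np.round(conf.atoms.coord[near], 6).tobytes()
        cached = self._store.get(site.site_id)
        if cached is not None and cached[0] == key:
            return cached[1]
        av = compute_av(conf, site, self.grid_spacing, self.acv)
        self._store[site.site_id] = (key, av)
        return av


@dataclass
class GuidedRun:
    """Full record of one FRET-guided sampling run."""

    accepted_conformers: list[Conformer]
    state_index: np.ndarray  # per iteration: index into accepted_conformers
    kt: np.ndarray
    proposed_chi2n: np.ndarray
    current_chi2n: np.ndarray
    accepted: np.ndarray
    best_conformer: Conformer
    best_chi2n: float
    seed: int
    n_guiding_pairs: int
    validation_chi2n: float | None = None
    validation_n_dof: int | None = None
    stalls: int = 0

    @property
    def reached_consistency(self) -> bool:
        """Whether the run approached statistical agreement (chi2n -> 1)."""
        return self.best_chi2n < 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.kt.size + 1),
                "kT": self.kt,
                "chi2n_proposed": self.proposed_chi2n,
                "chi2n_current": self.current_chi2n,
                "accepted": self.accepted,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_trajectory(self, path: str | Path) -> None:
        write_ensemble(Ensemble(self.accepted_conformers), path)


def _score(
    conf: Conformer,
    pairs: list[FRETPair],
    meas: MeasurementSet,
    cache: _AVCache,
    n_dof: int,
    n_samples: int = 20_000,
) -> float:
    # 20k weighted samples keep the mean_RDA Monte-Carlo error well below
    # 0.1 A on toy-sized AV clouds, far under any distance uncertainty
    dists = {}
    for pair in pairs:
        av_d = cache.get(conf, pair.donor)
        av_a = cache.get(conf, pair.acceptor)
        if av_d.empty or av_a.empty:
            return np.inf  # a buried site cannot satisfy the data
        dists[pair.pair_id] = model_distance(
            av_d, av_a, "mean_RDA", n_samples=n_samples
        )
    return screening.chi2_n(screening.chi2(dists, meas), n_dof)


def run_guided(
    seed_conf: Conformer,
    engine: ProposalEngine,
    pairs: list[FRETPair],
    meas: MeasurementSet,
    schedule: AnnealingSchedule,
    seed: int,
    n_fit_param: int = 0,
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    validation: MeasurementSet | None = None,
    validation_pairs: list[FRETPair] | None = None,
) -> GuidedRun:
    """Metropolis-guided refinement of a seed conformer against FRET data.

    Each iteration proposes a move, recomputes the accessible volumes and
    model distances, scores the candidate by chi2n and applies the
    Metropolis criterion at the scheduled kT.  The guiding score uses
    ``n_fit_param`` (0 by default: all guiding pairs are fitted, so the
    guiding chi2n ranks states only *relatively*).  If a held-out
    ``validation`` set is supplied, the best conformer is re-scored on it
    with N_fit.param equal to the number of guiding pairs, which is the
    statistically meaningful quality estimate.
    """
    rng = np.random.default_rng(seed)
    cache = _AVCache(grid_spacing, acv)
    k = screening.n_dof(meas.n_measurements, n_fit_param)
    if k < 1:
        raise ValueError("guidance scoring needs N_dof >= 1")
    topo = seed_conf.ca_topology_key()

    n_iter = schedule.n_iterations
    proposed_chi2n = np.empty(n_iter)
    current_chi2n = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)
    state_index = np.empty(n_iter, dtype=np.int64)

    current = seed_conf
    current_score = _score(current, pairs, meas, cache, k)
    accepted_conformers = [current]
    best, best_score = current, current_score
    stalls = 0

    for it in range(n_iter):
        candidate = engine.propose(current, rng)
        if getattr(engine, "last_stalled", False):
            stalls += 1
        if candidate.ca_topology_key() != topo:
            raise TopologyError(
                "proposal engine returned a conformer with a different topology"
            )
        cand_score = _score(candidate, pairs, meas, cache, k)
        p = accept_probability(current_score, cand_score, schedule.kt[it])
        if p > rng.uniform():
            current, current_score = candidate, cand_score
            accepted[it] = True
            if current is not accepted_conformers[-1]:
                accepted_conformers.append(current)
        if cand_score < best_score:
            best, best_score = candidate, cand_score
        proposed_chi2n[it] = cand_score
        current_chi2n[it] = current_score
        state_index[it] = len(accepted_conformers) - 1

    run = GuidedRun(
        accepted_conformers=accepted_conformers,
        state_index=state_index,
        kt=schedule.kt.copy(),
        proposed_chi2n=proposed_chi2n,
        current_chi2n=current_chi2n,
        accepted=accepted,
        best_conformer=best,
        best_chi2n=float(best_score),
        seed=seed,
        n_guiding_pairs=len(pairs),
        stalls=stalls,
    )
    if validation is not None:
        vpairs = validation_pairs if validation_pairs is not None else pairs
        kv = screening.n_dof(validation.n_measurements, len(pairs))
        if kv >= 1:
            run.validation_chi2n = _score(best, vpairs, validation, cache, kv)
            run.validation_n_dof = kv
    return run
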