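"""Automated design of FRET experiments: which pairs to measure, and how
many.

The expected model uncertainty <<RMSD>> of a candidate pair set is a double
average over an ensemble: every conformer in turn plays the reference whose
simulated distances stand in for the experiment; all conformers are scored
against it by chi-squared, and the p-values weight the pairwise RMSD matrix
(self term included with p = 1, RMSD = 0).  A pair set is informative if it
makes conformers statistically distinguishable, i.e. drives <<RMSD>> down.

Three selection strategies are provided: greedy forward selection, greedy
backward elimination, and a minimum-redundancy style pick by maximal
minimum Shannon conditional entropy.  A two-stage heuristic estimates the
effective number of fit parameters of the structure model and from it the
recommended number of measurements including cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import Ensemble, rmsd_matrix
from .dye_model import (
    ACVParams,
    FRETPair,
    LabelingSite,
    compute_av,
    model_distance,
)

__all__ = [
    "CandidatePairPool",
    "SelectionTrace",
    "ComplexityEstimate",
    "build_pool",
    "expected_rmsd",
    "select_greedy_forward",
    "select_greedy_backward",
    "select_mutual_information",
    "choose_algorithm",
    "estimate_complexity",
    "rigid_body_n_fit_param",
    "read_pool_csv",
    "read_exclusions_csv",
]

#: Backward elimination is discouraged above this ensemble size.
BACKWARD_CONFORMER_LIMIT = 10_000
#: Requests below this pair count use greedy forward selection.
GREEDY_FORWARD_LIMIT = 6
#: Histogram bin width (A) for the entropy-based selector; about one
#: typical distance uncertainty.
MI_BIN_WIDTH = 3.0


@dataclass
class CandidatePairPool:
    """Candidate FRET pairs with precomputed per-conformer model distances."""

    pairs: list[FRETPair]
    distances: np.ndarray  # (n_conf, n_pairs)
    excluded: dict[str, str] = field(default_factory=dict)  # site_id -> reason
    dropped_pairs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.distances.shape[1] != len(self.pairs):
            raise ValueError("distance matrix does not match the pair list")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("distance matrix must be complete and finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    @property
    def r0s(self) -> np.ndarray:
        return np.array([p.r0 for p in self.pairs])


def build_pool(
    ens: Ensemble,
    pairs: list[FRETPair],
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    exclusions: dict[str, str] | None = None,
) -> CandidatePairPool:
    """Precompute model distances for every (conformer, pair) combination.

    Sites listed in ``exclusions`` (site_id -> reason) remove all their
    pairs.  A pair whose AV is empty on any conformer is dropped for all
    conformers and recorded in ``dropped_pairs``.
    """
    exclusions = exclusions or {}
    kept = [
        p
        for p in pairs
        if p.donor.site_id not in exclusions and p.acceptor.site_id not in exclusions
    ]
    dist = np.full((ens.n_conf, len(kept)), np.nan)
    for i, conf in enumerate(ens):
        av_cache = {}
        for j, pair in enumerate(kept):
            for site in (pair.donor, pair.acceptor):
                if site.site_id not in av_cache:
                    av_cache[site.site_id] = compute_av(conf, site, grid_spacing, acv)
            av_d = av_cache[pair.donor.site_id]
            av_a = av_cache[pair.acceptor.site_id]
            if not (av_d.empty or av_a.empty):
                dist[i, j] = model_distance(av_d, av_a, "mean_RDA")
    ok = np.all(np.isfinite(dist), axis=0)
    dropped = [p.pair_id for p, good in zip(kept, ok) if not good]
    return CandidatePairPool(
        pairs=[p for p, good in zip(kept, ok) if good],
        distances=dist[:, ok],
        excluded=dict(exclusions),
        dropped_pairs=dropped,
    )


# ---------------------------------------------------------------------------
# Expected model uncertainty
# ---------------------------------------------------------------------------


def _dr_array(
    r: np.ndarray,
    r0: np.ndarray,
    d_efficiency: float,
    clamp: tuple[float, float],
) -> np.ndarray:
    """Vectorized efficiency-error propagation (see dye_model)."""
    q = (r / r0) ** 6
    dr = d_efficiency * (1.0 + q) ** 2 * r0**6 / (6.0 * r**5)
    return np.clip(dr, clamp[0], clamp[1])


def expected_rmsd(
    rmsd_mat: np.ndarray,
    pool: CandidatePairPool,
    subset: list[int],
    n_fit_param: int = 0,
    d_efficiency: float = 0.06,
    clamp: tuple[float, float] = (0.5, 30.0),
) -> float:
    """Expected model uncertainty <<RMSD>> (A) for a candidate pair subset.

    Each conformer in turn acts as the reference: its model distances play
    the experiment, with uncertainties from efficiency-error propagation at
    the reference's own distances.  The p-values of the chi-squared scores
    weight the RMSD row of that reference; the outer mean over references
    gives <<RMSD>>.
    """
    n_conf = rmsd_mat.shape[0]
    if n_conf < 2:
        raise ValueError("expected_rmsd needs at least 2 conformers")
    k = len(subset) - n_fit_param
    if k < 1:
        raise ValueError(
            f"N_dof = {len(subset)} - {n_fit_param} < 1: add more pairs"
        )
    D = pool.distances[:, list(subset)]
    r0 = pool.r0s[list(subset)]
    inner = np.empty(n_conf)
    for ref in range(n_conf):
        dr = _dr_array(D[ref], r0, d_efficiency, clamp)
        chi2_vals = np.sum(((D - D[ref]) / dr) ** 2, axis=1)
        p = stats.chi2.sf(chi2_vals, df=k)
        psum = p.sum()  # >= 1: the self term has p = 1
        inner[ref] = (p @ rmsd_mat[:, ref]) / psum
    return float(inner.mean())


# ---------------------------------------------------------------------------
# Selection algorithms
# ---------------------------------------------------------------------------


@dataclass
class SelectionTrace:
    """Ordered record of a pair-selection run."""

    algorithm: str
    order: list[str]  # pair ids, in event (addition/removal) order
    values: list[float]  # <<RMSD>> after each event (NaN if undefined)
    selected: list[str]  # final chosen pair ids
    stop_criterion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.order) + 1),
                "pair_id": self.order,
                "expected_rmsd": self.values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ordered_candidates(pool: CandidatePairPool, indices) -> list[int]:
    """Candidate indices sorted by pair id (the documented tie-break)."""
    return sorted(indices, key=lambda j: pool.pair_ids[j])


def select_greedy_forward(
    pool: CandidatePairPool,
    rmsd_mat: np.ndarray,
    target_rmsd: float | None = None,
    max_pairs: int | None = None,
    n_fit_param: int = 0,
    initial: list[int] | None = None,
    **err_kwargs,
) -> SelectionTrace:
    """Greedy forward selection: repeatedly add the candidate pair that
    minimizes <<RMSD>>; stop when the target uncertainty is reached or
    ``max_pairs`` pairs are chosen.

    Ties resolve to the lowest pair id.  ``initial`` optionally seeds the
    chosen set (used by the complexity heuristic's second stage).
    """
    chosen: list[int] = list(initial or [])
    remaining = [j for j in range(pool.n_pairs) if j not in set(chosen)]
    order, values = [], []
    stop = "pool exhausted"
    while remaining:
        if max_pairs is not None and len(chosen) >= max_pairs:
            stop = "max_pairs reached"
            break
        if len(chosen) + 1 - n_fit_param < 1:
            # not yet enough pairs for a defined statistic: add by id order
            best = _ordered_candidates(pool, remaining)[0]
            best_val = np.nan
        else:
            best, best_val = None, np.inf
            for j in _ordered_candidates(pool, remaining):
                val = expected_rmsd(
                    rmsd_mat, pool, chosen + [j], n_fit_param, **err_kwargs
                )
                if val < best_val:
                    best, best_val = j, val
        chosen.append(best)
        remaining.remove(best)
        order.append(pool.pair_ids[best])
        values.append(best_val)
        if target_rmsd is not None and np.isfinite(best_val) and best_val <= target_rmsd:
            stop = "target reached"
            break
    else:
        stop = "pool exhausted"
    return SelectionTrace(
        "greedy_forward", order, values, [pool.pair_ids[j] for j in chosen], stop
    )


def select_greedy_backward(
    pool: CandidatePairPool,
    rmsd_mat: np.ndarray,
    target_rmsd: float | None = None,
    min_pairs: int = 1,
    n_fit_param: int = 0,
    **err_kwargs,
) -> SelectionTrace:
    """Greedy backward elimination: starting from the full pool, repeatedly
    remove the pair whose removal least degrades <<RMSD>>.

    Elimination stops when ``min_pairs`` remain, when N_dof would drop
    below 1, or when the best possible removal would exceed ``target_rmsd``.
    """
    if pool.n_pairs < 2:
        raise ValueError("backward elimination needs a pool of at least 2 pairs")
    current = list(range(pool.n_pairs))
    order, values = [], []
    stop = "min_pairs reached"
    while len(current) > max(min_pairs, n_fit_param + 1):
        best, best_val = None, np.inf
        for j in _ordered_candidates(pool, current):
            rest = [c for c in current if c != j]
            val = expected_rmsd(rmsd_mat, pool, rest, n_fit_param, **err_kwargs)
            if val < best_val:
                best, best_val = j, val
        if target_rmsd is not None and best_val > target_rmsd:
            stop = "target would be exceeded"
            break
        current.remove(best)
        order.append(pool.pair_ids[best])
        values.append(best_val)
    else:
        stop = (
            "min_pairs reached"
            if len(current) <= min_pairs
            else "N_dof floor reached"
        )
    return SelectionTrace(
        "greedy_backward", order, values, [pool.pair_ids[j] for j in current], stop
    )


def _entropy_from_codes(*codes: np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of jointly discretized variables."""
    joint = np.stack(codes, axis=1)
    _, counts = np.unique(joint, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def select_mutual_information(
    pool: CandidatePairPool,
    rmsd_mat: np.ndarray,
    n_pairs: int,
    bin_width: float = MI_BIN_WIDTH,
    n_fit_param: int = 0,
    **err_kwargs,
) -> SelectionTrace:
    """Entropy-based selection in the spirit of minimum-redundancy
    maximum-relevance: the first pick maximizes the marginal Shannon
    entropy of the discretized distance distribution over the ensemble;
    each later pick maximizes the minimum conditional entropy with respect
    to the already chosen pairs.

    Distances are discretized into fixed-width bins (3 A by default,
    roughly one typical distance uncertainty) spanning the pooled range.
    Constant (zero-entropy) candidates are never picked before informative
    ones.  <<RMSD>> is recorded for reporting whenever it is defined.
    """
    D = pool.distances
    lo = float(D.min())
    codes = np.floor((D - lo) / bin_width).astype(np.int64)  # (n_conf, n_pairs)

    marginal = np.array(
        [_entropy_from_codes(codes[:, j]) for j in range(pool.n_pairs)]
    )
    chosen: list[int] = []
    remaining = list(range(pool.n_pairs))
    order, values = [], []
    stop = "n_pairs reached"
    while remaining and len(chosen) < n_pairs:
        best, best_score = None, -np.inf
        for j in _ordered_candidates(pool, remaining):
            if not chosen:
                score = marginal[j]
            else:
                score = min(
                    _entropy_from_codes(codes[:, j], codes[:, s])
                    - _entropy_from_codes(codes[:, s])
                    for s in chosen
                )
            if score > best_score:
                best, best_score = j, score
        chosen.append(best)
        remaining.remove(best)
        order.append(pool.pair_ids[best])
        if len(chosen) - n_fit_param >= 1 and rmsd_mat.shape[0] >= 2:
            values.append(
                expected_rmsd(rmsd_mat, pool, chosen, n_fit_param, **err_kwargs)
            )
        else:
            values.append(np.nan)
    if remaining:
        stop = "n_pairs reached"
    else:
        stop = "pool exhausted"
    return SelectionTrace(
        "mutual_information", order, values, [pool.pair_ids[j] for j in chosen], stop
    )


def choose_algorithm(
    n_requested: int, n_conf: int, explicit: str | None = None
) -> str:
    """Pick the selection algorithm for a request.

    Greedy forward for fewer than six requested pairs, otherwise the
    entropy-based selector.  Backward elimination runs only on explicit
    request and warns for ensembles of 10,000 conformers or more.
    """
    if explicit == "greedy_backward":
        if n_conf >= BACKWARD_CONFORMER_LIMIT:
            warnings.warn(
                f"backward elimination on {n_conf} conformers is only advisable "
                f"below {BACKWARD_CONFORMER_LIMIT} conformers",
                stacklevel=2,
            )
        return "greedy_backward"
    if explicit is not None:
        return explicit
    return (
        "greedy_forward"
        if n_requested < GREEDY_FORWARD_LIMIT
        else "mutual_information"
    )


# ---------------------------------------------------------------------------
# Model-complexity heuristic
# ---------------------------------------------------------------------------


@dataclass
class ComplexityEstimate:
    """Result of the two-stage model-complexity heuristic."""

    n_fit_param: int
    n_recommended: int
    stage1: SelectionTrace
    stage2: SelectionTrace
    target_reached: bool


def estimate_complexity(
    pool: CandidatePairPool,
    rmsd_mat: np.ndarray,
    target_rmsd: float,
    max_pairs: int | None = None,
    **err_kwargs,
) -> ComplexityEstimate:
    """Two-stage estimate of model complexity and measurement count.

    Stage 1 runs forward selection with zero fit parameters until the
    target <<RMSD>> is reached; the number of chosen pairs estimates
    N_fit.param (each informative pair acts as one model coordinate).
    Stage 2 repeats the selection with that N_fit.param held fixed (seeded
    with the stage-1 pairs, which are the fitted coordinates); the new
    count is the recommended number of measurements including
    cross-validation, and always exceeds the estimate so that N_dof > 0.
    """
    # with no measurements every conformer is equally plausible (p = 1):
    # the baseline uncertainty is the plain mean of the RMSD matrix
    baseline = float(rmsd_mat.mean())
    if baseline <= target_rmsd:
        trivial = SelectionTrace(
            "greedy_forward", [], [], [], "target met without measurements"
        )
        return ComplexityEstimate(0, 1, trivial, trivial, True)
    stage1 = select_greedy_forward(
        pool, rmsd_mat, target_rmsd=target_rmsd, max_pairs=max_pairs,
        n_fit_param=0, **err_kwargs,
    )
    n_fit = len(stage1.selected)
    reached1 = stage1.stop_criterion == "target reached"
    if n_fit == 0:
        # degenerate (e.g. rigid) ensemble: nothing to fit
        return ComplexityEstimate(0, 1, stage1, stage1, reached1)
    stage2 = select_greedy_forward(
        pool,
        rmsd_mat,
        target_rmsd=target_rmsd,
        max_pairs=max_pairs,
        n_fit_param=n_fit,
        initial=[pool.pair_ids.index(pid) for pid in stage1.selected],
        **err_kwargs,
    )
    reached = stage2.stop_criterion == "target reached"
    if not (reached1 and reached):
        warnings.warn(
            "target <<RMSD>> not reached with the available pool; the "
            "complexity estimate is a lower bound",
            stacklevel=2,
        )
    return ComplexityEstimate(
        n_fit, len(stage2.selected), stage1, stage2, reached1 and reached
    )


def rigid_body_n_fit_param(n_bodies: int, n_bonds: int = 0) -> int:
    """Analytic fit-parameter count for a rigid-body model:
    (N_bodies - 1) * 6 - N_bonds."""
    return (n_bodies - 1) * 6 - n_bonds


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def _parse_site(spec: str, role: str) -> LabelingSite:
    chain, resid, atom = spec.split(":")
    return LabelingSite(chain, int(resid), atom, role=role)


def read_pool_csv(path: str | Path, r0: float = 52.0) -> list[FRETPair]:
    """Read a candidate-pair CSV with columns donor, acceptor (chain:resid:atom)
    and optional r0."""
    df = pd.read_csv(path)
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            FRETPair(
                donor=_parse_site(str(row.donor), "donor"),
                acceptor=_parse_site(str(row.acceptor), "acceptor"),
                r0=float(getattr(row, "r0", r0)),
            )
        )
    return pairs


def read_exclusions_csv(path: str | Path) -> dict[str, str]:
    """Read a site-exclusion CSV with columns site (chain:resid:atom), reason."""
    df = pd.read_csv(path)
    return {str(r.site): str(r.reason) for r in df.itertuples(index=False)}


def plot_selection_trace(trace: SelectionTrace, path: str | Path) -> None:
    """Save an expected-uncertainty-vs-pair-count curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, len(trace.values) + 1), trace.values, "o-")
    ax.set_xlabel("number of FRET pairs")
    ax.set_ylabel(r"$\langle\langle \mathrm{RMSD} \rangle\rangle$ / $\AA$")
    ax.set_title(trace.algorithm)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
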