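"""Statistical screening of conformers against FRET distance sets.

Agreement of a conformer with a measurement set is the weighted sum of
squared residuals chi2 = sum_i ((R_conf_i - R_ref_i) / dR_ref_i)^2.  With
N_dof = N_measurements - N_fit.param degrees of freedom, a p-value follows
from the chi-squared survival function.  Because a fixed confidence level
maps to different reduced chi-squared values as N_dof varies, conformers of
models with different complexity are compared on the *normalized*
chi-squared chi2_n = chi2 / chi2_68%(N_dof), which equals 1 exactly at the
68% (one-sigma) confidence bound for any N_dof.  Conformers with chi2_n < 1
form the FRET-selected ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedQualityError
from .structure_io import Ensemble, rmsd_matrix
from .dye_model import (
    ACVParams,
    FRETPair,
    MeasurementSet,
    compute_av,
    model_distance,
)

__all__ = [
    "ScreeningResult",
    "chi2",
    "n_dof",
    "p_value",
    "chi2_reduced",
    "chi2_threshold",
    "chi2_n",
    "model_distances",
    "screen_ensemble",
]

#: Selection threshold on chi2_n (one-sigma confidence bound).
SELECTION_THRESHOLD = 1.0
#: Convergence criterion on the maximum pairwise RMSD of the selection (A).
CONVERGENCE_RMSD = 3.0


def chi2(model_distances: dict[str, float], meas: MeasurementSet) -> float:
    """Weighted sum of squared deviations of model vs. reference distances."""
    total = 0.0
    for rec in meas.records:
        if rec.pair_id not in model_distances:
            raise KeyError(f"no model distance for pair {rec.pair_id!r}")
        total += ((model_distances[rec.pair_id] - rec.r_ref) / rec.dr_ref) ** 2
    return total


def n_dof(n_meas: int, n_fit_param: int) -> int:
    """Degrees of freedom: measurements minus fitted parameters.

    May be <= 0; quality statistics must refuse such values.
    """
    if n_meas < 0 or n_fit_param < 0:
        raise ValueError("counts must be nonnegative")
    return n_meas - n_fit_param


def _require_dof(k: int) -> None:
    if k < 1:
        raise UndefinedQualityError(
            f"N_dof = {k} <= 0: the model is not overdetermined. Add "
            "cross-validation FRET pairs that were not used for fitting."
        )


def p_value(chi2_value: float, n_dof: int) -> float:
    """Probability that a chi-squared sample exceeds ``chi2_value``.

    Upper-tail integral of the chi-squared density with ``n_dof`` degrees
    of freedom (survival function).
    """
    _require_dof(n_dof)
    return float(stats.chi2.sf(chi2_value, df=n_dof))


def chi2_reduced(chi2_value: float, n_dof: int) -> float:
    """Chi-squared per degree of freedom."""
    _require_dof(n_dof)
    return chi2_value / n_dof


def chi2_threshold(confidence: float = 0.68, n_dof: int = 1) -> float:
    """Chi-squared value at the given upper-tail confidence bound.

    The value c with p_value(c, n_dof) = 1 - confidence, i.e. the
    chi-squared upper-tail quantile.  At confidence 0.68 this is the
    one-sigma bound used to normalize chi2_n.
    """
    _require_dof(n_dof)
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return float(stats.chi2.isf(1.0 - confidence, df=n_dof))


def chi2_n(chi2_value: float, n_dof: int, confidence: float = 0.68) -> float:
    """Normalized chi-squared: chi2 relative to its confidence bound.

    Equals 1 exactly when chi2 sits at the 68% bound, independent of
    N_dof, which makes models of different complexity directly comparable.
    """
    return chi2_value / chi2_threshold(confidence, n_dof)


@dataclass
class ScreeningResult:
    """Per-conformer screening statistics and the FRET-selected ensemble."""

    labels: list[str]
    chi2: np.ndarray
    p: np.ndarray
    chi2_r: np.ndarray
    chi2_n: np.ndarray
    n_dof: int
    n_fit_param: int
    selected_indices: list[int] = field(default_factory=list)
    max_selected_rmsd: float = float("nan")
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "conformer": self.labels,
                "chi2": self.chi2,
                "p": self.p,
                "chi2_r": self.chi2_r,
                "chi2_n": self.chi2_n,
            }
        )
        df["selected"] = [i in set(self.selected_indices) for i in range(len(df))]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def model_distances(
    conf,
    pairs: list[FRETPair],
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    kind: str = "mean_RDA",
) -> dict[str, float]:
    """AV-based model distances for all pairs on one conformer.

    Pairs with a buried site are omitted from the result.
    """
    av_cache = {}
    out: dict[str, float] = {}
    for pair in pairs:
        for site in (pair.donor, pair.acceptor):
            if site.site_id not in av_cache:
                av_cache[site.site_id] = compute_av(conf, site, grid_spacing, acv)
        av_d = av_cache[pair.donor.site_id]
        av_a = av_cache[pair.acceptor.site_id]
        if av_d.empty or av_a.empty:
            continue
        out[pair.pair_id] = model_distance(av_d, av_a, kind)
    return out


def screen_ensemble(
    ens: Ensemble,
    pairs: list[FRETPair],
    meas: MeasurementSet,
    n_fit_param: int = 0,
    grid_spacing: float = 0.9,
    acv: ACVParams | None = None,
    confidence: float = 0.68,
    selection_threshold: float = SELECTION_THRESHOLD,
    convergence_rmsd: float = CONVERGENCE_RMSD,
) -> tuple[ScreeningResult, Ensemble | None]:
    """Score every conformer against a measurement set and select the
    FRET-consistent sub-ensemble (chi2_n below the selection threshold).

    Also reports the maximum pairwise C-alpha RMSD within the selection and
    whether the ensemble is converged (all pairwise RMSD below the
    convergence criterion, 3 A by default).
    """
    k = n_dof(meas.n_measurements, n_fit_param)
    _require_dof(k)

    chi2_vals = np.empty(ens.n_conf)
    for i, conf in enumerate(ens):
        dists = model_distances(conf, pairs, grid_spacing, acv)
        chi2_vals[i] = chi2(dists, meas)

    bound = chi2_threshold(confidence, k)
    p_vals = stats.chi2.sf(chi2_vals, df=k)
    result = ScreeningResult(
        labels=ens.labels,
        chi2=chi2_vals,
        p=p_vals,
        chi2_r=chi2_vals / k,
        chi2_n=chi2_vals / bound,
        n_dof=k,
        n_fit_param=n_fit_param,
    )
    result.selected_indices = [
        int(i) for i in np.flatnonzero(result.chi2_n < selection_threshold)
    ]
    selection = None
    if result.selected_indices:
        selection = ens.subset(result.selected_indices)
        if selection.n_conf > 1:
            sub = rmsd_matrix(selection)
            result.max_selected_rmsd = float(sub.max())
        else:
            result.max_selected_rmsd = 0.0
        result.converged = result.max_selected_rmsd < convergence_rmsd
    return result, selection
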