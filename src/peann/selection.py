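"""Tenfold cross-validation for joint choice of hidden units H and decay lambda.

Subjects (not person-period rows) are randomly assigned to K folds of nearly
equal size.  For each fold an ensemble is fitted on the remaining subjects and
evaluated on the held-out subjects' person-period rows.  The criterion is the
negative mean held-out log-likelihood per row,

    score = -(1 / sum_i J_i) * sum_ij ( d_ij log h^(-m(i)) - h^(-m(i)) tau_ij ),

where h^(-m(i)) is the ensemble hazard fitted without subject i's fold.
Smaller is better; overfitted configurations blow up because held-out hazards
collapse toward 0 or spike where no events are.  The grid search picks the
minimizing (H, lambda), breaking ties toward fewer hidden units, then a larger
decay (parsimony, then smoothness).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .fitting import FitConfig, fit_ensemble
from .netmodel import hazard_forward
from .survdata import IntervalGrid, SurvivalCohort, expand_person_period

__all__ = ["CVResult", "assign_folds", "cv_criterion", "cv_score", "grid_search"]

# Advised explorative range for the decay parameter.
LAMBDA_RANGE = (1e-3, 1e-1)


@dataclass
class CVResult:
    grid_cells: list[tuple[int, float]]  # (H, lambda) per cell
    scores: np.ndarray
    folds: np.ndarray  # subject -> fold index
    selected: tuple[int, float]
    diagnostics: dict

    def score_table(self):
        """Scores reshaped as a lambda-by-H table (rows: lambda, cols: H)."""
        import pandas as pd

        Hs = sorted({h for h, _ in self.grid_cells})
        lams = sorted({l for _, l in self.grid_cells})
        tab = pd.DataFrame(index=lams, columns=Hs, dtype=float)
        for (h, l), s in zip(self.grid_cells, self.scores):
            tab.loc[l, h] = s
        tab.index.name = "decay"
        tab.columns = [f"H={h}" for h in Hs]
        return tab

    def to_dict(self) -> dict:
        return {
            "grid": [[h, l] for h, l in self.grid_cells],
            "scores": self.scores.tolist(),
            "folds": self.folds.tolist(),
            "selected": {"H": self.selected[0], "lam": self.selected[1]},
            "diagnostics": self.diagnostics,
        }


def assign_folds(cohort: SurvivalCohort, K: int = 10, seed: int = 0) -> np.ndarray:
    """Random subject-level fold assignment with sizes differing by <= 1."""
    n = cohort.n
    if n < K:
        raise ValueError(f"need at least K={K} subjects, got {n}")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % K
    return folds[rng.permutation(n)]


def cv_criterion(d: np.ndarray, tau: np.ndarray, h: np.ndarray) -> float:
    """Negative mean log-likelihood per person-period row for given hazards."""
    d = np.asarray(d, float)
    tau = np.asarray(tau, float)
    h = np.asarray(h, float)
    return float(-(d @ np.log(h) - tau @ h) / d.size)


def cv_score(
    cohort: SurvivalCohort,
    grid: IntervalGrid,
    H: int,
    lam: float,
    folds: np.ndarray,
    config: FitConfig = FitConfig(),
) -> tuple[float, dict]:
    """Cross-validated criterion for one (H, lambda) cell.

    Per-fold ensembles reuse ``config.n_starts`` restarts; member seeds are
    derived from ``config.seed`` and the fold index so folds are independent
    but reproducible.
    """
    folds = np.asarray(folds)
    if folds.size != cohort.n:
        raise ValueError("fold assignment must cover every subject")
    pp_all = expand_person_period(cohort, grid)
    held_h = np.empty(pp_all.n_rows)
    diag = {"fold_events": [], "fold_converged": []}
    for m in np.unique(folds):
        train = cohort.subset(folds != m)
        if train.events.sum() == 0:
            warnings.warn(f"fold {m}: training set has zero events")
        pp_train = expand_person_period(train, grid, encoding=pp_all.encoding)
        fold_cfg = FitConfig(
            n_starts=config.n_starts,
            init_range=config.init_range,
            max_iter=config.max_iter,
            grad_tol=config.grad_tol,
            seed=int(np.random.SeedSequence([config.seed, int(m)]).generate_state(1)[0] % (2**31)),
        )
        ens = fit_ensemble(pp_train, H, lam, fold_cfg)
        # evaluate the held-out ensemble on the held-out subjects' rows
        subj_mask = folds[pp_all.subject] == m
        X = pp_all.X[subj_mask]
        t = pp_all.t_scaled[subj_mask]
        hvals = np.mean([hazard_forward(net, X, t) for net in ens.members], axis=0)
        held_h[subj_mask] = hvals
        diag["fold_events"].append(int(cohort.subset(folds == m).events.sum()))
        diag["fold_converged"].append(
            sum(net.diagnostics.get("converged", False) for net in ens.members)
        )
    return cv_criterion(pp_all.d, pp_all.tau, held_h), diag


def grid_search(
    cohort: SurvivalCohort,
    grid: IntervalGrid,
    H_list,
    lam_list,
    K: int = 10,
    config: FitConfig = FitConfig(),
) -> CVResult:
    """CV score for every (H, lambda) cell; select the minimizer."""
    H_list = list(H_list)
    lam_list = list(lam_list)
    if not H_list or not lam_list:
        raise ValueError("H_list and lam_list must be nonempty")
    for lam in lam_list:
        if not (LAMBDA_RANGE[0] <= lam <= LAMBDA_RANGE[1]):
            warnings.warn(
                f"decay {lam} outside the advised explorative range "
                f"{LAMBDA_RANGE[0]:g}-{LAMBDA_RANGE[1]:g}"
            )
    folds = assign_folds(cohort, K, config.seed)
    cells, scores, diags = [], [], {}
    for H in H_list:
        for lam in lam_list:
            s, diag = cv_score(cohort, grid, H, lam, folds, config)
            cells.append((int(H), float(lam)))
            scores.append(s)
            diags[f"H={H},lam={lam}"] = diag
    scores_arr = np.asarray(scores)
    # argmin with ties broken toward smaller H, then larger lambda
    order = sorted(
        range(len(cells)), key=lambda i: (scores_arr[i], cells[i][0], -cells[i][1])
    )
    selected = cells[order[0]]
    return CVResult(cells, scores_arr, folds, selected, diags)
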