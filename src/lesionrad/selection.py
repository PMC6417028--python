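"""Three-stage feature selection: variance threshold -> univariate filter
-> LASSO, applied per sequence.

Stage 1 keeps features whose across-lesion variance is >= the threshold
(default 0.8) on the raw feature scale.  Stage 2 keeps features whose
two-sided Mann-Whitney U test between classes gives p <= 0.05 (no
multiple-testing correction -- deliberately liberal).  Stage 3 fits a
linear (least-squares) LASSO on 0/1 labels over a log-spaced alpha grid,
picking the alpha that minimizes subject-grouped cross-validated MSE; the
selected features are those with nonzero coefficients at the optimum.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold, KFold

from .io import FeatureTable


@dataclasses.dataclass
class SelectionResult:
    """Per-sequence record of the cascade: survivors at each stage plus the
    LASSO alpha and coefficients."""

    sequence_tag: str
    all_names: list[str]
    names_after_variance: list[str]
    names_after_univariate: list[str]
    p_values: dict[str, float]
    lasso_alpha: float | None
    lasso_coefficients: dict[str, float]
    selected_names: list[str]
    alpha_grid: list[float] = dataclasses.field(default_factory=list)
    cv_mse: list[float] = dataclasses.field(default_factory=list)
    coefficient_path: dict[str, list[float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        chain = [set(self.selected_names), set(self.names_after_univariate),
                 set(self.names_after_variance), set(self.all_names)]
        for smaller, larger in zip(chain, chain[1:]):
            if not smaller <= larger:
                raise ValueError("selection cascade violates the subset chain")

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "input": len(self.all_names),
            "after_variance": len(self.names_after_variance),
            "after_univariate": len(self.names_after_univariate),
            "selected": len(self.selected_names),
        }

    def to_dict(self) -> dict:
        return {
            "sequence_tag": self.sequence_tag,
            "stage_counts": self.stage_counts,
            "names_after_variance": self.names_after_variance,
            "names_after_univariate": self.names_after_univariate,
            "p_values": self.p_values,
            "lasso_alpha": self.lasso_alpha,
            "lasso_coefficients": self.lasso_coefficients,
            "selected_names": self.selected_names,
            "alpha_grid": self.alpha_grid,
            "cv_mse": self.cv_mse,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def variance_filter(X: np.ndarray, names: list[str],
                    threshold: float = 0.8) -> list[str]:
    """Keep features whose (population) variance is >= threshold.

    Boundary rule: a variance exactly at the threshold is kept.
    """
    if X.shape[0] < 2:
        raise ValueError("variance undefined for a single-row table")
    variances = X.var(axis=0)
    return [n for n, v in zip(names, variances) if v >= threshold]


def univariate_filter(X: np.ndarray, names: list[str], labels: np.ndarray,
                      alpha: float = 0.05) -> tuple[list[str], dict[str, float]]:
    """Two-sided Mann-Whitney U per feature; keep p <= alpha."""
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present for the univariate filter")
    g0 = labels == 0
    g1 = labels == 1
    p_values: dict[str, float] = {}
    kept: list[str] = []
    for idx, name in enumerate(names):
        x = X[:, idx]
        if np.all(x[g0] == x[g0][0]) and np.all(x == x[g0][0]):
            p = 1.0  # identical constant in both classes
        else:
            p = float(stats.mannwhitneyu(x[g1], x[g0],
                                         alternative="two-sided").pvalue)
        p_values[name] = p
        if p <= alpha:
            kept.append(name)
    return kept, p_values


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def lasso_select(X: np.ndarray, names: list[str], labels: np.ndarray,
                 alpha_grid: np.ndarray | None = None,
                 cv_folds: int = 5,
                 groups: np.ndarray | None = None,
                 seed: int = 0) -> dict:
    """L1-penalized least-squares selection with CV-chosen alpha.

    Features are standardized internally; the optimal alpha minimizes the
    mean cross-validated MSE (subject-grouped folds when groups are
    given).  ``alpha=0`` entries in the grid are fitted by ordinary least
    squares.
    """
    n, p = X.shape
    if n < cv_folds:
        raise ValueError(f"need at least {cv_folds} rows for {cv_folds}-fold CV")
    if alpha_grid is None:
        alpha_grid = np.logspace(-4, 0.5, 60)
    alpha_grid = np.sort(np.asarray(alpha_grid, dtype=float))
    y = np.asarray(labels, dtype=np.float64)
    Xs = _standardize(X)

    if groups is not None and len(np.unique(groups)) >= cv_folds:
        splitter = GroupKFold(n_splits=cv_folds)
        splits = list(splitter.split(Xs, y, groups=groups))
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(Xs, y))

    def fit_coefs(Xtr, ytr, alpha):
        if alpha == 0:
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(Xtr)), Xtr]), ytr, rcond=None)
            return coef[1:], coef[0]
        model = Lasso(alpha=alpha, max_iter=50000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        return model.coef_, model.intercept_

    cv_mse = []
    for alpha in alpha_grid:
        errs = []
        for tr, te in splits:
            coef, intercept = fit_coefs(Xs[tr], y[tr], alpha)
            pred = Xs[te] @ coef + intercept
            errs.append(float(np.mean((pred - y[te]) ** 2)))
        cv_mse.append(float(np.mean(errs)))
    best_idx = int(np.argmin(cv_mse))
    best_alpha = float(alpha_grid[best_idx])

    path = {}
    for alpha in alpha_grid:
        coef, _ = fit_coefs(Xs, y, alpha)
        path[float(alpha)] = coef
    best_coef = path[best_alpha]
    coefficients = {name: float(c) for name, c in zip(names, best_coef)}
    selected = [name for name, c in coefficients.items() if c != 0.0]
    return {
        "alpha": best_alpha,
        "coefficients": coefficients,
        "selected": selected,
        "alpha_grid": [float(a) for a in alpha_grid],
        "cv_mse": cv_mse,
        "coefficient_path": {name: [float(path[float(a)][i]) for a in alpha_grid]
                             for i, name in enumerate(names)},
    }


def select_pipeline(table: FeatureTable, sequence_tag: str,
                    variance_threshold: float = 0.8,
                    univariate_alpha: float = 0.05,
                    alpha_grid: np.ndarray | None = None,
                    cv_folds: int = 5,
                    seed: int = 0,
                    feature_names: list[str] | None = None) -> SelectionResult:
    """Run the full cascade on one sequence's feature columns.

    An empty survivor set at any stage yields a valid result with an empty
    selection (and a warning) rather than an error; downstream model
    fitting is then skipped for that sequence.
    """
    names = feature_names if feature_names is not None \
        else table.sequence_columns(sequence_tag)
    if not names:
        raise ValueError(f"no feature columns for sequence {sequence_tag!r}")
    labels = table.labels
    X = table.values(names)

    kept_var = variance_filter(X, names, variance_threshold)
    if not kept_var:
        warnings.warn(f"{sequence_tag}: variance filter removed every feature")
        return SelectionResult(sequence_tag, names, [], [], {}, None, {}, [])

    Xv = table.values(kept_var)
    kept_uni, p_values = univariate_filter(Xv, kept_var, labels, univariate_alpha)
    if not kept_uni:
        warnings.warn(f"{sequence_tag}: univariate filter removed every feature")
        return SelectionResult(sequence_tag, names, kept_var, [], p_values,
                               None, {}, [])

    Xu = table.values(kept_uni)
    lasso = lasso_select(Xu, kept_uni, labels, alpha_grid=alpha_grid,
                         cv_folds=cv_folds, groups=table.subjects, seed=seed)
    if not lasso["selected"]:
        warnings.warn(f"{sequence_tag}: LASSO selected no features")
    return SelectionResult(
        sequence_tag=sequence_tag,
        all_names=names,
        names_after_variance=kept_var,
        names_after_univariate=kept_uni,
        p_values=p_values,
        lasso_alpha=lasso["alpha"],
        lasso_coefficients=lasso["coefficients"],
        selected_names=lasso["selected"],
        alpha_grid=lasso["alpha_grid"],
        cv_mse=lasso["cv_mse"],
        coefficient_path=lasso["coefficient_path"],
    )


def plot_coefficient_path(result: SelectionResult, path: str | Path) -> None:
    """Diagnostic plot of LASSO coefficients versus alpha (log scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    alphas = result.alpha_grid
    for name, coefs in result.coefficient_path.items():
        ax1.plot(alphas, coefs, lw=0.8)
    ax1.set_xscale("log")
    ax1.set_xlabel("alpha")
    ax1.set_ylabel("coefficient")
    ax1.set_title(f"{result.sequence_tag}: coefficient path")
    ax2.plot(alphas, result.cv_mse)
    if result.lasso_alpha is not None:
        ax2.axvline(result.lasso_alpha, color="red", ls="--",
                    label=f"alpha* = {result.lasso_alpha:.4g}")
        ax2.legend()
    ax2.set_xscale("log")
    ax2.set_xlabel("alpha")
    ax2.set_ylabel("CV MSE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
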