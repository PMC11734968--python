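"""Pairwise mixed graphical model estimation by nodewise ℓ1 regression.

Each variable is regressed on all others — linear for Gaussian nodes,
multinomial logistic for categorical nodes — with an ℓ1 penalty whose
strength is selected per node by the Extended Bayesian Information
Criterion (EBIC, hyper-parameter γ).  Nonzero coefficients define candidate
edges; the two directed estimates of a pair are combined by the AND rule
(edge kept only when both regressions select it; OR available) into a
symmetric signed weighted network.  Edge magnitudes are on the standardized
scale and comparable to partial correlations for Gaussian pairs; pairs that
involve a categorical node are unsigned.

Moderated models augment every nodewise regression with product terms
``x_j·x_m`` for a designated continuous moderator ``m``, estimating the
strength of three-way interactions with the same selection machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, lasso_path

from .data_io import MixedDataset, VariableSpec, standardize_continuous

__all__ = [
    "EstimatorConfig",
    "NodewiseFit",
    "WeightedNetwork",
    "PredictabilityReport",
    "ModeratedNetwork",
    "ebic_score",
    "fit_nodewise",
    "aggregate_network",
    "predictability",
    "fit_moderated",
    "estimate_mgm",
]

#: Coefficients below this absolute value count as zero (saga may leave
#: sub-threshold noise where coordinate descent returns exact zeros).
ZERO_TOL = 1e-6

_LOGLIK_VAR_FLOOR = 1e-12


def ebic_score(loglik: float, df: int, n: int, q: int, gamma: float) -> float:
    """Extended BIC: −2·loglik + df·ln(n) + 2·γ·df·ln(q).

    ``q`` is the number of candidate predictor terms in the nodewise
    regression; γ = 0 recovers the ordinary BIC.
    """
    if n < 1 or q < 1 or gamma < 0:
        raise ValueError("need n >= 1, q >= 1, gamma >= 0")
    return -2.0 * loglik + df * np.log(n) + 2.0 * gamma * df * np.log(q)


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by every nodewise fit of one network estimation."""

    gamma: float = 0.25
    rule: str = "AND"
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    moderator: str | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be AND or OR")


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class _Design:
    X: np.ndarray
    var: list[str]        # source variable per column
    label: list[str]      # term label per column
    is_mod: np.ndarray    # True for product (moderation) columns


def _build_design(
    dataset: MixedDataset, exclude: str, moderator: str | None = None
) -> _Design:
    """Dummy-expanded predictor matrix for one nodewise regression.

    Categorical predictors are coded against their first level.  When a
    moderator is given, product columns ``term·x_m`` are appended for every
    main-effect term whose source variable is neither the response nor the
    moderator itself.
    """
    cols: list[np.ndarray] = []
    var: list[str] = []
    label: list[str] = []
    for s in dataset.specs:
        if s.name == exclude:
            continue
        if s.is_categorical:
            codes = dataset.values[s.name].astype(str).to_numpy()
            for level in s.levels[1:]:
                cols.append((codes == level).astype(float))
                var.append(s.name)
                label.append(f"{s.name}={level}")
        else:
            cols.append(dataset.values[s.name].to_numpy(dtype=float))
            var.append(s.name)
            label.append(s.name)
    is_mod = [False] * len(cols)
    if moderator is not None:
        spec_m = dataset.spec(moderator)
        if spec_m.is_categorical:
            raise ValueError("categorical moderators are not supported")
        xm = dataset.values[moderator].to_numpy(dtype=float)
        if np.std(xm) == 0:
            raise ValueError(f"moderator {moderator!r} is constant")
        for j in range(len(cols)):
            if var[j] in (exclude, moderator) or is_mod[j]:
                continue
            cols.append(cols[j] * xm)
            var.append(var[j])
            label.append(f"{label[j]}*{moderator}")
            is_mod.append(True)
    return _Design(
        X=np.column_stack(cols),
        var=var,
        label=label,
        is_mod=np.asarray(is_mod, dtype=bool),
    )


def _response(dataset: MixedDataset, node: str) -> tuple[np.ndarray, str]:
    spec = dataset.spec(node)
    if spec.is_categorical:
        codes = dataset.values[node].astype(str).map(
            {l: i for i, l in enumerate(spec.levels)}
        )
        return codes.to_numpy(dtype=int), "categorical"
    return dataset.values[node].to_numpy(dtype=float), "gaussian"


def _default_grid(
    X: np.ndarray, y: np.ndarray, kind: str, n_lambdas: int, min_ratio: float
) -> np.ndarray:
    """Log-spaced λ grid from λ_max (all-zero fit) down to min_ratio·λ_max."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    if kind == "gaussian":
        lam_max = np.max(np.abs(Xc.T @ (y - y.mean()))) / n
    else:
        classes = np.unique(y)
        Y = (y[:, None] == classes[None, :]).astype(float)
        resid = Y.mean(axis=0)[None, :] - Y
        lam_max = np.max(np.abs(Xc.T @ resid)) / n
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


# ---------------------------------------------------------------------------
# nodewise fits


@dataclass
class NodewiseFit:
    """One ℓ1-penalized nodewise regression with its EBIC-selected λ."""

    node: str
    kind: str                      # "gaussian" | "categorical"
    lambda_grid: np.ndarray
    selected_lambda: float
    coef: np.ndarray               # (q,) gaussian, (n_classes', q) categorical
    intercept: np.ndarray
    terms: tuple[str, ...]         # label per design column
    term_var: tuple[str, ...]      # source variable per design column
    term_is_mod: np.ndarray
    loglik: float
    df: int
    ebic: float
    ebic_path: np.ndarray
    fitted: np.ndarray             # yhat (gaussian) or predicted level index
    y: np.ndarray
    n: int
    q: int
    skipped_lambdas: tuple[float, ...] = ()

    @property
    def coefficients(self) -> dict[str, float]:
        """Term label → coefficient (gaussian) or max-|coef| across classes."""
        c = self.coef if self.coef.ndim == 1 else np.abs(self.coef).max(axis=0)
        return dict(zip(self.terms, c.tolist()))

    def _block(self, variable: str, moderation: bool) -> np.ndarray:
        idx = [
            j
            for j, v in enumerate(self.term_var)
            if v == variable and self.term_is_mod[j] == moderation
        ]
        if not idx:
            return np.zeros(0)
        block = self.coef[..., idx]
        return np.ravel(block)

    def block(self, variable: str) -> np.ndarray:
        """All main-effect coefficients linking ``variable`` in this fit."""
        return self._block(variable, moderation=False)

    def moderation_block(self, variable: str) -> np.ndarray:
        """All product-term coefficients pairing ``variable`` with the moderator."""
        return self._block(variable, moderation=True)


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, _LOGLIK_VAR_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _fit_gaussian_path(X, y, grid):
    """Coefficients along the λ grid via coordinate-descent lasso."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    _, coefs, _ = lasso_path(Xc, yc, alphas=grid)
    # lasso_path returns alphas descending; our grid is already descending
    out = []
    for a_idx in range(coefs.shape[1]):
        w = coefs[:, a_idx]
        resid = yc - Xc @ w
        rss = float(resid @ resid)
        intercept = y_mean - x_mean @ w
        out.append((w, np.atleast_1d(intercept), _gaussian_loglik(rss, len(y)), None))
    return out, []


def _fit_categorical_path(X, y, grid, skipped):
    """Multinomial-logistic ℓ1 path, warm-started across descending λ (lazy)."""
    n = X.shape[0]
    clf = LogisticRegression(
        penalty="l1",
        solver="saga",
        warm_start=True,
        fit_intercept=True,
        max_iter=2000,
        tol=1e-3,
    )
    for lam in grid:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        if not converged:
            skipped.append(float(lam))
            yield None
            continue
        logp = clf.predict_log_proba(X)
        class_pos = np.searchsorted(clf.classes_, y)
        loglik = float(logp[np.arange(n), class_pos].sum())
        yield clf.coef_.copy(), clf.intercept_.copy(), loglik, clf.classes_.copy()


def fit_nodewise(
    dataset: MixedDataset,
    node: str,
    lambda_grid: Sequence[float] | None = None,
    gamma: float = 0.25,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    moderator: str | None = None,
) -> NodewiseFit:
    """Fit one node's ℓ1 regression path and select λ by EBIC.

    The dataset is expected standardized (continuous columns mean 0, SD 1).
    ``df`` counts nonzero coefficients at each λ; ties in EBIC are broken
    toward the larger λ (sparser model).
    """
    design = _build_design(dataset, exclude=node, moderator=moderator)
    y, kind = _response(dataset, node)
    col_sd = design.X.std(axis=0)
    if np.any(col_sd == 0):
        bad = design.label[int(np.argmax(col_sd == 0))]
        raise ValueError(f"zero-variance predictor term {bad!r}")
    if lambda_grid is None:
        grid = _default_grid(design.X, y, kind, n_lambdas, lambda_min_ratio)
    else:
        grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)
    n, q = design.X.shape

    skipped: list[float] = []
    if kind == "gaussian":
        path, skipped = _fit_gaussian_path(design.X, y, grid)
        patience = None
    else:
        path = _fit_categorical_path(design.X, y, grid, skipped)
        # descending the λ path past the EBIC optimum only densifies the
        # model; stop after this many consecutive non-improving λ values
        patience = 8

    best = None
    since_best = 0
    ebic_path = np.full(len(grid), np.nan)
    for idx, entry in enumerate(path):
        if entry is None:
            continue
        coef, intercept, loglik, classes = entry
        df = int(np.sum(np.abs(coef) > ZERO_TOL))
        score = ebic_score(loglik, df, n, q, gamma)
        ebic_path[idx] = score
        if best is None or score < best[0]:
            best = (score, idx, coef, intercept, loglik, df, classes)
            since_best = 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                break
    if best is None:
        raise RuntimeError(f"no lambda converged for node {node!r}")
    if skipped:
        warnings.warn(
            f"node {node!r}: {len(skipped)} lambda value(s) skipped "
            "(solver not converged)",
            stacklevel=2,
        )
    score, idx, coef, intercept, loglik, df, classes = best

    coef = np.asarray(coef)
    if kind == "gaussian":
        fitted = design.X @ coef + float(intercept[0])
    else:
        scoremat = design.X @ coef.T + intercept
        if coef.shape[0] == 1:  # binary: single decision column
            pred_pos = (scoremat[:, 0] > 0).astype(int)
            fitted = classes[pred_pos]
        else:
            fitted = classes[np.argmax(scoremat, axis=1)]

    return NodewiseFit(
        node=node,
        kind=kind,
        lambda_grid=grid,
        selected_lambda=float(grid[idx]),
        coef=coef,
        intercept=np.atleast_1d(intercept),
        terms=tuple(design.label),
        term_var=tuple(design.var),
        term_is_mod=design.is_mod,
        loglik=float(loglik),
        df=df,
        ebic=float(score),
        ebic_path=ebic_path,
        fitted=np.asarray(fitted),
        y=np.asarray(y),
        n=n,
        q=q,
        skipped_lambdas=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric nonnegative edge magnitudes with a separate sign layer.

    ``sign`` is ±1 only for continuous–continuous edges whose two directed
    coefficients agree in sign, and 0 (undefined) otherwise; edges touching
    a categorical node are flagged by ``involves_categorical``.
    """

    nodes: tuple[str, ...]
    magnitude: np.ndarray
    sign: np.ndarray
    involves_categorical: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.nodes)
        for name in ("magnitude", "sign", "involves_categorical"):
            m = getattr(self, name)
            if m.shape != (p, p):
                raise ValueError(f"{name} must be p x p")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.diag(self.magnitude) != 0):
            raise ValueError("magnitude diagonal must be zero")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be nonnegative")
        bad = (self.sign != 0) & ((self.magnitude == 0) | self.involves_categorical)
        if np.any(bad):
            raise ValueError("sign defined on a zero or categorical edge")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def edge_frame(self, include_zero: bool = False) -> pd.DataFrame:
        """Upper-triangle edge list (node_i, node_j, magnitude, sign, …)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.magnitude[i, j] == 0 and not include_zero:
                    continue
                rows.append(
                    {
                        "node_i": self.nodes[i],
                        "node_j": self.nodes[j],
                        "magnitude": float(self.magnitude[i, j]),
                        "sign": int(self.sign[i, j]),
                        "involves_categorical": bool(
                            self.involves_categorical[i, j]
                        ),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["node_i", "node_j", "magnitude", "sign", "involves_categorical"],
        )

    def thresholded(self, min_magnitude: float) -> "WeightedNetwork":
        """Copy with edges of magnitude ≤ ``min_magnitude`` suppressed."""
        keep = self.magnitude > min_magnitude
        return WeightedNetwork(
            nodes=self.nodes,
            magnitude=np.where(keep, self.magnitude, 0.0),
            sign=np.where(keep, self.sign, 0),
            involves_categorical=self.involves_categorical,
        )

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_frame().iterrows():
            g.add_edge(
                row.node_i,
                row.node_j,
                magnitude=row.magnitude,
                sign=int(row.sign),
                involves_categorical=bool(row.involves_categorical),
            )
        nx.write_graphml(g, str(path))


def _directed_magnitudes(
    fits: Mapping[str, NodewiseFit], nodes: Sequence[str], moderation: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = len(nodes)
    mag = np.zeros((p, p))
    nz = np.zeros((p, p), dtype=bool)
    sgn = np.zeros((p, p))
    for i, ni in enumerate(nodes):
        fit = fits[ni]
        for j, nj in enumerate(nodes):
            if i == j:
                continue
            block = (
                fit.moderation_block(nj) if moderation else fit.block(nj)
            )
            if block.size == 0:
                continue
            nz[i, j] = bool(np.any(np.abs(block) > ZERO_TOL))
            mag[i, j] = float(np.mean(np.abs(block)))
            if block.size == 1:
                sgn[i, j] = np.sign(block[0]) if np.abs(block[0]) > ZERO_TOL else 0
    return mag, nz, sgn


def aggregate_network(
    fits: Mapping[str, NodewiseFit],
    specs: Sequence[VariableSpec],
    rule: str = "AND",
) -> WeightedNetwork:
    """Combine the p directed nodewise fits into one symmetric network.

    Directed magnitude i→j is the mean of the absolute values of all
    coefficient terms linking j in i's fit (several terms when categorical
    levels are involved).  Under AND an edge needs both directions nonzero
    (magnitude = mean of the two); under OR the mean of the nonzero
    direction(s) suffices.  Signs are defined only for continuous pairs
    whose two directed coefficients agree.
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be AND or OR")
    nodes = tuple(s.name for s in specs)
    if set(fits) != set(nodes):
        raise ValueError("fits do not cover the node set")
    is_cat = np.array([s.is_categorical for s in specs])
    mag_d, nz_d, sgn_d = _directed_magnitudes(fits, nodes)
    p = len(nodes)
    magnitude = np.zeros((p, p))
    sign = np.zeros((p, p))
    involves = is_cat[:, None] | is_cat[None, :]
    np.fill_diagonal(involves, False)
    for i in range(p):
        for j in range(i + 1, p):
            both, either = nz_d[i, j] and nz_d[j, i], nz_d[i, j] or nz_d[j, i]
            if rule == "AND":
                if both:
                    magnitude[i, j] = 0.5 * (mag_d[i, j] + mag_d[j, i])
            elif either:
                vals = [m for m, f in ((mag_d[i, j], nz_d[i, j]), (mag_d[j, i], nz_d[j, i])) if f]
                magnitude[i, j] = float(np.mean(vals))
            if (
                magnitude[i, j] > 0
                and not involves[i, j]
                and sgn_d[i, j] != 0
                and sgn_d[i, j] == sgn_d[j, i]
            ):
                sign[i, j] = sgn_d[i, j]
            magnitude[j, i] = magnitude[i, j]
            sign[j, i] = sign[i, j]
    return WeightedNetwork(
        nodes=nodes, magnitude=magnitude, sign=sign, involves_categorical=involves
    )


# ---------------------------------------------------------------------------
# predictability


@dataclass(frozen=True)
class PredictabilityReport:
    """Per-node predictability: R² (continuous) or accuracy vs mode baseline."""

    r2: Mapping[str, float]
    accuracy: Mapping[str, float]
    baseline: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": k, "measure": "R2", "value": v, "baseline": np.nan}
            for k, v in self.r2.items()
        ] + [
            {
                "node": k,
                "measure": "accuracy",
                "value": v,
                "baseline": self.baseline[k],
            }
            for k, v in self.accuracy.items()
        ]
        return pd.DataFrame(rows, columns=["node", "measure", "value", "baseline"])


def predictability(
    dataset: MixedDataset, fits: Mapping[str, NodewiseFit]
) -> PredictabilityReport:
    """In-sample predictability of every node from its selected nodewise model."""
    r2: dict[str, float] = {}
    acc: dict[str, float] = {}
    base: dict[str, float] = {}
    for node, fit in fits.items():
        if fit.kind == "gaussian":
            resid = fit.y - fit.fitted
            tss = float(np.sum((fit.y - fit.y.mean()) ** 2))
            r2[node] = float(max(0.0, 1.0 - float(resid @ resid) / tss))
        else:
            acc[node] = float(np.mean(fit.fitted == fit.y))
            counts = np.bincount(fit.y)
            base[node] = float(counts.max() / counts.sum())
    return PredictabilityReport(r2=r2, accuracy=acc, baseline=base)


# ---------------------------------------------------------------------------
# moderated models


@dataclass(frozen=True)
class ModeratedNetwork:
    """A pairwise network plus three-way term strengths for one moderator."""

    base: WeightedNetwork
    moderator: str
    moderation_magnitude: np.ndarray

    def __post_init__(self) -> None:
        m = self.base.index(self.moderator)
        if np.any(self.moderation_magnitude[m]) or np.any(
            self.moderation_magnitude[:, m]
        ):
            raise ValueError("moderation row/column of the moderator must be zero")

    def moderation_frame(self) -> pd.DataFrame:
        rows = []
        p = self.base.p
        for i in range(p):
            for j in range(i + 1, p):
                if self.moderation_magnitude[i, j] > 0:
                    rows.append(
                        {
                            "node_i": self.base.nodes[i],
                            "node_j": self.base.nodes[j],
                            "moderator": self.moderator,
                            "magnitude": float(self.moderation_magnitude[i, j]),
                        }
                    )
        return pd.DataFrame(
            rows, columns=["node_i", "node_j", "moderator", "magnitude"]
        )


def fit_moderated(
    dataset: MixedDataset,
    moderator: str,
    lambda_grid: Sequence[float] | None = None,
    gamma: float = 0.25,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    rule: str = "AND",
) -> ModeratedNetwork:
    """Fit the moderated network for one continuous moderator.

    Every nodewise regression (except the moderator's own) gains product
    terms ``x_j·x_m``; the three-way strength of pair (i, j) is aggregated
    from the two product coefficients by the same mean-of-absolutes + AND
    convention as pairwise edges.
    """
    spec_m = dataset.spec(moderator)
    if spec_m.is_categorical:
        raise ValueError("categorical moderators are not supported")
    if np.std(dataset.values[moderator].to_numpy(dtype=float)) == 0:
        raise ValueError(f"moderator {moderator!r} is constant")
    fits = {}
    for s in dataset.specs:
        mod = moderator if s.name != moderator else None
        fits[s.name] = fit_nodewise(
            dataset,
            s.name,
            lambda_grid=lambda_grid,
            gamma=gamma,
            n_lambdas=n_lambdas,
            lambda_min_ratio=lambda_min_ratio,
            moderator=mod,
        )
    base = aggregate_network(fits, dataset.specs, rule=rule)
    nodes = base.nodes
    mag_d, nz_d, _ = _directed_magnitudes(fits, nodes, moderation=True)
    p = len(nodes)
    mod_mag = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if nz_d[i, j] and nz_d[j, i]:
                mod_mag[i, j] = mod_mag[j, i] = 0.5 * (mag_d[i, j] + mag_d[j, i])
    m = base.index(moderator)
    mod_mag[m, :] = 0.0
    mod_mag[:, m] = 0.0
    return ModeratedNetwork(base=base, moderator=moderator, moderation_magnitude=mod_mag)


# ---------------------------------------------------------------------------
# one-call estimation


def estimate_mgm(
    dataset: MixedDataset,
    config: EstimatorConfig | None = None,
) -> tuple[WeightedNetwork, dict[str, NodewiseFit]]:
    """Standardize, fit all nodewise regressions, and aggregate the network."""
    config = config or EstimatorConfig()
    std, _ = standardize_continuous(dataset)
    fits = {
        s.name: fit_nodewise(
            std,
            s.name,
            gamma=config.gamma,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        for s in std.specs
    }
    network = aggregate_network(fits, std.specs, rule=config.rule)
    return network, fits
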