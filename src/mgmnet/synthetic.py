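"""Planted pairwise models and samplers for mixed (Gaussian + categorical) data.

The generative family is the same pairwise Markov random field the estimator
assumes: continuous nodes enter through linear-Gaussian conditionals,
categorical nodes through multinomial-logistic conditionals, and every
pairwise dependence is encoded by one entry of a symmetric interaction
matrix.  Planted models are block-structured — overlapping or disjoint
communities with a stronger within-community weight — so community
detection, edge recovery and index computations all have exact ground truth.

For an all-continuous model the joint is the zero-mean Gaussian whose
precision matrix is ``D − W`` (``W`` the pairwise weights, ``D`` a diagonal
loading chosen to make the matrix positive definite), and the planted
partial correlation of a pair equals ``W_ij`` divided by the loading.  A
complete block of ``m`` equal partial correlations ρ is only realizable for
ρ < 1/(m−1); beyond that the loading attenuates every partial uniformly,
preserving the within/between contrast that structure-recovery experiments
need.  A warning is emitted when the attenuation exceeds 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import MixedDataset, VariableSpec

__all__ = [
    "Moderation",
    "PlantedModel",
    "make_planted_model",
    "sample_mgm",
    "true_partial_correlations",
    "study_mimic",
    "exclusion_flow_dataset",
    "write_planted_model",
    "STUDY_VARIABLES",
]

#: Margin added above λmax(W) when diagonal loading is required.
_PD_MARGIN = 0.05


def _level_scores(n_levels: int) -> np.ndarray:
    """Centered, unit-variance numeric scores for the levels of a categorical node."""
    raw = np.arange(n_levels, dtype=float)
    raw -= raw.mean()
    return raw / raw.std()


@dataclass(frozen=True)
class Moderation:
    """A sparse set of three-way interaction terms sharing one moderator."""

    moderator: str
    terms: tuple[tuple[str, str, float], ...]  # (node_i, node_j, strength)


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth pairwise model with planted community structure.

    ``pair_params`` is symmetric with zero diagonal; entry (i, j) is the
    pairwise interaction weight (0 = conditional independence).
    ``community_labels`` maps node name → set of community ids (empty =
    isolated).  ``diagonal`` may pin the precision diagonal explicitly; when
    ``None`` a minimal positive-definite loading is computed.
    """

    specs: tuple[VariableSpec, ...]
    pair_params: np.ndarray
    community_labels: Mapping[str, frozenset[int]]
    cont_means: Mapping[str, float] = field(default_factory=dict)
    cont_sds: Mapping[str, float] = field(default_factory=dict)
    moderation: Moderation | None = None
    diagonal: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.pair_params, dtype=float)
        if W.shape != (self.p, self.p):
            raise ValueError("pair_params shape does not match spec count")
        if not np.allclose(W, W.T):
            raise ValueError("pair_params must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("pair_params must have zero diagonal")

    @property
    def p(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def is_all_continuous(self) -> bool:
        return all(not s.is_categorical for s in self.specs)

    def loading(self) -> np.ndarray:
        """Diagonal of the implied precision (explicit or minimal PD loading).

        With moderation terms the conditional Gaussian subsystem must stay
        positive definite for every configuration of the conditioning
        variables on the truncated support, so each three-way term adds its
        worst-case coupling |t|·clip to the three pairs it touches before
        the spectral bound is taken.
        """
        if self.diagonal is not None:
            return np.asarray(self.diagonal, dtype=float)
        W = np.asarray(self.pair_params, dtype=float)
        lam_max = float(np.linalg.eigvalsh(W)[-1]) if self.p else 0.0
        if self.moderation is not None:
            extra = np.zeros_like(W)
            name_to_idx = {name: i for i, name in enumerate(self.names)}
            m = name_to_idx[self.moderation.moderator]
            for ni, nj, t in self.moderation.terms:
                i, j = name_to_idx[ni], name_to_idx[nj]
                for a_, b_ in ((i, j), (i, m), (j, m)):
                    extra[a_, b_] += abs(t) * _GIBBS_CLIP
                    extra[b_, a_] = extra[a_, b_]
            lam_max += float(np.linalg.eigvalsh(extra)[-1])
        a = max(1.0, lam_max + _PD_MARGIN)
        if a > 1.0 / 0.95:
            warnings.warn(
                f"diagonal loading {a:.3f} attenuates planted partial "
                f"correlations by more than 5% (factor {1/a:.3f})",
                stacklevel=2,
            )
        return np.full(self.p, a)

    def precision(self) -> np.ndarray:
        """Implied precision matrix Θ = diag(loading) − W (all-continuous view)."""
        theta = np.diag(self.loading()) - np.asarray(self.pair_params, dtype=float)
        return theta

    def communities(self) -> dict[int, frozenset[str]]:
        """Invert the node → community-ids map."""
        out: dict[int, set[str]] = {}
        for name, ids in self.community_labels.items():
            for cid in ids:
                out.setdefault(cid, set()).add(name)
        return {cid: frozenset(members) for cid, members in out.items()}


def true_partial_correlations(model: PlantedModel) -> np.ndarray:
    """Planted partial correlations ρ_ij = −Θ_ij / √(Θ_ii·Θ_jj), diagonal 1.

    Only defined for all-continuous models (the Gaussian case, where the
    precision matrix determines the partials in closed form).
    """
    if not model.is_all_continuous:
        raise ValueError("partial correlations require an all-continuous model")
    theta = model.precision()
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _plant(
    specs: Sequence[VariableSpec],
    memberships: Mapping[int, Sequence[int]],
    within_weight: float,
    between_weight: float,
    rng: np.random.Generator,
    neg_fraction: float = 0.25,
    between_pairs: Sequence[tuple[int, int]] | None = None,
    extra_edges: Sequence[tuple[int, int, float]] = (),
) -> tuple[np.ndarray, dict[str, frozenset[int]]]:
    """Build the block pair-parameter matrix for explicit community memberships."""
    p = len(specs)
    W = np.zeros((p, p))

    def put(i: int, j: int, w: float) -> None:
        sign = -1.0 if rng.random() < neg_fraction else 1.0
        W[i, j] = W[j, i] = sign * w

    for members in memberships.values():
        ms = sorted(members)
        for a_i, i in enumerate(ms):
            for j in ms[a_i + 1 :]:
                if W[i, j] == 0:
                    put(i, j, within_weight)
    if between_weight != 0:
        if between_pairs is None:
            # one random cross edge between each consecutive pair of communities
            cids = sorted(memberships)
            between_pairs = []
            for c1, c2 in zip(cids, cids[1:]):
                only1 = [i for i in memberships[c1] if i not in memberships[c2]]
                only2 = [j for j in memberships[c2] if j not in memberships[c1]]
                if only1 and only2:
                    between_pairs.append(
                        (int(rng.choice(only1)), int(rng.choice(only2)))
                    )
        for i, j in between_pairs:
            if W[i, j] == 0:
                put(i, j, between_weight)
    for i, j, w in extra_edges:
        if W[i, j] == 0:
            sign = -1.0 if rng.random() < neg_fraction else 1.0
            W[i, j] = W[j, i] = sign * w
    labels = {
        s.name: frozenset(
            cid for cid, members in memberships.items() if i in set(members)
        )
        for i, s in enumerate(specs)
    }
    return W, labels


def make_planted_model(
    n_continuous: int,
    categorical_specs: Sequence[int],
    community_sizes: Sequence[int],
    within_weight: float,
    between_weight: float,
    n_isolated: int,
    seed: int,
    neg_fraction: float = 0.25,
    moderation: Moderation | None = None,
) -> PlantedModel:
    """Plant disjoint block communities over ``p`` mixed nodes.

    Nodes are ordered continuous first (``V01``, ``V02``, …) then categorical
    (``C1``, …, with the given level counts); communities are filled in node
    order and the last ``n_isolated`` nodes stay edge-free.  Every
    within-community pair receives ``±within_weight`` (negative with
    probability ``neg_fraction``); one random between-community pair per
    consecutive community pair receives ``±between_weight``.
    """
    p = n_continuous + len(categorical_specs)
    if sum(community_sizes) + n_isolated != p:
        raise ValueError(
            f"community sizes {tuple(community_sizes)} + {n_isolated} isolated "
            f"must cover p = {p} nodes"
        )
    if abs(within_weight) <= abs(between_weight) and within_weight != 0:
        raise ValueError("|within_weight| must exceed |between_weight|")
    rng = np.random.default_rng(seed)
    specs = [
        VariableSpec(name=f"V{i + 1:02d}", domain="continuous")
        for i in range(n_continuous)
    ]
    specs += [
        VariableSpec(
            name=f"C{c + 1}",
            domain="categorical",
            levels=tuple(str(l) for l in range(n_levels)),
        )
        for c, n_levels in enumerate(categorical_specs)
    ]
    memberships: dict[int, list[int]] = {}
    start = 0
    for cid, size in enumerate(community_sizes):
        memberships[cid] = list(range(start, start + size))
        start += size
    W, labels = _plant(
        specs, memberships, within_weight, between_weight, rng, neg_fraction
    )
    return PlantedModel(
        specs=tuple(specs),
        pair_params=W,
        community_labels=labels,
        moderation=moderation,
    )


# ---------------------------------------------------------------------------
# sampling


def _sample_gaussian_exact(
    model: PlantedModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    theta = model.precision()
    eigvals = np.linalg.eigvalsh(theta)
    if eigvals[0] <= 0:
        raise ValueError("all-continuous model has a non-positive-definite precision")
    sigma = np.linalg.inv(theta)
    d = 1.0 / np.sqrt(np.diag(sigma))
    corr = sigma * np.outer(d, d)  # unit-variance scale
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n, model.p)) @ chol.T


def _moderation_terms_idx(
    model: PlantedModel,
) -> list[tuple[int, int, int, float]]:
    if model.moderation is None:
        return []
    name_to_idx = {name: i for i, name in enumerate(model.names)}
    m = name_to_idx[model.moderation.moderator]
    return [
        (name_to_idx[i], name_to_idx[j], m, t)
        for i, j, t in model.moderation.terms
    ]


#: Support truncation (in SDs) for Gibbs draws.  A pairwise model with
#: three-way (moderation) terms has a non-normalizable density on an
#: unbounded domain; restricting the continuous support to ±_GIBBS_CLIP
#: makes the joint proper while leaving the bulk of the distribution alone.
_GIBBS_CLIP = 3.0


def _sample_gibbs(
    model: PlantedModel,
    n: int,
    rng: np.random.Generator,
    burn_in: int,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Parallel-chain Gibbs: n independent chains, one draw each after burn-in.

    Running one chain per observation (vectorized across chains) returns
    exactly independent rows at the cost of ``burn_in`` sweeps, instead of
    autocorrelated rows from a single long chain.
    """
    p = model.p
    W = np.asarray(model.pair_params, dtype=float)
    loading = model.loading()
    cat_idx = [i for i, s in enumerate(model.specs) if s.is_categorical]
    scores = {i: _level_scores(len(model.specs[i].levels)) for i in cat_idx}
    mod_terms = _moderation_terms_idx(model)

    Z = rng.standard_normal((n, p))
    levels: dict[int, np.ndarray] = {}
    for i in cat_idx:
        lv = rng.integers(0, len(model.specs[i].levels), size=n)
        levels[i] = lv
        Z[:, i] = scores[i][lv]

    for _ in range(burn_in):
        for s in range(p):
            eta = Z @ W[:, s]
            for i, j, m, t in mod_terms:
                if s == i:
                    eta += t * Z[:, j] * Z[:, m]
                elif s == j:
                    eta += t * Z[:, i] * Z[:, m]
                elif s == m:
                    eta += t * Z[:, i] * Z[:, j]
            if s in levels:
                logits = np.outer(eta, scores[s])
                gumbel = rng.gumbel(size=logits.shape)
                lv = np.argmax(logits + gumbel, axis=1)
                levels[s] = lv
                Z[:, s] = scores[s][lv]
            else:
                a = loading[s]
                draw = eta / a + rng.standard_normal(n) / np.sqrt(a)
                Z[:, s] = np.clip(draw, -_GIBBS_CLIP, _GIBBS_CLIP)
    return Z, {model.specs[i].name: levels[i] for i in cat_idx}


def sample_mgm(
    model: PlantedModel,
    n: int,
    seed: int,
    burn_in: int = 200,
) -> MixedDataset:
    """Draw ``n`` observations from a planted model.

    All-continuous models without moderation are sampled exactly from the
    implied Gaussian (on the unit-variance scale) and then de-standardized
    by ``cont_means``/``cont_sds``.  Models with categorical nodes or
    moderation terms are sampled by parallel-chain Gibbs (``burn_in`` sweeps
    over the full conditionals per chain); their continuous columns are
    empirically standardized before de-standardization so the reported
    location/scale calibration is exact.
    """
    rng = np.random.default_rng(seed)
    exact = model.is_all_continuous and model.moderation is None
    if exact:
        Z = _sample_gaussian_exact(model, n, rng)
        cat_levels: dict[str, np.ndarray] = {}
    else:
        Z, cat_levels = _sample_gibbs(model, n, rng, burn_in)

    columns: dict[str, object] = {}
    for i, s in enumerate(model.specs):
        if s.is_categorical:
            columns[s.name] = np.asarray(s.levels, dtype=object)[cat_levels[s.name]]
        else:
            col = Z[:, i]
            if not exact:
                col = (col - col.mean()) / col.std()
            mu = float(model.cont_means.get(s.name, 0.0))
            sd = float(model.cont_sds.get(s.name, 1.0))
            columns[s.name] = col * sd + mu
    table = pd.DataFrame(columns, columns=list(model.names))
    return MixedDataset(values=table, specs=model.specs)


# ---------------------------------------------------------------------------
# the 30-node study mimic

# (name, mean, sd, display_group) for the 28 continuous constructs; the two
# categorical nodes (an 8-level disease history and a 3-level mental-health
# history) are appended after them.
STUDY_VARIABLES: tuple[tuple[str, float, float, str], ...] = (
    ("MWB", 55.6, 5.88, "outcome"),
    ("QoL", 94.7, 9.46, "outcome"),
    ("HAP", 7.80, 1.02, "mental_health"),
    ("DEP", 15.9, 4.59, "mental_health"),
    ("ANX", 11.0, 3.32, "mental_health"),
    ("PS", 10.5, 5.42, "stress"),
    ("LON", 2.76, 3.07, "mental_health"),
    ("SSD", 15.0, 4.43, "mental_health"),
    ("HEA", 82.8, 13.6, "lifestyle"),
    ("SQ", 5.3, 3.22, "lifestyle"),
    ("CON", 168.8, 73.9, "lifestyle"),
    ("SMA", 69.4, 11.5, "coping"),
    ("BC", 21.5, 3.66, "coping"),
    ("PAS", 0.04, 0.6, "coping"),
    ("GSE", 32.6, 4.14, "coping"),
    ("SE", 33.0, 4.17, "coping"),
    ("BRS", 21.3, 3.88, "coping"),
    ("SPoA", 51.8, 9.18, "ageism"),
    ("PNA", 7.39, 2.61, "ageism"),
    ("PPA", 9.56, 2.28, "ageism"),
    ("PRM", 24.5, 4.8, "lifestyle"),
    ("BOR", 1.74, 0.74, "mental_health"),
    ("AU", 3.35, 2.15, "lifestyle"),
    ("PHY", 3619.1, 2098.2, "lifestyle"),
    ("SES", 85.0, 10.3, "demographics"),
    ("URB", 2859.0, 2665.0, "demographics"),
    ("MLE", 7.13, 6.42, "stress"),
    ("SI", 70.2, 8.52, "stress"),
)

# Overlapping community template (node indices into the order above + the two
# categorical nodes at 28, 29): five communities of sizes 12, 6, 6, 4, 4
# chained by single shared nodes, two nodes community-less.
_MIMIC_MEMBERSHIPS: dict[int, tuple[int, ...]] = {
    0: tuple(range(0, 12)),       # psycho-social block (MWB … SMA)
    1: tuple(range(11, 17)),      # coping block, shares SMA
    2: tuple(range(16, 22)),      # ageing-perception block, shares BRS
    3: tuple(range(21, 25)),      # lifestyle block, shares BOR
    4: tuple(range(24, 28)),      # context block, shares SES
}


def study_mimic(
    seed: int,
    n: int = 2000,
    within_weight: float = 0.3,
    between_weight: float = 0.05,
    neg_fraction: float = 0.25,
    moderation: Moderation | None = None,
) -> tuple[PlantedModel, MixedDataset]:
    """A 30-node mixed dataset shaped like the study sample.

    28 continuous constructs calibrated to the published means/SDs (e.g.
    mental well-being 55.6/5.88, quality of life 94.7/9.46), one 8-level and
    one 3-level categorical history variable, and five planted overlapping
    communities of sizes (12, 6, 6, 4, 4); the categorical nodes attach only
    through weak edges and stay outside every community.
    """
    rng = np.random.default_rng(seed)
    specs = [
        VariableSpec(name=name, domain="continuous", display_group=group)
        for name, _, _, group in STUDY_VARIABLES
    ]
    specs.append(
        VariableSpec(
            name="PND",
            domain="categorical",
            levels=tuple(str(l) for l in range(8)),
            display_group="health",
        )
    )
    specs.append(
        VariableSpec(
            name="MHD",
            domain="categorical",
            levels=tuple(str(l) for l in range(3)),
            display_group="health",
        )
    )
    # weak attachments keeping the categorical nodes connected but communityless
    extra = [(28, 8, between_weight), (29, 3, between_weight)]
    W, labels = _plant(
        specs,
        _MIMIC_MEMBERSHIPS,
        within_weight,
        between_weight,
        rng,
        neg_fraction,
        extra_edges=extra,
    )
    model = PlantedModel(
        specs=tuple(specs),
        pair_params=W,
        community_labels=labels,
        cont_means={name: mu for name, mu, _, _ in STUDY_VARIABLES},
        cont_sds={name: sd for name, _, sd, _ in STUDY_VARIABLES},
        moderation=moderation,
    )
    dataset = sample_mgm(model, n, seed=int(rng.integers(2**31)))
    return model, dataset


def exclusion_flow_dataset(
    seed: int,
    n_total: int = 2886,
    n_invalid_postal: int = 176,
    n_activity_outliers: int = 217,
) -> MixedDataset:
    """An inventory-completer table emulating the study's exclusion flow.

    ``n_total`` rows carry a postal-validity flag (``n_invalid_postal`` rows
    invalid) and a physical-activity score whose bulk is uniform (so the MAD
    rule at threshold 2.5 never flags it) with ``n_activity_outliers``
    extreme values planted among the postal-valid rows — the robust filter
    applied after the postal exclusion flags exactly those.
    """
    rng = np.random.default_rng(seed)
    if n_invalid_postal + n_activity_outliers > n_total:
        raise ValueError("planted exclusions exceed the table size")
    postal = np.array(["yes"] * n_total, dtype=object)
    postal[rng.choice(n_total, size=n_invalid_postal, replace=False)] = "no"
    # bulk uniform: MAD = range/4, so the 2.5 robust-z cutoff exceeds the range
    activity = rng.uniform(1000.0, 6000.0, size=n_total)
    valid_rows = np.flatnonzero(postal == "yes")
    outlier_rows = rng.choice(valid_rows, size=n_activity_outliers, replace=False)
    activity[outlier_rows] = rng.uniform(25_000.0, 40_000.0, size=n_activity_outliers)
    table = pd.DataFrame({"postal_valid": postal, "PHY": activity})
    specs = (
        VariableSpec("postal_valid", "categorical", levels=("yes", "no")),
        VariableSpec("PHY", "continuous"),
    )
    return MixedDataset(values=table, specs=specs)


def write_planted_model(model: PlantedModel, path: str | Path) -> None:
    """Serialize the planted truth (weights, labels) as YAML for test oracles."""
    doc = {
        "nodes": list(model.names),
        "pair_params": [
            {"i": model.names[i], "j": model.names[j], "weight": float(w)}
            for i in range(model.p)
            for j in range(i + 1, model.p)
            if (w := model.pair_params[i, j]) != 0
        ],
        "community_labels": {
            name: sorted(ids) for name, ids in model.community_labels.items()
        },
        "cont_means": {k: float(v) for k, v in model.cont_means.items()},
        "cont_sds": {k: float(v) for k, v in model.cont_sds.items()},
        "moderation": (
            None
            if model.moderation is None
            else {
                "moderator": model.moderation.moderator,
                "terms": [
                    {"i": i, "j": j, "strength": float(t)}
                    for i, j, t in model.moderation.terms
                ],
            }
        ),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
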