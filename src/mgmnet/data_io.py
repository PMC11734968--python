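"""Mixed tabular data with per-variable domain declarations.

A *mixed dataset* is a rectangular table in which every column is declared
either continuous (Gaussian) or categorical (a finite set of levels).  The
declaration travels with the data as a structured sidecar (YAML) so that
every downstream stage — estimation, resampling, community analysis — knows
each variable's domain without re-inference.

Preprocessing mirrors a typical epidemiological exclusion flow: ordered,
named row predicates, each counted against the rows surviving the earlier
rules, an optional robust (median absolute deviation) outlier filter, and
sparse-category pooling for categorical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "MixedDataset",
    "ExclusionReport",
    "read_mixed_table",
    "write_mixed_table",
    "mad_outlier_flags",
    "apply_exclusions",
    "FrameRule",
    "merge_sparse_categories",
    "standardize_continuous",
    "MAD_CONSISTENCY",
    "DEFAULT_MAD_THRESHOLD",
]

#: Normal-consistency constant for the MAD scale estimate (1/Φ⁻¹(3/4)).
MAD_CONSISTENCY = 1.4826

#: Default robust-z cutoff for the outlier filter.
DEFAULT_MAD_THRESHOLD = 2.5


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single column's domain.

    Parameters
    ----------
    name
        Column identifier, unique within a dataset.
    domain
        ``"continuous"`` or ``"categorical"``.
    levels
        Ordered level labels; required (≥ 2) for categorical variables and
        must be empty for continuous ones.
    display_group
        Optional free-form grouping label (e.g. ``"lifestyle"``).
    """

    name: str
    domain: str
    levels: tuple[str, ...] = ()
    display_group: str | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("continuous", "categorical"):
            raise ValueError(f"unknown domain {self.domain!r} for {self.name!r}")
        if self.domain == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical variable {self.name!r} needs >= 2 levels")
        if self.domain == "continuous" and self.levels:
            raise ValueError(f"continuous variable {self.name!r} must not declare levels")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))

    @property
    def is_categorical(self) -> bool:
        return self.domain == "categorical"


@dataclass(frozen=True)
class MixedDataset:
    """An N×p table plus the aligned variable specifications."""

    values: pd.DataFrame
    specs: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in spec")
        if list(self.values.columns) != names:
            raise ValueError("spec order does not match table columns")
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("dataset needs N >= 1 rows and p >= 2 columns")
        for s in self.specs:
            col = self.values[s.name]
            if col.isna().any():
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise ValueError(f"missing value in column {s.name!r} at row {row}")
            if s.is_categorical:
                observed = set(col.astype(str))
                extra = observed - set(s.levels)
                if extra:
                    raise ValueError(
                        f"column {s.name!r} contains undeclared level(s) {sorted(extra)}"
                    )

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def p(self) -> int:
        return int(self.values.shape[1])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs if not s.is_categorical)

    def categorical_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs if s.is_categorical)


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for an ordered exclusion flow."""

    initial_count: int
    per_rule_removed: tuple[tuple[str, int], ...]
    remaining: int
    selected: int

    def __post_init__(self) -> None:
        removed = sum(c for _, c in self.per_rule_removed)
        if self.remaining != self.initial_count - removed:
            raise ValueError("remaining inconsistent with per-rule counts")
        if not 0 <= self.selected <= self.remaining:
            raise ValueError("selected outside [0, remaining]")

    def to_text(self) -> str:
        lines = [f"initial: {self.initial_count}"]
        for rule, count in self.per_rule_removed:
            lines.append(f"removed by {rule}: {count}")
        lines.append(f"remaining: {self.remaining}")
        lines.append(f"selected: {self.selected}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reading / writing


def _specs_from_sidecar(doc: Sequence[Mapping]) -> tuple[VariableSpec, ...]:
    specs = []
    for entry in doc:
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                domain=str(entry["domain"]),
                levels=tuple(str(l) for l in entry.get("levels", []) or []),
                display_group=entry.get("display_group"),
            )
        )
    return tuple(specs)


def read_mixed_table(data_path: str | Path, spec_path: str | Path) -> MixedDataset:
    """Read a CSV table plus its variable-spec sidecar.

    The CSV must have a header row whose names match the sidecar's entries
    (same order).  Categorical cells are validated against the declared
    levels; any undeclared column, undeclared level or missing cell raises a
    :class:`ValueError` naming the offending column.
    """
    with open(spec_path) as fh:
        doc = yaml.safe_load(fh)
    specs = _specs_from_sidecar(doc["variables"] if isinstance(doc, Mapping) else doc)
    table = pd.read_csv(
        data_path,
        dtype={s.name: str for s in specs if s.is_categorical},
        float_precision="round_trip",
    )
    declared = [s.name for s in specs]
    if list(table.columns) != declared:
        extra = set(table.columns) - set(declared)
        missing = set(declared) - set(table.columns)
        raise ValueError(
            f"CSV columns do not match spec (undeclared: {sorted(extra)}, "
            f"missing: {sorted(missing)})"
        )
    for s in specs:
        if not s.is_categorical:
            table[s.name] = pd.to_numeric(table[s.name]).astype(float)
    return MixedDataset(values=table, specs=specs)


def write_mixed_table(
    dataset: MixedDataset, data_path: str | Path, spec_path: str | Path
) -> None:
    """Write the table as CSV (full float precision) and the spec as YAML."""
    dataset.values.to_csv(data_path, index=False, float_format="%.17g")
    doc = {
        "variables": [
            {
                "name": s.name,
                "domain": s.domain,
                **({"levels": list(s.levels)} if s.is_categorical else {}),
                **({"display_group": s.display_group} if s.display_group else {}),
            }
            for s in dataset.specs
        ]
    }
    with open(spec_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# preprocessing


def mad_outlier_flags(
    values: Sequence[float], threshold: float = DEFAULT_MAD_THRESHOLD
) -> np.ndarray:
    """Flag observations whose robust z-score exceeds ``threshold``.

    The robust z of ``x_i`` is ``|x_i − median| / (1.4826·MAD)`` with
    ``MAD = median(|x − median|)``.  A degenerate scale (MAD = 0) carries no
    outlier information, so nothing is flagged and a warning is emitted.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; outlier filter skipped", stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - med) / (MAD_CONSISTENCY * mad) > threshold


class FrameRule:
    """An exclusion rule evaluated on the whole surviving sub-table at once.

    Wraps a callable ``DataFrame → boolean array`` (True = remove).  Needed
    for statistics like the MAD outlier filter, whose cutoff depends on the
    rows that survived the earlier rules.
    """

    def __init__(self, fn: Callable[[pd.DataFrame], Sequence[bool]]):
        self.fn = fn

    def __call__(self, frame: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.fn(frame), dtype=bool)


def apply_exclusions(
    dataset: MixedDataset,
    rules: Sequence[tuple[str, Callable[[pd.Series], bool]]] | Sequence,
    select_first: int | None = None,
) -> tuple[MixedDataset, ExclusionReport]:
    """Apply named exclusion rules in order, then optionally keep the first rows.

    Each rule is a ``(name, predicate)`` pair; the predicate receives a row
    (:class:`pandas.Series`) and returns ``True`` when the row must be
    *removed* (or is a :class:`FrameRule` acting on the surviving table).
    Rules are counted sequentially: each sees only the rows that survived
    the earlier ones.  ``select_first`` keeps the first surviving rows in
    their original order.
    """
    table = dataset.values
    initial = len(table)
    keep = np.ones(initial, dtype=bool)
    per_rule: list[tuple[str, int]] = []
    for name, predicate in rules:
        idx = np.flatnonzero(keep)
        if isinstance(predicate, FrameRule):
            flags = predicate(table.iloc[idx])
            if flags.shape != (idx.size,):
                raise ValueError(f"rule {name!r} returned a wrong-length flag vector")
        else:
            flags = np.fromiter(
                (bool(predicate(table.iloc[i])) for i in idx),
                dtype=bool,
                count=idx.size,
            )
        per_rule.append((name, int(flags.sum())))
        keep[idx[flags]] = False
    remaining = int(keep.sum())
    if select_first is not None:
        if select_first > remaining:
            raise ValueError(
                f"select_first={select_first} exceeds remaining rows ({remaining})"
            )
        selected = select_first
    else:
        selected = remaining
    surviving = table.loc[keep].head(selected).reset_index(drop=True)
    report = ExclusionReport(
        initial_count=initial,
        per_rule_removed=tuple(per_rule),
        remaining=remaining,
        selected=selected,
    )
    return MixedDataset(values=surviving, specs=dataset.specs), report


def merge_sparse_categories(
    dataset: MixedDataset,
    variable: str,
    mapping: Mapping[str, str] | None = None,
    min_count: int | None = None,
    other_label: str = "other",
) -> MixedDataset:
    """Recode a categorical variable, either by an explicit level mapping or by
    pooling levels observed fewer than ``min_count`` times into one level."""
    spec = dataset.spec(variable)
    if not spec.is_categorical:
        raise ValueError(f"{variable!r} is not categorical")
    if (mapping is None) == (min_count is None):
        raise ValueError("provide exactly one of mapping / min_count")
    col = dataset.values[variable].astype(str)
    if mapping is not None:
        unknown = set(mapping) - set(spec.levels)
        if unknown:
            raise ValueError(f"mapping references unknown level(s) {sorted(unknown)}")
        full = {l: str(mapping.get(l, l)) for l in spec.levels}
    else:
        counts = col.value_counts()
        full = {
            l: (other_label if counts.get(l, 0) < min_count else l) for l in spec.levels
        }
    new_levels = tuple(dict.fromkeys(full.values()))  # first-appearance order
    new_col = col.map(full)
    new_spec = replace(spec, levels=new_levels)
    values = dataset.values.copy()
    values[variable] = new_col
    specs = tuple(new_spec if s.name == variable else s for s in dataset.specs)
    return MixedDataset(values=values, specs=specs)


def standardize_continuous(
    dataset: MixedDataset,
) -> tuple[MixedDataset, dict[str, tuple[float, float]]]:
    """Scale every continuous column to sample mean 0, sample SD 1 (ddof = 1).

    Returns the transformed dataset and the per-column ``(mean, sd)`` pairs
    so reports can map weights back to the original scale.  A zero-variance
    continuous column is an error (it cannot carry network structure).
    """
    if dataset.n < 2:
        raise ValueError("standardization needs at least 2 rows")
    values = dataset.values.copy()
    params: dict[str, tuple[float, float]] = {}
    for s in dataset.specs:
        if s.is_categorical:
            continue
        col = values[s.name].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0:
            raise ValueError(f"continuous column {s.name!r} has zero variance")
        values[s.name] = (col - mu) / sd
        params[s.name] = (mu, sd)
    return MixedDataset(values=values, specs=dataset.specs), params
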