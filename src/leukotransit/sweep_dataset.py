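"""Supervised-learning tables built from batch transit simulations.

Two datasets feed the surrogates.  The transit-time table maps the flow
condition (Re, AR) of every retained (non-impaction) sweep case to its
simulated transit time.  The motion/force tables map (Re, AR, downstream
displacement) to one of the four trajectory observables — deformation
extent R_max, downstream velocity V_y, fluid lift F_l or drag F_d — with
one row per stored trajectory sample.

Cases in which the cell lodges in the pore (impaction) never complete a
transit and are excluded before any table is built; the exclusion can come
from the simulated outcomes or from an explicit list (the canonical
six-pair corner of the study grid ships as a constant).

All tables carry a seeded train/validation/test split and per-column
min-max normalization to [-1, 1] fitted on the training split only.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SweepGrid",
    "SampleTable",
    "build_grid",
    "exclude_impaction",
    "make_time_table",
    "make_motion_table",
    "split_dataset",
    "STUDY_RE_VALUES",
    "STUDY_AR_VALUES",
    "PAPER_COMPAT_AR_VALUES",
    "CANONICAL_IMPACTION_PAIRS",
    "TIME_TEST_PAIRS",
    "MOTION_TEST_PAIRS",
    "MOTION_TARGETS",
]

# The study's sweep values: Re from 0.1 to 0.2 in steps of 0.01, AR from
# 0.5 to 0.95 in steps of 0.05.
STUDY_RE_VALUES = tuple(round(0.1 + 0.01 * i, 2) for i in range(11))
STUDY_AR_VALUES = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
# The stated case total (121) needs an 11th AR column; the compat grid
# appends AR = 1.0 (pore exactly cell-sized).
PAPER_COMPAT_AR_VALUES = STUDY_AR_VALUES + (1.0,)

# The six (Re, AR) combinations reported to end in impaction.
CANONICAL_IMPACTION_PAIRS = (
    (0.1, 0.5),
    (0.1, 0.55),
    (0.11, 0.5),
    (0.12, 0.5),
    (0.13, 0.5),
    (0.14, 0.5),
)

# Off-grid scenarios held out to test the transit-time surrogate.
TIME_TEST_PAIRS = (
    (0.2, 0.53),
    (0.19, 0.57),
    (0.18, 0.63),
    (0.17, 0.67),
    (0.16, 0.73),
    (0.15, 0.77),
    (0.14, 0.83),
    (0.13, 0.87),
    (0.12, 0.93),
    (0.11, 0.97),
)

# Scenarios held out to test the motion/force surrogates.
MOTION_TEST_PAIRS = ((0.16, 0.73), (0.15, 0.77), (0.14, 0.83), (0.13, 0.87))

MOTION_TARGETS = ("R_max", "V_y", "F_l", "F_d")


# ---------------------------------------------------------------------------
# sweep grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian (Re, AR) study grid with an optional exclusion list."""

    re_values: tuple
    ar_values: tuple
    exclusions: tuple = ()

    def cases(self) -> list:
        """All retained (Re, AR) pairs in deterministic Re-major order."""
        excluded = set(self.exclusions)
        return [
            (re, ar)
            for re, ar in itertools.product(self.re_values, self.ar_values)
            if (re, ar) not in excluded
        ]

    def __len__(self) -> int:
        return len(self.cases())


def build_grid(re_values, ar_values) -> SweepGrid:
    """Build a sweep grid from explicit Re and AR value lists.

    Values are sorted; duplicates are a configuration error.
    """
    re_values = tuple(float(v) for v in re_values)
    ar_values = tuple(float(v) for v in ar_values)
    if not re_values or not ar_values:
        raise ValueError("re_values and ar_values must be non-empty")
    for name, vals in (("re_values", re_values), ("ar_values", ar_values)):
        if len(set(vals)) != len(vals):
            raise ValueError(f"duplicate entries in {name}: {vals}")
    return SweepGrid(tuple(sorted(re_values)), tuple(sorted(ar_values)))


def exclude_impaction(grid: SweepGrid, outcomes=None, pairs=None) -> SweepGrid:
    """Drop impaction cases from a grid.

    Either ``outcomes`` (a mapping/DataFrame of simulated outcome flags, as
    produced by a sweep) or an explicit ``pairs`` list may be given.  Every
    excluded pair must exist in the grid.  An exclusion that empties the
    grid is rejected: there would be nothing left to train on.
    """
    if pairs is None:
        if outcomes is None:
            raise ValueError("provide simulated outcomes or an explicit pair list")
        if isinstance(outcomes, pd.DataFrame):
            bad = outcomes.loc[outcomes["outcome"] != "transit", ["Re", "AR"]]
            pairs = [tuple(r) for r in bad.itertuples(index=False)]
        else:
            pairs = [k for k, v in outcomes.items() if v != "transit"]
    pairs = [(float(re), float(ar)) for re, ar in pairs]
    gridset = set(itertools.product(grid.re_values, grid.ar_values))
    unknown = [p for p in pairs if p not in gridset]
    if unknown:
        raise ValueError(f"excluded pairs not in grid: {unknown}")
    out = SweepGrid(grid.re_values, grid.ar_values, tuple(sorted(set(grid.exclusions) | set(pairs))))
    if len(out) == 0:
        raise ValueError("exclusion removes every case; grid unusable for training")
    return out


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

_SPLIT_NAMES = ("train", "val", "test")


def split_dataset(n: int, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> np.ndarray:
    """Seeded random train/val/test assignment for ``n`` items.

    Counts follow floor-then-distribute rounding: each split gets
    ``floor(f*n)`` and leftover items go to the splits with the largest
    fractional remainders (ties broken in train/val/test order).  115 items
    at 60/20/20 therefore split 69/23/23.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("expected three fractions (train, val, test)")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError(f"fractions must lie in [0, 1], got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in range(rem):
        counts[order[i % 3]] += 1
    labels = np.repeat(np.array(_SPLIT_NAMES, dtype=object), counts)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Flat supervised table with normalization metadata and split labels.

    ``norm`` maps each input column and the target column to the (min, max)
    of the *training* rows, so no information from validation or test rows
    leaks into the scaling.  Normalized values are min-max mapped to
    [-1, 1].
    """

    df: pd.DataFrame
    input_columns: list
    target_column: str
    norm: dict = field(default_factory=dict)
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.input_columns) + [self.target_column]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"table is missing columns {missing}")
        if self.df[cols].isna().any().any():
            raise ValueError("table contains missing values")
        if "split" not in self.df.columns:
            raise ValueError("table has no split labels; use from_frame()")
        if not self.norm:
            self._fit_norm()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        input_columns,
        target_column: str,
        fractions=(0.6, 0.2, 0.2),
        seed: int = 0,
        provenance: dict | None = None,
    ) -> "SampleTable":
        """Attach a seeded split and train-fitted normalization to a frame.

        The split assignment is keyed to a canonical row ordering (sorted by
        the input columns), so shuffling the arrival order of rows does not
        change which sample lands in which split.
        """
        df = df.reset_index(drop=True).copy()
        order = df.sort_values(list(input_columns), kind="mergesort").index.to_numpy()
        labels_sorted = split_dataset(len(df), fractions, seed)
        labels = np.empty(len(df), dtype=object)
        labels[order] = labels_sorted
        df["split"] = labels
        return cls(df, list(input_columns), target_column, seed=seed, provenance=provenance or {})

    def _fit_norm(self) -> None:
        train = self.df[self.df["split"] == "train"]
        if len(train) == 0:
            raise ValueError("no training rows to fit normalization on")
        for col in list(self.input_columns) + [self.target_column]:
            lo = float(train[col].min())
            hi = float(train[col].max())
            if hi <= lo:
                raise ValueError(
                    f"column {col!r} is constant on the training split "
                    f"(min == max == {lo}); normalization would be degenerate. "
                    "Provide more than one distinct value (e.g. more sweep cases)."
                )
            self.norm[col] = (lo, hi)

    # -- normalization ------------------------------------------------------

    def normalize_column(self, values, col):
        lo, hi = self.norm[col]
        return 2.0 * (np.asarray(values, dtype=float) - lo) / (hi - lo) - 1.0

    def denormalize_column(self, values, col):
        lo, hi = self.norm[col]
        return (np.asarray(values, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo

    def normalized_arrays(self, split: str | None = None):
        """(X, Y) arrays in normalized units, optionally for one split."""
        sub = self.df if split is None else self.df[self.df["split"] == split]
        X = np.column_stack(
            [self.normalize_column(sub[c].to_numpy(), c) for c in self.input_columns]
        ) if len(sub) else np.empty((0, len(self.input_columns)))
        Y = self.normalize_column(sub[self.target_column].to_numpy(), self.target_column)
        return X, Y.reshape(-1, 1)

    def split_counts(self) -> dict:
        return self.df["split"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.df)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write the table as CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {
            "input_columns": list(self.input_columns),
            "target_column": self.target_column,
            "norm": {k: list(v) for k, v in self.norm.items()},
            "seed": self.seed,
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "SampleTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        df = pd.read_csv(path)
        return cls(
            df,
            meta["input_columns"],
            meta["target_column"],
            norm={k: tuple(v) for k, v in meta["norm"].items()},
            seed=meta["seed"],
            provenance=meta.get("provenance", {}),
        )


def toy_surface_table(
    n_re: int = 8,
    n_ar: int = 8,
    noise: float = 0.0,
    seed: int = 0,
    fractions=(0.6, 0.2, 0.2),
) -> SampleTable:
    """Analytic transit-time-like surface for exercising the network code.

    ``t(Re, AR) = (1/Re) * exp(2 * (1 - AR))`` sampled on a regular grid
    over the study box — smooth, monotone decreasing in both inputs, with
    the right qualitative shape (slow transit at low Re and tight pores) —
    so surrogate trainers can be tested without running the solver.
    Optional Gaussian noise (relative standard deviation ``noise``) is
    seeded.
    """
    re_vals = np.linspace(0.1, 0.2, n_re)
    ar_vals = np.linspace(0.5, 0.95, n_ar)
    RE, AR = np.meshgrid(re_vals, ar_vals, indexing="ij")
    t = (1.0 / RE) * np.exp(2.0 * (1.0 - AR))
    if noise > 0:
        rng = np.random.default_rng(seed)
        t = t * (1.0 + noise * rng.standard_normal(t.shape))
    df = pd.DataFrame(
        {"Re": RE.ravel(), "AR": AR.ravel(), "transit_time": t.ravel()}
    )
    return SampleTable.from_frame(
        df, ["Re", "AR"], "transit_time", fractions, seed, provenance={"kind": "toy"}
    )


def _provenance_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def make_time_table(
    summaries: pd.DataFrame, fractions=(0.6, 0.2, 0.2), seed: int = 0
) -> SampleTable:
    """(Re, AR) -> transit_time table from a sweep summary frame.

    Every row must be a completed transit; a lodged (impaction) or
    timed-out case present in the input is an error — exclude it first with
    :func:`exclude_impaction`.
    """
    required = {"Re", "AR", "outcome", "transit_time"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary frame is missing columns {sorted(missing)}")
    bad = summaries[summaries["outcome"] != "transit"]
    if len(bad):
        raise ValueError(
            f"{len(bad)} non-transit rows present (e.g. Re={bad.iloc[0]['Re']}, "
            f"AR={bad.iloc[0]['AR']}, outcome={bad.iloc[0]['outcome']}); "
            "exclude impaction cases before building the time table"
        )
    if len(summaries) < 2:
        raise ValueError(
            "at least two transit cases are needed for a non-degenerate table"
        )
    df = summaries[["Re", "AR", "transit_time"]].copy()
    return SampleTable.from_frame(
        df,
        ["Re", "AR"],
        "transit_time",
        fractions,
        seed,
        provenance={"kind": "time", "hash": _provenance_hash(df.values.tolist())},
    )


def make_motion_table(
    trajectories, target: str, fractions=(0.6, 0.2, 0.2), seed: int = 0
) -> SampleTable:
    """(Re, AR, displacement) -> observable table from stored trajectories.

    ``trajectories`` is an iterable of objects exposing ``Re``, ``AR`` and
    per-sample arrays ``displacement`` plus the requested target column
    (one of R_max, V_y, F_l, F_d).  Each trajectory contributes one row per
    stored sample, at the solver's output interval.
    """
    if target not in MOTION_TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {MOTION_TARGETS}")
    frames = []
    for traj in trajectories:
        series = traj.series(target) if hasattr(traj, "series") else getattr(traj, target)
        disp = np.asarray(traj.displacement, dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "Re": traj.Re,
                    "AR": traj.AR,
                    "displacement": disp,
                    target: np.asarray(series, dtype=float),
                }
            )
        )
    if not frames:
        raise ValueError("no trajectories supplied")
    df = pd.concat(frames, ignore_index=True)
    return SampleTable.from_frame(
        df,
        ["Re", "AR", "displacement"],
        target,
        fractions,
        seed,
        provenance={
            "kind": "motion",
            "target": target,
            "n_cases": len(frames),
            "hash": _provenance_hash([len(f) for f in frames]),
        },
    )
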