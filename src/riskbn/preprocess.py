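"""Analysis-variable derivation and discretization for the discrete network.

Turns a raw survey table (fixed CSV schema) into the all-discrete predictor
matrix the classifier consumes: binary suicidal-ideation outcome from PHQ-9
item 9, PHQ-8 total as the depression-severity predictor, equal-frequency
binning of continuous scales, schema-fixed levels for categoricals, and the
two outcome-independent noise (shadow) predictors used as the empirical
selection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthdata import CATEGORY_LEVELS

__all__ = [
    "derive_outcome",
    "derive_phq8_and_depression",
    "build_feature_frame",
    "FeatureFrame",
    "inject_noise_variables",
    "Discretizer",
    "AnalysisTable",
    "ColumnMeta",
    "OUTCOME_NAME",
    "NOISE_CONTINUOUS",
    "NOISE_CATEGORICAL",
]

OUTCOME_NAME = "suicidal_ideation"
NOISE_CONTINUOUS = "noise_continuous"
NOISE_CATEGORICAL = "noise_categorical"

#: analysis predictors: name -> ("continuous" | "categorical", ordered?)
PREDICTOR_KINDS = {
    "age_group": ("categorical", True),
    "gender": ("categorical", True),       # binary
    "education": ("categorical", True),    # ordinal bands
    "children": ("categorical", True),     # binary
    "employment": ("categorical", False),
    "income_band": ("categorical", True),  # ordinal bands
    "housing": ("categorical", False),
    "illness": ("categorical", True),      # binary
    "occupants": ("continuous", True),
    "exercise_days": ("continuous", True),
    "phq8": ("continuous", True),
    "gad7": ("continuous", True),
    "pss_helplessness": ("continuous", True),
    "pss_selfefficacy": ("continuous", True),
    "isi": ("continuous", True),
    "loneliness": ("continuous", True),
    "cdrisc": ("continuous", True),
    "whoqol_physical": ("continuous", True),
    "whoqol_psychological": ("continuous", True),
    "whoqol_relationships": ("continuous", True),
    "whoqol_environment": ("continuous", True),
}

_BINARY_LEVELS = {"children": ["0", "1"], "illness": ["0", "1"],
                  NOISE_CATEGORICAL: ["0", "1"]}


# ---------------------------------------------------------------- derivations

def derive_outcome(item9: np.ndarray | pd.Series) -> np.ndarray:
    """Binarize PHQ-9 item 9: 0 stays 0, any endorsement (1–3) becomes 1."""
    arr = np.asarray(item9)
    bad = ~np.isin(arr, [0, 1, 2, 3])
    if bad.any():
        rows = np.flatnonzero(bad)[:5].tolist()
        raise ValueError(f"item 9 responses outside 0..3 at rows {rows}")
    return (arr >= 1).astype(np.int64)


def derive_phq8_and_depression(phq_items: pd.DataFrame | np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """PHQ-8 total (items 1–8) and the depression flag (PHQ-9 total >= 10)."""
    arr = np.asarray(phq_items)
    if arr.ndim != 2 or arr.shape[1] != 9:
        raise ValueError(f"expected 9 PHQ item columns, got shape {arr.shape}")
    phq8 = arr[:, :8].sum(axis=1)
    depressed = (arr.sum(axis=1) >= 10).astype(np.int64)
    return phq8, depressed


# ---------------------------------------------------------------- containers

@dataclass
class ColumnMeta:
    name: str
    kind: str                 # continuous | categorical
    levels: list[str]
    ordered: bool
    is_noise: bool = False
    bin_edges: list[float] | None = None


@dataclass
class FeatureFrame:
    """Raw-unit analysis variables plus the binary outcome.

    ``X`` keeps continuous columns numeric and categorical columns as string
    labels; discretization happens later (and per CV fold) so that bin edges
    are always fit on training data only.
    """

    X: pd.DataFrame
    y: np.ndarray
    kinds: dict[str, tuple[str, bool]]
    noise_columns: list[str] = field(default_factory=list)
    country: str | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset_columns(self, cols: list[str]) -> "FeatureFrame":
        return replace(self, X=self.X[cols].copy(),
                       kinds={c: self.kinds[c] for c in cols},
                       noise_columns=[c for c in self.noise_columns if c in cols])

    def subset_rows(self, idx: np.ndarray) -> "FeatureFrame":
        return replace(self, X=self.X.iloc[idx].reset_index(drop=True),
                       y=self.y[idx])


def build_feature_frame(survey: pd.DataFrame) -> FeatureFrame:
    """Derive the candidate-predictor frame and outcome from a raw survey table."""
    item_cols = [f"phq_i{i}" for i in range(1, 10)]
    missing = [c for c in item_cols if c not in survey.columns]
    if missing:
        raise ValueError(f"survey table lacks PHQ item columns {missing}")
    y = derive_outcome(survey["phq_i9"].to_numpy())
    phq8, _ = derive_phq8_and_depression(survey[item_cols])
    X = {}
    for col, (kind, _ordered) in PREDICTOR_KINDS.items():
        if col == "phq8":
            X[col] = phq8
        elif kind == "categorical" and col in _BINARY_LEVELS:
            X[col] = survey[col].astype(int).astype(str)
        elif kind == "categorical":
            X[col] = survey[col].astype(str)
        else:
            X[col] = pd.to_numeric(survey[col])
    country = None
    if "country" in survey.columns and survey["country"].nunique() == 1:
        country = str(survey["country"].iloc[0])
    return FeatureFrame(X=pd.DataFrame(X), y=y, kinds=dict(PREDICTOR_KINDS),
                        country=country)


def inject_noise_variables(frame: FeatureFrame, phq9_mean: float,
                           phq9_sd: float, male_rate: float,
                           seed: int) -> FeatureFrame:
    """Append the two outcome-independent shadow predictors.

    A continuous column drawn N(phq9_mean, phq9_sd) — matched to the PHQ-9
    total of the sample at hand — and a binary column with P(1) = male rate.
    Both are generated once per dataset, before any cross-validation.
    """
    if phq9_sd <= 0:
        raise ValueError("phq9_sd must be positive")
    if not 0 < male_rate < 1:
        raise ValueError("male_rate must lie in (0,1)")
    rng = np.random.default_rng(seed)
    n = len(frame.y)
    X = frame.X.copy()
    X[NOISE_CONTINUOUS] = rng.normal(phq9_mean, phq9_sd, size=n)
    X[NOISE_CATEGORICAL] = (rng.random(n) < male_rate).astype(int).astype(str)
    kinds = dict(frame.kinds)
    kinds[NOISE_CONTINUOUS] = ("continuous", True)
    kinds[NOISE_CATEGORICAL] = ("categorical", True)
    return replace(frame, X=X, kinds=kinds,
                   noise_columns=[NOISE_CONTINUOUS, NOISE_CATEGORICAL])


def phq9_moments(survey: pd.DataFrame) -> tuple[float, float]:
    """Sample mean and SD of the PHQ-9 total (items 1–9)."""
    total = survey[[f"phq_i{i}" for i in range(1, 10)]].sum(axis=1)
    return float(total.mean()), float(total.std(ddof=1))


def male_rate(survey: pd.DataFrame) -> float:
    return float((survey["gender"] == "male").mean())


# ---------------------------------------------------------------- discretizer

class AnalysisTable:
    """All-discrete predictor matrix (integer codes) plus binary outcome."""

    def __init__(self, codes: np.ndarray, y: np.ndarray, columns: list[str],
                 meta: dict[str, ColumnMeta]):
        self.codes = np.asarray(codes, dtype=np.int64)
        self.y = np.asarray(y, dtype=np.int64)
        self.columns = list(columns)
        self.meta = meta
        if self.codes.shape != (len(self.y), len(self.columns)):
            raise ValueError("codes shape inconsistent with columns/outcome")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.y)

    def n_levels(self, col: str) -> int:
        return len(self.meta[col].levels)

    def column(self, col: str) -> np.ndarray:
        return self.codes[:, self.columns.index(col)]

    @property
    def noise_columns(self) -> list[str]:
        return [c for c in self.columns if self.meta[c].is_noise]

    def subset_columns(self, cols: list[str]) -> "AnalysisTable":
        idx = [self.columns.index(c) for c in cols]
        return AnalysisTable(self.codes[:, idx], self.y, cols,
                             {c: self.meta[c] for c in cols})

    def without_noise(self) -> "AnalysisTable":
        return self.subset_columns(
            [c for c in self.columns if not self.meta[c].is_noise])

    def subset_rows(self, idx: np.ndarray) -> "AnalysisTable":
        return AnalysisTable(self.codes[idx], self.y[idx], self.columns, self.meta)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable labelled view of the coded table."""
        data = {}
        for j, c in enumerate(self.columns):
            labels = np.asarray(self.meta[c].levels, dtype=object)
            data[c] = labels[self.codes[:, j]]
        data[OUTCOME_NAME] = self.y
        return pd.DataFrame(data)


class Discretizer:
    """Equal-frequency binning scheme, fit on one sample, applicable to another.

    Continuous variables get cut points at the k-quantiles of the training
    sample (duplicate quantiles merged, so fewer bins are possible);
    categorical variables keep their schema-fixed level list.  Values outside
    the training range land in the first/last bin, which is what makes a
    scheme fit on one country transferable to the other.
    """

    def __init__(self, k: int = 5):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.meta: dict[str, ColumnMeta] = {}
        self.columns: list[str] = []

    def fit(self, frame: FeatureFrame) -> "Discretizer":
        self.meta = {}
        self.columns = []
        for col in frame.columns:
            kind, ordered = frame.kinds[col]
            is_noise = col in frame.noise_columns
            if kind == "categorical":
                levels = self._category_levels(col, frame.X[col])
                if len(levels) < 2:
                    warnings.warn(f"dropping constant column {col!r}")
                    continue
                self.meta[col] = ColumnMeta(col, "categorical", levels,
                                            ordered, is_noise)
            else:
                v = frame.X[col].to_numpy(dtype=float)
                qs = np.quantile(v, np.linspace(0, 1, self.k + 1)[1:-1])
                edges = np.unique(qs).tolist()
                # an edge equal to the max would leave the last bin empty
                edges = [e for e in edges if e < v.max()]
                if len(edges) == 0:
                    warnings.warn(f"dropping constant column {col!r}")
                    continue
                labels = self._bin_labels(edges)
                self.meta[col] = ColumnMeta(col, "continuous", labels,
                                            True, is_noise, bin_edges=edges)
            self.columns.append(col)
        return self

    @staticmethod
    def _category_levels(col: str, values: pd.Series) -> list[str]:
        if col in CATEGORY_LEVELS:
            return list(CATEGORY_LEVELS[col])
        if col in _BINARY_LEVELS:
            return list(_BINARY_LEVELS[col])
        levels = sorted(values.astype(str).unique().tolist())
        return levels

    @staticmethod
    def _bin_labels(edges: list[float]) -> list[str]:
        lo = ["(-inf"] + [f"({e:g}" for e in edges]
        hi = [f"{e:g}]" for e in edges] + ["inf)"]
        return [f"{a}, {b}" for a, b in zip(lo, hi)]

    def transform(self, frame: FeatureFrame) -> AnalysisTable:
        if not self.columns:
            raise ValueError("discretizer is not fitted")
        cols = [c for c in self.columns if c in frame.columns]
        codes = np.empty((len(frame.y), len(cols)), dtype=np.int64)
        for j, col in enumerate(cols):
            m = self.meta[col]
            if m.kind == "categorical":
                mapping = {lev: i for i, lev in enumerate(m.levels)}
                vals = frame.X[col].astype(str)
                unknown = set(vals.unique()) - set(m.levels)
                if unknown:
                    raise ValueError(
                        f"column {col!r} has unmapped levels {sorted(unknown)}")
                codes[:, j] = vals.map(mapping).to_numpy()
            else:
                v = frame.X[col].to_numpy(dtype=float)
                codes[:, j] = np.searchsorted(np.asarray(m.bin_edges), v,
                                              side="left")
        return AnalysisTable(codes, frame.y, cols, {c: self.meta[c] for c in cols})

    def fit_transform(self, frame: FeatureFrame) -> AnalysisTable:
        return self.fit(frame).transform(frame)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "columns": self.columns,
            "meta": {c: {
                "name": m.name, "kind": m.kind, "levels": m.levels,
                "ordered": m.ordered, "is_noise": m.is_noise,
                "bin_edges": m.bin_edges,
            } for c, m in self.meta.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Discretizer":
        disc = cls(k=d["k"])
        disc.columns = list(d["columns"])
        disc.meta = {c: ColumnMeta(**m) for c, m in d["meta"].items()}
        return disc
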