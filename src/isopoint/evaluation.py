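"""Dataset handling and the regression metric suite.

Labelled datasets pair sequences with experimental pI values, or residue
sites with experimental pKa values, in a tab-separated dialect
(``id  sequence  value[  position  residue]``, header row). Before any
training or benchmarking, datasets are clustered (identical entries merged,
labels averaged) and split 75/25 into training and held-out test sets.

Accuracy is reported as RMSE, MAE, correlation and the number of outliers —
predictions deviating from experiment by more than a threshold (0.5 pH units
for proteins and pKa values, 0.25 for peptides). Two correlation columns are
kept: squared Pearson correlation (``r2_pearson``) and the coefficient of
determination (``r2_determination``), which can go negative for methods
worse than the mean predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from isopoint.charge import PKaSet, isoelectric_point, registry
from isopoint.seqio import PolypeptideSequence

PI_COLUMNS = ["id", "sequence", "value"]
PKA_COLUMNS = ["id", "sequence", "value", "position", "residue"]


@dataclass
class LabelledDataset:
    """Sequences with experimental pI labels, or residue sites with pKa labels.

    ``records`` columns: ``id``, ``sequence``, ``value`` (pH units), and for
    pKa datasets additionally ``position`` (1-based site) and ``residue``.
    """

    records: pd.DataFrame
    kind: str = "pI"
    provenance: str = ""
    split: str = "none"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("pI", "pKa"):
            raise ValueError(f"kind must be 'pI' or 'pKa', got {self.kind!r}")
        cols = PKA_COLUMNS if self.kind == "pKa" else PI_COLUMNS
        missing = set(cols) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        vals = self.records["value"].to_numpy(dtype=float)
        if len(vals) and (vals.min() <= 0.0 or vals.max() >= 14.0):
            raise ValueError("experimental values must lie in (0, 14) pH units")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return self.records["sequence"].tolist()

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def to_tsv(self, destination: IO[str] | str) -> None:
        cols = PKA_COLUMNS if self.kind == "pKa" else PI_COLUMNS
        self.records[cols].to_csv(destination, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source: IO[str] | str, kind: str | None = None,
                 provenance: str = "") -> "LabelledDataset":
        df = pd.read_csv(source, sep="\t")
        if kind is None:
            kind = "pKa" if "position" in df.columns else "pI"
        return cls(records=df, kind=kind, provenance=provenance)


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy of one method on one dataset."""

    method: str
    rmse: float
    mae: float
    r2_pearson: float
    r2_determination: float
    outliers: int
    threshold: float
    n: int
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if self.rmse < self.mae - 1e-12 or self.mae < 0:
                raise ValueError("invariant violated: RMSE >= MAE >= 0")
            if not (0 <= self.outliers <= self.n):
                raise ValueError("outlier count outside [0, n]")


def cluster_and_average(dataset: LabelledDataset) -> LabelledDataset:
    """Merge duplicate entries, averaging their experimental labels.

    Duplicates are exact-identity: same sequence for pI data, same
    (sequence, position) pair for pKa data. The merged label is the
    arithmetic mean; a ``merged_n`` column records how many measurements
    each surviving record absorbed (the counts sum to the original n).
    """
    df = dataset.records.copy()
    keys = ["sequence"] if dataset.kind == "pI" else ["sequence", "position"]
    agg: dict[str, object] = {"value": "mean", "id": "first"}
    if dataset.kind == "pKa":
        agg["residue"] = "first"
    grouped = (
        df.groupby(keys, sort=False, as_index=False)
        .agg(**{k: (k, v) for k, v in agg.items()}, merged_n=("value", "size"))
    )
    cols = (PKA_COLUMNS if dataset.kind == "pKa" else PI_COLUMNS) + ["merged_n"]
    return replace(dataset, records=grouped[cols])


def split_dataset(
    dataset: LabelledDataset, fraction: float = 0.25, seed: int = 0
) -> tuple[LabelledDataset, LabelledDataset]:
    """Random disjoint split into (training, held-out test) sets.

    ``fraction`` is the test share (default 25%); membership is
    seed-reproducible and the two parts are exhaustive.
    """
    n = len(dataset)
    if n < 4:
        raise ValueError(f"dataset too small to split (n={n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * fraction))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    train = replace(dataset, records=dataset.records.iloc[train_idx], split="train75")
    test = replace(dataset, records=dataset.records.iloc[test_idx], split="test25")
    return train, test


def metrics(
    predicted: Sequence[float],
    experimental: Sequence[float],
    outlier_threshold: float = 0.5,
    method: str = "",
) -> EvaluationReport:
    """RMSE, MAE, correlation and outlier count for one prediction vector.

    An outlier is a prediction deviating from experiment by strictly more
    than ``outlier_threshold`` pH units.
    """
    y_hat = np.asarray(predicted, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if y_hat.shape != y.shape or y.ndim != 1:
        raise ValueError("predicted and experimental must be equal-length 1-D vectors")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 points")
    err = y_hat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("experimental vector has zero variance; correlation undefined")
        r2_p, r2_d = float("nan"), float("nan")
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(y_hat, y)[0, 1]
        r2_p = float(r**2) if np.isfinite(r) else float("nan")
        r2_d = 1.0 - ss_res / ss_tot
    outliers = int(np.sum(np.abs(err) > outlier_threshold))
    return EvaluationReport(
        method=method, rmse=rmse, mae=mae, r2_pearson=r2_p,
        r2_determination=r2_d, outliers=outliers,
        threshold=outlier_threshold, n=n,
    )


def cross_validate(
    model_factory: Callable[[], object],
    dataset: LabelledDataset,
    folds: int = 10,
    seed: int = 0,
    outlier_threshold: float = 0.5,
) -> tuple[list[EvaluationReport], EvaluationReport]:
    """K-fold cross-validation of a trainable pI/pKa model.

    ``model_factory()`` must return a fresh object exposing
    ``fit(dataset: LabelledDataset)`` and
    ``predict(dataset: LabelledDataset) -> array``. Folds are disjoint and
    exhaustive with seed-reproducible assignment; the pooled report is
    computed over the concatenated out-of-fold predictions (pooled n equals
    the dataset n).
    """
    n = len(dataset)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_indices = np.array_split(perm, folds)
    per_fold: list[EvaluationReport] = []
    pooled_pred = np.empty(n)
    pooled_true = np.empty(n)
    cursor = 0
    for k, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(perm, test_idx)
        train = replace(dataset, records=dataset.records.iloc[np.sort(train_idx)])
        test = replace(dataset, records=dataset.records.iloc[np.sort(test_idx)])
        model = model_factory()
        model.fit(train)
        pred = np.asarray(model.predict(test), dtype=float)
        per_fold.append(
            metrics(pred, test.values, outlier_threshold, method=f"fold{k + 1}")
        )
        pooled_pred[cursor:cursor + len(pred)] = pred
        pooled_true[cursor:cursor + len(pred)] = test.values
        cursor += len(pred)
    pooled = metrics(pooled_pred, pooled_true, outlier_threshold, method="pooled")
    return per_fold, pooled


MethodLike = Callable[[str], float]


def _resolve_methods(
    methods: Iterable[str] | Mapping[str, MethodLike],
) -> dict[str, MethodLike]:
    if isinstance(methods, Mapping):
        return dict(methods)
    reg = registry()
    resolved: dict[str, MethodLike] = {}
    for name in methods:
        if name not in reg:
            raise KeyError(
                f"unknown method {name!r}; available: {', '.join(sorted(reg))}"
            )
        resolved[name] = _pka_set_predictor(reg[name])
    return resolved


def _pka_set_predictor(pka: PKaSet) -> MethodLike:
    def predict(sequence: str) -> float:
        return isoelectric_point(PolypeptideSequence("q", sequence), pka)
    return predict


def benchmark(
    methods: Iterable[str] | Mapping[str, MethodLike],
    dataset: LabelledDataset,
    outlier_threshold: float = 0.5,
) -> pd.DataFrame:
    """Compare prediction methods on one labelled dataset.

    ``methods`` is either a list of registered pKa-set names or a mapping
    name -> callable(sequence) -> pI. Returns one row per method sorted by
    RMSE ascending (ties broken by name), with the standard column layout
    (RMSE, MAE, correlation, outliers). A method that fails on any sequence
    is marked invalid; the others are unaffected.
    """
    resolved = _resolve_methods(methods)
    y = dataset.values
    rows = []
    for name, fn in resolved.items():
        try:
            pred = np.array([fn(s) for s in dataset.sequences], dtype=float)
            rep = metrics(pred, y, outlier_threshold, method=name)
        except Exception as exc:  # noqa: BLE001 - isolate per-method failure
            warnings.warn(f"method {name!r} failed: {exc}")
            rep = EvaluationReport(
                method=name, rmse=float("nan"), mae=float("nan"),
                r2_pearson=float("nan"), r2_determination=float("nan"),
                outliers=0, threshold=outlier_threshold, n=len(y), valid=False,
            )
        rows.append(rep)
    df = pd.DataFrame(
        {
            "method": [r.method for r in rows],
            "rmse": [r.rmse for r in rows],
            "mae": [r.mae for r in rows],
            "r2_pearson": [r.r2_pearson for r in rows],
            "r2_determination": [r.r2_determination for r in rows],
            "outliers": [r.outliers for r in rows],
            "n": [r.n for r in rows],
            "valid": [r.valid for r in rows],
        }
    )
    df = df.sort_values(["rmse", "method"], na_position="last", kind="mergesort")
    return df.reset_index(drop=True)
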