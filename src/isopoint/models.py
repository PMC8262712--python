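"""Trainable predictors: SVR stacking, peptide convnet, kmer pKa ensemble.

Three model families cover the two prediction tasks:

- **SVR stacking for pI** (proteins): an RBF-kernel support vector
  regressor with grid-searched C/gamma consumes a vector of 19 base pI
  predictions (one per Henderson-Hasselbalch method) — classic ensemble
  averaging. The input is deliberately restricted to pI-space features;
  heterogeneous extras (length, mass) are rejected by default because they
  sit on a different scale and destabilise the RBF geometry.
- **Separable-convolution network for peptide pI**: consumes the
  (60, 22, 4) multichannel tensor; two separable-convolution layers
  interleaved with average pooling (initial kernel spanning all 22 symbol
  columns with a window of five residues), then a three-layer dense head.
- **kmer MLP ensemble for per-residue pKa**: nine members, each a
  three-dense-layer MLP with dropout over one odd kmer size (3..15, size 9
  duplicated with different seeds), stacked by an SVR fitted on
  out-of-fold member predictions to avoid leakage.

All training entry points are seeded and all emitted pI/pKa values are
clipped to [0, 14].
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict
from sklearn.svm import SVR

from isopoint import nn
from isopoint.evaluation import LabelledDataset, metrics
from isopoint.features import (
    PropertyScaleTable,
    encode_kmer_window,
    kmer_window,
    load_bundled_scales,
    select_informative_scales,
)
from isopoint.seqio import IONIZABLE_RESIDUES, PolypeptideSequence

logger = logging.getLogger(__name__)

PH_MIN, PH_MAX = 0.0, 14.0


def _clip_ph(values: np.ndarray, what: str) -> np.ndarray:
    clipped = np.clip(values, PH_MIN, PH_MAX)
    n_clip = int(np.sum(clipped != values))
    if n_clip:
        logger.info("clipped %d %s prediction(s) into [0, 14]", n_clip, what)
    return clipped


# ---------------------------------------------------------------------------
# SVR stacking for pI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRConfig:
    """RBF support vector regression with grid-searched hyperparameters."""

    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0)
    cv_folds: int = 5
    # Epsilon-insensitive tube narrower than sklearn's 0.1 default: pI/pKa
    # labels are meaningful to ~0.01 pH, and a 0.1 tube alone already floors
    # the RMSE near 0.06.
    epsilon: float = 0.05
    allow_heterogeneous: bool = False

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class FittedStacker:
    """A fitted SVR stacker with its chosen hyperparameters."""

    model: SVR
    n_features: int
    C: float
    gamma: float
    cv_rmse: float


def train_svr_stack(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVRConfig | None = None,
    seed: int = 0,
) -> FittedStacker:
    """Fit the stacking SVR over base-method prediction vectors.

    Grid-searches (C, gamma) by K-fold CV, refits on all data, and reports
    the held-out RMSE of the chosen configuration via out-of-fold
    predictions.
    """
    cfg = cfg or SVRConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if len(X) < 30:
        raise ValueError(f"need at least 30 training rows, got {len(X)}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in training input")
    if np.var(y) == 0:
        raise ValueError("degenerate labels: zero variance")
    if not cfg.allow_heterogeneous and (X.min() < PH_MIN or X.max() > PH_MAX):
        raise ValueError(
            "input columns outside [0, 14]: the stacker accepts pI-space "
            "features only (set allow_heterogeneous=True to override)"
        )
    cv = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVR(kernel="rbf", epsilon=cfg.epsilon),
        {"C": list(cfg.c_grid), "gamma": list(cfg.gamma_grid)},
        cv=cv,
        scoring="neg_root_mean_squared_error",
    )
    search.fit(X, y)
    best = search.best_estimator_
    oof = cross_val_predict(
        SVR(kernel="rbf", epsilon=cfg.epsilon, **search.best_params_), X, y, cv=cv
    )
    cv_rmse = float(np.sqrt(np.mean((oof - y) ** 2)))
    return FittedStacker(
        model=best,
        n_features=X.shape[1],
        C=float(search.best_params_["C"]),
        gamma=float(search.best_params_["gamma"]),
        cv_rmse=cv_rmse,
    )


def predict_pi_stack(stacker: FittedStacker, X: np.ndarray) -> np.ndarray:
    """Stacked pI predictions, clipped to [0, 14]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != stacker.n_features:
        raise ValueError(
            f"expected {stacker.n_features} base predictions per row, got {X.shape[1]}"
        )
    return _clip_ph(stacker.model.predict(X), "pI")


# ---------------------------------------------------------------------------
# Separable-convolution peptide network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvNetConfig:
    """Architecture and training settings of the peptide pI network.

    Layer sequence is fixed: sepconv -> avgpool -> sepconv -> avgpool ->
    flatten -> dense x3 -> scalar. The first kernel spans all 22 symbol
    columns with a window of five sequence positions.
    """

    input_shape: tuple[int, int, int] = (60, 22, 4)
    filters: tuple[int, int] = (16, 32)
    first_kernel: tuple[int, int] = (5, 22)  # (positions, symbol columns)
    second_kernel: tuple[int, int] = (5, 1)
    pool: tuple[int, int] = (2, 1)
    dense_widths: tuple[int, int, int] = (256, 64, 16)
    activation: str = "selu"
    dropout: float = 0.2
    learning_rate: float = 3e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 10
    validation_split: float = 0.2

    def __post_init__(self) -> None:
        if self.activation not in ("selu", "elu"):
            raise ValueError("activation must be 'selu' or 'elu'")
        if self.first_kernel[1] != self.input_shape[1]:
            raise ValueError(
                "first kernel must span all symbol columns "
                f"({self.input_shape[1]}), got {self.first_kernel[1]}"
            )


def build_peptide_convnet(cfg: ConvNetConfig | None = None, seed: int = 0) -> nn.Network:
    """Untrained peptide network with deterministic seeded initialisation."""
    cfg = cfg or ConvNetConfig()
    layers: list[nn.Layer] = [
        nn.SeparableConv2D(cfg.filters[0], cfg.first_kernel, cfg.activation),
        nn.AveragePooling2D(cfg.pool),
        nn.SeparableConv2D(cfg.filters[1], cfg.second_kernel, cfg.activation),
        nn.AveragePooling2D(cfg.pool),
        nn.Flatten(),
    ]
    for width in cfg.dense_widths:
        layers.append(nn.Dense(width, cfg.activation))
        if cfg.dropout:
            layers.append(nn.Dropout(cfg.dropout))
    layers.append(nn.Dense(1, "linear"))
    return nn.Network(layers, input_shape=cfg.input_shape, seed=seed)


@dataclass
class TrainedRegressor:
    """A trained network plus the input/label standardisation it was fit with."""

    network: nn.Network
    history: nn.History
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = (np.asarray(x, dtype=float) - self.x_mean) / self.x_std
        raw = self.network.predict(x) * self.y_std + self.y_mean
        return _clip_ph(raw, "pI")


def train_regressor(
    model: nn.Network,
    tensors: np.ndarray,
    labels: np.ndarray,
    cfg: ConvNetConfig | None = None,
) -> TrainedRegressor:
    """Train a network on (tensor, label) pairs with early stopping.

    Inputs are standardised per channel and labels to zero mean / unit
    variance (restored at prediction time). Training halts by early
    stopping on the validation split or at ``max_epochs``; a non-finite
    loss aborts with a diagnostic.
    """
    cfg = cfg or ConvNetConfig()
    x = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(x) < 100:
        raise ValueError(
            f"need at least 100 examples for meaningful early stopping, got {len(x)}"
        )
    axes = tuple(range(x.ndim - 1))
    x_mean = x.mean(axis=axes)
    x_std = np.maximum(x.std(axis=axes), 1e-8)
    y_mean = float(y.mean())
    y_std = float(max(y.std(), 1e-8))
    history = model.fit(
        (x - x_mean) / x_std,
        (y - y_mean) / y_std,
        epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        validation_split=cfg.validation_split,
        patience=cfg.patience,
    )
    return TrainedRegressor(
        network=model, history=history,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
    )


# ---------------------------------------------------------------------------
# kmer MLP ensemble for pKa
# ---------------------------------------------------------------------------

#: One member per odd kmer size 3..15, plus two extra size-9 members
#: initialised with different seeds.
DEFAULT_MEMBER_SIZES = (3, 5, 7, 9, 11, 13, 15, 9, 9)


@dataclass(frozen=True)
class PKaEnsembleConfig:
    """Nine kmer-MLP members stacked by an SVR meta-regressor."""

    member_kmer_sizes: tuple[int, ...] = DEFAULT_MEMBER_SIZES
    hidden_widths: tuple[int, int, int] = (64, 32, 16)
    activation: str = "selu"
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 15
    validation_split: float = 0.2
    n_scales: int = 4
    scales: tuple[PropertyScaleTable, ...] | None = None
    oof_folds: int = 5
    svr: SVRConfig = field(default_factory=lambda: SVRConfig(allow_heterogeneous=True))

    def __post_init__(self) -> None:
        if len(self.member_kmer_sizes) != 9:
            raise ValueError("the ensemble has exactly nine members")
        for k in self.member_kmer_sizes:
            if k % 2 == 0 or not (3 <= k <= 15):
                raise ValueError(f"kmer sizes must be odd in [3, 15], got {k}")


@dataclass
class _Member:
    kmer_size: int
    network: nn.Network
    x_mean: np.ndarray
    x_std: np.ndarray


@dataclass
class FittedPKaEnsemble:
    """Nine trained members, a fitted SVR stacker, and the scales used.

    Members are trained on residuals from the per-site-type mean pKa
    (``type_means``): the mean captures the large between-group spread
    (an alpha-carboxyl sits ~2.5, a Lys amine ~10.5) so the networks spend
    their capacity on the sequence-context signal around each site.
    """

    members: list[_Member]
    stacker: SVR
    scales: tuple[PropertyScaleTable, ...]
    type_means: dict[str, float]
    global_mean: float
    y_std: float
    per_type_report: pd.DataFrame
    config: PKaEnsembleConfig
    seed: int

    def _member_matrix(self, windows_by_size: Mapping[int, list]) -> np.ndarray:
        """Member predictions in residual space (deviation from type mean)."""
        cols = []
        for m in self.members:
            X = np.array([
                encode_kmer_window(w, self.scales, site_type=st)
                for w, st in windows_by_size[m.kmer_size]
            ])
            Xs = (X - m.x_mean) / m.x_std
            cols.append(m.network.predict(Xs) * self.y_std)
        return np.column_stack(cols)

    def predict_sites(
        self, seq: PolypeptideSequence, sites: list[tuple[int, str]]
    ) -> np.ndarray:
        """Stacked pKa for (position, site_type) pairs; clipped to [0, 14]."""
        windows_by_size = {
            k: [
                (kmer_window(seq, pos, k, terminus_mode=st in ("n_term", "c_term")), st)
                for pos, st in sites
            ]
            for k in {m.kmer_size for m in self.members}
        }
        member_resids = self._member_matrix(windows_by_size)
        means = np.array([
            self.type_means.get(st, self.global_mean) for _, st in sites
        ])
        return _clip_ph(self.stacker.predict(member_resids) + means, "pKa")


def _site_type(residue: str) -> str:
    if residue in ("n_term", "c_term"):
        return residue
    if residue in IONIZABLE_RESIDUES:
        return residue
    raise ValueError(f"not an ionizable site type: {residue!r}")


class _WindowDataset:
    """Adapter: kmer windows as a tiny sequence/label dataset for selection."""

    def __init__(self, sequences: list[str], values: np.ndarray):
        self.sequences = sequences
        self.values = values

    def __len__(self) -> int:
        return len(self.sequences)


def _select_scales(sites: LabelledDataset, cfg: PKaEnsembleConfig, seed: int
                   ) -> tuple[PropertyScaleTable, ...]:
    if cfg.scales is not None:
        return tuple(cfg.scales)
    tables = load_bundled_scales()
    win_seqs = []
    for _, row in sites.records.iterrows():
        seq = PolypeptideSequence(str(row["id"]), row["sequence"])
        st = _site_type(str(row["residue"]))
        w = kmer_window(seq, int(row["position"]), 9,
                        terminus_mode=st in ("n_term", "c_term"))
        win_seqs.append(w.residues)
    selection = select_informative_scales(
        tables, _WindowDataset(win_seqs, sites.values), k=cfg.n_scales, seed=seed
    )
    return tuple(tables[sid] for sid in selection.ids[: cfg.n_scales])


def _encode_sites(
    sites: LabelledDataset,
    k: int,
    scales: Sequence[PropertyScaleTable],
) -> np.ndarray:
    rows = []
    for _, row in sites.records.iterrows():
        seq = PolypeptideSequence(str(row["id"]), row["sequence"])
        st = _site_type(str(row["residue"]))
        w = kmer_window(seq, int(row["position"]), k,
                        terminus_mode=st in ("n_term", "c_term"))
        rows.append(encode_kmer_window(w, scales, site_type=st))
    return np.array(rows)


def _build_member_net(cfg: PKaEnsembleConfig, input_dim: int, seed: int) -> nn.Network:
    layers: list[nn.Layer] = []
    for width in cfg.hidden_widths:
        layers.append(nn.Dense(width, cfg.activation))
        layers.append(nn.Dropout(cfg.dropout))
    layers.append(nn.Dense(1, "linear"))
    return nn.Network(layers, input_shape=(input_dim,), seed=seed)


def _fit_member(
    cfg: PKaEnsembleConfig, X: np.ndarray, y_std: np.ndarray, seed: int
) -> _Member:
    x_mean = X.mean(axis=0)
    x_std = np.maximum(X.std(axis=0), 1e-8)
    net = _build_member_net(cfg, X.shape[1], seed)
    net.fit(
        (X - x_mean) / x_std, y_std,
        epochs=cfg.max_epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, validation_split=cfg.validation_split,
        patience=cfg.patience,
    )
    return _Member(kmer_size=0, network=net, x_mean=x_mean, x_std=x_std)


def train_pka_ensemble(
    sites: LabelledDataset,
    cfg: PKaEnsembleConfig | None = None,
    seed: int = 0,
) -> FittedPKaEnsemble:
    """Train the nine-member kmer MLP ensemble and its SVR stacker.

    The stacker is fitted on out-of-fold member predictions (members
    retrained per fold) so that no member ever stacks its own training
    labels. Residue types with fewer than 5 examples are excluded from the
    per-type accuracy report with a warning.
    """
    cfg = cfg or PKaEnsembleConfig()
    if sites.kind != "pKa":
        raise ValueError("expected a pKa-labelled dataset")
    n = len(sites)
    if n < 200:
        raise ValueError(f"need at least 200 sites, got {n}")
    types = sites.records["residue"].astype(str)
    if types.nunique() < 4:
        raise ValueError("need sites spanning at least 4 residue types")

    scales = _select_scales(sites, cfg, seed)
    y = sites.values
    type_labels = types.to_numpy()
    global_mean = float(y.mean())

    def _centre(train_y: np.ndarray, train_t: np.ndarray):
        means = {t: float(train_y[train_t == t].mean()) for t in np.unique(train_t)}
        return means

    unique_sizes = sorted(set(cfg.member_kmer_sizes))
    X_by_size = {k: _encode_sites(sites, k, scales) for k in unique_sizes}

    # Out-of-fold member predictions for leakage-free stacking; per-type
    # centring is refitted inside each fold so no test label leaks in.
    # Everything downstream of the centring lives in residual space
    # (deviation from the per-type mean): the stacker never has to span
    # the ~8 pH units between an alpha-carboxyl and a Lys amine.
    kf = KFold(n_splits=cfg.oof_folds, shuffle=True, random_state=seed)
    oof = np.zeros((n, 9))
    y_resid_oof = np.zeros(n)
    for tr_idx, te_idx in kf.split(np.arange(n)):
        means_f = _centre(y[tr_idx], type_labels[tr_idx])
        resid = y[tr_idx] - np.array([
            means_f.get(t, global_mean) for t in type_labels[tr_idx]
        ])
        sd_f = float(max(resid.std(), 1e-8))
        y_resid_oof[te_idx] = y[te_idx] - np.array([
            means_f.get(t, global_mean) for t in type_labels[te_idx]
        ])
        for j, k in enumerate(cfg.member_kmer_sizes):
            member = _fit_member(
                cfg, X_by_size[k][tr_idx], resid / sd_f, seed + 1000 * j + 17
            )
            Xs = (X_by_size[k][te_idx] - member.x_mean) / member.x_std
            oof[te_idx, j] = member.network.predict(Xs) * sd_f

    # Final members on all data (same per-member seeds as the fold models).
    type_means = _centre(y, type_labels)
    resid_all = y - np.array([type_means[t] for t in type_labels])
    y_std_scalar = float(max(resid_all.std(), 1e-8))
    members: list[_Member] = []
    for j, k in enumerate(cfg.member_kmer_sizes):
        member = _fit_member(
            cfg, X_by_size[k], resid_all / y_std_scalar, seed + 1000 * j + 17
        )
        member.kmer_size = k
        members.append(member)

    cv = KFold(n_splits=cfg.svr.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVR(kernel="rbf", epsilon=cfg.svr.epsilon),
        {"C": list(cfg.svr.c_grid), "gamma": list(cfg.svr.gamma_grid)},
        cv=cv,
        scoring="neg_root_mean_squared_error",
    )
    search.fit(oof, y_resid_oof)
    stacker = search.best_estimator_

    stack_oof = cross_val_predict(
        SVR(kernel="rbf", epsilon=cfg.svr.epsilon, **search.best_params_),
        oof, y_resid_oof, cv=cv,
    )
    report_rows = []
    for t, group in sites.records.groupby(types):
        idx = group.index.to_numpy()
        if len(idx) < 5:
            warnings.warn(
                f"residue type {t!r} has only {len(idx)} examples; "
                "excluded from the per-type report"
            )
            continue
        rep = metrics(stack_oof[idx], y_resid_oof[idx], 0.5, method=str(t))
        report_rows.append({
            "residue": str(t), "n": rep.n, "rmse": rep.rmse,
            "mae": rep.mae, "outliers": rep.outliers,
        })
    report = pd.DataFrame(report_rows)

    return FittedPKaEnsemble(
        members=members, stacker=stacker, scales=scales,
        type_means=type_means, global_mean=global_mean, y_std=y_std_scalar,
        per_type_report=report, config=cfg, seed=seed,
    )


def enumerate_ionizable_sites(seq: PolypeptideSequence) -> list[tuple[int, str]]:
    """All (position, site_type) pairs: both termini plus C/D/E/H/K/R/Y."""
    sites: list[tuple[int, str]] = [(1, "n_term")]
    sites += [
        (i + 1, ch) for i, ch in enumerate(seq.residues) if ch in IONIZABLE_RESIDUES
    ]
    sites.append((seq.length, "c_term"))
    return sites


def predict_pka(
    model: FittedPKaEnsemble,
    seq: PolypeptideSequence,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-site pKa predictions for a sequence.

    When ``positions`` is omitted, all ionizable side chains plus both
    termini are enumerated. Explicit positions must be in range and
    ionizable. Returns a frame with 1-based ``position``, ``site`` type and
    predicted ``pka``.
    """
    if positions is None:
        sites = enumerate_ionizable_sites(seq)
    else:
        sites = []
        for pos in positions:
            if not (1 <= pos <= seq.length):
                raise ValueError(f"position {pos} outside sequence of length {seq.length}")
            ch = seq.residues[pos - 1]
            if ch not in IONIZABLE_RESIDUES:
                raise ValueError(f"residue {ch!r} at position {pos} is not ionizable")
            sites.append((pos, ch))
    preds = model.predict_sites(seq, sites)
    return pd.DataFrame({
        "id": seq.id,
        "position": [p for p, _ in sites],
        "site": [s for _, s in sites],
        "pka": preds,
    })


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(obj: object, path: str) -> None:
    """Persist a fitted model (single-file pickle archive)."""
    with open(path, "wb") as fh:
        pickle.dump(obj, fh)


def load_model(path: str) -> object:
    with open(path, "rb") as fh:
        return pickle.load(fh)
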