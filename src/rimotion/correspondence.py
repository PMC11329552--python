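"""Polynomial correspondence models between surrogate and liver motion.

The internal displacement ``y`` (mm) is modelled as a degree-n
polynomial in the scalar surrogate ``x`` (mm),

    y(beta) = beta_0 + beta_1 x + ... + beta_n x^n,

with coefficients obtained by ordinary least squares.  Three training
regimes address intra- vs. inter-fraction variability across the
sessions ``S_1..S_K`` of one subject:

* **single** — fit on all of ``S_1``, test on each remaining session;
* **specific** — fit on 70 % of one session, test on its held-out 30 %;
* **combined** — pool the 70 % training parts of every session, fit
  once, test on each session's held-out 30 %.

The default 70/30 split is chronologically contiguous, which respects
the serial correlation of breathing data; a seeded random split is
available behind a flag.  Performance is reported as mean absolute
error (MAE, mm) and the coefficient of determination (R^2, percent;
negative values from poor out-of-session fits are reported as-is).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .errors import DegenerateFitError, InvalidArgumentError

__all__ = [
    "PolynomialModel",
    "SessionData",
    "ModelReport",
    "fit_polynomial",
    "predict",
    "split_session",
    "mae",
    "r_squared",
    "run_single_model",
    "run_specific_model",
    "run_combined_model",
]

DEFAULT_DEGREE = 3
DEFAULT_TRAIN_FRACTION = 0.7


@dataclass
class PolynomialModel:
    """Fitted polynomial: ascending coefficients in the original x scale."""

    degree: int
    coefficients: np.ndarray  # beta_0 .. beta_n, mm per mm^k
    regime: str = ""
    sessions_used: tuple = ()
    train_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.degree + 1,):
            raise InvalidArgumentError("need degree + 1 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise InvalidArgumentError("coefficients must be finite")


@dataclass
class SessionData:
    """Synchronized (x, y) pair of one recording session.

    ``include`` flags samples usable for model fitting (breath-hold
    samples are flagged out, not deleted).
    """

    session_id: int
    timestamps: np.ndarray
    x: np.ndarray  # surrogate, mm
    y: np.ndarray  # internal displacement, mm
    include: np.ndarray | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.shape == self.x.shape == self.y.shape):
            raise InvalidArgumentError("timestamps, x and y must share a length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        if self.include is None:
            self.include = np.ones(self.x.shape, dtype=bool)
        else:
            self.include = np.asarray(self.include, dtype=bool)
            if self.include.shape != self.x.shape:
                raise InvalidArgumentError("include mask must match the data length")

    def __len__(self) -> int:
        return self.x.size

    def included(self) -> "SessionData":
        """The session restricted to fit-usable samples."""
        m = self.include
        return SessionData(
            session_id=self.session_id,
            timestamps=self.timestamps[m],
            x=self.x[m],
            y=self.y[m],
        )


@dataclass
class ModelReport:
    """MAE / R^2 per partition for one training regime."""

    regime: str
    degree: int
    train_mae: float
    train_r2: float
    test_mae: float
    test_r2: float
    train_mae_sd: float = 0.0
    train_r2_sd: float = 0.0
    test_mae_sd: float = 0.0
    test_r2_sd: float = 0.0
    per_session: list = field(default_factory=list)
    models: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "degree": self.degree,
            "train": {
                "mae_mm": self.train_mae,
                "mae_sd": self.train_mae_sd,
                "r2_pct": self.train_r2,
                "r2_sd": self.train_r2_sd,
            },
            "test": {
                "mae_mm": self.test_mae,
                "mae_sd": self.test_mae_sd,
                "r2_pct": self.test_r2,
                "r2_sd": self.test_r2_sd,
            },
            "per_session": self.per_session,
        }


def fit_polynomial(x, y, degree: int = DEFAULT_DEGREE, **metadata) -> PolynomialModel:
    """Least-squares polynomial fit of y on x.

    The solve is performed on a centred/scaled copy of ``x`` (the domain
    mapping of :class:`numpy.polynomial.Polynomial`), which keeps the
    Vandermonde matrix well conditioned for surrogate values far from
    zero; the returned coefficients are converted back to the original
    scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("x and y must be finite")
    if degree < 0:
        raise InvalidArgumentError("degree must be >= 0")
    if x.size < degree + 1:
        raise InvalidArgumentError(
            f"need at least degree + 1 = {degree + 1} samples, got {x.size}"
        )
    if np.unique(x).size < degree + 1:
        raise DegenerateFitError(
            f"degree-{degree} fit needs at least {degree + 1} distinct x values"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            poly = Polynomial.fit(x, y, deg=degree)
        except np.exceptions.RankWarning as exc:
            raise DegenerateFitError(
                f"rank-deficient design for degree-{degree} fit"
            ) from exc
    coefficients = poly.convert().coef
    if coefficients.size < degree + 1:  # trailing zeros trimmed by convert()
        coefficients = np.pad(coefficients, (0, degree + 1 - coefficients.size))
    return PolynomialModel(degree=degree, coefficients=coefficients, **metadata)


def predict(model: PolynomialModel, x) -> np.ndarray:
    """Evaluate the fitted polynomial (Horner scheme) at ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("x must be finite")
    # np.polyval expects descending coefficients -> Horner evaluation
    return np.polyval(model.coefficients[::-1], x)


def mae(y, y_hat) -> float:
    """Mean absolute error in mm."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise InvalidArgumentError("y and y_hat must be non-empty and equal length")
    return float(np.mean(np.abs(y - y_hat)))


def r_squared(y, y_hat) -> float:
    """Coefficient of determination in percent; nan for zero-variance y."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise InvalidArgumentError("y and y_hat must be non-empty and equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("R^2 undefined for zero-variance y; returning nan")
        return float("nan")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def split_session(
    session: SessionData,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    mode: str = "chronological",
    seed: int | None = None,
) -> tuple[SessionData, SessionData]:
    """70/30 (by default) partition of one session.

    Chronological mode takes the first ``floor(n * fraction)`` samples
    for training and the rest for testing; random mode shuffles sample
    indices with a mandatory seed.  Both parts must be non-empty.
    """
    if not (0.0 < train_fraction < 1.0):
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    data = session.included()
    n = len(data)
    n_train = int(np.floor(n * train_fraction))
    if n_train < 1 or n - n_train < 1:
        raise InvalidArgumentError(
            f"session too short to split: {n} samples at fraction {train_fraction}"
        )
    if mode == "chronological":
        idx_train = np.arange(n_train)
        idx_test = np.arange(n_train, n)
    elif mode == "random":
        if seed is None:
            raise InvalidArgumentError("random split requires a seed")
        perm = np.random.default_rng(seed).permutation(n)
        idx_train = np.sort(perm[:n_train])
        idx_test = np.sort(perm[n_train:])
    else:
        raise InvalidArgumentError(f"unknown split mode {mode!r}")

    def _take(idx):
        return SessionData(
            session_id=data.session_id,
            timestamps=data.timestamps[idx],
            x=data.x[idx],
            y=data.y[idx],
        )

    return _take(idx_train), _take(idx_test)


def _metrics(model: PolynomialModel, part: SessionData) -> tuple[float, float]:
    y_hat = predict(model, part.x)
    return mae(part.y, y_hat), r_squared(part.y, y_hat)


def _mean_sd(values) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd


def run_single_model(
    sessions: list[SessionData], degree: int = DEFAULT_DEGREE
) -> ModelReport:
    """Train on all of the first session, test on each remaining session."""
    if len(sessions) < 2:
        raise InvalidArgumentError("single-model regime needs at least 2 sessions")
    train = sessions[0].included()
    model = fit_polynomial(
        train.x, train.y, degree,
        regime="single", sessions_used=(sessions[0].session_id,),
    )
    train_mae, train_r2 = _metrics(model, train)
    per_session = []
    for s in sessions[1:]:
        part = s.included()
        m, r = _metrics(model, part)
        per_session.append(
            {"session_id": s.session_id, "test_mae_mm": m, "test_r2_pct": r}
        )
    t_mae, t_mae_sd = _mean_sd([p["test_mae_mm"] for p in per_session])
    t_r2, t_r2_sd = _mean_sd([p["test_r2_pct"] for p in per_session])
    return ModelReport(
        regime="single", degree=degree,
        train_mae=train_mae, train_r2=train_r2,
        test_mae=t_mae, test_mae_sd=t_mae_sd,
        test_r2=t_r2, test_r2_sd=t_r2_sd,
        per_session=per_session, models=[model],
    )


def run_specific_model(
    session: SessionData,
    degree: int = DEFAULT_DEGREE,
    n_repeats: int = 1,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    mode: str = "chronological",
    seed: int | None = None,
) -> ModelReport:
    """Within-session 70/30 fit and evaluation.

    With the chronological split the result is deterministic and
    ``n_repeats`` is ignored; with the random split the procedure is
    repeated ``n_repeats`` times (seeds ``seed + i``) and reported
    mean +/- sd.
    """
    repeats = 1 if mode == "chronological" else max(1, n_repeats)
    rows = []
    models = []
    for i in range(repeats):
        rep_seed = None if seed is None else seed + i
        train, test = split_session(session, train_fraction, mode=mode, seed=rep_seed)
        model = fit_polynomial(
            train.x, train.y, degree,
            regime="specific", sessions_used=(session.session_id,),
            train_fraction=train_fraction, seed=rep_seed,
        )
        tr = _metrics(model, train)
        te = _metrics(model, test)
        rows.append(tr + te)
        models.append(model)
    arr = np.asarray(rows)
    (tr_mae, tr_mae_sd) = _mean_sd(arr[:, 0])
    (tr_r2, tr_r2_sd) = _mean_sd(arr[:, 1])
    (te_mae, te_mae_sd) = _mean_sd(arr[:, 2])
    (te_r2, te_r2_sd) = _mean_sd(arr[:, 3])
    return ModelReport(
        regime="specific", degree=degree,
        train_mae=tr_mae, train_mae_sd=tr_mae_sd,
        train_r2=tr_r2, train_r2_sd=tr_r2_sd,
        test_mae=te_mae, test_mae_sd=te_mae_sd,
        test_r2=te_r2, test_r2_sd=te_r2_sd,
        per_session=[{"session_id": session.session_id, "n_repeats": repeats}],
        models=models,
    )


def run_specific_models(
    sessions: list[SessionData],
    degree: int = DEFAULT_DEGREE,
    **kwargs,
) -> ModelReport:
    """Specific regime on every session, aggregated mean +/- sd."""
    if not sessions:
        raise InvalidArgumentError("no sessions")
    reports = [run_specific_model(s, degree, **kwargs) for s in sessions]
    per_session = [
        {
            "session_id": s.session_id,
            "train_mae_mm": r.train_mae, "train_r2_pct": r.train_r2,
            "test_mae_mm": r.test_mae, "test_r2_pct": r.test_r2,
        }
        for s, r in zip(sessions, reports)
    ]
    tr_mae, tr_mae_sd = _mean_sd([r.train_mae for r in reports])
    tr_r2, tr_r2_sd = _mean_sd([r.train_r2 for r in reports])
    te_mae, te_mae_sd = _mean_sd([r.test_mae for r in reports])
    te_r2, te_r2_sd = _mean_sd([r.test_r2 for r in reports])
    return ModelReport(
        regime="specific", degree=degree,
        train_mae=tr_mae, train_mae_sd=tr_mae_sd,
        train_r2=tr_r2, train_r2_sd=tr_r2_sd,
        test_mae=te_mae, test_mae_sd=te_mae_sd,
        test_r2=te_r2, test_r2_sd=te_r2_sd,
        per_session=per_session,
        models=[m for r in reports for m in r.models],
    )


def run_combined_model(
    sessions: list[SessionData],
    degree: int = DEFAULT_DEGREE,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    mode: str = "chronological",
    seed: int | None = None,
) -> ModelReport:
    """Pool the training parts of every session, fit once, test per session."""
    if not sessions:
        raise InvalidArgumentError("no sessions")
    splits = [
        split_session(s, train_fraction, mode=mode, seed=seed) for s in sessions
    ]
    x_train = np.concatenate([tr.x for tr, _ in splits])
    y_train = np.concatenate([tr.y for tr, _ in splits])
    model = fit_polynomial(
        x_train, y_train, degree,
        regime="combined",
        sessions_used=tuple(s.session_id for s in sessions),
        train_fraction=train_fraction, seed=seed,
    )
    train_mae_v = mae(y_train, predict(model, x_train))
    train_r2_v = r_squared(y_train, predict(model, x_train))
    per_session = []
    for s, (_, test) in zip(sessions, splits):
        m, r = _metrics(model, test)
        per_session.append(
            {"session_id": s.session_id, "test_mae_mm": m, "test_r2_pct": r}
        )
    te_mae, te_mae_sd = _mean_sd([p["test_mae_mm"] for p in per_session])
    te_r2, te_r2_sd = _mean_sd([p["test_r2_pct"] for p in per_session])
    return ModelReport(
        regime="combined", degree=degree,
        train_mae=train_mae_v, train_r2=train_r2_v,
        test_mae=te_mae, test_mae_sd=te_mae_sd,
        test_r2=te_r2, test_r2_sd=te_r2_sd,
        per_session=per_session, models=[model],
    )


def select_degree(
    session: SessionData,
    degrees=range(1, 6),
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> int:
    """Pick the degree with the lowest held-out MAE (off by default)."""
    train, test = split_session(session, train_fraction)
    best_degree, best_mae = None, np.inf
    for d in degrees:
        model = fit_polynomial(train.x, train.y, d)
        m = mae(test.y, predict(model, test.x))
        if m < best_mae:
            best_degree, best_mae = d, m
    return best_degree
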