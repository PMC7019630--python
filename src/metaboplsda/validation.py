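"""Repeated double cross-validation and permutation testing for PLS-DA.

Double cross-validation (DCV) nests two stratified k-fold loops: the inner
loop picks the number of latent variables (the model complexity) by
minimising held-out misclassifications on the outer-training set only, and
the outer loop scores the refitted model on samples it has never touched —
an emulation of external validation.  The whole procedure is repeated with
fresh random splits so that the figures of merit do not depend on one
particular partition, and results are summarised as mean ± SD across
repetitions.

Three figures of merit are tracked on the pooled outer-test predictions:

* NMC — number of misclassifications;
* AUROC — rank probability that a random case outscores a random control
  (the Mann–Whitney U statistic divided by n₁·n₀, ties at half credit);
* DQ2 — a discriminant Q², i.e. cross-validated explained variance of the
  dummy response in which residuals that overshoot their own label in the
  correct direction (case predicted above 1, control below 0) are not
  penalised.

Statistical significance is assessed non-parametrically: the class labels
are permuted B times, the full DCV pipeline is re-run on each permutation,
and the observed figures are located in the resulting null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .plsda import classify, pls_fit, pls_predict, pls_predict_components
from .synthetic_cohort import Dataset


@dataclass(frozen=True)
class DCVConfig:
    """Configuration of the repeated double cross-validation procedure."""

    k_outer: int = 5
    k_inner: int = 5
    repetitions: int = 20
    max_components: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be at least 2")
        if self.repetitions < 1:
            raise ValueError("at least one repetition is required")
        if self.max_components < 1:
            raise ValueError("max_components must be at least 1")


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Random stratified assignment of samples to k folds.

    Per class, fold sizes differ by at most one; every sample lands in
    exactly one fold.
    """
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than k={k}"
            )
        labels = np.resize(rng.permutation(k), len(idx))
        rng.shuffle(labels)
        folds[idx] = labels
    return folds


def nmc(y_true: np.ndarray, y_pred: np.ndarray) -> int:
    """Number of misclassifications."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return int((y_true != y_pred).sum())


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUROC: U / (n₁ n₀) with mid-rank handling of ties."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def dq2(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Discriminant Q²: overshoot residuals in the correct direction are zeroed."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    overshoot = ((y == 1) & (s > 1)) | ((y == 0) & (s < 0))
    resid2 = np.where(overshoot, 0.0, (y - s) ** 2)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid2.sum()) / tss


def _inner_cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    k_inner: int,
    max_components: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Held-out inner-CV predictions for every complexity 1..A (n × A)."""
    folds = stratified_folds(y, k_inner, rng)
    counts = np.bincount(folds, minlength=k_inner)
    a_max = min(max_components, X.shape[1], len(y) - counts.max() - 1)
    if a_max < 1:
        raise ValueError("training folds too small to fit a single component")
    preds = np.empty((len(y), a_max))
    for f in range(k_inner):
        te = folds == f
        tr = ~te
        model = pls_fit(X[tr], y[tr], a_max)
        preds[te] = pls_predict_components(model, X[te])
    return preds


def select_components_inner(
    X: np.ndarray,
    y: np.ndarray,
    config: DCVConfig,
    rng: np.random.Generator,
) -> int:
    """Pick the LV count minimising inner-CV misclassifications (ties → smallest)."""
    preds = _inner_cv_scores(X, y, config.k_inner, config.max_components, rng)
    nmcs = [
        nmc(y, classify(preds[:, a], config.threshold))
        for a in range(preds.shape[1])
    ]
    return int(np.argmin(nmcs)) + 1


def _rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return 100.0 * float((y_true == y_pred).mean())


def _per_class_rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    overall = _rate(y_true, y_pred)
    case = _rate(y_true[y_true == 1], y_pred[y_true == 1])
    control = _rate(y_true[y_true == 0], y_pred[y_true == 0])
    return overall, case, control


@dataclass
class RepetitionResult:
    """Outcome of one DCV repetition (one fresh outer split)."""

    outer_folds: np.ndarray
    selected_components: list[int]
    outer_scores: np.ndarray
    outer_pred: np.ndarray
    calibration_rates: tuple[float, float, float]
    inner_rates: tuple[float, float, float]
    outer_rates: tuple[float, float, float]
    nmc: int
    auroc: float
    dq2: float


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class DCVResult:
    """Aggregated repeated-DCV outcome.

    Correct-classification rates are on a 0–100% scale; each of the
    calibration / inner / outer stages carries (overall, case, control)
    mean ± SD across repetitions.  The pooled outer figures of merit
    (NMC, AUROC, DQ2) are averaged across repetitions.
    """

    config: DCVConfig
    repetitions: list[RepetitionResult]
    rates: dict = field(init=False)
    nmc_mean: float = field(init=False)
    nmc_sd: float = field(init=False)
    auroc_mean: float = field(init=False)
    auroc_sd: float = field(init=False)
    dq2_mean: float = field(init=False)
    dq2_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.rates = {}
        for stage, attr in (
            ("calibration", "calibration_rates"),
            ("inner", "inner_rates"),
            ("outer", "outer_rates"),
        ):
            self.rates[stage] = {
                group: _mean_sd([getattr(r, attr)[i] for r in self.repetitions])
                for i, group in enumerate(("overall", "case", "control"))
            }
        self.nmc_mean, self.nmc_sd = _mean_sd([r.nmc for r in self.repetitions])
        self.auroc_mean, self.auroc_sd = _mean_sd([r.auroc for r in self.repetitions])
        self.dq2_mean, self.dq2_sd = _mean_sd([r.dq2 for r in self.repetitions])

    @property
    def outer_overall_mean(self) -> float:
        return self.rates["outer"]["overall"][0]

    @property
    def outer_case_mean(self) -> float:
        return self.rates["outer"]["case"][0]

    @property
    def outer_control_mean(self) -> float:
        return self.rates["outer"]["control"][0]

    def summary(self) -> dict:
        return {
            "rates_percent": {
                stage: {
                    group: {"mean": m, "sd": s}
                    for group, (m, s) in groups.items()
                }
                for stage, groups in self.rates.items()
            },
            "selected_components": [
                r.selected_components for r in self.repetitions
            ],
            "nmc": {"mean": self.nmc_mean, "sd": self.nmc_sd},
            "auroc": {"mean": self.auroc_mean, "sd": self.auroc_sd},
            "dq2": {"mean": self.dq2_mean, "sd": self.dq2_sd},
        }


def double_cv(dataset: Dataset, config: DCVConfig) -> DCVResult:
    """Repeated stratified double cross-validation of PLS-DA on a dataset.

    Every repetition draws a fresh outer split; within each outer fold the
    scaler, the LV count and the model are learned from the outer-training
    samples only, so the outer-test predictions are leakage-free.
    """
    X, y = dataset.X, dataset.y
    smallest = int(min(np.bincount(y)))
    if smallest < config.k_outer:
        raise ValueError("smallest class is smaller than k_outer")

    children = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    reps: list[RepetitionResult] = []
    for child in children:
        rng = np.random.default_rng(child)
        outer = stratified_folds(y, config.k_outer, rng)
        outer_scores = np.empty(len(y))
        chosen: list[int] = []
        calib_true: list[np.ndarray] = []
        calib_pred: list[np.ndarray] = []
        inner_true: list[np.ndarray] = []
        inner_pred: list[np.ndarray] = []
        for f in range(config.k_outer):
            te = outer == f
            tr = ~te
            inner_scores = _inner_cv_scores(
                X[tr], y[tr], config.k_inner, config.max_components, rng
            )
            inner_nmcs = [
                nmc(y[tr], classify(inner_scores[:, a], config.threshold))
                for a in range(inner_scores.shape[1])
            ]
            a_sel = int(np.argmin(inner_nmcs)) + 1
            chosen.append(a_sel)
            model = pls_fit(X[tr], y[tr], a_sel, threshold=config.threshold)
            calib_true.append(y[tr])
            calib_pred.append(
                classify(pls_predict(model, X[tr]), config.threshold)
            )
            inner_true.append(y[tr])
            inner_pred.append(
                classify(inner_scores[:, a_sel - 1], config.threshold)
            )
            outer_scores[te] = pls_predict(model, X[te])
        outer_pred = classify(outer_scores, config.threshold)
        reps.append(
            RepetitionResult(
                outer_folds=outer,
                selected_components=chosen,
                outer_scores=outer_scores,
                outer_pred=outer_pred,
                calibration_rates=_per_class_rates(
                    np.concatenate(calib_true), np.concatenate(calib_pred)
                ),
                inner_rates=_per_class_rates(
                    np.concatenate(inner_true), np.concatenate(inner_pred)
                ),
                outer_rates=_per_class_rates(y, outer_pred),
                nmc=nmc(y, outer_pred),
                auroc=auroc(y, outer_scores),
                dq2=dq2(y, outer_scores),
            )
        )
    return DCVResult(config=config, repetitions=reps)


@dataclass
class PermutationResult:
    """Null distributions and p-values from a label-permutation test.

    p-values use the add-one estimator (b + 1)/(B + 1): small NMC is
    extreme (null ≤ observed counted), large AUROC/DQ2 are extreme
    (null ≥ observed counted).  The smallest attainable p is 1/(B + 1).
    """

    B: int
    null_nmc: np.ndarray
    null_auroc: np.ndarray
    null_dq2: np.ndarray
    observed_nmc: float
    observed_auroc: float
    observed_dq2: float
    p_nmc: float = field(init=False)
    p_auroc: float = field(init=False)
    p_dq2: float = field(init=False)

    def __post_init__(self) -> None:
        self.p_nmc = float(
            ((self.null_nmc <= self.observed_nmc).sum() + 1) / (self.B + 1)
        )
        self.p_auroc = float(
            ((self.null_auroc >= self.observed_auroc).sum() + 1) / (self.B + 1)
        )
        self.p_dq2 = float(
            ((self.null_dq2 >= self.observed_dq2).sum() + 1) / (self.B + 1)
        )

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "observed": {
                "nmc": self.observed_nmc,
                "auroc": self.observed_auroc,
                "dq2": self.observed_dq2,
            },
            "p_values": {
                "nmc": self.p_nmc,
                "auroc": self.p_auroc,
                "dq2": self.p_dq2,
            },
            "null_nmc": self.null_nmc.tolist(),
            "null_auroc": self.null_auroc.tolist(),
            "null_dq2": self.null_dq2.tolist(),
        }


def permutation_test(
    dataset: Dataset,
    config: DCVConfig,
    B: int = 1000,
    *,
    permutation_repetitions: int = 5,
    observed: DCVResult | None = None,
) -> PermutationResult:
    """Locate the observed DCV figures of merit in a label-permutation null.

    Each of the B permutations shuffles the class labels and re-runs the
    complete repeated-DCV pipeline (with ``permutation_repetitions``
    repetitions to bound cost); the statistic entering the comparison is
    the across-repetition mean of the pooled outer figure, identical in
    form to the observed one.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if observed is None:
        observed = double_cv(dataset, config)

    root = np.random.SeedSequence(config.seed)
    # dedicated branch for the permutation loop, distinct from DCV children
    perm_seeds = root.spawn(config.repetitions + B)[config.repetitions:]
    null_nmc = np.empty(B)
    null_auroc = np.empty(B)
    null_dq2 = np.empty(B)
    for b, seq in enumerate(perm_seeds):
        rng = np.random.default_rng(seq)
        y_perm = rng.permutation(dataset.y)
        perm_dataset = Dataset(
            dataset.sample_ids, dataset.X, y_perm, dataset.analyte_names
        )
        cfg_b = replace(
            config,
            repetitions=permutation_repetitions,
            seed=int(rng.integers(2**31)),
        )
        res = double_cv(perm_dataset, cfg_b)
        null_nmc[b] = res.nmc_mean
        null_auroc[b] = res.auroc_mean
        null_dq2[b] = res.dq2_mean
    return PermutationResult(
        B=B,
        null_nmc=null_nmc,
        null_auroc=null_auroc,
        null_dq2=null_dq2,
        observed_nmc=observed.nmc_mean,
        observed_auroc=observed.auroc_mean,
        observed_dq2=observed.dq2_mean,
    )
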