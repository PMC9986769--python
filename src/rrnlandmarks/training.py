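"""Training loop, cross-validation, millimetre evaluation and comparisons.

Training minimizes the per-input mean squared pixel-space error with Adam on
mini-batches of cases.  Evaluation converts per-axis pixel residuals to
millimetres with the case's voxel spacing and reports, per target landmark,
the mean, standard deviation and RMSE of the Euclidean millimetre error over
evaluation cases.  Cross-validation groups augmented cases with their base
case so no information about a held-out subject leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .features import feature_tensor
from .landmarks import (CohortTable, ConfigurationSpec, DataError, Landmark,
                        LandmarkCase, ValidationError, VOCABULARY,
                        builtin_configuration, pixel_to_mm)
from .model import RRNModel, RUSpec, build_rrn, substream

__all__ = [
    "TrainConfig",
    "TrainingError",
    "FoldSplit",
    "LandmarkStats",
    "EvalReport",
    "default_epochs",
    "make_folds",
    "fold_members",
    "train",
    "evaluate_rmse",
    "detect_outliers",
    "compare_methods",
    "run_experiment",
    "mean_position_baseline",
    "baseline_errors",
]

_VOCAB_INDEX = {lm: k for k, lm in enumerate(VOCABULARY)}


class TrainingError(RuntimeError):
    """Raised when optimization diverges; carries the loss trace."""

    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = list(trace)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    folds: int = 4
    seed: int = 0
    learning_rate: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    ru_spec: RUSpec = field(default_factory=RUSpec)

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("need at least 2 folds")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


def default_epochs(ru_spec: RUSpec) -> int:
    """Epoch budget: 100 for the regular-dropout MLP, 20 otherwise."""
    if ru_spec.ru_type == "mlp" and ru_spec.dropout.variant == "regular":
        return 100
    return 20


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    assignments: Dict[str, int]
    k: int

    def fold_of(self, case_id: str) -> int:
        return self.assignments[case_id]


def fold_members(cohort: CohortTable, split: FoldSplit, fold: int):
    """(train_cases, test_cases) for one fold.

    Test cases are the held-out base cases; the training set drops any
    augmented case with a parent inside the test fold (no subject leakage).
    """
    test_cases = [c for c in cohort
                  if split.fold_of(c.case_id) == fold and not c.derived_from]
    train_cases = [c for c in cohort
                   if split.fold_of(c.case_id) != fold
                   and not any(split.fold_of(p) == fold for p in c.derived_from)]
    return train_cases, test_cases


def make_folds(cohort: CohortTable, k: int, seed: int) -> FoldSplit:
    """Seeded base-case partition; augmented cases follow their primary parent.

    Base folds are balanced to within one case.  An augmented case (one with
    a nonempty `derived_from`) is assigned the fold of its first — largest
    weight — parent.
    """
    base = [c for c in cohort if not c.derived_from]
    if len(base) < k:
        raise ValidationError(f"need at least {k} base cases, have {len(base)}")
    rng = substream(seed, "folds")
    order = rng.permutation(len(base))
    assignments = {base[int(i)].case_id: int(r % k) for r, i in enumerate(order)}
    for c in cohort:
        if c.derived_from:
            parent = c.derived_from[0]
            if parent not in assignments:
                raise ValidationError(
                    f"augmented case {c.case_id} references unknown parent {parent}")
            assignments[c.case_id] = assignments[parent]
    return FoldSplit(assignments=assignments, k=k)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr: float, betas: Tuple[float, float], eps: float = 1e-8):
        self.params = [t for _, t in params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _cohort_arrays(cases: Sequence[LandmarkCase], config: ConfigurationSpec):
    """Stacked positions/features/targets for a case list (must be complete
    for the configuration's input and target landmarks)."""
    needed = config.input_set + config.target_set
    positions = np.full((len(cases), len(VOCABULARY), 3), np.nan)
    for c_idx, case in enumerate(cases):
        for lm in needed:
            if lm not in case.positions:
                raise DataError(f"case {case.case_id} is missing landmark {lm.symbol}")
            positions[c_idx, _VOCAB_INDEX[lm]] = case.positions[lm]
    feats = feature_tensor(positions, config, _VOCAB_INDEX)        # (C, P, 19)
    me = positions[:, _VOCAB_INDEX[Landmark.Me], :]
    tgt_idx = [_VOCAB_INDEX[lm] for lm in config.target_set]
    targets = positions[:, tgt_idx, :]
    return positions, feats, me, targets


def _targeted_masks(model: RRNModel, rng: np.random.Generator) -> Dict[int, np.ndarray]:
    """Per-step targeted-dropout masks, one per weight matrix per unit block."""
    spec = model.ru_spec.dropout
    masks: Dict[int, np.ndarray] = {}
    for W in model.weight_tensors():
        flat = np.abs(W.data.reshape(W.data.shape[0], -1))
        U, rest = flat.shape
        k = int(np.floor(spec.gamma * rest))
        mask = np.ones_like(flat)
        if k > 0:
            order = np.argsort(flat, axis=1, kind="stable")[:, :k]
            drops = rng.random((U, k)) < spec.alpha
            rows = np.repeat(np.arange(U)[:, None], k, axis=1)
            mask[rows[drops], order[drops]] = 0.0
        masks[id(W)] = mask.reshape(W.data.shape)
    return masks


def train(model: RRNModel, cohort: Union[CohortTable, Sequence[LandmarkCase]],
          tc: TrainConfig) -> Tuple[RRNModel, List[float]]:
    """Mini-batch Adam on the per-input MSE loss; returns the epoch loss trace."""
    cases = list(cohort)
    if not cases:
        raise ValidationError("cannot train on an empty cohort")
    _, feats, me, targets = _cohort_arrays(cases, model.config)
    C = feats.shape[0]
    model.set_offset_normalization(targets - me[:, None, :])
    opt = _Adam(model.parameters(), tc.learning_rate, tc.betas)
    shuffle_rng = substream(tc.seed, "batches")
    noise_rng = substream(tc.seed, "noise")
    dropout = model.ru_spec.dropout
    trace: List[float] = []
    for epoch in range(tc.epochs):
        # cosine decay to a 10% floor: settles the last epochs near a minimum
        if tc.epochs > 1:
            frac = 0.5 * (1 + np.cos(np.pi * epoch / (tc.epochs - 1)))
            opt.lr = tc.learning_rate * (0.1 + 0.9 * frac)
        perm = shuffle_rng.permutation(C)
        epoch_losses = []
        for start in range(0, C, tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            X = np.ascontiguousarray(np.swapaxes(feats[idx], 0, 1))  # (P, B, 19)
            masks = (_targeted_masks(model, noise_rng)
                     if dropout.variant == "targeted" else None)
            loss = model.training_loss(X, me[idx], targets[idx],
                                       rng=noise_rng, weight_masks=masks)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}", trace + epoch_losses)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    model.recalibrate_bn(feats, tc.batch_size)
    return model, trace


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class LandmarkStats:
    mean_mm: float
    std_mm: float
    rmse_mm: float
    n: int


@dataclass
class EvalReport:
    config_name: str
    per_landmark: Dict[Landmark, LandmarkStats]
    overall_mean_mm: float
    errors: List[Tuple[str, Landmark, float]]
    outliers: List[Tuple[str, Landmark, float]] = field(default_factory=list)
    fold_breakdown: List["EvalReport"] = field(default_factory=list)

    def to_table(self):
        """Table-2-style frame: one row, landmark columns, mm units."""
        import pandas as pd
        row = {}
        for lm in VOCABULARY:
            if lm in self.per_landmark:
                s = self.per_landmark[lm]
                row[lm.symbol] = f"{s.mean_mm:.2f}±{s.std_mm:.2f}"
            else:
                row[lm.symbol] = "—"
        return pd.DataFrame([row], index=[self.config_name])

    def to_dict(self) -> dict:
        return {
            "config": self.config_name,
            "overall_mean_mm": self.overall_mean_mm,
            "per_landmark": {
                lm.symbol: {"mean_mm": s.mean_mm, "std_mm": s.std_mm,
                            "rmse_mm": s.rmse_mm, "n": s.n}
                for lm, s in self.per_landmark.items()},
            "outliers": [(cid, lm.symbol, e) for cid, lm, e in self.outliers],
        }


def _report_from_errors(config: ConfigurationSpec,
                        records: List[Tuple[str, Landmark, float]]) -> EvalReport:
    per_landmark: Dict[Landmark, LandmarkStats] = {}
    for lm in config.target_set:
        errs = np.array([e for _, l, e in records if l is lm])
        if errs.size == 0:
            continue
        per_landmark[lm] = LandmarkStats(
            mean_mm=float(errs.mean()), std_mm=float(errs.std()),
            rmse_mm=float(np.sqrt((errs ** 2).mean())), n=int(errs.size))
    overall = float(np.mean([s.mean_mm for s in per_landmark.values()]))
    report = EvalReport(config_name=config.name, per_landmark=per_landmark,
                        overall_mean_mm=overall, errors=records)
    report.outliers = detect_outliers(report)
    return report


def evaluate_rmse(model: RRNModel, cohort: Union[CohortTable, Sequence[LandmarkCase]],
                  spacing_override: Optional[np.ndarray] = None) -> EvalReport:
    """Consensus-prediction millimetre errors per case and target landmark."""
    cases = list(cohort)
    if not cases:
        raise ValidationError("cannot evaluate an empty cohort")
    positions, _, _, targets = _cohort_arrays(cases, model.config)
    _, consensus = model.predict_positions(positions)            # (C, m, 3)
    records: List[Tuple[str, Landmark, float]] = []
    for c_idx, case in enumerate(cases):
        spacing = (np.asarray(spacing_override, dtype=float)
                   if spacing_override is not None else case.spacing)
        diff_mm = pixel_to_mm(consensus[c_idx] - targets[c_idx], spacing)
        err = np.linalg.norm(diff_mm, axis=-1)
        for k, lm in enumerate(model.config.target_set):
            records.append((case.case_id, lm, float(err[k])))
    return _report_from_errors(model.config, records)


def detect_outliers(report: EvalReport, threshold_mm: Optional[float] = None
                    ) -> List[Tuple[str, Landmark, float]]:
    """Errors exceeding `threshold_mm` (default: per-landmark mean + 3 std)."""
    out = []
    for cid, lm, err in report.errors:
        if threshold_mm is not None:
            thr = threshold_mm
        else:
            s = report.per_landmark[lm]
            thr = s.mean_mm + 3.0 * s.std_mm
        if err > thr:
            out.append((cid, lm, err))
    return out


def compare_methods(errors_a: Sequence[float], errors_b: Sequence[float],
                    alpha: float = 0.05) -> Tuple[float, str]:
    """Paired two-sided t-test; verdict 'different' iff p < alpha."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired comparison needs equal-length 1-D sequences")
    if np.allclose(a, b):
        return 1.0, "not-different"
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0, "not-different"
    return p, ("different" if p < alpha else "not-different")


# ---------------------------------------------------------------------------
# baselines and the cross-validated experiment
# ---------------------------------------------------------------------------

def mean_position_baseline(cases: Sequence[LandmarkCase],
                           config: ConfigurationSpec) -> Dict[Landmark, np.ndarray]:
    """Training-set mean pixel position of each target landmark."""
    out = {}
    for lm in config.target_set:
        out[lm] = np.mean([c.positions[lm] for c in cases], axis=0)
    return out


def baseline_errors(cases: Sequence[LandmarkCase], config: ConfigurationSpec,
                    baseline: Dict[Landmark, np.ndarray]) -> Dict[Landmark, float]:
    """Mean mm error of the constant mean-position predictor per landmark."""
    errs: Dict[Landmark, List[float]] = {lm: [] for lm in config.target_set}
    for case in cases:
        for lm in config.target_set:
            diff = pixel_to_mm(baseline[lm] - case.positions[lm], case.spacing)
            errs[lm].append(float(np.linalg.norm(diff)))
    return {lm: float(np.mean(v)) for lm, v in errs.items()}


def run_experiment(config_name: Union[str, ConfigurationSpec], cohort: CohortTable,
                   tc: TrainConfig, collect_baseline: bool = False):
    """k-fold cross-validated training and held-out evaluation.

    Augmented cases train only; held-out evaluation uses the base cases of
    the test fold.  Augmented cases with any parent inside the test fold are
    excluded from that fold's training set (no subject leakage).  Returns the
    aggregated EvalReport (with per-fold breakdown); with
    `collect_baseline=True` returns (report, mean-position baseline errors).
    """
    config = (builtin_configuration(config_name)
              if isinstance(config_name, str) else config_name)
    split = make_folds(cohort, tc.folds, tc.seed)
    all_records: List[Tuple[str, Landmark, float]] = []
    fold_reports: List[EvalReport] = []
    baseline_acc: Dict[Landmark, List[float]] = {lm: [] for lm in config.target_set}
    for f in range(tc.folds):
        train_cases, test_cases = fold_members(cohort, split, f)
        fold_seed = int(substream(tc.seed, f"fold-{f}").integers(0, 2 ** 31 - 1))
        model = build_rrn(config, tc.ru_spec, seed=fold_seed)
        fold_tc = TrainConfig(epochs=tc.epochs, batch_size=tc.batch_size,
                              folds=tc.folds, seed=fold_seed,
                              learning_rate=tc.learning_rate, betas=tc.betas,
                              ru_spec=tc.ru_spec)
        train(model, train_cases, fold_tc)
        report = evaluate_rmse(model, test_cases)
        fold_reports.append(report)
        all_records.extend(report.errors)
        if collect_baseline:
            bl = mean_position_baseline(train_cases, config)
            for lm, e in baseline_errors(test_cases, config, bl).items():
                baseline_acc[lm].append(e)
    combined = _report_from_errors(config, all_records)
    combined.fold_breakdown = fold_reports
    if collect_baseline:
        return combined, {lm: float(np.mean(v)) for lm, v in baseline_acc.items()}
    return combined
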