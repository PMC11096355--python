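"""Prediction arms as model objects.

Every arm follows the same pattern: a model object is built from a
:class:`CohortData` container (preprocessed cases), ``fit()`` trains it
and returns a results object carrying the fitted estimator, training
history and diagnostics, and the results object scores new cases via
``predict()`` and renders a ``summary()`` table.

Arms
----
* :class:`DmaxBoostModel` — per-timepoint maximum axial diameters,
  concatenated in time order into a gradient-boosted-tree classifier.
* :class:`RadiomicsBoostModel` — the frozen radiomics vector per
  timepoint, concatenated likewise.
* :class:`ConvGRUModel` — residual CNN encoder (2D tri-planar or 3D
  volumetric) shared across timepoints, feeding a GRU over the feature
  sequence; trained end-to-end with focal loss.
* :class:`SimpleCNNModel` — same encoder with a fixed-length
  concatenation head instead of the GRU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Profile, TrainConfig, desk_profile
from .features import FeatureSequence, build_feature_sequence, fit_gbt_arm
from .preprocess import PreparedCase, preprocess_case
from .synth import CohortSpec, iter_cohort
from . import nn
from .nn import Adam, ConcatHead, GRUHead, ResNetEncoder, focal_loss_with_logits

ARM_NAMES = (
    "dmax", "radiomics",
    "conv_gru_2d", "conv_gru_3d", "simple_cnn_2d", "simple_cnn_3d",
)


@dataclass
class CohortData:
    """Preprocessed cohort: one :class:`PreparedCase` per lesion."""

    cases: list[PreparedCase]
    profile: Profile

    @classmethod
    def from_spec(cls, spec: CohortSpec, profile: Profile | None = None) -> "CohortData":
        profile = profile or desk_profile()
        return cls([preprocess_case(c, profile) for c in iter_cohort(spec)], profile)

    @classmethod
    def from_cases(cls, cases, profile: Profile | None = None) -> "CohortData":
        profile = profile or desk_profile()
        return cls([preprocess_case(c, profile) for c in cases], profile)

    @property
    def ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.y for c in self.cases])

    def subset(self, ids) -> "CohortData":
        wanted = set(ids)
        return CohortData([c for c in self.cases if c.case_id in wanted], self.profile)

    def with_labels(self, y: np.ndarray) -> "CohortData":
        """Copy with replaced labels (e.g. a permutation-null cohort)."""
        import copy

        out = []
        for c, yi in zip(self.cases, y):
            c2 = copy.copy(c)
            c2.y = int(yi)
            c2.label = "PD" if yi else "non-PD"
            out.append(c2)
        return CohortData(out, self.profile)

    def __len__(self) -> int:
        return len(self.cases)


class _SummaryMixin:
    def summary(self) -> str:
        rows = self._summary_rows()
        width = max(len(k) for k, _ in rows) + 2
        lines = [f"{self._title}", "=" * 48]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# boosted-tree arms


class _BoostArmModel:
    arm: str = ""

    def __init__(self, data: CohortData, n_timepoints: int = 4):
        if not 1 <= n_timepoints <= 4:
            raise ValueError("n_timepoints must be 1-4")
        self.data = data
        self.n_timepoints = n_timepoints

    def _sequences(self, data: CohortData) -> list[FeatureSequence]:
        return [
            build_feature_sequence(c, self.arm, self.n_timepoints)
            for c in data.cases
        ]

    def fit(self, seed: int = 0) -> "BoostArmResults":
        train_seqs = self._sequences(self.data)
        from xgboost import XGBClassifier

        x = np.stack([s.flat for s in train_seqs])
        y = np.array([s.y for s in train_seqs])
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        clf = XGBClassifier(
            max_depth=3, n_estimators=200, learning_rate=0.1,
            objective="binary:logistic", random_state=int(seed) % (2**31),
            n_jobs=1, verbosity=0, eval_metric="logloss",
        )
        clf.fit(x, y)
        return BoostArmResults(self, clf, train_seqs)


@dataclass
class BoostArmResults(_SummaryMixin):
    model: _BoostArmModel
    estimator: object
    train_sequences: list[FeatureSequence]

    @property
    def _title(self):
        return f"{self.model.arm} boosted-tree arm ({self.model.n_timepoints} timepoints)"

    def predict(self, data: CohortData) -> np.ndarray:
        """PD probability per case."""
        seqs = self.model._sequences(data)
        x = np.stack([s.flat for s in seqs])
        return self.estimator.predict_proba(x)[:, 1]

    def _summary_rows(self):
        from .evaluate import roc_auc

        scores = self.estimator.predict_proba(
            np.stack([s.flat for s in self.train_sequences])
        )[:, 1]
        y = np.array([s.y for s in self.train_sequences])
        return [
            ("arm", self.model.arm),
            ("timepoints", self.model.n_timepoints),
            ("flat features", len(self.train_sequences[0].flat)),
            ("n train cases", len(y)),
            ("train PD fraction", f"{y.mean():.3f}"),
            ("train AUC", f"{roc_auc(scores, y):.4f}"),
        ]


class DmaxBoostModel(_BoostArmModel):
    """Maximum-axial-diameter sequences into gradient-boosted trees."""

    arm = "dmax"


class RadiomicsBoostModel(_BoostArmModel):
    """Radiomics feature sequences into gradient-boosted trees."""

    arm = "radiomics"


# --------------------------------------------------------------------------
# neural arms


class _NeuralModel:
    head_kind = "gru"

    def __init__(
        self,
        data: CohortData,
        dims: str = "2d",
        n_timepoints: int = 4,
        train_config: TrainConfig | None = None,
    ):
        if dims not in ("2d", "3d"):
            raise ValueError("dims must be '2d' or '3d'")
        if not 1 <= n_timepoints <= 4:
            raise ValueError("n_timepoints must be 1-4")
        self.data = data
        self.dims = dims
        self.n_timepoints = n_timepoints
        profile = data.profile
        self.encoder_config = profile.encoder_2d if dims == "2d" else profile.encoder_3d
        self.train_config = train_config or profile.train

    def _tensor(self, case: PreparedCase, k: int | None = None) -> np.ndarray:
        k = k or self.n_timepoints
        if self.dims == "2d":
            return case.triplanar_stack(k)
        return case.patch_stack(k)

    def fit(self, seed: int = 0) -> "NeuralResults":
        cfg = self.train_config
        y = self.data.labels
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
        encoder = ResNetEncoder(self.encoder_config, rng=rng)
        f = self.encoder_config.feature_dim
        if self.head_kind == "gru":
            head = GRUHead(f, rng=rng)
        else:
            head = ConcatHead(self.n_timepoints, f, rng=rng)
        opt = Adam(encoder.params() + head.params(), lr=cfg.base_lr)
        alpha_pos = (
            cfg.focal_alpha if cfg.focal_alpha is not None else 1.0 - float(y.mean())
        )

        tensors = [self._tensor(c).astype(np.float32) for c in self.data.cases]
        n = len(tensors)
        history = []
        for epoch in range(1, cfg.epochs + 1):
            opt.lr = cfg.lr_at_epoch(epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = []
                for i in idx:
                    x = tensors[i]
                    if cfg.augment:
                        p = nn.sample_augment(rng, cfg, x.ndim - 2)
                        x = np.stack([nn.apply_augment(xt, p) for xt in x])
                    batch.append(x)
                xb = np.concatenate(batch, axis=0)  # (B*T, C, *S)
                yb = y[idx]
                b, t = len(idx), self.n_timepoints
                feats = encoder.forward(xb, train=True)
                logits = head.forward(feats.reshape(b, t, f), train=True)
                loss, dlogits = focal_loss_with_logits(
                    logits, yb, cfg.focal_gamma, alpha_pos
                )
                dfeats = head.backward(dlogits)
                encoder.backward(dfeats.reshape(b * t, f))
                opt.step()
                opt.zero_grad()
                losses.append(loss)
            history.append(
                {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses))}
            )
        return NeuralResults(self, encoder, head, pd.DataFrame(history), alpha_pos)


@dataclass
class NeuralResults(_SummaryMixin):
    model: _NeuralModel
    encoder: ResNetEncoder
    head: object
    history: pd.DataFrame
    alpha_pos: float

    @property
    def _title(self):
        return (
            f"{self.model.dims} {'Conv-GRU' if self.model.head_kind == 'gru' else 'simple CNN'}"
            f" arm ({self.model.n_timepoints} timepoints)"
        )

    @property
    def model_id(self) -> str:
        kind = "conv_gru" if self.model.head_kind == "gru" else "simple_cnn"
        return f"{kind}_{self.model.dims}"

    def predict(self, data: CohortData, n_timepoints: int | None = None) -> np.ndarray:
        """PD probability per case (deterministic eval-mode pass).

        The GRU head accepts any ``n_timepoints`` from 1 to the cohort
        length; the concatenation head only the length it was built for.
        """
        k = n_timepoints or self.model.n_timepoints
        f = self.model.encoder_config.feature_dim
        scores = []
        for case in data.cases:
            x = self.model._tensor(case, k).astype(np.float32)
            feats = self.encoder.forward(x, train=False)
            logit = self.head.forward(feats.reshape(1, k, f), train=False)
            scores.append(1.0 / (1.0 + np.exp(-float(logit[0]))))
        return np.asarray(scores)

    def _summary_rows(self):
        cfg = self.model.train_config
        return [
            ("encoder", f"{self.model.dims} residual CNN, width {self.model.encoder_config.width}"),
            ("feature dim", self.model.encoder_config.feature_dim),
            ("head", self.model.head_kind),
            ("epochs", cfg.epochs),
            ("focal gamma / alpha+", f"{cfg.focal_gamma} / {self.alpha_pos:.3f}"),
            ("final train loss", f"{self.history['loss'].iloc[-1]:.4f}"),
            ("n train cases", len(self.model.data)),
        ]


class ConvGRUModel(_NeuralModel):
    """CNN encoder + GRU sequence head, trained end-to-end."""

    head_kind = "gru"


class SimpleCNNModel(_NeuralModel):
    """CNN encoder + fixed-length concatenation head."""

    head_kind = "concat"


# --------------------------------------------------------------------------
# arm factory and focal-gamma grid search


def make_model(arm: str, data: CohortData, n_timepoints: int = 4,
               train_config: TrainConfig | None = None):
    """Construct the model object for an arm name from :data:`ARM_NAMES`."""
    if arm == "dmax":
        return DmaxBoostModel(data, n_timepoints)
    if arm == "radiomics":
        return RadiomicsBoostModel(data, n_timepoints)
    kind, dims = arm.rsplit("_", 1)
    if dims not in ("2d", "3d") or kind not in ("conv_gru", "simple_cnn"):
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARM_NAMES}")
    cls = ConvGRUModel if kind == "conv_gru" else SimpleCNNModel
    return cls(data, dims=dims, n_timepoints=n_timepoints, train_config=train_config)


def tune_focal_gamma(
    fit_and_score,
    val_labels: np.ndarray,
    gamma_grid=(0.0, 1.0, 2.0, 5.0),
    default: float = 2.0,
) -> float:
    """Grid-search the focal-loss gamma on a validation fold.

    ``fit_and_score(gamma)`` must return validation scores aligned with
    ``val_labels``.  Returns the gamma maximising validation AUC; ties go
    to the smallest gamma.  Degenerate (single-class) validation labels
    fall back to ``default`` with a warning.
    """
    from .evaluate import roc_auc

    if len(gamma_grid) == 0:
        raise ValueError("gamma grid is empty")
    if len(np.unique(np.asarray(val_labels))) < 2:
        warnings.warn(
            f"single-class validation labels; falling back to gamma={default}",
            stacklevel=2,
        )
        return default
    best_gamma, best_auc = None, -np.inf
    for gamma in sorted(gamma_grid):
        auc = roc_auc(np.asarray(fit_and_score(gamma)), val_labels)
        if auc > best_auc + 1e-12:
            best_gamma, best_auc = gamma, auc
    return float(best_gamma)
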