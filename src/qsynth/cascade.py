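"""Cascaded per-question generation of questionnaire batteries.

Given real SF-36 answers, the cascade generates the remaining five
questionnaires one at a time, in the order derived from the subscale
correlation graph.  Step k trains one class-weighted classifier per question
of the target questionnaire on [real SF-36 || synthetic answers of all
previously generated questionnaires]; its synthetic output is concatenated
into the next step's features.  Class weights n / (classes * count_i)
counteract answer-category imbalance, lifting recall on rare answers.

The user-facing surface is statsmodels-like: :class:`QuestionnaireCascade`
is the model specification, its :meth:`~QuestionnaireCascade.fit` returns a
:class:`CascadeResults` carrying the fitted question models, per-step
training diagnostics, a ``summary()`` table, and ``generate()`` /
``evaluate()`` methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backends import (
    STEP_DEFAULT_HYPERPARAMS,
    ConstantBackend,
    HyperParams,
    RoundedRegressorBackend,
    make_backend,
)
from .schema import CohortTable, QuestionnaireSchema, load_schema

logger = logging.getLogger(__name__)

__all__ = [
    "compute_class_weights",
    "StepSpec",
    "QuestionModel",
    "CascadeModel",
    "make_steps",
    "train_step",
    "train_cascade",
    "generate",
    "QuestionnaireCascade",
    "CascadeResults",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER = ["SF-36", "HAD", "SCL 90 R", "FIS8", "FIS40", "PSQI"]

MIN_TRAINING_RECORDS = 30


def compute_class_weights(labels) -> dict[int, float]:
    """Per-class weights w_i = n / (classes * count_i).

    ``n`` is the number of training labels, ``classes`` the number of
    distinct observed labels and ``count_i`` the support of class i; rare
    answers therefore receive proportionally larger weights (a single
    observed class gets weight 1).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    values, counts = np.unique(labels, return_counts=True)
    n = labels.size
    k = len(values)
    return {int(v): n / (k * c) for v, c in zip(values, counts)}


@dataclass(frozen=True)
class StepSpec:
    """One cascade step: inputs are SF-36 plus all previously generated
    questionnaires; the target is the next questionnaire in the order."""

    step_index: int
    input_questionnaires: tuple[str, ...]
    target_questionnaire: str
    input_dim: int
    target_dim: int
    hyperparams: HyperParams


@dataclass
class QuestionModel:
    """Fitted per-question predictor over the labels observed in training."""

    item: str
    observed_labels: np.ndarray
    class_weights: dict[int, float]
    backend: object

    def predict(self, X: np.ndarray, mode: str = "argmax", rng: np.random.Generator | None = None) -> np.ndarray:
        scores = np.asarray(self.backend.predict_scores(X), dtype=float)
        labels = np.asarray(self.backend.labels_)
        if mode == "argmax":
            return labels[scores.argmax(axis=1)]
        if mode == "sample":
            if rng is None:
                raise ValueError("sample mode requires a random generator")
            s = np.clip(scores, 0.0, None)
            rows = s.sum(axis=1)
            s[rows <= 0] = 1.0
            p = s / s.sum(axis=1, keepdims=True)
            cum = p.cumsum(axis=1)
            u = rng.random((len(p), 1))
            return labels[(u > cum[:, :-1]).sum(axis=1)] if p.shape[1] > 1 else labels[np.zeros(len(p), int)]
        raise ValueError(f"unknown prediction mode {mode!r}")


@dataclass
class CascadeModel:
    """Fitted cascade: ordered steps, each a bank of question models."""

    schema: QuestionnaireSchema
    order: list[str]
    steps: list[StepSpec]
    banks: list[list[QuestionModel]]
    provenance: dict = field(default_factory=dict)

    @property
    def n_question_models(self) -> int:
        return sum(len(b) for b in self.banks)

    @property
    def output_columns(self) -> list[str]:
        return [c for name in self.order[1:] for c in self.schema.block_columns(name)]

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a cascade model archive")
        return model


def make_steps(
    schema: QuestionnaireSchema,
    order: list[str] | None = None,
    hyperparams: list[HyperParams] | dict[int, HyperParams] | None = None,
) -> list[StepSpec]:
    """Lay out the cascade steps for a questionnaire order.

    Step k (1-based) takes order[0..k-1] concatenated as input features and
    order[k] as the target; under the default six-questionnaire battery the
    input dimensions are 36, 50, 140, 148 and 188 and the targets have 14,
    90, 8, 40 and 34 questions.
    """
    order = [schema.questionnaire(n).name for n in (order or DEFAULT_ORDER)]
    if sorted(order) != sorted(schema.names):
        raise ValueError(
            f"order {order} is not a permutation of schema questionnaires {schema.names}"
        )
    steps = []
    for k in range(1, len(order)):
        if isinstance(hyperparams, dict):
            hp = hyperparams.get(k)
        elif hyperparams is not None:
            hp = hyperparams[k - 1] if k - 1 < len(hyperparams) else None
        else:
            hp = None
        if hp is None:
            hp = (
                STEP_DEFAULT_HYPERPARAMS[k - 1]
                if k - 1 < len(STEP_DEFAULT_HYPERPARAMS)
                else HyperParams()
            )
        inputs = tuple(order[:k])
        steps.append(
            StepSpec(
                step_index=k,
                input_questionnaires=inputs,
                target_questionnaire=order[k],
                input_dim=sum(schema.questionnaire(q).n_questions for q in inputs),
                target_dim=schema.questionnaire(order[k]).n_questions,
                hyperparams=hp,
            )
        )
    return steps


def _fit_question(
    col: str,
    X: np.ndarray,
    y: np.ndarray,
    backend_kind: str,
    hp: HyperParams,
    seed: int,
    answer_min: int,
    answer_max: int,
) -> QuestionModel:
    weights = compute_class_weights(y)
    if len(weights) == 1:
        backend = ConstantBackend().fit(X, y)
        logger.warning("question %s: single observed class %s; constant predictor",
                       col, list(weights))
    elif backend_kind == "rounded":
        backend = RoundedRegressorBackend(answer_min, answer_max).fit(X, y, weights, hp, seed)
    else:
        backend = make_backend(backend_kind).fit(X, y, weights, hp, seed)
    return QuestionModel(col, np.unique(y), weights, backend)


def train_step(
    spec: StepSpec,
    features: np.ndarray,
    target_block: np.ndarray,
    target_columns: list[str],
    backend_kind: str = "linear",
    seed: int = 0,
    answer_min: int = 0,
    answer_max: int = 4,
    min_records: int = MIN_TRAINING_RECORDS,
) -> list[QuestionModel]:
    """Fit one bank of per-question models for a cascade step."""
    features = np.asarray(features, dtype=float)
    target_block = np.asarray(target_block)
    if len(features) < min_records:
        raise ValueError(
            f"step {spec.step_index} ({spec.target_questionnaire}): "
            f"{len(features)} training records < minimum {min_records}"
        )
    if features.shape[1] != spec.input_dim:
        raise ValueError(
            f"step {spec.step_index}: feature dim {features.shape[1]} != {spec.input_dim}"
        )
    bank = []
    for j, col in enumerate(target_columns):
        qm = _fit_question(
            col, features, target_block[:, j], backend_kind,
            spec.hyperparams, seed + j, answer_min, answer_max,
        )
        bank.append(qm)
    logger.info("step %d (%s): trained %d question models on %d records",
                spec.step_index, spec.target_questionnaire, len(bank), len(features))
    return bank


def _predict_block(
    bank: list[QuestionModel], X: np.ndarray, mode: str, rng: np.random.Generator | None
) -> np.ndarray:
    return np.column_stack([qm.predict(X, mode=mode, rng=rng) for qm in bank])


def train_cascade(
    cohort: CohortTable,
    schema: QuestionnaireSchema | None = None,
    order: list[str] | None = None,
    backend_kind: str = "linear",
    hyperparams=None,
    seed: int = 0,
    teacher_forcing: bool = False,
    min_records: int = MIN_TRAINING_RECORDS,
) -> CascadeModel:
    """Train the full cascade on a cohort.

    Each step trains on the records whose real input blocks and real target
    block are all present (complete-case per step, so the usable record count
    shrinks down the cascade).  Features for steps past the first are the
    synthetic outputs of the previous steps, regenerated for the step's
    training records - unless ``teacher_forcing`` substitutes the real prior
    blocks for ablation.
    """
    schema = schema or cohort.schema
    steps = make_steps(schema, order, hyperparams)
    order = [steps[0].input_questionnaires[0]] + [s.target_questionnaire for s in steps]
    input_q = order[0]

    banks: list[list[QuestionModel]] = []
    step_records: list[int] = []
    # synthetic prior blocks for every record whose input questionnaire is present
    base_records = cohort.records_with([input_q])
    base_X = cohort.values.loc[base_records, schema.block_columns(input_q)].to_numpy(float)
    synth_prior: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)

    for spec in steps:
        target_q = schema.questionnaire(spec.target_questionnaire)
        needed = list(spec.input_questionnaires) + [target_q.name]
        train_ids = cohort.records_with(needed)
        feats = [cohort.values.loc[train_ids, schema.block_columns(input_q)].to_numpy(float)]
        for prior in spec.input_questionnaires[1:]:
            if teacher_forcing:
                feats.append(cohort.values.loc[train_ids, schema.block_columns(prior)].to_numpy(float))
            else:
                feats.append(synth_prior[prior].loc[train_ids].to_numpy(float))
        X = np.hstack(feats)
        y_block = cohort.values.loc[train_ids, target_q.columns].to_numpy(float).astype(int)
        bank = train_step(
            spec, X, y_block, target_q.columns, backend_kind,
            seed=seed + 1000 * spec.step_index,
            answer_min=target_q.answer_min, answer_max=target_q.answer_max,
            min_records=min_records,
        )
        banks.append(bank)
        step_records.append(len(train_ids))
        # feed forward: synthesize this questionnaire for every record with
        # the input questionnaire present
        gen_feats = [base_X] + [synth_prior[p].to_numpy(float) for p in spec.input_questionnaires[1:]]
        block = _predict_block(bank, np.hstack(gen_feats), mode="argmax", rng=None)
        synth_prior[target_q.name] = pd.DataFrame(block, index=base_records, columns=target_q.columns)

    model = CascadeModel(
        schema=schema,
        order=order,
        steps=steps,
        banks=banks,
        provenance={
            "seed": seed,
            "backend": backend_kind,
            "teacher_forcing": teacher_forcing,
            "schema_digest": schema.digest(),
            "step_training_records": step_records,
        },
    )
    logger.info("cascade trained: %d steps, %d question models, per-step records %s",
                len(steps), model.n_question_models, step_records)
    return model


def generate(
    model: CascadeModel,
    sf36: np.ndarray | pd.DataFrame,
    mode: str = "argmax",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the five remaining questionnaire blocks from input answers.

    ``sf36`` is a records x n_questions matrix of the cascade's input
    questionnaire (values within its answer rank, complete rows).  The output
    concatenates the generated blocks in cascade order (186 columns for the
    default battery).  ``argmax`` is deterministic; ``sample`` draws each
    answer from the backend's class scores using ``seed``.
    """
    input_q = model.schema.questionnaire(model.order[0])
    if isinstance(sf36, pd.DataFrame):
        index = sf36.index
        X0 = sf36.to_numpy(dtype=float)
    else:
        X0 = np.asarray(sf36, dtype=float)
        index = pd.RangeIndex(len(X0))
    if X0.ndim != 2 or X0.shape[1] != input_q.n_questions:
        raise ValueError(
            f"input must be records x {input_q.n_questions} ({input_q.name}); got {X0.shape}"
        )
    if np.isnan(X0).any():
        raise ValueError("input rows must be complete (no missing answers)")
    if (X0 < input_q.answer_min).any() or (X0 > input_q.answer_max).any():
        raise ValueError(
            f"input values outside {input_q.name} answer rank "
            f"{{{input_q.answer_min}..{input_q.answer_max}}}"
        )
    rng = np.random.default_rng(seed) if mode == "sample" else None
    feats = [X0]
    blocks = []
    for spec, bank in zip(model.steps, model.banks):
        if len(bank) != model.schema.questionnaire(spec.target_questionnaire).n_questions:
            raise ValueError("model/schema mismatch: bank size differs from question count")
        block = _predict_block(bank, np.hstack(feats), mode=mode, rng=rng)
        blocks.append(block)
        feats.append(block.astype(float))
    cols = model.output_columns
    return pd.DataFrame(np.hstack(blocks), index=index, columns=cols)


class QuestionnaireCascade:
    """Model specification for the battery-generation cascade.

    Parameters
    ----------
    cohort : CohortTable
        Validated cohort with the blocks needed to train every step.
    schema : QuestionnaireSchema, optional
        Defaults to the cohort's schema.
    order : list of str, optional
        Questionnaire order; defaults to the battery order derived from the
        subscale correlation graph of this cohort (computed on demand) or the
        canonical order if graph derivation is disabled.
    backend : str
        Question-model backend: linear (default) | mlp | xgb | rounded.
    """

    def __init__(
        self,
        cohort: CohortTable,
        schema: QuestionnaireSchema | None = None,
        order: list[str] | None = None,
        backend: str = "linear",
        hyperparams=None,
        teacher_forcing: bool = False,
        min_records: int = MIN_TRAINING_RECORDS,
    ):
        self.cohort = cohort
        self.schema = schema or cohort.schema
        self.order = order
        self.backend = backend
        self.hyperparams = hyperparams
        self.teacher_forcing = teacher_forcing
        self.min_records = min_records

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: QuestionnaireSchema | None = None, policy: str = "reject", **kwargs
    ) -> "QuestionnaireCascade":
        from .schema import validate_cohort

        schema = schema or load_schema()
        return cls(validate_cohort(frame, schema, policy=policy), schema, **kwargs)

    def derive_order(self, tau: float = 0.5, start: str = "SF-36") -> list[str]:
        """Derive the cascade order from this cohort's subscale graph."""
        from .graph import build_graph, cascade_order, pearson_matrix
        from .schema import score_subscales

        corr = pearson_matrix(score_subscales(self.cohort, self.schema))
        return cascade_order(build_graph(corr, self.schema, tau), start=start)

    def fit(self, seed: int = 0) -> "CascadeResults":
        order = self.order or DEFAULT_ORDER
        model = train_cascade(
            self.cohort,
            self.schema,
            order=order,
            backend_kind=self.backend,
            hyperparams=self.hyperparams,
            seed=seed,
            teacher_forcing=self.teacher_forcing,
            min_records=self.min_records,
        )
        return CascadeResults(self, model)


class CascadeResults:
    """Fitted cascade with diagnostics, generation and evaluation."""

    def __init__(self, spec: QuestionnaireCascade, model: CascadeModel):
        self.model_spec = spec
        self.model = model

    def generate(self, sf36, mode: str = "argmax", seed: int = 0) -> pd.DataFrame:
        return generate(self.model, sf36, mode=mode, seed=seed)

    def evaluate(self, cohort: CohortTable | None = None, mode: str = "argmax", seed: int = 0):
        from .metrics import evaluate_cascade

        return evaluate_cascade(self.model, cohort or self.model_spec.cohort, mode=mode, seed=seed)

    def summary(self) -> str:
        lines = [
            "Questionnaire generation cascade",
            "================================",
            f"order:    {' -> '.join(self.model.order)}",
            f"backend:  {self.model.provenance['backend']}"
            f"   seed: {self.model.provenance['seed']}"
            f"   schema: {self.model.provenance['schema_digest']}",
            f"question models: {self.model.n_question_models}",
            "",
            f"{'step':>4} {'target':<10} {'input dim':>9} {'target dim':>10} {'records':>8}",
        ]
        for spec, n in zip(self.model.steps, self.model.provenance["step_training_records"]):
            lines.append(
                f"{spec.step_index:>4} {spec.target_questionnaire:<10} "
                f"{spec.input_dim:>9} {spec.target_dim:>10} {n:>8}"
            )
        return "\n".join(lines)
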