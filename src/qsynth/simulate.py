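"""Seeded synthetic-cohort generator with planted subject-level correlation.

Stands in for the hospital registry: each record draws a latent trait vector
over the subscale subject areas (Physic, Anxiety, Sleep quality, ...) from a
correlated Gaussian; each ordinal item loads on its subject's trait and is
discretised by equal-probability thresholds; questionnaire blocks are then
dropped record-wise to emulate per-instrument register counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable, QuestionnaireSchema, load_schema

logger = logging.getLogger(__name__)

__all__ = ["SyntheticCohortSpec", "generate_cohort", "default_registry_spec"]

# Relative register retention per questionnaire, proportional to the
# registry's available-forms counts (2346/2339/2361/2057/2362/1959 of 2522
# enrolled patients): PSQI is the scarcest block, FIS8 next.
DEFAULT_RETENTION = {
    "SF-36": 0.930,
    "HAD": 0.927,
    "SCL 90 R": 0.936,
    "FIS8": 0.816,
    "FIS40": 0.937,
    "PSQI": 0.777,
}


@dataclass
class SyntheticCohortSpec:
    """Parameters of the planted generative model.

    ``subject_corr`` (with row/column order ``subjects``) correlates the
    latent traits; ``item_loading`` is the default loading lambda of an item
    on its subject trait, overridable per questionnaire via ``loadings``;
    ``item_subject_map`` overrides the default item -> subject assignment
    (subject of the first subscale containing the item); ``item_probs``
    optionally skews an item's marginal away from uniform; ``retention`` is
    the per-questionnaire probability that a record's block is observed.
    """

    n_records: int = 2000
    seed: int = 0
    subjects: list[str] = field(default_factory=list)
    subject_corr: np.ndarray | None = None
    item_loading: float = 0.8
    loadings: dict[str, float] = field(default_factory=dict)
    item_subject_map: dict[str, str] = field(default_factory=dict)
    item_probs: dict[str, list[float]] = field(default_factory=dict)
    retention: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RETENTION))

    def loading_for(self, schema: QuestionnaireSchema, questionnaire: str) -> float:
        q = schema.questionnaire(questionnaire)
        for key, lam in self.loadings.items():
            if schema.questionnaire(key).name == q.name:
                return float(lam)
        return float(self.item_loading)


def _validate_corr(corr: np.ndarray, subjects: list[str]) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    k = len(subjects)
    if corr.shape != (k, k):
        raise ValueError(f"subject_corr must be {k}x{k} for subjects {subjects}")
    if not np.allclose(corr, corr.T):
        raise ValueError("subject_corr is not symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("subject_corr must have unit diagonal")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            f"subject_corr is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )
    return corr


def generate_cohort(spec: SyntheticCohortSpec, schema: QuestionnaireSchema | None = None) -> CohortTable:
    """Draw a cohort from the planted latent-trait model.

    For record r with latent subject vector z_r ~ N(0, subject_corr), item i
    with loading lambda has latent u = lambda * z_subject(i) + sqrt(1 -
    lambda^2) * eps, discretised into its answer rank by equal-probability
    normal quantiles (or the item's ``item_probs`` quantiles).  Whole
    questionnaire blocks are masked with probability 1 - retention.
    Bitwise reproducible from ``spec.seed``.
    """
    schema = schema or load_schema()
    subjects = spec.subjects or schema.subjects
    if spec.subject_corr is None:
        corr = np.eye(len(subjects))
    else:
        corr = _validate_corr(spec.subject_corr, subjects)
    subj_index = {s: i for i, s in enumerate(subjects)}
    item_subjects = schema.item_subjects()
    item_subjects.update(spec.item_subject_map)

    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(subjects)))
    z = rng.standard_normal((spec.n_records, len(subjects))) @ chol.T

    values = pd.DataFrame(
        np.nan, index=range(spec.n_records), columns=schema.columns
    )
    for q in schema.questionnaires:
        lam = spec.loading_for(schema, q.name)
        noise = rng.standard_normal((spec.n_records, q.n_questions))
        for j, col in enumerate(q.columns):
            subj = item_subjects[col]
            if subj not in subj_index:
                raise ValueError(f"item {col}: unknown subject {subj!r}")
            u = lam * z[:, subj_index[subj]] + np.sqrt(1.0 - lam * lam) * noise[:, j]
            k = q.answer_max - q.answer_min + 1
            if col in spec.item_probs:
                p = np.asarray(spec.item_probs[col], dtype=float)
                if len(p) != k or not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"item {col}: item_probs must be {k} values summing to 1")
                cuts = stats.norm.ppf(np.cumsum(p)[:-1])
            else:
                cuts = stats.norm.ppf(np.arange(1, k) / k)
            values[col] = q.answer_min + np.searchsorted(cuts, u)

    block_present = pd.DataFrame(index=values.index, columns=schema.names, dtype=bool)
    for q in schema.questionnaires:
        keep = spec.retention.get(q.name, 1.0)
        if not 0.0 < keep <= 1.0:
            raise ValueError(f"retention for {q.name} must be in (0, 1], got {keep}")
        present = rng.random(spec.n_records) < keep
        block_present[q.name] = present
        values.loc[~present, q.columns] = np.nan
    logger.info("synthetic cohort: %d records, blocks present %s",
                spec.n_records, block_present.sum().to_dict())
    return CohortTable(schema, values, block_present)


def default_registry_spec(n_records: int = 2000, seed: int = 0) -> SyntheticCohortSpec:
    """Planted structure emulating the registry's qualitative correlation
    pattern: the SF-36 core subjects, Mental/Emotional, and Anxiety/Depression
    are strongly inter-correlated; Cognitive couples weakly everywhere; Sleep
    quality is near-isolated, so the sleep questionnaire ends the cascade.

    One SCL-90-R subscale block (the discomfort-index items) is tied to the
    Depression trait with a reduced SCL-90-R loading, so that the anxiety/
    depression instrument - not the quality-of-life instrument - is what
    completes SCL-90-R's graph coverage, as observed on the registry.
    """
    schema = load_schema()
    subjects = schema.subjects  # 11 areas, Table-2 order of first appearance
    idx = {s: i for i, s in enumerate(subjects)}
    core = ["Physic", "Pain", "General health", "Vitality", "Social", "Emotional", "Mental"]
    R = np.eye(len(subjects))
    for a in core:
        for b in core:
            if a != b:
                R[idx[a], idx[b]] = 0.75
    for s in ("Anxiety", "Depression"):
        for t in core:
            R[idx[s], idx[t]] = R[idx[t], idx[s]] = 0.55
        R[idx[s], idx["Emotional"]] = R[idx["Emotional"], idx[s]] = 0.65
    R[idx["Mental"], idx["Anxiety"]] = R[idx["Anxiety"], idx["Mental"]] = 0.75
    R[idx["Mental"], idx["Depression"]] = R[idx["Depression"], idx["Mental"]] = 0.70
    R[idx["Anxiety"], idx["Depression"]] = R[idx["Depression"], idx["Anxiety"]] = 0.85
    for t in subjects:
        if t not in ("Cognitive", "Sleep quality"):
            R[idx["Cognitive"], idx[t]] = R[idx[t], idx["Cognitive"]] = 0.30
            R[idx["Sleep quality"], idx[t]] = R[idx[t], idx["Sleep quality"]] = 0.15
    R[idx["Cognitive"], idx["Sleep quality"]] = R[idx["Sleep quality"], idx["Cognitive"]] = 0.10

    psdi_items = {f"scl90r_q{i}": "Depression" for i in range(84, 91)}
    return SyntheticCohortSpec(
        n_records=n_records,
        seed=seed,
        subjects=subjects,
        subject_corr=R,
        item_loading=0.8,
        loadings={"SF-36": 0.8, "HAD": 0.95, "SCL 90 R": 0.34, "FIS8": 0.9, "FIS40": 0.85, "PSQI": 0.8},
        item_subject_map=psdi_items,
    )
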