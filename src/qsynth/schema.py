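"""Questionnaire battery structure: instruments, items, subscales, cohort tables.

The battery covers six patient-reported-outcome instruments used in ME/CFS
units: SF-36 (quality of life), HAD (anxiety/depression), SCL-90-R
(psychological symptom inventory), FIS8 and FIS40 (fatigue impact), and PSQI
(sleep quality).  Each instrument is a block of ordinal items; named
subscales aggregate subsets of items into scores, and each subscale carries a
thematic "subject" label (Physic, Anxiety, Sleep quality, ...).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Item",
    "Subscale",
    "Questionnaire",
    "QuestionnaireSchema",
    "CohortTable",
    "SchemaError",
    "CohortValidationError",
    "load_schema",
    "validate_cohort",
    "score_subscales",
]


class SchemaError(ValueError):
    """Raised when a schema file is malformed or self-inconsistent."""


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema under the active policy."""


@dataclass(frozen=True)
class Item:
    """One ordinal question: 1-based position within its questionnaire."""

    questionnaire: str
    index: int
    answer_min: int
    answer_max: int

    @property
    def answer_rank(self) -> range:
        return range(self.answer_min, self.answer_max + 1)

    @property
    def n_categories(self) -> int:
        return self.answer_max - self.answer_min + 1


@dataclass(frozen=True)
class Subscale:
    """A named subset of items aggregated (by default summed) into one score."""

    name: str
    questionnaire: str
    members: tuple[int, ...]
    subject: str
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaError(f"subscale {self.name!r} has no member items")
        if self.aggregation != "sum":
            raise SchemaError(
                f"subscale {self.name!r}: unsupported aggregation {self.aggregation!r}"
            )


@dataclass(frozen=True)
class Questionnaire:
    name: str
    short: str
    n_questions: int
    answer_min: int
    answer_max: int
    has_total: bool
    subscales: tuple[Subscale, ...]

    def __post_init__(self) -> None:
        for sub in self.subscales:
            bad = [i for i in sub.members if not 1 <= i <= self.n_questions]
            if bad:
                raise SchemaError(
                    f"subscale {sub.name!r} of {self.name!r}: member indices "
                    f"{bad} outside 1..{self.n_questions}"
                )

    @property
    def items(self) -> tuple[Item, ...]:
        return tuple(
            Item(self.name, i, self.answer_min, self.answer_max)
            for i in range(1, self.n_questions + 1)
        )

    @property
    def columns(self) -> list[str]:
        return [f"{self.short}_q{i}" for i in range(1, self.n_questions + 1)]


# short column-prefix aliases accepted everywhere a questionnaire name is taken
_SHORT = {
    "SF-36": "sf36",
    "HAD": "had",
    "SCL 90 R": "scl90r",
    "FIS8": "fis8",
    "FIS40": "fis40",
    "PSQI": "psqi",
}


class QuestionnaireSchema:
    """Ordered collection of questionnaires; the column layout of a cohort."""

    def __init__(self, questionnaires: Sequence[Questionnaire]):
        if not questionnaires:
            raise SchemaError("schema defines no questionnaires")
        names = [q.name for q in questionnaires]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate questionnaire names")
        self.questionnaires: tuple[Questionnaire, ...] = tuple(questionnaires)
        self._by_name: dict[str, Questionnaire] = {}
        for q in self.questionnaires:
            self._by_name[q.name.lower()] = q
            self._by_name[q.short.lower()] = q

    def __iter__(self):
        return iter(self.questionnaires)

    @property
    def names(self) -> list[str]:
        return [q.name for q in self.questionnaires]

    def questionnaire(self, name: str) -> Questionnaire:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise SchemaError(f"unknown questionnaire {name!r}") from None

    @property
    def n_items(self) -> int:
        return sum(q.n_questions for q in self.questionnaires)

    @property
    def subscales(self) -> list[Subscale]:
        return [s for q in self.questionnaires for s in q.subscales]

    @property
    def n_subscales(self) -> int:
        return len(self.subscales)

    @property
    def columns(self) -> list[str]:
        return [c for q in self.questionnaires for c in q.columns]

    def block_columns(self, name: str) -> list[str]:
        return self.questionnaire(name).columns

    def item_subjects(self) -> dict[str, str]:
        """Default item -> subject map: subject of the first subscale
        containing the item; items in no subscale inherit the questionnaire's
        first subscale's subject."""
        out: dict[str, str] = {}
        for q in self.questionnaires:
            fallback = q.subscales[0].subject if q.subscales else "Physic"
            for i in range(1, q.n_questions + 1):
                subj = fallback
                for sub in q.subscales:
                    if i in sub.members:
                        subj = sub.subject
                        break
                out[f"{q.short}_q{i}"] = subj
        return out

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for s in self.subscales:
            if s.subject not in seen:
                seen.append(s.subject)
        return seen

    def digest(self) -> str:
        import hashlib

        payload = json.dumps(
            [
                [
                    q.name,
                    q.n_questions,
                    q.answer_min,
                    q.answer_max,
                    q.has_total,
                    [[s.name, s.subject, list(s.members)] for s in q.subscales],
                ]
                for q in self.questionnaires
            ],
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _contig(start: int, n: int) -> tuple[int, ...]:
    return tuple(range(start, start + n))


def _default_schema() -> QuestionnaireSchema:
    """The bundled six-instrument battery.

    Question counts, answer ranks, total-score flags and subscale/subject
    labels follow the published battery description.  Item membership of each
    subscale is not published for this battery; contiguous item blocks with
    the standard instrument block sizes are used (component scores and totals
    aggregate the corresponding unions), which preserves the subscale counts
    and subject structure.
    """
    sf36 = Questionnaire(
        "SF-36", "sf36", 36, 1, 6, False,
        (
            Subscale("Physic function (PF)", "SF-36", _contig(1, 10), "Physic"),
            Subscale("Rol physic (RP)", "SF-36", _contig(11, 4), "Physic"),
            Subscale("Body pain (BP)", "SF-36", _contig(15, 2), "Pain"),
            Subscale("General health (GH)", "SF-36", _contig(17, 5), "General health"),
            Subscale("Vitality (VT)", "SF-36", _contig(22, 4), "Vitality"),
            Subscale("Social function (SF)", "SF-36", _contig(26, 2), "Social"),
            Subscale("Rol emotional (RE)", "SF-36", _contig(28, 3), "Emotional"),
            Subscale("Mental health (MH)", "SF-36", _contig(31, 5), "Mental"),
            Subscale("Physical component score (PCS)", "SF-36", _contig(1, 21), "Physic"),
            Subscale("Mental component score (MCS)", "SF-36", _contig(22, 14), "Mental"),
        ),
    )
    had = Questionnaire(
        "HAD", "had", 14, 0, 3, True,
        (
            Subscale("Total anxiety", "HAD", _contig(1, 7), "Anxiety"),
            Subscale("Total depression", "HAD", _contig(8, 7), "Depression"),
            Subscale("Total HAD", "HAD", _contig(1, 14), "Depression"),
        ),
    )
    scl90r = Questionnaire(
        "SCL 90 R", "scl90r", 90, 0, 4, False,
        (
            Subscale("Somatizations (SOM)", "SCL 90 R", _contig(1, 12), "Mental"),
            Subscale("Obsessions (OBS)", "SCL 90 R", _contig(13, 10), "Mental"),
            Subscale("Interpersonal sensitivity (SI)", "SCL 90 R", _contig(23, 9), "Mental"),
            Subscale("Depression (DEP)", "SCL 90 R", _contig(32, 13), "Depression"),
            Subscale("Anxiety (ANS)", "SCL 90 R", _contig(45, 10), "Anxiety"),
            Subscale("Hostility (HOS)", "SCL 90 R", _contig(55, 6), "Anxiety"),
            Subscale("Phobic anxiety (FOB)", "SCL 90 R", _contig(61, 7), "Anxiety"),
            Subscale("Paranoid (PAR)", "SCL 90 R", _contig(68, 6), "Mental"),
            Subscale("Psychoticism (SIC)", "SCL 90 R", _contig(74, 10), "Mental"),
            Subscale("Severity global index (GSI)", "SCL 90 R", _contig(1, 90), "Mental"),
            Subscale("Positive symptoms (PST)", "SCL 90 R", _contig(1, 90), "Mental"),
            Subscale("Symptomatic discomfort Index (PSDI)", "SCL 90 R", _contig(84, 7), "Mental"),
        ),
    )
    fis8 = Questionnaire(
        "FIS8", "fis8", 8, 0, 4, True,
        (Subscale("FIS8", "FIS8", _contig(1, 8), "Physic"),),
    )
    fis40 = Questionnaire(
        "FIS40", "fis40", 40, 0, 4, True,
        (
            Subscale("Physic dim", "FIS40", _contig(1, 10), "Physic"),
            Subscale("Cognitive dim", "FIS40", _contig(11, 10), "Cognitive"),
            Subscale("Social dim", "FIS40", _contig(21, 20), "Social"),
            Subscale("Total FIS40", "FIS40", _contig(1, 40), "Physic"),
        ),
    )
    psqi = Questionnaire(
        "PSQI", "psqi", 34, 0, 3, True,
        tuple(
            Subscale(f"Component {k}", "PSQI", _contig(1 + 5 * (k - 1), 5 if k < 7 else 4), "Sleep quality")
            for k in range(1, 8)
        )
        + (Subscale("Total PSQI", "PSQI", _contig(1, 34), "Sleep quality"),),
    )
    return QuestionnaireSchema([sf36, had, scl90r, fis8, fis40, psqi])


def load_schema(path: str | Path = "bundled-default") -> QuestionnaireSchema:
    """Load a questionnaire schema from a JSON/YAML file, or the bundled default.

    The file format is a mapping with key ``questionnaires``: a list of
    ``{name, short?, questions, answer_min, answer_max, has_total,
    subscales: [{name, subject, items}]}``.
    """
    if path == "bundled-default":
        return _default_schema()
    p = Path(path)
    text = p.read_text()
    try:
        import yaml

        data = yaml.safe_load(text)
    except ImportError:  # pragma: no cover
        data = json.loads(text)
    if not isinstance(data, Mapping) or "questionnaires" not in data:
        raise SchemaError(f"{p}: expected a mapping with a 'questionnaires' key")
    qs = []
    for entry in data["questionnaires"]:
        try:
            name = entry["name"]
            subs = tuple(
                Subscale(
                    s["name"], name, tuple(int(i) for i in s["items"]),
                    s["subject"], s.get("aggregation", "sum"),
                )
                for s in entry.get("subscales", [])
            )
            qs.append(
                Questionnaire(
                    name,
                    entry.get("short", name.lower().replace(" ", "").replace("-", "")),
                    int(entry["questions"]),
                    int(entry["answer_min"]),
                    int(entry["answer_max"]),
                    bool(entry.get("has_total", False)),
                    subs,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{p}: malformed questionnaire entry {entry!r}: {exc}") from exc
    return QuestionnaireSchema(qs)


@dataclass
class CohortTable:
    """Validated records x items table with block-level missingness.

    ``values`` holds one column per item in schema order (float, NaN where a
    questionnaire block is missing for a record); ``block_present`` is a
    records x questionnaires boolean frame.  A block is either fully present
    or fully absent for a record.
    """

    schema: QuestionnaireSchema
    values: pd.DataFrame
    block_present: pd.DataFrame
    record_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_ids:
            self.record_ids = list(self.values.index)

    @property
    def n_records(self) -> int:
        return len(self.values)

    def block(self, name: str, records: Sequence | None = None) -> np.ndarray:
        """Integer matrix for one questionnaire block (present records only
        unless ``records`` is given)."""
        q = self.schema.questionnaire(name)
        if records is None:
            present = self.block_present[q.name]
            sub = self.values.loc[present, q.columns]
        else:
            sub = self.values.loc[records, q.columns]
        return sub.to_numpy(dtype=float).astype(int)

    def records_with(self, names: Iterable[str]) -> pd.Index:
        """Index of records whose blocks for all ``names`` are present."""
        mask = pd.Series(True, index=self.values.index)
        for name in names:
            q = self.schema.questionnaire(name)
            mask &= self.block_present[q.name]
        return self.values.index[mask]

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "record_id", self.record_ids)
        # keep integers readable: empty cell = missing block
        out.to_csv(path, index=False, float_format="%.0f")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        schema: QuestionnaireSchema | None = None,
        policy: str = "reject",
    ) -> "CohortTable":
        schema = schema or _default_schema()
        raw = pd.read_csv(path)
        return validate_cohort(raw, schema, policy=policy)


def validate_cohort(
    table: pd.DataFrame | str | Path,
    schema: QuestionnaireSchema,
    policy: str = "reject",
) -> CohortTable:
    """Validate a raw cohort table against the schema.

    Columns must be named ``<short>_q<index>`` (an optional ``record_id``
    column is used as the index).  Every present value must lie in its item's
    answer rank.  A record's questionnaire block must be complete or entirely
    empty; under ``policy="reject"`` a partial block is an error, under
    ``policy="drop-partial"`` the partial block is blanked out.
    """
    if policy not in ("reject", "drop-partial"):
        raise ValueError(f"unknown policy {policy!r}")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    table = table.copy()
    if "record_id" in table.columns:
        record_ids = table["record_id"].tolist()
        table = table.drop(columns=["record_id"])
    else:
        record_ids = list(range(len(table)))
    known = set(schema.columns)
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise CohortValidationError(f"unknown columns: {unknown}")
    # absent columns count as missing
    values = pd.DataFrame(np.nan, index=range(len(table)), columns=schema.columns)
    for c in table.columns:
        values[c] = pd.to_numeric(table[c], errors="coerce").to_numpy()

    block_present = pd.DataFrame(index=values.index, columns=schema.names, dtype=bool)
    dropped: dict[str, int] = {}
    for q in schema.questionnaires:
        blk = values[q.columns]
        n_present = blk.notna().sum(axis=1)
        complete = n_present == q.n_questions
        partial = (n_present > 0) & ~complete
        if partial.any():
            rows = list(values.index[partial][:5])
            if policy == "reject":
                raise CohortValidationError(
                    f"partial {q.name} block for records {rows} "
                    f"(policy='reject'; use 'drop-partial' to blank them)"
                )
            values.loc[partial, q.columns] = np.nan
            dropped[q.name] = int(partial.sum())
            complete = values[q.columns].notna().sum(axis=1) == q.n_questions
        sub = values.loc[complete, q.columns]
        bad = (sub < q.answer_min) | (sub > q.answer_max) | (sub != np.floor(sub))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            row = sub.index[r]
            col = q.columns[c]
            raise CohortValidationError(
                f"value {sub.iloc[r, c]!r} at record {record_ids[row]}, column "
                f"{col} outside answer rank "
                f"{{{q.answer_min}..{q.answer_max}}} of {q.name}"
            )
        block_present[q.name] = complete.to_numpy()
    kept = {q.name: int(block_present[q.name].sum()) for q in schema.questionnaires}
    logger.info("cohort validated: %d records; blocks kept %s; partial blocks dropped %s",
                len(values), kept, dropped or "none")
    return CohortTable(schema, values, block_present, record_ids)


def score_subscales(cohort: CohortTable, schema: QuestionnaireSchema | None = None) -> pd.DataFrame:
    """Records x subscales score matrix (sum aggregation; NaN where the
    subscale's questionnaire block is missing)."""
    schema = schema or cohort.schema
    out = {}
    for q in schema.questionnaires:
        present = cohort.block_present[q.name].to_numpy()
        for sub in q.subscales:
            cols = [f"{q.short}_q{i}" for i in sub.members]
            score = cohort.values[cols].sum(axis=1).to_numpy(dtype=float)
            score[~present] = np.nan
            out[sub.name] = score
    return pd.DataFrame(out, index=cohort.values.index)
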