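"""Data model and I/O for the instrument, responses, and screener-derived outcomes.

The instrument is a bank of Likert items (0--4), each tagged with one of five
syndrome criteria and an optional reverse-coding flag.  Outcomes are binary
labels derived from a nine-item yes/no screener: the first five screener items
define the broad ideation outcome (any "yes"), item six defines the
ideation-with-preparation outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Criterion tokens, in canonical order.
CRITERIA = ("A", "B1", "B2", "B3", "B4")

#: Human-readable criterion names.
CRITERION_NAMES = {
    "A": "entrapment",
    "B1": "affective_disturbance",
    "B2": "loss_of_cognitive_control",
    "B3": "hyperarousal",
    "B4": "social_withdrawal",
}

#: Likert response bounds (inclusive).
LIKERT_MIN, LIKERT_MAX = 0, 4

#: Number of screener items; the first five define the broad outcome.
N_SCREENER_ITEMS = 9


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item."""

    item_id: str
    text: str
    criterion: str
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be nonempty")
        if self.criterion not in CRITERIA:
            raise ValidationError(
                f"unknown criterion {self.criterion!r} for item {self.item_id!r}; "
                f"expected one of {CRITERIA}"
            )


@dataclass
class ItemBank:
    """Ordered collection of items; ids are opaque tokens, never indices."""

    items: list[ItemDefinition]
    version: str = "1"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate item ids in bank: {sorted(dupes)}")
        self._index = {it.item_id: k for k, it in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> ItemDefinition:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"item {item_id!r} not in bank") from None

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def position(self, item_id: str) -> int:
        """Stable bank position, used as the universal tie-break order."""
        return self._index[item_id]

    def criterion_of(self, item_id: str) -> str:
        return self[item_id].criterion

    @property
    def criteria_present(self) -> set[str]:
        return {it.criterion for it in self.items}

    @property
    def criterion_coverage_complete(self) -> bool:
        """True when every one of the five criteria has at least one item."""
        return self.criteria_present == set(CRITERIA)

    def subset(self, item_ids: list[str]) -> "ItemBank":
        return ItemBank(items=[self[i] for i in item_ids], version=self.version)

    def items_of_criterion(self, criterion: str) -> list[ItemDefinition]:
        return [it for it in self.items if it.criterion == criterion]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "text": [it.text for it in self.items],
                "criterion": [it.criterion for it in self.items],
                "reverse_coded": [it.reverse_coded for it in self.items],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ResponseMatrix:
    """n x p integer Likert response matrix with aligned id vectors."""

    respondent_ids: list
    item_ids: list[str]
    values: np.ndarray
    reverse_coding_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.respondent_ids) != n:
            raise ValidationError("respondent_ids length mismatch with rows")
        if len(self.item_ids) != p:
            raise ValidationError("item_ids length mismatch with columns")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("responses must be integers")
        if self.values.size and (
            self.values.min() < LIKERT_MIN or self.values.max() > LIKERT_MAX
        ):
            raise ValidationError(
                f"responses must lie in {LIKERT_MIN}..{LIKERT_MAX}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CssrsResponses:
    """n x 9 binary screener matrix."""

    respondent_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_SCREENER_ITEMS:
            raise ValidationError(
                f"screener matrix must have {N_SCREENER_ITEMS} columns"
            )
        if len(self.respondent_ids) != self.values.shape[0]:
            raise ValidationError("respondent_ids length mismatch with rows")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValidationError("screener entries must be 0 or 1")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            columns=[f"item_{k}" for k in range(1, N_SCREENER_ITEMS + 1)],
        )
        df.insert(0, "respondent_id", self.respondent_ids)
        df.to_csv(path, index=False)


@dataclass
class OutcomeLabels:
    """Binary outcome vectors with their realized prevalences."""

    si: np.ndarray
    si_p: np.ndarray
    prevalence_si: float = field(init=False)
    prevalence_si_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.si = np.asarray(self.si).astype(np.int64)
        self.si_p = np.asarray(self.si_p).astype(np.int64)
        for name, v in (("si", self.si), ("si_p", self.si_p)):
            if v.ndim != 1:
                raise ValidationError(f"{name} must be a vector")
            if v.size and not np.isin(v, (0, 1)).all():
                raise ValidationError(f"{name} entries must be 0 or 1")
        if self.si.shape != self.si_p.shape:
            raise ValidationError("outcome vectors must have equal length")
        if self.si.size == 0:
            raise ValidationError("outcomes require at least one respondent")
        self.prevalence_si = float(self.si.mean())
        self.prevalence_si_p = float(self.si_p.mean())

    @classmethod
    def from_counts(cls, si_pos: int, si_neg: int,
                    si_p_pos: int = 0, si_p_neg: int = 0) -> "OutcomeLabels":
        """Build a labels fixture directly from case/control counts.

        The two outcomes are laid out independently; when the ideation-with-
        preparation counts are omitted the vector is all zeros of matching
        length.
        """
        n = si_pos + si_neg
        si = np.r_[np.ones(si_pos, dtype=int), np.zeros(si_neg, dtype=int)]
        if si_p_pos + si_p_neg == 0:
            si_p = np.zeros(n, dtype=int)
        else:
            if si_p_pos + si_p_neg != n:
                raise ValidationError("outcome count totals differ")
            si_p = np.r_[np.ones(si_p_pos, dtype=int),
                         np.zeros(si_p_neg, dtype=int)]
        return cls(si=si, si_p=si_p)

    def vector(self, outcome: str) -> np.ndarray:
        if outcome == "SI":
            return self.si
        if outcome == "SI_P":
            return self.si_p
        raise ValidationError(f"unknown outcome {outcome!r}; expected SI or SI_P")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BANK_COLUMNS = ("item_id", "text", "criterion", "reverse_coded")


def load_item_bank(path, version: str = "1") -> ItemBank:
    """Read an item bank from CSV/TSV, preserving file order.

    Warns (without failing) when the bank does not cover all five criteria,
    so degenerate fixtures remain loadable but flagged.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _BANK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"item bank file missing columns: {missing}")
    items = [
        ItemDefinition(
            item_id=row.item_id,
            text=row.text,
            criterion=row.criterion,
            reverse_coded=str(row.reverse_coded).strip().lower()
            in ("1", "true", "yes"),
        )
        for row in df.itertuples()
    ]
    bank = ItemBank(items=items, version=version)
    if not bank.criterion_coverage_complete:
        absent = sorted(set(CRITERIA) - bank.criteria_present)
        warnings.warn(
            f"item bank does not cover criteria {absent}", stacklevel=2
        )
    return bank


def load_response_matrix(path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a response CSV (first column respondent id, rest item columns).

    Rows with any missing entry are dropped (complete-case), with the count
    logged.  Column ids must be a subset of the bank's when a bank is given.
    """
    df = pd.read_csv(path)
    id_col = df.columns[0]
    item_ids = list(df.columns[1:])
    if bank is not None:
        unknown = [i for i in item_ids if i not in bank]
        if unknown:
            raise ValidationError(f"response columns not in bank: {unknown}")
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete respondent rows", n_dropped)
        df = df[complete]
    values = df[item_ids].to_numpy()
    if not np.all(values == np.floor(values)):
        raise ValidationError("responses must be integers")
    return ResponseMatrix(
        respondent_ids=df[id_col].tolist(),
        item_ids=item_ids,
        values=values.astype(np.int64),
    )


def load_cssrs(path) -> CssrsResponses:
    df = pd.read_csv(path)
    id_col = df.columns[0]
    values = df[df.columns[1:]].to_numpy()
    return CssrsResponses(respondent_ids=df[id_col].tolist(), values=values)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_reverse_coding(responses: ResponseMatrix, bank: ItemBank) -> ResponseMatrix:
    """Map flagged columns x -> 4 - x so higher always means more severe.

    The returned matrix records that reverse coding was applied; applying it a
    second time is an error (the map is an involution, so a silent re-apply
    would corrupt the data undetectably).
    """
    if responses.reverse_coding_applied:
        raise ValidationError("reverse coding already applied to this matrix")
    unknown = [i for i in responses.item_ids if i not in bank]
    if unknown:
        raise ValidationError(f"response columns not in bank: {unknown}")
    values = responses.values.copy()
    flagged = [j for j, i in enumerate(responses.item_ids) if bank[i].reverse_coded]
    if flagged:
        values[:, flagged] = LIKERT_MAX - values[:, flagged]
    return ResponseMatrix(
        respondent_ids=list(responses.respondent_ids),
        item_ids=list(responses.item_ids),
        values=values,
        reverse_coding_applied=True,
    )


def derive_outcomes(screener: CssrsResponses) -> OutcomeLabels:
    """Code outcomes from the screener: any yes on items 1-5, and item 6."""
    v = screener.values
    si = (v[:, :5].max(axis=1) > 0).astype(np.int64)
    si_p = v[:, 5].astype(np.int64)
    return OutcomeLabels(si=si, si_p=si_p)
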