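"""Criterion-distribution comparison and quota-constrained short-form assembly.

The reduced instrument takes, for each of the five criteria, a fixed quota of
the highest-ranked items of that criterion from a primary ranking; any
shortfall is filled from a fallback ranking (recording the source of every
pick).  Rankings are compared to a reference short form via their criterion
proportion vectors, scalarized as 1 - L1/2 (total-variation similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .instrument import CRITERIA, ItemBank, ValidationError
from .sfi import RankingTable

#: Default per-criterion quotas for the assembled nine-item form.
DEFAULT_QUOTAS = {"A": 2, "B1": 2, "B2": 2, "B3": 2, "B4": 1}


@dataclass
class ReferenceShortForm:
    """An existing abbreviated instrument used as comparator."""

    item_ids: list[str]
    bank: ItemBank

    def __post_init__(self) -> None:
        missing = [i for i in self.item_ids if i not in self.bank]
        if missing:
            raise ValidationError(f"reference items not in its bank: {missing}")


@dataclass
class SelectedItem:
    item_id: str
    criterion: str
    source_ranking: str   # outcome label of the ranking supplying the pick
    source_rank: int


@dataclass
class ShortForm:
    selected: list[SelectedItem]
    per_criterion_quota: dict[str, int]

    def __post_init__(self) -> None:
        got = {c: 0 for c in self.per_criterion_quota}
        for s in self.selected:
            got[s.criterion] = got.get(s.criterion, 0) + 1
        for crit, quota in self.per_criterion_quota.items():
            if got.get(crit, 0) != quota:
                raise ValidationError(
                    f"criterion {crit}: {got.get(crit, 0)} items selected, quota {quota}"
                )

    @property
    def item_ids(self) -> list[str]:
        return [s.item_id for s in self.selected]

    def __len__(self) -> int:
        return len(self.selected)


@dataclass
class OverlapReport:
    proportions_ranking: dict[str, float]
    proportions_reference: dict[str, float]
    similarity: float
    top_n: int = 10


def criterion_distribution(item_ids, bank: ItemBank) -> dict[str, float]:
    """Fraction of the list's items belonging to each criterion (0 if absent)."""
    item_ids = list(item_ids)
    if not item_ids:
        raise ValidationError("cannot take criterion distribution of empty list")
    counts = {c: 0 for c in CRITERIA}
    for item_id in item_ids:
        counts[bank.criterion_of(item_id)] += 1  # KeyError -> unknown id
    n = len(item_ids)
    return {c: counts[c] / n for c in CRITERIA}


def distribution_similarity(p: dict[str, float], q: dict[str, float]) -> float:
    """1 - L1/2 between two criterion proportion vectors; 1 iff identical."""
    return 1.0 - 0.5 * sum(abs(p[c] - q[c]) for c in CRITERIA)


def compare_rankings(
    ranking: RankingTable,
    reference: ReferenceShortForm,
    bank: ItemBank,
    top_n: int = 10,
) -> OverlapReport:
    """Criterion distribution of the ranking's top-n versus the reference."""
    if top_n > len(ranking.rows):
        raise ValidationError(
            f"top_n={top_n} exceeds ranking length {len(ranking.rows)}"
        )
    pr = criterion_distribution(ranking.item_ids(top_n), bank)
    pq = criterion_distribution(reference.item_ids, reference.bank)
    return OverlapReport(
        proportions_ranking=pr,
        proportions_reference=pq,
        similarity=distribution_similarity(pr, pq),
        top_n=top_n,
    )


def assemble_short_form(
    primary: RankingTable,
    fallback: RankingTable | None,
    bank: ItemBank,
    quotas: dict[str, int] | None = None,
) -> ShortForm:
    """Fill each criterion's quota from the primary ranking, then fallback.

    "Highest-ranked of a criterion" follows rank order within each ranking
    (ties therefore inherit the ranking's own tie rule).  Items already
    selected are never selected again via the fallback.  A criterion whose
    quota cannot be met from either ranking raises, naming the criterion.
    """
    quotas = dict(DEFAULT_QUOTAS if quotas is None else quotas)
    selected: list[SelectedItem] = []
    chosen: set[str] = set()
    for crit in CRITERIA:
        quota = quotas.get(crit, 0)
        if quota == 0:
            continue
        need = quota
        for source in (primary, fallback):
            if source is None or need == 0:
                continue
            for row in source.rows:
                if need == 0:
                    break
                if row.item_id in chosen:
                    continue
                if bank.criterion_of(row.item_id) != crit:
                    continue
                selected.append(
                    SelectedItem(
                        item_id=row.item_id,
                        criterion=crit,
                        source_ranking=source.outcome_label,
                        source_rank=row.rank,
                    )
                )
                chosen.add(row.item_id)
                need -= 1
        if need:
            raise ValidationError(
                f"criterion {crit} unsatisfiable: quota {quota}, "
                f"short by {need} even after fallback"
            )
    return ShortForm(selected=selected, per_criterion_quota=quotas)


def render_short_form(sf: ShortForm, bank: ItemBank) -> tuple[str, str]:
    """Emit (csv_text, markdown_text) listings grouped by criterion."""
    rows = [
        {
            "criterion": s.criterion,
            "source_ranking": s.source_ranking,
            "source_rank": s.source_rank,
            "item_id": s.item_id,
            "text": bank[s.item_id].text,
        }
        for s in sf.selected
    ]
    df = pd.DataFrame(
        rows, columns=["criterion", "source_ranking", "source_rank", "item_id", "text"]
    )
    csv_text = df.to_csv(index=False)
    lines = ["| Criterion | Ranking | Item | Text |", "| --- | --- | --- | --- |"]
    for r in rows:
        lines.append(
            f"| {r['criterion']} | {r['source_rank']} ({r['source_ranking']}) "
            f"| {r['item_id']} | {r['text']} |"
        )
    return csv_text, "\n".join(lines) + "\n"


def parse_short_form_csv(text_or_path, quotas: dict[str, int] | None = None) -> ShortForm:
    """Inverse of the CSV emitted by :func:`render_short_form`."""
    import io
    import os

    if isinstance(text_or_path, str) and not os.path.exists(text_or_path):
        src = io.StringIO(text_or_path)
    else:
        src = text_or_path
    df = pd.read_csv(src)
    selected = [
        SelectedItem(
            item_id=str(r["item_id"]),
            criterion=str(r["criterion"]),
            source_ranking=str(r["source_ranking"]),
            source_rank=int(r["source_rank"]),
        )
        for _, r in df.iterrows()
    ]
    if quotas is None:
        quotas = {}
        for s in selected:
            quotas[s.criterion] = quotas.get(s.criterion, 0) + 1
    return ShortForm(selected=selected, per_criterion_quota=quotas)
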