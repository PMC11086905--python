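"""Bundled fixtures: the default 61-item bank, the 8-item comparator short
form, and the published top-15 item rankings for both outcomes on the
full-length instrument.

Item ids follow the instrument's sparse historical numbering (ids run past
61 even though the bank holds 61 items), so ids are opaque tokens.  Only the
ids, criterion labels, reverse-coding flags and ranking counts are
reproduced here; item wording is replaced by neutral placeholders.

The criterion assignment of the 24 items that appear in the published
rankings is as reported; the remaining 37 items are given plausible
criterion labels to complete a 61-item bank with all five criteria
represented (A:12, B1:15, B2:14, B3:11, B4:9).
"""

from __future__ import annotations

from .instrument import ItemBank, ItemDefinition
from .sfi import RankingRow, RankingTable
from .shortform import ReferenceShortForm

# items with documented criterion labels (number -> (criterion, reverse flag))
_KNOWN_ITEMS = {
    1: ("B3", False),
    3: ("B2", False),
    4: ("A", False),
    7: ("B1", False),
    11: ("B2", False),
    12: ("A", False),
    13: ("A", False),
    14: ("B2", False),
    24: ("B2", False),
    34: ("B2", False),
    35: ("A", False),
    38: ("B1", False),
    41: ("B1", False),
    45: ("B2", False),
    47: ("B2", False),
    48: ("B1", False),
    51: ("B1", False),
    54: ("B1", False),
    57: ("B1", True),   # the one documented reverse-coded item
    59: ("B3", False),
    60: ("B3", False),
    61: ("B3", False),
    72: ("B3", False),
    74: ("B4", False),
}

# filler assignment completing the bank to 61 items / 5 criteria
_FILLER_CRITERIA = {
    "A": (2, 5, 6, 8, 9, 10, 15, 16),
    "B1": (17, 18, 19, 20, 21, 22, 23, 25),
    "B2": (26, 27, 28, 29, 30, 31, 32),
    "B3": (33, 36, 37, 39, 40, 42),
    "B4": (43, 44, 46, 49, 50, 52, 53, 55),
}


def default_item_bank() -> ItemBank:
    """The 61-item, five-criterion default bank."""
    table: dict[int, tuple[str, bool]] = dict(_KNOWN_ITEMS)
    for criterion, numbers in _FILLER_CRITERIA.items():
        for num in numbers:
            table[num] = (criterion, False)
    items = [
        ItemDefinition(
            item_id=f"SCI-{num}",
            text=f"Item {num}",
            criterion=criterion,
            reverse_coded=reverse,
        )
        for num, (criterion, reverse) in sorted(table.items())
    ]
    assert len(items) == 61
    return ItemBank(items=items, version="default-61")


def reference_short_form() -> ReferenceShortForm:
    """The 8-item comparator: four loss-of-cognitive-control items, two
    entrapment, two affective-disturbance (no hyperarousal, no social
    withdrawal)."""
    spec = [
        ("SF-2", "B2"),
        ("SF-4", "A"),
        ("SF-5", "B1"),
        ("SF-8", "B2"),
        ("SF-26", "B2"),
        ("SF-30", "A"),
        ("SF-37", "B1"),
        ("SF-47", "B2"),
    ]
    bank = ItemBank(
        items=[
            ItemDefinition(item_id=i, text=f"Short-form item {i}", criterion=c)
            for i, c in spec
        ],
        version="comparator-8",
    )
    return ReferenceShortForm(item_ids=[i for i, _ in spec], bank=bank)


# published top-15 rankings: (item number, count) per outcome
_SI_TOP15 = [
    (12, 4000), (60, 4000), (59, 3999), (38, 3977), (4, 3918),
    (51, 3901), (72, 3841), (57, 3306), (74, 2339), (3, 1870),
    (41, 1807), (13, 1192), (54, 580), (45, 534), (7, 235),
]
_SI_P_TOP15 = [
    (57, 3972), (11, 3260), (41, 2914), (7, 2678), (48, 2655),
    (4, 2224), (12, 1833), (1, 1749), (14, 1638), (38, 1609),
    (61, 1601), (34, 1464), (47, 1398), (35, 1217), (24, 1142),
]


def _ranking(entries, outcome_label: str, bank: ItemBank) -> RankingTable:
    rows = [
        RankingRow(
            rank=r + 1,
            item_id=f"SCI-{num}",
            sfi=count,
            criterion=bank.criterion_of(f"SCI-{num}"),
        )
        for r, (num, count) in enumerate(entries)
    ]
    return RankingTable(rows=rows, outcome_label=outcome_label)


def reference_ranking_si(bank: ItemBank | None = None) -> RankingTable:
    """Published top-15 ranking for the broad-ideation outcome."""
    return _ranking(_SI_TOP15, "SI", bank or default_item_bank())


def reference_ranking_si_p(bank: ItemBank | None = None) -> RankingTable:
    """Published top-15 ranking for the ideation-with-preparation outcome."""
    return _ranking(_SI_P_TOP15, "SI_P", bank or default_item_bank())
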