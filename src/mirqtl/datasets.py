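"""Bundled worked-example data.

``LUAD_NDUFS1_CLINICAL`` is a published-style clinicopathological
summary of a 39-patient lung-adenocarcinoma resection cohort: for each
characteristic, patient counts cross-tabulated against high vs low
tumor NDUFS1 mRNA expression (20 high, 19 low). It serves as the
worked example for the 2x2 odds-ratio machinery.

Each record carries the two levels of the characteristic with
(high-expression, low-expression) counts and the level used as the
outcome numerator in the logistic-regression orientation (the
orientation is a property of how each characteristic was coded and is
stored per characteristic, not assumed).
"""

from __future__ import annotations

import pandas as pd

from .survival import TwoByTwo, or_2x2

__all__ = ["LUAD_NDUFS1_CLINICAL", "clinical_or_table"]


#: characteristic -> (levels, counts_high, counts_low, numerator_level)
LUAD_NDUFS1_CLINICAL: list[dict] = [
    {
        "characteristic": "Age",
        "levels": ("<65", ">=65"),
        "high": (12, 8),
        "low": (11, 8),
        "numerator": "<65",
    },
    {
        "characteristic": "Sex",
        "levels": ("Female", "Male"),
        "high": (7, 13),
        "low": (9, 10),
        "numerator": "Male",
    },
    {
        "characteristic": "Stage",
        "levels": ("I+II", "III"),
        "high": (17, 3),
        "low": (11, 8),
        "numerator": "I+II",
    },
    {
        "characteristic": "T stage",
        "levels": ("T1+T2", "T3+T4"),
        "high": (16, 4),
        "low": (14, 5),
        "numerator": "T1+T2",
    },
    {
        "characteristic": "N stage",
        "levels": ("N0", "N1+N2+N3"),
        "high": (16, 4),
        "low": (8, 11),
        "numerator": "N0",
    },
    {
        "characteristic": "Differentiation",
        "levels": ("Poorly", "Well/moderate"),
        "high": (4, 16),
        "low": (10, 9),
        "numerator": "Poorly",
    },
    {
        "characteristic": "ki67",
        "levels": ("<20", ">=20"),
        "high": (12, 8),
        "low": (7, 12),
        "numerator": "<20",
    },
    {
        "characteristic": "Tumor maximum diameter",
        "levels": ("<3 cm", ">=3 cm"),
        "high": (14, 6),
        "low": (7, 12),
        "numerator": "<3 cm",
    },
    {
        "characteristic": "Lymphatic and vascular invasion",
        "levels": ("Negative", "Positive"),
        "high": (16, 4),
        "low": (6, 13),
        "numerator": "Negative",
    },
    {
        "characteristic": "Nerve invasion",
        "levels": ("Negative", "Positive"),
        "high": (15, 5),
        "low": (11, 8),
        "numerator": "Negative",
    },
]


def _table_for(record: dict) -> TwoByTwo:
    num_idx = record["levels"].index(record["numerator"])
    ref_idx = 1 - num_idx
    return TwoByTwo(
        a=record["high"][num_idx],
        b=record["low"][num_idx],
        c=record["high"][ref_idx],
        d=record["low"][ref_idx],
        row_labels=(record["numerator"], record["levels"][ref_idx]),
        col_labels=("high", "low"),
    )


def clinical_or_table(records: list[dict] | None = None) -> pd.DataFrame:
    """Odds ratio and Wald p for every characteristic of the bundled table.

    The exposure is high expression; the outcome numerator level is the
    one stored per characteristic, so each OR matches the logistic
    regression of that outcome coding on the expression group.
    """
    rows = []
    for rec in records if records is not None else LUAD_NDUFS1_CLINICAL:
        tab = _table_for(rec)
        res = or_2x2(tab)
        rows.append(
            {
                "characteristic": rec["characteristic"],
                "a": tab.a,
                "b": tab.b,
                "c": tab.c,
                "d": tab.d,
                "odds_ratio": res.odds_ratio,
                "wald_p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
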