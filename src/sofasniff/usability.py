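"""Usability-questionnaire summaries.

Five-point Likert ratings are categorized as favorable (4-5), neutral (3)
or unfavorable (1-2), and the proportion of item-responses in each
category is computed overall and within the three CSUQ domains: system
usability, information quality and interface quality.  The unit of
analysis is the item-response (respondent x item).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "DOMAINS",
    "DEFAULT_ITEM_DOMAINS",
    "Stratum",
    "UsabilitySummary",
    "categorize",
    "summarize",
    "response_rate",
]

DOMAINS = ("system_usability", "information_quality", "interface_quality")

#: standard 19-item CSUQ grouping: items 1-8 system usability, 9-15
#: information quality, 16-18 interface quality; item 19 (overall
#: satisfaction) contributes to the overall summary only.
DEFAULT_ITEM_DOMAINS: dict[int, Optional[str]] = {
    **{i: "system_usability" for i in range(1, 9)},
    **{i: "information_quality" for i in range(9, 16)},
    **{i: "interface_quality" for i in range(16, 19)},
    19: None,
}

CATEGORIES = ("favorable", "neutral", "unfavorable")


def categorize(rating: int) -> str:
    """Map a 1-5 Likert rating to favorable / neutral / unfavorable."""
    if rating not in (1, 2, 3, 4, 5):
        raise InvalidInputError(f"rating must be an integer in [1, 5], got {rating!r}")
    if rating >= 4:
        return "favorable"
    if rating == 3:
        return "neutral"
    return "unfavorable"


@dataclass(frozen=True)
class Stratum:
    """Category counts and proportions for one domain (or overall)."""

    n: int
    counts: Mapping[str, int]
    proportions: Mapping[str, float]


@dataclass(frozen=True)
class UsabilitySummary:
    overall: Stratum
    by_domain: Mapping[str, Stratum]
    respondents: int
    by_role: Mapping[str, int]


def _stratum(categories: Sequence[str]) -> Stratum:
    n = len(categories)
    counts = {c: sum(1 for x in categories if x == c) for c in CATEGORIES}
    props = {c: counts[c] / n for c in CATEGORIES}
    return Stratum(n, counts, props)


def summarize(
    responses: pd.DataFrame,
    item_domains: Optional[Mapping[Union[int, str], Optional[str]]] = None,
) -> UsabilitySummary:
    """Favorability proportions overall and per domain.

    ``responses`` needs columns ``respondent_id``, ``item_id``,
    ``rating`` and optionally ``role`` and ``domain``.  When no
    ``domain`` column is present, items are mapped through
    ``item_domains`` (default: the standard 19-item CSUQ grouping); an
    item mapped to ``None`` counts toward the overall summary only.
    """
    if len(responses) == 0:
        raise InvalidInputError("no questionnaire responses")
    df = responses.copy()
    if not df["rating"].isin([1, 2, 3, 4, 5]).all():
        raise InvalidInputError("ratings must be integers in [1, 5]")
    df["category"] = df["rating"].map(categorize)
    if "domain" not in df.columns:
        mapping = dict(DEFAULT_ITEM_DOMAINS if item_domains is None else item_domains)
        def to_domain(item):
            key = int(item) if str(item).isdigit() else item
            if key not in mapping:
                raise InvalidInputError(f"item {item!r} has no domain mapping")
            return mapping[key]
        df["domain"] = df["item_id"].map(to_domain)
    bad = set(df["domain"].dropna()) - set(DOMAINS)
    if bad:
        raise InvalidInputError(f"unknown domains {sorted(bad)}")
    by_domain = {
        d: _stratum(list(df.loc[df["domain"] == d, "category"]))
        for d in DOMAINS
        if (df["domain"] == d).any()
    }
    roles = (
        df.drop_duplicates("respondent_id")["role"].value_counts().to_dict()
        if "role" in df.columns
        else {}
    )
    return UsabilitySummary(
        overall=_stratum(list(df["category"])),
        by_domain=by_domain,
        respondents=int(df["respondent_id"].nunique()),
        by_role={str(k): int(v) for k, v in roles.items()},
    )


def response_rate(returned: int, distributed: int) -> int:
    """Survey response rate as a whole-number percentage."""
    if distributed <= 0 or not 0 <= returned <= distributed:
        raise InvalidInputError(
            f"need 0 <= returned <= distributed and distributed > 0, got {returned}/{distributed}"
        )
    return round(100.0 * returned / distributed)


def summary_as_dict(summary: UsabilitySummary) -> dict:
    """JSON-ready view of a summary (category x domain proportions)."""
    def stratum(s: Stratum) -> dict:
        return {"n": s.n, "counts": dict(s.counts), "proportions": dict(s.proportions)}

    return {
        "respondents": summary.respondents,
        "by_role": dict(summary.by_role),
        "overall": stratum(summary.overall),
        "by_domain": {d: stratum(s) for d, s in summary.by_domain.items()},
    }
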