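"""Keyword detection of hepatic steatosis in free-text ultrasound reports.

The detector is a case-insensitive substring matcher over a small term set
(default: "fatty liver", "steatosis"), which is how the cohort's imaging
evidence is characterized.  Negation handling is available but OFF by
default: the plain matcher is the documented method, and the optional
negation pass (a cue within five tokens before the matched term) is a
utility for users who want it.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SteatosisCall",
    "DEFAULT_TERMS",
    "NEGATION_CUES",
    "detect_steatosis",
    "patient_ever_steatosis",
]

DEFAULT_TERMS: tuple[str, ...] = ("fatty liver", "steatosis")
NEGATION_CUES: tuple[str, ...] = ("no", "without", "negative for", "absence of")
#: token distance within which a preceding cue negates a match
NEGATION_WINDOW = 5

_PUNCT = re.compile(r"[^\w\s]")


@dataclass
class SteatosisCall:
    patient_id: str | None
    report_date: dt.date | None
    matched_terms: list[str] = field(default_factory=list)
    negated: bool = False
    positive: bool = False


def _tokens(text: str) -> list[str]:
    return _PUNCT.sub(" ", text.lower()).split()


def _find_term_positions(tokens: list[str], term: str) -> list[int]:
    term_tokens = _tokens(term)
    k = len(term_tokens)
    return [
        i for i in range(len(tokens) - k + 1) if tokens[i : i + k] == term_tokens
    ]


def _is_negated(tokens: list[str], position: int) -> bool:
    window = tokens[max(0, position - NEGATION_WINDOW) : position]
    for cue in NEGATION_CUES:
        cue_tokens = _tokens(cue)
        k = len(cue_tokens)
        for i in range(len(window) - k + 1):
            if window[i : i + k] == cue_tokens:
                return True
    return False


def detect_steatosis(
    report_text: str,
    term_set: tuple[str, ...] = DEFAULT_TERMS,
    negation_enabled: bool = False,
    patient_id: str | None = None,
    report_date: dt.date | None = None,
) -> SteatosisCall:
    """Flag a single report for steatosis terms.

    With ``negation_enabled`` a match preceded within five tokens by a
    negation cue does not count as positive; ``negated`` is set when
    matches exist but all are negated.
    """
    if not report_text or not str(report_text).strip():
        raise ValueError("report_text must be non-empty")
    text = str(report_text).lower()
    matched = [t for t in term_set if t.lower() in text]
    call = SteatosisCall(patient_id, report_date, matched_terms=matched)
    if not matched:
        return call
    if not negation_enabled:
        call.positive = True
        return call
    tokens = _tokens(text)
    any_affirmed = False
    for term in matched:
        positions = _find_term_positions(tokens, term)
        if not positions:
            # matched inside a larger word; no token context to negate
            any_affirmed = True
            continue
        for pos in positions:
            if not _is_negated(tokens, pos):
                any_affirmed = True
    call.positive = any_affirmed
    call.negated = not any_affirmed
    return call


def patient_ever_steatosis(
    reports: pd.DataFrame,
    term_set: tuple[str, ...] = DEFAULT_TERMS,
    since: dt.date = dt.date(2000, 1, 1),
    negation_enabled: bool = False,
) -> bool:
    """True iff any ultrasound report from ``since`` onward is positive.

    Only the ultrasound modality counts (CT/MRI mentions are ignored for
    this cohort-characterization flag); the lookback window default covers
    the twenty years before the study period.
    """
    if reports.empty:
        return False
    d = pd.to_datetime(reports["report_date"])
    sel = reports[(reports["modality"] == "ultrasound") & (d >= pd.Timestamp(since))]
    for row in sel.itertuples(index=False):
        if detect_steatosis(
            row.report_text, term_set, negation_enabled=negation_enabled
        ).positive:
            return True
    return False
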