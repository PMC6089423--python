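"""Sentinel codes for structurally absent survey cells.

Two kinds of non-response are distinguished throughout the package:

* ``MISSING`` — the respondent was asked but no usable answer was recorded
  ("don't know", refusals, ...).
* ``INELIGIBLE`` — the questionnaire skip pattern never presented the
  question (e.g. specialist-care items for respondents who saw no
  specialist, or single-country items).

Both are stored as plain strings so survey tables round-trip through CSV
unchanged. The set of codes treated as missing on recoding matches the
conventional cleaning of telephone-survey data.
"""

MISSING = "MISSING"
INELIGIBLE = "INELIGIBLE"

SENTINELS = frozenset({MISSING, INELIGIBLE})

#: Free-text answer categories recoded to MISSING by default (matched
#: case-insensitively).
DEFAULT_MISSING_CODES = frozenset(
    {"don't know", "not sure", "refused", "decline to answer"}
)


def is_sentinel(value: object) -> bool:
    return value in SENTINELS
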