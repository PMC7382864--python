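"""Name standardization and invalid-name screening.

Administrative registers record names with inconsistent casing, accents,
punctuation and placeholder entries ("RN DE ...", "IGNORADO").  Before any
comparison, every name passes through :func:`standardize_name`; screening
then routes each name to one of three statuses:

* ``invalid`` — contains a stop-term token (newborn/unknown markers) or is
  empty after cleaning; excluded from linkage,
* ``needs_review`` — has a token absent from the name lexicon; a clerical
  decision (modeled as a plain keep/exclude mapping) resolves it,
* ``valid`` — every token is a known name component.

Middle initials, prefixes and suffixes are kept as recorded: they carry
discriminatory power.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._lexicon import DEFAULT_STOP_TERMS, default_lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "NameVerdict",
    "standardize_name",
    "screen_invalid_names",
    "apply_review_decisions",
]

_NON_ALNUM_SPACE = re.compile(r"[^A-Z0-9 ]+")
_MULTI_SPACE = re.compile(r" {2,}")


@dataclass(frozen=True)
class NameVerdict:
    """Outcome of screening one name."""

    raw: str
    standardized: str
    status: str  # "valid" | "invalid" | "needs_review"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("valid", "invalid", "needs_review"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "invalid" and not self.reason:
            raise ValueError("invalid verdict requires a reason")


def standardize_name(raw: str) -> str:
    """Uppercase, strip accents, drop punctuation, collapse whitespace.

    Punctuation (any non-alphanumeric, non-space character) is replaced by
    a space so that hyphenated compounds split into tokens, then runs of
    spaces collapse and the ends are trimmed.  Idempotent.  May return the
    empty string (punctuation-only input); callers flag that, never drop
    it silently.
    """
    text = unicodedata.normalize("NFKD", raw)
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.upper()
    text = _NON_ALNUM_SPACE.sub(" ", text)
    text = _MULTI_SPACE.sub(" ", text)
    return text.strip()


def screen_invalid_names(
    names: Iterable[str],
    lexicon: frozenset[str] | set[str] | None = None,
    stop_terms: frozenset[str] | set[str] | None = None,
) -> list[NameVerdict]:
    """Classify standardized names as valid / invalid / needs_review.

    A name containing any stop-term token is invalid regardless of its
    other tokens; an empty name is invalid; a name with at least one token
    outside the lexicon (and no stop-term) needs review; otherwise valid.
    Deterministic and order-independent.
    """
    lex = frozenset(lexicon) if lexicon is not None else default_lexicon()
    stops = frozenset(stop_terms) if stop_terms is not None else DEFAULT_STOP_TERMS
    if not lex:
        raise ValueError("lexicon must be non-empty")
    if not stops:
        raise ValueError("stop_terms must be non-empty")

    verdicts: list[NameVerdict] = []
    for raw in names:
        std = standardize_name(raw)
        if not std:
            verdicts.append(
                NameVerdict(raw, std, "invalid", "empty after standardization")
            )
            continue
        tokens = std.split(" ")
        hit = next((t for t in tokens if t in stops), None)
        if hit is not None:
            verdicts.append(
                NameVerdict(raw, std, "invalid", f"stop term {hit!r}")
            )
            continue
        unknown = [t for t in tokens if t not in lex]
        if unknown:
            verdicts.append(
                NameVerdict(
                    raw, std, "needs_review", f"unknown tokens {unknown}"
                )
            )
        else:
            verdicts.append(NameVerdict(raw, std, "valid"))
    return verdicts


def apply_review_decisions(
    verdicts: Sequence[NameVerdict],
    decisions: Mapping[str, str] | None,
) -> tuple[list[NameVerdict], list[NameVerdict]]:
    """Resolve screening with clerical keep/exclude decisions.

    ``decisions`` maps each standardized needs_review name to ``"keep"``
    or ``"exclude"``.  Returns ``(kept, excluded)``; the excluded list is
    the audit trail (invalid names plus reviewer-excluded ones).

    Raises
    ------
    ValueError
        If any needs_review name has no decision, or a decision value is
        neither keep nor exclude.
    """
    decisions = decisions or {}
    kept: list[NameVerdict] = []
    excluded: list[NameVerdict] = []
    for v in verdicts:
        if v.status == "valid":
            kept.append(v)
        elif v.status == "invalid":
            excluded.append(v)
        else:
            if v.standardized not in decisions:
                raise ValueError(
                    f"no review decision for name {v.standardized!r}"
                )
            choice = decisions[v.standardized]
            if choice == "keep":
                kept.append(v)
            elif choice == "exclude":
                excluded.append(
                    NameVerdict(v.raw, v.standardized, "invalid", "reviewer excluded")
                )
            else:
                raise ValueError(
                    f"decision for {v.standardized!r} must be 'keep' or "
                    f"'exclude', got {choice!r}"
                )
    logger.info(
        "name screening: %d kept, %d excluded (%d by review)",
        len(kept),
        len(excluded),
        sum(1 for v in excluded if v.reason == "reviewer excluded"),
    )
    return kept, excluded
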