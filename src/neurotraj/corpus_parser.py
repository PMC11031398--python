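"""Sentence segmentation and year-anchor resolution for clinical histories.

Medical-record clinical histories are narrative text in which each sentence
may carry zero, one or several calendar-year anchors: literal years
("In 2005 he developed tremor"), ranges ("2005-2007 progressive decline"),
relative expressions ("last 2 years", "at birth"), or nothing at all.
Sentences without a resolvable year are kept under the explicit
``YEAR_UNKNOWN`` category rather than dropped: they still contribute to
attribute counts but are excluded from temporal analyses downstream.

Resolution rules (conservative where the source material gives no rule):

* literal 4-digit years within plausible bounds (birth..death) are taken;
* "Y1-Y2" ranges expand to every year in the closed interval;
* "last N years" counts back from the sentence's anchor year — the section
  year when the history carries ``YEAR:`` headers, else the year of death;
* sub-year expressions ("last 2 months") resolve to the single anchor year;
* "at birth" maps to death_year - age_at_death;
* back-references ("in comparison to 2003") do not contribute that year;
* a year after the year of death is implausible: it is dropped with a parse
  warning, and the sentence falls back to YEAR_UNKNOWN if nothing remains.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "YEAR_UNKNOWN",
    "ClinicalSentence",
    "ParseContext",
    "split_history",
    "resolve_years",
    "parse_history",
]

#: Sentinel for sentences without a resolvable calendar year.
YEAR_UNKNOWN = "year_unknown"

# Common abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "dr", "mr", "mrs", "ms", "prof", "vs", "approx",
    "ca", "resp", "cf", "incl", "neurol", "psych",
}

_SENT_BOUNDARY = re.compile(r"([.!?])(\s+|$)")
_YEAR = re.compile(r"\b(1[89]\d{2}|20\d{2})\b")
_RANGE = re.compile(r"\b(1[89]\d{2}|20\d{2})\s*[-–—]\s*(1[89]\d{2}|20\d{2})\b")
_LAST_YEARS = re.compile(r"\blast\s+(\d+)\s+years?\b", re.IGNORECASE)
_LAST_SUBYEAR = re.compile(r"\blast\s+\d+\s+(?:months?|weeks?|days?)\b", re.IGNORECASE)
_AT_BIRTH = re.compile(r"\bat\s+birth\b", re.IGNORECASE)
_BACKREF = re.compile(
    r"\b(?:in\s+comparison\s+(?:to|with)|compared\s+(?:to|with)|since|as\s+in)\s+"
    r"(1[89]\d{2}|20\d{2})\b",
    re.IGNORECASE,
)
_SECTION_HEADER = re.compile(r"^\s*YEAR:\s*(1[89]\d{2}|20\d{2})\s*$", re.MULTILINE)


@dataclass(frozen=True)
class ClinicalSentence:
    """One donor-anchored sentence with its resolved year(s)."""

    donor_id: str
    text: str
    years: tuple[int, ...] | str  # sorted years, or YEAR_UNKNOWN
    source_order: int

    def __post_init__(self) -> None:
        if isinstance(self.years, str):
            if self.years != YEAR_UNKNOWN:
                raise ValueError(f"invalid year sentinel {self.years!r}")
        else:
            object.__setattr__(self, "years", tuple(sorted(set(self.years))))


@dataclass
class ParseContext:
    """Temporal anchors available while resolving one donor's history."""

    death_year: int | None = None
    age_at_death: float | None = None
    preceding_year: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def birth_year(self) -> int | None:
        if self.death_year is None or self.age_at_death is None:
            return None
        return int(self.death_year - self.age_at_death)


def split_history(history_text: str) -> list[str]:
    """Split free text into sentences without splitting inside abbreviations.

    The concatenation of the returned sentences equals the input modulo
    whitespace; empty input yields an empty list.
    """
    text = history_text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.end(1)
        candidate = text[start:end]
        prev_token = re.search(r"(\S+)[.!?]$", candidate)
        if prev_token is not None and match.group(1) == ".":
            word = prev_token.group(1).rstrip(".").lower().lstrip("(")
            if word in _ABBREVIATIONS or (len(word) == 1 and word.isalpha()):
                continue  # abbreviation or initial, keep scanning
        stripped = candidate.strip()
        if stripped:
            sentences.append(stripped)
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _plausible(year: int, context: ParseContext) -> bool:
    birth = context.birth_year
    if birth is not None and year < birth:
        return False
    return True


def resolve_years(
    sentence: str, context: ParseContext | None = None
) -> tuple[int, ...] | str:
    """Resolve a sentence's year anchors to concrete calendar years.

    Returns a sorted tuple of years, or :data:`YEAR_UNKNOWN` when the
    sentence has no resolvable anchor.
    """
    context = context if context is not None else ParseContext()
    years: set[int] = set()
    text = sentence

    # Back-references contribute nothing; strip them before literal scanning.
    text = _BACKREF.sub(" ", text)

    for match in _RANGE.finditer(text):
        lo, hi = int(match.group(1)), int(match.group(2))
        if lo <= hi:
            years.update(range(lo, hi + 1))
    text = _RANGE.sub(" ", text)

    for match in _YEAR.finditer(text):
        years.add(int(match.group(0)))

    anchor = context.preceding_year or context.death_year
    match = _LAST_YEARS.search(text)
    if match is not None and anchor is not None:
        n = int(match.group(1))
        years.update(range(anchor - n, anchor + 1))  # anchor-inclusive span
    if _LAST_SUBYEAR.search(text) and anchor is not None:
        years.add(anchor)
    if _AT_BIRTH.search(text) and context.birth_year is not None:
        years.add(context.birth_year)

    if context.death_year is not None:
        late = {y for y in years if y > context.death_year}
        if late:
            context.warnings.append(
                f"year(s) {sorted(late)} beyond death year {context.death_year}: "
                f"dropped in {sentence!r}"
            )
            years -= late
    years = {y for y in years if _plausible(y, context)}

    if not years:
        return YEAR_UNKNOWN
    return tuple(sorted(years))


def parse_history(
    donor_id: str,
    history_text: str,
    death_year: int | None = None,
    age_at_death: float | None = None,
    warn: bool = False,
) -> list[ClinicalSentence]:
    """Parse one donor's clinical history into year-anchored sentences.

    The fixture dialect allows ``YEAR: <yyyy>`` section headers; sentences
    under a header inherit it as the anchor for relative expressions.
    """
    context = ParseContext(death_year=death_year, age_at_death=age_at_death)
    out: list[ClinicalSentence] = []
    order = 0
    # Split the history at section headers, tracking the active section year.
    pos = 0
    segments: list[tuple[int | None, str]] = []
    current_year: int | None = None
    for match in _SECTION_HEADER.finditer(history_text):
        segment = history_text[pos : match.start()]
        if segment.strip():
            segments.append((current_year, segment))
        current_year = int(match.group(1))
        pos = match.end()
    tail = history_text[pos:]
    if tail.strip():
        segments.append((current_year, tail))

    for section_year, segment in segments:
        context.preceding_year = section_year
        for sentence in split_history(segment):
            years = resolve_years(sentence, context)
            if years == YEAR_UNKNOWN and section_year is not None:
                years = (section_year,)
            out.append(
                ClinicalSentence(
                    donor_id=donor_id, text=sentence, years=years, source_order=order
                )
            )
            order += 1
    if warn:
        for message in context.warnings:
            warnings.warn(message, stacklevel=2)
    return out
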