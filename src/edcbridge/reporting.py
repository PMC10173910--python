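"""Usability-survey scoring, respondent breakdowns, project-registry
summaries, data-management-plan rendering, and support/comment logs.

All displayed numbers are rounded half-up at two decimals; raw precision is
kept internally. The CSUQ scorer takes already-oriented ratings (higher is
better); reversing a reversed-scale export is the caller's preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from string import Template
from typing import Iterable, Optional, Sequence

__all__ = [
    "CsuqScores",
    "ProjectCounts",
    "ProjectSummary",
    "MissingField",
    "SupportLog",
    "CommentBoard",
    "round_half_up",
    "score_csuq",
    "respondent_breakdown",
    "summarize_registry",
    "fill_dmp",
]

N_ITEMS = 16
SYSUSE_ITEMS = slice(0, 6)  # questions 1-6
INFOQUAL_ITEMS = slice(6, 12)  # questions 7-12
INTQUAL_ITEMS = slice(12, 15)  # questions 13-15


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used for every displayed
    number in this module."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CsuqScores:
    """Raw (unrounded) scores; ``display()`` gives the 2-decimal view."""

    overall: float
    sysuse: float
    infoqual: float
    intqual: float

    def display(self) -> dict[str, float]:
        return {
            "overall": round_half_up(self.overall),
            "sysuse": round_half_up(self.sysuse),
            "infoqual": round_half_up(self.infoqual),
            "intqual": round_half_up(self.intqual),
        }


def _item_means(ratings: Sequence[Sequence[float]]) -> list[float]:
    if not ratings:
        raise ValueError("empty ratings matrix")
    for row in ratings:
        if len(row) != N_ITEMS:
            raise ValueError(f"each respondent needs {N_ITEMS} ratings, got {len(row)}")
        for r in row:
            if not 1 <= float(r) <= 7:
                raise ValueError(f"rating {r!r} outside [1, 7]")
    n = len(ratings)
    return [sum(float(row[j]) for row in ratings) / n for j in range(N_ITEMS)]


def score_csuq(ratings: Sequence) -> CsuqScores:
    """Score the 16-item usability questionnaire.

    Accepts either a respondents x 16 matrix or a flat sequence of the 16
    per-item means. Each subscale is the arithmetic mean of its items'
    means: overall = items 1-16, system usefulness = 1-6, information
    quality = 7-12, interface quality = 13-15.
    """
    if ratings and not isinstance(ratings[0], (list, tuple)):
        means = [float(x) for x in ratings]
        if len(means) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item means, got {len(means)}")
        for m in means:
            if not 1 <= m <= 7:
                raise ValueError(f"item mean {m!r} outside [1, 7]")
    else:
        means = _item_means(ratings)

    def mean(xs: Sequence[float]) -> float:
        return sum(xs) / len(xs)

    return CsuqScores(
        overall=mean(means),
        sysuse=mean(means[SYSUSE_ITEMS]),
        infoqual=mean(means[INFOQUAL_ITEMS]),
        intqual=mean(means[INTQUAL_ITEMS]),
    )


def respondent_breakdown(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (half-up, 2 decimals) computed from unrounded ratios."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero total")
    return {k: round_half_up(100.0 * c / total) for k, c in counts.items()}


@dataclass(frozen=True)
class ProjectCounts:
    name: str
    centers: int
    instruments: int
    fields: int
    expected_records: int

    def __post_init__(self) -> None:
        for attr in ("centers", "instruments", "fields", "expected_records"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass
class ProjectSummary:
    rows: list[ProjectCounts]
    totals: dict[str, int]


def summarize_registry(projects: Iterable[ProjectCounts]) -> ProjectSummary:
    """Exact integer column sums; rows echoed in registration order."""
    rows = list(projects)
    totals = {
        "centers": sum(p.centers for p in rows),
        "instruments": sum(p.instruments for p in rows),
        "fields": sum(p.fields for p in rows),
        "expected_records": sum(p.expected_records for p in rows),
    }
    return ProjectSummary(rows=rows, totals=totals)


# ---------------------------------------------------------------------------
# data management plan
# ---------------------------------------------------------------------------

REQUIRED_DMP_FIELDS = (
    "project_name",
    "project_number",
    "principal_investigator",
    "funding",
)


class MissingField(KeyError):
    def __init__(self, fields: list[str]):
        super().__init__(", ".join(fields))
        self.fields = fields


def fill_dmp(metadata: dict[str, str]) -> str:
    """Render the bundled plan template (Portuguese, markdown).

    Required metadata: project name/number, principal investigator and
    funding; every other placeholder defaults to an empty string so no
    marker survives in the output. Values are substituted verbatim, never
    interpreted.
    """
    missing = [k for k in REQUIRED_DMP_FIELDS if not metadata.get(k)]
    if missing:
        raise MissingField(missing)
    from importlib.resources import files

    template = Template(files("edcbridge.templates").joinpath("dmp_pt.md").read_text("utf-8"))
    defaults = {name: "" for name in template.get_identifiers()}
    return template.substitute({**defaults, **{k: str(v) for k, v in metadata.items()}})


# ---------------------------------------------------------------------------
# user support and instrument commenting
# ---------------------------------------------------------------------------


@dataclass
class SupportRequest:
    request_id: int
    project: str
    record_id: str
    kind: str  # unlock | delete | other
    requester: str
    status: str = "open"


class SupportLog:
    """Append-only audit trail of support requests and their transitions."""

    KINDS = ("unlock", "delete", "other")

    def __init__(self) -> None:
        self._requests: dict[int, SupportRequest] = {}
        self._audit: list[dict] = []
        self._next = 1
        self._clock = 0

    def _stamp(self) -> str:
        self._clock += 1
        return f"t{self._clock:06d}"

    def record_support_request(
        self, project: str, record_id: str, kind: str, requester: str
    ) -> SupportRequest:
        if kind not in self.KINDS:
            raise ValueError(f"unknown request kind {kind!r}")
        req = SupportRequest(self._next, project, record_id, kind, requester)
        self._next += 1
        self._requests[req.request_id] = req
        self._audit.append(
            {"request_id": req.request_id, "status": "open", "at": self._stamp()}
        )
        return req

    def transition(self, request_id: int, status: str) -> SupportRequest:
        req = self._requests.get(request_id)
        if req is None:
            raise KeyError(f"unknown request {request_id}")
        req.status = status
        self._audit.append({"request_id": request_id, "status": status, "at": self._stamp()})
        return req

    def audit_trail(self, request_id: int | None = None) -> list[dict]:
        if request_id is None:
            return list(self._audit)
        return [e for e in self._audit if e["request_id"] == request_id]


@dataclass
class Comment:
    comment_id: int
    form: str
    field: Optional[str]
    author: str
    text: str
    parent: Optional[int] = None


class CommentBoard:
    """Threaded commenting on data-collection forms and their fields."""

    def __init__(self, known_forms: Iterable[str] | None = None) -> None:
        self._known = set(known_forms) if known_forms is not None else None
        self._comments: list[Comment] = []
        self._next = 1

    def add_instrument_comment(
        self,
        form: str,
        field: Optional[str],
        author: str,
        text: str,
        parent: Optional[int] = None,
    ) -> Comment:
        if self._known is not None and form not in self._known:
            raise KeyError(f"unknown form {form!r}")
        if parent is not None and not any(c.comment_id == parent for c in self._comments):
            raise KeyError(f"unknown parent comment {parent}")
        comment = Comment(self._next, form, field, author, text, parent)
        self._next += 1
        self._comments.append(comment)
        return comment

    def thread(self, root_id: int) -> list[Comment]:
        """The root comment followed by its replies, in posting order."""
        out = [c for c in self._comments if c.comment_id == root_id]
        if not out:
            raise KeyError(f"unknown comment {root_id}")
        out.extend(c for c in self._comments if c.parent == root_id)
        return out

    def history(self) -> list[Comment]:
        return list(self._comments)
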