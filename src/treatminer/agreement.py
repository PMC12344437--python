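"""Inter-annotator agreement by Cohen's kappa over aligned spans.

Two annotators' entity layers are first aligned one-to-one — exact mode
requires identical spans, partial mode allows each boundary to differ by
at most ``tolerance`` characters (default 4) — by greedy matching in
order of increasing combined boundary distance.  Agreement units are the
alignment products: each matched pair contributes its two labels, each
unmatched annotation contributes its label against ``none``.  Cohen's
kappa is then computed from the resulting contingency table as
``(p_o - p_e) / (1 - p_e)``.

No synthetic true-negative mass is added: the ``(none, none)`` cell is
empty by construction, which makes the kappa conservative relative to
token-level unitisations.  Kappa values are therefore comparable only
between runs of this same unitisation.

Relations are aligned by their endpoint spans (within the same
tolerance) regardless of type, so two annotators linking the same pair
with different relation types count as a disagreement unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import EntityAnnotation, ValidationError
from .evaluation import ResolvedRelation


@dataclass
class SpanAlignment:
    """One-to-one alignment of two annotators' spans."""

    pairs: list[tuple[EntityAnnotation, EntityAnnotation, str]]  # kind: exact|partial
    unmatched_a: list[EntityAnnotation]
    unmatched_b: list[EntityAnnotation]


@dataclass
class AgreementReport:
    doc_id: str
    layer: str  # {entities, relations}
    mode: str  # {exact, partial}
    tolerance: int
    kappa: float
    p_o: float
    p_e: float
    n_units: int
    agreed: int
    disagreed: int
    unmatched_a: int
    unmatched_b: int
    table: dict[tuple[str, str], int] = field(default_factory=dict)


def _kappa_from_table(table: dict[tuple[str, str], int]) -> tuple[float, float, float]:
    n = sum(table.values())
    if n < 2:
        raise ValidationError(f"kappa undefined for {n} unit(s)")
    labels = sorted({a for a, _ in table} | {b for _, b in table})
    p_o = sum(table.get((lab, lab), 0) for lab in labels) / n
    row = {lab: sum(v for (a, _), v in table.items() if a == lab) for lab in labels}
    col = {lab: sum(v for (_, b), v in table.items() if b == lab) for lab in labels}
    p_e = sum(row[lab] * col[lab] for lab in labels) / (n * n)
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return kappa, p_o, p_e


def _boundary_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def _spans_match(a: tuple[int, int], b: tuple[int, int], mode: str, tolerance: int) -> bool:
    if mode == "exact":
        return a == b
    return abs(a[0] - b[0]) <= tolerance and abs(a[1] - b[1]) <= tolerance


def align_spans(
    a: Sequence[EntityAnnotation],
    b: Sequence[EntityAnnotation],
    mode: str = "partial",
    tolerance: int = 4,
) -> SpanAlignment:
    """Greedy one-to-one span alignment by increasing boundary distance.

    Exact mode pairs identical spans only; partial mode pairs spans whose
    start and end each differ by at most ``tolerance`` characters.  Ties
    are broken by the earlier first-annotator start, then by input order,
    making the alignment deterministic and order-stable.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    candidates = []
    for i, ann_a in enumerate(a):
        for j, ann_b in enumerate(b):
            if _spans_match(ann_a.span, ann_b.span, mode, tolerance):
                dist = _boundary_distance(ann_a.span, ann_b.span)
                candidates.append((dist, ann_a.start, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[EntityAnnotation, EntityAnnotation, str]] = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        kind = "exact" if a[i].span == b[j].span else "partial"
        pairs.append((a[i], b[j], kind))
    return SpanAlignment(
        pairs=pairs,
        unmatched_a=[ann for i, ann in enumerate(a) if i not in used_a],
        unmatched_b=[ann for j, ann in enumerate(b) if j not in used_b],
    )


def entity_kappa(
    a: Sequence[EntityAnnotation],
    b: Sequence[EntityAnnotation],
    mode: str = "partial",
    tolerance: int = 4,
    doc_id: str = "",
) -> AgreementReport:
    """Cohen's kappa over aligned entity units for one document."""
    alignment = align_spans(a, b, mode=mode, tolerance=tolerance)
    table: dict[tuple[str, str], int] = {}

    def bump(la: str, lb: str) -> None:
        table[(la, lb)] = table.get((la, lb), 0) + 1

    for ann_a, ann_b, _ in alignment.pairs:
        bump(ann_a.etype, ann_b.etype)
    for ann in alignment.unmatched_a:
        bump(ann.etype, "none")
    for ann in alignment.unmatched_b:
        bump("none", ann.etype)

    kappa, p_o, p_e = _kappa_from_table(table)
    agreed = sum(v for (la, lb), v in table.items() if la == lb)
    n = sum(table.values())
    return AgreementReport(
        doc_id=doc_id, layer="entities", mode=mode, tolerance=tolerance,
        kappa=kappa, p_o=p_o, p_e=p_e, n_units=n, agreed=agreed,
        disagreed=n - agreed, unmatched_a=len(alignment.unmatched_a),
        unmatched_b=len(alignment.unmatched_b), table=table,
    )


def relation_agreement(
    a: Sequence[ResolvedRelation],
    b: Sequence[ResolvedRelation],
    tolerance: int = 4,
    doc_id: str = "",
) -> AgreementReport:
    """Cohen's kappa over relation units for one document.

    Relations are aligned greedily by endpoint spans, both boundaries of
    both endpoints within ``tolerance``; the unit category is each
    annotator's relation type, so endpoint-matched pairs with different
    types are disagreement units and unmatched relations pair with
    ``none``.
    """
    candidates = []
    for i, (ha, ta, _) in enumerate(a):
        for j, (hb, tb, _) in enumerate(b):
            if _spans_match(ha, hb, "partial", tolerance) and _spans_match(
                ta, tb, "partial", tolerance
            ):
                dist = _boundary_distance(ha, hb) + _boundary_distance(ta, tb)
                candidates.append((dist, ha[0], i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    table: dict[tuple[str, str], int] = {}

    def bump(la: str, lb: str) -> None:
        table[(la, lb)] = table.get((la, lb), 0) + 1

    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        bump(a[i][2], b[j][2])
    for i, rel in enumerate(a):
        if i not in used_a:
            bump(rel[2], "none")
    for j, rel in enumerate(b):
        if j not in used_b:
            bump("none", rel[2])

    kappa, p_o, p_e = _kappa_from_table(table)
    agreed = sum(v for (la, lb), v in table.items() if la == lb)
    n = sum(table.values())
    return AgreementReport(
        doc_id=doc_id, layer="relations", mode="partial", tolerance=tolerance,
        kappa=kappa, p_o=p_o, p_e=p_e, n_units=n, agreed=agreed,
        disagreed=n - agreed, unmatched_a=len(a) - len(used_a),
        unmatched_b=len(b) - len(used_b), table=table,
    )


def pool_reports(reports: Sequence[AgreementReport]) -> AgreementReport:
    """Pooled-corpus kappa: sum the per-document contingency tables."""
    if not reports:
        raise ValidationError("no reports to pool")
    table: dict[tuple[str, str], int] = {}
    for report in reports:
        for key, value in report.table.items():
            table[key] = table.get(key, 0) + value
    kappa, p_o, p_e = _kappa_from_table(table)
    agreed = sum(v for (la, lb), v in table.items() if la == lb)
    n = sum(table.values())
    first = reports[0]
    return AgreementReport(
        doc_id="<pooled>", layer=first.layer, mode=first.mode,
        tolerance=first.tolerance, kappa=kappa, p_o=p_o, p_e=p_e,
        n_units=n, agreed=agreed, disagreed=n - agreed,
        unmatched_a=sum(r.unmatched_a for r in reports),
        unmatched_b=sum(r.unmatched_b for r in reports), table=table,
    )
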