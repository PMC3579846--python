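"""Somatic lesion analysis from cloned amplicon sequences.

Error-prone non-homologous end joining (NHEJ) repair of a nuclease cut
leaves insertions, deletions, or complex events (both an insertion of a few
random nucleotides and a deletion) at the cut site.  Each cloned amplicon
carries a single allele, so classification is a pairwise problem: globally
align the clone to the wild-type amplicon, parse the changed region into
events, and call the allele class.  The fraction of non-wild-type clones is
the somatic lesion frequency, the standard proxy for nuclease activity in
injected embryos.

Indel placement under microhomology is ambiguous; events are left-aligned
(shifted maximally 5') before reporting, following variant-normalisation
practice.  Substitution-only clones are scored wild-type by default
(PCR/sequencing errors would otherwise inflate the lesion frequency), but
mismatch runs contiguous with an indel at the cut are absorbed into the
event: an NHEJ junction that replaces wild-type bases is one lesion, not an
indel plus independent point mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from statsmodels.stats.proportion import proportion_confint

ALLELE_CLASSES = ("WT", "insertion", "deletion", "complex")


@dataclass
class CloneAlleleCall:
    """Classification of one cloned amplicon against the wild-type allele."""

    clone_id: str
    allele_class: str
    net_delta: int
    inserted_seq: str = ""
    deleted_seq: str = ""
    is_duplication: bool = False
    event_start: int = 0
    n_substitutions: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_mutant(self) -> bool:
        return self.allele_class != "WT"


@dataclass(frozen=True)
class LesionSummary:
    """Somatic lesion frequency with a 95% Wilson score interval."""

    n_mutant: int
    n_total: int
    frequency: float  # percent, one decimal
    ci_low: float     # percent
    ci_high: float    # percent


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _left_shift(wt: str, start: int, deleted: str, inserted: str) -> tuple[int, str, str]:
    """Shift a pure indel maximally 5' through its microhomology run."""
    if deleted and inserted:
        return start, deleted, inserted
    moving = deleted or inserted
    while start > 0 and moving and wt[start - 1] == moving[-1]:
        moving = wt[start - 1] + moving[:-1]
        start -= 1
    if deleted:
        return start, moving, ""
    return start, "", moving


def _shift_range(wt: str, start: int, deleted: str, inserted: str) -> tuple[int, int]:
    """[leftmost start, rightmost end) over all microhomology placements."""
    span = len(deleted)
    if deleted and inserted:
        return start, start + span
    ls, d, i = _left_shift(wt, start, deleted, inserted)
    moving = deleted or inserted
    rs = start
    while moving and rs + span < len(wt) and wt[rs + (span or 0)] == moving[0]:
        moving = moving[1:] + wt[rs + (span or 0)]
        rs += 1
    return ls, rs + max(span, 1)


def _parse_events(wt: str, clone: str, merge_dist: int = 10):
    """Align and parse into events: (wt_start, wt_end, deleted, inserted).

    Alignment columns are classed match / mismatch / gap; maximal runs of
    non-match columns become difference segments, and segments separated by
    at most ``merge_dist`` matching columns are merged (one NHEJ junction
    can align as mismatches interleaved with a gap).  Segments without any
    gap column are isolated substitutions and are returned separately.
    """
    alignment = _ALIGNER.align(wt, clone)[0]
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        raise ValueError("no alignment anchor between clone and wild type")
    # Walk columns, recording difference segments as (t0, t1, q0, q1, has_gap).
    segments: list[list] = []

    def add_diff(t0, t1, q0, q1, gap):
        if segments and segments[-1][1] == t0 and segments[-1][3] == q0:
            seg = segments[-1]
            seg[1], seg[3] = t1, q1
            seg[4] = seg[4] or gap
        else:
            segments.append([t0, t1, q0, q1, gap])

    prev_t = prev_q = 0
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if t0 > prev_t or q0 > prev_q:  # gap before this block
            add_diff(prev_t, t0, prev_q, q0, gap=True)
        for i in range(t1 - t0):
            if wt[t0 + i] != clone[q0 + i]:
                add_diff(t0 + i, t0 + i + 1, q0 + i, q0 + i + 1, gap=False)
        prev_t, prev_q = t1, q1
    if prev_t < len(wt) or prev_q < len(clone):  # trailing gap
        add_diff(prev_t, len(wt), prev_q, len(clone), gap=True)

    # Merge segments separated by short match runs.
    merged: list[list] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] <= merge_dist:
            prev = merged[-1]
            prev[1], prev[3] = seg[1], seg[3]
            prev[4] = prev[4] or seg[4]
        else:
            merged.append(list(seg))

    events, substitutions = [], []
    for t0, t1, q0, q1, gap in merged:
        if gap:
            events.append((t0, t1, wt[t0:t1], clone[q0:q1]))
        else:
            substitutions.append((t0, t1 - t0))
    n_subs = sum(n for _, n in substitutions)
    return events, n_subs


def classify_allele(
    wt: str,
    clone: str,
    cut_window: tuple[int, int],
    clone_id: str = "clone",
    merge_dist: int = 10,
    min_anchor: int = 20,
) -> CloneAlleleCall:
    """Classify one clone against the wild-type amplicon.

    ``cut_window`` is a 0-based half-open interval around the spacer in
    wild-type coordinates.  An event counts as a lesion when any of its
    microhomology-equivalent placements overlaps that window; events fully
    outside it (and isolated substitutions anywhere) leave the clone
    wild-type for lesion counting and are noted in ``warnings``.

    A duplication is an insertion identical to the wild-type bases
    immediately 5' of the (left-aligned) insertion point.
    """
    wt = wt.upper()
    clone = clone.upper()
    if not wt or not clone:
        raise ValueError("empty sequence")
    lo, hi = cut_window
    if not (0 <= lo <= hi <= len(wt)):
        raise ValueError(f"cut_window {cut_window} outside wild type")
    if wt == clone:
        return CloneAlleleCall(clone_id, "WT", 0)
    anchor = min(min_anchor, len(wt) // 4)
    if wt[:anchor] != clone[:anchor] or wt[-anchor:] != clone[-anchor:]:
        raise ValueError(
            f"{clone_id}: clone lacks {anchor} bp of identical flanking "
            "sequence on each end (no alignment anchor)")

    events, n_subs = _parse_events(wt, clone, merge_dist=merge_dist)
    warnings: list[str] = []

    in_window, outside = [], []
    for t0, t1, deleted, inserted in events:
        ls, re = _shift_range(wt, t0, deleted, inserted)
        (in_window if (ls <= hi and re >= lo) else outside).append(
            (t0, t1, deleted, inserted))
    if outside:
        warnings.append(f"{len(outside)} event(s) outside the cut window ignored")
    if n_subs:
        warnings.append(f"{n_subs} isolated substitution(s) not scored as lesion")

    if not in_window:
        return CloneAlleleCall(clone_id, "WT", 0, n_substitutions=n_subs,
                               warnings=tuple(warnings))

    if len(in_window) > 1:
        warnings.append("multiple separated indel events: classified complex "
                        "with concatenated event strings")
        deleted = "".join(e[2] for e in in_window)
        inserted = "".join(e[3] for e in in_window)
        return CloneAlleleCall(
            clone_id, "complex", len(inserted) - len(deleted),
            inserted_seq=inserted, deleted_seq=deleted,
            event_start=in_window[0][0], n_substitutions=n_subs,
            warnings=tuple(warnings))

    t0, t1, deleted, inserted = in_window[0]
    start, deleted, inserted = _left_shift(wt, t0, deleted, inserted)
    net = len(inserted) - len(deleted)
    if deleted and inserted:
        klass = "complex"
    elif inserted:
        klass = "insertion"
    else:
        klass = "deletion"
    # A tandem duplication's inserted bases equal the adjacent wild-type
    # copy; at the left-aligned placement the template copy lies 3' of the
    # insertion point (equivalently 5' at the rightmost placement).
    ni = len(inserted)
    is_dup = klass == "insertion" and (
        (start >= ni and wt[start - ni:start] == inserted)
        or wt[start:start + ni] == inserted)
    return CloneAlleleCall(
        clone_id, klass, net, inserted_seq=inserted, deleted_seq=deleted,
        is_duplication=is_dup, event_start=start, n_substitutions=n_subs,
        warnings=tuple(warnings))


def summarize_lesions(calls: list[CloneAlleleCall],
                      ci_level: float = 0.95) -> LesionSummary:
    """Somatic lesion frequency over a clone set, with Wilson interval.

    The Wilson score interval is used rather than the Wald interval because
    clone counts are small and observed frequencies are often near 0 or 1.
    The point frequency is reported in percent to one decimal.
    """
    if not calls:
        raise ValueError("empty call list")
    n_total = len(calls)
    n_mutant = sum(1 for c in calls if c.is_mutant)
    freq = round(100.0 * n_mutant / n_total, 1)
    lo, hi = proportion_confint(n_mutant, n_total, alpha=1 - ci_level,
                                method="wilson")
    ci_low, ci_high = 100.0 * lo, 100.0 * hi
    # one-decimal rounding of the point estimate must stay inside the CI
    ci_low, ci_high = min(ci_low, freq), max(ci_high, freq)
    return LesionSummary(n_mutant, n_total, freq, ci_low, ci_high)


def detection_power(p: float, n: int) -> float:
    """Probability of observing at least one mutant among ``n`` clones.

    With true lesion frequency ``p`` per clone, P(X >= 1) = 1 - (1-p)^n.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - p) ** n


def min_clones(p: float, confidence: float) -> int:
    """Smallest clone count whose detection power reaches ``confidence``.

    Closed form ceil(log(1-confidence) / log(1-p)), then verified against
    :func:`detection_power` to absorb floating-point boundary cases.
    """
    if not 0 < p < 1:
        raise ValueError("p must be strictly inside (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be strictly inside (0, 1)")
    n = max(1, math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p)))
    while n > 1 and detection_power(p, n - 1) >= confidence:
        n -= 1
    while detection_power(p, n) < confidence:
        n += 1
    return n
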