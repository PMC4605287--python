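"""Alignment and classification of AM profiles by cross-correlation.

A query profile (one imaged molecule) is compared to each reference
(theoretical barcode) by the maximum Pearson correlation over

* integer pixel shifts, subject to a minimum-overlap constraint,
* both molecule orientations (a molecule enters the channel either way),
* a grid of global stretch factors applied to the reference by linear
  interpolation (molecule-to-molecule stretching varies a few percent).

Pearson correlation is computed on the overlapping pixels only and is
invariant to affine intensity transforms, which is what makes a fixed CC
acceptance threshold (default 0.85) meaningful across molecules of
different brightness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AMProfile, DegenerateProfileError, NoValidAlignmentError

__all__ = [
    "UNCLASSIFIED",
    "MatchConfig",
    "MatchResult",
    "Assignment",
    "ClassificationReport",
    "PairedTTest",
    "znormalize",
    "cross_correlate",
    "classify",
    "classification_report",
    "paired_cc_test",
]

#: Sentinel assignment for molecules whose best CC fails the threshold.
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class MatchConfig:
    """Search-grid and acceptance parameters for profile matching."""

    cc_threshold: float = 0.85
    stretch_min: float = 0.94
    stretch_max: float = 1.06
    stretch_step: float = 0.005
    min_overlap_frac: float = 0.8
    try_both_orientations: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.cc_threshold <= 1.0:
            raise ValueError("cc_threshold must be in [-1, 1]")
        if not (0.0 < self.stretch_min <= self.stretch_max):
            raise ValueError("require 0 < stretch_min <= stretch_max")
        if not self.stretch_step > 0:
            raise ValueError("stretch_step must be positive")
        if not 0.0 < self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must be in (0, 1]")

    @property
    def stretch_grid(self) -> np.ndarray:
        n = int(math.floor((self.stretch_max - self.stretch_min) / self.stretch_step + 1e-9)) + 1
        return self.stretch_min + self.stretch_step * np.arange(n)


@dataclass(frozen=True)
class MatchResult:
    """Best alignment of one query against one reference."""

    reference_id: str
    cc: float
    shift_px: int
    orientation: str  # orientation of the query: '+' as given, '-' reversed
    stretch: float


def znormalize(profile: AMProfile) -> AMProfile:
    """Z-score a profile to mean 0, sd 1; idempotent up to round-off.

    Raises :class:`DegenerateProfileError` on zero-variance input.
    """
    v = profile.values
    sd = float(v.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateProfileError("cannot z-normalize a zero-variance profile")
    out = profile.copy_with((v - v.mean()) / sd, normalized=True)
    out.meta["znormalized"] = True
    return out


def _pearson_all_shifts(
    q: np.ndarray, r: np.ndarray, min_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between ``q`` and ``r`` at every integer shift.

    Shift ``t`` aligns query pixel 0 with reference pixel ``t``; the
    correlation uses only the overlapping pixels. Returns ``(shifts, cc)``
    with ``cc = -inf`` where the overlap is shorter than ``min_len`` or
    either window has zero variance.
    """
    Q, R = q.size, r.size
    t = np.arange(-(Q - 1), R)
    i0 = np.maximum(0, -t)
    i1 = np.minimum(Q, R - t)
    n = (i1 - i0).astype(float)

    pq = np.concatenate(([0.0], np.cumsum(q)))
    pqq = np.concatenate(([0.0], np.cumsum(q * q)))
    pr = np.concatenate(([0.0], np.cumsum(r)))
    prr = np.concatenate(([0.0], np.cumsum(r * r)))

    valid = i1 - i0 >= max(min_len, 2)
    i0c, i1c = np.where(valid, i0, 0), np.where(valid, i1, 0)
    a0, a1 = t + i0c, t + i1c
    a0 = np.clip(a0, 0, R)
    a1 = np.clip(a1, 0, R)

    Sq = pq[i1c] - pq[i0c]
    Sqq = pqq[i1c] - pqq[i0c]
    Sr = pr[a1] - pr[a0]
    Srr = prr[a1] - prr[a0]
    # zero-padded full cross-correlation equals the overlap sum q.r at each shift
    Sqr = np.correlate(r, q, mode="full")

    var_q = n * Sqq - Sq * Sq
    var_r = n * Srr - Sr * Sr
    den2 = np.maximum(var_q, 0.0) * np.maximum(var_r, 0.0)
    scale = np.max(den2) if den2.size else 0.0
    ok = valid & (den2 > 1e-24 * max(scale, 1e-300))
    cc = np.full(t.shape, -np.inf)
    num = n * Sqr - Sq * Sr
    # |r| <= 1 analytically; round-off can overshoot by ~1e-15
    cc[ok] = np.clip(num[ok] / np.sqrt(den2[ok]), -1.0, 1.0)
    return t, cc


def _resample(values: np.ndarray, stretch: float) -> np.ndarray:
    """Rescale a profile along its axis by ``stretch`` (linear interpolation)."""
    R = values.size
    n = max(2, int(round(R * stretch)))
    x = np.linspace(0.0, R - 1.0, n)
    return np.interp(x, np.arange(R), values)


def cross_correlate(
    query: AMProfile, reference: AMProfile, cfg: MatchConfig = MatchConfig()
) -> MatchResult:
    """Maximum Pearson CC of ``query`` against ``reference``.

    Searches all integer shifts with overlap >= ``min_overlap_frac`` times
    the query length, both orientations (if enabled) and every stretch on
    the config grid; the reference is resampled for each trial stretch.
    Ties are broken deterministically: smallest ``|shift|``, then '+'
    orientation, then stretch nearest 1.0.
    """
    if not math.isclose(query.bp_per_pixel, reference.bp_per_pixel, rel_tol=1e-9):
        raise ValueError(
            "query and reference must share a bp_per_pixel scale "
            f"({query.bp_per_pixel:g} vs {reference.bp_per_pixel:g})"
        )
    q = query.values.astype(float)
    min_len = int(math.ceil(cfg.min_overlap_frac * q.size))
    orientations = ("+", "-") if cfg.try_both_orientations else ("+",)

    best: tuple[float, float, int, float] | None = None  # sort key
    best_result: MatchResult | None = None
    any_valid = False
    ref_id = reference.genome_id or reference.meta.get("molecule_id", "")

    for stretch in cfg.stretch_grid:
        r = _resample(reference.values.astype(float), float(stretch))
        for orientation in orientations:
            qv = q if orientation == "+" else q[::-1]
            shifts, cc = _pearson_all_shifts(qv, r, min_len)
            if not np.any(np.isfinite(cc)):
                continue
            any_valid = True
            # per-combo argmax with |shift| (then signed shift) tie-break
            m = np.max(cc)
            cand = np.flatnonzero(cc == m)
            j = cand[np.lexsort((shifts[cand], np.abs(shifts[cand])))[0]]
            key = (float(cc[j]), -abs(int(shifts[j])), 1 if orientation == "+" else 0,
                   -abs(float(stretch) - 1.0))
            if best is None or key > best:
                best = key
                best_result = MatchResult(
                    reference_id=ref_id,
                    cc=float(cc[j]),
                    shift_px=int(shifts[j]),
                    orientation=orientation,
                    stretch=float(stretch),
                )
    if not any_valid or best_result is None:
        raise NoValidAlignmentError(
            "no shift satisfies the minimum-overlap constraint "
            f"(query {q.size} px, reference {reference.values.size} px, "
            f"min overlap {min_len} px)"
        )
    return best_result


@dataclass(frozen=True)
class Assignment:
    """Classification outcome of one query molecule."""

    reference_id: str  # winning reference id, or UNCLASSIFIED
    best: MatchResult
    cc_by_reference: dict[str, float]
    ambiguous: bool = False


def classify(
    query: AMProfile,
    references: list[AMProfile],
    cfg: MatchConfig = MatchConfig(),
) -> Assignment:
    """Assign a query to the reference with the highest CC.

    Only molecules whose winning CC exceeds ``cfg.cc_threshold`` (strictly)
    are accepted; otherwise the assignment is :data:`UNCLASSIFIED`. Exact
    CC ties across references are flagged ambiguous and resolved in
    reference list order.
    """
    if not references:
        raise ValueError("reference list must be non-empty")
    results = [cross_correlate(query, ref, cfg) for ref in references]
    ccs = [res.cc for res in results]
    top = max(ccs)
    winner_idx = ccs.index(top)  # first in list order on exact ties
    ambiguous = ccs.count(top) > 1
    best = results[winner_idx]
    assigned = best.reference_id if top > cfg.cc_threshold else UNCLASSIFIED
    return Assignment(
        reference_id=assigned,
        best=best,
        cc_by_reference={res.reference_id: res.cc for res in results},
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class ClassificationReport:
    """Per-reference histogram of assigned molecules with mean + 1 SD rule.

    References whose molecule count exceeds the histogram mean plus one
    sample standard deviation are reported as significantly detected.
    """

    assignments: dict[str, Assignment]
    histogram: dict[str, int]
    hist_mean: float
    hist_sd: float
    significant_refs: tuple[str, ...]

    @property
    def n_classified(self) -> int:
        return sum(self.histogram.values())

    @property
    def n_unclassified(self) -> int:
        return len(self.assignments) - self.n_classified


def classification_report(
    assignments: dict[str, Assignment], reference_ids: list[str]
) -> ClassificationReport:
    """Aggregate per-molecule assignments into the detection histogram.

    Zero-count references are included; ``hist_sd`` is the sample standard
    deviation (n-1 denominator) across all references.
    """
    counts = {rid: 0 for rid in reference_ids}
    n_classified = 0
    for a in assignments.values():
        if a.reference_id != UNCLASSIFIED:
            if a.reference_id not in counts:
                raise ValueError(f"assignment to unknown reference {a.reference_id!r}")
            counts[a.reference_id] += 1
            n_classified += 1
    if n_classified < 1:
        raise ValueError("need at least one classified molecule")
    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    significant = tuple(rid for rid in reference_ids if counts[rid] > mean + sd)
    return ClassificationReport(
        assignments=dict(assignments),
        histogram=counts,
        hist_mean=mean,
        hist_sd=sd,
        significant_refs=significant,
    )


@dataclass(frozen=True)
class PairedTTest:
    """Paired t-test result; ``degenerate`` marks an all-zero difference."""

    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_cc_test(cc_true: list[float], cc_false: list[float]) -> PairedTTest:
    """Paired t-test on per-molecule CC against true vs false reference.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on differences ``d_i``, df ``n-1``.
    A zero-variance difference with non-zero mean yields ``t = +/-inf`` and
    ``p = 0.0`` (below the machine floor); an identically zero difference is
    reported as degenerate rather than propagating NaN.
    """
    a = np.asarray(cc_true, dtype=float)
    b = np.asarray(cc_false, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("cc_true and cc_false must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        m = float(d.mean())
        if m == 0.0:
            return PairedTTest(t=float("nan"), p=float("nan"), n=n, degenerate=True)
        return PairedTTest(t=math.copysign(math.inf, m), p=0.0, n=n)
    res = stats.ttest_rel(a, b)
    return PairedTTest(t=float(res.statistic), p=float(res.pvalue), n=n)
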