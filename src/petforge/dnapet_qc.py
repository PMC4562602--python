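"""Mate-pair QC: pair classification, insert sizes, coverage tracks,
assembly-gap re-estimation (including bimodal cases) and breakpoint calls.

A pair is *concordant* when both tags map to the same reference, on the
same strand, in the correct 5'-to-3' ordering for the library geometry,
and the fragment span falls within the library's expected range.  Any
violation makes it discordant (same-reference or different-reference).

Gap lengths are re-estimated from pairs spanning exactly one gap: the
true length implied by one pair is

    annotated_len + (expected_insert_mean - observed_span)

i.e. a span shorter than expected means the gap is really longer than
annotated.  Per-gap estimates are aggregated as mean/median, with a
1-vs-2-component Gaussian mixture (BIC-selected) to flag biallelic gaps.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core_io import (
    AssemblyGap,
    GapEstimate,
    LibraryProfile,
    MappedTagPair,
    ScaffoldRecord,
)

__all__ = [
    "PetClass",
    "CoverageTrack",
    "Breakpoint",
    "classify_pair",
    "classify_pairs",
    "dedupe_pairs",
    "estimate_insert_size",
    "coverage_track",
    "per_base_fragment_coverage",
    "library_coverage_correlation",
    "estimate_gap_sizes",
    "estimate_gap_sizes_multilib",
    "detect_breakpoints",
]


class PetClass(enum.Enum):
    """Exhaustive, mutually exclusive mate-pair classes."""

    CPET = "cPET"
    DPET_SAME_REF = "dPET_same_ref"
    DPET_DIFF_REF = "dPET_diff_ref"


@dataclass
class CoverageTrack:
    """Windowed or per-base coverage of concordant pairs on one scaffold."""

    scaffold: str
    window_size: int
    step: int
    counts: np.ndarray
    mode: str  # "window_count" | "per_base_fragment"

    def __post_init__(self) -> None:
        if self.mode not in ("window_count", "per_base_fragment"):
            raise ValueError(f"unknown coverage mode {self.mode}")
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")


@dataclass
class Breakpoint:
    """Maximal interval of zero concordant-fragment coverage."""

    scaffold: str
    start: int
    end: int
    at_gap: AssemblyGap | None = None
    flanking_dpet_clusters: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(pair: MappedTagPair, lib: LibraryProfile) -> PetClass:
    """Classify one mapped pair against a library's span expectations."""
    t1, t2 = pair.tag1, pair.tag2
    if t1.ref != t2.ref:
        return PetClass.DPET_DIFF_REF
    if t1.strand != t2.strand:
        return PetClass.DPET_SAME_REF
    # correct 5'->3' ordering: on '+' the 5' tag precedes the 3' tag,
    # mirrored on '-'
    if t1.strand == "+":
        ordered = t1.start <= t2.start
    else:
        ordered = t2.start <= t1.start
    if not ordered:
        return PetClass.DPET_SAME_REF
    span = pair.span()
    if lib.concordant_span_min <= span <= lib.concordant_span_max:
        return PetClass.CPET
    return PetClass.DPET_SAME_REF


def classify_pairs(
    pairs: list[MappedTagPair], lib: LibraryProfile
) -> dict[PetClass, list[MappedTagPair]]:
    """Partition pairs into the three classes (counts always add up)."""
    out: dict[PetClass, list[MappedTagPair]] = {c: [] for c in PetClass}
    for p in pairs:
        out[classify_pair(p, lib)].append(p)
    return out


def dedupe_pairs(pairs: list[MappedTagPair]) -> list[MappedTagPair]:
    """Collapse duplicate pairs (identical tag coordinates), keeping first."""
    seen: set[tuple] = set()
    out = []
    for p in pairs:
        k = p.coord_key()
        if k not in seen:
            seen.add(k)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# insert size
# ---------------------------------------------------------------------------

def estimate_insert_size(
    cpets: list[MappedTagPair], trim_fraction: float = 0.05
) -> tuple[float, float]:
    """Trimmed mean and sd of concordant spans.  Requires >= 30 pairs."""
    if len(cpets) < 30:
        raise ValueError(f"need >= 30 concordant pairs, got {len(cpets)}")
    spans = np.array([p.span() for p in cpets], dtype=float)
    mean = float(sps.trim_mean(spans, trim_fraction))
    lo, hi = np.quantile(spans, [trim_fraction, 1 - trim_fraction])
    trimmed = spans[(spans >= lo) & (spans <= hi)]
    return mean, float(trimmed.std(ddof=1))


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def per_base_fragment_coverage(
    cpets: list[MappedTagPair], scaffold: ScaffoldRecord | str, length: int | None = None
) -> np.ndarray:
    """Count concordant fragments (tag1 start to tag2 end) covering each base."""
    if isinstance(scaffold, ScaffoldRecord):
        name, length = scaffold.name, scaffold.length
    else:
        name = scaffold
        if length is None:
            raise ValueError("length required when scaffold given by name")
    diff = np.zeros(length + 1, dtype=np.int64)
    for p in cpets:
        ref, s, e = p.fragment_interval()
        if ref != name:
            continue
        diff[max(0, s)] += 1
        diff[min(length, e)] -= 1
    return np.cumsum(diff[:-1])


def coverage_track(
    cpets: list[MappedTagPair],
    scaffold: ScaffoldRecord | str,
    window_size: int = 20_000,
    mode: str = "window_count",
    step: int | None = None,
    length: int | None = None,
) -> CoverageTrack:
    """Concordant-pair coverage on one scaffold.

    ``window_count`` counts pairs whose fragment overlaps each sliding
    window (step defaults to window_size/4); ``per_base_fragment`` counts
    fragments covering each base.
    """
    if isinstance(scaffold, ScaffoldRecord):
        name, length = scaffold.name, scaffold.length
    else:
        name = scaffold
        if length is None:
            raise ValueError("length required when scaffold given by name")
    if mode == "per_base_fragment":
        counts = per_base_fragment_coverage(cpets, name, length)
        return CoverageTrack(name, window_size, 1, counts, mode)
    if step is None:
        step = max(1, window_size // 4)
    window_size = min(window_size, length)
    n_windows = max(1, (length - window_size) // step + 1)
    counts = np.zeros(n_windows, dtype=np.int64)
    starts = np.arange(n_windows) * step
    for p in cpets:
        ref, s, e = p.fragment_interval()
        if ref != name:
            continue
        # windows [w, w+window_size) overlapping [s, e)
        first = max(0, (s - window_size) // step + 1)
        last = min(n_windows - 1, (e - 1) // step)
        if first <= last:
            counts[first:last + 1] += 1
    return CoverageTrack(name, window_size, step, counts, "window_count")


def library_coverage_correlation(
    track_a: CoverageTrack, track_b: CoverageTrack
) -> float:
    """Pearson r of two window tracks; NaN when either has zero variance."""
    if (track_a.scaffold != track_b.scaffold
            or track_a.window_size != track_b.window_size
            or track_a.step != track_b.step):
        raise ValueError("tracks must share scaffold and windowing")
    a = np.asarray(track_a.counts, float)
    b = np.asarray(track_b.counts, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# gap size estimation
# ---------------------------------------------------------------------------

def _fit_mixture(values: np.ndarray, *, min_sep_sd: float = 2.0,
                 min_weight: float = 0.15, random_state: int = 0):
    """1- vs 2-component Gaussian mixture by BIC.

    Returns a list of (mean, weight, n_eff) per accepted component,
    ordered by weight descending (the paper's alpha/beta populations).
    """
    from sklearn.mixture import GaussianMixture

    x = values.reshape(-1, 1)
    if len(values) < 8 or np.ptp(values) == 0:
        return [(float(values.mean()), 1.0, len(values))]
    g1 = GaussianMixture(1, random_state=random_state).fit(x)
    g2 = GaussianMixture(2, random_state=random_state, n_init=3).fit(x)
    if g2.bic(x) >= g1.bic(x):
        return [(float(values.mean()), 1.0, len(values))]
    means = g2.means_.ravel()
    weights = g2.weights_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    pooled_sd = float(np.sqrt(np.sum(weights * sds ** 2)))
    if (abs(means[0] - means[1]) <= min_sep_sd * pooled_sd
            or weights.min() < min_weight):
        return [(float(values.mean()), 1.0, len(values))]
    order = np.argsort(-weights)
    resp = g2.predict_proba(x)
    return [
        (float(means[i]), float(weights[i]), int(round(resp[:, i].sum())))
        for i in order
    ]


@dataclass
class GapSizeReport:
    """Per-run summary of gap re-estimation."""

    n_estimated: int = 0
    n_no_support: int = 0
    n_bimodal: int = 0
    assembly_size_delta: float = 0.0  # sum of (estimate - annotated)


def estimate_gap_sizes(
    cpets: list[MappedTagPair],
    gaps: list[AssemblyGap],
    lib: LibraryProfile,
    min_support: int = 5,
    *,
    expected_insert_mean: float | None = None,
) -> GapSizeReport:
    """Re-estimate gap lengths from concordant pairs spanning a single gap.

    Each usable pair overlaps exactly one gap and contains it fully; its
    implied length is ``annotated + expected_mean - observed_span``.
    Estimates (possibly two mixture components) are appended to each gap's
    ``estimates`` list; gaps with fewer than ``min_support`` pairs are
    left empty and counted.  ``expected_insert_mean`` defaults to the
    library's profile mean; pass the data-re-estimated trimmed mean when
    available.
    """
    mu = (lib.expected_insert_mean if expected_insert_mean is None
          else expected_insert_mean)
    return estimate_gap_sizes_multilib([(cpets, mu)], gaps, min_support)


def estimate_gap_sizes_multilib(
    datasets: list[tuple[list[MappedTagPair], float]],
    gaps: list[AssemblyGap],
    min_support: int = 5,
) -> GapSizeReport:
    """Pool single-gap-spanning pairs from several libraries.

    ``datasets`` is a list of (concordant pairs, expected insert mean);
    implied lengths are mean-corrected per library before pooling, so
    libraries of different insert sizes reinforce each other.
    """
    by_scaffold: dict[str, list[AssemblyGap]] = {}
    for g in gaps:
        g.estimates.clear()
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for gl in by_scaffold.values():
        gl.sort(key=lambda g: g.start)
    starts = {r: [g.start for g in gl] for r, gl in by_scaffold.items()}

    support: dict[int, list[float]] = {}
    for cpets, mu in datasets:
        for p in cpets:
            ref, fs, fe = p.fragment_interval()
            gl = by_scaffold.get(ref)
            if not gl:
                continue
            # gaps with any overlap with [fs, fe)
            i = bisect_left(starts[ref], fs)
            if i > 0 and gl[i - 1].end > fs:
                i -= 1
            j = bisect_right(starts[ref], fe - 1)
            touched = gl[i:j]
            if len(touched) != 1:
                continue
            g = touched[0]
            if not (fs <= g.start and g.end <= fe):
                continue  # partial overlap: not fully spanned
            implied = g.annotated_len + (mu - p.span())
            support.setdefault(id(g), []).append(implied)

    report = GapSizeReport()
    for gl in by_scaffold.values():
        for g in gl:
            vals = support.get(id(g))
            if not vals or len(vals) < min_support:
                report.n_no_support += 1
                continue
            arr = np.array(vals, dtype=float)
            comps = _fit_mixture(arr)
            if len(comps) == 1:
                g.estimates.append(
                    GapEstimate(float(arr.mean()), float(np.median(arr)),
                                len(arr), 1.0)
                )
            else:
                report.n_bimodal += 1
                # component medians from hard assignment to nearest mean
                means = np.array([c[0] for c in comps])
                assign = np.argmin(
                    np.abs(arr[:, None] - means[None, :]), axis=1)
                for k, (m, w, n_eff) in enumerate(comps):
                    members = arr[assign == k]
                    med = float(np.median(members)) if len(members) else m
                    g.estimates.append(
                        GapEstimate(m, med, max(1, n_eff), w)
                    )
            report.n_estimated += 1
            primary = g.estimates[0]
            report.assembly_size_delta += primary.mean_len - g.annotated_len
    return report


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def _zero_runs(cov: np.ndarray) -> list[tuple[int, int]]:
    zero = cov == 0
    if not zero.any():
        return []
    d = np.diff(zero.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if zero[0]:
        starts.insert(0, 0)
    if zero[-1]:
        ends.append(len(cov))
    return list(zip(starts, ends))


def detect_breakpoints(
    per_base_track: CoverageTrack,
    gaps: list[AssemblyGap],
    dpets: list[MappedTagPair],
    lib: LibraryProfile,
    *,
    terminal_margin: int | None = None,
) -> list[Breakpoint]:
    """Maximal zero-coverage intervals away from scaffold ends.

    Coverage geometrically drops to zero within ``concordant_span_max`` of
    each scaffold end, so zero runs are clipped to the interior before
    reporting.  Each breakpoint is annotated with the overlapping gap (if
    any) and the number of distinct other-reference discordant clusters
    within the margin on each side.
    """
    if per_base_track.mode != "per_base_fragment":
        raise ValueError("breakpoint detection requires per-base coverage")
    margin = terminal_margin if terminal_margin is not None else lib.concordant_span_max
    cov = np.asarray(per_base_track.counts)
    L = len(cov)
    lo, hi = margin, L - margin
    if hi <= lo:
        return []
    name = per_base_track.scaffold
    my_gaps = sorted((g for g in gaps if g.scaffold == name),
                     key=lambda g: g.start)
    out: list[Breakpoint] = []
    for s, e in _zero_runs(cov):
        s2, e2 = max(s, lo), min(e, hi)
        if s2 >= e2:
            continue
        at_gap = None
        for g in my_gaps:
            if g.start < e2 and s2 < g.end:
                at_gap = g
                break
        left_refs: set[str] = set()
        right_refs: set[str] = set()
        for p in dpets:
            for tag, other in ((p.tag1, p.tag2), (p.tag2, p.tag1)):
                if tag.ref != name or other.ref == name:
                    continue
                if s2 - margin <= tag.start < s2:
                    left_refs.add(other.ref)
                elif e2 <= tag.start < e2 + margin:
                    right_refs.add(other.ref)
        out.append(
            Breakpoint(name, s2, e2, at_gap, (len(left_refs), len(right_refs)))
        )
    return out
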