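"""Reliability and case-study statistics.

Inter-rater agreement on a segmentation is summarized by the Dice overlap of
the binarized foregrounds together with the difference in nucleus counts;
annotators are considered reliable once Dice >= 0.85 and the counts agree to
within one nucleus of the reference. Annotation-time comparisons between two
conditions use a two-tailed paired t-test with a Student-t 95% confidence
interval on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ShapeMismatchError, ValidationError
from .volume_io import LabelVolume

DEFAULT_DICE_THRESHOLD = 0.85
DEFAULT_COUNT_TOLERANCE = 1


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)


def dice(a, b) -> float:
    """Dice overlap 2|Fa n Fb| / (|Fa| + |Fb|) of the binarized foregrounds.

    Foreground is any voxel with label > 0. Two empty masks score 1.0 by
    convention.
    """
    fa = _as_array(a) > 0
    fb = _as_array(b) > 0
    if fa.shape != fb.shape:
        raise ShapeMismatchError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    na, nb = int(fa.sum()), int(fb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((fa & fb).sum()) / (na + nb)


def matched_region_dice(a: LabelVolume, b: LabelVolume) -> list[tuple[int, int, float]]:
    """Per-region Dice after greedy max-overlap matching of instance labels.

    Provided for diagnostics; the reliability gate itself uses the single
    foreground-binary :func:`dice`.
    """
    da, db = _as_array(a), _as_array(b)
    if da.shape != db.shape:
        raise ShapeMismatchError(f"shape mismatch: {da.shape} vs {db.shape}")
    both = (da > 0) & (db > 0)
    pairs, overlap = np.unique(
        np.stack([da[both], db[both]]), axis=1, return_counts=True
    )
    sizes_a = dict(zip(*np.unique(da[da > 0], return_counts=True)))
    sizes_b = dict(zip(*np.unique(db[db > 0], return_counts=True)))
    order = np.argsort(-overlap, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for idx in order:
        la, lb = int(pairs[0, idx]), int(pairs[1, idx])
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        d = 2.0 * int(overlap[idx]) / (int(sizes_a[la]) + int(sizes_b[lb]))
        matches.append((la, lb, d))
    return sorted(matches)


def count_regions(labels: LabelVolume) -> int:
    """Number of distinct positive labels present."""
    u = np.unique(_as_array(labels))
    return int((u > 0).sum())


@dataclass(frozen=True)
class ReliabilityReport:
    dice: float
    count_a: int
    count_b: int
    passed: bool
    dice_threshold: float = DEFAULT_DICE_THRESHOLD
    count_tolerance: int = DEFAULT_COUNT_TOLERANCE


def reliability_check(
    a: LabelVolume,
    b: LabelVolume,
    dice_threshold: float = DEFAULT_DICE_THRESHOLD,
    count_tolerance: int = DEFAULT_COUNT_TOLERANCE,
) -> ReliabilityReport:
    """Training reliability gate: Dice >= threshold AND counts within tolerance."""
    d = dice(a, b)
    ca, cb = count_regions(a), count_regions(b)
    passed = (d >= dice_threshold) and (abs(ca - cb) <= count_tolerance)
    return ReliabilityReport(
        dice=d,
        count_a=ca,
        count_b=cb,
        passed=passed,
        dice_threshold=dice_threshold,
        count_tolerance=count_tolerance,
    )


@dataclass(frozen=True)
class CaseStudyStats:
    """Paired comparison of per-image annotation times (minutes)."""

    mean_a: float
    mean_b: float
    mean_difference: float  # mean_a - mean_b
    percent_reduction: float  # 100 * (mean_a - mean_b) / mean_a, one decimal
    t_statistic: float
    p_value: float
    df: int
    ci95: tuple[float, float]
    n: int


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """Percent reduction 100 * (mean_a - mean_b) / mean_a, to one decimal."""
    if not mean_a > 0:
        raise ValidationError(f"mean_a must be positive, got {mean_a}")
    return round(100.0 * (mean_a - mean_b) / mean_a, 1)


def paired_t_test(times_a, times_b) -> CaseStudyStats:
    """Two-tailed paired t-test on per-image times, with a 95% CI (n-1 df).

    Degenerate case: if every difference is exactly zero, t is 0 and p is
    reported as exactly 1; a nonzero constant difference gives an infinite t,
    p = 0, and a point CI at the mean difference.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValidationError(f"paired samples must be equal-length vectors, got {a.shape} and {b.shape}")
    n = a.size
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing values are not allowed")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean_d == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if mean_d > 0 else -np.inf
            p = 0.0
        ci = (mean_d, mean_d)
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
        half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
        ci = (mean_d - half, mean_d + half)
    return CaseStudyStats(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=mean_d,
        percent_reduction=percent_reduction(float(a.mean()), float(b.mean())),
        t_statistic=t_stat,
        p_value=p,
        df=df,
        ci95=ci,
        n=n,
    )


def read_times_tsv(path) -> pd.Series:
    """Read a two-column TSV (image-id, minutes) into a Series indexed by id."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["image", "minutes"], comment="#")
    if frame["minutes"].isna().any():
        raise ValidationError(f"{path}: missing or non-numeric minutes")
    return frame.set_index("image")["minutes"].astype(float)


def paired_t_test_tables(path_a, path_b) -> CaseStudyStats:
    """Paired t-test on two timing tables, aligned on image id."""
    sa, sb = read_times_tsv(path_a), read_times_tsv(path_b)
    if set(sa.index) != set(sb.index):
        raise ValidationError("timing tables do not cover the same images")
    sb = sb.reindex(sa.index)
    return paired_t_test(sa.to_numpy(), sb.to_numpy())
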