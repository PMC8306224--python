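"""Pre/post-surgical statistics on region centralities.

The battery mirrors a classical non-parametric design: Wilcoxon signed-rank
tests for paired pre- vs post-surgical global centrality (pooled over the
ROIs of one region class across the cases of one surgery type, per band),
Wilcoxon rank-sum tests for between-group comparisons, and Spearman rank
correlations for covariates such as age, inter-EEG interval, drug load and
relative-power changes.  p < alpha (default 0.05) is called significant; no
multiple-testing correction is applied by default, a Holm option exists.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anatomy import ROILabeling
from .netmetrics import CentralityTable, centrality_delta

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"
NO_CHANGE = "no-change"

#: Largest number of non-zero pairs for which the signed-rank null is enumerated.
EXACT_SIGNED_RANK_MAX = 25
#: Largest combined sample size for which the rank-sum null is exact.
EXACT_RANK_SUM_MAX = 20
#: Largest n for which the Spearman null is a full permutation enumeration.
EXACT_SPEARMAN_MAX = 8


@dataclass
class StatResult:
    test: str
    n: int
    statistic: float
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _direction(effect: float, p: float, alpha: float) -> str:
    if p >= alpha or effect == 0:
        return NO_CHANGE
    return INCREASE if effect > 0 else DECREASE


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided signed-rank p by dynamic programming over sign patterns.

    Midranks can be half-integers, so everything is doubled to stay integral.
    The distribution of W+ under the symmetric null is the coefficient array
    of prod_i (1 + x^{2 r_i}) / 2^n.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    coeff = np.zeros(total + 1)
    coeff[0] = 1.0
    for r in doubled:
        coeff[r:] += coeff[:total + 1 - r].copy()
    coeff /= coeff.sum()
    w = int(round(2 * w_plus))
    p_low = coeff[:w + 1].sum()
    p_high = coeff[w:].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


def wilcoxon_signed_rank(pre, post, alpha: float = 0.05) -> StatResult:
    """Two-sided paired signed-rank test of post vs pre.

    Zero differences are dropped.  With <= 25 non-zero pairs the null
    distribution is enumerated exactly; above that a normal approximation
    with continuity and tie corrections is used.  The direction is the sign
    of the median difference when the test is significant.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult("wilcoxon-signed-rank", 0, 0.0, 1.0, NO_CHANGE)
    if n < 5:
        raise ValueError(f"need >= 5 non-zero pairs, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX:
        p = _signed_rank_exact_p(w_plus, ranks)
    else:
        mu = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
        shift = w_plus - mu
        z = (shift - 0.5 * np.sign(shift)) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    effect = float(np.median(post - pre))
    return StatResult("wilcoxon-signed-rank", n, w_plus, p,
                      _direction(effect, p, alpha))


def wilcoxon_rank_sum(a, b, alpha: float = 0.05) -> StatResult:
    """Two-sided rank-sum (Mann-Whitney) test of two independent samples.

    Exact null for combined n <= 20 without ties, normal approximation with
    tie correction otherwise.  Direction reports whether ``b`` sits above or
    below ``a`` when significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_RANK_SUM_MAX and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    effect = float(np.median(b) - np.median(a))
    return StatResult("wilcoxon-rank-sum", int(a.size + b.size),
                      float(res.statistic), float(res.pvalue),
                      _direction(effect, float(res.pvalue), alpha))


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    return float(np.corrcoef(x_ranks, y_ranks)[0, 1])


def spearman(x, y, alpha: float = 0.05) -> StatResult:
    """Spearman rank correlation with mid-rank ties.

    p comes from a full permutation enumeration for n <= 8 and from the
    t-approximation otherwise.  Constant input leaves the correlation
    undefined and is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Spearman test")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= EXACT_SPEARMAN_MAX:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return StatResult("spearman", n, rho, min(1.0, p), _direction(rho, p, alpha))


def holm(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; the default battery is
    uncorrected)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


# --- cohort-level containers and batteries ---------------------------------

SEIZURE_FREE = "seizure-free"
REPEATED_SURGERY = "repeated-surgery"

#: surgery_type -> (surgery index, pre timepoint, post timepoint, outcome)
SURGERY_TYPES: dict[str, tuple[int, str, str, str]] = {
    "first-successful": (1, "pre", "post", "good"),
    "first-failed": (1, "pre", "post", "poor"),
    "second-successful": (2, "post", "post2", "good"),
    "second-failed": (2, "post", "post2", "poor"),
}


@dataclass
class SurgeryCase:
    """One patient's centrality tables, resection labeling and metadata.

    ``centrality`` maps time point ('pre', 'post', 'post2') -> band name ->
    :class:`CentralityTable`; ``labeling`` maps surgery index (1 or 2) to the
    ROI classification for that resection; ``relative_power`` optionally maps
    time point -> per-ROI band-power DataFrame.
    """

    case_id: str
    group: str
    outcomes: dict[int, str]
    centrality: dict[str, dict[str, CentralityTable]]
    labeling: dict[int, ROILabeling]
    metadata: dict = field(default_factory=dict)
    relative_power: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (SEIZURE_FREE, REPEATED_SURGERY):
            raise ValueError(f"unknown group {self.group!r}")


def _cases_of_type(cases: list[SurgeryCase], surgery_type: str):
    if surgery_type not in SURGERY_TYPES:
        raise ValueError(f"unknown surgery type {surgery_type!r}")
    idx, tp_pre, tp_post, outcome = SURGERY_TYPES[surgery_type]
    for case in cases:
        if (case.outcomes.get(idx) == outcome
                and tp_pre in case.centrality and tp_post in case.centrality
                and idx in case.labeling):
            yield case, idx, tp_pre, tp_post


def compare_pre_post(cases: list[SurgeryCase], band: str, region_class: str,
                     surgery_type: str, alpha: float = 0.05) -> StatResult:
    """Signed-rank test of post vs pre global centrality for one stratum.

    Per-ROI (pre, post) pairs are pooled across all cases of the requested
    surgery type, restricted to the requested region class (relative to that
    surgery's resection) and frequency band.
    """
    pre_vals: list[float] = []
    post_vals: list[float] = []
    for case, idx, tp_pre, tp_post in _cases_of_type(cases, surgery_type):
        rois = case.labeling[idx].rois_in_class(region_class)
        tab_pre = case.centrality[tp_pre][band].to_frame()["global"]
        tab_post = case.centrality[tp_post][band].to_frame()["global"]
        for roi in rois:
            if roi in tab_pre.index and roi in tab_post.index:
                pre_vals.append(float(tab_pre[roi]))
                post_vals.append(float(tab_post[roi]))
    if not pre_vals:
        raise ValueError(
            f"no ROI pairs for stratum (band={band!r}, class={region_class!r}, "
            f"surgery={surgery_type!r})"
        )
    return wilcoxon_signed_rank(pre_vals, post_vals, alpha=alpha)


def _case_delta(case: SurgeryCase, band: str, surgery_index: int,
                region_class: str) -> float | None:
    idx_map = {1: ("pre", "post"), 2: ("post", "post2")}
    tp_pre, tp_post = idx_map[surgery_index]
    if tp_pre not in case.centrality or tp_post not in case.centrality:
        return None
    delta = centrality_delta(case.centrality[tp_pre][band],
                             case.centrality[tp_post][band])
    rois = [r for r in case.labeling[surgery_index].rois_in_class(region_class)
            if r in delta.index]
    if not rois:
        return None
    return float(delta[rois].mean())


def correlate_covariates(cases: list[SurgeryCase], covariate: str, response: str,
                         band: str, alpha: float = 0.05,
                         surgery_index: int = 1) -> StatResult:
    """Spearman correlation of a per-case covariate with a centrality response.

    Scalar covariates ('age', 'interval', 'n_aed') are paired with one value
    per case: the mean post-pre change in global centrality over far or
    adjacent regions ('mean_delta_far' / 'mean_delta_adjacent'), or the mean
    pre-surgical global centrality of the untouched regions ('centrality').
    The covariate 'delta_relative_power' is instead paired per ROI within
    each case (delta relative power vs delta global centrality) and pooled.
    Cases with a missing covariate or response are dropped with a warning.
    """
    idx_map = {1: ("pre", "post"), 2: ("post", "post2")}
    tp_pre, tp_post = idx_map[surgery_index]

    if covariate == "delta_relative_power":
        xs: list[float] = []
        ys: list[float] = []
        for case in cases:
            if tp_pre not in case.relative_power or tp_post not in case.relative_power:
                continue
            delta_c = centrality_delta(case.centrality[tp_pre][band],
                                       case.centrality[tp_post][band])
            delta_p = (case.relative_power[tp_post][band]
                       - case.relative_power[tp_pre][band])
            labeling = case.labeling[surgery_index]
            for cls in ("far", "adjacent"):
                for roi in labeling.rois_in_class(cls):
                    if roi in delta_c.index and roi in delta_p.index:
                        xs.append(float(delta_p[roi]))
                        ys.append(float(delta_c[roi]))
        if len(xs) < 4:
            raise ValueError("fewer than 4 ROI pairs with power and centrality")
        return spearman(xs, ys, alpha=alpha)

    cls = {"mean_delta_far": "far", "mean_delta_adjacent": "adjacent"}.get(response)
    xs, ys = [], []
    dropped = 0
    for case in cases:
        if covariate == "age":
            cov = case.metadata.get("age_years")
        elif covariate == "interval":
            cov = case.metadata.get("interval_years")
        elif covariate == "n_aed":
            cov = case.metadata.get("n_aed", {}).get(tp_pre)
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        if cls is not None:
            resp = _case_delta(case, band, surgery_index, cls)
        elif response == "centrality":
            labeling = case.labeling.get(surgery_index)
            if labeling is None or tp_pre not in case.centrality:
                resp = None
            else:
                tab = case.centrality[tp_pre][band].to_frame()["global"]
                rois = [r for c in ("far", "adjacent")
                        for r in labeling.rois_in_class(c) if r in tab.index]
                resp = float(tab[rois].mean()) if rois else None
        else:
            raise ValueError(f"unknown response {response!r}")
        if cov is None or resp is None:
            dropped += 1
            continue
        xs.append(float(cov))
        ys.append(resp)
    if dropped:
        logger.warning("dropped %d case(s) with missing covariate/response", dropped)
    if len(xs) < 4:
        raise ValueError("fewer than 4 complete cases for the correlation")
    return spearman(xs, ys, alpha=alpha)


def pre_post_table(cases: list[SurgeryCase], bands: list[str],
                   surgery_types: list[str] | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Frequency x region-class x surgery-type battery of signed-rank results."""
    surgery_types = surgery_types or list(SURGERY_TYPES)
    rows = []
    for band in bands:
        for region_class in ("adjacent", "far"):
            for st in surgery_types:
                try:
                    r = compare_pre_post(cases, band, region_class, st, alpha)
                except ValueError:
                    continue
                rows.append({"band": band, "region_class": region_class,
                             "surgery_type": st, "n_pairs": r.n,
                             "p_value": r.p_value, "direction": r.direction})
    return pd.DataFrame(rows)
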