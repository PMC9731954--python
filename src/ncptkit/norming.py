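"""Census-reweighted inverse normal transformation, Grand Index, and norms.

The normalization maps each oriented raw score to a normal scale (mean 100,
SD 15) through a rank-based inverse normal transformation (INT) in which each
observation's percentile "width" is reweighted by the ratio of its
demographic bin's reference-population proportion to its sample proportion.
For observation i in demographic bin k,

    w_i = f*_k / (N f_k)          (reweighted percentile width)
    r~_i = w_i / 2 + sum_{j<i} w_j   (over scores sorted ascending)
    y_i = Phi^-1(r~_i)            (normal quantile at mean 100, SD 15)

With f* = f this collapses to the standard centered-rank INT,
r~_i = (i - 0.5)/N.  The half-width term centers each percentile bin.
Normalized scores therefore express standing in the *reference* population
rather than in the (demographically skewed) observed sample.

The Grand Index (GI) is a battery-level composite: the mean of the
normalized subtest scores of a complete test run, itself re-mapped through
the same reweighted INT to mean 100, SD 15.  A GI of 100 is average
performance relative to the reference population.

Scores for time-scored subtests (go/no-go, trail making) are negated before
ranking so that higher always means better; released raw scores are never
negated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import K_BINS, ReferenceComposition, assign_bins
from .records import NormRow
from .registry import NEGATED_SUBTESTS, get_battery, get_subtest
from .binning import AGE_BIN_LABELS, EDU_BIN_LABELS

__all__ = [
    "orient_score",
    "orient_scores",
    "reweighted_ranks",
    "ReweightedNormalizer",
    "completeness_flags",
    "norm_sample_mask",
    "normalize_scores",
    "compute_grand_index",
    "compute_norm_tables",
    "NormalizationResult",
]

GI_NAME = "grand_index"


def orient_score(subtest_id: int, raw_score: float) -> float:
    """Orient a raw score so that higher always means better performance.

    Time-scored subtests (go/no-go 26/32, trail making 39/40) are negated;
    all other scores pass through unchanged.
    """
    get_subtest(subtest_id)  # validates the id
    return -raw_score if subtest_id in NEGATED_SUBTESTS else raw_score


def orient_scores(subtest_ids: Sequence[int], raw_scores: Sequence[float]) -> np.ndarray:
    sid = np.asarray(subtest_ids, dtype=int)
    raw = np.asarray(raw_scores, dtype=float)
    neg = np.isin(sid, list(NEGATED_SUBTESTS))
    return np.where(neg, -raw, raw)


def reweighted_ranks(
    bins_sorted: Sequence[int],
    sample_proportions: Sequence[float],
    reference: ReferenceComposition,
) -> tuple[np.ndarray, np.ndarray]:
    """Reweighted percentile widths w and centered ranks r~.

    Parameters
    ----------
    bins_sorted : flat demographic-bin index of each observation, given in
        ascending order of the oriented scores.
    sample_proportions : f_k, the sample proportion of each of the 18 bins
        (must be positive for every bin that occurs in ``bins_sorted``).
    reference : target proportions f*_k.

    Returns ``(w, r~)`` with w_i = f*_k/(N f_k) and
    r~_i = w_i/2 + sum_{j<i} w_j.  When every reference bin is present in
    the sample the widths sum to 1 and every r~ lies strictly inside (0, 1).
    """
    k = np.asarray(bins_sorted, dtype=int)
    if k.size == 0:
        return np.empty(0), np.empty(0)
    if (k < 0).any() or (k >= K_BINS).any():
        raise ValueError("observations must carry a valid demographic bin")
    f = np.asarray(sample_proportions, dtype=float)
    n = k.size
    present = np.bincount(k, minlength=K_BINS) > 0
    if (f[present] <= 0).any():
        raise ValueError("sample proportion f_k must be positive for every present bin")
    fstar = reference.proportions
    missing_mass = fstar[~present].sum()
    if missing_mass > 1e-12:
        warnings.warn(
            f"reference bins absent from the sample carry mass {missing_mass:.4g}; "
            "widths will sum to less than 1",
            stacklevel=2,
        )
    w = fstar[k] / (n * f[k])
    r = np.cumsum(w) - w / 2.0
    return w, r


def _collapse_ties(scores_sorted: np.ndarray, w: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Give every tied score the weight-averaged r~ of its tie group."""
    if scores_sorted.size == 0:
        return r
    boundaries = np.flatnonzero(np.diff(scores_sorted) != 0) + 1
    groups = np.concatenate([[0], boundaries, [scores_sorted.size]])
    out = r.copy()
    for a, b in zip(groups[:-1], groups[1:]):
        if b - a > 1:
            wg = w[a:b]
            total = wg.sum()
            out[a:b] = (wg * r[a:b]).sum() / total if total > 0 else r[a:b].mean()
    return out


@dataclass
class NormalizationResult:
    """Per-observation output of the reweighted INT, in input order."""

    w: np.ndarray
    r: np.ndarray
    y: np.ndarray
    target_mean: float = 100.0
    target_sd: float = 15.0


class ReweightedNormalizer:
    """Rank-based inverse normal transformation reweighted to a reference
    demographic composition.

    Fit on a norm sample of (oriented score, demographic bin) pairs; the
    fitted object maps any oriented score — in-sample or not — to a
    normalized score on the (target_mean, target_sd) normal scale.
    Out-of-sample scores are mapped by linear interpolation of the
    score -> r~ curve between adjacent sample points, clamped to
    [w_min/2, 1 - w_min/2] beyond the observed range.

    Tied raw scores receive the weight-averaged r~ of their tie group, so
    equal scores always receive equal normalized scores.
    """

    def __init__(self, reference: ReferenceComposition,
                 target_mean: float = 100.0, target_sd: float = 15.0,
                 tie_policy: str = "midrank"):
        if tie_policy not in ("midrank", "ordinal"):
            raise ValueError(f"unknown tie policy: {tie_policy!r}")
        self.reference = reference
        self.target_mean = float(target_mean)
        self.target_sd = float(target_sd)
        self.tie_policy = tie_policy
        self._knots_x: Optional[np.ndarray] = None
        self._knots_r: Optional[np.ndarray] = None
        self._w_min: Optional[float] = None

    def fit(self, scores: Sequence[float], bins: Sequence[int]) -> "ReweightedNormalizer":
        x = np.asarray(scores, dtype=float)
        k = np.asarray(bins, dtype=int)
        if x.shape != k.shape:
            raise ValueError("scores and bins must have equal length")
        if x.size == 0:
            raise ValueError("cannot fit a normalizer on an empty sample")
        if not np.isfinite(x).all():
            raise ValueError("scores must be finite")
        order = np.argsort(x, kind="stable")
        xs, ks = x[order], k[order]
        counts = np.bincount(ks, minlength=K_BINS)
        f = counts / ks.size
        w, r_raw = reweighted_ranks(ks, f, self.reference)
        r = _collapse_ties(xs, w, r_raw)
        # After tie collapsing, r is constant within tie groups: keep one knot
        # per unique score.
        uniq, first = np.unique(xs, return_index=True)
        self._knots_x = uniq
        self._knots_r = r[first]
        self._w_min = float(w.min())
        self._fit_w = w
        # "midrank" (default): tied scores share the weight-averaged rank;
        # "ordinal": in-sample ties keep their stable-sort prefix-sum ranks.
        self._fit_r = r if self.tie_policy == "midrank" else r_raw
        self._fit_order = order
        return self

    def _require_fit(self):
        if self._knots_x is None:
            raise RuntimeError("normalizer has not been fitted")

    def rank_transform(self, scores: Sequence[float]) -> np.ndarray:
        """Map oriented scores to reweighted ranks r~ in (0, 1)."""
        self._require_fit()
        x = np.asarray(scores, dtype=float)
        r = np.interp(x, self._knots_x, self._knots_r)
        lo, hi = self._w_min / 2.0, 1.0 - self._w_min / 2.0
        r = np.where(x < self._knots_x[0], min(lo, self._knots_r[0]), r)
        r = np.where(x > self._knots_x[-1], max(hi, self._knots_r[-1]), r)
        return r

    def transform(self, scores: Sequence[float]) -> np.ndarray:
        """Map oriented scores to the (target_mean, target_sd) normal scale."""
        r = self.rank_transform(scores)
        return stats.norm.ppf(r, loc=self.target_mean, scale=self.target_sd)

    def fit_transform_result(self, scores, bins) -> NormalizationResult:
        """Fit and return the full per-observation result in input order."""
        self.fit(scores, bins)
        n = len(self._fit_order)
        inv = np.empty(n, dtype=int)
        inv[self._fit_order] = np.arange(n)
        w = self._fit_w[inv]
        r = self._fit_r[inv]
        y = stats.norm.ppf(r, loc=self.target_mean, scale=self.target_sd)
        if ((r <= 0) | (r >= 1)).any():
            raise AssertionError("internal invariant violated: r~ outside (0, 1)")
        return NormalizationResult(w=w, r=r, y=y,
                                   target_mean=self.target_mean,
                                   target_sd=self.target_sd)

    def fit_transform(self, scores, bins) -> np.ndarray:
        return self.fit_transform_result(scores, bins).y


# ---------------------------------------------------------------------------
# Pipeline steps over released-schema score frames
# ---------------------------------------------------------------------------

def completeness_flags(frame: pd.DataFrame) -> dict[str, bool]:
    """Whether each test run contains exactly one score per battery subtest.

    The Grand Index is only defined for complete runs.  Duplicate
    (run, subtest) rows are a data-integrity error.
    """
    pair_sizes = frame.groupby(
        ["test_run_id", "specific_subtest_id"], sort=False).size()
    if (pair_sizes > 1).any():
        run_id, sid = pair_sizes[pair_sizes > 1].index[0]
        raise ValueError(f"test run {run_id!r} has duplicate rows for subtest {sid}")
    per_run = frame.groupby("test_run_id", sort=False).agg(
        battery_id=("battery_id", "first"), n=("specific_subtest_id", "size"))
    sizes = {}
    for bid in per_run["battery_id"].unique():
        battery = get_battery(int(bid))
        sizes[bid] = len(battery.subtest_ids)
        rows = frame["battery_id"] == bid
        bad = rows & ~frame["specific_subtest_id"].isin(battery.subtest_ids)
        if bad.any():
            sid = frame.loc[bad, "specific_subtest_id"].iloc[0]
            raise ValueError(f"subtest {sid} is not part of battery {bid}")
    # with no duplicates a run is complete iff it holds one row per battery subtest
    complete = per_run["n"] == per_run["battery_id"].map(sizes)
    return {str(r): bool(c) for r, c in complete.items()}


def norm_sample_mask(
    frame: pd.DataFrame,
    completeness: Mapping[str, bool],
    gameplay_counts: Optional[Mapping[str, int]] = None,
    max_gameplays: int = 25,
) -> pd.Series:
    """Row mask for the norm sample.

    The norm sample excludes participants who did not report age or
    education (or whose education is "Other", which belongs to no attainment
    bin), who logged more than ``max_gameplays`` training gameplays before
    the assessment, or who did not complete the entire battery.  When no
    gameplay counts are supplied, that criterion is skipped with a warning.
    """
    k = assign_bins(frame["age"], frame["education_level"])
    mask = pd.Series(k >= 0, index=frame.index)
    mask &= frame["test_run_id"].astype(str).map(lambda r: bool(completeness.get(r, False)))
    if gameplay_counts is None:
        warnings.warn(
            "no gameplay counts supplied; the >25-gameplays norm-sample "
            "exclusion is skipped",
            stacklevel=2,
        )
    else:
        plays = frame["user_id"].astype(str).map(lambda u: gameplay_counts.get(u, 0))
        mask &= plays <= max_gameplays
    return mask


def normalize_scores(
    frame: pd.DataFrame,
    reference: ReferenceComposition,
    completeness: Optional[Mapping[str, bool]] = None,
    gameplay_counts: Optional[Mapping[str, int]] = None,
    target_mean: float = 100.0,
    target_sd: float = 15.0,
    tie_policy: str = "midrank",
) -> tuple[pd.DataFrame, dict[int, ReweightedNormalizer]]:
    """Attach a ``normalized_score`` column to a released-schema frame.

    One reweighted INT is fitted per subtest version on the norm sample
    (versions of the same task are never pooled); every row — norm sample or
    not — is then mapped through its subtest's fitted curve.  Returns the
    augmented copy of the frame and the per-subtest normalizers.
    """
    if completeness is None:
        completeness = completeness_flags(frame)
    mask = norm_sample_mask(frame, completeness, gameplay_counts)
    out = frame.copy()
    out["normalized_score"] = np.nan
    normalizers: dict[int, ReweightedNormalizer] = {}
    k_all = assign_bins(frame["age"], frame["education_level"])
    oriented = orient_scores(frame["specific_subtest_id"].to_numpy(dtype=int),
                             frame["raw_score"].to_numpy(dtype=float))
    for sid in sorted(set(int(s) for s in frame["specific_subtest_id"])):
        sel = (frame["specific_subtest_id"].to_numpy(dtype=int) == sid)
        fit_sel = sel & mask.to_numpy() & (k_all >= 0)
        if not fit_sel.any():
            warnings.warn(f"subtest {sid}: empty norm sample; scores left unnormalized",
                          stacklevel=2)
            continue
        nz = ReweightedNormalizer(reference, target_mean, target_sd, tie_policy)
        nz.fit(oriented[fit_sel], k_all[fit_sel])
        out.loc[sel, "normalized_score"] = nz.transform(oriented[sel])
        normalizers[sid] = nz
    return out, normalizers


def compute_grand_index(
    normalized_frame: pd.DataFrame,
    reference: ReferenceComposition,
    completeness: Optional[Mapping[str, bool]] = None,
    gameplay_counts: Optional[Mapping[str, int]] = None,
    target_mean: float = 100.0,
    target_sd: float = 15.0,
    tie_policy: str = "midrank",
) -> pd.Series:
    """Grand Index per test run (missing for incomplete runs).

    The per-run mean of normalized subtest scores is re-mapped through a
    second census-reweighted INT, fitted per battery on the norm-sample runs
    and applied to every complete run (runs with unbinnable demographics are
    mapped by interpolation).  Requires a frame that already carries
    ``normalized_score``.
    """
    if "normalized_score" not in normalized_frame.columns:
        raise ValueError("frame must carry a 'normalized_score' column; "
                         "run normalize_scores first")
    frame = normalized_frame
    if completeness is None:
        completeness = completeness_flags(frame)
    mask = norm_sample_mask(frame, completeness, gameplay_counts)

    runs = frame.groupby("test_run_id", sort=False).agg(
        battery_id=("battery_id", "first"),
        age=("age", "first"),
        education_level=("education_level", "first"),
        mean_norm=("normalized_score", "mean"),
        any_nan=("normalized_score", lambda s: s.isna().any()),
    )
    runs["complete"] = [bool(completeness.get(str(r), False)) for r in runs.index]
    run_in_norm = frame.loc[mask, "test_run_id"].astype(str).unique()
    runs["in_norm_sample"] = runs.index.astype(str).isin(run_in_norm)

    gi = pd.Series(np.nan, index=runs.index, name=GI_NAME)
    for bid, grp in runs.groupby("battery_id", sort=False):
        usable = grp["complete"] & ~grp["any_nan"]
        fit_grp = grp[usable & grp["in_norm_sample"]]
        if fit_grp.empty:
            continue
        k_fit = assign_bins(fit_grp["age"], fit_grp["education_level"])
        keep = k_fit >= 0
        nz = ReweightedNormalizer(reference, target_mean, target_sd, tie_policy)
        nz.fit(fit_grp["mean_norm"].to_numpy(dtype=float)[keep], k_fit[keep])
        apply_grp = grp[usable]
        gi.loc[apply_grp.index] = nz.transform(apply_grp["mean_norm"].to_numpy(dtype=float))
    return gi


def _direction_percentiles(values: np.ndarray, negate: bool,
                           percs=(10, 25, 50, 75, 90)) -> list[float]:
    """Raw-score values at performance percentiles.

    A higher percentile always indicates better performance, so for
    subtests where lower raw scores are better (times), the p-th
    performance percentile is the (100-p)-th raw-score quantile.
    """
    out = []
    for p in percs:
        q = (100 - p) / 100.0 if negate else p / 100.0
        out.append(float(np.quantile(values, q, method="linear")))
    return out


def compute_norm_tables(
    frame: pd.DataFrame,
    gi: Optional[pd.Series] = None,
    gender_set: Sequence[str] = ("m", "f"),
    min_bin_n: int = 20,
    completeness: Optional[Mapping[str, bool]] = None,
    gameplay_counts: Optional[Mapping[str, int]] = None,
) -> dict[int, list[NormRow]]:
    """Normative tables per battery over 36 demographic bins.

    Bins are the 18 age x education cells additionally partitioned by
    gender.  A battery's norms are emitted only when every
    (subtest x bin) cell — Grand Index included — holds at least
    ``min_bin_n`` participants.  All summary statistics are computed on raw
    scores; percentiles follow the higher-is-better performance convention.
    """
    if completeness is None:
        completeness = completeness_flags(frame)
    mask = norm_sample_mask(frame, completeness, gameplay_counts)
    gset = {g.lower() for g in gender_set}
    gender = frame["gender"].astype("string").str.lower()
    mask &= gender.isin(gset).fillna(False).astype(bool)
    df = frame[mask].copy()
    if df.empty:
        return {}
    if gi is None:
        gi = df.groupby("test_run_id", sort=False)["grand_index"].first()
    k = assign_bins(df["age"], df["education_level"])
    df["_age_bin"] = k // 3
    df["_edu_bin"] = k % 3
    df["_gender"] = gender[mask].str.lower()

    tables: dict[int, list[NormRow]] = {}
    cells = [(a, e, g) for a in range(6) for e in range(3) for g in sorted(gset)]
    for bid, bgrp in df.groupby("battery_id", sort=False):
        bid = int(bid)
        battery = get_battery(bid)
        rows: list[NormRow] = []
        ok = True
        for sid in battery.subtest_ids:
            sgrp = bgrp[bgrp["specific_subtest_id"] == sid]
            for a, e, g in cells:
                cell = sgrp[(sgrp["_age_bin"] == a) & (sgrp["_edu_bin"] == e)
                            & (sgrp["_gender"] == g)]
                if len(cell) < min_bin_n:
                    ok = False
                    break
                vals = cell["raw_score"].to_numpy(dtype=float)
                p10, p25, p50, p75, p90 = _direction_percentiles(
                    vals, sid in NEGATED_SUBTESTS)
                rows.append(NormRow(
                    subtest_name=get_subtest(sid).short_name,
                    specific_subtest_id=sid,
                    age=AGE_BIN_LABELS[a],
                    education_level=EDU_BIN_LABELS[e],
                    gender=g,
                    N=len(cell),
                    mean=float(vals.mean()),
                    SD=float(vals.std(ddof=1)),
                    perc_10=p10, perc_25=p25, perc_50=p50, perc_75=p75, perc_90=p90,
                ))
            if not ok:
                break
        if ok:
            # Grand Index rows over the same 36 cells (one value per run).
            per_run = bgrp.groupby("test_run_id", sort=False).agg(
                _age_bin=("_age_bin", "first"), _edu_bin=("_edu_bin", "first"),
                _gender=("_gender", "first"))
            per_run[GI_NAME] = [gi.get(r, np.nan) for r in per_run.index]
            per_run = per_run.dropna(subset=[GI_NAME])
            for a, e, g in cells:
                cell = per_run[(per_run["_age_bin"] == a) & (per_run["_edu_bin"] == e)
                               & (per_run["_gender"] == g)]
                if len(cell) < min_bin_n:
                    ok = False
                    break
                vals = cell[GI_NAME].to_numpy(dtype=float)
                p10, p25, p50, p75, p90 = _direction_percentiles(vals, False)
                rows.append(NormRow(
                    subtest_name=GI_NAME, specific_subtest_id=None,
                    age=AGE_BIN_LABELS[a], education_level=EDU_BIN_LABELS[e],
                    gender=g, N=len(cell),
                    mean=float(vals.mean()), SD=float(vals.std(ddof=1)),
                    perc_10=p10, perc_25=p25, perc_50=p50, perc_75=p75, perc_90=p90,
                ))
        if ok:
            tables[bid] = rows
    return tables
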