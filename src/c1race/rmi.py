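"""Redundant-target behavior: gains, race-model inequality, permutation test.

The race model inequality (RMI) bounds the reaction-time benefit that two
parallel sensory channels can produce by statistical facilitation alone:
``F_AV(t) ≤ F_A(t) + F_V(t)`` for every t, where the F are the cumulative
RT distributions to auditory-target, visual-target and double-target
stimuli.  Violations are measured geometrically as the nonnegative area
``∫ max[F_AV − F_A − F_V, 0] dt`` (ms) and tested two ways: a group-level
cluster-based sign-flip permutation test on the violation profile over the
5th–30th percentiles, and a Bayesian test asking whether the per-participant
areas sit further from zero than an exponential prior with the data's
variance predicts.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bayes import (
    InferenceResult,
    ModelSpec,
    bayes_factor_directional,
    decide,
    gibbs_exponential_intercept,
    gibbs_lmm,
    rope_test,
)

logger = logging.getLogger(__name__)

#: Percentile grid of the permutation test (5th–30th, step 5).
DEFAULT_PERCENTILES = (5, 10, 15, 20, 25, 30)

#: RT classes entering the race-model comparison: bimodal stimuli where only
#: the auditory, only the visual, or both components are targets.
RMI_CLASSES = ("AT_V0", "A0_VT", "AT_VT")

GAIN_CLASSES = ("A_T", "AT_V0", "V_T", "A0_VT")


# --------------------------------------------------------------------------
# Performance and gain
# --------------------------------------------------------------------------

def performance_rates(rts: pd.DataFrame,
                      window: tuple[float, float] | None = None) -> pd.DataFrame:
    """Hit and false-positive rates per participant.

    A trial counts as responded when ``rt_ms`` is present (and inside
    ``window`` when one is given).  Hits are responded targets / targets;
    false positives are responded standards / standards.
    """
    df = rts.copy()
    responded = df["rt_ms"].notna()
    if window is not None:
        lo, hi = window
        responded &= (df["rt_ms"] >= lo) & (df["rt_ms"] <= hi)
    df["_responded"] = responded
    rows = []
    for pid, sub in df.groupby("participant", sort=True):
        targets = sub[sub["is_target"].astype(bool)]
        standards = sub[~sub["is_target"].astype(bool)]
        if len(targets) == 0:
            raise ValueError(f"no target trials for participant {pid}")
        rows.append(dict(
            participant=pid,
            hit_rate=float(targets["_responded"].mean()),
            false_positive_rate=(float(standards["_responded"].mean())
                                 if len(standards) else np.nan),
            n_targets=len(targets), n_standards=len(standards),
        ))
    return pd.DataFrame(rows)


def redundancy_gain(rts: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Redundancy gain: fastest single-target class mean minus the
    double-target mean, ``gain_AV = min(RT̄_AT, RT̄_ATV0, RT̄_VT, RT̄_A0VT) −
    RT̄_ATVT`` (ms, may be negative).

    ``scope`` is 'participant' (one row each) or 'group' (pooled trials).
    """
    if scope not in ("participant", "group"):
        raise ValueError("scope must be 'participant' or 'group'")
    df = rts[rts["rt_ms"].notna()]

    def one(sub, label):
        means = {}
        for cls in GAIN_CLASSES + ("AT_VT",):
            x = sub.loc[sub["stimulus"] == cls, "rt_ms"]
            if len(x) == 0:
                raise ValueError(f"empty RT class {cls!r} ({label})")
            means[cls] = float(x.mean())
        gain = min(means[c] for c in GAIN_CLASSES) - means["AT_VT"]
        return dict(scope=label, gain_av_ms=gain, **{
            f"mean_{c.lower()}": means[c] for c in GAIN_CLASSES + ("AT_VT",)})

    if scope == "group":
        return pd.DataFrame([one(df, "group")])
    rows = [dict(participant=pid, **one(sub, pid))
            for pid, sub in df.groupby("participant", sort=True)]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CDF estimation and violation area
# --------------------------------------------------------------------------

class CDFTriple(NamedTuple):
    """The three RT CDFs evaluated on a common time grid, plus the raw
    samples they came from."""

    percentiles: np.ndarray
    t: np.ndarray
    f_a: np.ndarray
    f_v: np.ndarray
    f_av: np.ndarray
    samples: dict


def interp_ecdf(sample: np.ndarray, t) -> np.ndarray:
    """Empirical CDF by linear interpolation between order statistics
    (inverse of the type-7 quantile convention; ties average)."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size == 1:
        return (np.asarray(t, dtype=float) >= x[0]).astype(float)
    probs = np.arange(x.size) / (x.size - 1)
    return np.interp(t, x, probs, left=0.0, right=1.0)


def estimate_cdfs(rt_a, rt_v, rt_av,
                  percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                  min_trials: int = 10) -> CDFTriple:
    """Evaluate F_A, F_V, F_AV at the pooled-percentile time points.

    The time grid is the type-7 quantile of the pooled sample (all three
    classes together) at each requested percentile, so the three CDFs are
    compared at identical times.
    """
    samples = {"A": np.asarray(rt_a, float), "V": np.asarray(rt_v, float),
               "AV": np.asarray(rt_av, float)}
    for k, v in samples.items():
        if v.size < min_trials:
            raise InsufficientTrialsError(
                f"class {k}: {v.size} correct RTs < required {min_trials}")
    pooled = np.concatenate(list(samples.values()))
    pct = np.asarray(percentiles, dtype=float)
    t = np.quantile(pooled, pct / 100.0)  # linear interpolation (type 7)
    return CDFTriple(
        percentiles=pct, t=t,
        f_a=interp_ecdf(samples["A"], t),
        f_v=interp_ecdf(samples["V"], t),
        f_av=interp_ecdf(samples["AV"], t),
        samples=samples,
    )


class InsufficientTrialsError(ValueError):
    """Raised when an RT class has too few correct trials for CDF work."""


def violation_area_from_grids(t, f_a, f_v, f_av) -> float:
    """Trapezoidal integral of max(F_AV − F_A − F_V, 0) over the grid (ms)."""
    t = np.asarray(t, float)
    for f in (f_a, f_v, f_av):
        f = np.asarray(f, float)
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("non-monotone CDF input")
        if np.any((f < -1e-12) | (f > 1 + 1e-12)):
            raise ValueError("CDF values outside [0, 1]")
    excess = np.maximum(np.asarray(f_av, float) - np.asarray(f_a, float)
                        - np.asarray(f_v, float), 0.0)
    return float(np.trapezoid(excess, t))


def rmi_violation_area(cdfs: CDFTriple, resolution_ms: float = 1.0) -> float:
    """Nonnegative RMI violation area from the raw samples of a triple.

    The interpolated empirical CDFs are integrated on a dense grid
    (``resolution_ms``) spanning the pooled RT range; zero when the
    inequality holds everywhere.
    """
    pooled = np.concatenate(list(cdfs.samples.values()))
    lo, hi = float(pooled.min()), float(pooled.max())
    grid = np.arange(lo, hi + resolution_ms, resolution_ms)
    return violation_area_from_grids(
        grid,
        interp_ecdf(cdfs.samples["A"], grid),
        interp_ecdf(cdfs.samples["V"], grid),
        interp_ecdf(cdfs.samples["AV"], grid),
    )


def violation_profiles(
    rts: pd.DataFrame,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    min_trials: int = 10,
    by_congruence: bool = True,
) -> pd.DataFrame:
    """Per participant (× congruence): violation profile d(t) = F_AV − F_A −
    F_V on the percentile grid, plus the dense violation area (ms).

    Participants with fewer than ``min_trials`` correct RTs in any class are
    excluded with a logged reason.
    """
    df = rts[rts["rt_ms"].notna() & rts["correct"].astype(bool)]
    keys = ["participant", "congruence"] if by_congruence else ["participant"]
    rows = []
    group_cols = df.groupby(keys, sort=True)
    for key, sub in group_cols:
        key = key if isinstance(key, tuple) else (key,)
        if by_congruence and key[1] == "none":
            continue
        cls = {c: sub.loc[sub["stimulus"] == c, "rt_ms"].to_numpy()
               for c in RMI_CLASSES}
        try:
            triple = estimate_cdfs(cls["AT_V0"], cls["A0_VT"], cls["AT_VT"],
                                   percentiles, min_trials)
        except InsufficientTrialsError as err:
            logger.info("excluding %s from RMI analysis: %s", key, err)
            continue
        d = triple.f_av - triple.f_a - triple.f_v
        row = dict(zip(keys, key))
        row.update({f"d_p{int(p)}": float(v)
                    for p, v in zip(triple.percentiles, d)})
        row["violation_area_ms"] = rmi_violation_area(triple)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cluster-based sign-flip permutation test
# --------------------------------------------------------------------------

def _t_onesample(x: np.ndarray) -> np.ndarray:
    """One-sample t statistics per column; zero-variance columns map to
    ±inf (sign of the mean) or 0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    t[zero] = np.where(mean[zero] > 0, np.inf,
                       np.where(mean[zero] < 0, -np.inf, 0.0))
    return t


def _clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal runs of adjacent grid points with t > threshold; mass = sum t."""
    out = []
    start = None
    for i, above in enumerate(t > threshold):
        if above and start is None:
            start = i
        elif not above and start is not None:
            out.append((start, i - 1, float(t[start:i].sum())))
            start = None
    if start is not None:
        out.append((start, len(t) - 1, float(t[start:].sum())))
    return out


def cluster_permutation_test(
    profiles: np.ndarray,
    n_perm: int = 10_001,
    alpha_cluster: float = 0.05,
    cluster_forming_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Group-level test for positive RMI violation profiles.

    At each grid point a one-sided one-sample t statistic across
    participants tests E[d(t)] > 0; clusters are maximal runs of adjacent
    points with t above the one-sided critical value at
    ``cluster_forming_alpha`` (n−1 df); cluster mass is the sum of t inside.
    The null distribution is the maximum cluster mass over ``n_perm`` random
    whole-profile sign flips, and each cluster's p-value is
    ``(1 + #{perm ≥ observed}) / (n_perm + 1)``.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n, k = profiles.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if np.all(profiles == 0):
        return {"clusters": [], "min_p": 1.0, "threshold": np.nan,
                "significant": False, "n_perm": n_perm}
    threshold = float(stats.t.ppf(1.0 - cluster_forming_alpha, df=n - 1))

    t_obs = _t_onesample(profiles)
    observed = _clusters(t_obs, threshold)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # sufficient statistics under sign flips: column sums and sums of squares
    sumsq = np.sum(profiles**2, axis=0)
    flip_sums = signs @ profiles  # (n_perm, k)
    mean = flip_sums / n
    var = (sumsq[None, :] - n * mean**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean / np.sqrt(var / n)
    zero = var <= 0
    t_perm[zero] = np.where(mean[zero] > 0, np.inf,
                            np.where(mean[zero] < 0, -np.inf, 0.0))

    # max cluster mass per permutation via a running-sum sweep over columns
    above = t_perm > threshold
    run = np.zeros(n_perm)
    max_mass = np.zeros(n_perm)
    for j in range(k):
        contrib = np.where(above[:, j], t_perm[:, j], 0.0)
        run = np.where(above[:, j], run + contrib, 0.0)
        max_mass = np.maximum(max_mass, run)

    clusters = []
    for start, end, mass in observed:
        # tolerance keeps exact ties (e.g. the identity sign pattern) in the
        # exceedance count despite float-path differences; errs conservative
        tol = 1e-9 * (1.0 + abs(mass)) if np.isfinite(mass) else 0.0
        exceed = int(np.sum(max_mass >= mass - tol))
        p = (1 + exceed) / (n_perm + 1)
        clusters.append({"start": start, "end": end, "mass": mass, "p": p})
    min_p = min((c["p"] for c in clusters), default=1.0)
    return {"clusters": clusters, "min_p": min_p, "threshold": threshold,
            "significant": min_p <= alpha_cluster, "n_perm": n_perm}


def bh_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up decisions and monotone adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# --------------------------------------------------------------------------
# Exponential-null Bayesian test on violation areas
# --------------------------------------------------------------------------

def exponential_null_test(areas: pd.DataFrame, spec: ModelSpec | None = None,
                          response: str = "violation_area_ms") -> InferenceResult:
    """Are the nonnegative violation areas distributed further from zero
    than an exponential with the data's variance predicts?

    An intercept model with participant grouping is fitted to the areas
    under an Exponential(λ) prior on the intercept, with λ chosen so the
    prior variance 1/λ² equals the sample variance of the areas.  BF_10 is
    the Savage–Dickey density ratio at intercept = 0 (the prior density
    there is exactly λ); the ROPE test uses 0.1 × SD(areas).  When the table
    carries 2-level ``group`` and ``congruence`` columns, a factorial model
    with the standard normal-prior rule is fitted as well and per-factor
    BF_10 values are reported.
    """
    spec = spec or ModelSpec()
    y = areas[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("violation areas must be nonnegative")
    if len(areas["participant"].unique()) < 2:
        raise ValueError("need at least 2 participants")
    sd = float(np.std(y, ddof=1))
    rope_h = 0.1 * sd

    if sd == 0.0:
        if np.allclose(y, 0.0):
            # all-zero areas: the null is exactly recovered
            summary = pd.DataFrame([dict(
                parameter="intercept", mean=0.0, hdi_low=0.0, hdi_high=0.0,
                bf_plus0=0.0, bf_10=0.0, rope_halfwidth=0.0,
                frac_hdi_in_rope=1.0, decision_one_sided="absent-evidence",
                decision_two_sided="absent-evidence", effect_d=0.0,
                prior_sd=np.nan, data_sd=0.0)])
            return InferenceResult(summary, {}, {"degenerate": True})
        raise ValueError("zero variance in areas")

    rate = 1.0 / sd
    participants = sorted(areas["participant"].astype(str).unique())
    g = areas["participant"].astype(str).map(
        {p: i for i, p in enumerate(participants)}).to_numpy()
    per_participant = np.bincount(g).max()
    use_groups = per_participant >= 2  # random intercept needs replication

    fit = gibbs_exponential_intercept(
        y, rate, g if use_groups else None,
        draws=spec.draws, warmup=spec.warmup, seed=spec.seed)
    bf10 = rate / max(fit["posterior_density_at_zero"], 1e-300)
    rope = rope_test(fit["beta0"], rope_h)
    resid_sd = float(np.mean(np.sqrt(fit["sigma2"])))
    rows = [dict(
        parameter="intercept", mean=float(np.mean(fit["beta0"])),
        hdi_low=rope["hdi_low"], hdi_high=rope["hdi_high"],
        bf_plus0=bf10, bf_10=bf10, rope_halfwidth=rope_h,
        frac_hdi_in_rope=rope["frac_hdi_in_rope"],
        decision_one_sided=decide(bf10, rope),
        decision_two_sided=decide(bf10, rope),
        effect_d=float(np.mean(fit["beta0"])) / resid_sd,
        prior_sd=sd, data_sd=sd,
    )]
    draws = {"intercept": fit["beta0"], "sigma2": fit["sigma2"]}
    diagnostics = {"prior_rate": rate, "random_intercept": use_groups}

    # factorial companion model (Group × Congruence), normal-prior rule
    factors = [c for c in ("group", "congruence") if c in areas.columns
               and areas[c].nunique() == 2]
    if len(factors) == 2:
        Xcols, names = [np.ones(len(y))], ["intercept"]
        coded = {}
        for f in factors:
            levels = sorted(areas[f].astype(str).unique())
            coded[f] = np.where(areas[f].astype(str) == levels[1], 0.5, -0.5)
            Xcols.append(coded[f])
            names.append(f)
        Xcols.append(coded[factors[0]] * coded[factors[1]] * 2.0)
        names.append("group:congruence")
        X = np.column_stack(Xcols)
        prior_sds = np.array([spec.intercept_scale * sd]
                             + [spec.prior_scale * sd] * 3)
        ffit = gibbs_lmm(y, X, prior_sds, g if use_groups else None,
                         spec.draws, spec.warmup, spec.seed)
        for j, nm in enumerate(names):
            if nm == "intercept":
                continue
            bf_plus0_f, bf10_f = bayes_factor_directional(
                ffit["beta"][:, j], prior_sds[j])
            rp = rope_test(ffit["beta"][:, j], rope_h)
            rows.append(dict(
                parameter=nm, mean=float(np.mean(ffit["beta"][:, j])),
                hdi_low=rp["hdi_low"], hdi_high=rp["hdi_high"],
                bf_plus0=bf_plus0_f, bf_10=bf10_f, rope_halfwidth=rope_h,
                frac_hdi_in_rope=rp["frac_hdi_in_rope"],
                decision_one_sided=decide(bf_plus0_f, rp),
                decision_two_sided=decide(bf10_f, rp),
                effect_d=np.nan, prior_sd=prior_sds[j], data_sd=sd,
            ))
            draws[nm] = ffit["beta"][:, j]

    return InferenceResult(pd.DataFrame(rows), draws, diagnostics)
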