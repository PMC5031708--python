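"""Per-edge group inference: repeated-measures ANOVA, bootstrap-averaged
effect sizes, and the condition-scramble permutation decision rule.

Model
-----
For every directed edge, each of N participants contributes one Granger
weight per condition (own-race, other-race) plus a continuous age.  A
two-level within-subject factor reduces the repeated-measures ANOVA exactly
to two ordinary regressions on per-participant scores:

* mean score  M_i = (own_i + other_i)/2  regressed on centered age -> the
  **age** main effect (slope test);
* difference score  D_i = own_i - other_i  regressed on centered age -> the
  **race** main effect (intercept test, i.e. the race difference at the
  cohort mean age) and the **race x age interaction** (slope test).

Each F has df (1, N-2) and partial eta-squared equals F/(F + N - 2).
``D_i`` is also the per-participant *neural other-race effect* (NORE), whose
Pearson correlation with age quantifies the developmental trend of the race
difference.

Decision procedure
------------------
Following the bootstrap-averaging scheme: the observed statistic per effect
is the mean partial eta-squared over B random 50% participant subsamples
(drawn without replacement).  Its significance is judged against a
permutation null built by scrambling each participant's two condition labels
with a fair coin (for the race and interaction effects) or by permuting ages
across participants (for the age effect, which condition scrambling cannot
touch because participant means are invariant to it).  An effect is declared
significant when the observed average lies strictly in the top 5% of the
null distribution.

Two null flavors are provided.  ``null_stat="averaged"`` (default) makes
each null replicate the same statistic as the observed one - a
subsample-averaged effect size after scrambling - which gives the rule its
nominal 5% level.  ``null_stat="subsample"`` records one single-subsample
effect size per scrambled replicate; because a single draw spreads more
widely than an average of draws, comparing the observed average against this
null is conservative (empirical type-I well below 5%).  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, PreconditionError

__all__ = [
    "EffectTest",
    "rm_anova_2xcontinuous",
    "partial_eta_sq",
    "bootstrap_effect_size",
    "permutation_null",
    "significance_decision",
    "nore",
    "pearson_r",
    "behavioral_anova",
    "posthoc_ttests",
    "null_rejection_rate",
    "RaceAgeAnova",
    "RaceAgeAnovaResults",
]

EFFECTS = ("age", "race", "interaction")
EffectName = Literal["age", "race", "interaction"]
NullStat = Literal["averaged", "subsample"]


class EffectTest(NamedTuple):
    F: float
    eta2: float
    df1: int
    df2: int

    @property
    def p(self) -> float:
        return float(sps.f.sf(self.F, self.df1, self.df2))


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise PreconditionError("F statistic must be non-negative")
    if df1 < 1 or df2 < 1:
        raise PreconditionError("degrees of freedom must be >= 1")
    return float(F * df1) / (F * df1 + df2)


def _validate(y_own, y_other, age) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y_own = np.asarray(y_own, dtype=float)
    y_other = np.asarray(y_other, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (len(y_own) == len(y_other) == len(age)):
        raise PreconditionError("y_own, y_other and age must have equal length")
    if len(age) < 4:
        raise PreconditionError("need at least 4 participants")
    if np.var(age) == 0:
        raise DegenerateInputError("age has zero variance")
    return y_own, y_other, age


def _slope_F(y: np.ndarray, agec: np.ndarray) -> tuple[float, float]:
    """(F, eta2) for the slope of y ~ 1 + agec; eta2 is the squared
    correlation."""
    n = len(y)
    syy = float(np.var(y))
    sxx = float(np.var(agec))
    sxy = float(np.mean(y * agec) - y.mean() * agec.mean())
    if syy == 0:
        return 0.0, 0.0
    r2 = sxy * sxy / (sxx * syy)
    r2 = min(r2, 1.0)
    if r2 >= 1.0:
        return np.inf, 1.0
    F = (n - 2) * r2 / (1.0 - r2)
    return F, r2


def _intercept_F(y: np.ndarray, agec: np.ndarray) -> tuple[float, float]:
    """(F, eta2) for the intercept of y ~ 1 + agec with centered age."""
    n = len(y)
    ybar = float(y.mean())
    sxx = float(np.var(agec))
    sxy = float(np.mean(y * agec) - y.mean() * agec.mean())
    rss = n * (float(np.var(y)) - (sxy * sxy / sxx if sxx > 0 else 0.0))
    rss = max(rss, 0.0)
    num = n * ybar * ybar
    if rss == 0:
        return (np.inf, 1.0) if num > 0 else (0.0, 0.0)
    F = num / (rss / (n - 2))
    eta2 = num / (num + rss)
    return F, eta2


def rm_anova_2xcontinuous(y_own, y_other, age) -> dict[str, EffectTest]:
    """Repeated-measures ANOVA, 2-level within factor x continuous age.

    Returns ``{"age": ..., "race": ..., "interaction": ...}`` with F,
    partial eta-squared and df (1, N-2) per effect.  Age is centered at the
    analyzed sample's mean, so the race effect is evaluated at the mean age.
    """
    y_own, y_other, age = _validate(y_own, y_other, age)
    n = len(age)
    agec = age - age.mean()
    M = 0.5 * (y_own + y_other)
    D = y_own - y_other
    f_age, e_age = _slope_F(M, agec)
    f_race, e_race = _intercept_F(D, agec)
    f_int, e_int = _slope_F(D, agec)
    df2 = n - 2
    return {
        "age": EffectTest(f_age, e_age, 1, df2),
        "race": EffectTest(f_race, e_race, 1, df2),
        "interaction": EffectTest(f_int, e_int, 1, df2),
    }


def nore(y_own, y_other) -> np.ndarray:
    """Per-participant neural other-race effect: own - other weight."""
    y_own = np.asarray(y_own, dtype=float)
    y_other = np.asarray(y_other, dtype=float)
    if len(y_own) != len(y_other):
        raise PreconditionError("equal lengths required")
    return y_own - y_other


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise PreconditionError("need equal-length vectors with N >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# vectorized subsample machinery


def _draw_subsets(rng: np.random.Generator, n: int, size: int, b: int) -> np.ndarray:
    """(b, size) index rows, each a uniform subset drawn without replacement."""
    return np.argsort(rng.random((b, n)), axis=1)[:, :size]


def _subset_eta2(y: np.ndarray, age: np.ndarray, idx: np.ndarray,
                 kind: str) -> np.ndarray:
    """Vectorized per-subset partial eta-squared.

    ``y``: scores, either (n,) shared across rows or (..., n) broadcast
    against ``idx``'s leading axes; ``idx``: (..., size) subset indices;
    ``kind``: "slope" or "intercept".
    """
    ys = np.take(y, idx) if y.ndim == 1 else np.take_along_axis(y, idx, axis=-1)
    xs = np.take(age, idx)
    m = idx.shape[-1]
    xm = xs.mean(axis=-1, keepdims=True)
    xc = xs - xm
    ym = ys.mean(axis=-1)
    sxx = np.einsum("...i,...i->...", xc, xc) / m
    sxy = np.einsum("...i,...i->...", xc, ys) / m
    syy = ys.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "slope":
            eta2 = np.where(
                (sxx > 0) & (syy > 0), (sxy * sxy) / (sxx * syy), 0.0
            )
            return np.clip(eta2, 0.0, 1.0)
        rss = m * np.maximum(syy - np.where(sxx > 0, sxy * sxy / sxx, 0.0), 0.0)
        num = m * ym * ym
        denom = num + rss
        return np.where(denom > 0, num / denom, 0.0)


_EFFECT_KIND = {"age": ("M", "slope"), "race": ("D", "intercept"),
                "interaction": ("D", "slope")}


def bootstrap_effect_size(
    y_own, y_other, age, b: int = 10_000, frac: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Bootstrap-averaged partial eta-squared per effect.

    Draws ``b`` subsets of ``floor(frac*N)`` participants without
    replacement, runs the reduced RM-ANOVA on each, and returns the mean
    partial eta-squared per effect.  Deterministic under a fixed seed.
    """
    y_own, y_other, age = _validate(y_own, y_other, age)
    n = len(age)
    size = int(np.floor(frac * n))
    if size < 4:
        raise PreconditionError("subsample size floor(frac*N) must be >= 4")
    if b < 1:
        raise PreconditionError("b must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _draw_subsets(rng, n, size, b)
    scores = {"M": 0.5 * (y_own + y_other), "D": y_own - y_other}
    out = {}
    for effect in EFFECTS:
        score, kind = _EFFECT_KIND[effect]
        out[effect] = float(_subset_eta2(scores[score], age, idx, kind).mean())
    return out


def _null_replicates(
    score: np.ndarray, age: np.ndarray, kind: str, scramble: str,
    b: int, size: int, rng: np.random.Generator,
    null_stat: NullStat, b_inner: int,
) -> np.ndarray:
    """Null distribution replicates for one effect.

    ``scramble`` is "flip" (fair-coin per-participant condition scrambling,
    applied to difference scores) or "age" (permute ages across
    participants).  With ``null_stat="averaged"`` each replicate is a mean
    over ``b_inner`` fresh subsamples of the scrambled cohort; with
    "subsample" it is a single subsample statistic.
    """
    n = len(age)
    inner = b_inner if null_stat == "averaged" else 1
    null = np.empty(b)
    chunk = max(1, int(2_000_000 // max(1, inner * size)))
    for start in range(0, b, chunk):
        m = min(chunk, b - start)
        if scramble == "flip":
            signs = rng.integers(0, 2, size=(m, n)) * 2.0 - 1.0
            y = signs * score[None, :]
            a = age
        else:
            y = np.take(score, np.argsort(rng.random((m, n)), axis=1))
            a = age  # permuting scores against fixed ages == permuting ages
        idx = _draw_subsets(rng, n, size, m * inner).reshape(m, inner, size)
        eta = _subset_eta2(y[:, None, :], a, idx, kind)
        null[start:start + m] = eta.mean(axis=1)
    return null


def permutation_null(
    y_own, y_other, age, b: int = 10_000, frac: float = 0.5,
    seed: int | np.random.Generator = 0,
    effects: Sequence[str] = EFFECTS,
    null_stat: NullStat = "averaged", b_inner: int = 100,
) -> dict[str, np.ndarray]:
    """Permutation null distributions of the (averaged) effect size.

    Race and interaction nulls scramble each participant's own/other labels
    with a fair coin; the age null permutes ages across participants
    (condition scrambling leaves participant means untouched, so it carries
    no information about the age effect).
    """
    y_own, y_other, age = _validate(y_own, y_other, age)
    n = len(age)
    size = int(np.floor(frac * n))
    if size < 4:
        raise PreconditionError("subsample size floor(frac*N) must be >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = {"M": 0.5 * (y_own + y_other), "D": y_own - y_other}
    out = {}
    for effect in effects:
        score, kind = _EFFECT_KIND[effect]
        scramble = "age" if effect == "age" else "flip"
        out[effect] = _null_replicates(
            scores[score], age, kind, scramble, b, size, rng, null_stat, b_inner
        )
    return out


def perm_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + B)."""
    null = np.asarray(null, dtype=float)
    return float(1 + np.sum(null >= observed)) / (1 + len(null))


def significance_decision(observed: float, null: np.ndarray) -> bool:
    """Top-5% rule: observed strictly exceeds the empirical 95th percentile."""
    null = np.asarray(null, dtype=float)
    if len(null) == 0:
        raise PreconditionError("empty null distribution")
    return bool(observed > np.quantile(null, 0.95))


def behavioral_anova(records: pd.DataFrame | Sequence) -> dict[str, EffectTest]:
    """RM-ANOVA on recognition accuracy (race within, continuous age between).

    ``records`` is a DataFrame with columns age, acc_own, acc_other (or a
    sequence of objects with those attributes).
    """
    if isinstance(records, pd.DataFrame):
        age = records["age"].to_numpy()
        own = records["acc_own"].to_numpy()
        other = records["acc_other"].to_numpy()
    else:
        age = np.array([r.age for r in records], dtype=float)
        own = np.array([r.acc_own for r in records], dtype=float)
        other = np.array([r.acc_other for r in records], dtype=float)
    if np.any((own < 0) | (own > 1) | (other < 0) | (other > 1)):
        raise PreconditionError("accuracies must lie in [0, 1]")
    return rm_anova_2xcontinuous(own, other, age)


class PosthocResult(NamedTuple):
    paired_t_younger: tuple[float, float]
    paired_t_older: tuple[float, float]
    twosample_t_own: tuple[float, float]
    twosample_t_other: tuple[float, float]
    split_age: float


def posthoc_ttests(y_own, y_other, age, split: float | None = None) -> PosthocResult:
    """Post-hoc t tests after a significant interaction.

    Paired t (own minus other) within the younger and older age groups, and
    two-sample t (younger minus older) per condition.  ``split`` defaults to
    the cohort median age; participants at or below the split are "younger".
    """
    y_own, y_other, age = _validate(y_own, y_other, age)
    split_age = float(np.median(age)) if split is None else float(split)
    young = age <= split_age
    old = ~young
    if young.sum() < 2 or old.sum() < 2:
        raise PreconditionError("both age groups must have >= 2 members")
    def _paired(a, b):
        if np.ptp(a - b) == 0 and np.allclose(a, b):
            return 0.0, 1.0  # identical conditions: no race difference
        r = sps.ttest_rel(a, b)
        return float(r.statistic), float(r.pvalue)

    pt_y = _paired(y_own[young], y_other[young])
    pt_o = _paired(y_own[old], y_other[old])
    ts_own = sps.ttest_ind(y_own[young], y_own[old])
    ts_other = sps.ttest_ind(y_other[young], y_other[old])
    as_pair = lambda r: (float(r.statistic), float(r.pvalue))
    return PosthocResult(pt_y, pt_o, as_pair(ts_own),
                         as_pair(ts_other), split_age)


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class RaceAgeAnovaResults:
    """Results of :class:`RaceAgeAnova`.

    ``effects`` maps effect name to :class:`EffectTest`; when the model was
    fitted with resampling, ``boot_mean_eta2``, ``perm_p`` and
    ``significant`` are populated per effect.
    """

    nobs: int
    effects: dict[str, EffectTest]
    nore_r: float
    nore_p: float
    boot_mean_eta2: dict[str, float] | None = None
    perm_p: dict[str, float] | None = None
    significant: dict[str, bool] | None = None
    null_dists: dict[str, np.ndarray] | None = None
    resampling: dict | None = None

    def summary(self) -> str:
        lines = [
            "Repeated-measures race x continuous-age ANOVA",
            f"N participants: {self.nobs}   df per effect: (1, {self.nobs - 2})",
            f"{'effect':<12}{'F':>10}{'p':>10}{'eta_p^2':>10}"
            + ("" if self.boot_mean_eta2 is None
               else f"{'boot eta2':>11}{'perm p':>9}{'sig':>5}"),
        ]
        for name, eff in self.effects.items():
            row = f"{name:<12}{eff.F:>10.3f}{eff.p:>10.4f}{eff.eta2:>10.4f}"
            if self.boot_mean_eta2 is not None:
                row += (f"{self.boot_mean_eta2[name]:>11.4f}"
                        f"{self.perm_p[name]:>9.4f}"
                        f"{str(self.significant[name]):>5}")
            lines.append(row)
        lines.append(f"NORE-age Pearson r = {self.nore_r:.4f} (p = {self.nore_p:.4g})")
        return "\n".join(lines)


class RaceAgeAnova:
    """Two-condition repeated-measures model for one dependent variable.

    Parameters
    ----------
    y_own, y_other : array-like, shape (N,)
        Per-participant values under the own- and other-race conditions
        (Granger weights of one edge, or accuracies).
    age : array-like, shape (N,)
        Participant ages in years.
    """

    def __init__(self, y_own, y_other, age):
        self.y_own, self.y_other, self.age = _validate(y_own, y_other, age)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, own: str = "y_own",
                       other: str = "y_other", age: str = "age") -> "RaceAgeAnova":
        return cls(df[own].to_numpy(), df[other].to_numpy(), df[age].to_numpy())

    def fit(
        self,
        b_boot: int = 0,
        b_perm: int = 0,
        frac: float = 0.5,
        seed: int | np.random.Generator | None = None,
        null_stat: NullStat = "averaged",
        b_inner: int = 100,
    ) -> RaceAgeAnovaResults:
        """Fit the ANOVA; with ``b_boot``/``b_perm`` > 0 also run the
        bootstrap-averaged effect sizes and the permutation decision rule."""
        effects = rm_anova_2xcontinuous(self.y_own, self.y_other, self.age)
        d = nore(self.y_own, self.y_other)
        if np.var(d) > 0:
            r, p = pearson_r(self.age, d)
        else:
            r, p = 0.0, 1.0
        res = RaceAgeAnovaResults(
            nobs=len(self.age), effects=effects, nore_r=r, nore_p=p
        )
        if b_boot > 0 and b_perm > 0:
            rng = (seed if isinstance(seed, np.random.Generator)
                   else np.random.default_rng(seed))
            boot = bootstrap_effect_size(self.y_own, self.y_other, self.age,
                                         b=b_boot, frac=frac, seed=rng)
            nulls = permutation_null(self.y_own, self.y_other, self.age,
                                     b=b_perm, frac=frac, seed=rng,
                                     null_stat=null_stat, b_inner=b_inner)
            res.boot_mean_eta2 = boot
            res.perm_p = {e: perm_pvalue(boot[e], nulls[e]) for e in EFFECTS}
            res.significant = {e: significance_decision(boot[e], nulls[e])
                               for e in EFFECTS}
            res.null_dists = nulls
            res.resampling = {"b_boot": b_boot, "b_perm": b_perm, "frac": frac,
                              "null_stat": null_stat, "b_inner": b_inner}
        return res


def null_rejection_rate(
    n_cohorts: int = 200,
    n_participants: int = 124,
    age_range: tuple[float, float] = (3.25, 13.49),
    b_boot: int = 500,
    b_perm: int = 500,
    frac: float = 0.5,
    effect: EffectName = "interaction",
    seed: int = 0,
    null_stat: NullStat = "averaged",
    b_inner: int = 100,
) -> float:
    """Empirical type-I rate of the edge decision rule on pure-null cohorts.

    Each cohort draws per-participant own/other weights i.i.d. from the same
    distribution (no condition, age, or interaction effect) with ages uniform
    on ``age_range``, runs the full bootstrap + permutation procedure, and
    applies the top-5% rule to ``effect``.  Returns the fraction of cohorts
    declared significant.
    """
    from .synthcohort import simulate_null_weights

    master = np.random.SeedSequence(seed)
    hits = 0
    for ss in master.spawn(n_cohorts):
        rng = np.random.default_rng(ss)
        w_own, w_other, ages = simulate_null_weights(n_participants, rng,
                                                     age_range=age_range)
        res = RaceAgeAnova(w_own, w_other, ages).fit(
            b_boot=b_boot, b_perm=b_perm, frac=frac, seed=rng,
            null_stat=null_stat, b_inner=b_inner,
        )
        hits += int(res.significant[effect])
    return hits / n_cohorts
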