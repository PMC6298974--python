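"""Signal-detection analysis of figure-detection behaviour.

The pipeline mirrors standard Go/No-Go psychophysics practice: reaction
times are corrected for sound-output latency, anticipatory responses
(faster than 0.4 s after stimulus onset) are excluded, hit and false-alarm
rates are tabulated per coherence level, and sensitivity is summarized as

    d' = Z(hit rate) - Z(false-alarm rate)

with Z the standard-normal quantile function.  Per-coherence statistics
receive percentile-bootstrap confidence intervals; trends over coherence
are fitted with a second-order polynomial; and the effect of coherence on
d', mean reaction time and reaction-time variability is tested across
sessions with a one-way repeated-measures ANOVA, guarded by Mauchly's
sphericity test with the conservative lower-bound degrees-of-freedom
correction when sphericity is violated.

The module-level functions implement the individual operations; the
:class:`DetectionModel` / :class:`DetectionResults` pair wraps them into a
fit-and-summarize workflow over a collection of sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session import SessionData, TrialRecord
from .stimgen import ParameterError

__all__ = [
    "CoherenceSummary",
    "AnovaResult",
    "correct_rt_latency",
    "exclude_fast_responses",
    "exclusion_fraction",
    "rates_by_coherence",
    "dprime",
    "response_variability",
    "bootstrap_ci",
    "fit_poly2",
    "rm_anova",
    "DetectionModel",
    "DetectionResults",
]


@dataclass
class CoherenceSummary:
    """Behavioural statistics for one coherence level (one session or pooled)."""

    coherence: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    mean_rt: float
    rt_variability: float
    n_trials: int
    n_hits: int = 0
    ci: dict = field(default_factory=dict)  # statistic -> (low, high)


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA output with sphericity diagnostics."""

    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float
    sphericity_violated: bool
    mauchly_W: float
    mauchly_p: float
    ks_normal_p: tuple[float, ...]
    correction: str = "none"


# ---------------------------------------------------------------------------
# trial-level preprocessing


def correct_rt_latency(rt: float, output_latency: float) -> float:
    """Subtract the sound-output latency of the presentation system.

    A response earlier than the latency itself is physically impossible
    and marks a corrupt trial.
    """
    if rt < output_latency:
        raise ParameterError(
            f"response at {rt} s precedes the {output_latency} s output latency"
        )
    return rt - output_latency


def apply_latency_correction(session: SessionData, output_latency: float) -> SessionData:
    """Latency-correct every response time in a session (new SessionData).

    Trials whose response precedes the latency are flagged excluded.
    """
    if output_latency == 0.0:
        return session
    trials: list[TrialRecord] = []
    for t in session.trials:
        if t.response_time is None:
            trials.append(t)
        elif t.response_time < output_latency:
            trials.append(dc_replace_trial(t, excluded=True))
        else:
            trials.append(dc_replace_trial(t, response_time=t.response_time - output_latency))
    return SessionData(session.session_id, session.subject_id, trials,
                       session.design, session.observer)


def dc_replace_trial(t: TrialRecord, **kw) -> TrialRecord:
    d = dict(t.__dict__)
    d.update(kw)
    return TrialRecord(**d)


def exclude_fast_responses(session: SessionData, threshold: float = 0.4) -> SessionData:
    """Flag trials with responses faster than ``threshold`` after stimulus onset.

    The comparison is strict (`response_time < threshold`); flagged trials
    are removed from every downstream rate.  Use
    :func:`exclusion_fraction` to report the excluded proportion.
    """
    if threshold < 0:
        raise ParameterError("exclusion threshold must be non-negative")
    trials = [
        dc_replace_trial(t, excluded=True)
        if (t.response_time is not None and t.response_time < threshold)
        else t
        for t in session.trials
    ]
    return SessionData(session.session_id, session.subject_id, trials,
                       session.design, session.observer)


def exclusion_fraction(session: SessionData) -> float:
    """Proportion of trials flagged as excluded."""
    if not session.trials:
        return 0.0
    return sum(t.excluded for t in session.trials) / len(session.trials)


# ---------------------------------------------------------------------------
# rates and sensitivity


def dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Sensitivity index d' = Z(hit rate) - Z(false-alarm rate).

    Perfect rates (0 or 1) would map to infinite quantiles; they are
    nudged to ``1/(2n)`` and ``1 - 1/(2n)`` first (the Macmillan-Creelman
    convention), with ``n`` the trial count behind the rate.
    """
    for r in (hit_rate, fa_rate):
        if not (0.0 <= r <= 1.0):
            raise ParameterError(f"rate {r} outside [0, 1]")

    def adjust(rate: float, n: int) -> float:
        if rate in (0.0, 1.0):
            if n <= 0:
                raise ParameterError("edge rate needs a positive trial count")
            return 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)
        return rate

    return float(
        stats.norm.ppf(adjust(hit_rate, n_signal)) - stats.norm.ppf(adjust(fa_rate, n_noise))
    )


def response_variability(rts) -> float:
    """Response variability: sample standard deviation of hit reaction times.

    The summary statistic is deliberately simple — the SD (ddof=1) of the
    hit RTs within one coherence level of one session.  Undefined for
    fewer than two values.
    """
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 2:
        raise ParameterError("variability needs at least two reaction times")
    return float(np.std(rts, ddof=1))


def rates_by_coherence(session: SessionData) -> list[CoherenceSummary]:
    """Per-coherence hit rates, d', and hit-RT summaries for one session.

    Hit rate is hits / (hits + misses) within each coherence level; the
    false-alarm rate is false alarms on catch trials / catch trials — one
    session-level value repeated on every row.  Pre-figure releases on
    figure trials are labelled false alarms but are *not* part of the FA
    denominator; they simply drop out of hits + misses.  Reaction times
    are measured from figure onset.  Excluded trials contribute nowhere.
    """
    kept = [t for t in session.trials if not t.excluded]
    catch = [t for t in kept if t.condition == "catch"]
    n_catch = len(catch)
    n_catch_fa = sum(t.outcome == "false_alarm" for t in catch)
    fa_rate = n_catch_fa / n_catch if n_catch else np.nan

    levels = sorted({t.coherence for t in kept if t.condition == "figure"})
    out: list[CoherenceSummary] = []
    for c in levels:
        trials = [t for t in kept if t.condition == "figure" and t.coherence == c]
        hits = [t for t in trials if t.outcome == "hit"]
        misses = [t for t in trials if t.outcome == "miss"]
        n_hm = len(hits) + len(misses)
        if n_hm == 0 or n_catch == 0:
            warnings.warn(f"coherence {c}: empty denominator, level omitted")
            continue
        hit_rate = len(hits) / n_hm
        rts = np.array([t.response_time - t.figure_onset for t in hits])
        out.append(
            CoherenceSummary(
                coherence=int(c),
                hit_rate=hit_rate,
                fa_rate=fa_rate,
                d_prime=dprime(hit_rate, fa_rate, n_hm, n_catch),
                mean_rt=float(rts.mean()) if len(rts) else np.nan,
                rt_variability=response_variability(rts) if len(rts) >= 2 else np.nan,
                n_trials=n_hm,
                n_hits=len(hits),
            )
        )
    return out


# ---------------------------------------------------------------------------
# uncertainty and trend


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 5000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval.

    ``n_boot`` resamples (with replacement) of ``values`` are drawn, the
    statistic is computed on each, and the interval endpoints are the
    order statistics at (1-based) ranks ``ceil(alpha/2 * n_boot)`` and
    ``floor((1 - alpha/2) * n_boot)`` of the sorted bootstrap
    distribution.  Deterministic given ``rng``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ParameterError("bootstrap needs at least two values")
    if n_boot < 100:
        raise ParameterError("n_boot must be at least 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    if statistic is np.mean:                     # fast path for the common case
        boot = values[idx].mean(axis=1)
    else:
        boot = np.array([statistic(values[row]) for row in idx])
    boot.sort()
    alpha = 1.0 - level
    lo_rank = max(int(np.ceil(alpha / 2 * n_boot)), 1)
    hi_rank = min(int(np.floor((1 - alpha / 2) * n_boot)), n_boot)
    return float(boot[lo_rank - 1]), float(boot[hi_rank - 1])


def fit_poly2(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least-squares quadratic fit.

    Returns ``(coefficients, fitted)`` with coefficients ordered highest
    degree first (numpy ``polyfit`` convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ParameterError("quadratic fit needs at least three distinct x values")
    coeffs = np.polyfit(x, y, deg=2)
    return coeffs, np.polyval(coeffs, x)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an n x k within-subject matrix.

    Sphericity holds when the variances of all pairwise condition
    differences are equal — equivalently when the covariance of the
    orthonormally transformed data is spherical.  Returns (W, p) using the
    standard chi-square approximation.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    d = k - 1
    contrasts = _orthonormal_contrasts(k)
    y = data @ contrasts.T                       # n x (k-1)
    s = np.cov(y, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 1e-300, None)
    log_w = float(np.sum(np.log(eig)) - d * np.log(eig.mean()))
    w = float(np.exp(log_w))
    chi_df = d * (d + 1) / 2 - 1
    if chi_df <= 0:
        return w, 1.0
    # two-term chi-square series for the null distribution of -n f log W
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    chi2 = -(n - 1) * f_corr * log_w
    p1 = stats.chi2.sf(chi2, chi_df)
    p2 = stats.chi2.sf(chi2, chi_df + 4)
    return w, float(p1 + w2 * (p2 - p1))


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the orthonormal-contrast covariance."""
    n, k = data.shape
    d = k - 1
    contrasts = _orthonormal_contrasts(k)
    s = np.cov(data @ contrasts.T, rowvar=False, ddof=1)
    return float(np.trace(s) ** 2 / (d * np.sum(s * s)))


def rm_anova(
    data,
    sphericity_alpha: float = 0.05,
    correction: str = "lower-bound",
) -> AnovaResult:
    """One-way within-subject ANOVA on an n-sessions x k-conditions matrix.

    F = MS_condition / MS_(condition x subject) with degrees of freedom
    (k-1, (k-1)(n-1)).  A one-sample Kolmogorov-Smirnov normality check is
    run per condition (against a normal with the condition's estimated
    mean and SD) and Mauchly's test on the orthonormal-contrast
    covariance; when Mauchly's p falls below ``sphericity_alpha`` the
    requested correction is applied.  ``"lower-bound"`` (default) uses the
    most conservative epsilon, 1/(k-1), so the corrected degrees of
    freedom are (1, n-1); ``"greenhouse-geisser"`` uses the data-driven
    epsilon; ``"none"`` reports the uncorrected test regardless.

    Missing cells are an error — no imputation is attempted.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ParameterError("data must be a 2-d sessions x conditions matrix")
    if np.any(~np.isfinite(data)):
        raise ParameterError("missing cells in the within-subject matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ParameterError("need at least 2 sessions and 2 conditions")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num = k - 1.0
    df_den = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    f_stat = float(ms_cond / ms_err)

    ks_p = tuple(
        float(stats.kstest(col, "norm", args=(col.mean(), col.std(ddof=1))).pvalue)
        for col in data.T
    )
    w, mauchly_p = mauchly_test(data)
    violated = mauchly_p < sphericity_alpha

    eps = 1.0
    used = "none"
    if violated and correction != "none":
        if correction == "lower-bound":
            eps = 1.0 / (k - 1.0)
            used = "lower-bound"
        elif correction in ("greenhouse-geisser", "gg"):
            eps = _gg_epsilon(data)
            used = "greenhouse-geisser"
        else:
            raise ParameterError(f"unknown correction {correction!r}")
        df_num *= eps
        df_den *= eps
    p = float(stats.f.sf(f_stat, df_num, df_den))

    return AnovaResult(
        F=f_stat, df_num=df_num, df_den=df_den, p=p,
        epsilon=eps, sphericity_violated=bool(violated),
        mauchly_W=w, mauchly_p=mauchly_p, ks_normal_p=ks_p, correction=used,
    )


# ---------------------------------------------------------------------------
# model / results


class DetectionModel:
    """Figure-detection performance model over a set of Go/No-Go sessions.

    Parameters
    ----------
    sessions
        List of :class:`~sfg.session.SessionData` (simulated or parsed
        from the session-log CSV schema).  Sessions from several subjects
        may be pooled, matching the paper-style overall-trend analysis.
    output_latency
        Sound-output latency subtracted from every response time (s).
    exclude_below
        Responses faster than this after stimulus onset are excluded (s).
    sphericity_alpha, correction
        Sphericity handling for the repeated-measures ANOVAs.
    """

    def __init__(
        self,
        sessions: list[SessionData],
        output_latency: float = 0.0,
        exclude_below: float = 0.4,
        sphericity_alpha: float = 0.05,
        correction: str = "lower-bound",
    ) -> None:
        if not sessions:
            raise ParameterError("need at least one session")
        self.raw_sessions = list(sessions)
        self.output_latency = output_latency
        self.exclude_below = exclude_below
        self.sphericity_alpha = sphericity_alpha
        self.correction = correction
        self.sessions = [
            exclude_fast_responses(
                apply_latency_correction(s, output_latency), exclude_below
            )
            for s in sessions
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DetectionModel":
        """Build from a concatenated trial table (one row per trial)."""
        sessions = [
            SessionData.from_dataframe(g) for _, g in df.groupby("session_id", sort=True)
        ]
        return cls(sessions, **kwargs)

    def session_matrix(self, statistic: str) -> tuple[np.ndarray, list[int]]:
        """Sessions x coherence matrix of a per-level statistic.

        ``statistic`` is one of ``d_prime``, ``hit_rate``, ``mean_rt``,
        ``rt_variability``.  Only coherence levels present in every
        session are included (the ANOVA needs a complete matrix).
        """
        per_session = [
            {s.coherence: getattr(s, statistic) for s in rates_by_coherence(sess)}
            for sess in self.sessions
        ]
        common = sorted(set.intersection(*(set(d) for d in per_session)))
        mat = np.array([[d[c] for c in common] for d in per_session], dtype=float)
        keep = np.all(np.isfinite(mat), axis=1)
        if not np.all(keep):
            warnings.warn(
                f"{int((~keep).sum())} session(s) dropped from the {statistic} "
                "matrix (undefined cells)"
            )
        return mat[keep], [int(c) for c in common]

    def fit(
        self,
        n_boot: int = 5000,
        ci_level: float = 0.95,
        rng: np.random.Generator | int | None = None,
    ) -> "DetectionResults":
        """Run the full analysis and return a results object."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)

        stats_names = ("hit_rate", "d_prime", "mean_rt", "rt_variability")
        matrices: dict[str, tuple[np.ndarray, list[int]]] = {
            name: self.session_matrix(name) for name in stats_names
        }
        per_session_rates = [rates_by_coherence(s) for s in self.sessions]
        fa_rates = np.array([r[0].fa_rate for r in per_session_rates if r])

        levels = matrices["d_prime"][1]
        rows = []
        for name in stats_names:
            mat, lv = matrices[name]
            for j, c in enumerate(lv):
                col = mat[:, j]
                lo, hi = bootstrap_ci(col, np.mean, n_boot, ci_level, rng)
                rows.append({
                    "coherence": c, "statistic": name,
                    "mean": float(col.mean()), "ci_low": lo, "ci_high": hi,
                    "n_sessions": len(col),
                })
        fa_ci = bootstrap_ci(fa_rates, np.mean, n_boot, ci_level, rng) \
            if len(fa_rates) >= 2 else (np.nan, np.nan)

        anovas = {
            name: rm_anova(matrices[name][0], self.sphericity_alpha, self.correction)
            for name in ("d_prime", "mean_rt", "rt_variability")
        }
        poly_fits = {}
        x = np.array(levels, dtype=float)
        for name in stats_names:
            mat, lv = matrices[name]
            if len(lv) >= 3:
                coeffs, fitted = fit_poly2(np.array(lv, float), mat.mean(axis=0))
                poly_fits[name] = coeffs

        exclusion = float(np.mean([exclusion_fraction(s) for s in self.sessions]))
        return DetectionResults(
            model=self,
            coherence_levels=levels,
            table=pd.DataFrame(rows),
            fa_rate=float(fa_rates.mean()),
            fa_rate_ci=fa_ci,
            anovas=anovas,
            poly_fits=poly_fits,
            matrices=matrices,
            exclusion_fraction=exclusion,
            ci_level=ci_level,
        )


@dataclass
class DetectionResults:
    """Fitted behavioural summary: per-coherence statistics, CIs and ANOVAs."""

    model: DetectionModel
    coherence_levels: list[int]
    table: pd.DataFrame
    fa_rate: float
    fa_rate_ci: tuple[float, float]
    anovas: dict[str, AnovaResult]
    poly_fits: dict[str, np.ndarray]
    matrices: dict[str, tuple[np.ndarray, list[int]]]
    exclusion_fraction: float
    ci_level: float

    def by_coherence(self, statistic: str = "d_prime") -> pd.DataFrame:
        """Tidy per-coherence table for one statistic."""
        return (
            self.table[self.table.statistic == statistic]
            .drop(columns="statistic")
            .reset_index(drop=True)
        )

    def mean_curve(self, statistic: str) -> np.ndarray:
        mat, _ = self.matrices[statistic]
        return mat.mean(axis=0)

    def summary(self) -> str:
        """Human-readable summary table in the style of a model report."""
        lines = ["Figure-detection behavioural summary",
                 "=" * 52,
                 f"sessions: {len(self.model.sessions)}   "
                 f"excluded trials: {self.exclusion_fraction:.2%}",
                 f"false-alarm rate: {self.fa_rate:.3f} "
                 f"(CI {self.fa_rate_ci[0]:.3f}-{self.fa_rate_ci[1]:.3f})",
                 "",
                 f"{'coh':>4} {'hit rate':>9} {'d-prime':>8} "
                 f"{'mean RT':>8} {'RT SD':>7}"]
        hits = self.mean_curve("hit_rate")
        dps = self.mean_curve("d_prime")
        rts = self.mean_curve("mean_rt")
        sds = self.mean_curve("rt_variability")
        for i, c in enumerate(self.coherence_levels):
            lines.append(
                f"{c:>4} {hits[i]:>9.3f} {dps[i]:>8.3f} {rts[i]:>8.3f} {sds[i]:>7.3f}"
            )
        lines.append("")
        for name, a in self.anovas.items():
            corr = f", {a.correction} corrected" if a.correction != "none" else ""
            lines.append(
                f"rmANOVA {name}: F({a.df_num:g}, {a.df_den:g}) = {a.F:.2f}, "
                f"p = {a.p:.3g} (Mauchly p = {a.mauchly_p:.3g}{corr})"
            )
        return "\n".join(lines)

    def anova_report(self) -> dict:
        """JSON-ready ANOVA report."""
        return {
            name: {
                "F": a.F, "df_num": a.df_num, "df_den": a.df_den, "p": a.p,
                "epsilon": a.epsilon, "sphericity_violated": a.sphericity_violated,
                "mauchly_W": a.mauchly_W, "mauchly_p": a.mauchly_p,
                "ks_normal_p": list(a.ks_normal_p), "correction": a.correction,
            }
            for name, a in self.anovas.items()
        }
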