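"""Parallel-line bioassay analysis: common-slope fit, validity ANOVA,
relative potency with Fieller fiducial limits, weighted combination of
replicate estimates, and specific-activity conversion.

Implements the compendial parallel-line scheme for a completely randomised
design: responses are modelled as linear in log-dose with a slope common to
all preparations; the log relative potency of a test preparation is its
horizontal offset from the standard, and 95% fiducial limits follow from
Fieller's theorem.  Log-doses are natural logs internally; potency ratios
are scale-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayData",
    "ParallelLineFit",
    "PotencyEstimate",
    "CombinedPotency",
    "BatchPotency",
    "DegenerateFitError",
    "fit_parallel_line",
    "estimate_potency",
    "combine_potencies",
    "specific_activity",
    "relative_percent",
    "batch_potency",
]

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Raised when the assay data cannot support a regression fit."""


@dataclass
class AssayData:
    """One parallel-line assay: long-format dose-response records.

    ``records`` needs columns ``preparation``, ``dose_iu`` and
    ``response_mg`` (ovary weight); every preparation must be measured at the
    same number of dose levels.
    """

    records: pd.DataFrame
    standard: str = "standard"
    assumed_potency: float = 147.5  # IU per ampoule of the standard

    def __post_init__(self) -> None:
        required = {"preparation", "dose_iu", "response_mg"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"assay records missing columns: {sorted(missing)}")
        if self.standard not in set(self.records["preparation"]):
            raise ValueError(f"standard preparation {self.standard!r} not in records")
        if (self.records["dose_iu"] <= 0).any():
            raise ValueError("doses must be positive")
        if (self.records["response_mg"] <= 0).any():
            raise ValueError("responses must be positive")
        n_levels = self.records.groupby("preparation")["dose_iu"].nunique()
        if n_levels.nunique() != 1:
            raise ValueError(
                f"unequal numbers of dose levels per preparation: {dict(n_levels)}"
            )
        for prep, doses in self.records.groupby("preparation")["dose_iu"]:
            levels = np.sort(doses.unique())
            if len(levels) >= 3:
                ratios = levels[1:] / levels[:-1]
                if not np.allclose(ratios, ratios[0], rtol=1e-6):
                    logger.warning(
                        "doses for %r are not geometrically spaced: %s", prep, levels
                    )

    @property
    def preparations(self) -> list[str]:
        preps = list(dict.fromkeys(self.records["preparation"]))
        preps.remove(self.standard)
        return [self.standard] + preps

    @property
    def tests(self) -> list[str]:
        return [p for p in self.preparations if p != self.standard]

    @classmethod
    def from_csv(cls, path, standard: str = "standard", assumed_potency: float = 147.5,
                 assay_id: str | None = None) -> "AssayData":
        """Read assay CSV with columns assay_id, preparation, dose_iu,
        animal_id, ovary_weight_mg (or the internal response_mg)."""
        df = pd.read_csv(path)
        if "ovary_weight_mg" in df.columns:
            df = df.rename(columns={"ovary_weight_mg": "response_mg"})
        if assay_id is not None and "assay_id" in df.columns:
            df = df[df["assay_id"].astype(str) == str(assay_id)]
        return cls(records=df.reset_index(drop=True), standard=standard,
                   assumed_potency=assumed_potency)


@dataclass
class ParallelLineFit:
    """Common-slope least-squares fit plus the validity ANOVA partition."""

    data: AssayData
    common_slope: float
    prep_means: dict[str, float]  # mean response per preparation
    prep_mean_logdose: dict[str, float]
    prep_counts: dict[str, int]
    sxx_pooled: float  # pooled within-preparation Σ(x − x̄)²
    anova: pd.DataFrame  # rows: preparations/regression/parallelism/linearity/residual/total
    residual_ms: float
    residual_df: int

    def p_value(self, component: str) -> float:
        return float(self.anova.loc[component, "p"])

    @property
    def regression_significant(self) -> bool:
        return self.residual_df == 0 or self.p_value("regression") < 0.05

    @property
    def parallel(self) -> bool:
        return self.residual_df == 0 or self.p_value("parallelism") > 0.05

    @property
    def linear(self) -> bool:
        if "linearity" not in self.anova.index or self.residual_df == 0:
            return True
        return self.p_value("linearity") > 0.05


def fit_parallel_line(data: AssayData) -> ParallelLineFit:
    """Fit the common-slope log-dose model and partition the treatment
    sum of squares into preparations, regression, parallelism and deviation
    from linearity, each tested against the within-cell residual."""
    df = data.records.copy()
    df["x"] = np.log(df["dose_iu"].to_numpy(dtype=float))
    y = df["response_mg"].to_numpy(dtype=float)
    n_total = len(df)
    n_doses = df.groupby("preparation")["dose_iu"].nunique().iloc[0]
    if n_doses < 2:
        raise DegenerateFitError("at least 2 dose levels are required")
    if np.ptp(y) == 0:
        raise DegenerateFitError("all responses are identical; no regression possible")
    counts = df.groupby("preparation")["response_mg"].size()
    if counts.nunique() != 1 or df.groupby(["preparation", "dose_iu"]).size().nunique() != 1:
        logger.warning("unbalanced design: unequal replication across cells")

    grand_mean = y.mean()
    ss_total = float(((y - grand_mean) ** 2).sum())

    cells = df.groupby(["preparation", "dose_iu"])["response_mg"]
    ss_treat = float(
        (cells.size() * (cells.mean() - grand_mean) ** 2).sum()
    )
    # within-cell SS computed directly so zero-noise data give exactly 0
    ss_resid = float(cells.transform(lambda s: s - s.mean()).pow(2).sum())
    if ss_resid < 1e-10 * max(ss_total, 1.0):
        ss_resid = 0.0
    df_resid = n_total - cells.ngroups

    preps = df.groupby("preparation")
    ss_prep = float((preps.size() * (preps["response_mg"].mean() - grand_mean) ** 2).sum())

    sxy_sum, sxx_sum, ss_slopes = 0.0, 0.0, 0.0
    prep_means: dict[str, float] = {}
    prep_xbar: dict[str, float] = {}
    prep_counts: dict[str, int] = {}
    for prep, group in preps:
        gx = group["x"].to_numpy()
        gy = group["response_mg"].to_numpy()
        dx = gx - gx.mean()
        dy = gy - gy.mean()
        sxy = float((dx * dy).sum())
        sxx = float((dx * dx).sum())
        sxy_sum += sxy
        sxx_sum += sxx
        ss_slopes += sxy**2 / sxx
        prep_means[prep] = float(gy.mean())
        prep_xbar[prep] = float(gx.mean())
        prep_counts[prep] = len(group)
    if sxx_sum <= 0:
        raise DegenerateFitError("no within-preparation dose spread")
    slope = sxy_sum / sxx_sum
    ss_reg = sxy_sum**2 / sxx_sum
    tiny = 1e-10 * max(ss_total, 1.0)  # float dust from SS subtraction
    ss_par = ss_slopes - ss_reg
    ss_par = 0.0 if ss_par < tiny else ss_par
    ss_lin = ss_treat - ss_prep - ss_reg - ss_par
    ss_lin = 0.0 if ss_lin < tiny else ss_lin

    rows = [("preparations", ss_prep, len(prep_means) - 1),
            ("regression", ss_reg, 1),
            ("parallelism", ss_par, len(prep_means) - 1)]
    if n_doses >= 3:
        rows.append(("linearity", ss_lin, len(prep_means) * (n_doses - 2)))
    rows.append(("residual", max(ss_resid, 0.0), df_resid))
    rows.append(("total", ss_total, n_total - 1))

    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0
    table = []
    for name, ss, dfree in rows:
        ms = ss / dfree if dfree > 0 else np.nan
        if name in ("residual", "total") or df_resid == 0 or ms_resid == 0:
            f_stat, p = np.nan, np.nan
            if name not in ("residual", "total") and df_resid > 0 and ms_resid == 0:
                # zero residual variance: any signal is infinitely significant
                f_stat = np.inf if ss > 0 else 0.0
                p = 0.0 if ss > 0 else 1.0
        else:
            f_stat = ms / ms_resid
            p = float(stats.f.sf(f_stat, dfree, df_resid))
        table.append({"component": name, "ss": ss, "df": dfree, "ms": ms, "F": f_stat, "p": p})
    anova = pd.DataFrame(table).set_index("component")

    return ParallelLineFit(
        data=data,
        common_slope=float(slope),
        prep_means=prep_means,
        prep_mean_logdose=prep_xbar,
        prep_counts=prep_counts,
        sxx_pooled=float(sxx_sum),
        anova=anova,
        residual_ms=float(ms_resid),
        residual_df=int(df_resid),
    )


@dataclass
class PotencyEstimate:
    """Relative potency of one test preparation with 95% fiducial limits."""

    preparation: str
    log_relative_potency: float  # natural log
    relative_potency: float
    fiducial_limits: tuple[float, float]  # on the ratio scale; (nan, nan) if g ≥ 1
    g_criterion: float
    t_value: float
    df: int
    validity: dict[str, bool]
    assumed_potency: float
    potency_iu: float

    @property
    def valid(self) -> bool:
        return all(self.validity.values())

    @property
    def log_limits(self) -> tuple[float, float]:
        lo, hi = self.fiducial_limits
        return (math.log(lo), math.log(hi)) if np.isfinite(lo) and lo > 0 else (np.nan, np.nan)


def estimate_potency(
    fit: ParallelLineFit,
    assumed: float | None = None,
    test: str | None = None,
    alpha: float = 0.05,
) -> PotencyEstimate:
    """Relative potency of ``test`` versus the standard from a parallel-line fit.

    The log relative potency is ``M = (ȳ_T − ȳ_S)/b − (x̄_T − x̄_S)``; with a
    shared dose schedule the second term vanishes.  Fiducial limits come from
    Fieller's theorem with the g-criterion ``g = t²s²/(b²·Sxx)``; at zero
    residual variance they collapse onto the point estimate, and at g ≥ 1
    they are undefined and flagged.
    """
    data = fit.data
    if assumed is None:
        assumed = data.assumed_potency
    if test is None:
        tests = data.tests
        if len(tests) != 1:
            raise ValueError(f"specify `test`; assay has test preparations {tests}")
        test = tests[0]
    if test not in fit.prep_means:
        raise ValueError(f"unknown preparation {test!r}")

    b = fit.common_slope
    if b == 0:
        raise DegenerateFitError("zero common slope; potency undefined")
    a = fit.prep_means[test] - fit.prep_means[data.standard]
    dx = fit.prep_mean_logdose[test] - fit.prep_mean_logdose[data.standard]
    m = a / b  # ratio part subject to Fieller
    M = m - dx

    s2 = fit.residual_ms
    df_resid = fit.residual_df
    inv_n = 1.0 / fit.prep_counts[test] + 1.0 / fit.prep_counts[data.standard]

    if df_resid > 0 and s2 > 0:
        t_val = float(stats.t.ppf(1 - alpha / 2, df_resid))
        g = t_val**2 * s2 / (b**2 * fit.sxx_pooled)
        if g >= 1:
            logger.warning("g-criterion %.3f ≥ 1: fiducial limits undefined", g)
            limits = (float("nan"), float("nan"))
        else:
            half = (t_val / abs(b)) * math.sqrt(
                s2 * ((1 - g) * inv_n + m**2 / fit.sxx_pooled)
            )
            m_lo = (m - half) / (1 - g)
            m_hi = (m + half) / (1 - g)
            limits = (math.exp(m_lo - dx), math.exp(m_hi - dx))
    else:
        t_val, g = float("nan"), 0.0
        limits = (math.exp(M), math.exp(M))

    validity = {
        "regression": fit.regression_significant,
        "parallelism": fit.parallel,
        "linearity": fit.linear,
    }
    if not validity["regression"]:
        logger.warning("regression not significant: potency estimate is not valid")

    rho = math.exp(M)
    return PotencyEstimate(
        preparation=test,
        log_relative_potency=M,
        relative_potency=rho,
        fiducial_limits=limits,
        g_criterion=float(g),
        t_value=t_val,
        df=df_resid,
        validity=validity,
        assumed_potency=assumed,
        potency_iu=rho * assumed,
    )


@dataclass
class CombinedPotency:
    """Weighted combination of replicate potency estimates."""

    log_relative_potency: float
    relative_potency: float
    fiducial_limits: tuple[float, float]
    weights: list[float]
    homogeneity_chi2: float
    homogeneity_p: float
    homogeneous: bool
    n_estimates: int
    potency_iu: float


def combine_potencies(
    estimates: Sequence[PotencyEstimate],
    alpha: float = 0.05,
    weights: Sequence[float] | None = None,
) -> CombinedPotency:
    """Combine replicate assays as a weighted mean of log potencies.

    Weights default to the compendial inverse-variance weights derived from
    each assay's fiducial-limit width on the log scale, ``W = 4t²/L²``.  A
    homogeneity chi-square is reported; a heterogeneous set still yields a
    combined value, flagged as such.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    logs = np.array([e.log_relative_potency for e in estimates])
    assumed = estimates[0].assumed_potency
    if weights is None:
        w = []
        for e in estimates:
            lo, hi = e.log_limits
            width = hi - lo
            if not np.isfinite(width) or width <= 0:
                raise ValueError(
                    f"estimate for {e.preparation!r} has no finite fiducial "
                    "limits; pass explicit weights to combine"
                )
            w.append(4 * e.t_value**2 / width**2)
        weights_arr = np.array(w)
    else:
        weights_arr = np.asarray(weights, dtype=float)
        if len(weights_arr) != len(estimates):
            raise ValueError("one weight per estimate required")

    if len(estimates) == 1:
        e = estimates[0]
        return CombinedPotency(
            log_relative_potency=e.log_relative_potency,
            relative_potency=e.relative_potency,
            fiducial_limits=e.fiducial_limits,
            weights=list(weights_arr),
            homogeneity_chi2=0.0,
            homogeneity_p=1.0,
            homogeneous=True,
            n_estimates=1,
            potency_iu=e.potency_iu,
        )

    w_sum = weights_arr.sum()
    m_bar = float((weights_arr * logs).sum() / w_sum)
    chi2 = float((weights_arr * (logs - m_bar) ** 2).sum())
    chi2_df = len(estimates) - 1
    p_hom = float(stats.chi2.sf(chi2, chi2_df))
    if p_hom < alpha:
        logger.warning(
            "heterogeneous potency set (chi² = %.2f, p = %.4f); combined value flagged",
            chi2, p_hom,
        )
    df_comb = int(sum(e.df for e in estimates))
    t_comb = float(stats.t.ppf(1 - alpha / 2, df_comb)) if df_comb > 0 else float("nan")
    se = math.sqrt(1.0 / w_sum)
    if np.isfinite(t_comb):
        limits = (math.exp(m_bar - t_comb * se), math.exp(m_bar + t_comb * se))
    else:
        limits = (math.exp(m_bar), math.exp(m_bar))
    rho = math.exp(m_bar)
    return CombinedPotency(
        log_relative_potency=m_bar,
        relative_potency=rho,
        fiducial_limits=limits,
        weights=list(weights_arr),
        homogeneity_chi2=chi2,
        homogeneity_p=p_hom,
        homogeneous=p_hom >= alpha,
        n_estimates=len(estimates),
        potency_iu=rho * assumed,
    )


def specific_activity(potency_iu: float, mass_ug: float) -> float:
    """Specific activity in IU/mg from a container's IU potency and µg protein."""
    if mass_ug <= 0:
        raise ValueError("mass must be positive")
    return potency_iu / (mass_ug / 1000.0)


def relative_percent(potency_iu: float, nominal_iu: float) -> float:
    """Potency as percent of the nominal label value."""
    if nominal_iu <= 0:
        raise ValueError("nominal value must be positive")
    return 100.0 * potency_iu / nominal_iu


@dataclass
class BatchPotency:
    """Per-batch potency summary on the label scale."""

    batch_id: str
    potency_iu_per_container: float
    nominal_iu: float
    nominal_mass_ug: float
    specific_activity_iu_mg: float = field(init=False)
    relative_percent_of_nominal: float = field(init=False)

    def __post_init__(self) -> None:
        self.specific_activity_iu_mg = specific_activity(
            self.potency_iu_per_container, self.nominal_mass_ug
        )
        self.relative_percent_of_nominal = relative_percent(
            self.potency_iu_per_container, self.nominal_iu
        )


def batch_potency(
    batch_id: str, potency_iu: float, nominal_iu: float, nominal_mass_ug: float
) -> BatchPotency:
    return BatchPotency(batch_id, potency_iu, nominal_iu, nominal_mass_ug)
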