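"""Multi-stage inference for radioligand binding experiments.

The pipeline mirrors standard practice for muscarinic receptor kinetics:

1. Saturation binding: after subtraction of nonspecific binding, fit
   ``Y = B_MAX * X / (K_D + X)`` for the tracer's equilibrium dissociation
   constant (reported as pK_D) and the number of sites B_MAX.
2. Dissociation time courses, normalized to 100% at the start of
   dissociation: fit mono-exponential ``Y = 100 * exp(-k_off * t)`` and
   bi-exponential ``Y = (100 - f) * exp(-k_off1 * t) + f * exp(-k_off2 * t)``
   decays; the bi-exponential model is accepted only when the
   extra-sum-of-squares F-test rejects the mono model at alpha = 0.05, and
   the *slower* phase rate is carried forward.
3. Allosteric retardation (Lazareno & Birdsall): the observed rates k_obs
   across competitor concentrations X are fitted with
   ``k_obs = k_0 / (1 + X / K_A)`` or, for steep relationships, with a
   slope factor nH, ``k_obs = k_0 / (1 + (X / K_A)**nH)``; K_A is the
   apparent affinity of the competitor for the vestibule (allosteric) site
   of the tracer-occupied receptor, reported as pK_A.
4. Group summaries: fits are performed per independent experiment, then
   averaged (mean +/- SEM across experiments, not wells), with Dunnett
   many-to-one comparisons against a reference condition.

All equilibrium constants are parameterized on the log10 scale internally;
least squares is unweighted by default (a weights hook is provided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from tandemsite.errors import FitError, ValidationError

RATE_BOUNDS = (1e-6, 10.0)        # 1/min
PK_BOUNDS = (0.0, 12.0)           # pK = -log10 M
NH_BOUNDS = (0.1, 5.0)
N_MULTISTART = 5
ALPHA_SELECT = 0.05
#: mono RSS below this fraction of the signal's sum of squares is treated
#: as a numerically perfect fit (noise-free data) — no nested test needed
_PERFECT_RSS = 1e-12


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SaturationFit:
    """Result of an equilibrium saturation fit."""

    K_D: float                 # molar
    B_MAX: float               # signal units
    pK_D: float
    stderr_pK_D: float | None
    stderr_B_MAX: float | None
    rss: float
    n_points: int
    identifiable: bool         # False when K_D's SE exceeds one log unit


@dataclass
class DissociationFit:
    """Result of a mono/bi-exponential dissociation fit."""

    model: str                 # "mono" | "bi"
    k_off: float               # 1/min (mono rate, or faster phase for bi)
    k_off2: float | None       # 1/min, slower phase (bi only)
    f: float | None            # percent of sites dissociating at k_off2
    selected_rate: float       # slower-phase rule
    stderr: dict
    rss_mono: float
    rss_bi: float | None
    p_value: float | None      # extra-sum-of-squares F-test mono vs bi
    no_dissociation: bool = False


@dataclass
class AllostericFit:
    """Result of a dissociation-retardation fit for K_A (and nH)."""

    K_A: float                 # molar
    pK_A: float
    k_0: float                 # 1/min, competitor-free dissociation rate
    nH: float                  # slope factor (1.0 under eq4)
    slope_model: str           # "eq4" | "eq5"
    stderr_pK_A: float | None
    stderr_k_0: float | None
    stderr_nH: float | None
    rss: float
    unbounded_K_A: bool = False  # flat k_obs: no retardation detectable


@dataclass
class GroupSummary:
    """Per-condition means +/- SEM with Dunnett comparisons vs reference."""

    table: pd.DataFrame           # index condition; mean/sem/n per parameter
    comparisons: pd.DataFrame     # condition, parameter, p_adj, significant
    per_experiment: pd.DataFrame  # one row per (condition, experiment)
    reference: str


# ---------------------------------------------------------------------------
# helpers


def _stderr(params: lmfit.Parameters, name: str) -> float | None:
    err = params[name].stderr
    return float(err) if err is not None and math.isfinite(err) else None


def _f_test(rss_small: float, rss_big: float, p_small: int, p_big: int,
            n: int) -> float:
    """Extra-sum-of-squares F-test p-value for nested least-squares models."""
    df_extra = p_big - p_small
    df_big = n - p_big
    if df_big <= 0 or rss_big <= 0:
        return 0.0
    f_stat = ((rss_small - rss_big) / df_extra) / (rss_big / df_big)
    if f_stat <= 0:
        return 1.0
    return float(stats.f.sf(f_stat, df_extra, df_big))


def _minimize_multistart(residual, params: lmfit.Parameters, rng_jitter=0.3):
    """Least-squares; jittered restarts (up to N_MULTISTART) on failure."""
    rng = np.random.default_rng(0)
    for attempt in range(N_MULTISTART):
        p = params.copy()
        if attempt > 0:
            for par in p.values():
                if par.vary:
                    lo, hi = par.min, par.max
                    val = par.value * math.exp(rng.normal(0.0, rng_jitter))
                    par.value = min(max(val, lo + abs(lo) * 1e-9 + 1e-12),
                                    hi - abs(hi) * 1e-9)
        try:
            out = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if out.success:
            return out
    raise FitError("least-squares failed to converge after multi-start")


def _specific_binding(curve: pd.DataFrame) -> pd.DataFrame:
    """Subtract nonspecific binding when present; validate columns."""
    df = curve.copy()
    if "specific_binding" in df.columns:
        return df
    if "total_binding" in df.columns and "nonspecific_binding" in df.columns:
        df["specific_binding"] = df["total_binding"] - df["nonspecific_binding"]
        return df
    raise ValidationError(
        "saturation data needs 'specific_binding' or both "
        "'total_binding' and 'nonspecific_binding' columns")


# ---------------------------------------------------------------------------
# stage 1: saturation


def fit_saturation(curve: pd.DataFrame,
                   weights: np.ndarray | None = None) -> SaturationFit:
    """Fit a one-site saturation isotherm to specific binding.

    ``curve`` holds one experiment with a ``conc_tracer_M`` column and
    either ``specific_binding`` or ``total_binding`` +
    ``nonspecific_binding`` (per well; replicates are rows).
    """
    df = _specific_binding(curve)
    if "conc_tracer_M" not in df.columns:
        raise ValidationError("missing 'conc_tracer_M' column")
    x = df["conc_tracer_M"].to_numpy(dtype=float)
    y = df["specific_binding"].to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise ValidationError("need >= 4 distinct tracer concentrations")
    if (x <= 0).any():
        raise ValidationError("tracer concentrations must be > 0")
    if np.all(np.abs(y) < 1e-300) or np.nanmax(y) <= 0:
        raise FitError("degenerate data: specific binding is all zero")

    params = lmfit.Parameters()
    params.add("log10_K_D", value=math.log10(np.median(x)),
               min=-PK_BOUNDS[1], max=-PK_BOUNDS[0])
    params.add("B_MAX", value=float(np.nanmax(y)) * 1.2, min=1e-300)

    def residual(p):
        kd = 10.0 ** p["log10_K_D"].value
        model = p["B_MAX"].value * x / (kd + x)
        r = model - y
        return r if weights is None else r * weights

    out = _minimize_multistart(residual, params)
    kd = 10.0 ** out.params["log10_K_D"].value
    se_log = _stderr(out.params, "log10_K_D")
    # K_D is trustworthy only if its SE is tight and the half-saturation
    # point actually lies inside the sampled concentration range
    in_range = x.min() / 3.0 <= kd <= x.max() * 3.0
    return SaturationFit(
        K_D=kd,
        B_MAX=float(out.params["B_MAX"].value),
        pK_D=-math.log10(kd),
        stderr_pK_D=se_log,
        stderr_B_MAX=_stderr(out.params, "B_MAX"),
        rss=float(out.chisqr),
        n_points=len(y),
        identifiable=(se_log is not None and se_log < 1.0 and in_range),
    )


# ---------------------------------------------------------------------------
# stage 2: dissociation


def _fit_mono(t, y, weights):
    params = lmfit.Parameters()
    k_init = _rate_guess(t, y)
    params.add("k_off", value=k_init, min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])

    def residual(p):
        r = 100.0 * np.exp(-p["k_off"].value * t) - y
        return r if weights is None else r * weights

    return _minimize_multistart(residual, params)


def _fit_bi(t, y, weights):
    params = lmfit.Parameters()
    k_init = _rate_guess(t, y)
    params.add("k_off1", value=min(k_init * 3, RATE_BOUNDS[1] * 0.9),
               min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
    params.add("k_off2", value=max(k_init / 3, RATE_BOUNDS[0] * 10),
               min=RATE_BOUNDS[0], max=RATE_BOUNDS[1])
    params.add("f", value=30.0, min=0.0, max=100.0)

    def residual(p):
        f = p["f"].value
        model = ((100.0 - f) * np.exp(-p["k_off1"].value * t)
                 + f * np.exp(-p["k_off2"].value * t))
        r = model - y
        return r if weights is None else r * weights

    return _minimize_multistart(residual, params)


def _rate_guess(t: np.ndarray, y: np.ndarray) -> float:
    pos = (y > 1e-6) & (t > 0)
    if not pos.any():
        return 0.1
    k = math.log(100.0 / max(y[pos][-1], 1e-6)) / t[pos][-1]
    return float(np.clip(k, RATE_BOUNDS[0] * 10, RATE_BOUNDS[1] * 0.5))


def fit_dissociation(tc: pd.DataFrame,
                     weights: np.ndarray | None = None,
                     alpha: float = ALPHA_SELECT,
                     criterion: str = "ftest") -> DissociationFit:
    """Fit a normalized dissociation time course (100% at t = 0).

    ``tc`` needs ``time_min`` and ``bound_pct`` columns with >= 5 time
    points.  The bi-exponential model is selected only when the nested
    F-test rejects the mono model at ``alpha`` (``criterion="aic"``
    selects by AIC instead); the reported ``selected_rate`` follows the
    slower-phase rule.
    """
    for col in ("time_min", "bound_pct"):
        if col not in tc.columns:
            raise ValidationError(f"missing '{col}' column")
    t = tc["time_min"].to_numpy(dtype=float)
    y = tc["bound_pct"].to_numpy(dtype=float)
    if np.unique(t).size < 5:
        raise ValidationError("need >= 5 distinct time points")
    if y[t == t.min()].mean() <= 0:
        raise ValidationError("binding at start of dissociation must be > 0")

    mono = _fit_mono(t, y, weights)
    k_mono = float(mono.params["k_off"].value)
    rss_mono = float(mono.chisqr)
    n = len(y)

    no_diss = k_mono <= RATE_BOUNDS[0] * 1.01 and np.ptp(y) < 5.0
    scale = float(np.sum(y ** 2))
    if no_diss or rss_mono <= _PERFECT_RSS * max(scale, 1.0):
        return DissociationFit(
            model="mono", k_off=k_mono, k_off2=None, f=None,
            selected_rate=k_mono,
            stderr={"k_off": _stderr(mono.params, "k_off")},
            rss_mono=rss_mono, rss_bi=None, p_value=None,
            no_dissociation=no_diss)

    try:
        bi = _fit_bi(t, y, weights)
    except FitError:
        bi = None
    if bi is None or bi.chisqr > rss_mono:
        p_val = 1.0
    elif criterion == "aic":
        p_val = 0.0 if bi.aic < mono.aic else 1.0
    else:
        p_val = _f_test(rss_mono, float(bi.chisqr), 1, 3, n)

    if bi is not None and p_val < alpha:
        k1 = float(bi.params["k_off1"].value)
        k2 = float(bi.params["k_off2"].value)
        f = float(bi.params["f"].value)
        # report k_off as the faster phase, k_off2 as the slower one, with
        # f the percentage of sites dissociating at k_off2
        if k2 > k1:
            k1, k2, f = k2, k1, 100.0 - f
        return DissociationFit(
            model="bi", k_off=k1, k_off2=k2, f=f,
            selected_rate=min(k1, k2),
            stderr={"k_off1": _stderr(bi.params, "k_off1"),
                    "k_off2": _stderr(bi.params, "k_off2"),
                    "f": _stderr(bi.params, "f")},
            rss_mono=rss_mono, rss_bi=float(bi.chisqr), p_value=p_val)
    return DissociationFit(
        model="mono", k_off=k_mono, k_off2=None, f=None,
        selected_rate=k_mono,
        stderr={"k_off": _stderr(mono.params, "k_off")},
        rss_mono=rss_mono,
        rss_bi=float(bi.chisqr) if bi is not None else None,
        p_value=p_val)


# ---------------------------------------------------------------------------
# stage 3: allosteric retardation


def _retardation(x, k_0, log10_K_A, nH):
    ka = 10.0 ** log10_K_A
    return k_0 / (1.0 + (x / ka) ** nH)


def fit_allosteric(kobs_table: pd.DataFrame, slope_model: str = "eq4",
                   weights: np.ndarray | None = None,
                   fix_k_0: float | None = None,
                   alpha: float = ALPHA_SELECT) -> AllostericFit:
    """Fit the dissociation-retardation relationship for K_A (and nH).

    ``kobs_table`` needs ``conc_competitor_M`` and ``k_obs`` columns with
    observed rates at >= 4 competitor concentrations spanning >= 2 log
    units (a zero-competitor row, if present, anchors k_0).

    ``slope_model``: ``"eq4"`` fixes nH = 1 (simple retardation),
    ``"eq5"`` floats the slope factor, ``"auto"`` selects eq5 only when
    the nested F-test rejects eq4 at ``alpha``.  ``fix_k_0`` pins the
    competitor-free rate to a measured value instead of floating it.
    """
    for col in ("conc_competitor_M", "k_obs"):
        if col not in kobs_table.columns:
            raise ValidationError(f"missing '{col}' column")
    if slope_model not in ("eq4", "eq5", "auto"):
        raise ValidationError("slope_model must be 'eq4', 'eq5' or 'auto'")
    x = kobs_table["conc_competitor_M"].to_numpy(dtype=float)
    y = kobs_table["k_obs"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValidationError("k_obs values must be > 0")
    pos = x[x > 0]
    if np.unique(pos).size < 4 or math.log10(pos.max() / pos.min()) < 2:
        raise ValidationError(
            "need >= 4 competitor concentrations spanning >= 2 log units")

    def _run(nh_vary: bool):
        params = lmfit.Parameters()
        k0_init = float(y[np.argmin(x)])
        params.add("k_0", value=fix_k_0 if fix_k_0 is not None else k0_init,
                   min=RATE_BOUNDS[0], max=RATE_BOUNDS[1],
                   vary=fix_k_0 is None)
        params.add("log10_K_A", value=math.log10(np.median(pos)),
                   min=-PK_BOUNDS[1], max=-PK_BOUNDS[0])
        params.add("nH", value=1.0, min=NH_BOUNDS[0], max=NH_BOUNDS[1],
                   vary=nh_vary)

        def residual(p):
            r = _retardation(x, p["k_0"].value, p["log10_K_A"].value,
                             p["nH"].value) - y
            return r if weights is None else r * weights

        return _minimize_multistart(residual, params)

    eq4 = _run(nh_vary=False)
    chosen, model_name = eq4, "eq4"
    if slope_model == "eq5":
        chosen, model_name = _run(nh_vary=True), "eq5"
    elif slope_model == "auto":
        eq5 = _run(nh_vary=True)
        n_par = 1 if fix_k_0 is not None else 2
        scale = max(float(np.sum(y ** 2)), 1e-300)
        if float(eq4.chisqr) <= _PERFECT_RSS * scale:
            p_val = 1.0  # eq4 already numerically perfect
        else:
            p_val = _f_test(float(eq4.chisqr), float(eq5.chisqr),
                            n_par, n_par + 1, len(y))
        if p_val < alpha and eq5.chisqr < eq4.chisqr:
            chosen, model_name = eq5, "eq5"

    log_ka = float(chosen.params["log10_K_A"].value)
    se_log = _stderr(chosen.params, "log10_K_A")
    # flat k_obs: K_A runs into its bound or its SE explodes
    unbounded = (se_log is None or se_log > 2.0
                 or log_ka >= -PK_BOUNDS[0] - 1e-6)
    if unbounded:
        warnings.warn("no retardation detectable: K_A is unbounded",
                      stacklevel=2)
    return AllostericFit(
        K_A=10.0 ** log_ka,
        pK_A=-log_ka,
        k_0=float(chosen.params["k_0"].value),
        nH=float(chosen.params["nH"].value),
        slope_model=model_name,
        stderr_pK_A=se_log,
        stderr_k_0=_stderr(chosen.params, "k_0"),
        stderr_nH=_stderr(chosen.params, "nH") if model_name == "eq5" else None,
        rss=float(chosen.chisqr),
        unbounded_K_A=unbounded,
    )


# ---------------------------------------------------------------------------
# stage 4: orchestration and group statistics


def normalize_timecourse(tc: pd.DataFrame) -> pd.DataFrame:
    """Normalize bound signal to 100% at the earliest time point.

    Accepts either raw ``bound`` counts (optionally with a
    ``nonspecific`` column to subtract first) or an already normalized
    ``bound_pct`` column, which is renormalized so the mean at t = 0 is
    exactly 100.
    """
    df = tc.copy()
    if "bound_pct" not in df.columns:
        if "bound" not in df.columns:
            raise ValidationError("need 'bound' or 'bound_pct' column")
        sig = df["bound"].astype(float)
        if "nonspecific" in df.columns:
            sig = sig - df["nonspecific"].astype(float)
        df["bound_pct"] = sig
    t0 = df["time_min"].min()
    base = df.loc[df["time_min"] == t0, "bound_pct"].mean()
    if base <= 0:
        raise ValidationError("binding at start of dissociation must be > 0")
    df["bound_pct"] = 100.0 * df["bound_pct"] / base
    return df


def analyze_dissociation_experiment(tc: pd.DataFrame,
                                    slope_model: str = "auto",
                                    alpha: float = ALPHA_SELECT) -> dict:
    """Full single-experiment dissociation analysis.

    Normalizes each competitor-concentration series, fits its decay with
    mono/bi model selection, assembles the k_obs table from the
    slower-phase rates, and fits the retardation relationship.
    Returns a dict with the per-concentration fits, the k_obs table, and
    the :class:`AllostericFit`.
    """
    if "conc_competitor_M" not in tc.columns:
        raise ValidationError("missing 'conc_competitor_M' column")
    rows, fits = [], {}
    for conc, grp in tc.groupby("conc_competitor_M"):
        fit = fit_dissociation(normalize_timecourse(grp), alpha=alpha)
        fits[conc] = fit
        rows.append({"conc_competitor_M": conc, "k_obs": fit.selected_rate})
    kobs = pd.DataFrame(rows).sort_values("conc_competitor_M",
                                          ignore_index=True)
    allo = fit_allosteric(kobs, slope_model=slope_model, alpha=alpha)
    k_off = (fits[0.0].selected_rate if 0.0 in fits else allo.k_0)
    return {"kobs_table": kobs, "dissociation_fits": fits,
            "allosteric": allo, "k_off": k_off}


def _check_uniform_design(frames: Sequence[pd.DataFrame]) -> None:
    designs = [tuple(sorted(np.unique(f["conc_competitor_M"])))
               for f in frames]
    if len(set(designs)) > 1:
        raise ValidationError(
            "mixed designs: experiments use different competitor "
            "concentration grids")


def run_pipeline(raw_experiments: Mapping[str, pd.DataFrame],
                 reference: str,
                 saturation_experiments: Mapping[str, pd.DataFrame] | None = None,
                 slope_model: str = "auto",
                 alpha: float = 0.05) -> GroupSummary:
    """Fit every experiment of every condition and summarize by group.

    Parameters
    ----------
    raw_experiments : mapping condition -> DataFrame
        Dissociation time courses in the package CSV schema (columns
        ``experiment_id``, ``conc_competitor_M``, ``time_min`` and
        ``bound_pct`` or raw ``bound``); each condition needs >= 2
        experiments sharing one concentration grid.
    reference : str
        Condition the Dunnett many-to-one comparisons are made against.
    saturation_experiments : optional mapping condition -> DataFrame
        Saturation data (with ``experiment_id``) for pK_D summaries.
    """
    if reference not in raw_experiments:
        raise ValidationError(f"reference condition {reference!r} not present")
    per_rows = []
    for cond, df in raw_experiments.items():
        if "experiment_id" not in df.columns:
            raise ValidationError(f"{cond}: missing 'experiment_id' column")
        frames = [g for _, g in df.groupby("experiment_id")]
        if len(frames) < 2:
            raise ValidationError(f"{cond}: need >= 2 experiments")
        _check_uniform_design(frames)
        for exp_id, grp in df.groupby("experiment_id"):
            res = analyze_dissociation_experiment(grp, slope_model=slope_model,
                                                  alpha=alpha)
            per_rows.append({
                "condition": cond, "experiment_id": exp_id,
                "pK_A": res["allosteric"].pK_A,
                "k_off": res["k_off"],
                "k_0": res["allosteric"].k_0,
                "nH": res["allosteric"].nH,
                "slope_model": res["allosteric"].slope_model,
            })
    per = pd.DataFrame(per_rows)

    if saturation_experiments:
        for cond, df in saturation_experiments.items():
            for exp_id, grp in df.groupby("experiment_id"):
                fit = fit_saturation(grp)
                mask = ((per["condition"] == cond)
                        & (per["experiment_id"] == exp_id))
                if mask.any():
                    per.loc[mask, "pK_D"] = fit.pK_D
                else:
                    per = pd.concat([per, pd.DataFrame([{
                        "condition": cond, "experiment_id": exp_id,
                        "pK_D": fit.pK_D}])], ignore_index=True)

    params = [c for c in ("pK_D", "k_off", "pK_A") if c in per.columns]
    summary = per.groupby("condition")[params].agg(["mean", "sem", "count"])
    summary.columns = [f"{p}_{s}" for p, s in summary.columns]

    comp_rows = []
    for param in params:
        ref_vals = per.loc[per["condition"] == reference, param].dropna()
        others = [c for c in per["condition"].unique() if c != reference]
        samples, names = [], []
        for cond in others:
            vals = per.loc[per["condition"] == cond, param].dropna()
            if len(vals) >= 2:
                samples.append(vals.to_numpy())
                names.append(cond)
        if not samples or len(ref_vals) < 2:
            continue
        res = stats.dunnett(*samples, control=ref_vals.to_numpy())
        for cond, p_adj in zip(names, np.atleast_1d(res.pvalue)):
            comp_rows.append({"condition": cond, "parameter": param,
                              "p_adj": float(p_adj),
                              "significant": bool(p_adj < alpha)})
    comparisons = pd.DataFrame(
        comp_rows, columns=["condition", "parameter", "p_adj", "significant"])
    return GroupSummary(table=summary, comparisons=comparisons,
                        per_experiment=per, reference=reference)
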