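"""Population simulations and the in-silico impairment screen.

A "population" is a set of parameter draws around a base profile emulating
between-cell/well heterogeneity (independent lognormal variation of the flux
activity constants, default CV 10%).  Each member is driven through the
simulated mitochondrial stress test; OCR metrics are read from the complex IV
flux (the model's proxy for oxygen consumption) 20 min after each addition.

The impairment screen compares six single-flux impairments (CI/CIII/CIV/F1Fo
at 70%, H+ leak at 150%, NADH delivery at 95% of baseline) against the
unimpaired profile on *paired* parameter draws, and classifies each predicted
metric change against two detection thresholds: the +/-10% band, and a
minimal detectable difference from a two-sample statistical power analysis at
the experimental group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import protocols as proto
from .metrics import BioenergeticMetrics, OCR_METRIC_NAMES, ocr_metrics_from_plateaus
from .rc_model import (
    ACTIVITY_NAMES,
    ModelError,
    ModelParameters,
    ModelState,
    TimeCourse,
    find_steady_state,
    simulate,
)

__all__ = [
    "PopulationSpec",
    "ScreenResult",
    "sample_population",
    "extract_ocr_metrics",
    "extract_dpsi_readouts",
    "extract_redox_readouts",
    "power_threshold",
    "run_stress_test",
    "run_impairment_screen",
]

#: default solver settings for population work (trajectories are smooth at the
#: read-out times; per-member tolerances are relaxed relative to single runs)
_POP_RTOL = 1e-6
_POP_GRID_DT = 60.0


@dataclass(frozen=True)
class PopulationSpec:
    """How to draw a heterogeneous population around a base parameter set."""

    n: int = 100
    cv: float = 0.10
    varied: tuple[str, ...] = ACTIVITY_NAMES
    distribution: str = "lognormal"
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self):
        if self.n < 1:
            raise ModelError("population size must be >= 1")
        if self.cv < 0:
            raise ModelError("population CV must be >= 0")
        unknown = set(self.varied) - set(ACTIVITY_NAMES)
        if unknown:
            raise ModelError(f"cannot vary unknown activities: {sorted(unknown)}")
        if self.distribution != "lognormal":
            raise ModelError("only lognormal population variability is supported")


def population_factors(spec: PopulationSpec) -> np.ndarray:
    """Unit-mean lognormal multiplicative factors, shape (n, len(varied)).

    sigma^2 = ln(1 + CV^2) and mu = -sigma^2/2, so E[factor] = 1 exactly and
    the factor CV equals ``spec.cv``.  The draw is fully determined by the
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.cv == 0:
        return np.ones((spec.n, len(spec.varied)))
    sigma = np.sqrt(np.log1p(spec.cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                         size=(spec.n, len(spec.varied)))


def sample_population(base: ModelParameters,
                      spec: PopulationSpec,
                      factors: np.ndarray | None = None) -> list[ModelParameters]:
    """n parameter sets with lognormally varied activity constants."""
    base.validate()
    if factors is None:
        factors = population_factors(spec)
    out = []
    for row in factors:
        changes = {name: getattr(base, name) * f
                   for name, f in zip(spec.varied, row)}
        out.append(base.replace(**changes))
    return out


# ---------------------------------------------------------------------------
# read-out extraction from simulated trajectories
# ---------------------------------------------------------------------------

def _readout_times(tc: TimeCourse, delay: float) -> dict[str, float]:
    """Per-event read-out times, clipped to the trajectory end."""
    t_end = tc.time[-1]
    return {name: min(t + delay, t_end) for t, name, _tg, _sc in tc.events}

def _rel_slope(tc: TimeCourse, name: str, t_read: float,
               window: float = 120.0) -> float:
    """Relative movement of a variable over the trailing window at read-out."""
    t0 = max(t_read - window, float(tc.time[0]))
    v0 = float(np.interp(t0, tc.time, tc.variable(name)))
    v1 = float(np.interp(t_read, tc.time, tc.variable(name)))
    ref = max(abs(v1), 1e-12)
    return abs(v1 - v0) / ref


def extract_ocr_metrics(tc: TimeCourse,
                        readout_delay: float = proto.READOUT_DELAY_S,
                        plateau_rel_tol: float = 0.02) -> BioenergeticMetrics:
    """Stress-test OCR metrics from a simulated trajectory.

    Uses the complex IV flux at the read-out times (20 min after each drug by
    default).  Simulated non-mitochondrial OCR is zero, so no subtraction is
    applied.  A metric is flagged when its plateau is still moving at
    read-out.
    """
    ev = tc.event_times()
    required = {"oligomycin", "fccp", "antimycin_a"}
    if not required <= set(ev):
        raise ModelError(f"stress-test protocol required; found events {sorted(ev)}")
    reads = _readout_times(tc, readout_delay)
    t_basal = min(ev.values()) - 1.0
    basal = tc.flux_at(t_basal, "J_C4")
    post_oligo = tc.flux_at(reads["oligomycin"], "J_C4")
    post_fccp = tc.flux_at(reads["fccp"], "J_C4")
    post_antia = tc.flux_at(reads["antimycin_a"], "J_C4")
    m = ocr_metrics_from_plateaus(basal, post_oligo, post_fccp, post_antia,
                                  subtract_nonmito=False)
    for drug in ("oligomycin", "fccp", "antimycin_a"):
        if _rel_slope(tc, "J_C4", reads[drug]) > plateau_rel_tol:
            m.flags.append(f"{drug}_plateau_not_reached")
    return m


def extract_dpsi_readouts(tc: TimeCourse,
                          readout_delay: float = proto.READOUT_DELAY_S
                          ) -> dict[str, float]:
    """Baseline membrane potential (mV) and per-drug fold changes."""
    ev = tc.event_times()
    if not ev:
        raise ModelError("protocol with at least one drug event required")
    t_basal = min(ev.values()) - 1.0
    base = float(np.interp(t_basal, tc.time, tc.variable("dpsi")))
    out = {"baseline_mV": base}
    for drug, t_read in _readout_times(tc, readout_delay).items():
        v = float(np.interp(t_read, tc.time, tc.variable("dpsi")))
        out[f"fc_{drug}"] = v / base
    return out


def extract_redox_readouts(tc: TimeCourse, params: ModelParameters,
                           readout_delay: float = proto.READOUT_DELAY_S
                           ) -> dict[str, float]:
    """Redox status NADH/NAD+ at baseline and at each drug read-out."""
    nadh = tc.variable("NADH_x")
    ev = tc.event_times()
    t_basal = min(ev.values()) - 1.0 if ev else tc.time[-1]

    def redox_at(t: float) -> float:
        v = float(np.interp(t, tc.time, nadh))
        return v / (params.NADtot - v)

    out = {"baseline": redox_at(t_basal)}
    for drug, t_read in _readout_times(tc, readout_delay).items():
        out[drug] = redox_at(t_read)
    return out


# ---------------------------------------------------------------------------
# statistical power threshold
# ---------------------------------------------------------------------------

def power_threshold(n1: int, n2: int, sd_pct: float,
                    alpha: float = 0.05, power: float = 0.8) -> float:
    """Minimal detectable percent difference in means for a two-sided
    two-sample t test.

    ``sd_pct`` is the per-group dispersion expressed as percent of the group
    mean (CV x 100).  Returns the smallest |percent difference| detectable at
    the given alpha and power for group sizes ``n1``/``n2``; linear in
    ``sd_pct`` and -> 0 as n -> infinity.
    """
    if n1 < 2 or n2 < 2:
        raise ModelError("power threshold requires n >= 2 per group")
    if sd_pct <= 0:
        raise ModelError("dispersion must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ModelError("alpha and power must lie in (0, 1)")
    from statsmodels.stats.power import TTestIndPower

    d = TTestIndPower().solve_power(effect_size=None, nobs1=n1,
                                    ratio=n2 / n1, alpha=alpha, power=power,
                                    alternative="two-sided")
    return float(d) * sd_pct


# ---------------------------------------------------------------------------
# stress-test runs and the impairment screen
# ---------------------------------------------------------------------------

def run_stress_test(params: ModelParameters,
                    initial: ModelState | None = None,
                    first_event: float = proto.DEFAULT_SPACING_S,
                    spacing: float = proto.DEFAULT_SPACING_S,
                    rtol: float = _POP_RTOL,
                    grid_dt: float = _POP_GRID_DT) -> TimeCourse:
    """Steady state, then the simulated mitochondrial stress test."""
    ss = find_steady_state(params, initial)
    protocol = proto.preset_protocols(first_event, spacing)["mito_stress_test"]
    return simulate(params, ss, protocol,
                    horizon=protocol.horizon(spacing), rtol=rtol,
                    grid_dt=grid_dt)


@dataclass
class ScreenResult:
    """Impairment-screen output: per-condition metric means, percent changes
    vs the unimpaired profile, and threshold classifications."""

    table: pd.DataFrame
    spec: PopulationSpec
    thresholds_pct: dict[str, float]
    band_pct: float = 10.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def classification(self, condition: str, metric: str) -> str:
        row = self.table[(self.table.condition == condition)
                         & (self.table.metric == metric)]
        return row["label"].item()

    def reclassified(self, band_pct: float | None = None,
                     thresholds_pct: dict[str, float] | None = None
                     ) -> pd.DataFrame:
        """Re-label the stored percent changes under different thresholds
        (no re-simulation)."""
        band = self.band_pct if band_pct is None else band_pct
        thr = self.thresholds_pct if thresholds_pct is None else thresholds_pct
        out = self.table.copy()
        out["altered_10pct"] = out.pct_change_vs_WTsim.abs() > band
        out["exceeds_power_threshold"] = [
            abs(p) > thr[m] for p, m in zip(out.pct_change_vs_WTsim, out.metric)]
        out["label"] = [
            "exceeds-power-threshold" if a and e else
            "altered-by-10%" if a else "unchanged"
            for a, e in zip(out.altered_10pct, out.exceeds_power_threshold)]
        return out


def _condition_metrics(base: ModelParameters, spec: PopulationSpec,
                       factors: np.ndarray, initial: ModelState | None,
                       metric_names=OCR_METRIC_NAMES,
                       condition: str = "") -> pd.DataFrame:
    """Stress-test metrics for every population member of one condition.

    A draw whose simulation fails (non-physiological steady state) is
    reported and replaced by a fresh draw, up to ``spec.max_retries`` times;
    persistent failures propagate with the condition identified.
    """
    import logging

    log = logging.getLogger("mitoflux")
    members = sample_population(base, spec, factors)
    rows = []
    for i, member in enumerate(members):
        last_err: Exception | None = None
        for attempt in range(spec.max_retries + 1):
            try:
                tc = run_stress_test(member, initial)
                m = extract_ocr_metrics(tc)
                break
            except ModelError as err:
                last_err = err
                log.warning("condition %s member %d draw failed (%s); "
                            "resampling (%d/%d)", condition or "?", i, err,
                            attempt + 1, spec.max_retries)
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, i, attempt]))
                sigma = np.sqrt(np.log1p(max(spec.cv, 1e-12) ** 2))
                redraw = rng.lognormal(-0.5 * sigma ** 2, sigma,
                                       size=len(spec.varied))
                member = sample_population(base, spec, redraw[None, :])[0]
        else:
            raise ModelError(
                f"condition {condition or '?'}: member {i} failed after "
                f"{spec.max_retries} resamples: {last_err}") from last_err
        rows.append({"member": i, **{k: getattr(m, k) for k in metric_names}})
    return pd.DataFrame(rows)


def run_impairment_screen(
    base: ModelParameters,
    spec: PopulationSpec | None = None,
    impairments: dict[str, float] | None = None,
    initial: ModelState | None = None,
    band_pct: float = 10.0,
    exp_n: tuple[int, int] = (67, 75),
    exp_sd_pct: float = 25.0,
    alpha: float = 0.05,
    power: float = 0.8,
    metric_names=OCR_METRIC_NAMES,
) -> ScreenResult:
    """The in-silico impairment screen.

    Simulates the stress test for the unimpaired profile ("WTsim") and for
    each single-flux impairment on paired population draws (the same lognormal
    factors per condition), then classifies the percent change of the
    population-mean metrics against the +/-10% band and the power-analysis
    threshold.  ``exp_n`` and ``exp_sd_pct`` describe the experimental groups
    the power analysis refers to.
    """
    spec = spec or PopulationSpec()
    impairments = dict(proto.IMPAIRMENT_PRESETS if impairments is None
                       else impairments)
    factors = population_factors(spec)

    thr = power_threshold(exp_n[0], exp_n[1], exp_sd_pct, alpha, power)
    thresholds = {m: thr for m in metric_names}

    conditions: dict[str, ModelParameters] = {"WTsim": base}
    for target, severity in impairments.items():
        ev = proto.make_impairment(target, severity)
        conditions[f"{target}_{int(round(severity * 100))}"] = \
            proto.apply_perturbation(base, ev)

    per_cond: dict[str, pd.DataFrame] = {}
    for cname, cparams in conditions.items():
        per_cond[cname] = _condition_metrics(cparams, spec, factors, initial,
                                             metric_names, condition=cname)

    wt_means = per_cond["WTsim"][list(metric_names)].mean()
    rows = []
    for cname, df in per_cond.items():
        means = df[list(metric_names)].mean()
        sds = df[list(metric_names)].std(ddof=1) if spec.n > 1 \
            else means * 0.0
        for m in metric_names:
            pct = 100.0 * (means[m] - wt_means[m]) / wt_means[m]
            altered = bool(abs(pct) > band_pct)
            exceeds = bool(abs(pct) > thresholds[m])
            label = ("exceeds-power-threshold" if altered and exceeds
                     else "altered-by-10%" if altered else "unchanged")
            rows.append({
                "condition": cname, "metric": m,
                "mean": float(means[m]), "sd": float(sds[m]),
                "pct_change_vs_WTsim": float(pct),
                "altered_10pct": altered,
                "exceeds_power_threshold": exceeds,
                "label": label,
            })
    table = pd.DataFrame(rows)
    return ScreenResult(table=table, spec=spec, thresholds_pct=thresholds,
                        band_pct=band_pct)
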