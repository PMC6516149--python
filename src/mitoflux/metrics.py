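"""Bioenergetic metric computation for plate (OCR/ECAR) and imaging data.

The mitochondrial stress test partitions respiration with three sequential
additions: oligomycin (F1Fo inhibition), FCCP (uncoupling) and antimycin A
(electron-flow block).  Non-mitochondrial OCR (the post-antimycin residual) is
subtracted from every phase, after which

    basal          = mitochondria-specific respiration at rest
    ATP synthesis  = oligomycin-sensitive respiration   (basal - post-oligo)
    H+ leak        = oligomycin-insensitive respiration (post-oligo)
    maximal        = post-FCCP respiration
    spare capacity = maximal - basal
    coupling efficiency = ATP synthesis / basal
    cell RCR basal / max = basal / leak and maximal / leak

ECAR metrics: maximal glycolysis is the post-oligomycin ECAR, glycolytic
reserve = maximal glycolysis - basal ECAR.  ATP production rates follow the
proton-production-rate bookkeeping of the Mookerjee-Brand framework: total PPR
from ECAR and the assay buffering power, respiratory acidification from
mitochondrial OCR via CO2/bicarbonate speciation, glycolytic PPR by
difference, and stoichiometric conversion to ATP rates.

The same plateau->metric arithmetic (``ocr_metrics_from_plateaus``) is used by
the simulation read-out layer, so simulated and measured metrics share one
formula core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateSeries",
    "ImagingTrace",
    "BioenergeticMetrics",
    "AtpStoichiometry",
    "ocr_metrics_from_plateaus",
    "compute_ocr_metrics",
    "compute_ecar_metrics",
    "compute_atp_rates",
    "normalize_trace",
    "group_compare",
    "plates_to_tidy",
    "plates_from_tidy",
    "plates_from_wide",
    "metrics_table",
]

# canonical injection names and accepted aliases
_INJECTION_ALIASES = {
    "oligomycin": ("oligomycin", "oligo"),
    "fccp": ("fccp",),
    "antimycin_a": ("antimycin_a", "antimycin", "antia", "antimycina"),
    "rotenone": ("rotenone", "rot"),
}


def _canon_injections(injections: Mapping[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, t in injections.items():
        key = name.strip().lower().replace(" ", "_").replace("-", "_")
        for canon, aliases in _INJECTION_ALIASES.items():
            if key in aliases:
                key = canon
                break
        out[key] = float(t)
    return out


@dataclass
class PlateSeries:
    """One well of a plate assay: OCR and/or ECAR versus time."""

    well: str
    group: str
    time_min: np.ndarray
    ocr: np.ndarray | None = None            # pmol O2 / min
    ecar: np.ndarray | None = None           # mpH / min
    injections: dict[str, float] = field(default_factory=dict)  # name -> min

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"well {self.well}: times must be strictly increasing")
        for nm in ("ocr", "ecar"):
            v = getattr(self, nm)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time_min.shape:
                    raise ValueError(f"well {self.well}: {nm} length mismatch")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"well {self.well}: non-finite {nm} values")
                setattr(self, nm, v)
        self.injections = _canon_injections(self.injections)


@dataclass
class ImagingTrace:
    """A single-cell fluorescence trace (TMRM or NAD(P)H, arbitrary units)."""

    cell: str
    group: str
    time_min: np.ndarray
    signal: np.ndarray
    drugs: dict[str, float] = field(default_factory=dict)  # name -> min
    channel: str = "nadph"

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"cell {self.cell}: times must be strictly increasing")
        if self.signal.shape != self.time_min.shape:
            raise ValueError(f"cell {self.cell}: signal length mismatch")
        self.drugs = _canon_injections(self.drugs)


@dataclass
class BioenergeticMetrics:
    """Per-well (or per-simulation) bioenergetic metrics; absent pieces None."""

    basal: float | None = None
    atp_synthesis: float | None = None
    h_leak: float | None = None
    maximal: float | None = None
    spare_capacity: float | None = None
    nonmito: float | None = None
    coupling_efficiency: float | None = None
    rcr_basal: float | None = None
    rcr_max: float | None = None
    basal_ecar: float | None = None
    maximal_glycolysis: float | None = None
    glycolytic_reserve: float | None = None
    ocr_ecar_ratio: float | None = None
    atp_glycolytic: float | None = None
    atp_oxidative: float | None = None
    atp_total: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items()
             if k != "flags" and v is not None}
        return d


OCR_METRIC_NAMES = ("basal", "atp_synthesis", "h_leak", "maximal",
                    "spare_capacity", "coupling_efficiency",
                    "rcr_basal", "rcr_max")


def ocr_metrics_from_plateaus(
    basal: float,
    post_oligo: float,
    post_fccp: float,
    post_antia: float | None = None,
    subtract_nonmito: bool = True,
) -> BioenergeticMetrics:
    """OCR metrics from the four phase plateaus (shared formula core).

    When ``post_antia`` is given and ``subtract_nonmito`` is true, the
    post-antimycin residual is subtracted from every phase first.  Simulated
    trajectories have zero non-mitochondrial respiration and pass
    ``subtract_nonmito=False``.
    """
    flags: list[str] = []
    nonmito = 0.0
    if post_antia is not None and subtract_nonmito:
        nonmito = post_antia
    vals = {"basal": basal - nonmito,
            "h_leak": post_oligo - nonmito,
            "maximal": post_fccp - nonmito}
    for k, v in vals.items():
        if v < 0:
            flags.append(f"{k}_clipped_negative")
            vals[k] = 0.0
    m = BioenergeticMetrics(
        basal=vals["basal"],
        h_leak=vals["h_leak"],
        maximal=vals["maximal"],
        atp_synthesis=vals["basal"] - vals["h_leak"],
        spare_capacity=vals["maximal"] - vals["basal"],
        nonmito=post_antia if post_antia is not None else None,
        flags=flags,
    )
    if m.basal > 0:
        m.coupling_efficiency = m.atp_synthesis / m.basal
    if m.h_leak > 0:
        m.rcr_basal = m.basal / m.h_leak
        m.rcr_max = m.maximal / m.h_leak
    return m


def _phase_plateaus(series: PlateSeries, channel: str,
                    cycles: int = 3) -> dict[str, float]:
    """Mean of the last ``cycles`` measurements of each injection phase."""
    sig = getattr(series, channel)
    if sig is None:
        raise ValueError(f"well {series.well} has no {channel} data")
    inj = sorted(series.injections.items(), key=lambda kv: kv[1])
    bounds = [-math.inf] + [t for _, t in inj] + [math.inf]
    names = ["baseline"] + [n for n, _ in inj]
    out = {}
    for name, a, b in zip(names, bounds[:-1], bounds[1:]):
        mask = (series.time_min > a) & (series.time_min <= b) \
            if a != -math.inf else (series.time_min <= b)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        out[name] = float(np.mean(sig[idx[-cycles:]]))
    return out


def compute_ocr_metrics(series: PlateSeries, cycles: int = 3,
                        subtract_nonmito: bool = True) -> BioenergeticMetrics:
    """Stress-test OCR metrics for one well (Seahorse-style plateaus)."""
    ph = _phase_plateaus(series, "ocr", cycles)
    missing = [k for k in ("baseline", "oligomycin", "fccp") if k not in ph]
    if missing:
        m = BioenergeticMetrics()
        m.flags.append(f"missing_phases:{','.join(missing)}")
        return m
    m = ocr_metrics_from_plateaus(
        ph["baseline"], ph["oligomycin"], ph["fccp"],
        ph.get("antimycin_a"), subtract_nonmito=subtract_nonmito)
    if "antimycin_a" not in ph:
        m.flags.append("no_antimycin_phase_nonmito_not_subtracted")
    return m


def compute_ecar_metrics(series: PlateSeries, cycles: int = 3,
                         ocr_basal: float | None = None) -> BioenergeticMetrics:
    """ECAR metrics (basal, maximal glycolysis, reserve, OCR/ECAR ratio)."""
    ph = _phase_plateaus(series, "ecar", cycles)
    m = BioenergeticMetrics()
    if "baseline" not in ph or "oligomycin" not in ph:
        m.flags.append("missing_phases:ecar")
        return m
    m.basal_ecar = ph["baseline"]
    m.maximal_glycolysis = ph["oligomycin"]
    m.glycolytic_reserve = m.maximal_glycolysis - m.basal_ecar
    if ocr_basal is None and series.ocr is not None:
        ocr_ph = _phase_plateaus(series, "ocr", cycles)
        if "antimycin_a" in ocr_ph:
            ocr_basal = ocr_ph["baseline"] - ocr_ph["antimycin_a"]
        elif "baseline" in ocr_ph:
            ocr_basal = ocr_ph["baseline"]
    if ocr_basal is not None and m.basal_ecar > 0:
        m.ocr_ecar_ratio = ocr_basal / m.basal_ecar
    return m


@dataclass(frozen=True)
class AtpStoichiometry:
    """Stoichiometric constants of the OCR/ECAR -> ATP-rate conversion.

    Defaults follow the glucose-fuelled proton-production-rate framework:
    one H+ per lactate (hence ATP/lactate = 1 for glycolytic ATP), a maximal
    CO2-derived H+/O2 of 1 partitioned by carbonic-acid speciation at the
    assay pH, oxidative phosphorylation P/O of 2.486 and TCA substrate-level
    P/O of 0.121.  All values are auditable config, not hard-coded science.
    """

    atp_per_lactate: float = 1.0
    h_per_o2_max: float = 1.0
    po_oxphos: float = 2.486
    po_tca: float = 0.121
    assay_pH: float = 7.4
    pK1: float = 6.093

    @property
    def co2_speciation(self) -> float:
        f = 10 ** (self.assay_pH - self.pK1)
        return f / (1 + f)


def compute_atp_rates(series: PlateSeries, buffering_power: float,
                      stoich: AtpStoichiometry | None = None,
                      cycles: int = 3) -> dict[str, BioenergeticMetrics]:
    """Glycolytic / oxidative / total ATP production rates per phase.

    ``buffering_power`` is the assay-medium buffering power in mpH per pmol
    H+ (per well volume); it is a required user input.  Returns metrics for
    the ``basal`` and ``oligomycin`` phases (pmol ATP/min).
    """
    if buffering_power <= 0:
        raise ValueError("buffering power must be > 0")
    stoich = stoich or AtpStoichiometry()
    if series.ecar is None:
        raise ValueError("ATP-rate partitioning requires ECAR data")
    ecar_ph = _phase_plateaus(series, "ecar", cycles)
    ocr_ph = _phase_plateaus(series, "ocr", cycles) if series.ocr is not None else {}
    if "oligomycin" not in ecar_ph:
        raise ValueError("ATP-rate partitioning requires an oligomycin phase")

    nonmito = ocr_ph.get("antimycin_a", 0.0)
    leak = max(ocr_ph.get("oligomycin", 0.0) - nonmito, 0.0)
    out: dict[str, BioenergeticMetrics] = {}
    for phase, ecar_key in (("basal", "baseline"), ("oligomycin", "oligomycin")):
        m = BioenergeticMetrics()
        ppr_tot = ecar_ph[ecar_key] / buffering_power
        ocr_mito = max(ocr_ph.get(ecar_key, 0.0) - nonmito, 0.0) if ocr_ph else 0.0
        ppr_resp = ocr_mito * stoich.h_per_o2_max * stoich.co2_speciation
        ppr_glyc = ppr_tot - ppr_resp
        if ppr_glyc < 0:
            m.flags.append("negative_glycolytic_ppr")
            ppr_glyc = 0.0
        coupled = max(ocr_mito - leak, 0.0)
        m.atp_glycolytic = ppr_glyc * stoich.atp_per_lactate
        m.atp_oxidative = (coupled * 2 * stoich.po_oxphos
                           + ocr_mito * 2 * stoich.po_tca)
        m.atp_total = m.atp_glycolytic + m.atp_oxidative
        if not ocr_ph:
            m.flags.append("oxidative_rate_without_ocr")
        out[phase] = m
    return out


@dataclass
class NormalizedTrace:
    """Baseline-normalized imaging trace with per-drug fold changes."""

    trace: ImagingTrace
    normalized: np.ndarray
    baseline_mean: float
    baseline_slope_pct_per_min: float
    stable: bool
    fold_changes: dict[str, float]
    flags: list[str]


def normalize_trace(trace: ImagingTrace, readout_delay_min: float = 20.0,
                    slope_tol_pct_per_min: float = 0.5) -> NormalizedTrace:
    """Normalize a trace to its pre-drug baseline and read per-drug fold changes.

    Requires >= 3 baseline points; the baseline is flagged unstable when its
    linear-trend slope exceeds ``slope_tol_pct_per_min`` percent of the
    baseline mean per minute.  Fold change per drug = normalized signal at
    (addition time + readout delay), or at the end of the trace if shorter.
    """
    t, s = trace.time_min, trace.signal
    flags: list[str] = []
    if not trace.drugs:
        base_mask = np.ones_like(t, dtype=bool)
    else:
        first = min(trace.drugs.values())
        base_mask = t < first
    if base_mask.sum() < 3:
        raise ValueError(f"cell {trace.cell}: need >=3 baseline points")
    base_t, base_s = t[base_mask], s[base_mask]
    baseline = float(np.mean(base_s))
    if baseline <= 0:
        raise ValueError(f"cell {trace.cell}: non-positive baseline")
    slope = float(np.polyfit(base_t, base_s, 1)[0]) if len(base_t) > 1 else 0.0
    slope_pct = 100.0 * slope / baseline
    stable = abs(slope_pct) <= slope_tol_pct_per_min
    if not stable:
        flags.append("unstable_baseline")
    norm = s / baseline
    fc: dict[str, float] = {}
    for drug, t_add in sorted(trace.drugs.items(), key=lambda kv: kv[1]):
        t_read = t_add + readout_delay_min
        if t_read > t[-1]:
            t_read = t[-1]
            flags.append(f"{drug}_readout_truncated")
        fc[drug] = float(np.interp(t_read, t, norm))
    return NormalizedTrace(trace=trace, normalized=norm, baseline_mean=baseline,
                           baseline_slope_pct_per_min=slope_pct, stable=stable,
                           fold_changes=fc, flags=flags)


def post_drug_slope(trace: ImagingTrace, drug: str,
                    window_min: float = 5.0) -> float:
    """Initial slope of the baseline-normalized signal after a drug addition
    (fraction of baseline per minute); used e.g. for the post-rotenone
    NAD(P)H recovery rate."""
    nt = normalize_trace(trace)
    t_add = trace.drugs[drug]
    mask = (trace.time_min >= t_add) & (trace.time_min <= t_add + window_min)
    if mask.sum() < 2:
        raise ValueError("not enough points after the drug addition")
    return float(np.polyfit(trace.time_min[mask], nt.normalized[mask], 1)[0])


def group_compare(table: pd.DataFrame, value_cols: Sequence[str],
                  group_col: str = "group",
                  groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Two-group comparison per metric: means, percent change, t and rank-sum p.

    Percent change is reported for the second group relative to the first.
    """
    names = list(table[group_col].unique()) if groups is None else list(groups)
    if len(names) != 2:
        raise ValueError("group_compare requires exactly two groups")
    g1 = table[table[group_col] == names[0]]
    g2 = table[table[group_col] == names[1]]
    rows = []
    for col in value_cols:
        a = g1[col].dropna().to_numpy(dtype=float)
        b = g2[col].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"metric {col}: need >=2 observations per group")
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        if np.ptp(np.concatenate([a, b])) == 0:
            t_p, u_p = 1.0, 1.0
        else:
            t_p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            u_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "metric": col,
            "group_ref": names[0], "group_test": names[1],
            "mean_ref": mean_a, "mean_test": mean_b,
            "mean_difference": mean_b - mean_a,
            "percent_change": 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0
            else np.nan,
            "p_ttest": t_p, "p_ranksum": u_p,
            "n_ref": len(a), "n_test": len(b),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular I/O helpers
# ---------------------------------------------------------------------------

def plates_to_tidy(wells: Sequence[PlateSeries]) -> pd.DataFrame:
    """Tidy long table (well, group, time_min, channel, value) for a plate."""
    recs = []
    for w in wells:
        for channel in ("ocr", "ecar"):
            v = getattr(w, channel)
            if v is None:
                continue
            for t, x in zip(w.time_min, v):
                recs.append((w.well, w.group, t, channel, x))
    df = pd.DataFrame(recs, columns=["well", "group", "time_min",
                                     "channel", "value"])
    return df


def plates_from_tidy(df: pd.DataFrame,
                     injections: Mapping[str, float]) -> list[PlateSeries]:
    wells = []
    for (well, group), sub in df.groupby(["well", "group"], sort=True):
        wide = sub.pivot_table(index="time_min", columns="channel",
                               values="value").sort_index()
        wells.append(PlateSeries(
            well=str(well), group=str(group),
            time_min=wide.index.to_numpy(),
            ocr=wide["ocr"].to_numpy() if "ocr" in wide else None,
            ecar=wide["ecar"].to_numpy() if "ecar" in wide else None,
            injections=dict(injections)))
    return wells


def plates_from_wide(df: pd.DataFrame, injections: Mapping[str, float],
                     groups: Mapping[str, str] | None = None,
                     channel: str = "ocr") -> list[PlateSeries]:
    """Read a plate from an analyzer-export-like wide table.

    Expected layout: a ``time_min`` column plus one column per well.  Group
    labels come from ``groups`` (well -> group) or, if omitted, from well
    names of the form ``group/well`` (e.g. ``WT/A1``).
    """
    if "time_min" not in df.columns:
        raise ValueError("wide plate tables need a time_min column")
    t = df["time_min"].to_numpy(dtype=float)
    wells = []
    for col in df.columns:
        if col == "time_min":
            continue
        if groups is not None:
            group = groups.get(col, "")
            well = col
        elif "/" in col:
            group, well = col.split("/", 1)
        else:
            group, well = "", col
        wells.append(PlateSeries(
            well=well, group=group, time_min=t.copy(),
            **{channel: df[col].to_numpy(dtype=float)},
            injections=dict(injections)))
    return wells


def metrics_table(wells: Sequence[PlateSeries], cycles: int = 3,
                  buffering_power: float | None = None) -> pd.DataFrame:
    """Per-well metric table for a plate (OCR, ECAR and optional ATP rates)."""
    rows = []
    for w in wells:
        row: dict = {"well": w.well, "group": w.group}
        if w.ocr is not None:
            row.update(compute_ocr_metrics(w, cycles).as_dict())
        if w.ecar is not None:
            m = compute_ecar_metrics(w, cycles)
            row.update({k: v for k, v in m.as_dict().items()})
            if buffering_power is not None and w.ocr is not None:
                rates = compute_atp_rates(w, buffering_power, cycles=cycles)
                row.update({
                    "atp_glycolytic": rates["basal"].atp_glycolytic,
                    "atp_oxidative": rates["basal"].atp_oxidative,
                    "atp_total": rates["basal"].atp_total,
                    "atp_glycolytic_oligo": rates["oligomycin"].atp_glycolytic,
                    "atp_oxidative_oligo": rates["oligomycin"].atp_oxidative,
                    "atp_total_oligo": rates["oligomycin"].atp_total,
                })
        rows.append(row)
    return pd.DataFrame(rows)
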