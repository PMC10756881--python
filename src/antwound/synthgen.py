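"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one experimental readout of the wound-care study
with its published design and effect sizes as defaults: qPCR designs with
10x/100x load ratios, 18-ASV/11-genus count tables with pathogen blooms,
exponential-hazard survival cohorts hitting the printed 36-h mortalities,
24-h behavior logs with an MG-care fraction of 43/411 and the published
care-bout durations, logistic OD curves with a >25% growth-rate reduction,
three-compartment iBAQ tables, and four-class CHC profiles. All outputs
are plain DataFrames matching the pipeline's TSV schemas and are fully
determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "hazard_from_mortality",
    "lognormal_from_moments",
    "QpcrParams",
    "SurvivalParams",
    "BehaviorParams",
    "MicrobiomeParams",
    "GrowthParams",
    "ProteomeParams",
    "ChcParams",
    "SimParams",
    "gen_qpcr",
    "gen_survival",
    "sample_durations",
    "gen_behavior",
    "gen_asv_counts",
    "gen_growth",
    "gen_proteome",
    "gen_chc",
]


def hazard_from_mortality(m: float, horizon_h: float = 36.0) -> float:
    """Constant hazard (per hour) whose ``horizon_h``-hour cumulative
    mortality is ``m``: lambda = -ln(1 - m) / horizon."""
    if not (0.0 <= m < 1.0):
        raise ValueError("mortality must lie in [0, 1)")
    return -math.log1p(-m) / horizon_h


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(log-mean, log-sd) of the lognormal with the given arithmetic
    mean and standard deviation (moment matching)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


# --------------------------------------------------------------------------
# parameter blocks


@dataclass
class QpcrParams:
    """Treatment x time x location qPCR design.

    ``fold`` maps (treatment, timepoint_h) -> relative load multiple of
    the sterile 2-h baseline; defaults encode the 10x load excess of
    infected ants at 2 h growing to 100x by 11 h.
    """

    n_per_cell: int = 10
    host_cq_mean: float = 18.0
    host_cq_sd: float = 0.5
    noise_sd: float = 0.3  # cycles, target Cq technical noise
    baseline_rel_load: float = 0.01  # sterile 2-h dCq baseline
    fold: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: {
            ("sterile", 2.0): 1.0,
            ("sterile", 11.0): 1.0,
            ("infected", 2.0): 10.0,
            ("infected", 11.0): 100.0,
        }
    )
    location: str = "isolation"
    target: str = "total_16s"
    n_colonies: int = 3


@dataclass
class SurvivalParams:
    """Per-group 36-h mortality targets, converted to exponential hazards.

    Defaults are the published mortalities: 93% infected/isolation, 8%
    infected/nest, 33% infected with MG access, 22% soil-infected/nest,
    90% soil-infected/isolation. The sterile baseline is not printed in
    the main text; 0.20 is an assumption (config key).
    """

    mortality_36h: Mapping[str, float] = field(
        default_factory=lambda: {
            "infected_isolation": 0.93,
            "infected_nest": 0.08,
            "infected_mg_open": 0.33,
            "soil_nest": 0.22,
            "soil_isolation": 0.90,
            "sterile_nest": 0.20,
        }
    )
    n_per_group: int = 12
    n_colonies: int = 3
    horizon_h: float = 36.0


@dataclass
class BehaviorParams:
    """24-h care logs in 10-min bins for sterile vs infected focal ants.

    Per-bin care probabilities: a low baseline for both groups, elevated
    for infected ants in the configured windows (arrival and the 10-12 h
    infection peak). The MG-care fraction defaults to the published
    43/411; durations are lognormal matched to 85+/-53 s (MG care) and
    53+/-36 s (plain care).
    """

    n_per_group: int = 6
    baseline_p: float = 0.05
    elevated_p: float = 0.30
    elevated_windows_h: Sequence[tuple[float, float]] = ((0.0, 1.0), (10.0, 12.0))
    mg_fraction: float = 43 / 411
    dur_care_mean: float = 53.0
    dur_care_sd: float = 36.0
    dur_mg_mean: float = 85.0
    dur_mg_sd: float = 53.0
    n_colonies: int = 3


@dataclass
class MicrobiomeParams:
    """18 ASVs in 11 genera over 40 samples (2 groups x 2 timepoints x 10).

    ``perturbed`` maps genus -> fold increase in infected ants at each
    timepoint; defaults bloom the three pathogenic genera, with the
    total-16S copy number of infected samples 10x (2 h) and 100x (11 h)
    the sterile baseline.
    """

    genera: Sequence[str] = (
        "Pseudomonas", "Klebsiella", "Burkholderia", "Lactobacillus",
        "Enterobacter", "Acinetobacter", "Serratia", "Bacillus",
        "Staphylococcus", "Paenibacillus", "Wolbachia",
    )
    asvs_per_genus: Sequence[int] = (3, 2, 2, 2, 2, 1, 1, 1, 2, 1, 1)
    base_mean: Mapping[str, float] | None = None  # genus -> mean copies; uniform if None
    base_total: float = 5e4
    perturbed: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {
            "Pseudomonas": {2.0: 10.0, 11.0: 100.0},
            "Klebsiella": {2.0: 5.0, 11.0: 20.0},
            "Burkholderia": {2.0: 5.0, 11.0: 20.0},
        }
    )
    total_fold: Mapping[float, float] = field(
        default_factory=lambda: {2.0: 10.0, 11.0: 100.0}
    )
    abund_log_sd: float = 0.5
    total_log_sd: float = 0.3
    depth: int = 20_000
    n_per_cell: int = 10
    timepoints: Sequence[float] = (2.0, 11.0)


@dataclass
class GrowthParams:
    """96-well growth assay: 6 control wells, 9 MG-treated wells, blanks.

    The treated intrinsic growth rate is reduced by ``reduction`` (default
    30%, comfortably past the published >25% threshold); readings every
    10 min for 8 h with Gaussian OD noise.
    """

    r_control: float = 0.6  # per hour
    reduction: float = 0.30
    K: float = 1.0
    N0: float = 0.05
    noise_sd: float = 0.005
    n_control: int = 6
    n_treat: int = 9
    n_blank: int = 3
    duration_h: float = 8.0
    cadence_min: float = 10.0
    well_r_log_sd: float = 0.05  # between-well variation of r


@dataclass
class ProteomeParams:
    """Three-compartment iBAQ design: 6 pooled samples per compartment.

    Protein classes: atrium-only secreted proteins, atrium-enriched
    proteins (fold over hemolymph), flat background shared across
    compartments, and hemolymph-only proteins.
    """

    n_replicates: int = 6
    n_atrium_only: int = 8
    n_enriched: int = 12
    n_flat: int = 25
    n_hemolymph_only: int = 10
    enriched_fold: float = 3.0
    base_ibaq: float = 1e6
    log_sd: float = 0.4


@dataclass
class ChcParams:
    """Four-class CHC profiles; infected ants at the late timepoint shift
    mass toward alkadienes (the published infection cue)."""

    class_fracs: Mapping[str, float] = field(
        default_factory=lambda: {
            "alkane": 0.45, "methyl_branched": 0.30, "alkene": 0.15, "alkadiene": 0.10,
        }
    )
    compounds_per_class: int = 8
    alkadiene_shift: float = 1.8  # multiplier on the alkadiene share, renormalized
    shift_group: str = "infected"
    shift_timepoint: float = 11.0
    noise_log_sd: float = 0.25
    n_per_cell: int = 12
    timepoints: Sequence[float] = (0.0, 2.0, 11.0)


@dataclass
class SimParams:
    """Bundle of all generator parameter blocks plus the master seed."""

    seed: int = 0
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    microbiome: MicrobiomeParams = field(default_factory=MicrobiomeParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    proteome: ProteomeParams = field(default_factory=ProteomeParams)
    chc: ChcParams = field(default_factory=ChcParams)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# generators


def gen_qpcr(params: QpcrParams | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Tidy Cq table (sample_id, colony, treatment, location, timepoint_h,
    target, cq) with one host and one target row per sample.

    Target Cq is the host Cq minus log2 of the sample's relative load
    (one cycle per doubling) plus technical noise.
    """
    p = params or QpcrParams()
    rng = _rng(seed)
    rows = []
    i = 0
    for (treatment, tp), fold in p.fold.items():
        for j in range(p.n_per_cell):
            sid = f"q{i:03d}"
            colony = f"c{j % p.n_colonies + 1}"
            host_cq = rng.normal(p.host_cq_mean, p.host_cq_sd)
            rel_load = p.baseline_rel_load * fold
            target_cq = host_cq - math.log2(rel_load) + rng.normal(0.0, p.noise_sd)
            rows.append((sid, colony, treatment, p.location, tp, "host_28s", host_cq))
            rows.append((sid, colony, treatment, p.location, tp, p.target, target_cq))
            i += 1
    return pd.DataFrame(
        rows,
        columns=["sample_id", "colony", "treatment", "location", "timepoint_h", "target", "cq"],
    )


def gen_survival(
    params: SurvivalParams | None = None,
    seed: int | None = 0,
    hazards: Mapping[str, float] | None = None,
    n_per_group: int | None = None,
) -> pd.DataFrame:
    """Survival table with exponential event times per group.

    Hazards default to the closed-form transform of the per-group 36-h
    mortality targets; ``hazards`` overrides them directly (per hour).
    Event times are rounded up to the observation hour and survivors past
    the horizon are administratively censored.
    """
    p = params or SurvivalParams()
    rng = _rng(seed)
    if hazards is None:
        hazards = {g: hazard_from_mortality(m, p.horizon_h) for g, m in p.mortality_36h.items()}
    n = n_per_group if n_per_group is not None else p.n_per_group
    rows = []
    i = 0
    for group, lam in hazards.items():
        if lam < 0:
            raise ValueError("hazard must be nonnegative")
        for j in range(n):
            colony = f"c{j % p.n_colonies + 1}"
            if lam == 0:
                t, status = p.horizon_h, 0
            else:
                raw = rng.exponential(1.0 / lam)
                if raw <= p.horizon_h:
                    t, status = float(math.ceil(raw)), 1
                else:
                    t, status = p.horizon_h, 0
            t = min(max(t, 1.0), p.horizon_h)
            rows.append((f"a{i:04d}", group, colony, t, status))
            i += 1
    return pd.DataFrame(rows, columns=["ant_id", "group", "colony", "time_h", "status"])


def sample_durations(
    n: int,
    rng: np.random.Generator,
    mean: float | None = None,
    sd: float | None = None,
    log_mean: float | None = None,
    log_sd: float | None = None,
) -> np.ndarray:
    """Lognormal care-bout durations, parameterized either by the target
    arithmetic mean/sd (moment matched) or directly on the log scale."""
    if log_mean is None or log_sd is None:
        if mean is None or sd is None:
            raise ValueError("give either (mean, sd) or (log_mean, log_sd)")
        log_mean, log_sd = lognormal_from_moments(mean, sd)
    return rng.lognormal(log_mean, log_sd, size=n)


def gen_behavior(params: BehaviorParams | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Behavior event log (ant_id, colony, treatment, event_type,
    event_start_s, duration_s) over 24 h.

    Care events are Bernoulli per 10-min bin with the group's bin
    probability; each event independently becomes MG care with probability
    ``mg_fraction`` and draws its duration from the class's lognormal.
    """
    p = params or BehaviorParams()
    rng = _rng(seed)
    n_bins = 144
    rows = []
    i = 0
    for treatment in ("sterile", "infected"):
        for j in range(p.n_per_group):
            ant = f"{treatment[:3]}{j:02d}"
            colony = f"c{j % p.n_colonies + 1}"
            for b in range(n_bins):
                hour = b / 6.0
                prob = p.baseline_p
                if treatment == "infected" and any(
                    lo <= hour < hi for lo, hi in p.elevated_windows_h
                ):
                    prob = p.elevated_p
                if rng.random() < prob:
                    is_mg = rng.random() < p.mg_fraction
                    if is_mg:
                        dur = float(sample_durations(1, rng, p.dur_mg_mean, p.dur_mg_sd)[0])
                        etype = "mg_care"
                    else:
                        dur = float(sample_durations(1, rng, p.dur_care_mean, p.dur_care_sd)[0])
                        etype = "care"
                    start = b * 600 + rng.uniform(0, max(600 - dur, 1.0))
                    rows.append((ant, colony, treatment, etype, float(start), dur))
                    i += 1
    return pd.DataFrame(
        rows,
        columns=["ant_id", "colony", "treatment", "event_type", "event_start_s", "duration_s"],
    )


def gen_asv_counts(
    params: MicrobiomeParams | None = None, seed: int | None = 0
):
    """(AsvCountTable, taxonomy Series, metadata DataFrame, totals Series).

    Per-sample genus abundances are lognormal around group-specific means
    (perturbed genera multiplied by their fold in infected samples), split
    into ASVs by fixed within-genus weights, and converted to counts by a
    multinomial draw at the configured depth. Totals carry the 10x/100x
    total-16S shifts of infected samples.
    """
    p = params or MicrobiomeParams()
    if len(p.asvs_per_genus) != len(p.genera):
        raise ValueError("asvs_per_genus must match genera")
    rng = _rng(seed)
    base = p.base_mean or {g: 1.0 for g in p.genera}

    asv_ids, taxonomy, weights = [], {}, []
    k = 0
    for g, n_asv in zip(p.genera, p.asvs_per_genus):
        w = rng.dirichlet(np.ones(n_asv) * 5.0)
        for a in range(n_asv):
            aid = f"ASV{k:02d}"
            asv_ids.append(aid)
            taxonomy[aid] = f"d__Bacteria;f__Synthetic;g__{g}"
            weights.append((aid, g, w[a]))
            k += 1

    samples, meta_rows, totals = [], [], {}
    counts = np.zeros((len(asv_ids), 0), dtype=int)
    cols = []
    i = 0
    for treatment in ("sterile", "infected"):
        for tp in p.timepoints:
            for j in range(p.n_per_cell):
                sid = f"s{i:03d}"
                genus_ab = {}
                for g in p.genera:
                    mu = base[g]
                    if treatment == "infected" and g in p.perturbed:
                        mu *= p.perturbed[g].get(tp, 1.0)
                    genus_ab[g] = mu * rng.lognormal(0.0, p.abund_log_sd)
                asv_ab = np.array([genus_ab[g] * w for (_, g, w) in weights])
                props = asv_ab / asv_ab.sum()
                col = rng.multinomial(p.depth, props)
                counts = np.column_stack([counts, col]) if counts.size else col[:, None]
                cols.append(sid)
                tf = p.total_fold.get(tp, 1.0) if treatment == "infected" else 1.0
                totals[sid] = p.base_total * tf * rng.lognormal(0.0, p.total_log_sd)
                meta_rows.append((sid, treatment, tp, f"c{j % 3 + 1}"))
                i += 1

    table = pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id"), columns=cols)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "treatment", "timepoint_h", "colony"]
    ).set_index("sample_id")
    return table, pd.Series(taxonomy, name="lineage"), meta, pd.Series(totals, name="total_copies")


def gen_growth(params: GrowthParams | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Tidy plate table (well_id, condition, time_min, od600): logistic
    control and treated wells plus flat blank wells, Gaussian noise."""
    p = params or GrowthParams()
    rng = _rng(seed)
    t_min = np.arange(0.0, p.duration_h * 60.0 + 1e-9, p.cadence_min)
    t_h = t_min / 60.0
    rows = []

    def add_wells(prefix, n, r_mean):
        for w in range(n):
            r = r_mean * rng.lognormal(0.0, p.well_r_log_sd)
            od = p.K / (1.0 + ((p.K - p.N0) / p.N0) * np.exp(-r * t_h))
            od = od + 0.04 + rng.normal(0.0, p.noise_sd, size=len(t_h))
            cond = "control" if prefix == "C" else "mg"
            for tm, o in zip(t_min, od):
                rows.append((f"{prefix}{w+1}", cond, tm, max(float(o), 0.0)))

    add_wells("C", p.n_control, p.r_control)
    add_wells("M", p.n_treat, p.r_control * (1.0 - p.reduction))
    for w in range(p.n_blank):
        od = 0.04 + rng.normal(0.0, p.noise_sd, size=len(t_h))
        for tm, o in zip(t_min, od):
            rows.append((f"B{w+1}", "blank", tm, max(float(o), 0.0)))
    return pd.DataFrame(rows, columns=["well_id", "condition", "time_min", "od600"])


def gen_proteome(params: ProteomeParams | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Tidy iBAQ table (protein_id, sample_id, compartment, ibaq) with
    known atrium-only, enriched, flat and hemolymph-only protein sets
    (recorded in ``DataFrame.attrs['truth']``)."""
    p = params or ProteomeParams()
    rng = _rng(seed)
    compartments = ("atrium", "secretory", "hemolymph")
    samples = {c: [f"{c[:3]}{r+1}" for r in range(p.n_replicates)] for c in compartments}

    def draw(mu):
        return mu * rng.lognormal(0.0, p.log_sd)

    rows = []
    truth = {"atrium_only": [], "enriched": [], "flat": [], "hemolymph_only": []}
    pid = 0

    def add(klass, n, present, mu_by_comp):
        nonlocal pid
        for _ in range(n):
            name = f"P{pid:03d}"
            truth[klass].append(name)
            for comp in compartments:
                if comp not in present:
                    continue
                for s in samples[comp]:
                    rows.append((name, s, comp, draw(mu_by_comp[comp])))
            pid += 1

    b = p.base_ibaq
    add("atrium_only", p.n_atrium_only, ("atrium", "secretory"),
        {"atrium": b, "secretory": b})
    add("enriched", p.n_enriched, compartments,
        {"atrium": b * p.enriched_fold, "secretory": b, "hemolymph": b})
    add("flat", p.n_flat, compartments, {c: b for c in compartments})
    add("hemolymph_only", p.n_hemolymph_only, ("hemolymph",), {"hemolymph": b})

    out = pd.DataFrame(rows, columns=["protein_id", "sample_id", "compartment", "ibaq"])
    out.attrs["truth"] = truth
    return out


def gen_chc(params: ChcParams | None = None, seed: int | None = 0):
    """(profile DataFrame, metadata DataFrame) of CHC relative abundances.

    Compound abundances are lognormal around their class share divided
    evenly among class members, renormalized to 1 per sample; the shift
    group/timepoint multiplies the alkadiene share before renormalization.
    """
    p = params or ChcParams()
    rng = _rng(seed)
    classes = list(p.class_fracs)
    compounds = [
        (f"{cls}_{c:02d}", cls) for cls in classes for c in range(p.compounds_per_class)
    ]
    rows, meta_rows = [], []
    i = 0
    for treatment in ("sterile", "infected"):
        for tp in p.timepoints:
            for _ in range(p.n_per_cell):
                sid = f"chc{i:03d}"
                fracs = dict(p.class_fracs)
                if treatment == p.shift_group and tp == p.shift_timepoint:
                    fracs["alkadiene"] *= p.alkadiene_shift
                ab = np.array(
                    [
                        fracs[cls] / p.compounds_per_class * rng.lognormal(0.0, p.noise_log_sd)
                        for (_, cls) in compounds
                    ]
                )
                ab = ab / ab.sum()
                for (cid, cls), v in zip(compounds, ab):
                    rows.append((sid, cid, cls, float(v)))
                meta_rows.append((sid, treatment, tp))
                i += 1
    profile = pd.DataFrame(
        rows, columns=["sample_id", "compound_id", "compound_class", "rel_abund"]
    )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "treatment", "timepoint_h"]).set_index(
        "sample_id"
    )
    return profile, meta
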