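"""Synthetic cohorts with planted ground truth.

Real elderly-cohort lifestyle/metabolomics data of the kind this pipeline
targets are not redistributable, so every downstream stage is exercised on
simulated data with known truth:

* a cohort of elderly participants (age 55-80) with 8 lifestyle-component
  adherence levels drawn i.i.d. over {0, 0.5, 1}, raw component values
  consistent with the scoring rules, covariates, a 3-arm intervention
  assignment and recruitment centers;
* a participants x metabolites abundance matrix in which a known subset of
  metabolites carries linear loadings on the (standardized) healthy-lifestyle
  score on the log scale, noise is block-equicorrelated, values are missing
  at random, and pooled-reference pseudo-samples are interleaved along the
  injection order;
* exponential (optionally Weibull) event times whose log hazard is
  proportional to the true signature, administratively censored;
* case-cohort samples: all cases plus a simple random subcohort, overlap
  retained once with both roles recorded.

All generators are pure functions of (config, seed); per-stage RNGs are
derived deterministically from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from ._containers import (
    CaseCohortDesign,
    ConfigurationError,
    DimensionError,
    MetaboliteMatrix,
)
from . import lifestyle
from .lifestyle import COMPONENTS, ComponentDefinition, load_component_rules

# stage tags for deterministic per-stage RNG derivation
_STAGE_COHORT = 1
_STAGE_METABOLOME = 2
_STAGE_OUTCOMES = 3
_STAGE_CASECOHORT = 4
_STAGE_FIXTURE = 5


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults describe the study conditions the pipeline is demonstrated
    under: ~1500 elderly participants, 385 metabolites of which 20 carry
    signal, per-SD loadings sized so the best linear signature correlates
    about 0.5 with the lifestyle score, a protective hazard of the signature
    (log HR -0.6 per SD), and a 30% subcohort.
    """

    n_participants: int = 1500
    n_metabolites: int = 385
    n_true_signal: int = 20
    loading_scale: float = 0.129  # per-SD effect of HL on each signal metabolite
    block_size: int = 5
    block_rho: float = 0.3
    missing_rate: float = 0.02
    logHR_per_unit: float = -0.6
    baseline_hazard: float = 0.02
    censor_time: float = 6.0
    subcohort_fraction: float = 0.3
    seed: int = 0
    # component-level adherence probabilities for levels (0, 0.5, 1)
    component_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    # extra structure knobs
    n_internal_standards: int = 0
    n_high_missing: int = 0
    high_missing_rate: float = 0.35
    pooled_ref_every: int = 20
    pooled_ref_noise_sd: float = 0.05
    noise_sd: float = 1.0
    weibull_shape: float = 1.0  # 1.0 = exponential
    n_centers: int = 4

    def __post_init__(self) -> None:
        def _check(name, cond):
            if not cond:
                raise ConfigurationError(f"invalid SimConfig.{name}: {getattr(self, name)!r}")

        _check("n_participants", self.n_participants >= 1)
        _check("n_metabolites", self.n_metabolites >= 1)
        _check("n_true_signal", 0 <= self.n_true_signal <= self.n_metabolites)
        _check("block_size", self.block_size >= 1)
        _check("block_rho", 0.0 <= self.block_rho < 1.0)
        _check("missing_rate", 0.0 <= self.missing_rate < 1.0)
        _check("baseline_hazard", self.baseline_hazard > 0)
        _check("censor_time", self.censor_time > 0)
        _check("subcohort_fraction", 0.0 < self.subcohort_fraction <= 1.0)
        _check("component_probs",
               len(self.component_probs) == 3
               and abs(sum(self.component_probs) - 1.0) < 1e-9
               and min(self.component_probs) >= 0)
        _check("n_internal_standards",
               0 <= self.n_internal_standards <= self.n_metabolites)
        _check("n_high_missing",
               0 <= self.n_high_missing
               <= self.n_metabolites - self.n_internal_standards)
        _check("high_missing_rate", 0.0 <= self.high_missing_rate < 1.0)
        _check("pooled_ref_every", self.pooled_ref_every >= 1)
        _check("noise_sd", self.noise_sd > 0)
        _check("weibull_shape", self.weibull_shape > 0)
        _check("n_centers", self.n_centers >= 1)
        _check("seed", int(self.seed) == self.seed)

    def hl_mean(self) -> float:
        """Theoretical mean of the HL score under the component model."""
        p0, p05, p1 = self.component_probs
        return 8.0 * (0.5 * p05 + 1.0 * p1)

    def hl_sd(self) -> float:
        """Theoretical SD of the HL score under the component model."""
        p0, p05, p1 = self.component_probs
        m = 0.5 * p05 + 1.0 * p1
        v = 0.25 * p05 + 1.0 * p1 - m**2
        return float(np.sqrt(8.0 * v))

    def replace(self, **kw) -> "SimConfig":
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d.update(kw)
        return SimConfig(**d)


@dataclass
class GroundTruth:
    """Planted truth underlying one simulated study."""

    true_loadings: np.ndarray  # per metabolite; 0 for non-signal
    true_signature_values: np.ndarray  # per participant (standardized HL)
    true_logHR: float
    signal_metabolites: list[str] = field(default_factory=list)


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stage]))


def _metabolite_names(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Column names and internal-standard flags.

    Internal standards occupy the last ``n_internal_standards`` columns.
    """
    p = config.n_metabolites
    n_is = config.n_internal_standards
    names = [f"met_{j + 1:04d}" for j in range(p - n_is)]
    names += [f"IS_{k + 1}" for k in range(n_is)]
    is_flag = np.zeros(p, dtype=bool)
    is_flag[p - n_is:] = True
    return names, is_flag


def _signal_indices(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Place signal metabolites in distinct correlation blocks.

    One signal metabolite per block keeps signal-carrying noise independent
    across the planted set, so the loading needed for a target signature
    correlation has a closed form. High-missingness and internal-standard
    columns are never chosen.
    """
    p_usable = config.n_metabolites - config.n_internal_standards - config.n_high_missing
    n_blocks = int(np.ceil(p_usable / config.block_size))
    if config.n_true_signal > n_blocks:
        raise ConfigurationError(
            "n_true_signal exceeds the number of correlation blocks; "
            "decrease block_size or n_true_signal"
        )
    blocks = rng.choice(n_blocks, size=config.n_true_signal, replace=False)
    idx = []
    for b in sorted(blocks):
        lo = b * config.block_size
        hi = min(lo + config.block_size, p_usable)
        idx.append(int(rng.integers(lo, hi)))
    return np.array(idx, dtype=int)


def _level_regions(
    defn: ComponentDefinition, sex: str | None
) -> dict[float, list[tuple[float, float]]]:
    """Sub-intervals of the component domain mapping to each points level."""
    if defn.kind == "numeric_by_sex":
        high, inter, domain = defn.by_sex[sex]
    else:
        high, inter, domain = defn.high, defn.intermediate, defn.domain
    lo, hi = domain

    def clip(iv):
        a, b = max(iv.min, lo), min(iv.max, hi)
        return (a, b) if a <= b else None

    h = clip(high)
    m = clip(inter)
    regions = {1.0: [h] if h else [], 0.5: [m] if m else []}
    # low region: domain minus the healthier intervals
    cuts = sorted({lo, hi} | {x for iv in (h, m) if iv for x in iv})
    low = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        in_h = h and h[0] <= mid <= h[1]
        in_m = m and m[0] <= mid <= m[1]
        if not in_h and not in_m and b > a:
            low.append((a, b))
    regions[0.0] = low
    for lvl, regs in regions.items():
        if not regs:
            raise ConfigurationError(
                f"component {defn.name}: no domain region maps to level {lvl}"
            )
    return regions


def _draw_from_regions(
    regions: list[tuple[float, float]], size: int, rng: np.random.Generator
) -> np.ndarray:
    lengths = np.array([b - a for a, b in regions], dtype=float)
    if lengths.sum() == 0:
        return np.full(size, regions[0][0])
    probs = lengths / lengths.sum()
    which = rng.choice(len(regions), size=size, p=probs)
    u = rng.random(size)
    out = np.empty(size)
    for k, (a, b) in enumerate(regions):
        sel = which == k
        out[sel] = a + u[sel] * (b - a)
    return out


_SMOKING_BY_LEVEL = {1.0: "never", 0.5: "former", 0.0: "current"}


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the cohort table and the planted ground truth.

    Adherence levels are i.i.d. categorical over {0, 0.5, 1} per component
    with probabilities ``config.component_probs``; raw component values are
    drawn uniformly within the scoring-rule region of the drawn level, so
    re-scoring the raw values reproduces the levels exactly. The true
    signature is the theoretically standardized HL score.
    """
    rng = _rng(config.seed, _STAGE_COHORT)
    n = config.n_participants
    rules = load_component_rules()

    cohort = pd.DataFrame(index=pd.RangeIndex(n, name="id"))
    cohort["sex"] = np.where(rng.random(n) < 0.575, "female", "male")
    cohort["age"] = np.clip(rng.normal(67.0, 6.0, n), 55.0, 80.0).round(1)
    cohort["center"] = rng.integers(1, config.n_centers + 1, n)
    cohort["center"] = "C" + cohort["center"].astype(str)
    cohort["arm"] = rng.choice(["control", "medd_evoo", "medd_nuts"], size=n)
    cohort["energy_kcal"] = np.clip(rng.normal(2400.0, 450.0, n), 1000.0, 3400.0).round(0)
    cohort["education"] = rng.choice(
        ["primary", "secondary", "college"], size=n, p=[0.55, 0.30, 0.15]
    )
    for col, prev in [
        ("famhist_chd", 0.25),
        ("hypercholesterolemia", 0.76),
        ("chol_lowering_med", 0.40),
        ("hypertension", 0.87),
        ("antihtn_med", 0.70),
        ("diabetes_prev", 0.29),
    ]:
        cohort[col] = (rng.random(n) < prev).astype(int)
    cohort["ffq_missing"] = False

    levels = rng.choice(
        [0.0, 0.5, 1.0], size=(n, len(COMPONENTS)), p=list(config.component_probs)
    )
    for k, comp in enumerate(COMPONENTS):
        defn = rules[comp]
        lvl = levels[:, k]
        cohort[f"lvl_{comp}"] = lvl
        if defn.kind == "categorical":
            cohort[comp] = pd.Series(lvl, index=cohort.index).map(_SMOKING_BY_LEVEL)
        elif defn.kind == "numeric_by_sex":
            raw = np.empty(n)
            for sex in ("female", "male"):
                sel_sex = cohort["sex"].to_numpy() == sex
                regions = _level_regions(defn, sex)
                for level in (0.0, 0.5, 1.0):
                    sel = sel_sex & (lvl == level)
                    raw[sel] = _draw_from_regions(regions[level], int(sel.sum()), rng)
            cohort[comp] = np.round(raw, 3)
        else:
            regions = _level_regions(defn, None)
            raw = np.empty(n)
            for level in (0.0, 0.5, 1.0):
                sel = lvl == level
                raw[sel] = _draw_from_regions(regions[level], int(sel.sum()), rng)
            cohort[comp] = np.round(raw, 3)

    cohort["hl_true"] = levels.sum(axis=1)

    sig = (cohort["hl_true"].to_numpy() - config.hl_mean()) / config.hl_sd()

    names, _ = _metabolite_names(config)
    loadings = np.zeros(config.n_metabolites)
    sig_idx = _signal_indices(config, rng)
    loadings[sig_idx] = config.loading_scale
    truth = GroundTruth(
        true_loadings=loadings,
        true_signature_values=sig,
        true_logHR=config.logHR_per_unit,
        signal_metabolites=[names[j] for j in sig_idx],
    )
    return cohort, truth


def generate_metabolome(
    cohort: pd.DataFrame, truth: GroundTruth, config: SimConfig, stage: int = _STAGE_METABOLOME
) -> MetaboliteMatrix:
    """Simulate the abundance matrix with planted loadings.

    Log-abundance of metabolite j in participant i is
    ``m_j + loading_j * s_i + noise_sd * eps_ij`` where ``s`` is the
    standardized HL score and the unit-variance noise is equicorrelated at
    ``block_rho`` within consecutive blocks of ``block_size`` metabolites.
    Pooled-reference pseudo-samples (noisy copies of the per-metabolite
    geometric grand mean) are interleaved every ``pooled_ref_every``
    participant records; internal standards are near-constant spiked
    columns; values are missing at random at ``missing_rate`` (a designated
    tail of columns at ``high_missing_rate``).
    """
    n = len(cohort)
    if len(truth.true_signature_values) != n:
        raise DimensionError(
            f"cohort has {n} participants but truth has "
            f"{len(truth.true_signature_values)} signature values"
        )
    if len(truth.true_loadings) != config.n_metabolites:
        raise DimensionError(
            f"truth has {len(truth.true_loadings)} loadings for "
            f"{config.n_metabolites} metabolites"
        )
    rng = _rng(config.seed, stage)
    p = config.n_metabolites
    names, is_flag = _metabolite_names(config)
    s = truth.true_signature_values

    baselines = rng.normal(8.0, 1.0, p)
    n_blocks = int(np.ceil(p / config.block_size))
    shared = rng.normal(size=(n, n_blocks))
    idio = rng.normal(size=(n, p))
    block_of = np.arange(p) // config.block_size
    rho = config.block_rho
    eps = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * idio

    logx = baselines[None, :] + np.outer(s, truth.true_loadings) + config.noise_sd * eps
    # internal standards: spiked, independent of biology
    if config.n_internal_standards:
        k = config.n_internal_standards
        logx[:, p - k:] = baselines[p - k:][None, :] + 0.05 * rng.normal(size=(n, k))
    values = np.exp(logx)

    # missing at random
    rates = np.full(p, config.missing_rate)
    if config.n_high_missing:
        lo = p - config.n_internal_standards - config.n_high_missing
        hi = p - config.n_internal_standards
        rates[lo:hi] = config.high_missing_rate
    mask = rng.random((n, p)) < rates[None, :]
    values = values.astype(float)
    values[mask] = np.nan

    # interleave pooled references every `pooled_ref_every` participant rows
    grand = np.exp(np.nanmean(np.log(values), axis=0))
    rows, run_order, is_ref, labels = [], [], [], []
    pos = 0
    ref_count = 0
    ids = cohort.index.to_numpy()
    for i in range(n):
        if i > 0 and i % config.pooled_ref_every == 0:
            ref = grand * np.exp(rng.normal(0.0, config.pooled_ref_noise_sd, p))
            rows.append(ref)
            run_order.append(pos)
            is_ref.append(True)
            ref_count += 1
            labels.append(f"REF_{ref_count:03d}")
            pos += 1
        rows.append(values[i])
        run_order.append(pos)
        is_ref.append(False)
        labels.append(ids[i])
        pos += 1

    vdf = pd.DataFrame(np.vstack(rows), columns=names, index=pd.Index(labels, name="record"))
    meta = pd.DataFrame({"is_internal_standard": is_flag}, index=pd.Index(names, name="metabolite"))
    return MetaboliteMatrix(
        values=vdf,
        meta=meta,
        run_order=np.array(run_order),
        is_reference=np.array(is_ref),
    )


def generate_outcomes(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    stage: int = _STAGE_OUTCOMES,
) -> pd.DataFrame:
    """Simulate incident-event times under a proportional-hazards model.

    The hazard for participant i is
    ``baseline_hazard * exp(logHR_per_unit * s_i)`` with ``s`` the (already
    centered) true signature; times are exponential (Weibull if
    ``weibull_shape != 1``) and administratively censored at
    ``censor_time``. Returns a table with ``time`` (observed) and ``event``.
    """
    if len(truth.true_signature_values) != len(cohort):
        raise DimensionError("cohort and truth sizes differ")
    rng = _rng(config.seed, stage)
    s = truth.true_signature_values
    hazard = config.baseline_hazard * np.exp(config.logHR_per_unit * s)
    e = rng.exponential(1.0, len(cohort))
    t = (e / hazard) ** (1.0 / config.weibull_shape)
    time = np.minimum(t, config.censor_time)
    event = (t <= config.censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=cohort.index)


def draw_case_cohort(
    survival: pd.DataFrame, fraction: float, seed: int
) -> CaseCohortDesign:
    """Draw a case-cohort sample: all cases plus a simple random subcohort.

    The subcohort has size ``round(fraction * N)``; members who are also
    cases are retained once with both roles recorded, so
    ``n_unique == n_cases + n_subcohort - n_overlap``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"invalid sampling fraction: {fraction!r}")
    rng = _rng(seed, _STAGE_CASECOHORT)
    ids = survival.index.to_numpy()
    n = len(ids)
    k = int(round(fraction * n))
    sub = set(rng.choice(ids, size=k, replace=False).tolist())
    cases = set(ids[survival["event"].to_numpy().astype(bool)].tolist())
    sampled = sorted(sub | cases)
    tab = pd.DataFrame(
        {
            "id": sampled,
            "in_subcohort": [i in sub for i in sampled],
            "is_case": [i in cases for i in sampled],
            "entry_time": 0.0,
            "event_time": survival.loc[sampled, "time"].to_numpy(),
            "event": survival.loc[sampled, "event"].to_numpy(),
        }
    )
    return CaseCohortDesign(table=tab, sampling_fraction=k / n, n_full_cohort=n)


def build_case_cohort_fixture(
    n_cases: int, n_subcohort: int, n_overlap: int, n_full: int, seed: int = 0
) -> CaseCohortDesign:
    """Construct a case-cohort design with exact membership counts.

    Used for accounting checks: ``n_overlap`` of the cases are placed inside
    the subcohort, so the design must contain exactly
    ``n_cases + n_subcohort - n_overlap`` unique participants. Event times
    are exponential, censoring times fill the rest.
    """
    if not (0 <= n_overlap <= min(n_cases, n_subcohort)):
        raise ConfigurationError("n_overlap must be <= min(n_cases, n_subcohort)")
    if n_cases + n_subcohort - n_overlap > n_full:
        raise ConfigurationError("counts exceed the full cohort size")
    rng = _rng(seed, _STAGE_CASECOHORT + 1)
    ids = np.arange(n_full)
    # cases: first n_cases ids; subcohort: n_overlap of them + the next block
    case_ids = ids[:n_cases]
    sub_ids = np.concatenate([ids[:n_overlap],
                              ids[n_cases:n_cases + n_subcohort - n_overlap]])
    sampled = np.unique(np.concatenate([case_ids, sub_ids]))
    is_case = np.isin(sampled, case_ids)
    t = np.where(is_case, rng.exponential(2.0, len(sampled)), 10.0)
    tab = pd.DataFrame({
        "id": sampled,
        "in_subcohort": np.isin(sampled, sub_ids),
        "is_case": is_case,
        "entry_time": 0.0,
        "event_time": t,
        "event": is_case.astype(int),
    })
    return CaseCohortDesign(
        table=tab, sampling_fraction=n_subcohort / n_full, n_full_cohort=n_full
    )


def make_exclusion_fixture(
    n_start: int,
    n_missing_ffq: int,
    n_energy_out: int,
    n_met_missing: int,
    seed: int = 0,
    n_metabolites: int = 30,
) -> tuple[pd.DataFrame, MetaboliteMatrix]:
    """Build a cohort + metabolome in which exactly the requested numbers of
    records violate each exclusion rule (all other records pass all rules).

    Violations are planted on disjoint participant sets: FFQ/lifestyle
    missingness flags, energy intake pushed strictly outside the
    sex-specific plausibility bounds, and >= 20% of metabolite values
    masked. Returns (cohort, metabolome) ready for
    :func:`hlmetsig.lifestyle.apply_exclusions`.
    """
    total = n_missing_ffq + n_energy_out + n_met_missing
    for name, v in [("n_start", n_start), ("n_missing_ffq", n_missing_ffq),
                    ("n_energy_out", n_energy_out), ("n_met_missing", n_met_missing)]:
        if v < 0:
            raise ConfigurationError(f"invalid count {name}: {v}")
    if total > n_start:
        raise ConfigurationError(
            f"exclusion counts sum to {total} > n_start={n_start}"
        )
    config = SimConfig(
        n_participants=n_start, n_metabolites=n_metabolites, n_true_signal=0,
        missing_rate=0.0, seed=seed,
    )
    cohort, truth = generate_cohort(config)
    metabolome = generate_metabolome(cohort, truth, config, stage=_STAGE_FIXTURE)

    rng = _rng(seed, _STAGE_FIXTURE + 100)
    order = rng.permutation(cohort.index.to_numpy())
    ffq_ids = order[:n_missing_ffq]
    energy_ids = order[n_missing_ffq:n_missing_ffq + n_energy_out]
    met_ids = order[n_missing_ffq + n_energy_out:total]

    cohort.loc[ffq_ids, "ffq_missing"] = True
    is_female = cohort.loc[energy_ids, "sex"] == "female"
    cohort.loc[energy_ids[is_female.to_numpy()], "energy_kcal"] = 3600.0
    cohort.loc[energy_ids[~is_female.to_numpy()], "energy_kcal"] = 4100.0

    n_mask = max(int(np.ceil(lifestyle.PARTICIPANT_MISSING_CUTOFF * n_metabolites)), 1)
    for pid in met_ids:
        cols = rng.choice(n_metabolites, size=n_mask, replace=False)
        metabolome.values.loc[pid, metabolome.values.columns[cols]] = np.nan
    return cohort, metabolome
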