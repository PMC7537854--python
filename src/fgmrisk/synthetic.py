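"""Synthetic populations and DHS/MICS-like survey samples with known FGM hazards.

Real inputs for this kind of analysis are restricted-access household survey
microdata.  This module generates stand-ins with a fully known data-generating
process so every downstream stage — event-history reconstruction, weighting,
pooling, weighted Kaplan-Meier estimation — can be validated against ground
truth.

The generative model is a discrete per-year-of-age hazard of being cut,
``h(a)``, shifted on the log-odds scale by birth cohort and by rural residence:

    logit h(a; birth_year, rural) = logit h0(a) + delta * (birth_year - ref_year) + beta_rural * rural

A negative ``delta`` produces the secular decline in cutting risk across birth
cohorts that the analysis is designed to detect.  Sampling mimics a stratified
two-stage cluster design: clusters (PSUs) are drawn without replacement within
strata, then households within clusters; one eligible woman (aged 15-49 at
interview) per household, each with a Poisson number of daughters aged 0-14.
Normalized sampling weights follow the DHS convention (inverse inclusion
probability scaled to mean 1 over sampled women); daughters inherit their
mother's weight.  Optional misreporting: event-age heaping onto multiples of
five and "during infancy" coding of events at ages 0-1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .km import MAX_AGE, N_AGES, SurvivalCurve

#: sentinel event age for individuals who are never cut
NEVER = -1


def default_hazard() -> np.ndarray:
    """A realistic baseline hazard of cutting by single year of age.

    Risk is concentrated in infancy and around ages 5-10, tails off through
    the teens and is zero from age 20 on — the broad age pattern reported for
    practising countries.  Lifetime risk under this baseline is ~48%.
    """
    h = np.zeros(N_AGES)
    h[0] = 0.10
    h[1:5] = [0.05, 0.04, 0.03, 0.03]
    h[5:10] = [0.05, 0.06, 0.06, 0.05, 0.04]
    h[10:15] = [0.03, 0.02, 0.015, 0.010, 0.008]
    h[15:20] = 0.004
    return h


@dataclass
class SyntheticSpec:
    """Full description of one synthetic population and its survey design.

    Parameters
    ----------
    baseline_hazard
        Per-age event probabilities h0(a), a = 0..49, each in [0, 1].
    cohort_trend
        Log-odds shift per birth year (delta); negative = declining risk.
    residence_effect
        Log-odds shift for rural relative to urban residence.
    birth_year_range
        Inclusive range of birth years the population may contain.
    p_rural
        Proportion of clusters designated rural.
    n_strata, clusters_per_stratum, households_per_cluster
        Population frame sizes (one eligible woman per household).
    clusters_sampled_per_stratum, households_sampled_per_cluster
        Second/third numbers of the two-stage sample; a scalar applies to
        every stratum, a sequence gives per-stratum sizes (unequal sampling
        fractions produce unequal weights).
    daughters_mean
        Poisson mean number of daughters aged 0-14 per woman.
    heaping_prob
        Probability a recorded event age is rounded to the nearest multiple
        of 5 (ties round down); applied to event ages only.
    infancy_code_prob
        Probability an event at age 0 or 1 is recorded as "during infancy".
    ref_year, interview_year
        Reference birth year for the cohort trend and the interview year.
    seed
        Seed for all randomness; identical specs give byte-identical output.
    """

    baseline_hazard: np.ndarray = field(default_factory=default_hazard)
    cohort_trend: float = -0.03
    residence_effect: float = 0.6
    birth_year_range: tuple[int, int] = (1960, 2015)
    p_rural: float = 0.65
    n_strata: int = 2
    clusters_per_stratum: int = 30
    households_per_cluster: int = 20
    clusters_sampled_per_stratum: int | Sequence[int] = 10
    households_sampled_per_cluster: int | Sequence[int] = 10
    daughters_mean: float = 1.2
    heaping_prob: float = 0.2
    infancy_code_prob: float = 0.25
    ref_year: int = 1990
    interview_year: int = 2015
    seed: int = 0

    def __post_init__(self):
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if self.baseline_hazard.shape != (N_AGES,):
            raise ValueError(
                f"baseline_hazard must have length {N_AGES}, got {self.baseline_hazard.shape}"
            )
        if np.any(self.baseline_hazard < 0) or np.any(self.baseline_hazard > 1):
            raise ValueError("baseline_hazard values must lie in [0, 1]")
        if not 0.0 <= self.p_rural <= 1.0:
            raise ValueError("p_rural must lie in [0, 1]")
        for name in ("n_strata", "clusters_per_stratum", "households_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name, frame in (
            ("clusters_sampled_per_stratum", self.clusters_per_stratum),
            ("households_sampled_per_cluster", self.households_per_cluster),
        ):
            vals = np.atleast_1d(np.asarray(getattr(self, name)))
            if np.any(vals < 1) or np.any(vals > frame):
                raise ValueError(f"{name} must lie in [1, {frame}]")

    def _per_stratum(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=np.int64))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_strata)
        if arr.size != self.n_strata:
            raise ValueError("per-stratum sampling sizes must match n_strata")
        return arr

    def hazard(self, birth_year, rural) -> np.ndarray:
        """Per-age hazard vector(s) for given birth year(s) and residence.

        The logistic link keeps every shifted hazard inside [0, 1]; baseline
        entries of exactly 0 or 1 are preserved under any shift.
        """
        scalar = np.isscalar(birth_year) or np.ndim(birth_year) == 0
        by = np.atleast_1d(np.asarray(birth_year, dtype=float))
        ru = np.atleast_1d(np.asarray(rural, dtype=float))
        with np.errstate(divide="ignore"):
            lo = logit(self.baseline_hazard)
        shift = self.cohort_trend * (by - self.ref_year) + self.residence_effect * ru
        h = expit(lo[np.newaxis, :] + shift[:, np.newaxis])
        return h[0] if scalar else h


@dataclass
class SyntheticPopulation:
    """A generated population frame: women 15-49 and their daughters 0-14.

    ``women`` and ``daughters`` are DataFrames sharing the design columns
    (stratum, cluster, household, residence) with ``birth_year``,
    ``current_age`` and the ground-truth ``true_age_at_fgm`` (-1 = never);
    daughters carry ``mother_id``.
    """

    women: pd.DataFrame
    daughters: pd.DataFrame
    spec: SyntheticSpec

    @property
    def size(self) -> int:
        return len(self.women) + len(self.daughters)


def _draw_event_ages(hazards: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sequential Bernoulli over ages 0..49; returns age of event or NEVER."""
    n = hazards.shape[0]
    u = rng.random((n, N_AGES))
    hit = u < hazards
    any_hit = hit.any(axis=1)
    ages = np.where(any_hit, hit.argmax(axis=1), NEVER)
    return ages.astype(np.int64)


def make_population(spec: SyntheticSpec) -> SyntheticPopulation:
    """Generate the full population frame described by ``spec``.

    Women's birth years are uniform over the eligible window (aged 15-49 at
    interview, intersected with ``birth_year_range``); residence is assigned
    at cluster level (clusters are residence-homogeneous, as DHS enumeration
    areas are).  Every individual's age at cutting is drawn by sequential
    Bernoulli trials over ages with her own cohort/residence hazard.
    """
    rng = np.random.default_rng(spec.seed)
    iy = spec.interview_year
    lo = max(spec.birth_year_range[0], iy - MAX_AGE)
    hi = min(spec.birth_year_range[1], iy - 15)
    if lo > hi:
        raise ValueError("no eligible women: birth_year_range excludes ages 15-49 at interview")

    n_clusters = spec.n_strata * spec.clusters_per_stratum
    n_women = n_clusters * spec.households_per_cluster
    stratum = np.repeat(np.arange(spec.n_strata), spec.clusters_per_stratum * spec.households_per_cluster)
    cluster = np.repeat(np.arange(n_clusters), spec.households_per_cluster)
    household = np.tile(np.arange(spec.households_per_cluster), n_clusters)
    cluster_rural = (rng.random(n_clusters) < spec.p_rural).astype(np.int64)
    rural = cluster_rural[cluster]

    birth_year = rng.integers(lo, hi + 1, size=n_women)
    haz = spec.hazard(birth_year, rural)
    true_age = _draw_event_ages(haz, rng)

    women = pd.DataFrame(
        {
            "woman_id": np.arange(n_women),
            "stratum": np.char.add("S", (stratum + 1).astype(str)),
            "cluster": np.char.add("C", (cluster + 1).astype(str)),
            "household": household + 1,
            "region": np.char.add("R", (stratum + 1).astype(str)),
            "residence": np.where(rural == 1, "rural", "urban"),
            "birth_year": birth_year,
            "current_age": iy - birth_year,
            "true_age_at_fgm": true_age,
        }
    )

    # daughters aged 0-14 at interview, born within the allowed range
    n_d = rng.poisson(spec.daughters_mean, size=n_women)
    mother_idx = np.repeat(np.arange(n_women), n_d)
    d_lo = max(spec.birth_year_range[0], iy - 14)
    d_age = rng.integers(0, min(14, iy - d_lo) + 1, size=mother_idx.size)
    d_by = iy - d_age
    d_haz = spec.hazard(d_by, rural[mother_idx])
    d_true = _draw_event_ages(d_haz, rng)
    daughters = pd.DataFrame(
        {
            "daughter_id": np.arange(mother_idx.size),
            "mother_id": mother_idx,
            "stratum": women["stratum"].to_numpy()[mother_idx],
            "cluster": women["cluster"].to_numpy()[mother_idx],
            "household": women["household"].to_numpy()[mother_idx],
            "region": women["region"].to_numpy()[mother_idx],
            "residence": women["residence"].to_numpy()[mother_idx],
            "birth_year": d_by,
            "current_age": d_age,
            "true_age_at_fgm": d_true,
        }
    )
    return SyntheticPopulation(women=women, daughters=daughters, spec=spec)


def true_survival(spec: SyntheticSpec, birth_year: int, residence: str) -> SurvivalCurve:
    """Ground-truth S(t) = prod_{a<=t} (1 - h(a)) for one birth year and residence."""
    lo, hi = spec.birth_year_range
    if not lo <= birth_year <= hi:
        raise ValueError(f"birth_year {birth_year} outside range {spec.birth_year_range}")
    rural = {"rural": 1, "urban": 0}[residence]
    h = spec.hazard(birth_year, rural)
    s = np.cumprod(1.0 - h)
    return SurvivalCurve(s=s, meta={"birth_year": birth_year, "residence": residence, "truth": True})


def true_mixture_survival(spec: SyntheticSpec, birth_years: Sequence[int],
                          residence: str | None = None) -> np.ndarray:
    """Population-mixture truth: mean of S(t) over birth years (and residences).

    With ``residence=None`` the urban/rural mix uses ``spec.p_rural``.  This is
    the estimand a cohort-pooled Kaplan-Meier curve targets when the cohort
    spans several birth years.
    """
    curves = []
    for by in birth_years:
        if residence is None:
            s = (spec.p_rural * true_survival(spec, by, "rural").s
                 + (1 - spec.p_rural) * true_survival(spec, by, "urban").s)
        else:
            s = true_survival(spec, by, residence).s
        curves.append(s)
    return np.mean(curves, axis=0)


def _heap(ages: np.ndarray) -> np.ndarray:
    # nearest multiple of 5, ties (impossible for integers) toward zero
    return np.clip(5 * ((ages + 2) // 5), 0, MAX_AGE)


@dataclass
class SurveyTables:
    """Sampled women's and daughters' tables in the pipeline's input format."""

    women: pd.DataFrame
    daughters: pd.DataFrame
    survey_id: str
    interview_year: int


def sample_survey(pop: SyntheticPopulation, spec: SyntheticSpec | None = None,
                  interview_year: int | None = None, survey_id: str = "SYN1",
                  rng=None) -> SurveyTables:
    """Draw a stratified two-stage cluster sample and record it as survey tables.

    Weights are inverse inclusion probabilities normalized to mean 1 over
    sampled women; daughters inherit their mother's weight.  Recorded FGM
    status right-censors true event ages at the current age, and age heaping /
    infancy coding are applied to recorded event ages per the spec.
    """
    spec = spec or pop.spec
    iy = interview_year if interview_year is not None else spec.interview_year
    rng = np.random.default_rng(spec.seed + 1 if rng is None else rng)

    c_samp = spec._per_stratum(spec.clusters_sampled_per_stratum)
    h_samp = spec._per_stratum(spec.households_sampled_per_cluster)

    women = pop.women
    keep_rows = []
    incl_prob = []
    for h in range(spec.n_strata):
        label = f"S{h + 1}"
        clusters = women.loc[women["stratum"] == label, "cluster"].unique()
        chosen = rng.choice(clusters, size=c_samp[h], replace=False)
        p_cluster = c_samp[h] / len(clusters)
        for cl in chosen:
            hh = women.index[(women["stratum"] == label) & (women["cluster"] == cl)].to_numpy()
            take = rng.choice(hh, size=min(h_samp[h], len(hh)), replace=False)
            p = p_cluster * (len(take) / len(hh))
            keep_rows.append(np.sort(take))
            incl_prob.append(np.full(len(take), p))
    keep = np.concatenate(keep_rows)
    prob = np.concatenate(incl_prob)

    sw = women.loc[keep].copy().reset_index(drop=True)
    age_now = (iy - sw["birth_year"]).to_numpy()
    sw["current_age"] = age_now
    eligible = (age_now >= 15) & (age_now <= MAX_AGE)
    sw = sw.loc[eligible].reset_index(drop=True)
    prob = prob[eligible]
    if not len(sw):
        import warnings

        warnings.warn(f"no woman aged 15-49 at interview year {iy}; empty survey")
    raw_w = 1.0 / prob
    weight = raw_w * (len(sw) / raw_w.sum()) if len(sw) else raw_w

    def record(df, weights):
        true_age = df["true_age_at_fgm"].to_numpy()
        cur = df["current_age"].to_numpy()
        status = (true_age != NEVER) & (true_age <= cur)
        rec_age = true_age.astype(object)
        ev = np.where(status)[0]
        heap_mask = rng.random(len(df)) < spec.heaping_prob
        inf_mask = rng.random(len(df)) < spec.infancy_code_prob
        for i in ev:
            a = int(true_age[i])
            if heap_mask[i]:
                # heaped ages never exceed the reported current age: a report
                # "cut at 10" for a 9-year-old cannot occur in a clean interview
                a = min(int(_heap(np.array([a]))[0]), int(cur[i]))
            if a <= 1 and inf_mask[i]:
                rec_age[i] = "during infancy"
            else:
                rec_age[i] = a
        out = df[["stratum", "cluster", "household", "region", "residence",
                  "birth_year", "current_age"]].copy()
        out.insert(0, "survey_id", survey_id)
        out["fgm_status"] = status.astype(np.int64)
        out["age_at_fgm"] = [rec_age[i] if status[i] else "" for i in range(len(df))]
        out["weight"] = weights
        out["interview_year"] = iy
        return out

    women_out = record(sw, weight)
    women_out.insert(1, "woman_id", sw["woman_id"].to_numpy())

    dmask = pop.daughters["mother_id"].isin(sw["woman_id"])
    sd = pop.daughters.loc[dmask].copy().reset_index(drop=True)
    d_age = (iy - sd["birth_year"]).to_numpy()
    sd["current_age"] = d_age
    sd = sd.loc[(d_age >= 0) & (d_age <= 14)].reset_index(drop=True)
    wmap = dict(zip(sw["woman_id"], weight))
    daughters_out = record(sd, sd["mother_id"].map(wmap).to_numpy())
    daughters_out.insert(1, "daughter_id", sd["daughter_id"].to_numpy())
    daughters_out.insert(2, "mother_id", sd["mother_id"].to_numpy())

    return SurveyTables(women=women_out, daughters=daughters_out,
                        survey_id=survey_id, interview_year=iy)


def simulate_survey(spec: SyntheticSpec, survey_id: str = "SYN1",
                    interview_year: int | None = None) -> SurveyTables:
    """Convenience: population + sample in one call."""
    pop = make_population(spec)
    return sample_survey(pop, spec, interview_year=interview_year, survey_id=survey_id)


def write_survey(tables: SurveyTables, out_dir) -> tuple[Path, Path]:
    """Write the women's and daughters' tables as CSV; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wp = out_dir / f"{tables.survey_id}_women.csv"
    dp = out_dir / f"{tables.survey_id}_daughters.csv"
    tables.women.to_csv(wp, index=False)
    tables.daughters.to_csv(dp, index=False)
    return wp, dp
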