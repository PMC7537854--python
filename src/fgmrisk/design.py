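"""Complex-sampling structure: weights, strata/PSUs, de-normalization, pooling.

DHS/MICS-style surveys ship *normalized* sampling weights (inverse inclusion
probabilities scaled to mean 1 over sampled women).  Within one survey any
positive rescaling of the weights leaves a Kaplan-Meier point estimate
unchanged, but pooling several surveys requires each to contribute in
proportion to the population it represents: weights are therefore
*de-normalized* by a user-supplied population total (eligible women in the
country-year) before pooling.  Pooled records keep their design structure,
with stratum and PSU identifiers namespaced by survey so the pooled set
behaves as one super-design whose strata are the union of the surveys'
strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .events import ExclusionLog


@dataclass
class SurveyDesignSpec:
    """Design declaration for one survey.

    ``population_total`` is the number of eligible women (15-49) in the
    country-year, supplied by the user (e.g. from World Population Prospects);
    ``sample_size_women`` is the number of sampled women the normalization was
    taken over.
    """

    survey_id: str
    population_total: float
    sample_size_women: int
    country: str = ""
    normalization: str = "normalized_mean_one"  # or "raw"

    def __post_init__(self):
        if self.population_total <= 0:
            raise ValueError(f"population_total must be positive, got {self.population_total}")
        if self.sample_size_women <= 0:
            raise ValueError(f"sample_size_women must be positive, got {self.sample_size_women}")

    @property
    def denorm_factor(self) -> float:
        return self.population_total / self.sample_size_women


def denormalize_weights(records: pd.DataFrame, spec: SurveyDesignSpec) -> pd.DataFrame:
    """Rescale normalized weights so women's weights sum to the population total.

    Every record's weight (daughters included — they carry their mother's
    weight) is multiplied by ``population_total / sample_size_women``.
    """
    out = records.copy()
    out["weight"] = out["weight"].astype(float) * spec.denorm_factor
    return out


def pool_surveys(surveys: Sequence[tuple[pd.DataFrame, SurveyDesignSpec]]) -> pd.DataFrame:
    """Concatenate de-normalized surveys into one analysis table.

    Stratum and PSU identifiers are namespaced as ``survey_id:stratum`` and
    ``survey_id:psu`` so no identifier collides across surveys; each survey's
    strata remain distinct strata of the pooled super-design.
    """
    seen = set()
    parts = []
    for records, spec in surveys:
        if spec.survey_id in seen:
            raise ValueError(f"duplicate survey_id in pool: {spec.survey_id!r}")
        seen.add(spec.survey_id)
        part = records.copy()
        part["survey_id"] = spec.survey_id
        if spec.country:
            part["country"] = spec.country
        part["stratum_id"] = spec.survey_id + ":" + part["stratum_id"].astype(str)
        part["psu_id"] = spec.survey_id + ":" + part["psu_id"].astype(str)
        parts.append(part)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def apply_region_exclusions(records: pd.DataFrame, exclusions: Iterable[str],
                            *, survey_id: str, region_col: str = "region",
                            log: ExclusionLog | None = None,
                            ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop listed regions from one survey's raw table, logging the counts.

    Used to keep pooled surveys geographically comparable when a region was
    not continuously covered across a country's surveys.  Naming a region
    absent from the data is a warning, not an error.
    """
    log = log if log is not None else ExclusionLog()
    exclusions = [str(r) for r in exclusions]
    if not exclusions:
        return records, log
    if region_col not in records.columns:
        raise ValueError(f"region exclusions given but column {region_col!r} is absent")
    regions = records[region_col].astype(str)
    present = set(regions)
    for r in exclusions:
        if r not in present:
            import warnings

            warnings.warn(f"survey {survey_id}: region {r!r} not present in data")
    mask = regions.isin(exclusions)
    n_drop = int(mask.sum())
    if n_drop:
        log.add(survey_id, "region_excluded", n_drop)
    return records.loc[~mask].reset_index(drop=True), log
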