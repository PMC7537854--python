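"""End-to-end cohort analysis: ingest, reconstruct, pool, estimate, report.

``run_analysis`` drives the full chain — raw women's/daughters' tables per
survey → region exclusions → event-history reconstruction → weight
de-normalization → pooling → cohort/residence/country-stratified weighted
Kaplan-Meier curves with design-based confidence intervals — and writes the
tabular outputs (curves, unweighted cohort counts, exclusion log, run report)
deterministically: the same config and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import km
from .design import SurveyDesignSpec, apply_region_exclusions, denormalize_weights, pool_surveys
from .events import CohortScheme, ColumnMapping, ExclusionLog, build_event_table

FLOAT_FORMAT = "%.12g"


@dataclass
class SurveyInput:
    """One survey's files and design declaration inside a run config."""

    survey_id: str
    women_file: str
    population_total: float
    sample_size_women: int | None = None  # default: number of women rows read
    daughters_file: str | None = None
    country: str = ""
    region_exclusions: tuple = ()

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyInput":
        d = dict(d)
        if "region_exclusions" in d:
            d["region_exclusions"] = tuple(d["region_exclusions"])
        return cls(**d)


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``group_by`` adds stratification on top of birth cohort: any subset of
    ``{"residence", "country"}`` (empty = pooled cohort curves only).
    """

    surveys: list[SurveyInput]
    cohort_width: int = 10
    group_by: tuple = ()
    ci_level: float = 0.95
    ci_method: str = "log"
    lonely_psu: str = "error"
    output_dir: str = "fgmrisk_output"
    seed: int = 0
    mapping: ColumnMapping = field(default_factory=ColumnMapping)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["surveys"] = [SurveyInput.from_dict(s) for s in d["surveys"]]
        if "mapping" in d:
            d["mapping"] = ColumnMapping.from_dict(d["mapping"])
        if "group_by" in d:
            d["group_by"] = tuple(d["group_by"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> str:
        """Canonical JSON of everything that affects the analysis.

        ``output_dir`` is excluded so re-running the same analysis into a
        different directory yields byte-identical outputs.
        """

        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items() if k != "output_dir"}
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        return json.dumps(self, default=default, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Curves per grouping cell plus bookkeeping for audit and reproduction."""

    curves: dict[tuple, km.SurvivalCurve]
    counts: pd.DataFrame
    exclusions: ExclusionLog
    records: pd.DataFrame
    report: dict

    def cell(self, cohort: str, **labels) -> km.SurvivalCurve:
        """Look up one cell by cohort label and any extra grouping labels."""
        for key, curve in self.curves.items():
            meta = dict(key)
            if meta.get("cohort") == cohort and all(meta.get(k) == v for k, v in labels.items()):
                return curve
        raise KeyError(f"no cell with cohort={cohort!r}, {labels}")

    def curves_frame(self) -> pd.DataFrame:
        parts = [curve.to_frame() for key, curve in sorted(self.curves.items())]
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def cohort_counts(records: pd.DataFrame, scheme: CohortScheme) -> pd.DataFrame:
    """Unweighted record counts per cohort label, in chronological order."""
    if not len(records):
        return pd.DataFrame({"cohort": [], "count": []})
    counts = records.groupby("cohort").size()
    order = [lab for lab in scheme.labels() if lab in counts.index]
    return pd.DataFrame({"cohort": order,
                         "count": [int(counts[lab]) for lab in order]})


def _load_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path, keep_default_na=False)


def build_pooled_table(config: RunConfig) -> tuple[pd.DataFrame, ExclusionLog, dict]:
    """Ingest every survey, reconstruct events, de-normalize and pool."""
    scheme = CohortScheme(width=config.cohort_width)
    log = ExclusionLog()
    pieces = []
    per_survey = {}
    for si in config.surveys:
        women = _load_table(si.women_file)
        daughters = _load_table(si.daughters_file) if si.daughters_file else None
        n_raw = len(women) + (len(daughters) if daughters is not None else 0)
        if si.region_exclusions:
            women, _ = apply_region_exclusions(
                women, si.region_exclusions, survey_id=si.survey_id,
                region_col=config.mapping.region, log=log)
            if daughters is not None:
                daughters, _ = apply_region_exclusions(
                    daughters, si.region_exclusions, survey_id=si.survey_id,
                    region_col=config.mapping.region, log=log)
        table, survey_log = build_event_table(
            women, daughters, config.mapping, scheme,
            survey_id=si.survey_id, country=si.country or si.survey_id)
        log.merge(survey_log)
        n_women = int((table["source"] == "self").sum()) if len(table) else 0
        spec = SurveyDesignSpec(
            survey_id=si.survey_id,
            population_total=si.population_total,
            sample_size_women=si.sample_size_women or max(n_women, 1),
            country=si.country or si.survey_id,
        )
        pieces.append((denormalize_weights(table, spec), spec))
        per_survey[si.survey_id] = {"raw_rows": n_raw, "retained": len(table),
                                    "excluded": log.total(si.survey_id)}
    pooled = pool_surveys(pieces)
    return pooled, log, per_survey


def run_analysis(config: RunConfig, write: bool = True) -> AnalysisResult:
    """Execute the full pipeline described by ``config``.

    Grouping is computed by splitting the pooled event table once; cells with
    no records are skipped with a warning collected in the report.  When
    ``write`` is true the curve, count, exclusion and report files are written
    under ``config.output_dir``.
    """
    scheme = CohortScheme(width=config.cohort_width)
    pooled, log, per_survey = build_pooled_table(config)
    group_cols = ["cohort"] + [c for c in config.group_by if c in ("residence", "country")]

    curves: dict[tuple, km.SurvivalCurve] = {}
    warnings_list = []
    if len(pooled):
        for key, cell in pooled.groupby(group_cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            labels = tuple(zip(group_cols, (str(k) for k in key)))
            if not len(cell):
                warnings_list.append(f"empty cell skipped: {dict(labels)}")
                continue
            try:
                curve = km.km_variance(cell, lonely_psu=config.lonely_psu)
                km.confidence_interval(curve, level=config.ci_level, method=config.ci_method)
            except ValueError as err:
                warnings_list.append(f"cell {dict(labels)}: {err}")
                curve = km.km_estimate(km.risk_table(cell))
            curve.meta.update(dict(labels))
            curves[labels] = curve

    counts = cohort_counts(pooled, scheme)
    report = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "cohort_width": config.cohort_width,
        "group_by": list(config.group_by),
        "n_cells": len(curves),
        "records_retained": int(len(pooled)),
        "records_excluded": log.total(),
        "per_survey": per_survey,
        "total_weight": float(pooled["weight"].sum()) if len(pooled) else 0.0,
        "warnings": warnings_list,
    }
    result = AnalysisResult(curves=curves, counts=counts, exclusions=log,
                            records=pooled, report=report)
    if write:
        write_outputs(result, config)
    return result


def write_outputs(result: AnalysisResult, config: RunConfig) -> Path:
    """Write curves.csv, counts.csv, exclusions.json and report.json."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.curves_frame().to_csv(out / "curves.csv", index=False,
                                 float_format=FLOAT_FORMAT, lineterminator="\n")
    result.counts.to_csv(out / "counts.csv", index=False, lineterminator="\n")
    result.exclusions.to_json(out / "exclusions.json")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    try:  # plots are optional artifacts; a missing backend never fails a run
        plot_curves(result, out / "curves.png")
    except Exception:
        pass
    return out


def plot_curves(result: AnalysisResult, path) -> None:
    """Survival curves per grouping cell, one panel per non-cohort label combo."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels: dict[tuple, list] = {}
    for key, curve in sorted(result.curves.items()):
        meta = dict(key)
        panel = tuple((k, v) for k, v in meta.items() if k != "cohort")
        panels.setdefault(panel, []).append((meta.get("cohort", ""), curve))
    n = max(len(panels), 1)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), squeeze=False, sharey=True)
    for ax, (panel, items) in zip(axes[0], sorted(panels.items())):
        for cohort, curve in items:
            ax.step(curve.age, curve.s, where="post", label=cohort)
        ax.set_title(", ".join(f"{k}={v}" for k, v in panel) or "pooled")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("S(t) = P(not cut by age t)")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rural_urban_report(result: AnalysisResult, ages) -> pd.DataFrame:
    """Per cohort and age: urban vs rural survival, difference, SE, z, p.

    Cohorts missing one of the two residence cells are omitted with a note
    column rather than failing the whole report.
    """
    cohorts = sorted({dict(k).get("cohort") for k in result.curves})
    rows = []
    for cohort in cohorts:
        try:
            urban = result.cell(cohort, residence="urban")
            rural = result.cell(cohort, residence="rural")
        except KeyError:
            rows.append({"cohort": cohort, "note": "missing residence cell"})
            continue
        if urban.se is None or rural.se is None:
            rows.append({"cohort": cohort, "note": "no variance estimate for this cell"})
            continue
        cmp = km.compare_curves(urban, rural, ages)
        cmp = cmp.rename(columns={"s_a": "s_urban", "s_b": "s_rural"})
        cmp.insert(0, "cohort", cohort)
        rows.append(cmp)
    frames = [r for r in rows if isinstance(r, pd.DataFrame)]
    notes = pd.DataFrame([r for r in rows if isinstance(r, dict)])
    out = pd.concat(frames + ([notes] if len(notes) else []), ignore_index=True) \
        if frames or len(notes) else pd.DataFrame()
    return out
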