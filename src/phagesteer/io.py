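"""File formats, run configuration and the end-to-end pipeline.

All artifacts are plain CSV/TSV (the wet-lab analogue is plate-reader
exports) with commented ``# key: value`` metadata headers carrying the seed
and a hash of the run configuration, so any numeric output can be traced back
to the exact run that produced it.  Schemas are validated strictly on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import growth as growth_mod
from . import resistance as resistance_mod
from . import simulator as sim_mod
from . import stats as stats_mod
from .design import TreatmentSpec, arms_from_config, enumerate_design
from .resistance import KillingAssayRecord
from .simulator import SimParams, Trajectory

__all__ = [
    "TableSchema",
    "SchemaError",
    "OD_SCHEMA",
    "PRESENCE_SCHEMA",
    "ASSAY_SCHEMA",
    "GROWTH_CURVE_SCHEMA",
    "DESIGN_SCHEMA",
    "write_table",
    "read_table",
    "trajectories_to_od_table",
    "trajectories_to_presence_table",
    "assays_to_table",
    "table_to_assays",
    "profiles_to_table",
    "RunConfig",
    "config_hash",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A tabular artifact does not match its documented schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column names and numpy dtype kinds ('i' int, 'f' float, 'b' bool,
    'O' string) of one tabular artifact."""

    name: str
    columns: tuple[tuple[str, str], ...]

    @property
    def column_names(self) -> list[str]:
        return [c for c, _ in self.columns]


OD_SCHEMA = TableSchema(
    "od", (("population_id", "O"), ("day", "i"), ("od600", "f"), ("censored", "b"))
)
PRESENCE_SCHEMA = TableSchema(
    "presence", (("population_id", "O"), ("day", "i"), ("phage", "O"), ("present", "b"))
)
ASSAY_SCHEMA = TableSchema(
    "assays",
    (
        ("isolate_id", "O"),
        ("day", "i"),
        ("phage", "O"),
        ("replicate", "i"),
        ("iso_p", "f"),
        ("iso_np", "f"),
        ("wt_p", "f"),
        ("wt_np", "f"),
        ("below_detection", "b"),
    ),
)
GROWTH_CURVE_SCHEMA = TableSchema(
    "growth_curves", (("isolate_id", "O"), ("minute", "f"), ("od600", "f"))
)
DESIGN_SCHEMA = TableSchema(
    "design",
    (
        ("population_id", "O"),
        ("strategy", "O"),
        ("first_phage", "O"),
        ("timing", "O"),
        ("second_dose_phage", "O"),
        ("replicate", "i"),
    ),
)

_KIND_CAST = {"i": "int64", "f": "float64", "b": "bool", "O": "object"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    schema: TableSchema | None = None,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Write a table as CSV/TSV (by extension) with a commented metadata
    header; validates against ``schema`` first when given."""
    path = Path(path)
    if schema is not None:
        df = _validate(df, schema)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)
    return path


def _validate(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name} table missing columns: {missing}")
    out = df[schema.column_names].copy()
    for col, kind in schema.columns:
        try:
            out[col] = out[col].astype(_KIND_CAST[kind])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{schema.name}.{col}: cannot coerce to {kind!r}: {exc}")
    return out


def read_table(path: str | Path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a CSV/TSV artifact, skipping ``#`` metadata lines; validates
    against ``schema`` when given.  Accepts either newline convention."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", encoding="utf-8")
    if schema is not None:
        df = _validate(df, schema)
    return df


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse the commented ``# key: value`` header of an artifact."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# Converters between domain objects and tables

def trajectories_to_od_table(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for day, od, cens in zip(traj.days, traj.od600, traj.censored):
            rows.append(
                {
                    "population_id": traj.population_id,
                    "day": int(day),
                    "od600": float(od),
                    "censored": bool(cens),
                }
            )
    return pd.DataFrame(rows, columns=OD_SCHEMA.column_names)


def trajectories_to_presence_table(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for phage, flags in traj.phage_present.items():
            for day, flag in zip(traj.days, flags):
                rows.append(
                    {
                        "population_id": traj.population_id,
                        "day": int(day),
                        "phage": phage,
                        "present": bool(flag),
                    }
                )
    return pd.DataFrame(rows, columns=PRESENCE_SCHEMA.column_names)


def assays_to_table(records: Iterable[KillingAssayRecord]) -> pd.DataFrame:
    rows = [
        {
            "isolate_id": r.isolate_id,
            "day": r.day,
            "phage": r.phage,
            "replicate": r.replicate_index,
            "iso_p": r.iso_p,
            "iso_np": r.iso_np,
            "wt_p": r.wt_p,
            "wt_np": r.wt_np,
            "below_detection": r.below_detection,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ASSAY_SCHEMA.column_names)


def table_to_assays(df: pd.DataFrame) -> list[KillingAssayRecord]:
    df = _validate(df, ASSAY_SCHEMA)
    return [
        KillingAssayRecord(
            isolate_id=row.isolate_id,
            day=int(row.day),
            phage=row.phage,
            iso_p=float(row.iso_p),
            iso_np=float(row.iso_np),
            wt_p=float(row.wt_p),
            wt_np=float(row.wt_np),
            replicate_index=int(row.replicate),
            below_detection=bool(row.below_detection),
        )
        for row in df.itertuples(index=False)
    ]


def profiles_to_table(profiles: Iterable[resistance_mod.ResistanceProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "isolate_id": p.isolate_id,
                "day": p.day,
                "rc_t2": p.rc_t2.rc,
                "rc_t2_ci_low": p.rc_t2.ci_low,
                "rc_t2_ci_high": p.rc_t2.ci_high,
                "rc_lambda": p.rc_lambda.rc,
                "rc_lambda_ci_low": p.rc_lambda.ci_low,
                "rc_lambda_ci_high": p.rc_lambda.ci_high,
                "quadrant": p.quadrant.value,
                "significant": p.significant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration and the pipeline

@dataclass
class RunConfig:
    """Everything needed to reproduce one synthetic experiment + analysis."""

    arms: list[TreatmentSpec]
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0
    alpha: float = 0.05
    n_boot: int = 2000
    sampling_days: tuple[int, ...] = (1, 3, 6)
    isolates_per_day: int = 3
    assay_replicates: int = 3
    candidate_terms: tuple[tuple[str, ...], ...] = (
        ("strategy",),
        ("strategy", "first_phage"),
        ("strategy", "first_phage", "timing"),
        ("strategy", "first_phage", "timing", "strategy:first_phage"),
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RunConfig":
        payload = dict(payload)
        arms = arms_from_config(payload.pop("arms", []))
        params = payload.pop("params", None)
        sim = SimParams(**params) if isinstance(params, Mapping) else (params or SimParams())
        if "candidate_terms" in payload:
            payload["candidate_terms"] = tuple(
                tuple(terms) for terms in payload["candidate_terms"]
            )
        if "sampling_days" in payload:
            payload["sampling_days"] = tuple(payload["sampling_days"])
        return cls(arms=arms, params=sim, **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value"):
        return obj.value
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full run configuration."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate the design and run every analysis stage, writing all
    artifacts under ``outdir``.  Fully deterministic given the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    written: dict[str, Path] = {}

    design_table = enumerate_design(config.arms)
    written["design"] = write_table(
        design_table, outdir / "design.tsv", DESIGN_SCHEMA, meta
    )

    trajectories = sim_mod.run_design(config.arms, config.params, config.seed)
    od_table = trajectories_to_od_table(trajectories)
    written["od"] = write_table(od_table, outdir / "od.csv", OD_SCHEMA, meta)
    written["presence"] = write_table(
        trajectories_to_presence_table(trajectories),
        outdir / "presence.csv",
        PRESENCE_SCHEMA,
        meta,
    )

    # treatment-level inference on the mean-density response
    response = stats_mod.mean_density_response(od_table, design_table)
    written["responses"] = write_table(response, outdir / "responses.tsv", None, meta)
    multi = response[response["strategy"] != "control"]
    def _estimable(terms: Sequence[str]) -> bool:
        factors = {f for term in terms for f in term.split(":")}
        return all(multi[f].nunique() > 1 for f in factors)

    usable_terms = [terms for terms in config.candidate_terms if _estimable(terms)]
    if usable_terms:
        best, comparison = stats_mod.select_model(multi, usable_terms)
        written["model_comparison"] = write_table(
            comparison, outdir / "model_comparison.tsv", None, meta
        )
        coef = pd.DataFrame(
            {"coefficient": best.params, "t": best.tvalues, "p": best.pvalues}
        ).reset_index(names="term")
        written["coefficients"] = write_table(
            coef, outdir / "coefficients.tsv", None, {**meta, "formula": best.formula}
        )

    # pairwise Mann-Whitney family on the mean response per arm
    arm_groups = {
        label: sub["response"].to_numpy()
        for label, sub in response.groupby(
            response["population_id"].str.rsplit("_r", n=1).str[0]
        )
        if len(sub) >= 2 and label != "control"
    }
    comparisons = [
        (a, b)
        for i, a in enumerate(sorted(arm_groups))
        for b in sorted(arm_groups)[i + 1 :]
    ]
    if comparisons:
        tests = stats_mod.pairwise_family(arm_groups, comparisons)
        pairwise = pd.DataFrame(
            {
                "group_a": [t.comparison[0] for t in tests],
                "group_b": [t.comparison[1] for t in tests],
                "u": [t.statistic for t in tests],
                "p": [t.p_value for t in tests],
                "p_holm": [t.adjusted_p for t in tests],
                "method": [t.method for t in tests],
            }
        )
        written["pairwise"] = write_table(pairwise, outdir / "pairwise.tsv", None, meta)

    # killing assays + resistance profiles for sampled isolates
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xA55A])
    )
    records: list[KillingAssayRecord] = []
    profiles = []
    for traj in trajectories:
        if "control" in traj.population_id:
            continue
        for day in config.sampling_days:
            if day not in traj.days:
                continue
            try:
                isolates = sim_mod.sample_isolates(
                    traj, day, config.isolates_per_day, rng
                )
            except sim_mod.ExtinctPopulationError:
                continue
            for i, genotype in enumerate(isolates, start=1):
                iso_id = f"{traj.population_id}_d{day}.{i}"
                per_phage = {}
                for phage in sim_mod.PHAGES:
                    recs = [
                        sim_mod.simulate_killing_assay(
                            genotype,
                            phage,
                            config.params,
                            rng,
                            isolate_id=iso_id,
                            day=day,
                            replicate_index=rep,
                        )
                        for rep in range(1, config.assay_replicates + 1)
                    ]
                    records.extend(recs)
                    per_phage[phage] = recs
                profiles.append(
                    resistance_mod.build_profile(
                        iso_id,
                        day,
                        per_phage["T2"],
                        per_phage["LAMBDA"],
                        n_boot=config.n_boot,
                        seed=rng,
                    )
                )
    if records:
        written["assays"] = write_table(
            assays_to_table(records), outdir / "assays.csv", ASSAY_SCHEMA, meta
        )
        written["profiles"] = write_table(
            profiles_to_table(profiles), outdir / "profiles.tsv", None, meta
        )

    # growth curves + rate estimates for each genotype class
    curves = []
    estimates: dict[str, list[float]] = {}
    genotype_set = {g.label: g for g in config.params.genotypes}
    for label, genotype in genotype_set.items():
        name = "WT" if label == "sensitive" else label
        for rep in range(1, 4):
            times, od = sim_mod.simulate_growth_curve(
                genotype, config.params, noise_sd=0.02, seed=rng
            )
            curve = growth_mod.GrowthCurve(f"{name}_r{rep}", times, od)
            curves.append(curve)
            est = growth_mod.estimate_max_growth_rate(curve)
            estimates.setdefault(name, []).append(est.mumax)
    curve_table = pd.DataFrame(
        [
            {"isolate_id": c.isolate_id, "minute": m, "od600": o}
            for c in curves
            for m, o in zip(c.times_min, c.od600)
        ]
    )
    written["growth_curves"] = write_table(
        curve_table, outdir / "growth_curves.csv", GROWTH_CURVE_SCHEMA, meta
    )
    comparison = growth_mod.compare_growth_rates(estimates, wt_label="WT")
    written["growth_rates"] = write_table(
        comparison.table,
        outdir / "growth_rates.tsv",
        None,
        {**meta, "anova_f": comparison.f_statistic, "anova_p": comparison.p_value},
    )
    return written
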