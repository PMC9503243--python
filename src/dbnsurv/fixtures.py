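"""Synthetic gastrectomy-like cohort generator and pipeline orchestration.

The fixture emulates a post-gastrectomy gastric-cancer cohort: 760
subjects, follow-up in whole years with 14 event years (no event in year
13), eight discrete baseline covariates whose marginals match the
published descriptive table of such a cohort, and a dependency structure
among covariates (sex -> smoking, smoking -> metastasis, metastasis ->
stage, sex -> pathology, site -> surgery).  Survival and censoring
dynamics are driven by designated covariates: baseline age shifts the
death hazard in years 1-2, metastasis in year 4; censoring probabilities
depend on pathology in years 3 and 5 and on age in years 6-7.  All effect
sizes are synthetic calibrations — the generator provides a known ground
truth, not a reconstruction of any real patient data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import (
    SurvivalRecord,
    build_slice_grid,
    encode_states,
    read_survival_table,
    records_to_frame,
    tabulate_counts,
)
from .estimation import curve_to_text, dbn_marginal_survival, km_estimate
from .fitting import fit_transition_cpts, panel_to_frame, tbn_to_json
from .search import SearchConfig, hill_climb, tabu_search, temporal_constraints
from .validation import ModelSpec, repeated_holdout

log = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "generate_fixture", "fixture_frame", "run_pipeline"]

EVENT_YEARS = tuple(list(range(1, 13)) + [14, 15])


@dataclass
class FixtureSpec:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 760
    seed: int = 0
    horizon_year: int = 16  # survivors are censored here
    # baseline hazard of death per slice, among at-risk subjects
    base_death: float = 0.06
    # slice-specific hazards by designated covariate (year -> level -> p)
    death_by_age: dict = field(
        default_factory=lambda: {
            1: {"<61": 0.12, "61-70": 0.25, ">70": 0.45},
            2: {"<61": 0.025, "61-70": 0.04, ">70": 0.08},
        }
    )
    death_by_metastasis: dict = field(
        default_factory=lambda: {4: {"No": 0.02, "Yes": 0.08}}
    )
    base_censor: float = 0.02
    censor_by_pathology: dict = field(
        default_factory=lambda: {
            3: {"Adeno": 0.015, "Other": 0.10},
            5: {"Adeno": 0.015, "Other": 0.10},
        }
    )
    censor_by_age: dict = field(
        default_factory=lambda: {
            6: {"<61": 0.02, "61-70": 0.02, ">70": 0.12},
            7: {"<61": 0.12, "61-70": 0.02, ">70": 0.02},
        }
    )


def _sample_level(rng, n, levels, probs):
    return rng.choice(levels, size=n, p=probs)


def _sample_covariates(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    sex = _sample_level(rng, n, ["Female", "Male"], [0.32, 0.68])
    age = _sample_level(rng, n, ["<61", "61-70", ">70"], [0.24, 0.48, 0.28])
    site = _sample_level(rng, n, ["Antrum", "Cardia", "Other"], [0.20, 0.45, 0.35])

    smoking = np.where(
        sex == "Male",
        rng.random(n) < 0.42,
        rng.random(n) < 0.07,
    )
    smoking = np.where(smoking, "Smoker", "Non-smoker")
    pathology = np.where(
        sex == "Male",
        rng.random(n) < 0.90,
        rng.random(n) < 0.85,
    )
    pathology = np.where(pathology, "Adeno", "Other")
    metastasis = np.where(
        smoking == "Smoker",
        rng.random(n) < 0.66,
        rng.random(n) < 0.545,
    )
    metastasis = np.where(metastasis, "Yes", "No")

    surgery_levels = ["Total", "Subtotal", "Distal", "Partial", "Proximal"]
    surgery_probs = {
        "Cardia": [0.60, 0.15, 0.02, 0.08, 0.15],
        "Antrum": [0.40, 0.45, 0.08, 0.05, 0.02],
        "Other": [0.50, 0.27, 0.05, 0.10, 0.08],
    }
    surgery = np.empty(n, dtype=object)
    for s, probs in surgery_probs.items():
        mask = site == s
        surgery[mask] = _sample_level(rng, int(mask.sum()), surgery_levels, probs)

    stage_levels = ["I", "II", "III", "IV"]
    stage_probs = {
        "Yes": [0.01, 0.15, 0.52, 0.32],
        "No": [0.18, 0.62, 0.18, 0.02],
    }
    stage = np.empty(n, dtype=object)
    for m, probs in stage_probs.items():
        mask = metastasis == m
        stage[mask] = _sample_level(rng, int(mask.sum()), stage_levels, probs)

    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "site": site,
            "smoking": smoking,
            "pathology": pathology,
            "metastasis": metastasis,
            "surgery": surgery,
            "stage": stage,
        }
    )


def _hazards(spec: FixtureSpec, covs: pd.DataFrame, year: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(covs)
    death = np.full(n, spec.base_death)
    if year in spec.death_by_age:
        table = spec.death_by_age[year]
        death = covs["age"].map(table).to_numpy(dtype=float)
    if year in spec.death_by_metastasis:
        table = spec.death_by_metastasis[year]
        death = covs["metastasis"].map(table).to_numpy(dtype=float)
    censor = np.full(n, spec.base_censor)
    if year in spec.censor_by_pathology:
        table = spec.censor_by_pathology[year]
        censor = covs["pathology"].map(table).to_numpy(dtype=float)
    if year in spec.censor_by_age:
        table = spec.censor_by_age[year]
        censor = covs["age"].map(table).to_numpy(dtype=float)
    return death, censor


def generate_fixture(spec: FixtureSpec | None = None) -> list[SurvivalRecord]:
    """Ancestral sampling: covariate network first, then the N/Q chain."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    covs = _sample_covariates(spec, rng)
    n = spec.n_subjects
    time = np.full(n, float(spec.horizon_year))
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for year in EVENT_YEARS:
        death_p, censor_p = _hazards(spec, covs, year)
        dies = alive & (rng.random(n) < death_p)
        time[dies], event[dies] = year, 1
        alive &= ~dies
        censored = alive & (rng.random(n) < censor_p)
        time[censored] = year
        alive &= ~censored
    cov_records = covs.to_dict("records")
    return [
        SurvivalRecord(time=float(t), event=int(e), covariates=c)
        for t, e, c in zip(time, event, cov_records)
    ]


def fixture_frame(spec: FixtureSpec | None = None) -> pd.DataFrame:
    return records_to_frame(generate_fixture(spec))


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    data,
    out_dir=None,
    algorithm: str = "tabu",
    score_name: str = "bde",
    iss: float = 1.0,
    seed: int = 0,
    validate: bool = False,
    validate_reps: int = 10,
    test_fraction: float = 0.30,
    n_samples: int = 1000,
    delimiter: str = ",",
    extra_whitelist: frozenset = frozenset(),
    extra_blacklist: frozenset = frozenset(),
) -> dict:
    """encode -> learn structure -> fit -> estimate -> (validate) -> export.

    ``data`` is a path to a delimited survival table or a DataFrame with
    ``time``/``event`` columns.  Returns the report bundle as a dict; when
    ``out_dir`` is given, also writes DAG (DOT + edge list), the fitted
    model (JSON), the marginal survival curve (TSV), the validation report
    and an exact configuration echo.
    """
    config_echo = {
        "algorithm": algorithm,
        "score_name": score_name,
        "iss": iss,
        "seed": seed,
        "validate": validate,
        "validate_reps": validate_reps,
        "test_fraction": test_fraction,
        "n_samples": n_samples,
    }
    if isinstance(data, (str, Path)):
        records = read_survival_table(data, delimiter=delimiter)
    elif isinstance(data, pd.DataFrame):
        from .encoding import frame_to_records

        records = frame_to_records(data)
    else:
        records = list(data)

    log.info("pipeline stage: encode (%d records)", len(records))
    grid = build_slice_grid(records)
    panel = encode_states(records, grid)
    covariates = records_to_frame(records).drop(columns=["time", "event"])
    flat = panel_to_frame(panel, covariates)

    log.info("pipeline stage: structure learning (%s / %s)", algorithm, score_name)
    constraints = temporal_constraints(covariates.columns, grid.n_slices)
    if extra_whitelist or extra_blacklist:
        from .bn import EdgeConstraints

        constraints = EdgeConstraints(
            whitelist=constraints.whitelist | frozenset(extra_whitelist),
            blacklist=(constraints.blacklist | frozenset(extra_blacklist))
            - frozenset(extra_whitelist),
        )
    search = SearchConfig(
        score_name=score_name, iss=iss, constraints=constraints, random_seed=seed
    )
    if algorithm == "hc":
        dag = hill_climb(flat, search)
    elif algorithm == "tabu":
        dag = tabu_search(flat, search)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    log.info("pipeline stage: parameter fitting")
    tbn = fit_transition_cpts(panel, covariates, dag)

    log.info("pipeline stage: survival estimation")
    counts = tabulate_counts(panel)
    km = km_estimate(counts, grid)
    marginal = dbn_marginal_survival(tbn, covariates)

    report = None
    if validate:
        log.info("pipeline stage: validation (%d reps)", validate_reps)
        spec = ModelSpec(
            algorithm=algorithm,
            search=search,
        )
        report = repeated_holdout(
            flat,
            spec,
            k_reps=validate_reps,
            test_fraction=test_fraction,
            n_samples=n_samples,
            seed=seed,
        )

    bundle = {
        "grid": grid,
        "dag": dag,
        "tbn": tbn,
        "km_curve": km,
        "marginal_curve": marginal,
        "validation": report,
        "config": config_echo,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "dag.dot").write_text(dag.to_dot())
        (out / "dag_edges.tsv").write_text(dag.to_edge_list())
        (out / "model.json").write_text(tbn_to_json(tbn))
        (out / "km_curve.tsv").write_text(curve_to_text(km))
        (out / "marginal_curve.tsv").write_text(curve_to_text(marginal))
        if report is not None:
            (out / "validation.tsv").write_text(report.to_text())
        (out / "config.json").write_text(json.dumps(config_echo, indent=1))
    return bundle
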