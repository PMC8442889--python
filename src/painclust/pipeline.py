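"""End-to-end orchestration: discovery, validation, and longitudinal runs.

Every stochastic stage draws its seed deterministically from a single master
seed via named substreams, so a stage can be re-run in isolation without
perturbing the draws of any other stage.  Each run writes its intermediate
artifacts (exclusion report, split ids, model JSON, labels, report tables)
to the output directory.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, dynamics, hierarchy, io, separability
from .schema import PAIN_MEASURES, SYMPTOMS
from .simulate import GeneratorConfig, simulate_baseline, simulate_followup


def substream_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-serializable)."""

    mode: str = "simulate"           # "simulate" | "load"
    cohort_path: str | None = None   # load mode
    n: int = 1500                    # simulate mode
    seed: int = 0
    out_dir: str = "painclust_run"
    kmax: int = 10
    n_reference: int = 50
    linkage: str = "ward"
    reference: str = "uniform"
    se_rule: str = "max-se"
    k: int | None = None             # fix k instead of selecting it
    split_fraction: float = 0.75
    epsilon: float = 3.0
    replicates: int = 1000
    correlation: float = 0.3
    window_days: tuple[int, int] = (90, 365)
    #: Share of simulated patients with a follow-up assessment (the published
    #: registry's longitudinal subset was 7.7% of retained patients).
    followup_fraction: float = 0.077

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window_days" in raw:
            raw["window_days"] = tuple(raw["window_days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {**self.__dict__, "window_days": list(self.window_days)}
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class DiscoveryResult:
    model: hierarchy.ClusterModel
    curve: hierarchy.GapCurve | None
    training: io.CohortTable
    validation: io.CohortTable
    longitudinal: io.CohortTable
    report: pd.DataFrame
    validation_report: pd.DataFrame
    contribution: separability.ContributionTable
    norm_dev: separability.NormDeviationSummary


def _obtain_cohort(config: RunConfig) -> io.CohortTable:
    if config.mode == "load":
        if not config.cohort_path:
            raise ValueError("load mode requires cohort_path")
        return io.load_cohort(config.cohort_path)
    gen = GeneratorConfig(
        n=config.n,
        correlation=config.correlation,
        seed=substream_seed(config.seed, "simulate"),
    )
    sim_base = simulate_baseline(gen)
    # Only a fraction of patients return for a follow-up assessment.
    rng = np.random.default_rng(substream_seed(config.seed, "followup-subset"))
    n_fol = round(config.followup_fraction * config.n)
    subset_idx = np.sort(rng.choice(config.n, size=n_fol, replace=False))
    from .simulate import subset_simulated

    sim_fol = simulate_followup(subset_simulated(sim_base, subset_idx), gen)
    merged = pd.concat(
        [sim_base.cohort.data, sim_fol.cohort.data], ignore_index=True
    )
    cohort = io.CohortTable(merged, sim_base.cohort.provenance + sim_fol.cohort.provenance)
    return cohort


def run_discovery(config: RunConfig) -> DiscoveryResult:
    """Exclusions, split, clustering with gap-based k-selection, profiling.

    Mirrors the discovery sequence: exclusion rules, extraction of the
    longitudinal subset, a 75:25 training/validation split of the remainder,
    Ward/Euclidean agglomeration with gap-statistic k-selection on training,
    severity-ordered model fit, contribution and norm-deviation summaries,
    and a profile report for training plus a classifier-based validation
    report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _obtain_cohort(config)
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cohort, report = io.apply_exclusions(cohort)
    report.to_json(out / "exclusions.json")
    if len(cohort) == 0:
        raise ValueError("no records survive exclusions")

    longitudinal = io.extract_longitudinal(cohort, config.window_days)
    longi_ids = set(longitudinal.data["patient_id"])
    pool = io.CohortTable(
        cohort.data[
            (cohort.data["timepoint"] == "baseline")
            & ~cohort.data["patient_id"].isin(longi_ids)
        ].reset_index(drop=True),
        list(cohort.provenance),
    )
    split = io.split_train_validation(
        pool, config.split_fraction, substream_seed(config.seed, "split")
    )
    split.longitudinal = sorted(longi_ids)
    (out / "split.json").write_text(json.dumps(split.__dict__, indent=2))

    training = io.subset_by_ids(pool, split.training)
    validation = io.subset_by_ids(pool, split.validation)
    X = training.data[list(SYMPTOMS)]

    curve = None
    k = config.k
    if k is None:
        curve = hierarchy.gap_statistic(
            X.to_numpy(),
            kmax=config.kmax,
            B=config.n_reference,
            reference=config.reference,
            seed=substream_seed(config.seed, "gap"),
            method=config.linkage,
        )
        k = hierarchy.select_k(curve, config.se_rule)
    model = hierarchy.fit_model(X, k, method=config.linkage, seed=config.seed)
    model.to_json(out / "model.json")

    contribution = separability.percent_contribution(model.centroids[list(SYMPTOMS)])
    contribution.to_frame().to_csv(out / "contribution.csv")
    norm_dev = separability.norm_deviation(model.centroids)
    norm_dev.deviation.to_frame("norm_deviation_sd").to_csv(out / "norm_deviation.csv")

    measures = [m for m in SYMPTOMS + PAIN_MEASURES if m in training.data.columns]
    profiles = separability.profile_measures(training.data, model.labels, measures)
    train_report = separability.render_profile_table(profiles)
    train_report.to_csv(out / "training_report.csv")
    train_report.to_json(out / "training_report.json", orient="index")

    clf = classify.fit(model)
    val_labels = clf.predict(validation.data[list(SYMPTOMS)])
    validation.data = validation.data.assign(cluster=val_labels)
    val_profiles = separability.profile_measures(validation.data, val_labels, measures)
    val_report = separability.render_profile_table(val_profiles)
    val_report.to_csv(out / "validation_report.csv")
    pd.DataFrame(
        {"patient_id": validation.data["patient_id"], "cluster": val_labels}
    ).to_csv(out / "validation_labels.csv", index=False)

    return DiscoveryResult(
        model, curve, training, validation, longitudinal,
        train_report, val_report, contribution, norm_dev,
    )


@dataclass
class LongitudinalResult:
    transitions: dynamics.TransitionSummary
    null: dynamics.JitterNull
    movement: tuple[float, int, float]
    change: dynamics.ChangeMagnitude
    ancova_report: pd.DataFrame


def run_longitudinal(
    config: RunConfig,
    model: hierarchy.ClusterModel,
    longitudinal: io.CohortTable,
) -> LongitudinalResult:
    """Baseline assignment, follow-up profiling, transitions, and the null.

    Baseline records are assigned by the nearest-centroid classifier;
    follow-up measures are profiled by baseline cluster with a
    days-between-assessments ANCOVA; follow-up re-assignment yields the
    transition summary; the jitter bootstrap and movement test quantify how
    much of the observed movement measurement error alone could produce.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = longitudinal.data
    base = df[df["timepoint"] == "baseline"].set_index("patient_id")
    fol = df[df["timepoint"] == "followup"]
    fol = fol.drop_duplicates("patient_id").set_index("patient_id")
    common = base.index.intersection(fol.index)
    if len(common) == 0:
        raise ValueError("no paired baseline/follow-up records")
    base, fol = base.loc[common], fol.loc[common]

    clf = classify.fit(model)
    base_labels = clf.predict(base[list(SYMPTOMS)])
    fol_labels = clf.predict(fol[list(SYMPTOMS)])
    gap_days = (
        pd.to_datetime(fol["assessment_date"]).to_numpy()
        - pd.to_datetime(base["assessment_date"]).to_numpy()
    ).astype("timedelta64[D]").astype(float)

    rows = []
    measures = [m for m in SYMPTOMS + PAIN_MEASURES if m in fol.columns]
    for m in measures:
        try:
            res = separability.ancova_time_adjusted(
                fol[m].to_numpy(dtype=float), base_labels, gap_days
            )
        except ValueError:
            continue
        rows.append(
            {
                "measure": m,
                "F": res.F,
                "df": f"{res.df_printed[0]}, {res.df_printed[1]}",
                "p": res.p,
            }
        )
    ancova_report = (
        pd.DataFrame(rows).set_index("measure")
        if rows
        else pd.DataFrame(columns=["F", "df", "p"])
    )
    ancova_report.to_csv(out / "followup_ancova.csv")

    trans = dynamics.transitions(base_labels, fol_labels, k=model.k)
    trans.counts.to_csv(out / "transitions.csv")
    trans.to_json(out / "transitions.json")

    null = dynamics.jitter_null(
        base[list(SYMPTOMS)],
        clf,
        epsilon=config.epsilon,
        replicates=config.replicates,
        seed=substream_seed(config.seed, "jitter"),
    )
    null.to_csv(out / "jitter_null.csv")
    movement = dynamics.movement_test(trans.moved_percent, null)

    change = dynamics.change_magnitude(
        base[list(SYMPTOMS)].to_numpy(dtype=float),
        fol[list(SYMPTOMS)].to_numpy(dtype=float),
        moved_mask=base_labels != fol_labels,
        threshold=config.epsilon,
    )
    summary = {
        "observed_moved_percent": trans.moved_percent,
        "null_mean": null.mean,
        "null_sd": null.sd,
        "t": movement[0],
        "df": movement[1],
        "p": movement[2],
        "group_summary": change.group_summary().to_dict(),
    }
    (out / "dynamics_summary.json").write_text(json.dumps(summary, indent=2))
    return LongitudinalResult(trans, null, movement, change, ancova_report)
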