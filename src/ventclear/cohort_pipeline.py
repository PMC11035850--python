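"""Two-pass cohort analysis of ventricular clearance.

Pass 1 fits every subject unconstrained: the gray-matter two-tissue model
(whose fitted unbound C1 curve becomes the interstitial input of the
dual-input ventricle model), then both ventricle clearance models by
FSD-weighted least squares.  Rate constants are recorded only for subjects
whose multistart fit converged to a single solution.

Pass 2 refits each ventricle model per subject as a MAP estimate with
empirical priors: the prior mean is the leave-one-out (LOO) mean of the
converged same-group, same-model pass-1 estimates (the target subject never
contributes to its own prior), and the prior SD is twice the LOO sample SD,
keeping the priors deliberately loose.  Models are then compared per subject
by AIC (convergence-gated) and the selected model's constants populate the
cohort table handed to :mod:`ventclear.stats`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, kinetics, stats, tac_io
from .fitting import FitResult, PriorSpec
from .tac_io import FrameSchedule, TimeActivityCurve

__all__ = [
    "PipelineConfig",
    "SubjectRecord",
    "SubjectFits",
    "load_cohort",
    "first_pass",
    "loo_priors",
    "second_pass",
    "run_cohort",
    "run_pipeline",
]

logger = logging.getLogger("ventclear")

VENTRICLE_MODELS = ("blood_only", "dual_input")

TAC_ROLES = ("idif", "gray_matter", "ventricle")


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """Tunable settings of the cohort pipeline (YAML/JSON loadable)."""

    dt: float = kinetics.DEFAULT_DT_MIN
    t_max: float = kinetics.DEFAULT_TMAX_MIN
    sigma0: float = 22.5
    floor_fraction: float = 0.05
    starts: int = 10
    seed: int = 0
    bounds: dict = field(default_factory=dict)
    prior_fallback: str = "pooled"
    include_age: bool = False
    models: tuple[str, ...] = VENTRICLE_MODELS
    reweight_rounds: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        raw = raw or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SubjectRecord:
    """One subject's manifest row plus its three TACs on a shared schedule."""

    subject_id: str
    group: str
    age_years: float
    sex: str
    alps_index: float | None
    tacs: dict[str, TimeActivityCurve]

    def __post_init__(self) -> None:
        if self.group not in tac_io.GROUPS:
            raise ValueError(f"{self.subject_id}: invalid group {self.group!r}")
        if self.sex not in tac_io.SEXES:
            raise ValueError(f"{self.subject_id}: invalid sex {self.sex!r}")
        missing = [r for r in TAC_ROLES if r not in self.tacs]
        if missing:
            raise ValueError(f"{self.subject_id}: missing TAC(s) {missing}")
        sched = self.tacs["idif"].schedule.frames
        for role in TAC_ROLES:
            if self.tacs[role].schedule.frames != sched:
                raise ValueError(f"{self.subject_id}: TACs do not share one schedule")


@dataclass
class SubjectFits:
    """Pass-1 artifacts for one subject."""

    subject_id: str
    two_tissue: FitResult | None = None
    c1_fine: np.ndarray | None = None
    cp_fine: np.ndarray | None = None
    ventricle: dict[str, FitResult] = field(default_factory=dict)
    ventricle_weights: fitting.WeightVector | None = None
    excluded_reason: str | None = None


def _subject_seed(master: int, subject_index: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(master), int(subject_index), int(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


def _as_dict_record(subject) -> SubjectRecord:
    """Accept either a SubjectRecord or the dict emitted by simulate_cohort."""
    if isinstance(subject, SubjectRecord):
        return subject
    return SubjectRecord(
        subject_id=subject["subject_id"],
        group=subject["group"],
        age_years=subject["age_years"],
        sex=subject["sex"],
        alps_index=subject.get("alps_index"),
        tacs={r: subject[r] for r in TAC_ROLES},
    )


def load_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load subjects from a manifest CSV; TACs live in per-subject files
    ``<tac_dir>/<subject_id>_{idif,gray_matter,ventricle}.csv``."""
    manifest_path = Path(manifest_path)
    df = tac_io.read_cohort_manifest(manifest_path)
    subjects = []
    for _, row in df.iterrows():
        tac_dir = Path(row["tac_dir"])
        if not tac_dir.is_absolute():
            tac_dir = manifest_path.parent / tac_dir
        tacs = {}
        for role in TAC_ROLES:
            path = tac_dir / f"{row['subject_id']}_{role}.csv"
            if not path.exists():
                raise PipelineError(
                    f"load_cohort: subject {row['subject_id']!r}: missing TAC file {path}"
                )
            tacs[role] = tac_io.read_tac_table(path)
        alps = row["alps_index"]
        subjects.append(SubjectRecord(
            subject_id=row["subject_id"],
            group=row["group"],
            age_years=float(row["age_years"]),
            sex=row["sex"],
            alps_index=None if pd.isna(alps) else float(alps),
            tacs=tacs,
        ))
    return subjects


def _usable(tac: TimeActivityCurve) -> str | None:
    if not np.all(np.isfinite(tac.activity)):
        return "non-finite activity"
    if np.max(tac.activity) <= 0:
        return "no positive activity"
    return None


def first_pass(subjects: list, config: PipelineConfig) -> dict[str, SubjectFits]:
    """Unconstrained fits for every subject (2TCM + both ventricle models)."""
    results: dict[str, SubjectFits] = {}
    t = kinetics.fine_time_grid(config.dt, config.t_max)
    for idx, subj in enumerate(subjects):
        rec = _as_dict_record(subj)
        sf = SubjectFits(subject_id=rec.subject_id)
        reason = None
        for role in TAC_ROLES:
            bad = _usable(rec.tacs[role])
            if bad:
                reason = f"{role}: {bad}"
                break
        if reason:
            sf.excluded_reason = reason
            logger.warning("first_pass: excluding %s (%s)", rec.subject_id, reason)
            results[rec.subject_id] = sf
            continue
        cp = kinetics.upsample_idif(rec.tacs["idif"], t)
        sf.cp_fine = cp
        inputs = {"t": t, "cp": cp}
        gm_weights = None
        if config.reweight_rounds > 0:
            gm_weights = fitting.forecast_weights(
                rec.tacs["gray_matter"], inputs, "two_tissue",
                floor_fraction=config.floor_fraction, starts=min(4, config.starts),
                seed=_subject_seed(config.seed, idx, 10),
                rounds=config.reweight_rounds,
                bounds=config.bounds.get("two_tissue"),
            )
        sf.two_tissue, sf.c1_fine = fitting.fit_two_tissue(
            rec.tacs["gray_matter"], inputs,
            bounds=config.bounds.get("two_tissue"),
            starts=config.starts, seed=_subject_seed(config.seed, idx, 1),
            weights=gm_weights,
        )
        vent = rec.tacs["ventricle"]
        if config.reweight_rounds > 0:
            weights = fitting.forecast_weights(
                vent, inputs, "blood_only",
                floor_fraction=config.floor_fraction, starts=min(4, config.starts),
                seed=_subject_seed(config.seed, idx, 11),
                rounds=config.reweight_rounds,
                bounds=config.bounds.get("blood_only"),
            )
        else:
            weights = fitting.fsd_weights(vent, config.floor_fraction)
        sf.ventricle_weights = weights
        for m, model_id in enumerate(config.models):
            model_inputs = dict(inputs)
            if model_id == "dual_input":
                model_inputs["c_tissue"] = sf.c1_fine
            sf.ventricle[model_id] = fitting.fit_wnlls(
                vent, model_inputs, model_id,
                bounds=config.bounds.get(model_id),
                starts=config.starts, seed=_subject_seed(config.seed, idx, 2 + m),
                weights=weights,
            )
        results[rec.subject_id] = sf
    return results


def loo_priors(
    pass1: dict[str, SubjectFits],
    groups: dict[str, str],
    target_subject: str,
    model_id: str,
    fallback: str = "pooled",
) -> PriorSpec:
    """Leave-one-out empirical priors for one subject and one model.

    Donors are the converged same-model pass-1 fits of same-group subjects,
    excluding the target.  Prior mean = donor mean; prior SD = 2 x donor
    sample SD (n-1 denominator).  With fewer than two same-group donors the
    donor pool falls back to all groups pooled (still LOO), with a warning.
    """
    def donors_from(pool_ids, require_converged=True):
        rows = []
        for sid in pool_ids:
            sf = pass1.get(sid)
            if sf is None or sid == target_subject or sf.excluded_reason:
                continue
            fit = sf.ventricle.get(model_id)
            if fit is not None and (fit.converged or not require_converged):
                rows.append(fit.estimates)
        return rows

    same_group = [sid for sid, g in groups.items() if g == groups[target_subject]]
    donors = donors_from(same_group)
    pooled = False
    if len(donors) < 2:
        if fallback != "pooled":
            raise PipelineError(
                f"loo_priors: <2 same-group donors for {target_subject} and fallback disabled"
            )
        logger.warning(
            "loo_priors: <2 same-group donors for %s (%s); pooling all groups",
            target_subject, model_id,
        )
        donors = donors_from(list(groups))
        pooled = True
        if len(donors) < 2:
            # last resort: a model may converge for (almost) nobody, e.g. the
            # dual model on blood-only data; its non-converged point estimates
            # still centre a (deliberately loose) prior
            logger.warning(
                "loo_priors: no converged %s donors for %s; using non-converged "
                "pass-1 estimates", model_id, target_subject,
            )
            donors = donors_from(list(groups), require_converged=False)
        if len(donors) < 2:
            raise PipelineError(
                f"loo_priors: <2 donors for {target_subject} even after pooling"
            )
    names = fitting.MODEL_PARAM_NAMES[model_id]
    means, sds = {}, {}
    for name in names:
        vals = np.array([d[name] for d in donors])
        means[name] = float(vals.mean())
        sd = 2.0 * float(vals.std(ddof=1))
        # guard: identical donors would give a dogmatic (zero-width) prior
        sds[name] = max(sd, 1e-3 * abs(means[name]) + 1e-9)
    return PriorSpec(means=means, sds=sds, group=groups[target_subject],
                     excluded_subject=target_subject, pooled_fallback=pooled)


def second_pass(
    subjects: list,
    pass1: dict[str, SubjectFits],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, FitResult]]]:
    """MAP refits with LOO priors, AIC model selection, cohort table assembly."""
    records = [_as_dict_record(s) for s in subjects]
    groups = {r.subject_id: r.group for r in records}
    t = kinetics.fine_time_grid(config.dt, config.t_max)
    rows = []
    map_fits: dict[str, dict[str, FitResult]] = {}
    for idx, rec in enumerate(records):
        sf = pass1[rec.subject_id]
        row: dict = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age_years": rec.age_years,
            "sex": rec.sex,
            "alps_index": np.nan if rec.alps_index is None else rec.alps_index,
            "excluded_reason": sf.excluded_reason or "",
        }
        if sf.excluded_reason:
            row.update({"selected_model": "", "k_clearance": np.nan,
                        "k1_blood": np.nan, "k1_tissue": np.nan})
            rows.append(row)
            continue
        vent = rec.tacs["ventricle"]
        weights = sf.ventricle_weights
        if weights is None:
            weights = fitting.fsd_weights(vent, config.floor_fraction)
        fits: dict[str, FitResult] = {}
        for m, model_id in enumerate(config.models):
            priors = loo_priors(pass1, groups, rec.subject_id, model_id,
                                fallback=config.prior_fallback)
            inputs = {"t": t, "cp": sf.cp_fine}
            if model_id == "dual_input":
                inputs["c_tissue"] = sf.c1_fine
            p1fit = sf.ventricle[model_id]
            err_scale = p1fit.wrss / max(p1fit.n_frames - p1fit.n_params, 1)
            fits[model_id] = fitting.fit_map(
                vent, inputs, model_id, priors,
                bounds=config.bounds.get(model_id),
                starts=config.starts, seed=_subject_seed(config.seed, idx, 20 + m),
                weights=weights, error_scale=err_scale,
            )
        map_fits[rec.subject_id] = fits
        selected = fitting.select_model(list(fits.values()))
        best = fits[selected]
        row["selected_model"] = selected
        row["k_clearance"] = best.estimates["k_clearance"]
        row["k1_blood"] = best.estimates["k1_blood"]
        row["k1_tissue"] = best.estimates.get("k1_tissue", np.nan)
        for model_id in config.models:
            row[f"aic_{model_id}"] = fits[model_id].aic
            row[f"converged_pass1_{model_id}"] = pass1[rec.subject_id].ventricle[model_id].converged
            row[f"converged_pass2_{model_id}"] = fits[model_id].converged
            row[f"pass1_k_clearance_{model_id}"] = sf.ventricle[model_id].estimates["k_clearance"]
            row[f"pass1_k1_blood_{model_id}"] = sf.ventricle[model_id].estimates["k1_blood"]
        rows.append(row)
    return pd.DataFrame(rows), map_fits


def run_cohort(subjects: list, config: PipelineConfig) -> dict:
    """First pass, LOO priors, MAP second pass; returns all artifacts."""
    try:
        pass1 = first_pass(subjects, config)
    except Exception as exc:
        raise PipelineError(f"first_pass: {exc}") from exc
    try:
        table, map_fits = second_pass(subjects, pass1, config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"second_pass: {exc}") from exc
    return {"cohort_table": table, "pass1": pass1, "map_fits": map_fits}


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig | str | Path | None = None,
    out_dir: str | Path = ".",
) -> tuple[Path, Path]:
    """Full file-to-file pipeline: manifest -> cohort_results.csv + stats_report.json.

    A run log recording the seed, config hash and per-subject flags is
    written next to the outputs.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config_hash=%s seed=%d", config.config_hash(), config.seed)
        try:
            subjects = load_cohort(manifest_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"load_cohort: {exc}") from exc
        result = run_cohort(subjects, config)
        table = result["cohort_table"]
        usable = table[table["excluded_reason"] == ""]
        try:
            report = stats.full_report(usable, include_age=config.include_age)
        except Exception as exc:
            raise PipelineError(f"stats: {exc}") from exc
        table_path = out_dir / "cohort_results.csv"
        table.to_csv(table_path, index=False, float_format="%.17g")
        report_path = out_dir / "stats_report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        for sid, sf in result["pass1"].items():
            if sf.excluded_reason:
                logger.info("subject %s excluded: %s", sid, sf.excluded_reason)
        logger.info("wrote %s and %s", table_path, report_path)
        return table_path, report_path
    finally:
        logger.removeHandler(handler)
        handler.close()
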