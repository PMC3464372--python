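"""End-to-end in-silico replication of a volumetry validation study.

The pipeline generates a two-group cohort of thalamus-scale phantoms, measures
every subject with two simulated human raters (boundary-perturbed masks run
through Cavalieri point counting) and one simulated automated method
(volume-level observer), then computes the study's statistics: an ICC matrix
across the three methods on a reliability sub-sample, whole-sample ICCs
between one rater and the automated method, left-right and asymmetry
comparisons, and patient-vs-control ANOVAs with multiple-comparison
adjustment.  Everything is deterministic given the master seed.

Seed-splitting rule: the master seed roots a ``numpy.random.SeedSequence``;
stage s, subject i, hemisphere h, observer o draw from
``SeedSequence(master, spawn_key=(s, i, h, o))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement
from .agreement import GroupTestResult, icc_absolute_agreement
from .masks import SegmentationMask, read_mask, write_mask  # noqa: F401 (re-export)
from .phantoms import (
    CohortSpec,
    ObserverModel,
    PhantomSpec,
    TrueSubject,
    make_phantom,
    observe_subject,
    sample_cohort,
)
from .precision import CEOptions, gundersen_jensen_ce
from .stereology import cavalieri_volume, count_points, make_design

HEMISPHERES = ("left", "right")

# Stage tags for the seed tree
_STAGE_COHORT = 0
_STAGE_OBSERVE = 1
_STAGE_DESIGN = 2

# Observer noise magnitudes calibrated (see calibrate_observers) so that the
# reliability sub-sample ICCs land in the >0.9 regime of a well-run study.
DEFAULT_OBSERVERS = (
    ObserverModel(label="rater1", mode="mask", boundary_noise_sd=0.15),
    ObserverModel(label="rater2", mode="mask", boundary_noise_sd=0.35, bias=0.016),
    ObserverModel(label="automated", mode="volume", volume_noise_sd=200.0, bias=-0.011),
)


@dataclass(frozen=True)
class StudyConfig:
    """Complete configuration of one simulated validation study."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    observers: tuple[ObserverModel, ...] = DEFAULT_OBSERVERS
    u: float = 3.12
    d: float = 1.0
    slice_axis: int = 2
    ce_options: CEOptions = field(default_factory=CEOptions)
    per_section_grid: bool = True
    n_icc_subjects: int = 10
    alpha: float = 0.05
    adjust_method: str = "bonferroni"
    seed: int = 0

    def __post_init__(self):
        if len(self.observers) < 2:
            raise ValueError("need at least two observers")
        labels = [o.label for o in self.observers]
        if len(set(labels)) != len(labels):
            raise ValueError("observer labels must be unique")
        if not 1 <= self.n_icc_subjects <= self.cohort.n_controls:
            raise ValueError("n_icc_subjects must be within the control group size")

    @classmethod
    def from_dict(cls, cfg: dict) -> "StudyConfig":
        cohort = CohortSpec(**cfg.get("cohort", {}))
        observers = tuple(
            ObserverModel(**o) for o in cfg.get("observers", [])
        ) or DEFAULT_OBSERVERS
        ce = CEOptions(**cfg.get("ce_options", {}))
        extra = {k: v for k, v in cfg.items()
                 if k not in ("cohort", "observers", "ce_options")}
        return cls(cohort=cohort, observers=observers, ce_options=ce, **extra)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyReport:
    """All tables produced by one study run."""

    volumes: pd.DataFrame
    icc_matrix: pd.DataFrame
    whole_sample_icc: pd.DataFrame
    asymmetry: pd.DataFrame
    group_tests: pd.DataFrame
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.volumes.to_csv(out / "volumes.csv", index=False, float_format="%.6f")
        self.icc_matrix.to_csv(out / "icc.csv", float_format="%.6f")
        self.whole_sample_icc.to_csv(out / "whole_sample_icc.csv", index=False,
                                     float_format="%.6f")
        self.asymmetry.to_csv(out / "asymmetry.csv", index=False, float_format="%.6f")
        self.group_tests.to_csv(out / "group_tests.csv", index=False,
                                float_format="%.6f")
        with open(out / "report.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=tuple(key))


def measure_subject(
    subject: TrueSubject,
    hemisphere: str,
    observer: ObserverModel,
    config: StudyConfig,
    subject_index: int,
    observer_index: int,
) -> tuple[float, float | None]:
    """One (volume, predicted CE) measurement of one hemisphere.

    Mask-mode observers go through the full stereological chain: perturbed
    mask -> random sampling design -> point counting -> Cavalieri volume and
    Gundersen-Jensen CE.  Volume-mode observers return their volume directly
    (no CE: the automated method reports no sampling error).

    With ``config.per_section_grid`` (the default) the point grid is
    re-randomised on every section, which keeps the measurement noise of a
    single estimate at the level the CE predictor promises; the shared-offset
    variant is available for strict single-grid protocols.
    """
    h = HEMISPHERES.index(hemisphere)
    obs_seed = _seed(config.seed, _STAGE_OBSERVE, subject_index, h, observer_index)
    observed = observe_subject(subject, observer, obs_seed, hemisphere=hemisphere)
    if observer.mode == "volume":
        return float(observed), None
    design_seed = _seed(config.seed, _STAGE_DESIGN, subject_index, h, observer_index)
    design_rng = np.random.default_rng(design_seed)
    design = make_design(config.u, config.d, slice_axis=config.slice_axis,
                         rng=design_rng)
    record = count_points(observed, design,
                          per_section_rng=design_rng if config.per_section_grid else None)
    ce = gundersen_jensen_ce(record, config.ce_options)
    return cavalieri_volume(record).volume, ce


def _ratings(volumes: pd.DataFrame, subjects, hemisphere, methods) -> np.ndarray:
    sub = volumes[(volumes.hemisphere == hemisphere)
                  & (volumes.subject_id.isin(subjects))
                  & (volumes.method.isin(methods))]
    table = sub.pivot(index="subject_id", columns="method", values="volume")
    return table[list(methods)].to_numpy()


def _test_row(label: str, res: GroupTestResult) -> dict:
    return {
        "test": label,
        "statistic": res.statistic,
        "statistic_name": res.statistic_name,
        "df1": res.df[0] if isinstance(res.df, tuple) else res.df,
        "df2": res.df[1] if isinstance(res.df, tuple) else np.nan,
        "pvalue": res.pvalue,
        "p_adjusted": res.p_adjusted if res.p_adjusted is not None else np.nan,
        "mean_a": res.group_means[0],
        "mean_b": res.group_means[1],
        "sd_a": res.group_sds[0],
        "sd_b": res.group_sds[1],
    }


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the full simulated validation study.

    Stages: (1) cohort generation; (2) per-subject, per-hemisphere
    measurement by every observer; (3) reliability ICC matrix on the first
    ``n_icc_subjects`` controls across all methods; (4) whole-sample ICC
    between the first rater and the automated method; (5) left-right ANOVA
    and between-method asymmetry comparison; (6) patient-vs-control ANOVAs
    per hemisphere per method with multiple-comparison adjustment.
    """
    cohort_spec = config.cohort
    if cohort_spec.seed is None:
        derived = int(_seed(config.seed, _STAGE_COHORT).generate_state(1)[0] % (2**31))
        cohort_spec = replace(cohort_spec, seed=derived)
    try:
        subjects = sample_cohort(cohort_spec)
    except Exception as exc:
        raise RuntimeError(f"[stage:cohort] {exc}") from exc

    rows = []
    for i, subject in enumerate(subjects):
        for hemisphere in HEMISPHERES:
            for o, observer in enumerate(config.observers):
                try:
                    vol, ce = measure_subject(subject, hemisphere, observer,
                                              config, i, o)
                except Exception as exc:
                    raise RuntimeError(
                        f"[stage:measure subject={subject.subject_id} "
                        f"hemisphere={hemisphere} method={observer.label}] {exc}"
                    ) from exc
                rows.append({
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "hemisphere": hemisphere,
                    "method": observer.label,
                    "volume": vol,
                    "ce": ce if ce is not None else np.nan,
                    "true_volume": (subject.true_volume_left if hemisphere == "left"
                                    else subject.true_volume_right),
                })
    volumes = pd.DataFrame(rows)

    methods = [o.label for o in config.observers]
    controls = [s.subject_id for s in subjects if s.group == "control"]
    icc_subjects = controls[: config.n_icc_subjects]

    # reliability sub-sample: pairwise ICC matrix per hemisphere
    icc_rows = {}
    for hemisphere in HEMISPHERES:
        mat = pd.DataFrame(np.nan, index=methods, columns=methods)
        for a in range(len(methods)):
            for b in range(a + 1, len(methods)):
                pair = (methods[a], methods[b])
                table = _ratings(volumes, icc_subjects, hemisphere, pair)
                try:
                    icc = icc_absolute_agreement(table).icc
                except Exception as exc:
                    raise RuntimeError(
                        f"[stage:icc pair={pair} hemisphere={hemisphere}] {exc}"
                    ) from exc
                mat.iloc[a, b] = mat.iloc[b, a] = icc
        icc_rows[hemisphere] = mat
    icc_matrix = pd.concat(icc_rows, names=["hemisphere", "method"])

    # whole sample (patients + controls pooled): first rater vs automated
    all_ids = [s.subject_id for s in subjects]
    ws_rows = []
    manual, automated = methods[0], methods[-1]
    for hemisphere in HEMISPHERES:
        table = _ratings(volumes, all_ids, hemisphere, (manual, automated))
        try:
            res = icc_absolute_agreement(table)
        except Exception as exc:
            raise RuntimeError(
                f"[stage:whole-sample-icc hemisphere={hemisphere}] {exc}") from exc
        ws_rows.append({"hemisphere": hemisphere, "method_a": manual,
                        "method_b": automated, "icc": res.icc,
                        "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                        "n": res.n})
    whole_sample_icc = pd.DataFrame(ws_rows)

    # left-right comparison and asymmetry per method
    asym_frames = []
    group_rows = []
    for method in (manual, automated):
        piv = volumes[volumes.method == method].pivot(
            index="subject_id", columns="hemisphere", values="volume")
        res = agreement.anova_between(piv["left"], piv["right"])
        group_rows.append(_test_row(f"left_vs_right[{method}]", res))
        asym = agreement.asymmetry_index(piv["left"], piv["right"])
        asym_frames.append(pd.DataFrame({
            "subject_id": piv.index, "method": method,
            "asymmetry_pct": np.asarray(asym)}))
    asymmetry = pd.concat(asym_frames, ignore_index=True)
    wide_asym = asymmetry.pivot(index="subject_id", columns="method",
                                values="asymmetry_pct")
    res = agreement.anova_between(wide_asym[manual], wide_asym[automated])
    group_rows.append(_test_row("asymmetry_between_methods", res))

    # atrophy: patient vs control per hemisphere per method, adjusted
    atrophy_results = []
    for method in (manual, automated):
        for hemisphere in HEMISPHERES:
            sub = volumes[(volumes.method == method)
                          & (volumes.hemisphere == hemisphere)]
            ctrl = sub[sub.group == "control"].volume
            pat = sub[sub.group == "patient"].volume
            res = agreement.anova_between(ctrl, pat)
            atrophy_results.append((f"atrophy[{method},{hemisphere}]", res))
    adj = agreement.adjust_pvalues([r.pvalue for _, r in atrophy_results],
                                   method=config.adjust_method)
    for (label, res), p_adj in zip(atrophy_results, adj):
        res.p_adjusted = float(p_adj)
        group_rows.append(_test_row(label, res))
    group_tests = pd.DataFrame(group_rows)

    summary = {
        "seed": config.seed,
        "n_controls": config.cohort.n_controls,
        "n_patients": config.cohort.n_patients,
        "methods": methods,
        "sampling": {"u_mm": config.u, "d_mm": config.d},
        "mean_ce": {
            m: float(volumes[(volumes.method == m)].ce.mean())
            for m in methods if not volumes[volumes.method == m].ce.isna().all()
        },
        "icc_matrix": {
            h: icc_rows[h].round(6).to_dict() for h in HEMISPHERES
        },
        "whole_sample_icc": whole_sample_icc.round(6).to_dict("records"),
        "group_tests": [
            {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
             for k, v in row.items()} for row in group_rows
        ],
    }
    report = StudyReport(volumes=volumes, icc_matrix=icc_matrix,
                         whole_sample_icc=whole_sample_icc,
                         asymmetry=asymmetry, group_tests=group_tests,
                         summary=summary)
    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# Fast volume-level simulation used for calibration and power/replication
# ---------------------------------------------------------------------------

def _simulate_observed_cohort(rng, cohort: CohortSpec, noise_sds, biases=None):
    """Volume-level cohort: true volumes plus per-method additive noise.

    Returns (groups, true_left, true_right, observed) where observed maps a
    method index to (left, right) arrays.  Shared true volumes across
    methods reproduce the strong between-method correlation of the study.
    """
    from .phantoms import _draw_truncated_pair

    n = cohort.n_controls + cohort.n_patients
    groups = np.array(["control"] * cohort.n_controls + ["patient"] * cohort.n_patients)
    tl = np.empty(n)
    tr = np.empty(n)
    for i in range(n):
        if groups[i] == "control":
            ml, sl = cohort.control_left
            mr, sr = cohort.control_right
        else:
            ml, sl = cohort.patient_left
            mr, sr = cohort.patient_right
        tl[i], tr[i] = _draw_truncated_pair(rng, ml, sl, mr, sr, cohort.lr_correlation)
    biases = biases or [0.0] * len(noise_sds)
    observed = {}
    for m, (sd, bias) in enumerate(zip(noise_sds, biases)):
        observed[m] = (tl * (1 + bias) + rng.normal(0, sd, n),
                       tr * (1 + bias) + rng.normal(0, sd, n))
    return groups, tl, tr, observed


def stereology_volume_noise_sd(
    observer: ObserverModel,
    config: StudyConfig,
    n_reps: int = 40,
    target_volume: float = 7400.0,
    seed=0,
) -> float:
    """Measure the effective volume-level SD of a mask-mode observer.

    Runs the full chain (boundary perturbation + point counting) ``n_reps``
    times on one phantom of typical size and returns the SD of the resulting
    Cavalieri volumes — the single number that summarises how noisy one
    stereological measurement is at the configured design.
    """
    spec = PhantomSpec(target_volume=target_volume)
    subject = TrueSubject("calib", "control", target_volume, target_volume,
                          spec, spec)
    rng = np.random.default_rng(seed)
    vols = []
    for _ in range(n_reps):
        s = int(rng.integers(2**31))
        observed = observe_subject(subject, observer, s, hemisphere="left")
        if observer.mode == "volume":
            vols.append(observed)
            continue
        drng = np.random.default_rng(int(rng.integers(2**31)))
        design = make_design(config.u, config.d, slice_axis=config.slice_axis,
                             rng=drng)
        record = count_points(observed, design,
                              per_section_rng=drng if config.per_section_grid else None)
        vols.append(cavalieri_volume(record).volume)
    return float(np.std(vols, ddof=1))


def calibrate_observers(
    target_iccs: dict[tuple[str, str], float],
    search_grid: dict[str, list[float]],
    seed: int = 0,
    cohort: CohortSpec | None = None,
    n_replicates: int = 50,
    n_icc_subjects: int = 10,
    tolerance: float = 0.05,
) -> dict[str, float]:
    """Grid-search volume-level noise SDs to match target pairwise ICCs.

    ``target_iccs`` maps method-label pairs to target ICC values in (0, 1);
    ``search_grid`` maps each method label to candidate volume-noise SDs
    (mm^3).  For every grid point the expected pairwise ICCs are estimated
    over ``n_replicates`` replicate reliability cohorts (common random
    numbers across grid points) and the point minimising the summed squared
    distance to the targets is returned.  Warns if the best point misses a
    target by more than ``tolerance``.
    """
    import itertools
    import warnings

    for pair, t in target_iccs.items():
        if not 0 < t <= 1:
            raise ValueError(f"target ICC for {pair} must be in (0, 1], got {t}")
    labels = list(search_grid)
    if not all(search_grid.values()):
        raise ValueError("search grid must be non-empty for every method")
    cohort = cohort or CohortSpec(n_controls=n_icc_subjects, n_patients=1)

    # replicate true cohorts + standard-normal noise, shared across grid points
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        groups, tl, tr, _ = _simulate_observed_cohort(
            rng, cohort, noise_sds=[0.0] * len(labels))
        ctrl = groups == "control"
        z = rng.standard_normal((len(labels), ctrl.sum()))
        reps.append((tl[ctrl][:n_icc_subjects], z[:, :n_icc_subjects]))

    best, best_loss = None, np.inf
    for point in itertools.product(*(search_grid[m] for m in labels)):
        sds = dict(zip(labels, point))
        loss = 0.0
        for pair, target in target_iccs.items():
            ia, ib = labels.index(pair[0]), labels.index(pair[1])
            iccs = []
            for true, z in reps:
                table = np.column_stack([
                    true + sds[pair[0]] * z[ia], true + sds[pair[1]] * z[ib]])
                try:
                    iccs.append(icc_absolute_agreement(table).icc)
                except agreement.DegenerateTableError:
                    continue
            loss += (np.mean(iccs) - target) ** 2
        if loss < best_loss:
            best, best_loss = sds, loss
    if np.sqrt(best_loss / len(target_iccs)) > tolerance:
        warnings.warn(
            f"calibration missed targets (rms distance "
            f"{np.sqrt(best_loss / len(target_iccs)):.3f} > {tolerance})",
            stacklevel=2,
        )
    return best


def replicate_sensitivity(
    config: StudyConfig,
    n_replicates: int = 200,
    seed: int = 0,
    manual_noise_sd: float | None = None,
    automated_noise_sd: float | None = None,
) -> dict:
    """Atrophy-detection concordance between methods over replicate cohorts.

    For each replicate cohort (volume-level fast path; shared true volumes),
    the patient-vs-control ANOVA is run per hemisphere for the manual and the
    automated method, and the two methods are said to agree when both reject
    at ``config.alpha`` or both fail to.  The manual method's effective
    volume-level noise is measured from the full stereological chain unless
    supplied.

    Returns per-hemisphere agreement fractions and rejection rates.
    """
    rng = np.random.default_rng(seed)
    manual_obs = config.observers[0]
    auto_obs = config.observers[-1]
    if manual_noise_sd is None:
        manual_noise_sd = stereology_volume_noise_sd(
            manual_obs, config, seed=int(rng.integers(2**31)))
    if automated_noise_sd is None:
        automated_noise_sd = auto_obs.volume_noise_sd

    agree = {h: 0 for h in HEMISPHERES}
    reject = {(m, h): 0 for m in ("manual", "automated") for h in HEMISPHERES}
    for _ in range(n_replicates):
        groups, _, _, observed = _simulate_observed_cohort(
            rng, config.cohort,
            noise_sds=[manual_noise_sd, automated_noise_sd],
            biases=[manual_obs.bias, auto_obs.bias],
        )
        ctrl = groups == "control"
        for hi, h in enumerate(HEMISPHERES):
            rejections = {}
            for mi, m in enumerate(("manual", "automated")):
                vals = observed[mi][hi]
                res = agreement.anova_between(vals[ctrl], vals[~ctrl])
                rejections[m] = res.pvalue < config.alpha
                reject[(m, h)] += rejections[m]
            agree[h] += rejections["manual"] == rejections["automated"]
    return {
        "n_replicates": n_replicates,
        "manual_noise_sd": float(manual_noise_sd),
        "automated_noise_sd": float(automated_noise_sd),
        "agreement": {h: agree[h] / n_replicates for h in HEMISPHERES},
        "rejection_rate": {f"{m}_{h}": reject[(m, h)] / n_replicates
                           for m in ("manual", "automated") for h in HEMISPHERES},
    }
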