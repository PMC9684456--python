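"""End-to-end weak-supervision experiment on synthetic cohorts.

The experiment mirrors a two-site weak-labelling study design:

1. simulate an "external" labelled cohort (clean, diagnostic-ECG-like) and a
   "target" cohort under domain shift (ICU-telemetry-like: noisier, with an
   out-of-distribution abstain-analog class);
2. train the surrogate (label generation) model on the external cohort with
   a 70/30 stratified train/validation split;
3. curate the target pool (drop-off rejection, spacing, per-patient caps)
   and weak-label it with the surrogate;
4. train a "weak labels only" model and a "confident learning" model (label
   cleaning every 3 epochs) on the weak labels;
5. evaluate all three models under the four uncertainty modes on a labelled
   target-distribution test set, and compare uncertainty distributions
   between clean/noisy and in-distribution/OOD groups.

Everything is reproducible from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confident_learning as cl
from . import evaluation as ev
from . import uncertainty as uq
from . import weak_labels as wl
from .network import Classifier, NetworkConfig, build
from .synthetic import DomainShift, EcgSegment, generate_cohort
from .training import LabeledDataset, TrainConfig, train

__all__ = ["CohortSpec", "ExperimentConfig", "ExperimentReport", "run_experiment"]

MODEL_NAMES = ("label_generation", "weak_labels_only", "confident_learning")
UNCERTAINTY_MODES = ("none", "epistemic", "aleatoric", "combined")


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    segments_per_patient: tuple = (3, 8)
    af_fraction: float = 0.25
    noise_rate: float = 0.05
    ood_rate: float = 0.0
    dropoff_rate: float = 0.0
    domain_shift: DomainShift = field(default_factory=DomainShift)

    def generate(self, seed: int) -> list[EcgSegment]:
        return generate_cohort(
            n_patients=self.n_patients,
            segments_per_patient=self.segments_per_patient,
            class_mix={"sinus": 1.0 - self.af_fraction, "af": self.af_fraction},
            noise_rate=self.noise_rate,
            ood_rate=self.ood_rate,
            dropoff_rate=self.dropoff_rate,
            domain_shift=self.domain_shift,
            seed=seed,
        )


#: ICU-telemetry-like shift relative to the clean external cohort: attenuated
#: electrode contact, a broadband telemetry noise floor, and the faster
#: heart-rate distribution of critical illness
DEFAULT_TARGET_SHIFT = DomainShift(amplitude_scale=0.75, noise_floor=0.035,
                                   heart_rate_shift_bpm=12.0)


def _default_external() -> CohortSpec:
    return CohortSpec(n_patients=32, segments_per_patient=25,
                      af_fraction=0.35, noise_rate=0.05, ood_rate=0.0)


def _default_target() -> CohortSpec:
    # noise/OOD fractions follow the observed test-set proportions (27% / 9%);
    # the pool is kept small relative to the epoch budget so that training on
    # raw weak labels has time to fit their errors, the regime in which label
    # cleaning matters
    return CohortSpec(n_patients=22, segments_per_patient=(20, 30),
                      af_fraction=0.25, noise_rate=0.27, ood_rate=0.0,
                      dropoff_rate=0.04, domain_shift=DEFAULT_TARGET_SHIFT)


def _default_test() -> CohortSpec:
    return CohortSpec(n_patients=48, segments_per_patient=5,
                      af_fraction=0.25, noise_rate=0.27, ood_rate=0.09,
                      domain_shift=DEFAULT_TARGET_SHIFT)


@dataclass(frozen=True)
class ExperimentConfig:
    external: CohortSpec = field(default_factory=_default_external)
    target: CohortSpec = field(default_factory=_default_target)
    test: CohortSpec = field(default_factory=_default_test)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=12, val_fraction=0.3))
    surrogate_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=6, val_fraction=0.3))
    cleaning: cl.CleaningSchedule = field(
        default_factory=lambda: cl.CleaningSchedule(burn_in=5))
    modes: tuple = UNCERTAINTY_MODES
    n_passes: int = 12
    mask_fraction: float = 0.10
    seed: int = 0


@dataclass
class ExperimentReport:
    metrics: pd.DataFrame            # 3 models x 4 uncertainty modes
    cleaning_history: pd.DataFrame   # per-epoch active counts (confident learning)
    cleaning_rounds: pd.DataFrame    # per-round report (flagged, removed, joint)
    comparisons: pd.DataFrame        # uncertainty group comparisons per model
    predictions: dict                # (model, mode) -> PredictionSet
    weak_label_error_rate: float
    histories: dict                  # model -> training history frame
    provenance: dict
    models: dict = field(default_factory=dict)  # model name -> Classifier

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.cleaning_history.to_csv(outdir / "cleaning_history.csv", index=False)
        self.cleaning_rounds.to_csv(outdir / "cleaning_rounds.csv", index=False)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        for name, hist in self.histories.items():
            hist.to_csv(outdir / f"history_{name}.csv", index=False)
        rows, curves = [], []
        for (model, mode), ps in self.predictions.items():
            rows.append(pd.DataFrame({
                "model": model, "mode": mode, "mean_p": ps.mean, "std": ps.std,
                "label": ps.labels, "noisy": ps.noisy, "ood": ps.ood,
            }))
            _, bins = ev.ece(ps)
            bins = bins.assign(model=model, mode=mode, curve="reliability")
            counts = ev.confidence_count_curve(ps).assign(
                model=model, mode=mode, curve="confidence_count")
            curves.extend([bins, counts])
        pd.concat(rows).to_csv(outdir / "predictions.csv", index=False)
        pd.concat(curves).to_csv(outdir / "curves.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_experiment(config: ExperimentConfig | None = None,
                   outdir: str | Path | None = None) -> ExperimentReport:
    """Run the full weak-supervision experiment; see the module docstring."""
    config = config or ExperimentConfig()
    seeds = _spawn_seeds(config.seed, 10)
    timings = {}

    def _stage(name):
        timings[name] = time.time()

    # --- cohorts ----------------------------------------------------------
    _stage("simulate")
    external = config.external.generate(seeds[0])
    target = config.target.generate(seeds[1])
    test = config.test.generate(seeds[2])

    # --- surrogate on the external cohort (70/30 stratified split) --------
    _stage("surrogate")
    surrogate = build(config.network, seed=seeds[3])
    ext_data = LabeledDataset.from_segments(external)
    surrogate_cfg = dataclasses.replace(config.surrogate_train,
                                        val_fraction=0.3, seed=seeds[4])
    surrogate, hist_surrogate = train(surrogate, ext_data, surrogate_cfg)

    # --- curate + weak-label the target pool ------------------------------
    _stage("weak_label")
    index = wl.build_segment_index(target)
    curated = wl.curate_segments(index)
    pool = [target[i] for i in curated["segment"]]
    weak = wl.assign_weak_labels(surrogate, pool)
    true_labels = np.array([s.label for s in pool])
    weak_err = float(np.mean(weak.labels != true_labels))

    # --- weak-labels-only model -------------------------------------------
    _stage("weak_only")
    # weak-label validation splits are small and carry the label noise, so
    # the monitored loss for these models is the training loss
    weak_cfg = dataclasses.replace(config.train, val_fraction=0.1,
                                   monitor="train", seed=seeds[5])
    weak_model = build(config.network, seed=seeds[6])
    weak_data = LabeledDataset.from_segments(pool, labels=weak.labels)
    weak_model, hist_weak = train(weak_model, weak_data, weak_cfg)

    # --- confident-learning model -----------------------------------------
    _stage("confident")
    cl_model = build(config.network, seed=seeds[7])
    cl_data = LabeledDataset.from_segments(pool, labels=weak.labels.copy())
    hook = cl.cleaning_hook(config.cleaning)
    cl_model, hist_cl = train(cl_model, cl_data, dataclasses.replace(
        weak_cfg, seed=seeds[8]), cleaner=hook)

    # --- evaluation grid ---------------------------------------------------
    _stage("evaluate")
    models = {
        "label_generation": surrogate,
        "weak_labels_only": weak_model,
        "confident_learning": cl_model,
    }
    mode_seeds = _spawn_seeds(seeds[9], len(models) * len(config.modes))
    rows, cmp_rows, predictions = [], [], {}
    k = 0
    for model_name, model in models.items():
        for mode in config.modes:
            ucfg = uq.UncertaintyConfig(mode=mode, n_passes=config.n_passes,
                                        mask_fraction=config.mask_fraction,
                                        seed=mode_seeds[k])
            k += 1
            preds = uq.batch_uncertainty(model, test, ucfg)
            predictions[(model_name, mode)] = preds
            rows.append(ev.metrics_report(preds, model_name).to_row())
            if mode in ("aleatoric", "combined"):
                for cmp in ev.compare_uncertainty_groups(
                        preds, groupings=("clean_vs_noisy", "id_vs_ood")):
                    cmp_rows.append({"model": model_name, "mode": mode,
                                     "grouping": cmp.name, "U": cmp.u_statistic,
                                     "p": cmp.p_value, "n1": cmp.n1,
                                     "n2": cmp.n2, "reject": cmp.reject})

    round_cols = ["epoch", "flagged", "cumulative_removed",
                  "C00", "C01", "C10", "C11"]
    report = ExperimentReport(
        metrics=pd.DataFrame(rows),
        cleaning_history=hist_cl,
        cleaning_rounds=pd.DataFrame(hook.rounds, columns=round_cols),
        comparisons=pd.DataFrame(cmp_rows),
        predictions=predictions,
        weak_label_error_rate=weak_err,
        histories={"label_generation": hist_surrogate,
                   "weak_labels_only": hist_weak,
                   "confident_learning": hist_cl},
        models=models,
        provenance={
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_external": len(external),
            "n_target_pool": len(pool),
            "n_test": len(test),
            "weak_label_error_rate": weak_err,
            "stages": list(timings),
        },
    )
    if outdir is not None:
        report.save(outdir)
    return report
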