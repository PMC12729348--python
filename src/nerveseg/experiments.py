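"""Experiment orchestration over phantom datasets.

Four designs, mirroring how segmentation studies are usually structured:

* **baseline** — one dataset, seeded 80–20 split, train, evaluate pixel
  metrics and CSA agreement on the held-out test split;
* **cross-generalization** — train on one dataset, evaluate on a second,
  id-disjoint one (optionally after expanding the training set with the
  intensity-augmentation protocol), measuring the domain gap;
* **augmented-internal** — the baseline design applied to an augmented
  dataset (80–20 split of the 11x-expanded pairs);
* **combined trials** — several independent seeded 80–20 splits of a merged
  dataset, reporting per-trial mean ± SD Dice/IoU and their spread.

Test counts use floor(n x test_fraction); trial seeds are base_seed + trial
index; no image id ever appears on both sides of one split, and every
source of randomness flows from the run seed, so identical configurations
reproduce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationSpec, apply_gamma, expand_dataset
from .metrics import METRIC_NAMES, MetricRecord, all_metrics
from .phantom import PhantomSample, PhantomSpec, RaterModel, generate_dataset
from .preprocess import fill_tracing
from .reliability import AgreementResults, CSAAgreement, csa_mm2
from .segnet import (SCALED_TRAIN, LearningCurves, TrainConfig, UNetConfig,
                     UNetSegmenter)

__all__ = [
    "SplitPlan",
    "make_split",
    "make_group_split",
    "DatasetItem",
    "items_from_samples",
    "items_from_pairs",
    "domain_shift",
    "ExperimentConfig",
    "ExperimentReport",
    "run_baseline",
    "run_cross_generalization",
    "run_combined_trials",
    "write_report",
]


@dataclass(frozen=True)
class SplitPlan:
    """Seeded shuffle-then-partition train/test split."""

    n_total: int
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_total < 2:
            raise ValueError("need at least 2 items to split")

    @property
    def n_test(self) -> int:
        return int(np.floor(self.n_total * self.test_fraction))

    @property
    def n_train(self) -> int:
        return self.n_total - self.n_test


def make_split(plan: SplitPlan) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (train_idx, test_idx) index arrays, deterministic in seed."""
    perm = np.random.default_rng(plan.seed).permutation(plan.n_total)
    return np.sort(perm[plan.n_test :]), np.sort(perm[: plan.n_test])


def make_group_split(groups, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Split that keeps all items of a group (e.g., one subject) together.

    Whole groups are assigned to the test side, in seeded shuffled order,
    until at least ``test_fraction`` of the items are covered. Off by
    default in the experiment designs (frames are split independently, the
    laxer convention common when subject links are unavailable); use this
    when subject identifiers exist and leakage across the split matters.
    """
    groups = np.asarray(groups)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups to split")
    order = np.random.default_rng(seed).permutation(uniq)
    target = test_fraction * len(groups)
    test_groups, covered = [], 0
    for g in order:
        if covered >= target:
            break
        test_groups.append(g)
        covered += int(np.sum(groups == g))
    test_mask = np.isin(groups, test_groups)
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


@dataclass(frozen=True)
class DatasetItem:
    """One training/evaluation unit: image, truth mask, manual tracing mask."""

    image: np.ndarray
    mask: np.ndarray  # ground truth
    manual_mask: np.ndarray  # filled simulated-rater tracing
    item_id: str
    pixel_spacing: float
    site: str = ""


def items_from_samples(samples: list[PhantomSample]) -> list[DatasetItem]:
    """Phantom triplets -> dataset items (tracings filled to manual masks)."""
    out = []
    for s in samples:
        h, w = s.mask.shape
        out.append(
            DatasetItem(
                image=s.image, mask=s.mask,
                manual_mask=fill_tracing(s.tracing, h, w),
                item_id=s.sample_id, pixel_spacing=s.pixel_spacing,
                site=s.spec.site,
            )
        )
    return out


def items_from_pairs(pairs, template: list[DatasetItem]) -> list[DatasetItem]:
    """Augmented pairs -> items, inheriting each source item's manual mask
    and calibration (intensity transforms do not move boundaries)."""
    by_id = {t.item_id: t for t in template}
    out = []
    for p in pairs:
        src = by_id[p.source_id]
        out.append(replace(src, image=p.image, item_id=p.pair_id))
    return out


def domain_shift(items: list[DatasetItem], gamma: float = 0.55,
                 tag: str = "shift") -> list[DatasetItem]:
    """Emulate an out-of-domain acquisition by a gamma shift outside the
    augmentation lineup; masks and ids-provenance kept aligned."""
    return [
        replace(it, image=apply_gamma(it.image, gamma),
                item_id=f"{it.item_id}_{tag}")
        for it in items
    ]


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale experiment description (phantoms + network + recipe)."""

    design: str  # baseline | cross_generalization | augmented_internal | combined_trials
    site: str = "wrist"
    n_images: int = 200
    image_size: int = 128
    pixel_spacing: float = 0.1
    base_filters: int = 8
    depth: int = 4
    train: TrainConfig = SCALED_TRAIN
    test_fraction: float = 0.2
    n_trials: int = 5
    augment: bool = False
    rater: RaterModel = field(default_factory=RaterModel)
    seed: int = 0

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec.default(
            self.site, image_height=self.image_size, image_width=self.image_size,
            pixel_spacing=self.pixel_spacing,
        )

    def unet_config(self) -> UNetConfig:
        return UNetConfig(depth=self.depth, base_filters=self.base_filters,
                          input_size=(self.image_size, self.image_size))

    def manifest(self) -> dict:
        d = self.__dict__.copy()
        d["train"] = self.train.__dict__
        d["rater"] = self.rater.__dict__
        return d

    @classmethod
    def from_manifest(cls, manifest: dict) -> "ExperimentConfig":
        """Reconstruct the exact configuration a report was produced with."""
        d = {k: v for k, v in manifest.items() if k in cls.__dataclass_fields__}
        d["train"] = TrainConfig(**manifest["train"])
        d["rater"] = RaterModel(**manifest["rater"])
        return cls(**d)


@dataclass
class ExperimentReport:
    """Everything one run produced, ready for :func:`write_report`."""

    design: str
    manifest: dict
    metrics: pd.DataFrame | None = None  # per image
    summary: pd.DataFrame | None = None  # mean/sd per metric
    agreement: AgreementResults | None = None
    curves: LearningCurves | None = None
    extras: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return self.metrics is not None and self.summary is not None


def _summarize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean/sample-SD per metric, skipping undefined (nan) entries —
    empty predictions leave precision undefined without voiding a report."""
    cols = list(METRIC_NAMES)
    return pd.DataFrame({"mean": frame[cols].mean(), "sd": frame[cols].std(ddof=1)})


def _safe_agreement(manual, predicted):
    """Agreement results, or None when the series are too short or
    degenerate (e.g., a collapsed model predicting no nerve anywhere)."""
    if len(manual) < 5:
        return None
    try:
        return CSAAgreement(manual, predicted).fit()
    except ValueError:
        return None


def _stack(items: list[DatasetItem]):
    return (np.stack([i.image for i in items]),
            np.stack([i.mask for i in items]))


def _evaluate(fit, items: list[DatasetItem]):
    """Per-image metric records + CSA pairs for a fitted model."""
    images, masks = _stack(items)
    preds = fit.predict(images)
    records: list[MetricRecord] = []
    manual, predicted = [], []
    for item, pred in zip(items, preds):
        records.append(all_metrics(pred, item.mask, image_id=item.item_id))
        manual.append(csa_mm2(item.manual_mask, item.pixel_spacing))
        predicted.append(csa_mm2(pred, item.pixel_spacing))
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame["site"] = [i.site for i in items]
    return frame, records, np.array(manual), np.array(predicted)


def _train_on(cfg: ExperimentConfig, items: list[DatasetItem], seed: int):
    images, masks = _stack(items)
    model = UNetSegmenter(cfg.unet_config(), replace(cfg.train, seed=seed))
    return model.fit(images, masks)


def run_baseline(cfg: ExperimentConfig,
                 items: list[DatasetItem] | None = None) -> ExperimentReport:
    """Single-dataset 80–20 experiment: split, train, test metrics + CSA."""
    if items is None:
        samples = generate_dataset(cfg.phantom_spec(), cfg.n_images,
                                   seed=cfg.seed, rater=cfg.rater)
        items = items_from_samples(samples)
        if cfg.augment:
            aug = AugmentationSpec().for_image_size(*items[0].image.shape)
            pairs = expand_dataset(
                [(i.image, i.mask, i.item_id) for i in items],
                aug, np.random.default_rng(cfg.seed + 1),
            )
            items = items_from_pairs(pairs, items)
    if not items:
        raise ValueError("baseline design needs a non-empty dataset")
    plan = SplitPlan(len(items), cfg.test_fraction, seed=cfg.seed)
    train_idx, test_idx = make_split(plan)
    fit = _train_on(cfg, [items[i] for i in train_idx], seed=cfg.seed)
    frame, records, manual, predicted = _evaluate(fit, [items[i] for i in test_idx])
    agreement = _safe_agreement(manual, predicted)
    return ExperimentReport(
        design=cfg.design, manifest=cfg.manifest(),
        metrics=frame, summary=_summarize_frame(frame),
        agreement=agreement, curves=fit.curves,
        extras={"n_train": int(plan.n_train), "n_test": int(plan.n_test)},
    )


def run_cross_generalization(cfg: ExperimentConfig,
                             train_items: list[DatasetItem],
                             test_items: list[DatasetItem],
                             augment: bool | None = None) -> ExperimentReport:
    """Train on dataset A, evaluate on id-disjoint dataset B.

    With ``augment`` the training set is first expanded by the
    11-variant intensity protocol. Overlapping ids raise (leakage guard).
    """
    train_ids = {i.item_id for i in train_items}
    if train_ids & {i.item_id for i in test_items}:
        raise ValueError("train and test datasets share image ids")
    augment = cfg.augment if augment is None else augment
    if augment:
        aug = AugmentationSpec().for_image_size(*train_items[0].image.shape)
        pairs = expand_dataset(
            [(i.image, i.mask, i.item_id) for i in train_items],
            aug, np.random.default_rng(cfg.seed + 1),
        )
        train_items = items_from_pairs(pairs, train_items)
    fit = _train_on(cfg, train_items, seed=cfg.seed)
    frame, records, manual, predicted = _evaluate(fit, test_items)
    agreement = _safe_agreement(manual, predicted)
    return ExperimentReport(
        design="cross_generalization", manifest=cfg.manifest(),
        metrics=frame, summary=_summarize_frame(frame), agreement=agreement,
        curves=fit.curves,
        extras={"n_train": len(train_items), "n_test": len(test_items),
                "augmented": bool(augment)},
    )


def run_combined_trials(cfg: ExperimentConfig,
                        items: list[DatasetItem] | None = None) -> ExperimentReport:
    """n_trials independent seeded 80–20 splits of one merged dataset."""
    if items is None:
        samples = generate_dataset(cfg.phantom_spec(), cfg.n_images,
                                   seed=cfg.seed, rater=cfg.rater)
        items = items_from_samples(samples)
    rows = []
    per_trial_metrics = []
    for trial in range(cfg.n_trials):
        seed = cfg.seed + trial
        plan = SplitPlan(len(items), cfg.test_fraction, seed=seed)
        train_idx, test_idx = make_split(plan)
        fit = _train_on(cfg, [items[i] for i in train_idx], seed=seed)
        frame, records, _, _ = _evaluate(fit, [items[i] for i in test_idx])
        summ = _summarize_frame(frame)
        per_trial_metrics.append(frame)
        rows.append({
            "trial": trial + 1, "seed": seed, "n_test": plan.n_test,
            "dice_mean": summ.loc["dice", "mean"], "dice_sd": summ.loc["dice", "sd"],
            "iou_mean": summ.loc["iou", "mean"], "iou_sd": summ.loc["iou", "sd"],
        })
    table = pd.DataFrame(rows)
    spread = float(table["dice_mean"].max() - table["dice_mean"].min())
    all_frames = pd.concat(per_trial_metrics, keys=range(1, cfg.n_trials + 1),
                           names=["trial"])
    return ExperimentReport(
        design="combined_trials", manifest=cfg.manifest(),
        metrics=all_frames.reset_index(level=0),
        summary=_summarize_frame(all_frames),
        extras={"trial_table": table, "dice_spread": spread},
    )


def generalization_gap_study(seeds=(1, 2, 3), site: str = "wrist",
                             n_train: int = 24, n_test: int = 12,
                             image_size: int = 64, pixel_spacing: float = 0.2,
                             epochs_plain: int = 60, epochs_aug: int = 8,
                             shift_gamma: float = 0.55) -> pd.DataFrame:
    """Repeat the domain-shift comparison over several seeds.

    For each seed: train one model on plain phantoms and one on their
    11-variant augmented expansion (fewer epochs, so the optimization
    budgets are comparable), then evaluate both on an id-disjoint test set
    rendered in-domain and on its gamma-shifted counterpart. Returns one
    row per seed with the four mean Dice values and the in-vs-out gap of
    each model.
    """
    rows = []
    for seed in seeds:
        cfg = ExperimentConfig(
            design="cross_generalization", site=site, image_size=image_size,
            pixel_spacing=pixel_spacing, base_filters=8,
            train=replace(SCALED_TRAIN, epochs=epochs_plain), seed=int(seed),
        )
        spec = cfg.phantom_spec()
        train_items = items_from_samples(generate_dataset(spec, n_train, seed=int(seed)))
        test_same = items_from_samples(
            generate_dataset(spec, n_test, seed=int(seed) + 5000))
        test_shift = domain_shift(test_same, gamma=shift_gamma)
        cfg_aug = replace(cfg, train=replace(cfg.train, epochs=epochs_aug))

        def _dice(c, te, aug):
            rep = run_cross_generalization(c, train_items, te, augment=aug)
            return float(rep.summary.loc["dice", "mean"])

        same_plain = _dice(cfg, test_same, False)
        shift_plain = _dice(cfg, test_shift, False)
        same_aug = _dice(cfg_aug, test_same, True)
        shift_aug = _dice(cfg_aug, test_shift, True)
        rows.append({
            "seed": int(seed),
            "dice_in_plain": same_plain, "dice_out_plain": shift_plain,
            "dice_in_aug": same_aug, "dice_out_aug": shift_aug,
            "gap_plain": same_plain - shift_plain,
            "gap_aug": same_aug - shift_aug,
        })
    return pd.DataFrame(rows)


def write_report(report: ExperimentReport, out_dir: str | Path) -> list[Path]:
    """Write metrics/summary CSVs, agreement JSON, curves CSV and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    manifest = dict(report.manifest)
    manifest["design"] = report.design
    manifest["complete"] = report.complete
    import nerveseg

    manifest["versions"] = {"nerveseg": getattr(nerveseg, "__version__", "0"),
                            "numpy": np.__version__}
    _w(out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if report.metrics is not None:
        report.metrics.to_csv(_w(out / "metrics.csv"), index=False)
    if report.summary is not None:
        report.summary.to_csv(_w(out / "summary.csv"))
    if report.agreement is not None:
        report.agreement.to_json(_w(out / "agreement.json"))
        report.agreement.ba_frame.to_csv(_w(out / "bland_altman.csv"), index=False)
    if report.curves is not None:
        report.curves.to_frame().to_csv(_w(out / "curves.csv"), index=False)
    if "trial_table" in report.extras:
        report.extras["trial_table"].to_csv(_w(out / "trials.csv"), index=False)
    return written
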