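"""End-to-end orchestration: classification and survival pipelines.

``run_classification`` chains tile -> background filter -> slide-level
split -> scorer training -> embedding extraction -> DAG-SVM -> metric
panel, and adds a slide-wise AUC computed from per-slide fractions of
positively classified patches.  ``run_survival`` chains patch scoring ->
probability heatmap -> strict 0.95 masking -> 1/3-of-main-region cleanup ->
tumor + nuclei morphometry -> patient aggregation -> univariate feature
screen -> integrative lasso-Cox stratification with Kaplan-Meier, log-rank
and multivariate Cox reporting.

One global seed determines every stochastic choice.  The demo dataset
generator builds a small fully synthetic study — subtype slides, matched
normals, and a survival cohort in which a latent hazard driver also drives
tumor area, planting a recoverable image-survival association.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dagsvm as _dagsvm
from . import heatmap as _heatmap
from . import morphometry as _morph
from . import scorer as _scorer
from . import survival as _survival
from . import tiling as _tiling
from .synthetic import SyntheticSlideSpec, TextureParams, generate_slide

__all__ = ["PipelineConfig", "Slide", "generate_demo_dataset",
           "run_classification", "run_survival", "demo_config"]


@dataclass
class PipelineConfig:
    """Single document holding every pipeline parameter.

    Defaults follow the reference protocol: 512-pixel tiles with 50%
    overlap, background threshold 210 on half the pixels, 224-pixel scorer
    inputs with batch 128 and learning rate 1e-5, probability threshold
    0.95, 1/3 region cleanup, 10-fold inner CV and a 70/15/15 split.
    """

    # tiling
    tile_size: int = 512
    overlap_fraction: float = 0.5
    bg_threshold: float = 210.0
    bg_fraction: float = 0.5
    # scorer
    backbone: str = "reference"
    resize: int = 224
    batch_size: int = 128
    learning_rate: float = 1e-5
    patience: int = 5
    max_epochs: int = 40
    embed_dim: int = 512
    # dag-svm
    svm_C: float = 1.0
    # heatmap / mask
    prob_threshold: float = 0.95
    min_region_fraction: float = 1.0 / 3.0
    heatmap_downsample: int = 8
    positive_threshold: float = 0.5
    # morphometry
    min_nucleus_area: int = 15
    # survival
    folds: int = 10
    alpha: float = 0.05
    # split
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        if "split_fractions" in doc:
            doc["split_fractions"] = tuple(doc["split_fractions"])
        return cls(**doc)

    @property
    def grid(self) -> _tiling.TileGrid:
        return _tiling.TileGrid(self.tile_size, self.overlap_fraction)

    def scorer_config(self, n_classes: int) -> _scorer.ScorerConfig:
        return _scorer.ScorerConfig(
            backbone=self.backbone, resize=self.resize,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            patience=self.patience, max_epochs=self.max_epochs,
            n_output_classes=n_classes, embed_dim=self.embed_dim,
            seed=self.seed,
        )


@dataclass
class Slide:
    slide_id: str
    image: np.ndarray
    label: str
    patient_id: str | None = None
    tumor_mask: np.ndarray | None = None  # ground truth, synthetic slides only


def demo_config(seed: int = 0) -> PipelineConfig:
    """Configuration scaled to the synthetic demo dataset.

    Small tiles and a light reference scorer keep the full pipeline within
    minutes on one CPU while exercising every stage.
    """
    return PipelineConfig(
        tile_size=32, overlap_fraction=0.5, resize=16,
        learning_rate=1e-3, batch_size=64, max_epochs=15, patience=4,
        embed_dim=128, heatmap_downsample=4, min_nucleus_area=8,
        seed=seed,
    )


_SUBTYPE_TEXTURES = {
    # distinct mean colors stand in for subtype-specific tissue appearance
    "KIRC": TextureParams(blob_density=10.0, base_color=(190, 150, 185)),
    "KIRP": TextureParams(blob_density=14.0, base_color=(150, 120, 170)),
    "KICH": TextureParams(blob_density=6.0, base_color=(175, 170, 140)),
    "normal": TextureParams(blob_density=4.0, base_color=(205, 175, 185)),
}


def _make_slide(slide_id: str, label: str, tumor_fraction: float,
                size: int, seed: int, patient_id: str | None = None) -> Slide:
    textures = dict(_SUBTYPE_TEXTURES)
    tumor_key = label if label in _SUBTYPE_TEXTURES and label != "normal" else "KIRC"
    textures["tumor"] = textures[tumor_key]
    spec = SyntheticSlideSpec(
        width=size, height=size, tumor_fraction=tumor_fraction,
        textures=textures, tissue_classes=["tumor", "normal"],
        label=label, seed=seed,
    )
    img, mask, _ = generate_slide(spec)
    return Slide(slide_id, img, label, patient_id, mask)


def generate_demo_dataset(
    n_per_subtype: int = 10,
    n_normal: int = 10,
    n_patients: int = 48,
    slide_size: int = 256,
    survival_beta: float = 1.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> dict:
    """Synthetic demo study: subtype slides, normals, and a survival cohort.

    Survival-cohort slides share one latent driver per patient: it scales
    the tumor fraction of the slide *and* the patient's hazard
    (``rate = baseline * exp(beta * u)``), so tumor-area features carry a
    real, recoverable survival signal.  Returns a dict with ``subtype``
    and ``binary`` slide lists, the ``cohort`` slide list and its
    ``clinical`` table.
    """
    rng = np.random.default_rng(seed)
    subtype_slides, binary_slides = [], []
    for label in ("KIRC", "KIRP", "KICH"):
        for k in range(n_per_subtype):
            s = _make_slide(f"{label}_{k}", label, tumor_fraction=1.0,
                            size=slide_size, seed=int(rng.integers(2**31)))
            subtype_slides.append(s)
    for k in range(n_normal):
        s = _make_slide(f"normal_{k}", "normal", tumor_fraction=0.0,
                        size=slide_size, seed=int(rng.integers(2**31)))
        binary_slides.append(s)
    # binary task reuses the KIRC slides as the tumor class
    binary_slides += [Slide(s.slide_id, s.image, "tumor", s.patient_id,
                            s.tumor_mask)
                      for s in subtype_slides if s.label == "KIRC"]

    # survival cohort: latent driver u -> tumor fraction and hazard
    u = rng.standard_normal(n_patients)
    tumor_fraction = np.clip(0.45 + 0.22 * u, 0.1, 0.9)
    baseline = 1.0 / 1000.0
    hazard = baseline * np.exp(survival_beta * u)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = float(hazard.mean()) * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    clinical = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n_patients)],
        "time": np.minimum(event_time, censor_time),
        "event": event_time <= censor_time,
        "age": np.round(rng.normal(60, 10, n_patients)).clip(30, 90),
        "gender": rng.integers(0, 2, n_patients),
        "stage": rng.integers(1, 5, n_patients),
        "grade": rng.integers(1, 5, n_patients),
    })
    cohort_slides = [
        _make_slide(f"S{i:03d}", "tumor", float(tumor_fraction[i]),
                    slide_size, int(rng.integers(2**31)),
                    patient_id=f"P{i:03d}")
        for i in range(n_patients)
    ]
    return {"subtype": subtype_slides, "binary": binary_slides,
            "cohort": cohort_slides, "clinical": clinical,
            "latent_driver": u}


# ---------------------------------------------------------------------------
# classification pipeline
# ---------------------------------------------------------------------------

def _tile_and_filter(slides: list[Slide], config: PipelineConfig):
    grid = config.grid
    kept_by_slide = {}
    for s in slides:
        patches = _tiling.tile_slide(s.image, grid, s.slide_id, s.label)
        kept, _ = _tiling.filter_patches(patches, config.bg_threshold,
                                         config.bg_fraction)
        kept_by_slide[s.slide_id] = kept
    return kept_by_slide


def run_classification(slides: list[Slide], config: PipelineConfig) -> dict:
    """Train and evaluate the patch scorer + DAG-SVM on labeled slides.

    Returns a report dict with the patch-wise metric panels of the scorer
    alone and of the DAG-SVM head, the slide-wise AUC, the split and the
    trained models (``scorer``, ``dag_model``).
    """
    if not slides:
        raise ValueError("no slides given")
    labels = {s.slide_id: s.label for s in slides}
    if any(l is None for l in labels.values()):
        raise ValueError("every slide needs a label")
    manifest = pd.DataFrame({"slide_id": list(labels), "label": list(labels.values())})
    folds = _scorer.split_dataset(manifest, config.split_fractions, config.seed)

    kept = _tile_and_filter(slides, config)
    def fold_patches(name):
        return [p for sid in sorted(folds[name]) for p in kept[sid]]
    train_p, val_p, test_p = (fold_patches(n) for n in ("train", "val", "test"))
    if not train_p or not test_p:
        raise ValueError("empty train or test fold after filtering")

    scfg = config.scorer_config(n_classes=len(set(labels.values())))
    sc = _scorer.train_scorer(train_p, val_p, scfg)

    # patch-wise scorer panel on the test fold
    y_test = [p.label for p in test_p]
    probs = sc.score(test_p)
    pred_cnn = [sc.classes_[k] for k in probs.argmax(axis=1)]
    panel_cnn = _dagsvm.metric_panel(y_test, pred_cnn, probs, sc.classes_)

    # DAG-SVM over penultimate embeddings
    E_train = _scorer.extract_embeddings(sc, train_p)
    E_test = _scorer.extract_embeddings(sc, test_p)
    dag = _dagsvm.train_dagsvm(E_train, [p.label for p in train_p], C=config.svm_C)
    pred_dag = _dagsvm.predict_dag_batch(dag, E_test)
    scores_dag = _dagsvm.decision_scores(dag, E_test)
    panel_dag = _dagsvm.metric_panel(y_test, pred_dag, scores_dag, dag.classes)

    # slide-wise AUC: per-slide fraction of patches DAG-assigned to a class
    test_ids = sorted(folds["test"])
    slide_rows, slide_true = [], []
    for sid in test_ids:
        if not kept[sid]:
            continue
        pred = _dagsvm.predict_dag_batch(dag, _scorer.extract_embeddings(sc, kept[sid]))
        slide_rows.append([float(np.mean(pred == c)) for c in dag.classes])
        slide_true.append(labels[sid])
    slide_auc = _dagsvm.multiclass_auc(np.asarray(slide_rows), slide_true,
                                       dag.classes) if slide_rows else None

    return {
        "split": {k: sorted(v) for k, v in folds.items()},
        "panel_scorer": panel_cnn, "panel_dag": panel_dag,
        "slide_auc": slide_auc,
        "scorer": sc, "dag_model": dag,
    }


# ---------------------------------------------------------------------------
# survival pipeline
# ---------------------------------------------------------------------------

def slide_survival_features(slide: Slide, sc, config: PipelineConfig,
                            tumor_class: str = "tumor") -> dict:
    """Heatmap -> cleaned mask -> tumor + nuclei features for one slide."""
    grid = config.grid
    patches = _tiling.tile_slide(slide.image, grid, slide.slide_id)
    kept, _ = _tiling.filter_patches(patches, config.bg_threshold,
                                     config.bg_fraction)
    if not kept:
        return {"slide_id": slide.slide_id, "n_patches": 0}
    probs = sc.score(kept)
    tumor_idx = list(sc.classes_).index(tumor_class)
    scores = probs[:, tumor_idx]
    manifest = pd.DataFrame({"x": [p.x for p in kept], "y": [p.y for p in kept],
                             "score": scores})
    hm = _heatmap.build_heatmap(manifest, slide.image.shape[:2], grid,
                                config.heatmap_downsample)
    mask = _heatmap.high_prob_mask(hm, config.prob_threshold)
    # patch probabilities describe tissue; drop near-white background cells
    # (sampled at the same representative pixel as heatmap coverage)
    ds = config.heatmap_downsample
    rep = slide.image[::ds, ::ds].astype(np.float64).mean(axis=2)
    mask &= rep[:mask.shape[0], :mask.shape[1]] <= config.bg_threshold
    tmask = _heatmap.clean_mask(mask, config.min_region_fraction)
    row = {"slide_id": slide.slide_id, "n_patches": len(kept)}
    row.update(_morph.slide_tumor_features(tmask))
    hi_patches = [p for p, s in zip(kept, scores) if s > config.prob_threshold]
    if hi_patches:
        row.update(_morph.slide_nuclei_features(
            hi_patches, lambda img: _morph.segment_nuclei(
                img, min_area=config.min_nucleus_area)))
    row["_mask"] = tmask
    return row


def run_survival(slides: list[Slide], clinical: pd.DataFrame, sc,
                 config: PipelineConfig, tumor_class: str = "tumor",
                 features: list[str] | None = None) -> dict:
    """Image-feature survival stratification over a slide cohort.

    ``sc`` is a trained tumor/normal scorer.  Slides with empty cleaned
    masks are excluded with a warning entry.  Features screened
    univariately (two-level CV per feature, log-rank p); those significant
    at ``config.alpha`` enter the integrative lasso-Cox stratification.
    """
    rows, masks, warnings_ = [], {}, []
    for s in slides:
        row = slide_survival_features(s, sc, config, tumor_class)
        masks[s.slide_id] = row.pop("_mask", None)
        if row.get("n_patches", 0) == 0 or not np.isfinite(
                row.get("total_area", np.nan)):
            warnings_.append(f"slide {s.slide_id}: empty mask, excluded")
            continue
        rows.append(row)
    if not rows:
        raise ValueError("no usable slides")
    slide_feats = pd.DataFrame(rows).fillna(0.0)
    mapping = {s.slide_id: s.patient_id for s in slides}
    patient_feats = _morph.aggregate_patients(
        slide_feats.drop(columns=["n_patches"]), mapping)

    records = clinical.merge(patient_feats, left_on="patient_id",
                             right_index=True, how="inner")
    if features is None:
        features = [c for c in _morph.CANONICAL_TUMOR_FEATURES
                    + _morph.NUCLEI_FEATURES if c in records.columns
                    and records[c].std() > 1e-12]
    screen = _survival.univariate_feature_screen(
        records, features, seed=config.seed, folds=config.folds,
        alpha=config.alpha)
    selected = screen.loc[screen["significant"], "feature"].tolist()
    integrative = None
    if selected:
        integrative = _survival.two_level_cv_stratify(
            records, selected, seed=config.seed, folds=config.folds)
    report = {
        "slide_features": slide_feats, "patient_features": patient_feats,
        "records": records, "screen": screen, "selected": selected,
        "integrative": integrative, "warnings": warnings_, "masks": masks,
    }
    if integrative is not None and not integrative.degenerate:
        records = records.assign(risk_group=integrative.group,
                                 risk_index=integrative.risk)
        km = {g: _survival.km_curve(sub["time"], sub["event"])
              for g, sub in records.groupby("risk_group")}
        report["km_curves"] = km
        cov_cols = [c for c in ("age", "gender", "stage", "grade")
                    if c in records.columns]
        try:
            report["multivariate"] = _survival.multivariate_cox(
                records.assign(risk_index=integrative.risk),
                ["risk_index"] + cov_cols)
        except Exception as exc:  # non-convergence reported, not fatal
            report["multivariate_error"] = str(exc)
    return report
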