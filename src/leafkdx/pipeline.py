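"""End-to-end orchestration: generate/ingest → preprocess → extract →
screen → reduce → train → evaluate, per growth period.

Each growth period (flowering, young fruit, fruit enlarging, mature) gets
its own screening, projection and classifier, fitted on an independent
stratified 70/30 split.  All randomness flows from one master seed, so a
rerun with the same config reproduces every numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import synthgen
from .classify import (
    ClassifierSpec,
    EvaluationReport,
    KDeficiencyDiagnoser,
    evaluate,
    split_dataset,
    train,
)
from .features import extract_leaf_features, features_to_frame
from .preprocess import (
    EmptySegmentationError,
    MSRCRParams,
    SegmentationParams,
    gaussian_denoise,
    msrcr,
    segment_leaf,
    segment_regions,
    split_leaves,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "field_validate", "image_to_features"]


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters for one reproducible run."""

    n_per_period: int = 500
    periods: tuple[str, ...] = synthgen.PERIODS
    seed: int = 0
    classifier: str = "svm"
    lda_dims: int = 2
    screening: bool = True
    threshold: float | None = None
    response: str = "k_content"
    train_frac: float = 0.7
    label_threshold: float = 0.8
    use_msrcr: bool = True
    gaussian_sigma: float = 1.0
    gaussian_ksize: int = 5
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    versions: dict
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def image_to_features(
    img: np.ndarray,
    sample_id: str = "",
    period: str = "",
    label: int | None = None,
    k_content: float | None = None,
    use_msrcr: bool = True,
    gaussian_sigma: float = 1.0,
    gaussian_ksize: int = 5,
    seg_params: SegmentationParams | None = None,
    msrcr_params: MSRCRParams | None = None,
) -> list[dict]:
    """Full image→FeatureVector path for one photograph.

    Denoise, remove the board background, apply MSRCR illumination
    correction, split into single leaves, segment discolor regions, and
    compute the 22 features per leaf.  Region masks come from the
    denoised image (the hue thresholds are calibrated on natural colors);
    color means come from the MSRCR-corrected raster so they are
    comparable across illumination conditions.
    """
    den = gaussian_denoise(img, sigma=gaussian_sigma, ksize=gaussian_ksize)
    mask = segment_leaf(den)
    if use_msrcr:
        mp = msrcr_params or MSRCRParams.for_image_size(den.shape)
        corrected = msrcr(den, mp)
    else:
        corrected = den
    # crop both rasters consistently by stacking them channel-wise
    stacked = np.concatenate([den, corrected], axis=2)
    leaves = split_leaves(mask, stacked)
    records = []
    for i, (crop, crop_mask) in enumerate(leaves):
        den_crop, cor_crop = crop[..., :3], crop[..., 3:]
        masks = segment_regions(den_crop, crop_mask, seg_params)
        sid = sample_id if len(leaves) == 1 else f"{sample_id}_leaf{i}"
        records.append(
            extract_leaf_features(
                den_crop,
                masks,
                color_img=cor_crop,
                sample_id=sid,
                period=period,
                label=label,
                k_content=k_content,
            )
        )
    return records


def _dataset_features(
    images: list[np.ndarray], table: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, list[str]]:
    records, warns = [], []
    for img, row in zip(images, table.itertuples()):
        try:
            recs = image_to_features(
                img,
                sample_id=row.sample_id,
                period=row.period,
                label=int(row.label),
                k_content=float(row.k_content),
                use_msrcr=config.use_msrcr,
                gaussian_sigma=config.gaussian_sigma,
                gaussian_ksize=config.gaussian_ksize,
            )
        except EmptySegmentationError as exc:  # pragma: no cover - defensive
            warns.append(f"{row.sample_id}: {exc}")
            continue
        records.extend(recs)
    return features_to_frame(records), warns


def run_pipeline(
    config: RunConfig,
) -> tuple[RunManifest, dict[str, EvaluationReport], dict[str, KDeficiencyDiagnoser]]:
    """Execute the full chain for every growth period.

    Returns (manifest, {period: EvaluationReport}, {period: fitted model}).
    Artifacts (features CSV, reports, manifest) are written under
    ``config.out_dir`` when set.
    """
    import sklearn
    import skimage

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        config_hash=config.config_hash(),
        versions={
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    )
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.periods)) % (2**31)
    reports: dict[str, EvaluationReport] = {}
    models: dict[str, KDeficiencyDiagnoser] = {}
    for period, pseed in zip(config.periods, seeds):
        t0 = time.perf_counter()
        pseed = int(pseed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            images, truth = synthgen.make_dataset(
                config.n_per_period,
                period=period,
                seed=pseed,
                label_threshold=config.label_threshold,
            )
            feats, warns = _dataset_features(images, truth, config)
            manifest.warnings.extend(warns)
            tr, te = split_dataset(feats, train_frac=config.train_frac, seed=pseed)
            spec = ClassifierSpec(kind=config.classifier, seed=pseed)
            model = train(
                spec,
                tr,
                screening=config.screening,
                threshold=config.threshold,
                response=config.response,
                lda_dims=config.lda_dims,
            )
            pred = model.predict(te)
            reports[period] = evaluate(te["label"].to_numpy(), pred, period=period)
            models[period] = model
        manifest.warnings.extend(f"{period}: {w.message}" for w in caught)
        manifest.timings[period] = time.perf_counter() - t0
        if out:
            fpath = out / f"features_{period}.csv"
            feats.to_csv(fpath, index=False)
            rpath = out / f"report_{period}.json"
            rpath.write_text(json.dumps(reports[period].to_dict(), indent=2))
            manifest.outputs[f"features_{period}"] = str(fpath)
            manifest.outputs[f"report_{period}"] = str(rpath)
    if out:
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest.to_dict(), indent=2, default=str))
        manifest.outputs["manifest"] = str(mpath)
    return manifest, reports, models


def field_validate(
    model: KDeficiencyDiagnoser,
    images: str | Path | list[np.ndarray],
    truth: str | Path | pd.DataFrame,
    config: RunConfig | None = None,
) -> EvaluationReport:
    """Run the full image→diagnosis path on unseen photographs.

    ``images`` is a directory of PNG/JPEG/TIFF files named by sample id
    (or an in-memory list matching the truth table order); ``truth`` is a
    CSV/DataFrame with sample_id and label columns.  Unreadable images
    are skipped with a logged warning.
    """
    config = config or RunConfig()
    truth_df = pd.read_csv(truth) if not isinstance(truth, pd.DataFrame) else truth.copy()
    truth_df = truth_df.set_index("sample_id")

    pairs: list[tuple[str, np.ndarray]] = []
    if isinstance(images, (str, Path)):
        files = sorted(
            p for p in Path(images).iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no images found in {images}")
        for f in files:
            try:
                pairs.append((f.stem, np.asarray(Image.open(f).convert("RGB"))))
            except OSError as exc:
                log.warning("skipping unreadable image %s: %s", f, exc)
    else:
        if len(images) != len(truth_df):
            raise ValueError("image list and truth table length mismatch")
        pairs = list(zip(truth_df.index.astype(str), images))

    orphans = [sid for sid, _ in pairs if sid not in truth_df.index]
    if orphans:
        raise ValueError(f"images without truth rows: {orphans}")

    records = []
    for sid, img in pairs:
        records.extend(
            image_to_features(
                img,
                sample_id=sid,
                period=str(truth_df.loc[sid].get("period", "")),
                label=int(truth_df.loc[sid, "label"]),
                use_msrcr=config.use_msrcr,
                gaussian_sigma=config.gaussian_sigma,
                gaussian_ksize=config.gaussian_ksize,
            )
        )
    feats = features_to_frame(records)
    pred = model.predict(feats)
    rep = evaluate(feats["label"].to_numpy(), pred, period="validation")
    return rep
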