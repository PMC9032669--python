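"""Five-stage classification pipeline: acquire → segment → extract → classify → report.

Ties the modules together for whole-image inference: HSV vegetation
segmentation, morphological clean-up, connected-component ROI extraction,
per-ROI classification (LBP+SVM or the CNN head), and an annotated output
image with class-coloured boxes — green Crop, red NLW, blue BLW.

A :class:`PipelineConfig` carries every tunable (thresholds, structuring
element, connectivity, minimum region area, LBP geometry, classifier
choice) and round-trips through YAML, so a run is reproducible from its
config file.  SVM models carry the fingerprint of the LBP geometry they
were trained on; the pipeline refuses a model whose fingerprint does not
match the config, which catches feature/model mismatches early.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import components as comp
from . import morphology, segmentation
from .lbp import LBPConfig, featurize_patch
from .segmentation import HSVThresholds
from .svm import MulticlassSVM

__all__ = ["PipelineConfig", "Detection", "run_pipeline", "detections_to_frame", "annotate"]

BOX_COLORS = {"Crop": (0, 255, 0), "NLW": (255, 0, 0), "BLW": (0, 0, 255)}


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: HSVThresholds = field(default_factory=HSVThresholds)
    se_size: int = 5
    se_shape: str = "square"  # or "disk"
    connectivity: int = 8
    min_area: int = 400
    padding: int = 0
    lbp: LBPConfig = field(default_factory=LBPConfig)
    classifier: str = "svm"  # or "cnn"
    seed: int = 0

    def structuring_element(self) -> np.ndarray:
        if self.se_shape == "square":
            return morphology.square_se(self.se_size)
        if self.se_shape == "disk":
            return morphology.disk_se(self.se_size // 2)
        raise ValueError(f"unknown structuring element shape {self.se_shape!r}")

    def to_yaml(self, path) -> None:
        data = {
            "thresholds": dataclasses.asdict(self.thresholds),
            "se_size": self.se_size,
            "se_shape": self.se_shape,
            "connectivity": self.connectivity,
            "min_area": self.min_area,
            "padding": self.padding,
            "lbp": dataclasses.asdict(self.lbp),
            "classifier": self.classifier,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return PipelineConfig(
            thresholds=HSVThresholds(**data.get("thresholds", {})),
            se_size=data.get("se_size", 5),
            se_shape=data.get("se_shape", "square"),
            connectivity=data.get("connectivity", 8),
            min_area=data.get("min_area", 400),
            padding=data.get("padding", 0),
            lbp=LBPConfig(**data.get("lbp", {})),
            classifier=data.get("classifier", "svm"),
            seed=data.get("seed", 0),
        )


@dataclass(frozen=True)
class Detection:
    image_id: str
    bbox: tuple[int, int, int, int]  # rmin, cmin, rmax, cmax inclusive
    label: str
    score: float  # winning decision magnitude (SVM) or probability (CNN)


def run_pipeline(
    image: np.ndarray, model, config: PipelineConfig = PipelineConfig(),
    image_id: str = "image",
) -> tuple[list[Detection], np.ndarray]:
    """Detect and classify every plant in one RGB field image.

    Returns (detections, annotated image).  ``model`` is a fitted
    :class:`~weedvision.svm.MulticlassSVM` (``config.classifier == "svm"``;
    ROIs are LBP-featurised with ``config.lbp``) or a
    :class:`~weedvision.cnn.TrainedClassifier` (``"cnn"``; ROIs are passed
    as images).
    """
    image = np.asarray(image)
    se = config.structuring_element()
    mask = segmentation.segment_vegetation(image, config.thresholds)
    mask = morphology.enhance_mask(mask, se)
    cm = comp.label_components(mask, connectivity=config.connectivity)
    cm = comp.filter_small_components(cm, config.min_area)
    patches = comp.extract_patches(image, cm, padding=config.padding)

    detections: list[Detection] = []
    if patches:
        if config.classifier == "svm":
            if not isinstance(model, MulticlassSVM):
                raise TypeError("config.classifier is 'svm' but model is not a MulticlassSVM")
            fp = config.lbp.fingerprint()
            if model.feature_fingerprint is not None and model.feature_fingerprint != fp:
                raise ValueError(
                    f"model was trained on features {model.feature_fingerprint!r} "
                    f"but the pipeline computes {fp!r}"
                )
            X = np.vstack([featurize_patch(p, config.lbp) for p in patches])
            labels = model.predict(X)
            decisions = model.decision_matrix(X)
            scores = np.zeros(len(patches))
            for (ci, cj), vals in decisions.items():
                for k, lab in enumerate(labels):
                    if lab in (ci, cj):
                        scores[k] = max(scores[k], abs(float(vals[k])))
        elif config.classifier == "cnn":
            probs = model.predict_proba(patches)
            labels = np.asarray([model.classes[i] for i in probs.argmax(axis=1)])
            scores = probs.max(axis=1)
        else:
            raise ValueError(f"unknown classifier kind {config.classifier!r}")
        for patch, lab, score in zip(patches, labels, scores):
            detections.append(
                Detection(image_id=image_id, bbox=patch.bbox, label=str(lab),
                          score=float(score))
            )

    return detections, annotate(image, detections)


def annotate(image: np.ndarray, detections) -> np.ndarray:
    """Draw class-coloured bounding boxes (green Crop, red NLW, blue BLW)."""
    out = np.asarray(image).copy()
    m, n = out.shape[:2]
    for det in detections:
        color = BOX_COLORS.get(det.label, (255, 255, 0))
        r0, c0, r1, c1 = det.bbox
        for t in range(2):  # 2 px frame
            rr0, cc0 = max(r0 - t, 0), max(c0 - t, 0)
            rr1, cc1 = min(r1 + t, m - 1), min(c1 + t, n - 1)
            out[rr0, cc0 : cc1 + 1] = color
            out[rr1, cc0 : cc1 + 1] = color
            out[rr0 : rr1 + 1, cc0] = color
            out[rr0 : rr1 + 1, cc1] = color
    return out


def detections_to_frame(detections) -> pd.DataFrame:
    rows = [
        {
            "image_id": d.image_id,
            "bbox_rmin": d.bbox[0],
            "bbox_cmin": d.bbox[1],
            "bbox_rmax": d.bbox[2],
            "bbox_cmax": d.bbox[3],
            "label": d.label,
            "score": d.score,
        }
        for d in detections
    ]
    return pd.DataFrame(
        rows,
        columns=["image_id", "bbox_rmin", "bbox_cmin", "bbox_rmax", "bbox_cmax",
                 "label", "score"],
    )
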