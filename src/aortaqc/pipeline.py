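"""End-to-end assessment: slice detection → ROI localization → classification.

``assess`` runs the full three-component pipeline on a canonical volume and
a template bank and returns a :class:`ContrastReport` that records every
intermediate decision: the per-SOI detection outcome (with similarity and
fallback status), every placed ROI with its mean HU and category, the rule
trace of the final class, and per-stage warnings. Failures degrade to
flagged partial reports — an ROI whose localization returned nothing is
omitted and the classifier runs on the remainder (two ROIs minimum); with
fewer than two measurable ROIs the study is marked for manual review.

The report is fully deterministic: assessing the same inputs twice yields
byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from . import aorta, femoral, matching
from .classify import ClassResult, RoiMeasurement, classify
from .config import RunConfig
from .templates import TemplateSet
from .volume_io import Volume

SCHEMA_VERSION = 1

STATUS_OK = "ok"
STATUS_MANUAL_REVIEW = "manual review required"


@dataclass
class ContrastReport:
    """Complete record of one automatic contrast-quality assessment."""

    source: str
    status: str
    sois: list[matching.SoiResult]
    rois: list[RoiMeasurement]
    classification: ClassResult | None
    warnings: list[str] = field(default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "source": self.source.replace("\\", "/"),
            "status": self.status,
            "sois": [s.to_dict() for s in self.sois],
            "rois": [r.to_dict() for r in self.rois],
            "classification": None
            if self.classification is None
            else {
                "class": self.classification.label,
                "matched_rule": self.classification.matched_rule,
                "n_rois_used": self.classification.n_rois_used,
            },
            "warnings": self.warnings,
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @property
    def klass(self) -> str | None:
        return None if self.classification is None else self.classification.label


def _split_bank(bank: Sequence[TemplateSet]) -> tuple[list[TemplateSet], list[TemplateSet]]:
    soi1_sets = [s for s in bank if s.soi_id == 1]
    soi3_sets = [s for s in bank if s.soi_id == 3]
    return soi1_sets, soi3_sets


def assess(
    volume: Volume,
    template_bank: Sequence[TemplateSet],
    config: RunConfig | None = None,
) -> ContrastReport:
    """Assess the contrast quality of one CTA volume."""
    cfg = config or RunConfig()
    warnings: list[str] = []
    soi1_sets, soi3_sets = _split_bank(template_bank)
    if not soi1_sets or not soi3_sets:
        raise ValueError("template bank must contain both SOI1 and SOI3 sets")
    n = volume.n_slices

    soi1 = matching.detect_soi(
        volume,
        soi1_sets,
        matching.upper_two_thirds(n, cfg.search_fraction),
        cfg.existence_threshold,
    )
    soi3 = matching.detect_soi(
        volume,
        soi3_sets,
        matching.lower_two_thirds(n, cfg.search_fraction),
        cfg.existence_threshold,
    )
    if soi1.status == matching.MISSING:
        warnings.append("SOI 1 declared non-existing (best similarity below threshold)")
    if soi3.status == matching.MISSING:
        warnings.append("SOI 3 declared non-existing (best similarity below threshold)")

    sois = [soi1]
    try:
        soi2 = matching.derive_soi2(
            soi1, soi3, cfg.offset_slices(volume.spacing[2]), n
        )
        if soi2.clamped:
            warnings.append("SOI 2 offset fell outside the volume and was clamped")
        sois.append(soi2)
    except ValueError:
        soi2 = None
        warnings.append("SOI 2 underivable: neither SOI 1 nor SOI 3 was found")
    sois.append(soi3)

    rois: list[RoiMeasurement] = []
    for roi_id, soi in ((1, soi1), (2, soi2)):
        if soi is None or soi.slice_index is None:
            continue
        if volume.n_slices - soi.slice_index < 3:
            warnings.append(f"ROI {roi_id}: too few slices below the SOI for a path")
            continue
        path = aorta.select_aorta(volume, soi.slice_index, cfg)
        if path is None:
            warnings.append(
                f"ROI {roi_id}: no circle scored below the selection threshold; "
                "aorta left to the reader"
            )
            continue
        if path.truncated:
            warnings.append(f"ROI {roi_id}: candidate path truncated at the volume boundary")
        rois.append(
            aorta.measure_aortic_roi(
                volume, path, roi_id, cfg.radius_reduction_px, cfg.category_boundaries
            )
        )

    if soi3.status == matching.FOUND:
        roi3 = femoral.locate_femoral_roi(
            volume, soi3.slice_index, soi3.template_hits, cfg
        )
        if roi3 is None:
            warnings.append("ROI 3: no vesselness region accepted")
        else:
            rois.append(roi3)

    if len(rois) >= 2:
        classification = classify(
            [r.category for r in sorted(rois, key=lambda r: r.roi_id)], cfg.total_coverage
        )
        status = STATUS_OK
    else:
        classification = None
        status = STATUS_MANUAL_REVIEW
        warnings.append(
            f"only {len(rois)} measurable ROI(s); at least 2 required for classification"
        )

    return ContrastReport(
        source=volume.source,
        status=status,
        sois=sois,
        rois=rois,
        classification=classification,
        warnings=warnings,
        config=cfg,
    )
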