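"""Template bank: 2D HU patches that anchor the slice-of-interest search.

A template is a patch cut around an anatomical landmark — the pulmonary
artery bifurcation for SOI 1, a femoral head for SOI 3 — together with the
in-plane spacing of the volume it came from, so it can be resampled to the
spacing of the volume under assessment before matching. Templates are
grouped into sets: an SOI-3 set contains at least a left and a right
femoral-head patch from the same reference volume, and its score on a slice
is the mean of the members' individual best matches.

On disk a bank is a directory of 2D NRRD patches plus a ``manifest.json``
listing, per patch, its file, SOI label, set id and source spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

SOI1 = "SOI1"
SOI3_LEFT = "SOI3_left"
SOI3_RIGHT = "SOI3_right"
_LABELS = {SOI1, SOI3_LEFT, SOI3_RIGHT}


@dataclass
class Template:
    """A 2D HU patch with its source in-plane spacing and SOI label."""

    patch: np.ndarray
    source_spacing: tuple[float, float]  # (x, y) mm
    soi_label: str

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 2:
            raise ValueError("a template patch must be 2D")
        if self.soi_label not in _LABELS:
            raise ValueError(f"unknown SOI label {self.soi_label!r}")
        if float(np.var(self.patch)) == 0.0:
            raise ValueError("template patch has zero intensity variance; NCC undefined")


@dataclass
class TemplateSet:
    """Templates scored together (mean of the members' best matches)."""

    members: list[Template]
    set_id: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a template set needs at least one member")
        labels = {m.soi_label for m in self.members}
        if SOI1 in labels and len(labels) > 1:
            raise ValueError("SOI1 templates cannot be mixed with SOI3 templates")
        if labels != {SOI1} and not {SOI3_LEFT, SOI3_RIGHT} <= labels:
            raise ValueError(
                "an SOI3 set must contain at least a left and a right femoral-head template"
            )

    @property
    def soi_id(self) -> int:
        return 1 if self.members[0].soi_label == SOI1 else 3

    @property
    def t(self) -> int:
        return len(self.members)


def _write_entries(entries: list[tuple[str, Template]], directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (set_id, tpl) in enumerate(entries):
        fname = f"{i:03d}_{set_id}_{tpl.soi_label}.nrrd"
        img = sitk.GetImageFromArray(tpl.patch)
        img.SetSpacing(tpl.source_spacing)
        sitk.WriteImage(img, str(directory / fname))
        manifest.append(
            {
                "file": fname,
                "soi_label": tpl.soi_label,
                "set_id": set_id,
                "spacing": list(tpl.source_spacing),
            }
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def save_bank(sets: list[TemplateSet], directory: str | Path) -> Path:
    directory = Path(directory)
    entries = [(tset.set_id, tpl) for tset in sets for tpl in tset.members]
    _write_entries(entries, directory)
    return directory


def _read_entries(directory: Path) -> list[tuple[str, Template]]:
    manifest_path = directory / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no template-bank manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = []
    for entry in manifest:
        img = sitk.ReadImage(str(directory / entry["file"]))
        patch = sitk.GetArrayFromImage(img).astype(np.float64)
        entries.append(
            (entry["set_id"], Template(patch, tuple(entry["spacing"]), entry["soi_label"]))
        )
    return entries


def append_template(directory: str | Path, set_id: str, template: Template) -> Path:
    """Add one template to a bank on disk, creating the bank if needed.

    Unlike :func:`load_bank` this does not require every set to be complete
    yet (an SOI-3 set is only valid once both femoral-head sides are
    present), so templates can be collected incrementally.
    """
    directory = Path(directory)
    entries = _read_entries(directory) if (directory / "manifest.json").is_file() else []
    entries.append((set_id, template))
    _write_entries(entries, directory)
    return directory


def load_bank(directory: str | Path) -> list[TemplateSet]:
    by_set: dict[str, list[Template]] = {}
    for set_id, tpl in _read_entries(Path(directory)):
        by_set.setdefault(set_id, []).append(tpl)
    return [TemplateSet(members, set_id) for set_id, members in sorted(by_set.items())]
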