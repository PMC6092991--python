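"""Sensorimotor regions of interest over the source space.

An ROI is a named set of dipole (vertex) indices.  The default catalogue
covers 12 sensorimotor areas per hemisphere (24 total): pre-supplementary
motor area (pSMA), supplementary motor area (SMA), cingulate motor area
(CMA), dorsal/ventral premotor cortex (PMd/PMv), primary motor foot /
hand / lip areas (M1F/M1H/M1L), primary somatosensory foot / hand areas
(S1F/S1H), secondary somatosensory area (S2) and the somatosensory
association cortex (SAC).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import SourceEpochs

__all__ = ["ROI", "ROICatalog", "load_roi_catalog", "save_roi_catalog",
           "extract_roi_timeseries", "AREA_NAMES"]

logger = logging.getLogger(__name__)

AREA_NAMES = ["pSMA", "SMA", "CMA", "PMd", "PMv", "M1F",
              "M1H", "M1L", "S1F", "S1H", "S2", "SAC"]


@dataclass
class ROI:
    """A named cortical region: hemisphere plus 0-based vertex indices."""

    name: str
    hemisphere: str
    vertices: np.ndarray

    def __post_init__(self):
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        v = np.unique(np.asarray(self.vertices, dtype=int))
        if v.size == 0:
            raise ValueError(f"ROI {self.name}: empty vertex set")
        if v.min() < 0:
            raise ValueError(f"ROI {self.name}: negative vertex index")
        self.vertices = v

    @property
    def size(self) -> int:
        return int(self.vertices.size)


@dataclass
class ROICatalog:
    """Ordered ROI collection; file order defines deterministic tie-breaks."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ROI names: {dupes}")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r}")

    def order_index(self, name: str) -> int:
        return self.names.index(name)

    def validate_against(self, n_dipoles: int) -> None:
        for r in self.rois:
            if r.vertices.max() >= n_dipoles:
                raise ValueError(
                    f"ROI {r.name}: vertex {int(r.vertices.max())} out of "
                    f"range for {n_dipoles} dipoles")
        cover = np.concatenate([r.vertices for r in self.rois])
        if np.unique(cover).size < cover.size:
            logger.info("ROI catalogue has overlapping vertex sets "
                        "(anatomical areas may abut); accepted")


def load_roi_catalog(path) -> ROICatalog:
    """Load a JSON catalogue: list of {name, hemisphere, vertices}."""
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict):
        doc = doc["rois"]
    rois = [ROI(name=e["name"], hemisphere=e["hemisphere"],
                vertices=np.asarray(e["vertices"], dtype=int)) for e in doc]
    return ROICatalog(rois=rois)


def save_roi_catalog(catalog: ROICatalog, path) -> None:
    doc = [{"name": r.name, "hemisphere": r.hemisphere,
            "vertices": r.vertices.tolist()} for r in catalog]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def extract_roi_timeseries(src: SourceEpochs, roi: ROI) -> SourceEpochs:
    """Restrict source epochs to an ROI's vertices (catalogue order)."""
    if roi.vertices.max() >= src.n_dipoles:
        raise ValueError(
            f"ROI {roi.name}: vertex {int(roi.vertices.max())} out of range "
            f"for {src.n_dipoles} dipoles")
    return src.copy_with(data=src.data[:, roi.vertices, :])
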