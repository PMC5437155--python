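"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SimConfig:
    """Parameters of one multi-subject simulation.

    Attributes
    ----------
    n_subjects : int
        Number of subjects M (>= 2 for group analyses).
    n_sources : int | Sequence[int]
        Number of sources C per subject; a sequence gives a per-subject
        count (subjects may differ).
    grid : tuple[int, int]
        Source-image dimensions in pixels; the standard presets use
        (148, 148).
    n_timepoints : int
        Length T of each subject's time courses.
    tr : float
        Repetition time in seconds (sampling interval of the TCs).
    cnr : float
        Contrast-to-noise ratio: in-source temporal signal SD divided
        by the Gaussian noise SD underlying the Rician corruption.
    translation_sd : float
        Per-axis SD (pixels) of the random per-subject source translation.
    rotation_sd : float
        SD (degrees) of the random per-subject source rotation.
    spread_mean, spread_sd : float
        Mean and SD of the per-subject magnification applied to each
        source about its centroid.
    unique_source_flags : Sequence[bool] | None
        Per-subject flag: does this subject carry one subject-unique
        source in addition to the common ones?
    baseline : float
        Positive offset added before Rician corruption so the magnitude
        operation never rectifies signal.
    seed : int
        Root seed; all randomness derives from it.
    """

    n_subjects: int = 10
    n_sources: int | Sequence[int] = 8
    grid: tuple[int, int] = (148, 148)
    n_timepoints: int = 150
    tr: float = 2.0
    cnr: float = 2.0
    translation_sd: float = 5.0
    rotation_sd: float = 3.0
    spread_mean: float = 3.0
    spread_sd: float = 0.03
    unique_source_flags: Sequence[bool] | None = None
    baseline: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        counts = self.source_counts
        if min(counts) < 2:
            raise ValueError("each subject needs at least 2 sources")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not self.cnr > 0:
            raise ValueError("cnr must be positive")
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        if self.unique_source_flags is not None and len(
            self.unique_source_flags
        ) != self.n_subjects:
            raise ValueError("unique_source_flags must have one entry per subject")

    @property
    def source_counts(self) -> list[int]:
        """Per-subject source count as a list of length n_subjects."""
        if np.isscalar(self.n_sources):
            return [int(self.n_sources)] * self.n_subjects
        return [int(c) for c in self.n_sources]

    @property
    def n_voxels(self) -> int:
        return int(self.grid[0] * self.grid[1])

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "n_sources": self.source_counts,
            "grid": list(self.grid),
            "n_timepoints": self.n_timepoints,
            "tr": self.tr,
            "cnr": self.cnr,
            "translation_sd": self.translation_sd,
            "rotation_sd": self.rotation_sd,
            "spread_mean": self.spread_mean,
            "spread_sd": self.spread_sd,
            "unique_source_flags": (
                None
                if self.unique_source_flags is None
                else [bool(f) for f in self.unique_source_flags]
            ),
            "baseline": self.baseline,
            "seed": self.seed,
        }
        return d


@dataclass
class GroundTruth:
    """True sources of one subject.

    ``maps`` holds one spatial map per row (C x V, row-major flattening
    of the grid); ``tcs`` the associated time courses (T x C).
    ``labels`` tags each source ``"common"`` or ``"unique"``, and
    ``source_ids`` gives the template index of each common source
    (-1 for subject-unique sources), so that sources can be aligned
    across subjects with differing source counts.
    """

    maps: np.ndarray
    tcs: np.ndarray
    labels: list[str]
    source_ids: list[int]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.tcs = np.asarray(self.tcs, dtype=float)
        if self.maps.shape[0] != self.tcs.shape[1]:
            raise ValueError("maps and tcs disagree on the number of sources")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per source required")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("ground-truth maps must be finite")

    @property
    def n_sources(self) -> int:
        return self.maps.shape[0]


@dataclass
class SubjectDataset:
    """One subject's observed data matrix (time x voxel) plus metadata."""

    data: np.ndarray
    mask: np.ndarray
    config: SimConfig | None = None
    subject: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be a (time x voxel) matrix")
        if self.mask.shape != (self.data.shape[1],):
            raise ValueError("mask length must equal the number of voxels")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class DecompositionResults:
    """Per-subject decomposition output of either method.

    ``subject_maps[m]`` is the (C x V) z-scored component map matrix of
    subject m, ``subject_tcs[m]`` the (T x C) time courses; component
    index is aligned across subjects by construction for both methods.
    ``group_maps`` holds the group-level maps used for matching:
    GIG-ICA's group ICs, or the voxel-wise mean of subjects' z-scored
    maps for IVA-GL.
    """

    method: str
    n_components: int
    subject_maps: list[np.ndarray]
    subject_tcs: list[np.ndarray]
    group_maps: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_maps)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            f"{self.method} decomposition",
            f"  subjects:       {self.n_subjects}",
            f"  components:     {self.n_components}",
            f"  map size:       {self.group_maps.shape[1]} voxels",
        ]
        for key in ("converged", "n_iterations", "final_cost"):
            if key in self.diagnostics:
                lines.append(f"  {key + ':':<15} {self.diagnostics[key]}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of per-subject component map statistics."""
        rows = []
        for m, maps in enumerate(self.subject_maps):
            for c in range(maps.shape[0]):
                rows.append(
                    {
                        "method": self.method,
                        "subject": m,
                        "component": c,
                        "map_skewness": _skewness(maps[c]),
                    }
                )
        return pd.DataFrame(rows)


def _skewness(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return 0.0
    return float(np.mean(((x - mu) / sd) ** 3))
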