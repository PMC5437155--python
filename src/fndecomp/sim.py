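"""Multi-subject fMRI-like simulator.

Generates per-subject spatial sources as 2-D Gaussian blobs derived
from common templates by random translation / rotation / magnification,
smoothed random time courses, linear mixing, and Rician noise at a
specified contrast-to-noise ratio (CNR).  Named presets reproduce the
standard experimental designs used throughout the package:

``exp1_quality``
    10 subjects, 8 common sources, 150 time points, CNR swept.
``exp1_quantity``
    As above at CNR = 2 with the number of time points swept.
``exp2_varied_sources``
    Subjects 1-5 carry 8 sources, subjects 6-10 carry 7 (the 8th
    template is absent), CNR = 2.
``exp2_model_order``
    The 8-source CNR = 2 data used for model-order robustness studies
    (identical generative design to ``exp1_quality`` at CNR = 2).
``exp3_unique``
    7 common sources plus one subject-unique source per subject, with
    the unique source placed independently per subject so that its
    cross-subject spatial similarity is low.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from fndecomp.datatypes import GroundTruth, SimConfig, SubjectDataset

__all__ = [
    "make_base_maps",
    "perturb_map",
    "make_tcs",
    "hrf_kernel",
    "add_rician_noise",
    "simulate_subjects",
    "generate_experiment",
    "save_experiment",
    "load_experiment",
    "PRESETS",
]

#: Default full width at half maximum (pixels) of the template blobs.
#: The per-subject magnification (mean 3) scales these up to the size
#: actually present in the data.
DEFAULT_FWHM = 9.0

#: Maximum allowed absolute pairwise spatial correlation between
#: template blobs.
DEFAULT_OVERLAP_CAP = 0.3

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gaussian_blob(grid: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    h, w = grid
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    blob = np.exp(-d2 / (2.0 * sigma**2))
    peak = blob.max()
    if peak > 0:
        blob /= peak
    return blob


def make_base_maps(
    C: int,
    grid: tuple[int, int] = (148, 148),
    seed: int = 0,
    *,
    fwhm: float = DEFAULT_FWHM,
    overlap_cap: float = DEFAULT_OVERLAP_CAP,
) -> np.ndarray:
    """Generate ``C`` compact, largely non-overlapping blob templates.

    Centers are sampled without replacement from a jittered lattice
    over the grid interior; each map is an isotropic 2-D Gaussian with
    the given FWHM, normalized to peak value 1 on a background of 0.

    Returns a (C x V) matrix, V = height * width, row-major flattening.

    Raises
    ------
    ValueError
        If ``C`` blobs cannot be placed without some pair exceeding the
        configured pairwise-overlap cap.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = grid
    side = int(np.ceil(np.sqrt(C)))
    # Keep lattice cells away from the border so that downstream
    # magnification and translation rarely clip source mass.
    margin_r, margin_c = h / 6.0, w / 6.0
    rows = np.linspace(margin_r, h - margin_r, side)
    cols = np.linspace(margin_c, w - margin_c, side)
    cells = [(r, c) for r in rows for c in cols]
    order = rng.permutation(len(cells))[:C]
    spacing_r = rows[1] - rows[0] if side > 1 else h / 2.0
    spacing_c = cols[1] - cols[0] if side > 1 else w / 2.0
    sigma = fwhm * _FWHM_TO_SIGMA
    maps = np.empty((C, h * w))
    for i, cell in enumerate(order):
        r0, c0 = cells[cell]
        jr = rng.uniform(-0.15, 0.15) * spacing_r
        jc = rng.uniform(-0.15, 0.15) * spacing_c
        maps[i] = _gaussian_blob(grid, (r0 + jr, c0 + jc), sigma).ravel()
    if C > 1:
        corr = np.corrcoef(maps)
        off = np.abs(corr[np.triu_indices(C, k=1)])
        if off.max() > overlap_cap:
            raise ValueError(
                f"cannot place {C} sources on a {h}x{w} grid without exceeding "
                f"the pairwise-overlap cap {overlap_cap} "
                f"(worst pairwise correlation {off.max():.3f})"
            )
    return maps


def perturb_map(
    base_map: np.ndarray,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation: float = 0.0,
    spread: float = 1.0,
    grid: tuple[int, int] | None = None,
) -> np.ndarray:
    """Translate, rotate (about the blob centroid) and magnify a map.

    ``translation = (dx, dy)`` moves the map ``dx`` pixels along x
    (columns) and ``dy`` along y (rows).  ``rotation`` is in degrees,
    ``spread`` is a relative magnification about the centroid.
    Bilinear interpolation; content leaving the grid is clipped.
    Accepts either a flattened map plus ``grid`` or a 2-D map, and
    returns a matching shape.
    """
    arr = np.asarray(base_map, dtype=float)
    flat = arr.ndim == 1
    if flat:
        if grid is None:
            raise ValueError("grid is required for a flattened input map")
        arr = arr.reshape(grid)
    total = arr.sum()
    if total > 0:
        rr, cc = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]]
        centroid = np.array([(rr * arr).sum() / total, (cc * arr).sum() / total])
    else:
        centroid = (np.array(arr.shape) - 1) / 2.0
    theta = np.deg2rad(rotation)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    # Output pixel -> input pixel: undo translation, rotation, spread.
    A = rot.T / spread
    dx, dy = translation
    c_out = centroid + np.array([dy, dx])
    offset = centroid - A @ c_out
    out = ndimage.affine_transform(
        arr, A, offset=offset, order=1, mode="constant", cval=0.0
    )
    return out.ravel() if flat else out


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``tr``.

    Peak at ~6 s, undershoot at ~16 s with 1/6 relative amplitude;
    normalized to unit sum.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration + tr / 2.0, tr)
    peak = gamma_dist.pdf(t, 6.0)
    under = gamma_dist.pdf(t, 16.0)
    h = peak - under / 6.0
    return h / h.sum()


def make_tcs(C: int, T: int, seed: int = 0, *, tr: float = 2.0) -> np.ndarray:
    """Simulate ``C`` independent smoothed time courses of length ``T``.

    Each column is white Gaussian noise convolved with a canonical
    HRF-shaped kernel at the configured TR, then standardized to zero
    mean and unit variance.  Smoothing yields positive lag-1
    autocorrelation; independent draws keep columns uncorrelated in
    expectation.
    """
    if T < 8:
        raise ValueError("T must be >= 8")
    rng = np.random.default_rng(seed)
    kernel = hrf_kernel(tr)
    pad = len(kernel)
    noise = rng.standard_normal((T + pad, C))
    smooth = signal.fftconvolve(noise, kernel[:, None], mode="full", axes=0)
    tcs = smooth[pad : pad + T]
    tcs = tcs - tcs.mean(axis=0)
    tcs = tcs / tcs.std(axis=0)
    return tcs


def add_rician_noise(
    clean: np.ndarray,
    cnr: float,
    baseline: float,
    seed: int = 0,
    *,
    source_sd_frac: float = 0.5,
) -> np.ndarray:
    """Apply Rician corruption at a target contrast-to-noise ratio.

    ``output = sqrt((clean + baseline + n1)^2 + n2^2)`` with n1, n2
    independent zero-mean Gaussians of SD sigma.  sigma is set so that
    the temporal SD of the noise-free signal, averaged over in-source
    voxels, divided by sigma equals ``cnr``.  In-source voxels are
    those within the half-maximum footprint of the sources (temporal
    SD above ``source_sd_frac`` of the maximum; for unit-variance time
    courses the SD profile follows the spatial map, so the default 0.5
    matches the half-maximum contour that conventionally delimits a
    source's extent).  ``cnr = inf`` returns the noiseless
    ``clean + baseline``.
    """
    if not cnr > 0:
        raise ValueError("cnr must be positive")
    clean = np.asarray(clean, dtype=float)
    sd = clean.std(axis=0)
    in_source = sd > source_sd_frac * sd.max()
    signal_sd = sd[in_source].mean()
    sigma = 0.0 if np.isinf(cnr) else signal_sd / cnr
    shifted = clean + baseline
    if sigma == 0.0:
        return np.abs(shifted)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt((shifted + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# Whole-experiment generation


def _subject_truth(
    config: SimConfig,
    subject: int,
    base_maps: np.ndarray,
    n_common: int,
    has_unique: bool,
    rng: np.random.Generator,
    *,
    fwhm: float = DEFAULT_FWHM,
) -> GroundTruth:
    grid = config.grid
    maps = []
    labels = []
    ids = []
    for t in range(n_common):
        translation = rng.normal(0.0, config.translation_sd, size=2)
        rotation = rng.normal(0.0, config.rotation_sd)
        spread = rng.normal(config.spread_mean, config.spread_sd)
        maps.append(
            perturb_map(
                base_maps[t],
                translation=(translation[0], translation[1]),
                rotation=rotation,
                spread=spread,
                grid=grid,
            )
        )
        labels.append("common")
        ids.append(t)
    if has_unique:
        # Subject-unique source: its own blob location per subject, drawn
        # uniformly over the grid interior, at the same effective size as
        # the magnified common sources.
        h, w = grid
        spread = rng.normal(config.spread_mean, config.spread_sd)
        center = (
            rng.uniform(h / 6.0, h - h / 6.0),
            rng.uniform(w / 6.0, w - w / 6.0),
        )
        sigma = fwhm * _FWHM_TO_SIGMA * spread
        maps.append(_gaussian_blob(grid, center, sigma).ravel())
        labels.append("unique")
        ids.append(-1)
    n_src = len(maps)
    tc_seed = int(rng.integers(0, 2**31 - 1))
    tcs = make_tcs(n_src, config.n_timepoints, seed=tc_seed, tr=config.tr)
    return GroundTruth(
        maps=np.asarray(maps), tcs=tcs, labels=labels, source_ids=ids
    )


def simulate_subjects(
    config: SimConfig, *, fwhm: float = DEFAULT_FWHM
) -> tuple[list[SubjectDataset], list[GroundTruth]]:
    """Generate all subjects of one simulation from its configuration.

    Before noise each subject's data is exactly ``tcs @ maps`` (linear
    mixture); Rician noise at the configured CNR is then applied on top
    of the baseline offset.
    """
    ss = np.random.SeedSequence(config.seed)
    base_seed, *subj_seeds = ss.spawn(1 + config.n_subjects)
    counts = config.source_counts
    uniques = config.unique_source_flags or [False] * config.n_subjects
    n_templates = max(
        c - int(u) for c, u in zip(counts, uniques)
    )
    base_maps = make_base_maps(
        n_templates,
        config.grid,
        seed=int(base_seed.generate_state(1)[0] % (2**31)),
        fwhm=fwhm,
    )
    datasets: list[SubjectDataset] = []
    truths: list[GroundTruth] = []
    mask = np.ones(config.n_voxels, dtype=bool)
    for m in range(config.n_subjects):
        rng = np.random.default_rng(subj_seeds[m])
        n_common = counts[m] - int(uniques[m])
        truth = _subject_truth(
            config, m, base_maps, n_common, bool(uniques[m]), rng, fwhm=fwhm
        )
        clean = truth.tcs @ truth.maps
        noise_seed = int(rng.integers(0, 2**31 - 1))
        data = add_rician_noise(
            clean, config.cnr, config.baseline, seed=noise_seed
        )
        datasets.append(
            SubjectDataset(data=data, mask=mask.copy(), config=config, subject=m)
        )
        truths.append(truth)
    return datasets, truths


def _preset_exp1_quality(seed: int, cnr: float = 2.0, **kw) -> SimConfig:
    return SimConfig(cnr=cnr, seed=seed, **kw)


def _preset_exp1_quantity(seed: int, n_timepoints: int = 150, **kw) -> SimConfig:
    return SimConfig(cnr=2.0, n_timepoints=n_timepoints, seed=seed, **kw)


def _preset_exp2_varied(seed: int, **kw) -> SimConfig:
    return SimConfig(
        n_sources=[8, 8, 8, 8, 8, 7, 7, 7, 7, 7], cnr=2.0, seed=seed, **kw
    )


def _preset_exp3_unique(seed: int, **kw) -> SimConfig:
    return SimConfig(
        n_sources=8,
        cnr=2.0,
        unique_source_flags=[True] * 10,
        seed=seed,
        **kw,
    )


PRESETS = {
    "exp1_quality": _preset_exp1_quality,
    "exp1_quantity": _preset_exp1_quantity,
    "exp2_varied_sources": _preset_exp2_varied,
    "exp2_model_order": _preset_exp1_quality,
    "exp3_unique": _preset_exp3_unique,
}


def generate_experiment(
    preset: str, seed: int = 0, *, fwhm: float = DEFAULT_FWHM, **params
) -> tuple[list[SubjectDataset], list[GroundTruth]]:
    """Generate a named experimental dataset.

    ``params`` forwards preset-specific knobs (``cnr`` for
    ``exp1_quality``, ``n_timepoints`` for ``exp1_quantity``) and any
    :class:`SimConfig` field override (e.g. a smaller ``grid``).
    Generation is fully deterministic under ``(preset, seed, params)``.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = PRESETS[preset](seed, **params)
    return simulate_subjects(config, fwhm=fwhm)


def save_experiment(
    path: str | Path,
    datasets: list[SubjectDataset],
    truths: list[GroundTruth],
) -> None:
    """Write datasets + ground truth to an ``.npz`` container with a
    JSON sidecar of the simulation configuration."""
    path = Path(path)
    arrays = {}
    for m, (ds, gt) in enumerate(zip(datasets, truths)):
        arrays[f"data_{m}"] = ds.data
        arrays[f"mask_{m}"] = ds.mask
        arrays[f"maps_{m}"] = gt.maps
        arrays[f"tcs_{m}"] = gt.tcs
    np.savez_compressed(path, **arrays)
    config = datasets[0].config
    sidecar = {
        "n_subjects": len(datasets),
        "config": None if config is None else config.to_dict(),
        "labels": [gt.labels for gt in truths],
        "source_ids": [gt.source_ids for gt in truths],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_experiment(
    path: str | Path,
) -> tuple[list[SubjectDataset], list[GroundTruth]]:
    """Inverse of :func:`save_experiment`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = (
        SimConfig(**sidecar["config"]) if sidecar["config"] is not None else None
    )
    with np.load(path.with_suffix(".npz")) as npz:
        datasets, truths = [], []
        for m in range(sidecar["n_subjects"]):
            datasets.append(
                SubjectDataset(
                    data=npz[f"data_{m}"],
                    mask=npz[f"mask_{m}"],
                    config=config,
                    subject=m,
                )
            )
            truths.append(
                GroundTruth(
                    maps=npz[f"maps_{m}"],
                    tcs=npz[f"tcs_{m}"],
                    labels=sidecar["labels"][m],
                    source_ids=sidecar["source_ids"][m],
                )
            )
    return datasets, truths
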