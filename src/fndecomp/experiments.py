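"""Experiment runners assembling the modules into full studies.

``run_simulation_experiment`` drives the named simulation presets:
generate multi-subject data, run both decomposition methods with an
identical component number, score them against ground truth, and emit
per-setting accuracy and paired-t-test tables (Bonferroni-corrected
across the settings of the experiment).

``run_realdata_study`` is the optional test-retest pipeline for
preprocessed 4D NIfTI data: both methods per model order, cross-method
component matching, user-supplied keep-list of meaningful networks,
then network reliability (ICC), FNC, signed modularity with AMI-based
modularity reliability, connectivity ICC and weighted graph metrics at
sparsity 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fndecomp import evaluate, netgraph, reliability, sim
from fndecomp.datatypes import DecompositionResults
from fndecomp.evaluate import MatchTable, greedy_match
from fndecomp.gigica import GIGICA
from fndecomp.iva import IVAGL

__all__ = [
    "RunConfig",
    "run_methods",
    "run_simulation_experiment",
    "cross_method_match",
    "run_realdata_study",
    "load_nifti_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_CNR_VALUES = [round(v, 1) for v in np.arange(0.5, 2.01, 0.1)]
DEFAULT_TIMEPOINT_VALUES = [40, 60, 80, 100, 120]
SIM_MODEL_ORDERS = {"exp2_varied_sources": [7, 8], "exp2_model_order": [6, 8, 10]}
REAL_MODEL_ORDERS = [20, 25, 30, 75, 100]


@dataclass
class RunConfig:
    """Configuration of one experiment run (simulation or real data)."""

    preset: str = "exp1_quality"
    cnr_values: list = None
    timepoint_values: list = None
    model_orders: list = None
    methods: tuple = ("iva_gl", "gigica")
    seed: int = 0
    outdir: str | None = None
    alpha: float = 0.05
    # real-data mode
    datasets: list = None  # entries: {"path": ..., "subject": ..., "scan": 1|2|3}
    match_threshold: float = 0.5
    sparsity: float = 0.5
    fdr_q: float = 0.01
    ami_pairing: str = "all"  # or "subject"
    # Simulation-scale overrides (grid, n_timepoints, fwhm, ...): the
    # presets' full-size defaults are the study conditions; overrides
    # exist for quick pipeline checks at reduced scale.
    sim_overrides: dict = None

    def __post_init__(self) -> None:
        if self.model_orders is not None and min(self.model_orders) < 2:
            raise ValueError("model orders must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_methods(
    datasets, n_components: int, seed: int = 0, methods=("iva_gl", "gigica")
) -> dict[str, DecompositionResults]:
    """Run the requested methods with an identical component number."""
    out = {}
    for name in methods:
        if name == "gigica":
            out[name] = GIGICA(datasets, n_components).fit(seed=seed)
        elif name == "iva_gl":
            out[name] = IVAGL(datasets, n_components).fit(seed=seed)
        else:
            raise ValueError(f"unknown method {name!r}")
        logger.info("ran %s at order %d (seed %d)", name, n_components, seed)
    return out


def _settings(config: RunConfig):
    """Yield (setting label, generator kwargs, model order, score mode)."""
    preset = config.preset
    if preset == "exp1_quality":
        for v in config.cnr_values or DEFAULT_CNR_VALUES:
            yield f"cnr={v:g}", {"cnr": float(v)}, 8, "per_subject"
    elif preset == "exp1_quantity":
        for v in config.timepoint_values or DEFAULT_TIMEPOINT_VALUES:
            yield f"T={v}", {"n_timepoints": int(v)}, 8, "per_subject"
    elif preset in SIM_MODEL_ORDERS:
        for order in config.model_orders or SIM_MODEL_ORDERS[preset]:
            yield f"order={order}", {}, int(order), "per_subject"
    elif preset == "exp3_unique":
        yield "exp3", {}, 8, "per_component"
    else:
        raise ValueError(f"unknown preset {preset!r}")


def run_simulation_experiment(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run one simulation experiment end to end.

    Returns ``{"accuracy": ..., "ttests": ...}`` DataFrames.  The
    accuracy table is long-format (setting, method, subject, source,
    spatial, temporal); the t-test table has one row per setting and
    domain with Bonferroni flags computed across all rows.  When
    ``config.outdir`` is set, both tables plus a JSON manifest of the
    configuration and seeds are written there; reruns with the same
    config produce byte-identical files.
    """
    acc_rows = []
    test_rows = []
    for label, kwargs, order, mode in _settings(config):
        datasets, truths = sim.generate_experiment(
            config.preset,
            seed=config.seed,
            **{**kwargs, **(config.sim_overrides or {})},
        )
        results = run_methods(
            datasets, order, seed=config.seed, methods=config.methods
        )
        score = evaluate.score_experiment(results, truths, mode=mode)
        for method, table in score.tables.items():
            for m in table.spatial.index:
                for col in table.spatial.columns:
                    acc_rows.append(
                        {
                            "setting": label,
                            "method": method,
                            "subject": int(m),
                            "component": col,
                            "spatial": table.spatial.loc[m, col],
                            "temporal": table.temporal.loc[m, col],
                        }
                    )
        for _, row in score.ttests.iterrows():
            test_rows.append({"setting": label, **row.to_dict()})
    accuracy = pd.DataFrame(acc_rows)
    ttests = pd.DataFrame(test_rows)
    flags = evaluate.bonferroni(ttests["p"].fillna(1.0), alpha=config.alpha)
    ttests["bonferroni_significant"] = flags
    tables = {"accuracy": accuracy, "ttests": ttests}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        accuracy.to_csv(outdir / "accuracy.csv", index=False)
        ttests.to_csv(outdir / "ttests.csv", index=False)
        manifest = {
            "preset": config.preset,
            "seed": config.seed,
            "methods": list(config.methods),
            "settings": [s[0] for s in _settings(config)],
            "alpha": config.alpha,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables


def cross_method_match(
    res_a: DecompositionResults,
    res_b: DecompositionResults,
    threshold: float = 0.5,
) -> MatchTable:
    """Greedy match of two methods' group-level maps; pairs whose
    similarity falls below ``threshold`` are discarded."""
    if res_a.n_components != res_b.n_components:
        raise ValueError("methods must use an equal model order")
    S = evaluate._abs_corr_matrix(res_a.group_maps, res_b.group_maps)
    table = greedy_match(S)
    kept = [p for p in table.pairs if p[2] >= threshold]
    dropped = [p for p in table.pairs if p[2] < threshold]
    return MatchTable(
        pairs=kept,
        unmatched_estimates=sorted(
            table.unmatched_estimates + [e for e, _, _ in dropped]
        ),
        unmatched_templates=sorted(
            table.unmatched_templates + [t for _, t, _ in dropped]
        ),
    )


# ---------------------------------------------------------------------------
# Real-data (test-retest) study


def load_nifti_dataset(
    path: str | Path, return_geometry: bool = False
) -> np.ndarray | tuple:
    """Load a preprocessed 4D NIfTI volume as a (T x V) matrix.

    With ``return_geometry=True`` also returns the spatial shape and
    affine, so masks can be written back as NIfTI volumes.
    """
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {vol.shape}")
    T = vol.shape[3]
    data = vol.reshape(-1, T).T
    if return_geometry:
        return data, vol.shape[:3], img.affine
    return data


def _write_mask_nifti(
    path: Path, flat_mask: np.ndarray, shape: tuple, affine: np.ndarray
) -> None:
    import nibabel as nib

    vol = np.asarray(flat_mask, dtype=np.uint8).reshape(shape)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def _mean_ami(parts_a: list[np.ndarray], parts_b: list[np.ndarray]) -> float:
    vals = [netgraph.ami(p, q) for p, q in product(parts_a, parts_b)]
    return float(np.mean(vals)) if vals else np.nan


def run_realdata_study(config: RunConfig, keep_list: list[int]) -> dict:
    """Test-retest reliability and FNC study on preprocessed data.

    ``config.datasets`` lists one entry per dataset with ``path``,
    ``subject`` and ``scan`` (1, 2 or 3; three scans per subject
    required).  ``keep_list`` selects, by index into the cross-method
    match table, the user-identified meaningful networks; selection is
    manual by design and never automated.  Returns per-model-order
    tables of network reliability, FNC/modularity summaries and graph
    metrics (also written as CSV when ``outdir`` is set).
    """
    if not config.datasets:
        raise ValueError("real-data mode requires config.datasets")
    entries = config.datasets
    for e in entries:
        if "scan" not in e or "subject" not in e:
            raise ValueError("each dataset entry needs 'subject' and 'scan' labels")
    first, geom_shape, geom_affine = load_nifti_dataset(
        entries[0]["path"], return_geometry=True
    )
    data = [first] + [load_nifti_dataset(e["path"]) for e in entries[1:]]
    # Brain mask: voxels with nonzero temporal variance in all datasets.
    mask = np.all([d.std(axis=0) > 0 for d in data], axis=0)
    data = [d[:, mask] for d in data]
    scans = np.array([int(e["scan"]) for e in entries])
    subjects = np.array([e["subject"] for e in entries])

    rel_rows, fnc_rows, graph_rows = [], [], []
    orders = config.model_orders or REAL_MODEL_ORDERS
    for order in orders:
        results = run_methods(data, order, seed=config.seed, methods=config.methods)
        name_a, name_b = config.methods
        match = cross_method_match(
            results[name_a], results[name_b], threshold=config.match_threshold
        )
        kept_pairs = [match.pairs[i] for i in keep_list]
        comp_of = {name_a: [p[0] for p in kept_pairs], name_b: [p[1] for p in kept_pairs]}

        # Joint FDR mask per network: intersection of both methods'
        # significant voxels from right-tailed one-sample t-tests.
        joint_masks = []
        for k in range(len(kept_pairs)):
            inter = None
            for name in config.methods:
                stack = np.array(
                    [res_maps[comp_of[name][k]] for res_maps in results[name].subject_maps]
                )
                _, fmask = reliability.one_sample_t_fdr(stack, q=config.fdr_q)
                inter = fmask if inter is None else (inter & fmask)
            joint_masks.append(inter)
        if config.outdir:
            mask_dir = Path(config.outdir) / "masks"
            mask_dir.mkdir(parents=True, exist_ok=True)
            for k, net_mask in enumerate(joint_masks):
                full = np.zeros(mask.size, dtype=bool)
                full[mask] = net_mask
                _write_mask_nifti(
                    mask_dir / f"order{order}_network{k}_mask.nii.gz",
                    full,
                    geom_shape,
                    geom_affine,
                )

        subj_order = sorted(set(subjects))
        for name in config.methods:
            res = results[name]
            for k in range(len(kept_pairs)):
                comp = comp_of[name][k]
                maps_by_scan = []
                for s in (1, 2, 3):
                    rows = []
                    for subj in subj_order:
                        idx = np.flatnonzero((subjects == subj) & (scans == s))
                        if idx.size != 1:
                            raise ValueError(
                                f"subject {subj} needs exactly one scan {s}"
                            )
                        rows.append(res.subject_maps[idx[0]][comp])
                    maps_by_scan.append(np.array(rows))
                net_mask = joint_masks[k]
                if not net_mask.any():
                    short = long = np.nan
                else:
                    short = reliability.network_reliability(
                        maps_by_scan, net_mask, mode="short"
                    )
                    long = reliability.network_reliability(
                        maps_by_scan, net_mask, mode="long"
                    )
                rel_rows.append(
                    {
                        "order": order,
                        "method": name,
                        "network": k,
                        "similarity": kept_pairs[k][2],
                        "short_icc": short,
                        "long_icc": long,
                    }
                )

            # FNC, modularity, AMI and graph metrics.
            comps = comp_of[name]
            fncs = [netgraph.fnc(res.subject_tcs[d][:, comps]) for d in range(len(data))]
            mean_fnc = np.mean(fncs, axis=0)
            mean_part, q_mean = netgraph.modularity_partition(mean_fnc)
            if config.outdir:
                outdir = Path(config.outdir)
                outdir.mkdir(parents=True, exist_ok=True)
                netgraph.export_fnc_csv(
                    mean_fnc, outdir / f"{name}_order{order}_mean_fnc.csv"
                )
                netgraph.export_partition(
                    mean_part, outdir / f"{name}_order{order}_partition.txt"
                )
            parts, qs = [], []
            for F in fncs:
                part, q = netgraph.modularity_partition(F)
                parts.append(part)
                qs.append(q)
            if config.ami_pairing == "subject":
                pairs23 = [
                    (parts[i], parts[j])
                    for subj in subj_order
                    for i in np.flatnonzero((subjects == subj) & (scans == 2))
                    for j in np.flatnonzero((subjects == subj) & (scans == 3))
                ]
                ami_short = float(
                    np.mean([netgraph.ami(p, q) for p, q in pairs23])
                )
                pairs1x = [
                    (parts[i], parts[j])
                    for subj in subj_order
                    for i in np.flatnonzero((subjects == subj) & (scans == 1))
                    for j in np.flatnonzero((subjects == subj) & (scans > 1))
                ]
                ami_long = float(np.mean([netgraph.ami(p, q) for p, q in pairs1x]))
            else:
                ami_short = _mean_ami(
                    [parts[i] for i in np.flatnonzero(scans == 2)],
                    [parts[i] for i in np.flatnonzero(scans == 3)],
                )
                ami_long = _mean_ami(
                    [parts[i] for i in np.flatnonzero(scans == 1)],
                    [parts[i] for i in np.flatnonzero(scans > 1)],
                )
            iu = np.triu_indices(len(comps), k=1)
            fnc_by_scan = []
            for s in (1, 2, 3):
                rows = []
                for subj in subj_order:
                    idx = np.flatnonzero((subjects == subj) & (scans == s))
                    rows.append(fncs[idx[0]][iu])
                fnc_by_scan.append(np.array(rows))
            icc_short = reliability.connectivity_icc(fnc_by_scan, mode="short")
            icc_long = reliability.connectivity_icc(fnc_by_scan, mode="long")
            fnc_rows.append(
                {
                    "order": order,
                    "method": name,
                    "q_mean_fnc": q_mean,
                    "q_individual_mean": float(np.mean(qs)),
                    "ami_short": ami_short,
                    "ami_long": ami_long,
                    "conn_icc_short_mean": float(icc_short.mean()),
                    "conn_icc_long_mean": float(icc_long.mean()),
                }
            )
            for d, F in enumerate(fncs):
                metrics = netgraph.graph_metrics(
                    netgraph.threshold_sparsity(F, config.sparsity)
                )
                graph_rows.append(
                    {"order": order, "method": name, "dataset": d, **metrics}
                )

    tables = {
        "network_reliability": pd.DataFrame(rel_rows),
        "fnc_summary": pd.DataFrame(fnc_rows),
        "graph_metrics": pd.DataFrame(graph_rows),
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "model_orders": list(orders),
            "seed": config.seed,
            "keep_list": list(keep_list),
            "match_threshold": config.match_threshold,
            "n_datasets": len(entries),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
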