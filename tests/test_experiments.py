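"""Experiment runners: simulation sweeps, cross-method matching, and
the real-data (NIfTI) reliability pipeline on a synthetic fixture."""

import numpy as np
import pandas as pd
import pytest

from fndecomp import experiments, sim
from fndecomp.datatypes import SimConfig
from fndecomp.experiments import RunConfig, cross_method_match, run_methods

SMALL = {"grid": (48, 48), "fwhm": 2.5, "n_timepoints": 60}


def test_settings_enumeration():
    labels = [s[0] for s in experiments._settings(RunConfig(preset="exp1_quality"))]
    assert len(labels) == 16
    assert labels[0] == "cnr=0.5" and labels[-1] == "cnr=2"
    orders = [s[2] for s in experiments._settings(RunConfig(preset="exp2_model_order"))]
    assert orders == [6, 8, 10]
    modes = [s[3] for s in experiments._settings(RunConfig(preset="exp3_unique"))]
    assert modes == ["per_component"]
    with pytest.raises(ValueError):
        list(experiments._settings(RunConfig(preset="bogus")))


class TestRunSimulationExperiment:
    @pytest.fixture(scope="class")
    def config(self, tmp_path_factory):
        return RunConfig(
            preset="exp1_quality",
            cnr_values=[2.0],
            seed=3,
            outdir=str(tmp_path_factory.mktemp("sim") / "out"),
            sim_overrides=SMALL,
        )

    @pytest.fixture(scope="class")
    def tables(self, config):
        return experiments.run_simulation_experiment(config)

    def test_table_shapes(self, tables):
        acc = tables["accuracy"]
        assert set(acc.method) == {"iva_gl", "gigica"}
        assert len(acc) == 1 * 2 * 10 * 8  # settings x methods x subjects x sources
        ts = tables["ttests"]
        assert list(ts.domain) == ["spatial", "temporal"]
        assert "bonferroni_significant" in ts.columns

    def test_rerun_is_byte_identical(self, config, tables, tmp_path):
        import filecmp
        from pathlib import Path

        config2 = RunConfig(**{**config.__dict__, "outdir": str(tmp_path / "out2")})
        experiments.run_simulation_experiment(config2)
        for name in ("accuracy.csv", "ttests.csv", "manifest.json"):
            assert filecmp.cmp(
                Path(config.outdir) / name, tmp_path / "out2" / name, shallow=False
            )


class TestCrossMethodMatch:
    @pytest.fixture(scope="class")
    def results(self, small_sim):
        _, datasets, _ = small_sim
        return run_methods(datasets, 4, seed=0)

    def test_identical_results_fully_matched(self, results):
        res = results["gigica"]
        table = cross_method_match(res, res, threshold=0.5)
        assert len(table.pairs) == 4
        assert all(s == pytest.approx(1.0) for _, _, s in table.pairs)

    def test_threshold_drops_weak_pairs(self, results):
        a = results["gigica"]
        rng = np.random.default_rng(0)
        from fndecomp.datatypes import DecompositionResults
        from fndecomp.decomp import zscore_maps

        noise_maps = zscore_maps(rng.standard_normal(a.group_maps.shape))
        b = DecompositionResults(
            method="iva_gl",
            n_components=a.n_components,
            subject_maps=a.subject_maps,
            subject_tcs=a.subject_tcs,
            group_maps=noise_maps,
        )
        table = cross_method_match(a, b, threshold=0.5)
        assert table.pairs == []
        assert len(table.unmatched_estimates) == 4

    def test_permutation_recovery(self, results):
        a = results["gigica"]
        from fndecomp.datatypes import DecompositionResults

        perm = [3, 1, 0, 2]
        b = DecompositionResults(
            method="iva_gl",
            n_components=4,
            subject_maps=[m[perm] for m in a.subject_maps],
            subject_tcs=[t[:, perm] for t in a.subject_tcs],
            group_maps=a.group_maps[perm],
        )
        table = cross_method_match(a, b, threshold=0.5)
        assert sorted((e, perm[t]) for e, t, _ in table.pairs) == [
            (i, i) for i in range(4)
        ]

    def test_order_mismatch_raises(self, results):
        a = results["gigica"]
        from fndecomp.datatypes import DecompositionResults

        b = DecompositionResults(
            method="iva_gl",
            n_components=3,
            subject_maps=[m[:3] for m in a.subject_maps],
            subject_tcs=[t[:, :3] for t in a.subject_tcs],
            group_maps=a.group_maps[:3],
        )
        with pytest.raises(ValueError):
            cross_method_match(a, b)


class TestRealDataStudy:
    @pytest.fixture(scope="class")
    def study(self, tmp_path_factory):
        import nibabel as nib

        root = tmp_path_factory.mktemp("nifti")
        entries = []
        # Scan 1 and scan 2 are independent simulations with the same
        # sources; scan 3 duplicates scan 2 (perfect short-term retest).
        for scan, seed in ((1, 21), (2, 22)):
            config = SimConfig(
                n_subjects=4,
                n_sources=3,
                grid=(20, 20),
                n_timepoints=40,
                cnr=3.0,
                seed=seed,
            )
            datasets, _ = sim.simulate_subjects(config, fwhm=2.5)
            for subj, ds in enumerate(datasets):
                vol = ds.data.T.reshape(20, 20, 1, 40)
                scans_to_write = (scan, 3) if scan == 2 else (scan,)
                for s in scans_to_write:
                    path = root / f"sub{subj}_scan{s}.nii.gz"
                    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
                    entries.append({"path": str(path), "subject": subj, "scan": s})
        config = RunConfig(
            model_orders=[3],
            seed=0,
            datasets=entries,
            outdir=str(root / "out"),
        )
        tables = experiments.run_realdata_study(config, keep_list=[0, 1])
        matched = experiments.run_realdata_study(
            RunConfig(**{**config.__dict__, "outdir": None, "ami_pairing": "subject"}),
            keep_list=[0, 1],
        )
        return tables, matched, config.outdir

    def test_tables_have_one_row_per_network_and_method(self, study):
        rel = study[0]["network_reliability"]
        assert len(rel) == 2 * 2  # methods x kept networks
        assert set(rel.method) == {"iva_gl", "gigica"}

    def test_duplicated_scan_gives_perfect_short_term_reliability(self, study):
        tables, matched, _ = study
        np.testing.assert_allclose(
            tables["network_reliability"].short_icc, 1.0, atol=1e-8
        )
        # All-cross-pairs AMI (the default) averages over different
        # subjects' partitions, so only the subject-matched pairing is
        # exactly 1 in the duplicated-scan limit.
        np.testing.assert_allclose(
            matched["fnc_summary"].ami_short, 1.0, atol=1e-12
        )
        assert (tables["fnc_summary"].ami_short <= 1.0 + 1e-12).all()

    def test_fdr_masks_written_as_nifti(self, study):
        import nibabel as nib
        from pathlib import Path

        mask_dir = Path(study[2]) / "masks"
        files = sorted(mask_dir.glob("*.nii.gz"))
        assert len(files) == 2  # one per kept network
        vol = np.asarray(nib.load(str(files[0])).dataobj)
        assert vol.shape == (20, 20, 1)
        assert set(np.unique(vol)) <= {0, 1}

    def test_graph_metrics_table(self, study):
        gm = study[0]["graph_metrics"]
        assert len(gm) == 2 * 12  # methods x datasets
        assert {"node_strength", "clustering", "global_eff", "local_eff"} <= set(
            gm.columns
        )

    def test_missing_scan_labels_raise(self):
        with pytest.raises(ValueError, match="scan"):
            experiments.run_realdata_study(
                RunConfig(datasets=[{"path": "x.nii"}]), keep_list=[]
            )


def test_mean_ami_counts_all_cross_pairs():
    parts_a = [np.array([1, 1, 2, 2])] * 4
    parts_b = [np.array([1, 1, 2, 2])] * 4
    # 4 x 4 = 16 pairs, all identical partitions.
    assert experiments._mean_ami(parts_a, parts_b) == pytest.approx(1.0)
    assert experiments._mean_ami([], parts_b) is not None  # nan, not crash
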