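"""End-to-end experiment runner, manifests, SBML export and CLI surface."""

import json
import xml.etree.ElementTree as ET

import pytest
from click.testing import CliRunner

from egfrnet.builder import build_egfr_network
from egfrnet.cli import main as cli_main
from egfrnet.experiments import EXPERIMENTS, run_all, run_experiment
from egfrnet.sbml import export_sbml
from egfrnet.synthetic import generate_random_massaction


class TestRunExperiment:
    def test_validation_transient_writes_summary(self, tmp_path):
        manifest = run_experiment("validation_transient", out_dir=tmp_path)
        summary = json.loads((tmp_path / "validation_transient_summary.json")
                             .read_text())
        assert summary["p-ERK.peak_time_min"] <= 5.0
        assert summary["p-p38_peak_after_p-ERK"] is True
        assert (tmp_path / "validation_transient.csv").exists()
        assert manifest.experiments[0]["status"] == "ok"

    def test_repeat_runs_have_identical_checksums(self, tmp_path):
        m1 = run_experiment("validation_transient", out_dir=tmp_path / "a")
        m2 = run_experiment("validation_transient", out_dir=tmp_path / "b")
        c1 = {o["file"]: o["sha256"] for o in m1.experiments[0]["outputs"]}
        c2 = {o["file"]: o["sha256"] for o in m2.experiments[0]["outputs"]}
        assert c1 == c2

    def test_variant_ros_summary_reports_low_p38(self, tmp_path):
        manifest = run_experiment("variant_ros", out_dir=tmp_path)
        summary = json.loads((tmp_path / "variant_ros_summary.json").read_text())
        sus = summary["sustained"]
        assert sus["p-p38.plateau_nM"] <= sus["p-p38.basal_nM"] * 1.05
        assert manifest.experiments[0]["status"] == "ok"

    def test_unknown_experiment_rejected(self):
        with pytest.raises(KeyError):
            run_experiment("no_such_experiment")


class TestRunAll:
    def test_manifest_covers_every_experiment(self, tmp_path):
        manifest = run_all(out_dir=tmp_path)
        names = [e["name"] for e in manifest.experiments]
        assert set(names) >= set(EXPERIMENTS)
        assert len(manifest.experiments) >= 6
        assert (tmp_path / "manifest.json").exists()
        statuses = {e["name"]: e["status"] for e in manifest.experiments}
        assert all(s == "ok" for s in statuses.values())


class TestSBMLExport:
    def test_fixture_exports_with_full_inventory(self, egfr_model):
        doc = export_sbml(egfr_model)
        root = ET.fromstring(doc)
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        species = root.findall(".//s:listOfSpecies/s:species", ns)
        reactions = root.findall(".//s:listOfReactions/s:reaction", ns)
        params = root.findall(".//s:listOfParameters/s:parameter", ns)
        assert len(species) == len(egfr_model.species)
        assert len(reactions) == len(egfr_model.reactions)
        assert len(params) == egfr_model.n_parameters
        assert all(r.find("s:kineticLaw", ns) is not None for r in reactions)

    def test_clamped_species_become_boundary_conditions(self):
        from egfrnet.builder import VariantSpec, apply_variant
        m = apply_variant(build_egfr_network(pad_to_cardinalities=False),
                          VariantSpec("clamp_EGF"))
        root = ET.fromstring(export_sbml(m))
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        egf = [sp for sp in root.findall(".//s:listOfSpecies/s:species", ns)
               if sp.get("name") == "EGF"]
        assert egf[0].get("boundaryCondition") == "true"

    def test_random_models_export(self):
        for seed in (0, 1):
            doc = export_sbml(generate_random_massaction(5, 8, seed))
            assert ET.fromstring(doc) is not None


class TestCLI:
    def test_model_build_and_validate(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["model", "build", "--out",
                                       str(tmp_path / "m")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "m" / "reactions.tsv").exists()
        res = runner.invoke(cli_main, ["model", "validate", "--model",
                                       str(tmp_path / "m")])
        assert res.exit_code == 0, res.output
        assert "160 species" in res.output

    def test_simulate_transient_writes_csv(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--scenario", "transient",
                                       "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "transient.csv").exists()

    def test_export_sbml_cli(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "model.xml"
        res = runner.invoke(cli_main, ["model", "export-sbml", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.read_text().startswith("<?xml")

    def test_synth_writes_dataset_and_truth(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["synth", "--seed", "5", "--out",
                                       str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "synthetic_timecourse.csv").exists()
        truth = json.loads((tmp_path / "synthetic_truth.json").read_text())
        assert truth["seed"] == 5


class TestPackagedData:
    def test_shipped_tables_reproduce_the_builder_model(self, egfr_model):
        """data/reactions.tsv + data/initials.tsv parse to a model
        structurally equal to build_egfr_network()."""
        import importlib.resources as resources
        from egfrnet.network import parse_reaction_table
        root = resources.files("egfrnet") / "data"
        parsed = parse_reaction_table((root / "reactions.tsv").read_text(),
                                      (root / "initials.tsv").read_text())
        assert parsed.structurally_equal(egfr_model)

    def test_scenario_definitions_match_constructors(self):
        from egfrnet.experiments import (REFERENCE_DOSE_NM,
                                         load_scenario_definitions,
                                         sustained_scenario)
        defs = load_scenario_definitions()
        assert defs["transient"]["stimulus"]["dose_nM"] == REFERENCE_DOSE_NM
        sc = sustained_scenario()
        kinds = {v.kind for v in sc.variants}
        assert set(defs["sustained"]["variants"]) == kinds


class TestPlotting:
    def test_readout_and_sensitivity_figures_render(self, transient_traj,
                                                    sensitivity_table,
                                                    tmp_path):
        import matplotlib.pyplot as plt
        from egfrnet.plotting import plot_readouts, plot_sensitivity
        ax = plot_readouts(transient_traj)
        ax.figure.savefig(tmp_path / "readouts.png")
        ax2 = plot_sensitivity(sensitivity_table, "p-p38", top=10)
        ax2.figure.savefig(tmp_path / "sens.png")
        plt.close("all")
        assert (tmp_path / "readouts.png").stat().st_size > 0
        assert (tmp_path / "sens.png").stat().st_size > 0
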