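"""Configuration, end-to-end runs, reproducibility, CLI surface."""

import json

import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from crispamp import RunConfig, run_genotype, run_simulate, run_stats
from crispamp.cli import main as cli_main
from crispamp.datasets import load_f1_alleles, load_f1_phenotypes
from crispamp.reference import fshr_exon2_reference, fshr_synthetic_amplicon


@pytest.fixture()
def alleles_tsv(tmp_path):
    path = tmp_path / "alleles.tsv"
    load_f1_alleles().to_csv(path, sep="\t", index=False)
    return path


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(min_count=3, min_allele_fraction=0.25, seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown config fields"):
            RunConfig.from_dict({"min_countz": 3})

    @pytest.mark.parametrize(
        "kwargs", [{"min_allele_fraction": 0.9}, {"max_primer_mismatch": 9}, {"gap_open": 1}]
    )
    def test_threshold_ranges_enforced(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)


class TestRunGenotype:
    def test_cohort_table_reproduces_published_genotypes(
        self, tmp_path, alleles_tsv, published_labels
    ):
        cfg = RunConfig(out_dir=str(tmp_path / "out"))
        result = run_genotype(cfg, fshr_exon2_reference(), alleles=str(alleles_tsv))
        geno = result["genotypes"].set_index("sample_id")
        assert len(geno) == 36
        for sample_id, row in geno.iterrows():
            assert row.label == published_labels[sample_id], sample_id
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["n_samples"] == 36
        assert manifest["config"]["min_allele_fraction"] == 0.2

    def test_outputs_byte_identical_across_runs(self, tmp_path, alleles_tsv):
        outputs = []
        for name in ("a", "b"):
            cfg = RunConfig(out_dir=str(tmp_path / name))
            run_genotype(cfg, fshr_exon2_reference(), alleles=str(alleles_tsv))
            outputs.append(
                (
                    (tmp_path / name / "alleles.tsv").read_bytes(),
                    (tmp_path / name / "genotypes.tsv").read_bytes(),
                )
            )
        assert outputs[0] == outputs[1]

    def test_vcf_output(self, tmp_path, alleles_tsv):
        cfg = RunConfig(out_dir=str(tmp_path / "out"))
        run_genotype(cfg, fshr_exon2_reference(), alleles=str(alleles_tsv), vcf=True)
        text = (tmp_path / "out" / "alleles.vcf").read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "ALLELE=del3" in text

    def test_empty_input_errors_without_outputs(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("sample_id\tsequence\n")
        cfg = RunConfig(out_dir=str(tmp_path / "out"))
        with pytest.raises(ValueError, match="no sequences"):
            run_genotype(cfg, fshr_exon2_reference(), alleles=str(empty))
        assert not (tmp_path / "out" / "genotypes.tsv").exists()

    def test_requires_some_input(self, tmp_path):
        with pytest.raises(ValueError, match="provide either"):
            run_genotype(RunConfig(out_dir=str(tmp_path)), fshr_exon2_reference())


class TestRunSimulate:
    def test_missing_scenario_field_named(self, tmp_path):
        cfg = RunConfig(out_dir=str(tmp_path), seed=1)
        with pytest.raises(ValueError, match="n_offspring"):
            run_simulate(cfg, {"kind": "f1_cross", "parent1_gametes": {}, "parent2_gametes": {}})

    def test_fastq_byte_identical_for_same_seed(self, tmp_path):
        ref = fshr_synthetic_amplicon()
        scenario = {
            "kind": "f0_cohort",
            "n_fish": 2,
            "dirichlet_concentration": 5.0,
            "n_reads": 40,
        }
        blobs = []
        for name in ("a", "b"):
            cfg = RunConfig(out_dir=str(tmp_path / name), seed=33)
            run_simulate(cfg, scenario, ref)
            import gzip

            blobs.append(
                gzip.open(tmp_path / name / "F0_000_R1.fastq.gz", "rb").read()
            )
        assert blobs[0] == blobs[1]

    def test_truth_table_written(self, tmp_path):
        cfg = RunConfig(out_dir=str(tmp_path), seed=2)
        run_simulate(
            cfg,
            {"kind": "f0_cohort", "n_fish": 3, "dirichlet_concentration": 5.0, "n_reads": 20},
        )
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert truth.sample_id.nunique() == 3


class TestRunStats:
    def test_published_phenotype_tallies(self, tmp_path, phenotypes):
        cfg = RunConfig(out_dir=str(tmp_path))
        result = run_stats(cfg, phenotypes)
        maturity = result["maturity"]
        by_label = maturity.groupby("genotype").n.sum()
        assert by_label["-/-"] == 12
        assert by_label["if/if"] == 17
        assert by_label["if/fs"] + by_label["if/wt"] == 7
        assert by_label["+/+"] == 2

    def test_synthetic_group_comparison(self, tmp_path):
        rng_rows = []
        import numpy as np

        rng = np.random.default_rng(5)
        for i, (label, mu) in enumerate([("+/+", 6.0), ("-/-", 0.05)]):
            for j in range(12):
                rng_rows.append(
                    {
                        "sample_id": f"f{i}_{j}",
                        "genotype": label,
                        "maturity": "Mature" if mu > 1 else "Immature",
                        "sampling_month": 8,
                        "gsi": max(0.01, rng.normal(mu, mu * 0.2)),
                    }
                )
        cfg = RunConfig(out_dir=str(tmp_path))
        result = run_stats(cfg, pd.DataFrame(rng_rows), variables=("gsi",))
        row = result["tests"].iloc[0]
        assert row.significant
        assert row.p_value < 0.001


class TestCli:
    def test_genotype_command(self, tmp_path, alleles_tsv, published_labels):
        runner = CliRunner()
        out = tmp_path / "cli_out"
        res = runner.invoke(
            cli_main,
            ["genotype", "--alleles", str(alleles_tsv), "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        geno = pd.read_csv(out / "genotypes.tsv", sep="\t", dtype={"sample_id": str})
        assert dict(zip(geno.sample_id, geno.label)) == {
            k: v for k, v in published_labels.items() if k in set(geno.sample_id)
        }

    def test_stats_command(self, tmp_path, phenotypes):
        pheno_path = tmp_path / "pheno.tsv"
        phenotypes.to_csv(pheno_path, sep="\t", index=False)
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["stats", "--phenotypes", str(pheno_path), "--out", str(tmp_path / "st")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "st" / "maturity_by_genotype.tsv").exists()

    def test_genotype_without_input_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["genotype", "--out", str(tmp_path)])
        assert res.exit_code != 0
        assert "provide either" in res.output
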