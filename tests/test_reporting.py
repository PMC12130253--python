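"""Quartile profiles, cross-cohort comparison, pipeline orchestration and
text I/O."""

import numpy as np
import pandas as pd
import pytest

from fluxgei import io as fio
from fluxgei.errors import ValidationError
from fluxgei.reporting import (
    compare_cohorts,
    demo_config,
    load_config,
    quartile_variant_effects,
    run_pipeline,
)


class TestQuartileEffects:
    def test_quartile_sizes_balanced(self, small_cohort):
        sim = small_cohort
        prof = quartile_variant_effects(
            sim.cohort, sim.genotypes.column("rs1"), sim.fluxes.column("R1")
        )
        assert prof.n.sum() == len(sim.cohort)
        assert prof.n.max() - prof.n.min() <= 1

    def test_positive_interaction_positive_trend(self, small_cohort):
        """Amplification (beta_interaction > 0): variant effect rises across
        flux quartiles."""
        sim = small_cohort
        prof = quartile_variant_effects(
            sim.cohort, sim.genotypes.column("rs1"), sim.fluxes.column("R1")
        )
        assert prof.slope > 0
        assert prof.beta[3] > prof.beta[0]

    def test_null_interaction_flat_profile(self):
        from fluxgei.experiments import single_pair_config
        from fluxgei.simulate import simulate_cohort

        cfg = single_pair_config(n=12000, beta_snp=0.2, beta_interaction=0.0, seed=31)
        sim = simulate_cohort(cfg)
        prof = quartile_variant_effects(
            sim.cohort, sim.genotypes.column("rs1"), sim.fluxes.column("R1")
        )
        # slope has roughly SE(beta)/sqrt(sum w (x-xbar)^2); just check the
        # profile is statistically flat
        pooled = np.sqrt(np.mean(prof.se**2))
        assert abs(prof.slope) < 3 * pooled
        assert abs(prof.beta.max() - prof.beta.min()) < 6 * pooled

    def test_constant_flux_rejected(self, small_cohort):
        sim = small_cohort
        with pytest.raises(ValidationError):
            quartile_variant_effects(
                sim.cohort,
                sim.genotypes.column("rs1"),
                np.ones(len(sim.cohort)),
            )


def _result_table(betas, p_int=None, p_dos=None, slopes=None):
    n = len(betas)
    return pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(n)],
            "reaction": [f"r{i}" for i in range(n)],
            "beta_interaction": betas,
            "p_interaction": p_int if p_int is not None else np.full(n, 0.01),
            "p_dosage": p_dos if p_dos is not None else np.full(n, 0.01),
            "slope_dosage": slopes if slopes is not None else betas,
        }
    )


class TestCompareCohorts:
    def test_identical_tables(self, rng):
        t = _result_table(rng.uniform(-0.3, 0.3, 10))
        out = compare_cohorts(t, t.copy())
        assert out.r_interaction == pytest.approx(1.0)
        assert out.r_slope == pytest.approx(1.0)
        assert out.sign_consistency == 1.0

    def test_negated_betas(self, rng):
        t = _result_table(rng.uniform(0.05, 0.3, 10))
        t2 = t.copy()
        t2["beta_interaction"] = -t2["beta_interaction"]
        out = compare_cohorts(t, t2)
        assert out.sign_consistency == 0.0

    def test_empty_intersection_rejected(self):
        t1 = _result_table(np.array([0.1]))
        t2 = _result_table(np.array([0.1]))
        t2["snp"] = ["other"]
        with pytest.raises(ValidationError):
            compare_cohorts(t1, t2)

    def test_two_cohort_replication(self):
        """Two cohorts from one truth with strong interactions: estimate
        correlation > 0.7 and sign consistency > 0.9, mirroring external
        replication behaviour."""
        from fluxgei.experiments import replication_study

        comparison, _ = replication_study(n=8000, n_pairs=8, seed=17)
        assert comparison.n_shared == 8
        assert comparison.r_interaction > 0.7
        assert comparison.r_slope > 0.7
        assert comparison.sign_consistency > 0.9


@pytest.fixture(scope="module")
def demo_run():
    return run_pipeline(demo_config(seed=3))


class TestPipeline:
    def test_demo_calls_planted_pair(self, demo_run):
        sig = demo_run.calls[demo_run.calls["call"] == "significant"]
        assert (("rs1" == sig["snp"]) & (sig["reaction"] == "R1")).any()
        assert (sig["direction"] == "amplification").all()

    def test_demo_block_structure(self, demo_run):
        # unlinked SNPs: every selected SNP is its own risk locus
        assert all(len(m) == 1 for m in demo_run.blocks.members.values())

    def test_demo_pruning_guarantee(self, demo_run):
        sim = demo_run.cohort_data
        kept = demo_run.pruned.retained_reactions
        from fluxgei.pruning import flux_correlation

        for organ in ("liver", "heart"):
            names = [r for r in kept if sim.fluxes.organ_of(r) == organ]
            if len(names) >= 2:
                corr = flux_correlation(sim.fluxes, organ).loc[names, names]
                off = corr.to_numpy()[~np.eye(len(names), dtype=bool)]
                assert np.all(np.abs(off) <= 0.5)

    def test_locus_aggregation_counts(self, demo_run):
        sig = demo_run.calls[demo_run.calls["call"] == "significant"]
        expected = {
            (demo_run.blocks.block_of[s], r)
            for s, r in zip(sig["snp"], sig["reaction"])
        }
        assert set(
            zip(demo_run.locus_pairs["block"], demo_run.locus_pairs["reaction"])
        ) == expected

    def test_determinism(self, demo_run, tmp_path):
        res2 = run_pipeline(demo_config(seed=3))
        a = demo_run.calls.to_csv(index=False)
        b = res2.calls.to_csv(index=False)
        assert a == b
        assert demo_run.manifest == res2.manifest

    def test_zero_reactions_clean_empty_run(self):
        cfg = demo_config(seed=0)
        cfg.sim.reaction_specs = []
        cfg.sim.flux_corr = {}
        cfg.sim.eqtl_effects = {}
        cfg.sim.true_effects = {}
        cfg.sim.__post_init__()
        res = run_pipeline(cfg)
        assert res.calls.empty
        assert res.locus_pairs.empty

    def test_persist_and_manifest(self, tmp_path):
        cfg = demo_config(seed=1, outdir=str(tmp_path / "out"))
        cfg.sim.n_individuals = 1200
        res = run_pipeline(cfg)
        out = tmp_path / "out"
        for f in ("cohort.tsv", "calls.tsv", "ld_blocks.tsv", "manifest.json",
                  "pruning_log.tsv", "locus_flux_pairs.tsv"):
            assert (out / f).exists()
        reread = fio.read_table(out / "calls.tsv")
        assert len(reread) == len(res.calls)


class TestIO:
    def test_cohort_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        fio.write_cohort(small_cohort.cohort, path)
        back = fio.read_cohort(path)
        assert np.allclose(back["age"], small_cohort.cohort["age"])
        assert (back["event"] == small_cohort.cohort["event"]).all()

    def test_flux_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "fluxes.tsv"
        fio.write_fluxes(small_cohort.fluxes, path)
        back = fio.read_fluxes(path)
        assert np.allclose(back.values, small_cohort.fluxes.values)
        assert back.organs == small_cohort.fluxes.organs

    def test_corrupted_cohort_named_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"event": [1, 0], "age": [50.0, 60.0]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValidationError, match="sex"):
            fio.read_cohort(path)

    def test_negative_age_rejected(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        pd.DataFrame(
            {"event": [1], "age": [-5.0], "sex": ["F"]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="age"):
            fio.read_cohort(path)

    def test_yaml_config_roundtrip(self, tmp_path):
        cfg_text = """
sim:
  n_individuals: 500
  seed: 4
  n_pcs: 2
  snps:
    - {name: rs1, maf: 0.3}
    - {name: rs2, maf: 0.2}
  reactions:
    - {name: R1, organ: liver}
    - {name: R2, organ: liver, gene_annotated: false}
  true_effects:
    - {snp: rs1, reaction: R1, beta_snp: 0.2, beta_interaction: 0.3}
pipeline:
  snp_p_threshold: 0.5
  alpha: 0.05
"""
        path = tmp_path / "cfg.yaml"
        path.write_text(cfg_text)
        cfg = load_config(path)
        assert cfg.sim.n_individuals == 500
        assert cfg.sim.snp_specs[1].maf == 0.2
        assert not cfg.sim.reaction_specs[1].gene_annotated
        assert cfg.snp_p_threshold == 0.5
        res = run_pipeline(cfg)
        assert "R2" not in set(res.pair_results["reaction"])
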