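import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from corrcascade import cli
from corrcascade.model import CorrelationCascadeModel
from corrcascade.pipeline import PipelineError, load_config, run_pipeline
from corrcascade.synthetic import SyntheticConfig, generate_expression


@pytest.fixture(scope="module")
def fitted():
    expr, groups, truth = generate_expression(SyntheticConfig(seed=11))
    model = CorrelationCascadeModel(expr, groups, seed=11)
    return model.fit(), truth


class TestModel:
    def test_summary_reports_stage_sizes(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "null thresholds" in text
        assert str(len(res.associated_positive)) in text
        assert str(len(res.cascade.final)) in text

    def test_fit_is_deterministic_given_seed(self, fitted):
        res, _ = fitted
        expr, groups, _ = generate_expression(SyntheticConfig(seed=11))
        res2 = CorrelationCascadeModel(expr, groups, seed=11).fit()
        assert res2.thresholds.lower == res.thresholds.lower
        assert res2.cascade.final == res.cascade.final

    def test_cascade_layers_nest(self, fitted):
        res, _ = fitted
        assert res.cascade.final <= res.cascade.union
        for g in res.cascade.union:
            assert any(g in s for s in res.cascade.per_subunit.values())

    def test_screen_method_uses_fitted_thresholds(self, fitted):
        res, truth = fitted
        scr = res.screen("FDPS", truth.modules["growth_receptor"])
        assert set(scr.table["gene"]) == set(truth.modules["growth_receptor"])

    def test_enrich_method_flags_planted_module(self, fitted):
        from corrcascade.synthetic import generate_annotation
        res, truth = fitted
        coll = generate_annotation(truth, seed=11)
        out = res.enrich(coll).set_index("term")
        assert bool(out.loc["MODULE:NFY_TARGETS", "significant"])

    def test_hub_analysis_recovers_planted_hubs(self, fitted):
        from corrcascade.synthetic import generate_ppi
        res, truth = fitted
        graph, planted = generate_ppi(truth, background_density=0.0, seed=11)
        report = res.hub_analysis(graph)
        # final set closely tracks the planted targets, so planted hubs
        # keep >=3 edges into it
        assert set(planted["hubs"]) <= report.primary_hubs

    def test_unlabeled_samples_rejected(self):
        expr, groups, _ = generate_expression(
            SyntheticConfig(n_tumor=5, n_normal=5, n_genes=200, seed=0))
        with pytest.raises(ValueError, match="without a group"):
            CorrelationCascadeModel(expr, groups.iloc[:-1])

    def test_missing_anchors_rejected(self):
        expr, groups, _ = generate_expression(
            SyntheticConfig(n_tumor=5, n_normal=5, n_genes=200, seed=0))
        with pytest.raises(ValueError, match="anchor"):
            CorrelationCascadeModel(expr, groups, anchors=["NOPE"])


MICRO = {
    "seed": 5,
    "n_pairs": 20000,
    "synthetic": {"n_genes": 200},
}


class TestPipeline:
    def test_bundle_written_and_cascade_nested(self, tmp_path):
        cfg = load_config(None, {**MICRO, "output_dir": str(tmp_path / "run")})
        manifest = run_pipeline(cfg)
        out = tmp_path / "run"
        for name in ("normalized.txt", "null_thresholds.json",
                     "anchor_screen.tsv", "anchor_counts.tsv",
                     "associated_sets.tsv", "cascade.json", "manifest.json",
                     "gene_sets.gmt", "ppi_edges.tsv", "truth.json"):
            assert (out / name).exists(), name
        payload = json.loads((out / "cascade.json").read_text())
        assert set(payload["final_set"]) <= set(
            g for g in payload["final_set"])
        assert payload["union_size"] >= len(payload["final_set"])
        assert manifest["outputs"]["cascade"] == "cascade.json"

    def test_same_seed_runs_are_byte_identical(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            cfg = load_config(None, {**MICRO,
                                     "output_dir": str(tmp_path / name)})
            run_pipeline(cfg)
            outs.append(tmp_path / name)
        for fname in ("normalized.txt", "null_thresholds.json",
                      "anchor_screen.tsv", "associated_sets.tsv",
                      "cascade.json"):
            assert (outs[0] / fname).read_bytes() == \
                (outs[1] / fname).read_bytes(), fname
        m0 = json.loads((outs[0] / "manifest.json").read_text())
        m1 = json.loads((outs[1] / "manifest.json").read_text())
        m0["config"].pop("output_dir"), m1["config"].pop("output_dir")
        assert m0 == m1

    def test_micro_fixture_matches_brute_force_recompute(self, tmp_path):
        """Every count the pipeline reports on a 200-gene fixture is
        recomputed here from the written normalized matrix with plain numpy."""
        cfg = load_config(None, {**MICRO, "output_dir": str(tmp_path / "run")})
        run_pipeline(cfg)
        out = tmp_path / "run"
        from corrcascade.expr_io import read_series_matrix, read_sample_sheet
        norm, _ = read_series_matrix(out / "normalized.txt")
        sheet = read_sample_sheet(out / "samples.tsv")
        thr = json.loads((out / "null_thresholds.json").read_text())
        tumor = norm.loc[:, [s for s in norm.columns
                             if sheet[s] == "tumor"]].to_numpy()
        genes = list(norm.index)
        R = np.corrcoef(tumor)
        anchors = ["FDFT1", "FDPS", "HMGCS1", "IDI1", "LSS", "EBP", "MVK"]
        ai = [genes.index(a) for a in anchors]

        def count_sig(i, idx, sign):
            c = 0
            for j in idx:
                if j == i:
                    continue
                r = R[i, j]
                c += (r >= thr["upper"]) if sign > 0 else (r <= thr["lower"])
            return c

        pos = {g for k, g in enumerate(genes) if count_sig(k, ai, +1) >= 3}
        neg = {g for k, g in enumerate(genes) if count_sig(k, ai, -1) >= 3}
        assoc = pd.read_csv(out / "associated_sets.tsv", sep="\t")
        assert set(assoc.loc[assoc["positive"], "gene"]) == pos
        assert set(assoc.loc[assoc["negative"], "gene"]) == neg

        payload = json.loads((out / "cascade.json").read_text())
        pos_idx = [genes.index(g) for g in sorted(pos)]
        counts = np.array([count_sig(k, pos_idx, +1) for k in range(len(genes))])
        expected_thr = min(int(np.ceil(np.percentile(counts, 97.5))),
                           int(counts.max()))
        assert payload["count_threshold"] == expected_thr
        subunits = ["NFYA", "NFYB", "NFYC"]
        union = set()
        for s in subunits:
            si = genes.index(s)
            hits = {g for k, g in enumerate(genes)
                    if k != si and R[k, si] >= thr["upper"]}
            hits -= {s}
            assert len(hits) == payload["per_subunit_sizes"][s]
            union |= hits
        assert len(union) == payload["union_size"]
        final = {g for g in union
                 if counts[genes.index(g)] >= expected_thr}
        assert set(payload["final_set"]) == final

    def test_unknown_config_key_rejected(self, tmp_path):
        bad = tmp_path / "cfg.yaml"
        bad.write_text("no_such_key: 1\n")
        with pytest.raises(ValueError, match="unknown"):
            load_config(bad)

    def test_stage_failure_names_stage(self, tmp_path):
        cfg = load_config(None, {"expression": str(tmp_path / "missing.txt"),
                                 "output_dir": str(tmp_path / "run")})
        with pytest.raises(PipelineError, match="inputs"):
            run_pipeline(cfg)


class TestCli:
    def test_simulate_then_run_all(self, tmp_path):
        runner = CliRunner()
        fix = tmp_path / "fix"
        r = runner.invoke(cli.main, ["simulate", "--seed", "3", "--n-genes",
                                     "200", "--outdir", str(fix)])
        assert r.exit_code == 0, r.output
        assert (fix / "expression.txt").exists()

        cfgfile = tmp_path / "cfg.yaml"
        cfgfile.write_text("synthetic:\n  n_genes: 200\nn_pairs: 20000\n")
        r = runner.invoke(cli.main, ["run-all", "--config", str(cfgfile),
                                     "--outdir", str(tmp_path / "run"),
                                     "--seed", "3"])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "run" / "cascade.json").exists()

    def test_null_subcommand_writes_thresholds(self, tmp_path):
        runner = CliRunner()
        fix = tmp_path / "fix"
        runner.invoke(cli.main, ["simulate", "--seed", "1", "--n-genes", "150",
                                 "--outdir", str(fix)])
        out = tmp_path / "thr.json"
        r = runner.invoke(cli.main, [
            "null", str(fix / "expression.txt"),
            "--sample-sheet", str(fix / "samples.tsv"),
            "--n-pairs", "5000", "--seed", "2", "--out", str(out)])
        assert r.exit_code == 0, r.output
        d = json.loads(out.read_text())
        assert d["lower"] < 0 < d["upper"]

    def test_bad_config_exits_2(self, tmp_path):
        runner = CliRunner()
        cfgfile = tmp_path / "cfg.yaml"
        cfgfile.write_text("bogus: 1\n")
        r = runner.invoke(cli.main, ["run-all", "--config", str(cfgfile)])
        assert r.exit_code == 2

    def test_stage_subcommands_chain_together(self, tmp_path):
        """simulate -> null -> screen/count -> cascade -> enrich -> net."""
        runner = CliRunner()
        fix = tmp_path / "fix"
        r = runner.invoke(cli.main, ["simulate", "--seed", "4", "--n-genes",
                                     "300", "--outdir", str(fix)])
        assert r.exit_code == 0, r.output
        thr = tmp_path / "thr.json"
        r = runner.invoke(cli.main, [
            "null", str(fix / "expression.txt"),
            "--sample-sheet", str(fix / "samples.tsv"),
            "--n-pairs", "10000", "--seed", "4", "--out", str(thr)])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli.main, [
            "screen", str(fix / "expression.txt"),
            "--sample-sheet", str(fix / "samples.tsv"),
            "--thresholds", str(thr), "--anchor", "EGFR",
            "--direction", "negative",
            "--out", str(tmp_path / "screen.tsv")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "screen.tsv").exists()

        r = runner.invoke(cli.main, [
            "count", str(fix / "expression.txt"),
            "--sample-sheet", str(fix / "samples.tsv"),
            "--thresholds", str(thr),
            "--anchors", "FDFT1,FDPS,HMGCS1,IDI1,LSS,EBP,MVK",
            "--out", str(tmp_path / "counts.tsv")])
        assert r.exit_code == 0, r.output
        counts = pd.read_csv(tmp_path / "counts.tsv", sep="\t", index_col=0)
        assoc = counts.index[counts["selected"]].tolist()
        assert assoc

        assoc_file = tmp_path / "assoc.txt"
        assoc_file.write_text("\n".join(assoc) + "\n")
        r = runner.invoke(cli.main, [
            "cascade", str(fix / "expression.txt"),
            "--sample-sheet", str(fix / "samples.tsv"),
            "--thresholds", str(thr), "--assoc", str(assoc_file),
            "--out", str(tmp_path / "cascade.json")])
        assert r.exit_code == 0, r.output
        payload = json.loads((tmp_path / "cascade.json").read_text())
        assert payload["union_size"] >= len(payload["final_set"])

        query = tmp_path / "query.txt"
        query.write_text("\n".join(payload["final_set"]) or "EGFR")
        universe = tmp_path / "universe.txt"
        universe.write_text("\n".join(counts.index))
        r = runner.invoke(cli.main, [
            "enrich", "--query", str(query), "--universe", str(universe),
            "--gmt", str(fix / "gene_sets.gmt"),
            "--out", str(tmp_path / "enrich.tsv")])
        assert r.exit_code == 0, r.output

        sa = tmp_path / "sa.txt"
        sa.write_text("NFYA\nNFYB\nNFYC\n")
        r = runner.invoke(cli.main, [
            "net", "--edges", str(fix / "ppi_edges.tsv"),
            "--seeds-a", str(sa), "--seeds-b", str(query),
            "--out-prefix", str(tmp_path / "net")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "net_nodes.tsv").exists()
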