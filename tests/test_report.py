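"""Chi-square testing, contingency assembly, length summaries, pipeline."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lwikit.composition import region_frequencies
from lwikit.io import AMINO_ACIDS, LabeledAlignment, LwiError, SeqMeta
from lwikit.report import (
    ConfigError,
    ContingencyTable,
    DegenerateTableError,
    build_group_contingency,
    chi_square_independence,
    run_pipeline,
    summarize_lengths,
)
from lwikit.simulate import make_fixture, write_bundle


def chi_square_oracle(counts):
    """Hand-rolled O/E loop for the Pearson statistic."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        result = chi_square_independence([[10, 10], [10, 10]])
        assert result.statistic == pytest.approx(0.0)
        assert result.dof == 1

    def test_perfect_association_closed_form(self):
        # all four expected counts are 10: statistic = 4 * 100/10 = 40
        result = chi_square_independence([[20, 0], [0, 20]])
        assert result.statistic == pytest.approx(40.0)
        assert result.dof == 1

    @given(st.integers(0, 2**31 - 1))
    def test_random_tables_match_oe_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 60, size=(3, 4))
        result = chi_square_independence(table)
        assert result.statistic == pytest.approx(chi_square_oracle(table), abs=1e-9)
        assert result.dof == 6

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_independence([[0, 0], [5, 5]])
        with pytest.raises(DegenerateTableError):
            chi_square_independence([[5], [5]])

    def test_invariant_under_permutation_and_scaling(self):
        rng = np.random.default_rng(3)
        table = rng.integers(1, 50, size=(4, 3))
        base = chi_square_independence(table).statistic
        permuted = table[rng.permutation(4)][:, rng.permutation(3)]
        assert chi_square_independence(permuted).statistic == pytest.approx(base)
        assert chi_square_independence(5 * table).statistic == pytest.approx(5 * base)


class TestBuildGroupContingency:
    def _profile(self, rows, name, stratum="all"):
        meta = {f"s{i}": SeqMeta(f"x{i}", "mammal") for i in range(len(rows))}
        aln = LabeledAlignment(
            records=[(f"s{i}", r) for i, r in enumerate(rows)], metadata=meta
        )
        return region_frequencies(
            aln, range(1, len(rows[0]) + 1), region_name=name, stratum=stratum
        )

    def test_letters_by_regions_assembly(self):
        p1 = self._profile(["FFFFF"], "r1")
        p2 = self._profile(["FFFFFLLLLL"], "r2")
        table = build_group_contingency([p1, p2])
        assert table.column_labels == ("r1", "r2")
        assert table.row_labels == ("F", "L")
        assert table.counts.tolist() == [[5, 5], [0, 5]]

    def test_single_profile_rejected(self):
        with pytest.raises(DegenerateTableError):
            build_group_contingency([self._profile(["FFFF"], "r1")])

    def test_mixed_strata_rejected_in_region_mode(self):
        p1 = self._profile(["FFFF"], "r1")
        p2 = self._profile(["LLLL"], "r2")
        p2.stratum = "mammal"
        with pytest.raises(LwiError):
            build_group_contingency([p1, p2])

    def test_null_calibration_p_values_approximately_uniform(self):
        """Strata drawn from one stationary composition: p-values ~ U(0,1).

        The rate is set near saturation so every residue is an independent
        draw from the shared stationary distribution; at lower rates the
        star-tree ancestor induces within-site clustering shared across
        strata, the counts are underdispersed relative to multinomial and
        the raw chi-square p-values are conservative by construction.
        """
        import scipy.stats

        from lwikit.simulate import GeneratorConfig, PhylumSpec, generate_family

        uniform = {a: 0.05 for a in AMINO_ACIDS}
        classes = ("TM", "LWI_inner", "LWI_outer", "loop", "tail")
        p_values = []
        for seed in range(200):
            cfg = GeneratorConfig(
                seed=seed,
                phyla=tuple(
                    PhylumSpec(p, 15, n_tail_length=0, c_tail_length=0, tail_jitter=0)
                    for p in ("mammal", "reptile", "fish")
                ),
                region_rates={c: 0.999 for c in classes},
                region_compositions={c: dict(uniform) for c in classes},
                tm_count=2,
                tm_length=10,
                loop_lengths=(12,),
            )
            aln, _, truth = generate_family(cfg)
            cols = [c for cols in truth["class_columns"].values() for c in cols]
            profiles = [
                region_frequencies(aln, cols, stratum=s, region_name="core")
                for s in ("mammal", "reptile", "fish")
            ]
            table = build_group_contingency(profiles, mode="letters_x_strata")
            p_values.append(chi_square_independence(table).p_value)
        ks = scipy.stats.kstest(p_values, "uniform")
        assert ks.pvalue > 1e-3


class TestSummarizeLengths:
    def test_gapless_equal_lengths_have_zero_spread(self, toy_alignment, toy_topology):
        summary = summarize_lengths(toy_alignment, toy_topology)
        mammal = summary.per_stratum.set_index("stratum").loc["mammal"]
        assert mammal["min_length"] == mammal["max_length"] == 40
        # N-tail proxy: non-gap characters before TM1's first column (11)
        assert (summary.per_sequence["n_tail_length"] >= 9).all()

    def test_planted_tail_lengths_separate_strata(self, catsper_family):
        aln, topo, _ = catsper_family
        summary = summarize_lengths(aln, topo)
        table = summary.per_stratum.set_index("stratum")
        assert table.loc["mammal", "median_n_tail"] > table.loc["fish", "median_n_tail"]
        assert table.loc["mammal", "median_length"] > table.loc["fish", "median_length"]
        # planted values: mammal N-tail 350 +- 12 jitter, fish 120 +- 10
        assert 338 <= table.loc["mammal", "median_n_tail"] <= 362
        assert 110 <= table.loc["fish", "median_n_tail"] <= 130


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    aln, topo, truth = make_fixture("catsper_like")
    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(aln, topo, truth, out)


class TestPipeline:
    def _config(self, bundle, out_dir, **overrides):
        cfg = {
            "alignment": bundle["alignment"],
            "metadata": bundle["metadata"],
            "topology": bundle["topology"],
            "seed": 11,
            "bootstrap_reps": 50,
            "out_dir": str(out_dir),
        }
        cfg.update(overrides)
        return cfg

    def test_smoke_produces_full_output_tree(self, bundle, tmp_path):
        out = run_pipeline(self._config(bundle, tmp_path / "out"))
        expected = {
            "segments.tsv", "composition.tsv", "group_ratios.tsv",
            "distance_summary.tsv", "dropped_sequences.tsv", "logo_heights.tsv",
            "chi_square.tsv", "lengths_per_sequence.tsv", "lengths_summary.tsv",
            "manifest.json",
        }
        produced = {p.name for p in out.iterdir()}
        assert expected <= produced
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["parameters"]["seed"] == 11
        assert manifest["alignment"]["n_sequences"] == 50
        assert set(manifest["outputs"]) >= expected - {"manifest.json"}

    def test_missing_topology_file_is_config_error(self, bundle, tmp_path):
        cfg = self._config(bundle, tmp_path / "out", topology="does_not_exist.yaml")
        with pytest.raises(ConfigError, match="topology"):
            run_pipeline(cfg)

    def test_missing_required_key_named(self, bundle, tmp_path):
        cfg = self._config(bundle, tmp_path / "out")
        del cfg["seed"]
        with pytest.raises(ConfigError, match="seed"):
            run_pipeline(cfg)

    def test_same_seed_twice_is_byte_identical(self, bundle, tmp_path):
        out1 = run_pipeline(self._config(bundle, tmp_path / "o1"))
        out2 = run_pipeline(self._config(bundle, tmp_path / "o2"))
        for path in sorted(out1.iterdir()):
            assert path.read_bytes() == (out2 / path.name).read_bytes()
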