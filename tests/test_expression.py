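import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lectinfam.expression import (
    ContrastError,
    ContrastSpec,
    DECall,
    ExpressionMatrix,
    call_differential,
    call_tissue_specific,
    cluster_divergence,
    divergence_summary,
    summarize_stress_sets,
)

CONTRAST = ContrastSpec("salt", "control", "salt", "abiotic")


def matrix_from_replicates(gene_rows, conditions=("control", "salt")):
    """gene_rows: {gene: {condition: [replicates]}}."""
    columns, meta = {}, []
    n_rep = {c: len(next(iter(gene_rows.values()))[c]) for c in conditions}
    for cond in conditions:
        for r in range(n_rep[cond]):
            name = f"{cond}_r{r + 1}"
            columns[name] = [gene_rows[g][cond][r] for g in gene_rows]
            meta.append({"sample": name, "condition": cond, "replicate": r + 1,
                         "tissue": "", "category": "abiotic" if cond != "control" else ""})
    values = pd.DataFrame(columns, index=list(gene_rows))
    return ExpressionMatrix(values, pd.DataFrame(meta))


def two_sample_t_pvalue(a, b):
    """Closed-form classical equal-variance two-sample t-test (two-sided)."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * t_dist.sf(abs(t), na + nb - 2)


class TestCallDifferential:
    def test_identical_conditions_not_significant(self):
        m = matrix_from_replicates({"g": {"control": [10, 10, 10], "salt": [10, 10, 10]}})
        (call,) = call_differential(m, CONTRAST)
        assert call.fold_change == pytest.approx(1.0)
        assert call.status == "ns"

    def test_two_fold_with_significant_t_is_up(self):
        ctrl, stress = [10, 10, 10], [25, 20, 27]
        m = matrix_from_replicates({"g": {"control": ctrl, "salt": stress}})
        (call,) = call_differential(m, CONTRAST)
        expected_fold = (sum(stress) / 3 + 1) / (sum(ctrl) / 3 + 1)
        assert call.fold_change == pytest.approx(expected_fold)
        assert call.p_value == pytest.approx(two_sample_t_pvalue(stress, ctrl))
        assert call.p_value < 0.05
        assert call.status == "up"

    def test_high_fold_high_variance_stays_ns(self):
        # mean fold ~3 but replicate spread keeps the t-test insignificant
        ctrl, stress = [10, 10, 10], [2, 5, 85]
        m = matrix_from_replicates({"g": {"control": ctrl, "salt": stress}})
        (call,) = call_differential(m, CONTRAST)
        assert call.fold_change > 2
        assert call.p_value == pytest.approx(two_sample_t_pvalue(stress, ctrl))
        assert call.p_value > 0.05
        assert call.status == "ns"

    def test_swapping_conditions_mirrors_status_and_inverts_fold(self):
        rows = {"g": {"control": [10, 11, 9], "salt": [40, 38, 45]}}
        m = matrix_from_replicates(rows)
        (fwd,) = call_differential(m, CONTRAST, pseudocount=0.0)
        rev_contrast = ContrastSpec("salt", "salt", "control", "abiotic")
        (rev,) = call_differential(m, rev_contrast, pseudocount=0.0)
        assert fwd.status == "up" and rev.status == "down"
        assert rev.fold_change == pytest.approx(1 / fwd.fold_change)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_degenerate_parameters_call_every_unequal_gene(self):
        m = matrix_from_replicates(
            {
                "g1": {"control": [10, 10, 10], "salt": [11, 11, 11]},
                "g2": {"control": [10, 10, 10], "salt": [10, 10, 10]},
            }
        )
        calls = {c.gene_id: c.status for c in
                 call_differential(m, CONTRAST, min_fold=1.0, alpha=1.0)}
        assert calls["g1"] == "up"  # unequal means always called
        calls2 = {c.gene_id: c.status for c in
                  call_differential(m, CONTRAST, min_fold=1.0 + 1e-9, alpha=1.0)}
        assert calls2["g1"] == "up" and calls2["g2"] == "ns"

    def test_fold_two_bound_is_inclusive(self):
        # fold = (21+1)/(10+1) = 2.0 exactly with the default pseudocount
        m = matrix_from_replicates(
            {"g": {"control": [10, 10, 10], "salt": [21, 21, 21]}}
        )
        (call,) = call_differential(m, CONTRAST)
        assert call.fold_change == 2.0
        assert call.status == "up"

    def test_single_replicate_is_fold_only_untested(self):
        m = matrix_from_replicates({"g": {"control": [10], "salt": [40]}})
        (call,) = call_differential(m, CONTRAST)
        assert not call.tested
        assert call.status == "up"

    def test_missing_condition_raises(self):
        m = matrix_from_replicates({"g": {"control": [10, 10], "salt": [20, 20]}})
        with pytest.raises(ContrastError):
            call_differential(m, ContrastSpec("cold", "control", "cold", "abiotic"))


class TestTagCounts:
    def test_tags_per_million_normalisation(self):
        values = pd.DataFrame(
            {"s1": [100, 900], "s2": [10, 90]}, index=["g1", "g2"]
        )
        meta = pd.DataFrame(
            [{"sample": s, "condition": "c", "replicate": i + 1,
              "tissue": "", "category": ""} for i, s in enumerate(["s1", "s2"])]
        )
        m = ExpressionMatrix(values, meta, platform="tag_count")
        # library depth differences vanish on the TPM scale
        assert m.values.loc["g1", "s1"] == pytest.approx(m.values.loc["g1", "s2"])
        assert m.values["s1"].sum() == pytest.approx(1e6)


class TestStressSets:
    def _calls(self, genes, contrast):
        return [DECall(g, contrast, 2.0, 0.01, "up") for g in genes]

    def test_rice_inclusion_exclusion(self):
        # |Mg| = 58, |Xoo| = 62, overlap 29 -> biotic union 91 (34% of 267);
        # |abiotic| = 68 (25%), biotic&abiotic = 50 -> any 109 (41%)
        mg = {f"g{i}" for i in range(58)}
        xoo = {f"g{i}" for i in range(29, 91)}
        abiotic = {f"g{i}" for i in range(50)} | {f"g{i}" for i in range(91, 109)}
        contrasts = [
            ContrastSpec("Mg", "control", "Mg", "biotic"),
            ContrastSpec("Xoo", "control", "Xoo", "biotic"),
            ContrastSpec("salt", "control", "salt", "abiotic"),
        ]
        summary = summarize_stress_sets(
            {"Mg": self._calls(mg, "Mg"), "Xoo": self._calls(xoo, "Xoo"),
             "salt": self._calls(abiotic, "salt")},
            contrasts,
            total_genes=267,
        )
        assert len(mg & xoo) == 29
        assert len(summary.biotic) == 91
        assert len(summary.abiotic) == 68
        assert len(summary.biotic_abiotic_overlap) == 50
        assert len(summary.any_stress) == 109
        assert summary.percent(summary.biotic) == 34
        assert summary.percent(summary.abiotic) == 25
        assert summary.percent(summary.any_stress) == 41

    def test_disjoint_sets_union_is_sum(self):
        a = {f"a{i}" for i in range(5)}
        b = {f"b{i}" for i in range(7)}
        contrasts = [ContrastSpec("x", "control", "x", "biotic"),
                     ContrastSpec("y", "control", "y", "abiotic")]
        summary = summarize_stress_sets(
            {"x": self._calls(a, "x"), "y": self._calls(b, "y")}, contrasts, 100
        )
        assert len(summary.any_stress) == 12

    def test_inclusion_exclusion_identity_holds(self, rng):
        genes = [f"g{i}" for i in range(50)]
        a = {g for g in genes if rng.random() < 0.4}
        b = {g for g in genes if rng.random() < 0.4}
        contrasts = [ContrastSpec("x", "control", "x", "biotic"),
                     ContrastSpec("y", "control", "y", "abiotic")]
        s = summarize_stress_sets(
            {"x": self._calls(a, "x"), "y": self._calls(b, "y")}, contrasts, 50
        )
        assert len(s.any_stress) == len(s.biotic) + len(s.abiotic) - len(
            s.biotic_abiotic_overlap
        )


class TestTissueSpecificity:
    def _matrix(self, profile):
        tissues = [f"t{i}" for i in range(len(profile))]
        columns, meta = {}, []
        for t, v in zip(tissues, profile):
            columns[f"{t}_r1"] = [v]
            meta.append({"sample": f"{t}_r1", "condition": t, "replicate": 1,
                         "tissue": t, "category": ""})
        return ExpressionMatrix(pd.DataFrame(columns, index=["g"]), pd.DataFrame(meta))

    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((100, 0, 0, 0, 0, 0), True),
            ((10, 10, 10, 10, 10, 10), False),
            ((50, 40, 6, 0, 0, 0), False),  # expressed in 3 tissues
        ],
    )
    def test_rule(self, profile, expected):
        flags = call_tissue_specific(self._matrix(profile))
        assert flags["g"] is expected

    def test_needs_three_tissues(self):
        with pytest.raises(ValueError):
            call_tissue_specific(self._matrix((1, 2)))


class TestDivergence:
    def _calls(self, status_by_gene, contrast):
        return [DECall(g, contrast, 2.0, 0.01, s) for g, s in status_by_gene.items()]

    def test_disagreement_under_one_contrast_is_divergent(self):
        calls = {"salt": self._calls({"a": "up", "b": "ns"}, "salt")}
        assert cluster_divergence(["a", "b"], calls) is True

    def test_all_ns_everywhere_not_divergent(self):
        calls = {
            "salt": self._calls({"a": "ns", "b": "ns"}, "salt"),
            "cold": self._calls({"a": "ns", "b": "ns"}, "cold"),
        }
        assert cluster_divergence(["a", "b"], calls) is False

    def test_members_without_data_excluded(self):
        calls = {"salt": self._calls({"a": "up"}, "salt")}
        assert cluster_divergence(["a", "b"], calls) is None

    def test_exhaustive_three_members_two_contrasts(self):
        """Brute-force status matrices agree with the two-member-disagree rule."""
        statuses = ("up", "down", "ns")
        for combo in itertools.product(statuses, repeat=6):
            s1, s2 = combo[:3], combo[3:]
            calls = {
                "c1": self._calls(dict(zip("abc", s1)), "c1"),
                "c2": self._calls(dict(zip("abc", s2)), "c2"),
            }
            expected = len(set(s1)) > 1 or len(set(s2)) > 1
            assert cluster_divergence(list("abc"), calls) is expected

    def test_summary_fractions(self):
        # 29 divergent of 42 clusters -> 69%
        units, calls = {}, {"salt": []}
        for i in range(42):
            a, b = f"u{i}a", f"u{i}b"
            units[f"cl{i}"] = [a, b]
            calls["salt"].append(DECall(a, "salt", 2.0, 0.01,
                                        "up" if i < 29 else "ns"))
            calls["salt"].append(DECall(b, "salt", 1.0, 0.9, "ns"))
        table = divergence_summary(units, calls)
        row = table[table["family"] == "all"].iloc[0]
        assert (row["units"], row["divergent"], row["percent_divergent"]) == (42, 29, 69)

    def test_zero_of_n_is_zero_percent(self):
        units = {"cl0": ["a", "b"]}
        calls = {"salt": [DECall("a", "salt", 1.0, 0.9, "ns"),
                          DECall("b", "salt", 1.0, 0.9, "ns")]}
        table = divergence_summary(units, calls)
        assert int(table.iloc[0]["percent_divergent"]) == 0


class TestSimulatedRecovery:
    def test_noise_free_plants_fully_recovered(self, rng):
        from lectinfam.simulate import SimulationConfig, simulate_expression

        # fold 2.5 sits safely above the inclusive fold-2 bound, which is
        # itself covered by the exact-integer boundary test below
        config = SimulationConfig(seed=0, fold_set=(2.5,), noise_cv=1e-6,
                                  de_fraction=0.4)
        genes = [f"g{i}" for i in range(200)]
        values, samples, truth = simulate_expression(genes, config, rng)
        m = ExpressionMatrix(values, samples)
        for cname, cat in config.contrasts:
            calls = call_differential(
                m, ContrastSpec(cname, "control", cname, cat), pseudocount=0.0
            )
            status = {c.gene_id: c.status for c in calls}
            for g in genes:
                if truth.de_labels[g][cname] != "ns":
                    assert status[g] == truth.de_labels[g][cname]

    def test_type_one_error_controlled_without_effects(self):
        from lectinfam.simulate import SimulationConfig, simulate_expression

        config = SimulationConfig(seed=0, de_fraction=0.0, noise_cv=0.2)
        fp = trials = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(300)]
            values, samples, _ = simulate_expression(genes, config, r)
            m = ExpressionMatrix(values, samples)
            calls = call_differential(
                m, ContrastSpec("salt", "control", "salt", "abiotic")
            )
            fp += sum(c.status != "ns" for c in calls)
            trials += len(calls)
        assert fp / trials <= 0.05 + 0.02

    def test_planted_tissue_specific_genes_recovered(self, rng):
        from lectinfam.simulate import SimulationConfig, simulate_expression

        config = SimulationConfig(seed=0, tissue_specific_fraction=0.3)
        genes = [f"g{i}" for i in range(300)]
        values, samples, truth = simulate_expression(genes, config, rng)
        m = ExpressionMatrix(values, samples)
        flags = call_tissue_specific(m)
        planted = [g for g in genes if truth.tissue_specific[g]]
        recovered = sum(flags[g] for g in planted)
        assert recovered / len(planted) >= 0.95
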