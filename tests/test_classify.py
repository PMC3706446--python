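"""Enrichment presets, filter semantics, and the pathway report."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_random_profile
from pigmentseq import tables
from pigmentseq.classify import FilterSpec, apply_filter, pathway_report, preset
from pigmentseq.diffstats import quote_fold


class TestPresets:
    def test_specific_preset_thresholds(self):
        spec = preset("mel_specific")
        assert spec.mode == "specific"
        assert spec.fold_vs_others == 2.0
        assert spec.p_max == 0.05
        assert spec.fold_vs_embryo == 8.0

    def test_shared_identity_thresholds(self):
        spec = preset("shared_identity")
        assert spec.within_fold == 2.0
        assert spec.min_rpkm == 4.0
        assert spec.fold_vs_embryo == 100.0
        assert spec.p_max is None

    def test_irid_stringent_thresholds(self):
        spec = preset("irid_stringent")
        assert spec.targets == ("iridophore",)
        assert spec.fold_vs_others == 30.0
        assert spec.fold_vs_embryo == 100.0
        assert spec.p_max is None

    def test_unknown_preset_lists_names(self):
        with pytest.raises(KeyError, match="shared_identity"):
            preset("nonexistent")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "specific", "targets": ("melanocyte", "rpe")},
            {"mode": "pairwise_shared", "targets": ("melanocyte",)},
            {"mode": "shared_all", "targets": ("melanocyte", "rpe", "iridophore")},
            {"mode": "specific", "targets": ("melanocyte",), "p_max": 0.0},
            {"mode": "specific", "targets": ("melanocyte",), "fold_vs_others": 0.5},
            {"mode": "banana", "targets": ("melanocyte",)},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterSpec(**kwargs)


class TestPublishedTables:
    """Every row of each published gene list passes its own caption's preset."""

    @pytest.mark.parametrize(
        "loader,preset_name",
        [
            (tables.shared_identity_genes, "shared_identity"),
            (tables.mel_rpe_genes, "mel_rpe_stringent"),
            (tables.mel_irid_genes, "mel_irid_stringent"),
            (tables.irid_enriched_genes, "irid_stringent"),
        ],
    )
    def test_all_rows_pass_caption_preset(self, loader, preset_name):
        profile = loader()
        calls = apply_filter(profile, preset(preset_name))
        failing = calls.loc[~calls["verdict"], "gene"].tolist()
        assert failing == []

    def test_moderate_embryo_fold_fails_shared_identity(self):
        profile = pd.DataFrame(
            {
                "gene": ["even"],
                "melanocyte": [50.0],
                "rpe": [50.0],
                "iridophore": [50.0],
                "embryo": [1.0],
            }
        )
        calls = apply_filter(profile, preset("shared_identity"))
        assert not calls["verdict"].iloc[0]
        assert not calls["embryo"].iloc[0]  # 50-fold < 100-fold

    def test_zero_embryo_passes_on_infinite_fold(self):
        profile = tables.shared_identity_genes()
        calls = apply_filter(profile, preset("shared_identity")).set_index("gene")
        assert math.isinf(calls.loc["rnd2", "fold_melanocyte_vs_embryo"])
        assert calls.loc["rnd2", "verdict"]


def _oracle_verdict(g, spec):
    """Independent per-gene evaluation of the filter conjunction."""

    def fold(num, den):
        if den > 0:
            return num / den
        return math.inf if num > 0 else math.nan

    def ge(x, k):
        return (not math.isnan(x)) and x >= k

    cells = {"melanocyte": g.melanocyte, "rpe": g.rpe, "iridophore": g.iridophore}
    others = [c for c in cells if c not in spec.targets]
    pcol = {
        frozenset(("melanocyte", "rpe")): "p_mel_rpe",
        frozenset(("melanocyte", "iridophore")): "p_mel_irid",
        frozenset(("rpe", "iridophore")): "p_rpe_irid",
    }
    checks = []
    if spec.mode == "shared_all":
        lo, hi = min(cells.values()), max(cells.values())
        ratio = fold(hi, lo)
        checks.append((not math.isnan(ratio)) and ratio <= spec.within_fold)
        checks.append(lo >= spec.min_rpkm)
        embryo = [ge(fold(v, g.embryo), spec.fold_vs_embryo) for v in cells.values()]
    else:
        if spec.min_rpkm > 0:
            checks.append(all(cells[t] >= spec.min_rpkm for t in spec.targets))
        for t in spec.targets:
            for o in others:
                checks.append(ge(fold(cells[t], cells[o]), spec.fold_vs_others))
                if spec.p_max is not None:
                    checks.append(getattr(g, pcol[frozenset((t, o))]) < spec.p_max)
        embryo = [ge(fold(cells[t], g.embryo), spec.fold_vs_embryo) for t in spec.targets]
    checks.append(all(embryo) if spec.embryo_rule == "min" else any(embryo))
    return all(checks)


ALL_PRESETS = [
    "shared_identity", "mel_rpe_shared", "mel_irid_shared", "rpe_irid_shared",
    "mel_specific", "irid_specific", "rpe_specific",
    "mel_rpe_stringent", "mel_irid_stringent", "irid_stringent",
]


class TestFilterSemantics:
    @pytest.mark.parametrize("preset_name", ALL_PRESETS)
    def test_matches_bruteforce_oracle(self, preset_name):
        profile = make_random_profile(500, seed=ALL_PRESETS.index(preset_name))
        spec = preset(preset_name)
        calls = apply_filter(profile, spec)
        expected = [_oracle_verdict(g, spec) for g in profile.itertuples()]
        assert calls["verdict"].tolist() == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        """Raising any fold/min-RPKM threshold or lowering p_max never adds
        genes to a pass set."""
        profile = make_random_profile(800, seed=seed)
        base = preset("mel_irid_shared")
        base_set = set(
            apply_filter(profile, base).query("verdict")["gene"]
        )
        tighter = [
            preset("mel_irid_shared", fold_vs_others=4.0),
            preset("mel_irid_shared", fold_vs_embryo=20.0),
            preset("mel_irid_shared", min_rpkm=5.0),
            preset("mel_irid_shared", p_max=0.01),
        ]
        for spec in tighter:
            assert set(apply_filter(profile, spec).query("verdict")["gene"]) <= base_set

    def test_embryo_rule_any_is_weaker_than_min(self):
        profile = make_random_profile(800, seed=77)
        strict = apply_filter(profile, preset("mel_rpe_shared", embryo_rule="min"))
        loose = apply_filter(profile, preset("mel_rpe_shared", embryo_rule="any"))
        assert set(strict.query("verdict")["gene"]) <= set(loose.query("verdict")["gene"])

    def test_missing_pvalue_column_rejected(self):
        profile = make_random_profile(10, seed=1, with_pvalues=False)
        with pytest.raises(ValueError, match="p-value column"):
            apply_filter(profile, preset("mel_irid_shared"))

    def test_missing_celltype_column_rejected(self):
        profile = make_random_profile(10, seed=1).drop(columns=["iridophore"])
        with pytest.raises(ValueError, match="iridophore"):
            apply_filter(profile, preset("shared_identity"))


class TestPathwayReport:
    def test_guanine_branch_enrichment_flags(self):
        profile = tables.guanine_pathway_profile()
        rep = pathway_report(profile, tables.guanine_pathway_groups())
        t = rep.table.set_index("gene")
        assert t.loc["impdh1b", "fold_vs_melanocyte"] == pytest.approx(71.28, abs=0.01)
        assert quote_fold(t.loc["impdh1b", "fold_vs_melanocyte"]) == 71.0
        assert t.loc["impdh1b", "sig_vs_melanocyte"]
        assert t.loc["adssl", "fold_vs_melanocyte"] == pytest.approx(0.70, abs=0.01)
        assert not t.loc["adssl", "sig_vs_melanocyte"]
        assert not t.loc["ak1", "sig_vs_rpe"]  # p = 0.175
        assert rep.missing == []

    def test_missing_genes_listed_not_dropped(self):
        profile = tables.guanine_pathway_profile()
        rep = pathway_report(profile, {"made_up": ["impdh1b", "not_a_gene"]})
        assert rep.missing == ["not_a_gene"]
        assert rep.table["gene"].tolist() == ["impdh1b"]

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            pathway_report(tables.guanine_pathway_profile(), {})

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            pathway_report(tables.guanine_pathway_profile(), {"x": ["nope"]})
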