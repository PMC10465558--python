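"""Rule-engine behaviour: condition evaluation, bypasses, set logic."""

import pytest

from conftest import make_psm
from fpf.features import FeatureVector, featurize
from fpf.filtering import (
    Condition,
    FilterConfig,
    apply_filter,
    filter_exclusive,
)
from fpf.model import SpectrumKey


def fv(**overrides):
    """A feature vector comfortably inside every default condition."""
    base = dict(
        charge=2,
        precursor_mass_da=1500.0,
        peptide_length=12,
        n_ptm=0,
        ptm_ratio=0.0,
        abs_mass_diff_da=0.01,
        avg_reporter_intensity=50000.0,
        f_value=2.0,
        iprotdist=0.1,
        ipepdist=0.1,
        sl_precursor_mz_diff_abs=0.005,
        sl_dot=0.9,
        sl_delta=0.3,
        sl_n_hits=4.0,
        sl_hit_mean=0.8,
        sl_hit_std=0.05,
    )
    base.update(overrides)
    return FeatureVector(**base)


KEY = SpectrumKey("run", 1, 2)


class TestApplyFilter:
    def test_all_features_inside_bounds_retained(self):
        (d,) = apply_filter({KEY: fv()})
        assert not d.removed
        assert d.triggered == ()
        assert d.bypassed == ()

    def test_case_study_outlier_removed_with_three_conditions(self):
        # weak reporter signal plus outlying intra-peptide and intra-protein
        # ratio distances: exactly those three conditions fire
        (d,) = apply_filter(
            {KEY: fv(avg_reporter_intensity=5912.0, ipepdist=1.4691, iprotdist=1.3082)}
        )
        assert d.removed
        assert set(d.triggered) == {"avg_reporter_intensity", "ipepdist", "iprotdist"}

    def test_missing_reporter_bypasses_intensity_and_distances(self):
        (d,) = apply_filter(
            {KEY: fv(charge=5, avg_reporter_intensity=None, iprotdist=None, ipepdist=None)}
        )
        assert d.removed
        assert d.triggered == ("charge",)
        assert {"avg_reporter_intensity", "iprotdist", "ipepdist"} <= set(d.bypassed)

    def test_db_only_psm_bypasses_library_conditions(self):
        (d,) = apply_filter(
            {
                KEY: fv(
                    sl_dot=None,
                    sl_delta=None,
                    sl_precursor_mz_diff_abs=None,
                    sl_n_hits=None,
                    sl_hit_mean=None,
                    sl_hit_std=None,
                )
            }
        )
        assert not d.removed
        assert "sl_dot" in d.bypassed

    @pytest.mark.parametrize(
        "overrides,removed",
        [
            ({"charge": 5}, True),  # >= comparator removes the boundary
            ({"charge": 4}, False),
            ({"precursor_mass_da": 4000.0}, True),
            ({"peptide_length": 25}, True),
            ({"peptide_length": 24}, False),
            ({"avg_reporter_intensity": 10000.0}, False),  # < comparator keeps boundary
            ({"avg_reporter_intensity": 9999.9}, True),
            ({"ipepdist": 0.8}, True),
            ({"iprotdist": 0.6}, True),
            ({"abs_mass_diff_da": 2.0}, True),
            ({"sl_dot": 0.4}, False),
            ({"sl_dot": 0.39}, True),
            ({"f_value": 0.4}, False),
            ({"f_value": 0.39}, True),
        ],
    )
    def test_boundary_conventions_follow_printed_inequalities(self, overrides, removed):
        (d,) = apply_filter({KEY: fv(**overrides)})
        assert d.removed is removed

    def test_unknown_feature_raises_before_evaluation(self):
        with pytest.raises(ValueError, match="unknown feature"):
            FilterConfig(conditions=(Condition("not_a_feature", "ge", 1.0),))

    def test_idempotence_on_retained_set(self, efficacy_run):
        retained = {
            k: v
            for k, v in efficacy_run["features"].items()
            if k not in efficacy_run["removed"]
        }
        again = apply_filter(retained)
        assert not any(d.removed for d in again)

    def test_relaxing_thresholds_never_removes_more(self, efficacy_run):
        relaxed = FilterConfig(
            conditions=tuple(
                Condition(
                    c.feature,
                    c.comparator,
                    c.threshold * 1.5 if c.comparator == "ge" else c.threshold / 1.5,
                )
                for c in FilterConfig().conditions
            )
        )
        removed_relaxed = {
            d.key for d in apply_filter(efficacy_run["features"], relaxed) if d.removed
        }
        assert removed_relaxed <= efficacy_run["removed"]

    def test_partition_every_key_decided_once(self, efficacy_run):
        decisions = efficacy_run["decisions"]
        assert {d.key for d in decisions} == set(efficacy_run["features"])
        assert len(decisions) == len(efficacy_run["features"])
        for d in decisions:
            assert d.removed == bool(d.triggered)

    def test_no_conditions_removes_nothing(self, efficacy_run):
        decisions = apply_filter(efficacy_run["features"], FilterConfig(conditions=()))
        assert not any(d.removed for d in decisions)


class TestFilterConfigToml:
    def test_bare_and_table_forms(self, tmp_path):
        cfg = tmp_path / "fpf.toml"
        cfg.write_text(
            "[conditions]\n"
            "charge = 5\n"
            "avg_reporter_intensity = 12000\n"
            'ptm_ratio = { op = "ge", threshold = 0.5 }\n'
        )
        config = FilterConfig.from_toml(cfg)
        by_name = {c.feature: c for c in config.conditions}
        assert by_name["charge"].comparator == "ge"
        assert by_name["avg_reporter_intensity"].comparator == "lt"
        assert by_name["avg_reporter_intensity"].threshold == 12000
        assert by_name["ptm_ratio"].threshold == 0.5
        assert len(config.conditions) == 3  # omitted features disabled

    def test_bare_value_for_unthresholded_feature_rejected(self, tmp_path):
        cfg = tmp_path / "fpf.toml"
        cfg.write_text("[conditions]\nptm_ratio = 0.5\n")
        with pytest.raises(ValueError, match="default comparator"):
            FilterConfig.from_toml(cfg)


class TestFilterExclusive:
    def _psms(self, design3):
        # scans 1-2 common; 3-7 exclusive, of which 3 (charge 5) and
        # 4 (length 25) trigger conditions
        high = (50000.0, 50000.0, 50000.0)
        return [
            make_psm(1, high, charge=5),
            make_psm(2, high),
            make_psm(3, high, charge=5),
            make_psm(4, high, peptide="A" * 25),
            make_psm(5, high),
            make_psm(6, high),
            make_psm(7, high),
        ]

    def test_nothing_exclusive_nothing_removed(self, design3):
        psms = self._psms(design3)
        result = filter_exclusive({p.key for p in psms}, psms, design3)
        assert result.removed == ()
        assert len(result.retained) == len(psms)

    def test_exclusive_partition(self, design3):
        psms = self._psms(design3)
        db_keys = {psms[0].key, psms[1].key}
        result = filter_exclusive(db_keys, psms, design3)
        assert len(result.removed) == 2
        assert {p.key.scan for p in result.removed} == {3, 4}
        assert len(result.retained) + len(result.removed) == len(psms)
        assert result.common_keys == frozenset(db_keys)

    def test_common_psm_triggering_condition_still_retained(self, design3):
        psms = self._psms(design3)
        db_keys = {p.key for p in psms}
        result = filter_exclusive(db_keys, psms, design3)
        # scan 1 has charge 5 but is common, so never filtered
        assert psms[0].key in {p.key for p in result.retained}
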